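"""Generator invariants: counts, planted structure, determinism."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from fusionscreen import io_formats as io
from fusionscreen.synthetic_data import (
    SimConfig,
    generate_cohort,
    generate_drug_kb,
    generate_pathway_db,
)


def test_config_invariants_enforced():
    with pytest.raises(ValueError):
        SimConfig(n_cases=10, n_tumor_samples=10)
    with pytest.raises(ValueError):
        SimConfig(module_rhos=(1.0,), module_sizes=(5,))
    with pytest.raises(ValueError):
        SimConfig(n_genes=10, module_sizes=(20,), module_rhos=(0.5,))


def test_metadata_counts_match_configured_cohort():
    # 379 tumor + 53 normal + 1 metastasis = 433 downloaded samples
    cfg = SimConfig(n_genes=50, n_tumor_samples=379, n_normal_samples=53,
                    n_metastasis_samples=1, module_sizes=(5,),
                    module_rhos=(0.5,), seed=0)
    c = generate_cohort(cfg)
    types = c.metadata.column("sample_type")
    assert len(c.metadata.sample_ids) == 433
    assert (types == "tumor").sum() == 379
    assert (types == "normal").sum() == 53
    assert (types == "metastasis").sum() == 1
    assert len(c.case_ids) == 7
    assert len(c.module_genes()) == 5


def test_truth_covers_planted_genes_and_modules_disjoint(small_cohort):
    t = small_cohort.truth
    planted = t[t.module >= 0]
    assert len(planted) == sum(small_cohort.config.module_sizes)
    assert small_cohort.config.reference_gene not in set(planted.gene)
    assert planted.gene.is_unique


def test_reference_case_elevation_near_delta(small_cohort):
    """Mean log difference between cases and tumor controls ~ delta (3 SE)."""
    c = small_cohort
    expr = c.expression
    ref = np.log(expr.gene(c.config.reference_gene))
    case_set = set(c.case_ids)
    tumor = [s for s, t in c.metadata.column("sample_type").items() if t == "tumor"]
    is_case = np.array([s in case_set for s in tumor])
    vals = ref[[expr.sample_ids.index(s) for s in tumor]]
    diff = vals[is_case].mean() - vals[~is_case].mean()
    sigma = c.config.lognormal_sigma
    se = sigma * np.sqrt(1 / is_case.sum() + 1 / (~is_case).sum())
    assert abs(diff - c.config.case_shift) < 3 * se


def test_zero_rho_module_correlations_match_fisher_z_tail():
    """With rho=0 the realized log-scale |r| tail follows the Fisher-z bound.

    At n=379 tumor samples, P(|r| < 0.1) = Phi(atanh(0.1)*sqrt(376)) -
    Phi(-atanh(0.1)*sqrt(376)) = 0.948; the observed fraction must sit within
    3 binomial SE of it.
    """
    cfg = SimConfig(n_genes=400, n_tumor_samples=379, n_normal_samples=0,
                    n_metastasis_samples=0, module_sizes=(200,),
                    module_rhos=(0.0,), zero_fraction=0.0, seed=5)
    c = generate_cohort(cfg)
    tumor = [s for s, t in c.metadata.column("sample_type").items() if t == "tumor"]
    logx = np.log(c.expression.subset(samples=tumor).values)
    ref = logx[0]
    module_rows = np.flatnonzero(c.truth.module.to_numpy() == 0)
    rs = np.array([stats.pearsonr(logx[i], ref)[0] for i in module_rows])
    z = np.arctanh(0.1) * np.sqrt(379 - 3)
    expected = stats.norm.cdf(z) - stats.norm.cdf(-z)
    se = np.sqrt(expected * (1 - expected) / len(rs))
    assert abs((np.abs(rs) < 0.1).mean() - expected) < 3 * se


def test_planted_rho_realized_on_log_scale():
    """Latent rho=0.6 modules realize log-scale correlation near the plant."""
    cfg = SimConfig(n_genes=300, n_tumor_samples=379, n_normal_samples=0,
                    n_metastasis_samples=0, module_sizes=(100,),
                    module_rhos=(0.6,), zero_fraction=0.0, seed=6)
    c = generate_cohort(cfg)
    logx = np.log(c.expression.values)
    ref = logx[0]
    module_rows = np.flatnonzero(c.truth.module.to_numpy() == 0)
    rs = np.array([stats.pearsonr(logx[i], ref)[0] for i in module_rows])
    # the case shift is shared between reference and module genes, so the
    # realized log-scale correlation is >= the latent rho on average
    assert 0.55 < np.median(rs) < 0.85


def test_zero_rows_present_and_flagged(small_cohort):
    t = small_cohort.truth
    zeros = t[t.zero_row]
    assert len(zeros) == int(
        small_cohort.config.zero_fraction * small_cohort.config.n_genes
    )
    values = small_cohort.expression.values
    for gene in zeros.gene:
        row = values[small_cohort.expression.gene_ids.index(gene)]
        assert (row == 0).all()


def test_same_seed_gives_byte_identical_files(tmp_path):
    cfg = SimConfig(n_genes=60, n_tumor_samples=40, n_normal_samples=4,
                    n_metastasis_samples=0, n_cases=3, module_sizes=(6,),
                    module_rhos=(0.4,), seed=17)
    for run in ("a", "b"):
        c = generate_cohort(cfg)
        io.write_expression(c.expression, tmp_path / f"{run}_expr.tsv")
        io.write_metadata(c.metadata, tmp_path / f"{run}_meta.tsv")
        io.write_fusions(c.fusion_calls, tmp_path / f"{run}_fus.tsv")
    for kind in ("expr", "meta", "fus"):
        assert (tmp_path / f"a_{kind}.tsv").read_bytes() == \
               (tmp_path / f"b_{kind}.tsv").read_bytes()


def test_pathway_db_no_enrichment_matches_background_rate():
    genes = [f"g{i}" for i in range(500)]
    planted = genes[:50]
    pw = generate_pathway_db(30, genes, planted, enrichment_factor=1.0,
                             seed=3, base_rate=0.1)
    inc_planted = np.mean([g in p.genes for p in pw.db for g in planted])
    inc_background = np.mean([g in p.genes for p in pw.db for g in genes[50:]])
    n_p = 30 * 50
    se = np.sqrt(inc_background * (1 - inc_background) / n_p)
    assert abs(inc_planted - inc_background) < 2 * se + 1e-9


def test_pathway_db_meta_group_count_and_empty_planted():
    genes = [f"g{i}" for i in range(200)]
    pw = generate_pathway_db(40, genes, planted=[], seed=1, n_meta=10)
    assert len(pw.meta_map) == 10
    assert pw.enriched_ids == frozenset()
    assert set().union(*pw.meta_map.values()) == set(pw.db.pathway_ids)


def test_pathway_db_requires_universe_and_membership():
    with pytest.raises(ValueError):
        generate_pathway_db(5, [], [], seed=0)
    with pytest.raises(ValueError):
        generate_pathway_db(5, ["a"], ["b"], seed=0)


def test_drug_kb_curated_alk_rows_and_determinism(tmp_path):
    genes = ["ALK", "TP53", "G1", "G2"]
    civic, oncokb, census = generate_drug_kb(genes, seed=2)
    alk = [e for e in civic if e.gene == "ALK"]
    assert {"crizotinib", "alectinib", "ceritinib"} <= {e.drug for e in alk}
    assert all(e.tier == "A" and e.interaction == "inhibits" for e in alk)
    assert census.role_of("ALK") == "oncogene"
    assert any(e.interaction == "activates" and e.gene_role == "tumor_suppressor"
               for e in civic)
    # determinism at file level
    for run in ("a", "b"):
        c2, o2, g2 = generate_drug_kb(genes, seed=2)
        io.write_drug_kb(c2, tmp_path / f"{run}.tsv", "civic")
    assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()


def test_drug_kb_tiers_round_trip_through_readers(tmp_path):
    genes = [f"g{i}" for i in range(50)]
    civic, oncokb, _ = generate_drug_kb(genes, seed=8, random_fraction=0.5)
    io.write_drug_kb(oncokb, tmp_path / "okb.tsv", "oncokb")
    rows = io.read_drug_kb(tmp_path / "okb.tsv", "oncokb")
    assert rows == oncokb
    assert {r.tier for r in rows} <= {"1", "2", "3", "4"}
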