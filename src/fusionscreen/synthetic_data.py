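"""Synthetic TCGA-like cohorts, pathway databases and drug knowledgebases.

The generator emulates the data shape the screening pipeline assumes: a bulk
RNA expression matrix of ~20,531 genes over ~379 tumor samples (plus normal
and metastasis samples that the cohort stage discards), a handful of
fusion-positive cases with an elevated reference gene (RSPO3 in colorectal
cancer carrying the PTPRK-RSPO3 fusion), a large below-median control pool,
heavy-tailed log-normal expression marginals, and planted gene modules with a
chosen latent correlation to the reference gene.

Correlation is planted on the latent Gaussian (log) scale::

    L_ref = z + (delta / sigma) * case_indicator
    L_g   = rho * L_ref + sqrt(1 - rho**2) * eps      (module gene g)
    expr  = exp(mu_g + sigma * L)

so module genes are co-elevated in fusion cases by ``rho * delta`` — the
downstream genes respond to the realized reference level, as they would if the
fusion drives the reference transcript which in turn drives its targets.  The
truth table records the latent rho; the Pearson R the screen realizes on the
raw (exponentiated) scale is attenuated relative to it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    CancerGeneList,
    DrugEvidence,
    ExpressionMatrix,
    FusionCallSet,
    Pathway,
    PathwayDB,
    SampleTable,
    MUTATION_FLAGS,
)

__all__ = [
    "SimConfig",
    "SyntheticCohort",
    "SyntheticPathwaySet",
    "generate_cohort",
    "generate_pathway_db",
    "generate_drug_kb",
]

# Real cancer-gene symbols sprinkled onto the first planted module so the
# enrichment and drug stages exercise census/knowledgebase matching end to end.
DEFAULT_CANCER_SYMBOLS = (
    "ALK", "FGFR2", "KRAS", "TP53", "MYC", "JUN", "APC", "AXIN2",
    "JAK2", "PTEN", "MDM2", "RAC1", "GNAQ", "ACVR2A", "FAS", "ACSL3",
)

# Control-group clinical composition (fractions of non-missing values) and
# per-variable missingness rates, matching a fusion-negative colorectal
# tumor cohort of 186 controls.
_CLINICAL = {
    "sex": ({"male": 68 / 121, "female": 53 / 121}, 65 / 186),
    "vital_status": ({"alive": 101 / 121, "dead": 20 / 121}, 65 / 186),
    "stage": ({"I": 20 / 116, "II": 48 / 116, "III": 33 / 116, "IV": 15 / 116},
              70 / 186),
    "msi_status": ({"MSI-high": 18 / 121, "MSI-low": 19 / 121, "MSS": 84 / 121},
                   65 / 186),
    "histology": ({"adenocarcinoma": 113 / 120, "mucinous_adenocarcinoma": 7 / 120},
                  66 / 186),
}
_MUTATION_RATES = {
    "tp53_mut": 113 / 186,
    "kras_mut": 80 / 186,
    "pik3ca_mut": 50 / 186,
    "pten_mut": 15 / 186,
    "braf_mut": 23 / 186,
}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic cohort.

    Defaults reproduce the study conditions the pipeline targets: 20,531
    genes, 433 downloaded samples (379 tumor + 53 normal + 1 metastasis),
    7 fusion-positive cases, and one 50-gene module correlated with the
    reference gene at latent rho 0.6.  ``case_shift`` is the natural-log
    elevation of the reference gene in fusion cases (4.0 ~ 55-fold, the
    order of magnitude promoter-swap fusions produce; large enough that all
    planted cases reliably pass the above-median elevation cross-check).
    ``lognormal_mu``/``lognormal_sigma`` are the marginal log-scale location
    and spread (median expression ~ e^6 ~ 400 normalized counts with a heavy
    right tail); ``gene_level_sd`` spreads per-gene baselines around mu.
    """

    n_genes: int = 20531
    n_tumor_samples: int = 379
    n_normal_samples: int = 53
    n_metastasis_samples: int = 1
    n_cases: int = 7
    reference_gene: str = "RSPO3"
    case_shift: float = 4.0
    module_sizes: tuple[int, ...] = (50,)
    module_rhos: tuple[float, ...] = (0.6,)
    lognormal_mu: float = 6.0
    lognormal_sigma: float = 1.25
    gene_level_sd: float = 1.5
    zero_fraction: float = 0.02
    cancer_gene_symbols: tuple[str, ...] = DEFAULT_CANCER_SYMBOLS
    seed: int = 0

    def __post_init__(self):
        counts = {
            "n_genes": self.n_genes,
            "n_tumor_samples": self.n_tumor_samples,
            "n_normal_samples": self.n_normal_samples,
            "n_metastasis_samples": self.n_metastasis_samples,
            "n_cases": self.n_cases,
        }
        for name, value in counts.items():
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")
        if self.n_cases >= self.n_tumor_samples:
            raise ValueError(
                f"n_cases ({self.n_cases}) must be < n_tumor_samples "
                f"({self.n_tumor_samples})"
            )
        if len(self.module_sizes) != len(self.module_rhos):
            raise ValueError("module_sizes and module_rhos must align")
        for rho in self.module_rhos:
            if not abs(rho) < 1:
                raise ValueError(f"module rho must satisfy |rho| < 1, got {rho}")
        for size in self.module_sizes:
            if size < 0:
                raise ValueError(f"module size must be >= 0, got {size}")
        # +1 for the reference gene itself
        if sum(self.module_sizes) + 1 > self.n_genes:
            raise ValueError("module sizes exceed n_genes")
        if not 0 <= self.zero_fraction < 1:
            raise ValueError("zero_fraction must be in [0, 1)")
        if self.lognormal_sigma <= 0:
            raise ValueError("lognormal_sigma must be > 0")

    @property
    def n_samples(self) -> int:
        return (self.n_tumor_samples + self.n_normal_samples
                + self.n_metastasis_samples)


@dataclass(frozen=True)
class SyntheticCohort:
    """Generated cohort plus ground truth about planted structure."""

    expression: ExpressionMatrix
    metadata: SampleTable
    fusion_calls: FusionCallSet
    truth: pd.DataFrame  # gene, module (int, -1 = none), target_rho, zero_row
    config: SimConfig

    @property
    def case_ids(self) -> list[str]:
        return list(self.fusion_calls.data.sample_id)

    def module_genes(self, module: int | None = None) -> list[str]:
        t = self.truth
        mask = t.module >= 0 if module is None else t.module == module
        return list(t.gene[mask])


def _gene_names(config: SimConfig) -> tuple[list[str], np.ndarray]:
    """Gene symbols plus per-gene module assignment (-1 for background)."""
    n = config.n_genes
    names = [f"G{i:05d}" for i in range(n)]
    module = np.full(n, -1, dtype=int)
    names[0] = config.reference_gene
    cursor = 1
    symbol_iter = iter(config.cancer_gene_symbols)
    for m, size in enumerate(config.module_sizes):
        for j in range(size):
            sym = next(symbol_iter, None)
            names[cursor] = sym if sym is not None else f"M{m}G{j:03d}"
            module[cursor] = m
            cursor += 1
    if len(set(names)) != n:
        raise ValueError("gene names collide; reduce cancer_gene_symbols")
    return names, module


def generate_cohort(config: SimConfig) -> SyntheticCohort:
    """Generate a reproducible synthetic cohort under ``config``.

    The reference gene occupies the first row; module genes follow, carrying
    curated cancer-gene symbols where available.  A ``zero_fraction`` of
    background genes is zeroed entirely to exercise degenerate-variance
    handling downstream.
    """
    rng = np.random.default_rng(config.seed)
    names, module = _gene_names(config)
    n_s = config.n_samples

    sample_ids = [f"S{i:04d}" for i in range(n_s)]
    sample_type = (
        ["tumor"] * config.n_tumor_samples
        + ["normal"] * config.n_normal_samples
        + ["metastasis"] * config.n_metastasis_samples
    )
    tumor_ids = sample_ids[: config.n_tumor_samples]
    case_ids = sorted(rng.choice(tumor_ids, size=config.n_cases, replace=False))
    case_indicator = np.array([sid in set(case_ids) for sid in sample_ids], float)

    sigma = config.lognormal_sigma
    z_ref = rng.standard_normal(n_s)
    latent_ref = z_ref + (config.case_shift / sigma) * case_indicator

    latent = rng.standard_normal((config.n_genes, n_s))
    for m, rho in enumerate(config.module_rhos):
        rows = module == m
        latent[rows] = rho * latent_ref + np.sqrt(1 - rho**2) * latent[rows]
    latent[0] = latent_ref

    mu = config.lognormal_mu + config.gene_level_sd * rng.standard_normal(config.n_genes)
    expr = np.exp(mu[:, None] + sigma * latent)

    background = np.flatnonzero(module < 0)
    background = background[background != 0]
    n_zero = int(config.zero_fraction * config.n_genes)
    zero_rows = rng.choice(background, size=min(n_zero, len(background)),
                           replace=False)
    expr[zero_rows] = 0.0

    expression = ExpressionMatrix(
        pd.DataFrame(expr, index=pd.Index(names, name="gene_id"),
                     columns=sample_ids)
    )
    metadata = _generate_metadata(rng, sample_ids, sample_type)
    fusions = FusionCallSet(
        pd.DataFrame(
            {"sample_id": case_ids,
             "gene_5prime": "PTPRK",
             "gene_3prime": config.reference_gene}
        )
    )
    zero_mask = np.zeros(config.n_genes, bool)
    zero_mask[zero_rows] = True
    truth = pd.DataFrame(
        {
            "gene": names,
            "module": module,
            "target_rho": [
                config.module_rhos[m] if m >= 0 else 0.0 for m in module
            ],
            "zero_row": zero_mask,
        }
    )
    return SyntheticCohort(expression, metadata, fusions, truth, config)


def _generate_metadata(rng: np.random.Generator, sample_ids: list[str],
                       sample_type: list[str]) -> SampleTable:
    n = len(sample_ids)
    cols: dict[str, list[str]] = {"sample_type": sample_type}
    age = rng.integers(31, 91, size=n)
    cols["age"] = [str(a) for a in age]
    for var, (dist, missing_rate) in _CLINICAL.items():
        levels = list(dist)
        probs = np.array([dist[l] for l in levels])
        probs = probs / probs.sum()
        draws = rng.choice(levels, size=n, p=probs)
        miss = rng.random(n) < missing_rate
        cols[var] = ["NA" if m else d for d, m in zip(draws, miss)]
    for flag in MUTATION_FLAGS:
        rate = _MUTATION_RATES[flag]
        draws = rng.random(n) < rate
        cols[flag] = ["mut" if d else "wt" for d in draws]
    df = pd.DataFrame(cols, index=pd.Index(sample_ids, name="sample_id"))
    return SampleTable(df)


# ---------------------------------------------------------------------------
# pathway database fixture
# ---------------------------------------------------------------------------

DEFAULT_META_NAMES = (
    "Apoptosis", "Direct p53", "EGFR", "ErbB", "JAK-STAT",
    "Tyrosine kinases", "Pathways in Cancer", "SCF-KIT", "VEGFR", "WNT",
)


@dataclass(frozen=True)
class SyntheticPathwaySet:
    """Pathway DB fixture plus the truth of which pathways were enriched."""

    db: PathwayDB
    meta_map: dict[str, frozenset[str]]
    enriched_ids: frozenset[str]


def generate_pathway_db(
    n_pathways: int,
    genes: Sequence[str],
    planted: Sequence[str],
    enrichment_factor: float = 5.0,
    seed: int = 0,
    n_meta: int = 10,
    base_rate: float = 0.05,
    n_enriched: int | None = None,
) -> SyntheticPathwaySet:
    """Generate a pathway database with planted genes over-represented.

    Background genes enter each pathway independently at ``base_rate``;
    in the designated enriched pathways, planted genes enter at
    ``enrichment_factor * base_rate`` (capped at 1).  Source pathways are
    grouped round-robin into ``n_meta`` named meta-pathways, the fixture
    analog of curated cancer meta-pathway collapsing.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("empty gene universe")
    planted_set = set(planted)
    if not planted_set <= set(genes):
        missing = sorted(planted_set - set(genes))
        raise ValueError(f"planted genes not in universe: {missing[:5]}")
    if enrichment_factor <= 0:
        raise ValueError("enrichment_factor must be > 0")
    rng = np.random.default_rng(seed)
    if n_enriched is None:
        n_enriched = max(1, n_pathways // 5)
    enriched = set(range(min(n_enriched, n_pathways))) if planted_set else set()
    planted_rate = min(1.0, enrichment_factor * base_rate)

    gene_arr = np.array(genes)
    is_planted = np.array([g in planted_set for g in genes])
    pathways: list[Pathway] = []
    for j in range(n_pathways):
        rate = np.where(is_planted & (j in enriched), planted_rate, base_rate)
        member = rng.random(len(genes)) < rate
        chosen = gene_arr[member]
        if len(chosen) == 0:  # keep gene sets non-empty
            chosen = gene_arr[rng.integers(len(gene_arr), size=1)]
        pathways.append(Pathway(f"PW{j:04d}", "synthetic", frozenset(chosen)))
    db = PathwayDB(tuple(pathways))

    names = list(DEFAULT_META_NAMES)
    while len(names) < n_meta:
        names.append(f"Meta{len(names):02d}")
    meta_map: dict[str, set[str]] = {name: set() for name in names[:n_meta]}
    for j, p in enumerate(db):
        meta_map[names[j % n_meta]].add(p.pathway_id)
    return SyntheticPathwaySet(
        db,
        {k: frozenset(v) for k, v in meta_map.items()},
        frozenset(f"PW{j:04d}" for j in enriched),
    )


# ---------------------------------------------------------------------------
# drug knowledgebase fixture
# ---------------------------------------------------------------------------

# Curated actionable relations used when the corresponding symbol is present:
# (drugs, interaction, civic tier, oncokb level, role)
_CURATED_KB = {
    "ALK": (("crizotinib", "alectinib", "ceritinib", "lorlatinib", "brigatinib"),
            "inhibits", "A", "1", "oncogene"),
    "FGFR2": (("erdafitinib", "infigratinib", "pemigatinib"),
              "inhibits", "B", "1", "oncogene"),
    "KRAS": (("sotorasib",), "inhibits", "B", "1", "oncogene"),
    "JAK2": (("ruxolitinib",), "inhibits", "B", "2", "oncogene"),
    "TP53": (("eprenetapopt",), "activates", "C", "4", "tumor_suppressor"),
    "PTEN": (("pten-restorer-1",), "activates", "D", "4", "tumor_suppressor"),
    "MYC": (("omomyc-mimetic",), "inhibits", "C", "3", "oncogene"),
}

_CENSUS_ROLES = {
    "ALK": "oncogene", "FGFR2": "oncogene", "KRAS": "oncogene",
    "JAK2": "oncogene", "MYC": "oncogene", "JUN": "oncogene",
    "GNAQ": "oncogene", "ACSL3": "oncogene", "RAC1": "oncogene",
    "MDM2": "oncogene", "TP53": "tumor_suppressor", "APC": "tumor_suppressor",
    "AXIN2": "tumor_suppressor", "PTEN": "tumor_suppressor",
    "ACVR2A": "tumor_suppressor", "FAS": "tumor_suppressor",
}


def generate_drug_kb(
    genes: Sequence[str],
    seed: int = 0,
    random_fraction: float = 0.1,
) -> tuple[list[DrugEvidence], list[DrugEvidence], CancerGeneList]:
    """Generate (civic records, oncokb records, census list) for ``genes``.

    Curated symbols (ALK, FGFR2, KRAS, ...) get their real drugs at fixed
    tiers; a ``random_fraction`` of the remaining genes gets one synthetic
    drug each with random interaction/tier/role.  The output always contains
    at least one oncogene with a top-tier inhibitor and one tumor suppressor
    with an activator.
    """
    genes = list(dict.fromkeys(genes))
    if not genes:
        raise ValueError("empty gene list")
    rng = np.random.default_rng(seed)

    civic: list[DrugEvidence] = []
    oncokb: list[DrugEvidence] = []
    roles: dict[str, str] = {}

    curated_present = [g for g in genes if g in _CURATED_KB]
    for g in curated_present:
        drugs, interaction, civic_tier, onco_level, role = _CURATED_KB[g]
        roles[g] = role
        for drug in drugs:
            civic.append(DrugEvidence(g, drug, interaction, civic_tier, "civic",
                                      role, "colorectal cancer"))
            oncokb.append(DrugEvidence(g, drug, interaction, onco_level, "oncokb",
                                       role, "colorectal cancer"))
    for g in genes:
        if g in _CENSUS_ROLES:
            roles.setdefault(g, _CENSUS_ROLES[g])

    remaining = [g for g in genes if g not in _CURATED_KB]
    n_random = int(round(random_fraction * len(remaining)))
    extra = list(rng.choice(remaining, size=min(n_random, len(remaining)),
                            replace=False)) if remaining else []
    for g in extra:
        role = str(rng.choice(["oncogene", "tumor_suppressor", "unknown"]))
        interaction = "inhibits" if role == "oncogene" else (
            "activates" if role == "tumor_suppressor" else "other")
        roles.setdefault(g, role)
        civic.append(DrugEvidence(g, f"cmpd-{g.lower()}", interaction,
                                  str(rng.choice(["B", "C", "D", "E"])), "civic",
                                  role, "solid tumor"))
        if rng.random() < 0.5:
            oncokb.append(DrugEvidence(g, f"cmpd-{g.lower()}", interaction,
                                       str(rng.choice(["2", "3", "4"])), "oncokb",
                                       role, "solid tumor"))

    # guarantees: one top-tier oncogene inhibitor, one TSG activator
    has_onco = any(e.interaction == "inhibits" and e.gene_role == "oncogene"
                   and e.tier == "A" for e in civic)
    if not has_onco:
        g = genes[0]
        roles[g] = "oncogene"
        civic.append(DrugEvidence(g, f"inh-{g.lower()}", "inhibits", "A", "civic",
                                  "oncogene", "solid tumor"))
        oncokb.append(DrugEvidence(g, f"inh-{g.lower()}", "inhibits", "1", "oncokb",
                                   "oncogene", "solid tumor"))
    has_tsg = any(e.interaction == "activates"
                  and e.gene_role == "tumor_suppressor" for e in civic)
    if not has_tsg:
        g = genes[-1] if len(genes) > 1 else genes[0]
        roles[g] = "tumor_suppressor"
        civic.append(DrugEvidence(g, f"act-{g.lower()}", "activates", "C", "civic",
                                  "tumor_suppressor", "solid tumor"))

    civic.sort(key=lambda e: (e.gene, e.drug))
    oncokb.sort(key=lambda e: (e.gene, e.drug))
    census = CancerGeneList({g: roles[g] for g in sorted(roles)})
    return civic, oncokb, census
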