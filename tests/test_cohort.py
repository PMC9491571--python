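"""Cohort construction rules and the exact clinical tests."""

from __future__ import annotations

from fractions import Fraction
from itertools import product
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from fusionscreen import cohort as ch
from fusionscreen.io_formats import FusionCallSet, SampleTable
from tests.conftest import make_expression


# ---------------------------------------------------------------------------
# independent Fisher oracle: exhaustive enumeration with exact rationals
# ---------------------------------------------------------------------------

def fisher_oracle(table) -> float:
    t = np.asarray(table, int)
    r1 = int(t[0].sum())
    cols = [int(c) for c in t.sum(axis=0)]
    N = int(t.sum())
    denom = comb(N, r1)

    def prob(a):
        num = 1
        for aj, cj in zip(a, cols):
            num *= comb(cj, aj)
        return Fraction(num, denom)

    p_obs = prob(tuple(int(x) for x in t[0]))
    total = Fraction(0)
    ranges = [range(min(c, r1) + 1) for c in cols]
    for a in product(*ranges):
        if sum(a) != r1:
            continue
        p = prob(a)
        if p <= p_obs:
            total += p
    return float(total)


def test_filter_tumor_samples_order_and_idempotence():
    df = pd.DataFrame(
        {"sample_type": ["tumor", "normal", "tumor", "metastasis", "tumor"]},
        index=[f"S{i}" for i in range(5)],
    )
    meta = SampleTable(df)
    tumors = ch.filter_tumor_samples(meta)
    assert tumors == ["S0", "S2", "S4"]
    sub = SampleTable(df.loc[tumors])
    assert ch.filter_tumor_samples(sub) == tumors


def test_filter_all_normal_gives_empty():
    meta = SampleTable(pd.DataFrame({"sample_type": ["normal"] * 3},
                                    index=["a", "b", "c"]))
    assert ch.filter_tumor_samples(meta) == []


def test_select_cases_applies_elevation_rule():
    # 6 tumors; fusion called on s0 (high ref) and s5 (lowest ref)
    values = np.array([[10.0, 6, 5, 4, 3, 1],
                       [1.0, 1, 1, 1, 1, 1]])
    expr = make_expression(values, genes=["REF", "other"])
    fus = FusionCallSet(pd.DataFrame(
        {"sample_id": ["s0", "s5"], "gene_5prime": "PTPRK", "gene_3prime": "REF"}
    ))
    cases = ch.select_cases(fus, expr, "REF", expr.sample_ids,
                            pair=("PTPRK", "REF"))
    assert cases == ["s0"]  # s5 is below the median and is excluded


def test_select_cases_mismatched_pair_warns_empty():
    values = np.abs(np.random.default_rng(0).normal(5, 1, (2, 6)))
    expr = make_expression(values, genes=["REF", "x"])
    fus = FusionCallSet(pd.DataFrame(
        {"sample_id": ["s0"], "gene_5prime": "EML4", "gene_3prime": "ALK"}
    ))
    with pytest.warns(UserWarning):
        cases = ch.select_cases(fus, expr, "REF", expr.sample_ids,
                                pair=("PTPRK", "REF"))
    assert cases == []


def test_control_pool_strict_below_median():
    # non-case values 1,2,3,4 -> median 2.5 -> pool = values 1 and 2
    values = np.array([[9.0, 1, 2, 3, 4]])
    expr = make_expression(values, genes=["REF"])
    pool = ch.build_control_pool(expr, expr.sample_ids, ["s0"], "REF")
    assert pool == ["s1", "s2"]


def test_control_pool_all_tied_raises():
    values = np.array([[5.0, 2, 2, 2, 2]])
    expr = make_expression(values, genes=["REF"])
    with pytest.raises(ValueError, match="tied"):
        ch.build_control_pool(expr, expr.sample_ids, ["s0"], "REF")


@given(st.integers(min_value=4, max_value=200), st.integers(min_value=0, max_value=10**6))
def test_pool_size_law_for_distinct_values(n_non_case, seed):
    """With distinct reference values, |pool| = floor(n_non_case / 2)."""
    rng = np.random.default_rng(seed)
    vals = rng.permutation(np.arange(1.0, n_non_case + 2))  # distinct, positive
    expr = make_expression(vals[None, :], genes=["REF"])
    pool = ch.build_control_pool(expr, expr.sample_ids, [expr.sample_ids[0]], "REF")
    assert len(pool) == n_non_case // 2


def test_draw_resamples_shapes_and_determinism():
    pool = [f"P{i}" for i in range(186)]
    cases = [f"C{i}" for i in range(7)]
    d1 = ch.draw_resamples(cases, pool, n_resamples=100, control_size=50, seed=9)
    d2 = ch.draw_resamples(cases, pool, n_resamples=100, control_size=50, seed=9)
    assert d1.resample_sets == d2.resample_sets
    assert len(d1.resample_sets) == 100
    assert all(len(set(rs)) == 50 for rs in d1.resample_sets)
    d3 = ch.draw_resamples(cases, pool, n_resamples=100, control_size=50, seed=10)
    assert d3.resample_sets != d1.resample_sets


def test_draw_resamples_pool_equals_control_size():
    pool = [f"P{i}" for i in range(50)]
    d = ch.draw_resamples(["c1", "c2"], pool, n_resamples=5, control_size=50, seed=0)
    assert all(sorted(rs) == sorted(pool) for rs in d.resample_sets)
    with pytest.raises(ValueError):
        ch.draw_resamples(["c1", "c2"], pool[:49], n_resamples=5,
                          control_size=50, seed=0)


def test_resample_inclusion_frequencies_exchangeable():
    """Each pool member appears in a resample at rate ~ control_size/|pool|."""
    pool = [f"P{i}" for i in range(60)]
    d = ch.draw_resamples(["c1", "c2"], pool, n_resamples=1000,
                          control_size=20, seed=4)
    counts = pd.Series(
        [sid for rs in d.resample_sets for sid in rs]
    ).value_counts()
    p = 20 / 60
    se = np.sqrt(p * (1 - p) / 1000)
    freq = counts.reindex(pool).fillna(0) / 1000
    assert ((freq - p).abs() < 4 * se).all()


def test_design_round_trip(tmp_path):
    pool = [f"P{i}" for i in range(30)]
    d = ch.draw_resamples(["c1", "c2", "c3"], pool, n_resamples=10,
                          control_size=5, seed=3)
    d.write(tmp_path / "design.tsv")
    d2 = ch.CohortDesign.read(tmp_path / "design.tsv")
    assert d2 == d


# ---------------------------------------------------------------------------
# exact tests
# ---------------------------------------------------------------------------


def test_fisher_worked_sex_table_is_one():
    # fusion 3 male / 2 female vs control 68 male / 53 female
    table = [[3, 2], [68, 53]]
    assert ch.fisher_exact_2xk(table) == pytest.approx(1.0, abs=1e-9)
    assert fisher_oracle(table) == pytest.approx(1.0, abs=1e-9)


@pytest.mark.parametrize(
    "table",
    [
        [[3, 2], [68, 53]],
        [[1, 4], [10, 2]],
        [[0, 5], [5, 0]],
        [[2, 2, 2], [4, 1, 7]],
        [[1, 0, 3], [2, 6, 1]],
        [[5, 0, 0, 2], [3, 4, 4, 2]],
    ],
)
def test_fisher_matches_enumeration_oracle(table):
    assert ch.fisher_exact_2xk(table) == pytest.approx(fisher_oracle(table),
                                                       abs=1e-10)


def test_fisher_2x2_matches_scipy():
    rng = np.random.default_rng(12)
    for _ in range(50):
        t = rng.integers(0, 15, size=(2, 2))
        if t.sum() == 0:
            continue
        ours = ch.fisher_exact_2xk(t)
        scipys = stats.fisher_exact(t, alternative="two-sided")[1]
        assert ours == pytest.approx(scipys, abs=1e-9)


def test_fisher_random_2xk_tables_match_oracle():
    rng = np.random.default_rng(3)
    for _ in range(25):
        k = rng.integers(2, 4)
        t = rng.integers(0, 8, size=(2, k))
        if t.sum() == 0 or t[0].sum() == 0 or t[1].sum() == 0:
            continue
        assert ch.fisher_exact_2xk(t) == pytest.approx(fisher_oracle(t), abs=1e-10)


def test_clinical_comparison_identical_groups_p_one(small_cohort):
    meta = small_cohort.metadata
    ids = meta.sample_ids[:40]
    # duplicate composition: compare a group against itself
    out = ch.clinical_comparison(meta, ids, ids)
    cat = out[out.test == "fisher_exact"]
    assert (cat.p_value > 0.999).all()


def test_clinical_comparison_reports_per_variable_denominators(small_cohort):
    c = small_cohort
    cases = c.case_ids
    controls = [s for s in c.metadata.sample_ids if s not in set(cases)][:60]
    out = ch.clinical_comparison(c.metadata, cases, controls)
    assert set(out.variable) >= {"age", "sex", "stage", "tp53_mut"}
    assert (out.n_case <= len(cases)).all()
    assert (out.n_control <= len(controls)).all()
    assert out.p_value.dropna().between(0, 1).all()
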