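"""Pearson machinery, screen ranking, permutation null, z-score export."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from fusionscreen import correlation_screen as cs
from fusionscreen.cohort import CohortDesign, draw_resamples
from tests.conftest import make_expression


def test_pearson_hand_computed_examples():
    assert cs.pearson_r([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
    assert cs.pearson_r([1, 2, 3], [6, 4, 2]) == pytest.approx(-1.0)
    # centered cross-product 4 over sqrt(5*5)
    assert cs.pearson_r([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)


def test_pearson_degenerate_and_errors():
    r, flag = cs.pearson_r([5, 5, 5], [1, 2, 3], return_degenerate=True)
    assert (r, flag) == (0.0, True)
    with pytest.raises(ValueError):
        cs.pearson_r([1, 2], [1, 2])
    with pytest.raises(ValueError):
        cs.pearson_r([1, 2, 3], [1, 2])


@given(
    st.lists(st.floats(-50, 50), min_size=5, max_size=20),
    st.floats(0.1, 4), st.floats(-10, 10),
    st.floats(0.1, 4), st.floats(-10, 10),
    st.sampled_from([-1.0, 1.0]), st.sampled_from([-1.0, 1.0]),
)
def test_pearson_affine_invariance(xs, a, b, c, d, sa, sc):
    rng = np.random.default_rng(1)
    x = np.asarray(xs)
    y = rng.normal(size=len(x))
    if np.std(x) == 0:
        return
    base = cs.pearson_r(x, y)
    scaled = cs.pearson_r(sa * a * x + b, sc * c * y + d)
    assert scaled == pytest.approx(np.sign(sa * c * a * sc) * base, abs=1e-10)


def _tiny_design(n_cohort=30, n_cases=4, control_size=10, n_res=20, seed=0):
    samples = [f"s{j}" for j in range(n_cohort)]
    return samples, draw_resamples(
        samples[:n_cases], samples[n_cases:], n_resamples=n_res,
        control_size=control_size, seed=seed,
    )


def test_run_screen_reference_ranks_first(small_cohort, small_screen):
    top = small_screen.records.iloc[0]
    assert top.gene == small_cohort.config.reference_gene
    assert top.median_abs_r == pytest.approx(1.0)
    assert top["rank"] == 1 and top.direction == "up"


def test_run_screen_matches_naive_pearson_loop(small_cohort, small_design):
    """Vectorized screen equals a scipy.stats.pearsonr double loop."""
    expr = small_cohort.expression
    res = cs.run_screen(expr, small_design, "RSPO3")
    rng = np.random.default_rng(0)
    sample_pos = {s: i for i, s in enumerate(expr.sample_ids)}
    ref = expr.gene("RSPO3")
    for gene in rng.choice(expr.gene_ids, 5, replace=False):
        vals = expr.gene(gene)
        rs = []
        for rs_ids in small_design.resample_sets:
            cols = [sample_pos[s] for s in (*small_design.case_ids, *rs_ids)]
            x, y = vals[cols], ref[cols]
            rs.append(0.0 if np.std(x) == 0 or np.std(y) == 0
                      else stats.pearsonr(x, y)[0])
        expected = np.median(np.abs(rs))
        assert res.record_of(gene).median_abs_r == pytest.approx(expected, abs=1e-10)


def test_all_zero_gene_is_degenerate_flat(small_cohort, small_design, small_screen):
    zero_gene = small_cohort.truth[small_cohort.truth.zero_row].gene.iloc[0]
    rec = small_screen.record_of(zero_gene)
    assert rec.median_abs_r == 0.0
    assert rec.direction == "flat"
    assert rec.n_degenerate == small_design.n_resamples


def test_selection_strict_inequality_and_nesting():
    records = pd.DataFrame(
        {
            "gene": ["a", "b", "c", "d"],
            "median_abs_r": [0.5, 0.21, 0.2, 0.1],
            "rank": [1, 2, 3, 4],
        }
    )
    assert cs.select_genes(records, 0.2) == ["a", "b"]
    assert cs.select_genes(records, 0.0) == ["a", "b", "c", "d"]
    assert set(cs.select_genes(records, 0.5)) <= set(cs.select_genes(records, 0.2))
    with pytest.raises(ValueError):
        cs.select_genes(records, 1.5)


def test_screen_monotone_nesting_on_cohort(small_screen):
    rec = small_screen.records
    for c1, c2 in [(0.1, 0.3), (0.2, 0.5)]:
        assert set(cs.select_genes(rec, c2)) <= set(cs.select_genes(rec, c1))


def test_permutation_moment_law():
    """Permutation distribution of R has E[R]=0, E[R^2]=1/(n-1) exactly."""
    rng = np.random.default_rng(42)
    n, m = 57, 20000
    x = np.exp(rng.normal(6, 1.25, n))   # fixed heavy-tailed vectors
    y = np.exp(rng.normal(6, 1.25, n))
    xc = (x - x.mean()) / np.sqrt(((x - x.mean()) ** 2).sum())
    yc = (y - y.mean()) / np.sqrt(((y - y.mean()) ** 2).sum())
    perms = np.array([rng.permutation(n) for _ in range(m)])
    r = xc[perms] @ yc
    se_mean = r.std() / np.sqrt(m)
    se_sq = (r**2).std() / np.sqrt(m)
    assert abs(r.mean()) < 4 * se_mean
    assert abs((r**2).mean() - 1 / (n - 1)) < 4 * se_sq


def test_calibration_cutoff_zero_rate_one(small_cohort, small_design):
    cur = cs.calibrate_cutoff(small_cohort.expression, small_design, "RSPO3",
                              n_permutations=500, cutoffs=(0.0, 0.2),
                              mode="single", seed=1)
    # all-zero genes give degenerate null statistics equal to 0; exclude them
    zero_frac = small_cohort.truth.zero_row.mean()
    assert cur.rate_at(0.0) >= 1.0 - zero_frac - 0.05
    assert cur.rates == tuple(sorted(cur.rates, reverse=True))  # non-increasing


def test_calibration_determinism_and_modes(small_cohort, small_design):
    kw = dict(n_permutations=400, cutoffs=(0.2,), seed=7)
    a = cs.calibrate_cutoff(small_cohort.expression, small_design, "RSPO3",
                            mode="full", **kw)
    b = cs.calibrate_cutoff(small_cohort.expression, small_design, "RSPO3",
                            mode="full", **kw)
    assert a.rates == b.rates
    assert np.array_equal(a.null_stats, b.null_stats)
    with pytest.raises(ValueError):
        cs.calibrate_cutoff(small_cohort.expression, small_design, "RSPO3",
                            n_permutations=50)


def test_full_mode_rate_not_above_single_mode(small_cohort, small_design):
    """Median over resamples concentrates: full rate <= single rate + 3 SE."""
    kw = dict(n_permutations=3000, cutoffs=(0.2,), seed=5)
    full = cs.calibrate_cutoff(small_cohort.expression, small_design, "RSPO3",
                               mode="full", **kw)
    single = cs.calibrate_cutoff(small_cohort.expression, small_design, "RSPO3",
                                 mode="single", **kw)
    se = np.sqrt(3) * max(full.mc_se(0.2), single.mc_se(0.2))
    assert full.rate_at(0.2) <= single.rate_at(0.2) + 3 * se


def test_zscore_examples_and_properties(small_cohort):
    expr = make_expression(np.array([[1.0, 2, 3], [5.0, 5, 5]]))
    z = cs.zscore_matrix(expr)
    # sample-SD convention: [1,2,3] has mean 2, sd 1 -> [-1, 0, 1]
    np.testing.assert_allclose(z.loc["g0"].to_numpy(), [-1.0, 0, 1.0], atol=1e-12)
    np.testing.assert_array_equal(z.loc["g1"].to_numpy(), [0.0, 0.0, 0.0])
    big = cs.zscore_matrix(small_cohort.expression)
    v = big.to_numpy()
    nonconstant = v.std(axis=1) > 0
    assert np.allclose(v[nonconstant].mean(axis=1), 0, atol=1e-9)
    assert np.allclose(v[nonconstant].std(axis=1, ddof=1), 1, atol=1e-9)
    with pytest.raises(KeyError):
        cs.zscore_matrix(small_cohort.expression, genes=["NOPE"])
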