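"""Case/control cohort construction and the clinical comparison table.

Fusion-positive tumor samples (cross-checked for elevated reference-gene
expression) form the case group; tumors in the lower half of reference-gene
expression form the control pool, from which fixed-size control sets are
repeatedly drawn without replacement.  Clinical variables are compared
between cases and controls with exact tests: a probability-ordered Fisher
exact test for 2 x k categorical tables (the case group is far too small for
asymptotic tests) and the Wilcoxon rank-sum test for age.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import count
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .io_formats import (
    ExpressionMatrix,
    FusionCallSet,
    SampleTable,
    MUTATION_FLAGS,
)

__all__ = [
    "CohortDesign",
    "filter_tumor_samples",
    "select_cases",
    "build_control_pool",
    "draw_resamples",
    "fisher_exact_2xk",
    "clinical_comparison",
]

DEFAULT_FUSION_PAIR = ("PTPRK", "RSPO3")


@dataclass(frozen=True)
class CohortDesign:
    """Cases, control pool and the resampled control sets of the screen."""

    case_ids: tuple[str, ...]
    control_pool_ids: tuple[str, ...]
    n_resamples: int
    control_size: int
    seed: int
    resample_sets: tuple[tuple[str, ...], ...]

    def __post_init__(self):
        if len(self.case_ids) < 2:
            raise ValueError("need at least 2 case samples")
        overlap = set(self.case_ids) & set(self.control_pool_ids)
        if overlap:
            raise ValueError(f"cases overlap control pool: {sorted(overlap)[:5]}")
        if len(self.resample_sets) != self.n_resamples:
            raise ValueError("resample_sets length must equal n_resamples")
        pool = set(self.control_pool_ids)
        for i, rs in enumerate(self.resample_sets):
            if len(rs) != self.control_size or len(set(rs)) != self.control_size:
                raise ValueError(f"resample {i} is not {self.control_size} distinct IDs")
            if not set(rs) <= pool:
                raise ValueError(f"resample {i} contains IDs outside the pool")

    @property
    def n_cases(self) -> int:
        return len(self.case_ids)

    def to_frame(self) -> pd.DataFrame:
        """One row per resample: resample index plus comma-joined control IDs."""
        return pd.DataFrame(
            {
                "resample": range(self.n_resamples),
                "control_ids": [",".join(rs) for rs in self.resample_sets],
            }
        )

    def write(self, path) -> None:
        header = pd.DataFrame(
            {
                "resample": [-1],
                "control_ids": [
                    "cases=" + ",".join(self.case_ids)
                    + ";pool=" + ",".join(self.control_pool_ids)
                    + f";seed={self.seed}"
                ],
            }
        )
        pd.concat([header, self.to_frame()]).to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "CohortDesign":
        df = pd.read_csv(path, sep="\t", dtype={"resample": int, "control_ids": str})
        meta = df.loc[df["resample"] == -1, "control_ids"].iloc[0]
        fields = dict(part.split("=", 1) for part in meta.split(";"))
        sets = tuple(
            tuple(row.split(","))
            for row in df.loc[df["resample"] >= 0, "control_ids"]
        )
        return cls(
            case_ids=tuple(fields["cases"].split(",")),
            control_pool_ids=tuple(fields["pool"].split(",")),
            n_resamples=len(sets),
            control_size=len(sets[0]) if sets else 0,
            seed=int(fields["seed"]),
            resample_sets=sets,
        )


def filter_tumor_samples(metadata: SampleTable) -> list[str]:
    """Primary tumor samples in input order (normals and metastases dropped)."""
    types = metadata.column("sample_type")
    return [sid for sid, t in types.items() if t == "tumor"]


def select_cases(
    fusions: FusionCallSet,
    expr: ExpressionMatrix,
    reference_gene: str,
    tumor_ids: Sequence[str],
    pair: tuple[str, str] = DEFAULT_FUSION_PAIR,
    elevation_rule: Callable[[float, np.ndarray], bool] | None = None,
) -> list[str]:
    """Tumor samples carrying the fusion pair with elevated reference expression.

    The default elevation rule keeps a fusion-positive sample only when its
    reference-gene expression is strictly above the median over all tumor
    samples (symmetric with the below-median control-pool rule).
    """
    if reference_gene not in expr.data.index:
        raise KeyError(f"reference gene {reference_gene!r} not in expression matrix")
    tumor_ids = list(tumor_ids)
    ref = expr.subset(genes=[reference_gene], samples=tumor_ids).values[0]
    ref_by_sample = dict(zip(tumor_ids, ref))
    if elevation_rule is None:
        med = float(np.median(ref))
        elevation_rule = lambda value, _all: value > med  # noqa: E731

    fusion_samples = fusions.samples_with_pair(pair)
    if not fusion_samples:
        warnings.warn(f"no fusion calls for pair {pair}; empty case set")
        return []
    cases = [
        sid for sid in tumor_ids
        if sid in set(fusion_samples) and elevation_rule(ref_by_sample[sid], ref)
    ]
    if not cases:
        warnings.warn(f"fusion calls for {pair} exist but none pass the elevation rule")
    return cases


def build_control_pool(
    expr: ExpressionMatrix,
    tumor_ids: Sequence[str],
    case_ids: Sequence[str],
    reference_gene: str,
) -> list[str]:
    """Non-case tumors whose reference expression is strictly below the median.

    The median is taken over the non-case tumors themselves (mean of the two
    central order statistics for even counts), so with distinct values the
    pool holds exactly floor(n/2) samples.
    """
    tumor_ids = list(tumor_ids)
    case_set = set(case_ids)
    if not case_set <= set(tumor_ids):
        raise ValueError("case_ids must be a subset of tumor_ids")
    non_case = [sid for sid in tumor_ids if sid not in case_set]
    if len(non_case) < 2:
        raise ValueError("fewer than 2 non-case tumor samples")
    ref = expr.subset(genes=[reference_gene], samples=non_case).values[0]
    med = float(np.median(ref))
    pool = [sid for sid, v in zip(non_case, ref) if v < med]
    if not pool:
        raise ValueError(
            "control pool is empty (reference expression tied at the median)"
        )
    return pool


def draw_resamples(
    case_ids: Sequence[str],
    pool: Sequence[str],
    n_resamples: int = 100,
    control_size: int = 50,
    seed: int = 0,
) -> CohortDesign:
    """Draw ``n_resamples`` control sets of ``control_size`` without replacement."""
    pool = list(pool)
    if len(pool) < control_size:
        raise ValueError(
            f"pool of {len(pool)} smaller than control_size {control_size}"
        )
    rng = np.random.default_rng(seed)
    sets = tuple(
        tuple(rng.choice(pool, size=control_size, replace=False))
        for _ in range(n_resamples)
    )
    return CohortDesign(
        case_ids=tuple(case_ids),
        control_pool_ids=tuple(pool),
        n_resamples=n_resamples,
        control_size=control_size,
        seed=seed,
        resample_sets=sets,
    )


# ---------------------------------------------------------------------------
# exact tests
# ---------------------------------------------------------------------------


def _log_table_prob(a: np.ndarray, cols: np.ndarray, r1: int, log_denom: float) -> float:
    # P(table) = prod_j C(c_j, a_j) / C(N, r1)
    num = np.sum(
        gammaln(cols + 1) - gammaln(a + 1) - gammaln(cols - a + 1)
    )
    return float(num - log_denom)


def fisher_exact_2xk(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p for a 2 x k table, probability-ordered.

    Enumerates every table with the observed margins (recursing over the
    smaller row margin, so tiny case groups keep the enumeration cheap) and
    sums the probabilities of tables no more probable than the observed one.
    """
    t = np.asarray(table, dtype=int)
    if t.ndim != 2 or t.shape[0] != 2 or t.shape[1] < 2:
        raise ValueError("expected a 2 x k table with k >= 2")
    if (t < 0).any():
        raise ValueError("table entries must be non-negative")
    if t.sum() == 0:
        return 1.0
    if t[0].sum() > t[1].sum():
        t = t[::-1]
    r1 = int(t[0].sum())
    cols = t.sum(axis=0)
    N = int(t.sum())
    log_denom = gammaln(N + 1) - gammaln(r1 + 1) - gammaln(N - r1 + 1)
    log_p_obs = _log_table_prob(t[0], cols, r1, log_denom)

    k = len(cols)
    total = 0.0
    a = np.zeros(k, dtype=int)

    def recurse(j: int, remaining: int):
        nonlocal total
        if j == k - 1:
            if remaining <= cols[j]:
                a[j] = remaining
                lp = _log_table_prob(a, cols, r1, log_denom)
                if lp <= log_p_obs + 1e-9:
                    total += np.exp(lp)
            return
        upper = min(cols[j], remaining)
        lower = max(0, remaining - int(cols[j + 1:].sum()))
        for v in range(lower, upper + 1):
            a[j] = v
            recurse(j + 1, remaining - v)

    recurse(0, r1)
    return min(1.0, total)


_CATEGORICAL_VARS = ["sex", "vital_status", "stage", "msi_status", "histology"]


def clinical_comparison(
    metadata: SampleTable,
    case_ids: Sequence[str],
    control_ids: Sequence[str],
) -> pd.DataFrame:
    """Table-1-style comparison of cases vs controls, one row per variable.

    Missing values are dropped per variable and the per-variable denominators
    are reported (``n_case``/``n_control``).  Categorical variables use the
    two-sided Fisher exact test; age uses the Wilcoxon rank-sum test.
    """
    if not case_ids or not control_ids:
        raise ValueError("both groups must be non-empty")
    rows = []
    variables = (["age"] + _CATEGORICAL_VARS
                 + [f for f in MUTATION_FLAGS if f in metadata.data.columns])
    for var in variables:
        if var not in metadata.data.columns:
            raise KeyError(f"variable {var!r} absent from metadata")
        col = metadata.column(var)
        case_vals = col.loc[[s for s in case_ids if s in col.index]].dropna()
        ctrl_vals = col.loc[[s for s in control_ids if s in col.index]].dropna()
        if var == "age":
            x = case_vals.astype(float)
            y = ctrl_vals.astype(float)
            if len(x) == 0 or len(y) == 0:
                p, test = float("nan"), "wilcoxon_rank_sum"
            else:
                p = float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
                test = "wilcoxon_rank_sum"
            case_summary = f"{x.min():.0f}~{x.max():.0f}" if len(x) else "NA"
            ctrl_summary = f"{y.min():.0f}~{y.max():.0f}" if len(y) else "NA"
        else:
            levels = sorted(set(case_vals) | set(ctrl_vals))
            if len(levels) < 2:
                p, test = 1.0, "fisher_exact"
            else:
                table = [
                    [int((case_vals == lv).sum()) for lv in levels],
                    [int((ctrl_vals == lv).sum()) for lv in levels],
                ]
                p = fisher_exact_2xk(table)
                test = "fisher_exact"
            case_summary = _summarize(case_vals, levels if levels else [])
            ctrl_summary = _summarize(ctrl_vals, levels if levels else [])
        rows.append(
            {
                "variable": var,
                "case_summary": case_summary,
                "control_summary": ctrl_summary,
                "n_case": int(len(case_vals)),
                "n_control": int(len(ctrl_vals)),
                "test": test,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)


def _summarize(values: pd.Series, levels: Sequence[str]) -> str:
    n = len(values)
    if n == 0:
        return "NA"
    parts = []
    for lv in levels:
        k = int((values == lv).sum())
        parts.append(f"{lv}:{k}/{n} ({100 * k / n:.1f}%)")
    return "; ".join(parts)
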