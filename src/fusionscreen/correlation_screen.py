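"""Resampled reference-gene correlation screen and its permutation calibration.

The selection statistic is the median of absolute Pearson R between a gene and
the reference gene, computed over repeated case + resampled-control sample
sets.  The R cutoff is calibrated by permutation: each permutation randomly
reorders a randomly chosen gene's expression values across the cohort samples
and recomputes the null selection statistic, either as a single Pearson test
on one case+control set ("single" mode) or as the complete median-over-
resamples screen statistic ("full" mode, the default — calibration mirrors
the selection procedure exactly, reusing the very same resample sets).

Degenerate (zero-variance) vectors contribute R = 0 with a flag instead of
being dropped, so every gene's R vector keeps length n_resamples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import CohortDesign
from .io_formats import ExpressionMatrix

__all__ = [
    "pearson_r",
    "ScreenResult",
    "run_screen",
    "select_genes",
    "CalibrationCurve",
    "calibrate_cutoff",
    "zscore_matrix",
]

TRANSFORMS = ("none", "log2p1")
DEFAULT_CUTOFF = 0.2
DEFAULT_CUTOFF_GRID = (0.05, 0.1, 0.15, 0.2, 0.25, 0.3, 0.4, 0.5)


def _apply_transform(values: np.ndarray, transform: str) -> np.ndarray:
    if transform == "none":
        return values
    if transform == "log2p1":
        return np.log2(values + 1.0)
    raise ValueError(f"unknown transform {transform!r}; expected one of {TRANSFORMS}")


def pearson_r(x, y, return_degenerate: bool = False):
    """Sample Pearson correlation of two equal-length vectors (n >= 3).

    A zero-variance vector yields the degenerate placeholder R = 0; with
    ``return_degenerate=True`` the result is the tuple ``(R, degenerate)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or len(x) != len(y):
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 3:
        raise ValueError(f"need at least 3 observations, got {len(x)}")
    xc = x - x.mean()
    yc = y - y.mean()
    nx = float(np.sqrt(xc @ xc))
    ny = float(np.sqrt(yc @ yc))
    if nx == 0.0 or ny == 0.0:
        return (0.0, True) if return_degenerate else 0.0
    r = float(np.clip((xc @ yc) / (nx * ny), -1.0, 1.0))
    return (r, False) if return_degenerate else r


@dataclass(frozen=True)
class ScreenResult:
    """Per-gene records of the screen plus the raw per-resample R matrix."""

    records: pd.DataFrame   # rank order: gene, median_abs_r, median_signed_r,
                            # direction, selected, rank, n_degenerate
    r_values: np.ndarray    # (n_genes, n_resamples), aligned with records rows
    cutoff: float
    transform: str

    def record_of(self, gene: str) -> pd.Series:
        hit = self.records[self.records.gene == gene]
        if hit.empty:
            raise KeyError(gene)
        return hit.iloc[0]

    def write(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False,
                            float_format="%.6f")


def _resample_indices(expr: ExpressionMatrix, design: CohortDesign) -> np.ndarray:
    """(n_resamples, n_cases + control_size) column indices into expr."""
    col_of = {sid: j for j, sid in enumerate(expr.sample_ids)}
    missing = [s for s in (*design.case_ids, *design.control_pool_ids)
               if s not in col_of]
    if missing:
        raise ValueError(f"design IDs absent from expression matrix: {missing[:5]}")
    return np.array(
        [[col_of[s] for s in (*design.case_ids, *rs)]
         for rs in design.resample_sets],
        dtype=np.intp,
    )


def _reference_blocks(values: np.ndarray, ref_row: int,
                      idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centered reference vectors per resample and their norms."""
    ref = values[ref_row][idx]                      # (R, n_set)
    refc = ref - ref.mean(axis=1, keepdims=True)
    norms = np.sqrt((refc * refc).sum(axis=1))      # (R,)
    return refc, norms


def run_screen(
    expr: ExpressionMatrix,
    design: CohortDesign,
    reference_gene: str,
    transform: str = "none",
    cutoff: float = DEFAULT_CUTOFF,
) -> ScreenResult:
    """Correlate every gene with the reference over each resampled sample set.

    Returns records ranked by decreasing median |R| (lexicographic gene-ID
    tie-break).  The reference gene correlates perfectly with itself, so it
    always ranks first with median |R| = 1.  ``selected`` flags genes whose
    median |R| strictly exceeds ``cutoff``.
    """
    if reference_gene not in expr.data.index:
        raise KeyError(f"reference gene {reference_gene!r} not in expression matrix")
    values = _apply_transform(expr.values, transform)
    genes = np.array(expr.gene_ids)
    ref_row = int(np.flatnonzero(genes == reference_gene)[0])
    idx = _resample_indices(expr, design)
    refc, ref_norms = _reference_blocks(values, ref_row, idx)

    n_genes = len(genes)
    n_res = design.n_resamples
    r = np.zeros((n_genes, n_res))
    degenerate = np.zeros((n_genes, n_res), dtype=bool)
    for k in range(n_res):
        sub = values[:, idx[k]]                       # (G, n_set)
        sub = sub - sub.mean(axis=1, keepdims=True)
        norms = np.sqrt((sub * sub).sum(axis=1))      # (G,)
        denom = norms * ref_norms[k]
        bad = denom == 0.0
        degenerate[:, k] = bad
        with np.errstate(invalid="ignore", divide="ignore"):
            rk = (sub @ refc[k]) / denom
        rk[bad] = 0.0
        r[:, k] = np.clip(rk, -1.0, 1.0)

    median_abs = np.median(np.abs(r), axis=1)
    median_signed = np.median(r, axis=1)
    direction = np.where(median_signed > 0, "up",
                         np.where(median_signed < 0, "down", "flat"))
    records = pd.DataFrame(
        {
            "gene": genes,
            "median_abs_r": median_abs,
            "median_signed_r": median_signed,
            "direction": direction,
            "selected": median_abs > cutoff,
            "n_degenerate": degenerate.sum(axis=1),
        }
    )
    order = np.lexsort((genes, -median_abs))
    records = records.iloc[order].reset_index(drop=True)
    records["rank"] = np.arange(1, n_genes + 1)
    return ScreenResult(records=records, r_values=r[order], cutoff=cutoff,
                        transform=transform)


def select_genes(records: pd.DataFrame, cutoff: float = DEFAULT_CUTOFF) -> list[str]:
    """Genes with median |R| strictly above ``cutoff``, in rank order."""
    if not 0 <= cutoff <= 1:
        raise ValueError(f"cutoff must be in [0, 1], got {cutoff}")
    ranked = records.sort_values("rank")
    return list(ranked.gene[ranked.median_abs_r > cutoff])


# ---------------------------------------------------------------------------
# permutation calibration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CalibrationCurve:
    """Estimated false-selection rate of the screen per candidate R cutoff."""

    cutoffs: tuple[float, ...]
    rates: tuple[float, ...]
    n_permutations: int
    mode: str
    seed: int
    null_stats: np.ndarray  # the n_permutations null selection statistics

    def rate_at(self, cutoff: float) -> float:
        for c, r in zip(self.cutoffs, self.rates):
            if c == cutoff:
                return r
        raise KeyError(f"cutoff {cutoff} not on the calibration grid")

    def mc_se(self, cutoff: float) -> float:
        r = self.rate_at(cutoff)
        return float(np.sqrt(r * (1 - r) / self.n_permutations))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cutoff": self.cutoffs,
                "rate": self.rates,
                "n_permutations": self.n_permutations,
                "mode": self.mode,
                "seed": self.seed,
            }
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.8g")


def calibrate_cutoff(
    expr: ExpressionMatrix,
    design: CohortDesign,
    reference_gene: str,
    n_permutations: int = 100_000,
    cutoffs: Sequence[float] = DEFAULT_CUTOFF_GRID,
    mode: str = "full",
    seed: int = 0,
    transform: str = "none",
    batch_size: int = 1000,
) -> CalibrationCurve:
    """Permutation calibration of the R cutoff.

    Each permutation draws a gene uniformly at random (with replacement),
    randomly reorders its expression values across the cohort samples (cases
    plus control pool), and computes the null selection statistic:

    - mode "single": |Pearson R| against the reference on one randomly chosen
      case+control resample set;
    - mode "full": the median of |R| over all of the design's resample sets —
      the exact statistic the real screen thresholds.

    The curve reports, per cutoff, the fraction of null statistics strictly
    exceeding it.
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    if mode not in ("single", "full"):
        raise ValueError(f"mode must be 'single' or 'full', got {mode!r}")
    cutoffs = tuple(float(c) for c in cutoffs)
    for c in cutoffs:
        if not 0 <= c <= 1:
            raise ValueError(f"cutoffs must lie in [0, 1], got {c}")
    if reference_gene not in expr.data.index:
        raise KeyError(f"reference gene {reference_gene!r} not in expression matrix")

    rng = np.random.default_rng(seed)
    cohort_samples = list(design.case_ids) + list(design.control_pool_ids)
    sub = expr.subset(samples=cohort_samples)
    values = _apply_transform(sub.values, transform)
    genes = np.array(sub.gene_ids)
    ref_row = int(np.flatnonzero(genes == reference_gene)[0])
    idx = _resample_indices(sub, design)                  # (R, n_set)
    refc, ref_norms = _reference_blocks(values, ref_row, idx)
    n_cohort = values.shape[1]
    n_res, n_set = idx.shape

    stats_out = np.empty(n_permutations)
    done = 0
    while done < n_permutations:
        b = min(batch_size, n_permutations - done)
        gene_pick = rng.integers(len(genes), size=b)
        perm = values[gene_pick]                          # (b, n_cohort)
        perm = rng.permuted(perm, axis=1)
        if mode == "single":
            set_pick = rng.integers(n_res, size=b)
            g = np.take_along_axis(perm, idx[set_pick], axis=1)  # (b, n_set)
            gc = g - g.mean(axis=1, keepdims=True)
            norms = np.sqrt((gc * gc).sum(axis=1))
            denom = norms * ref_norms[set_pick]
            with np.errstate(invalid="ignore", divide="ignore"):
                r = np.einsum("bs,bs->b", gc, refc[set_pick]) / denom
            r[denom == 0.0] = 0.0
            stats_out[done:done + b] = np.abs(np.clip(r, -1.0, 1.0))
        else:
            g = perm[:, idx.reshape(-1)].reshape(b, n_res, n_set)
            gc = g - g.mean(axis=2, keepdims=True)
            norms = np.sqrt((gc * gc).sum(axis=2))        # (b, R)
            denom = norms * ref_norms[None, :]
            with np.errstate(invalid="ignore", divide="ignore"):
                r = np.einsum("brs,rs->br", gc, refc) / denom
            r[denom == 0.0] = 0.0
            stats_out[done:done + b] = np.median(
                np.abs(np.clip(r, -1.0, 1.0)), axis=1
            )
        done += b

    rates = tuple(float((stats_out > c).mean()) for c in cutoffs)
    return CalibrationCurve(
        cutoffs=cutoffs,
        rates=rates,
        n_permutations=n_permutations,
        mode=mode,
        seed=seed,
        null_stats=stats_out,
    )


# ---------------------------------------------------------------------------
# z-score export
# ---------------------------------------------------------------------------


def zscore_matrix(
    expr: ExpressionMatrix,
    genes: Sequence[str] | None = None,
    samples: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Row-wise (per-gene) z-scores over the requested samples.

    Uses the sample-SD convention (ddof = 1), so the row [1, 2, 3] maps to
    [-1, 0, 1]; constant rows map to zeros.
    """
    sub = expr.subset(genes=genes, samples=samples)
    if sub.data.size == 0:
        raise ValueError("empty gene/sample selection")
    v = sub.values
    if v.shape[1] < 2:
        raise ValueError("need at least 2 samples for z-scores")
    mean = v.mean(axis=1, keepdims=True)
    sd = v.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (v - mean) / sd
    z[np.broadcast_to(sd == 0.0, z.shape)] = 0.0
    return pd.DataFrame(z, index=sub.data.index, columns=sub.data.columns)
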