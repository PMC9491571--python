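"""Pathway over-representation analysis, meta-pathway collapse and gene annotation.

ORA tests each pathway's overlap with the selected gene list against the
hypergeometric null (upper tail, P(X >= k)) on a stated background universe —
by default the measured genes that are annotated to at least one pathway, the
convention of annotated-background ORA services.  Benjamini-Hochberg q-values
control the FDR across pathways.  Significant pathways are collapsed through a
user-supplied meta-pathway map (the curated grouping of source pathways into
named cancer meta-pathways is taken as input, not reconstructed), their
query-overlap genes unioned into per-meta gene sets and a global component-gene
union.  Component genes are then annotated with cancer-census membership, the
number of meta-pathways they appear in, and the key-gene flag:
census gene AND median |R| > 0.3 AND involved in >= 2 meta-pathways.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io_formats import CancerGeneList, PathwayDB

__all__ = [
    "build_universe",
    "ora_hypergeometric",
    "bh_fdr",
    "validate_meta_map",
    "collapse_to_meta",
    "MetaCollapse",
    "annotate_genes",
    "pathway_jaccard",
]

DEFAULT_Q_THRESHOLD = 0.05   # headline profile; 0.2 is the documented alternative
DEFAULT_KEY_R = 0.3
DEFAULT_KEY_MIN_PATHWAYS = 2


def build_universe(
    measured_genes: Iterable[str],
    db: PathwayDB,
    annotated_only: bool = True,
) -> frozenset[str]:
    """Background universe: measured genes, optionally restricted to those
    annotated to at least one pathway of the database."""
    measured = frozenset(measured_genes)
    if not annotated_only:
        return measured
    return measured & db.all_genes()


def ora_hypergeometric(
    query: Iterable[str],
    db: PathwayDB,
    universe: Iterable[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric ORA of ``query`` against each pathway.

    Pathways are intersected with the universe before testing; pathways with
    no universe gene (K = 0) are skipped.  Returns one row per tested pathway
    with k, K, n, N, p_value and BH q_value.
    """
    universe = frozenset(universe)
    query = frozenset(query)
    if not universe:
        raise ValueError("empty universe")
    if not query:
        raise ValueError("empty query")
    if not query <= universe:
        extra = sorted(query - universe)
        raise ValueError(f"query genes outside the universe: {extra[:5]}")
    N = len(universe)
    n = len(query)
    rows = []
    for p in db:
        in_universe = p.genes & universe
        K = len(in_universe)
        if K == 0:
            continue
        k = len(in_universe & query)
        # P(X >= k) for X ~ Hypergeom(N, K, n)
        pval = float(hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {"pathway_id": p.pathway_id, "k": k, "K": K, "n": n, "N": N,
             "p_value": min(1.0, pval)}
        )
    records = pd.DataFrame(rows, columns=["pathway_id", "k", "K", "n", "N", "p_value"])
    if len(records):
        records["q_value"] = bh_fdr(records.p_value.to_numpy())
    else:
        records["q_value"] = pd.Series(dtype=float)
    return records


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    if len(p) == 0:
        return np.empty(0)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def validate_meta_map(meta_map: Mapping[str, Iterable[str]], db: PathwayDB) -> None:
    known = set(db.pathway_ids)
    for name, pids in meta_map.items():
        unknown = set(pids) - known
        if unknown:
            raise ValueError(
                f"meta-pathway {name!r} maps unknown pathways: {sorted(unknown)[:5]}"
            )


@dataclass(frozen=True)
class MetaCollapse:
    """Result of collapsing significant pathways into meta-pathways."""

    meta_sets: dict[str, frozenset[str]]   # meta name -> query genes
    component_genes: frozenset[str]        # global union
    significant_ids: tuple[str, ...]
    q_threshold: float

    def counts(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "meta_pathway": sorted(self.meta_sets),
                "n_genes": [len(self.meta_sets[m]) for m in sorted(self.meta_sets)],
            }
        )

    def long_table(self) -> pd.DataFrame:
        rows = [
            {"meta_pathway": m, "gene": g}
            for m in sorted(self.meta_sets)
            for g in sorted(self.meta_sets[m])
        ]
        return pd.DataFrame(rows, columns=["meta_pathway", "gene"])


def collapse_to_meta(
    records: pd.DataFrame,
    meta_map: Mapping[str, Iterable[str]],
    db: PathwayDB,
    query: Iterable[str],
    q_threshold: float = DEFAULT_Q_THRESHOLD,
) -> MetaCollapse:
    """Union query-overlap genes of significant pathways within each meta group.

    A pathway counts as significant when its q-value is strictly below
    ``q_threshold``.  Every meta group of the map appears in the output, empty
    if none of its member pathways is significant.
    """
    validate_meta_map(meta_map, db)
    query = frozenset(query)
    significant = set(records.pathway_id[records.q_value < q_threshold])
    meta_sets: dict[str, frozenset[str]] = {}
    for name, pids in meta_map.items():
        genes: set[str] = set()
        for pid in pids:
            if pid in significant:
                genes |= db[pid].genes & query
        meta_sets[name] = frozenset(genes)
    component = frozenset().union(*meta_sets.values()) if meta_sets else frozenset()
    return MetaCollapse(
        meta_sets=meta_sets,
        component_genes=component,
        significant_ids=tuple(sorted(significant)),
        q_threshold=q_threshold,
    )


def annotate_genes(
    component_genes: Iterable[str],
    census: CancerGeneList,
    screen_records: pd.DataFrame,
    meta_sets: Mapping[str, Iterable[str]],
    key_r_threshold: float = DEFAULT_KEY_R,
    key_min_pathways: int = DEFAULT_KEY_MIN_PATHWAYS,
) -> pd.DataFrame:
    """Annotate component genes with census role, multiplicity and key flag.

    ``key_gene`` requires census membership, median |R| strictly above
    ``key_r_threshold`` and membership in at least ``key_min_pathways``
    meta-pathways — the conjunction that picks out the screen's headline genes.
    """
    screen = screen_records.set_index("gene")
    rows = []
    for gene in sorted(set(component_genes)):
        count = sum(gene in set(genes) for genes in meta_sets.values())
        if gene in screen.index:
            med = float(screen.loc[gene, "median_abs_r"])
            direction = str(screen.loc[gene, "direction"])
        else:
            med, direction = float("nan"), "flat"
        is_cancer = gene in census
        key = (
            is_cancer
            and med > key_r_threshold
            and count >= key_min_pathways
        )
        rows.append(
            {
                "gene": gene,
                "is_cancer_gene": is_cancer,
                "role": census.role_of(gene),
                "meta_pathway_count": count,
                "median_abs_r": med,
                "direction": direction,
                "key_gene": bool(key),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["gene", "is_cancer_gene", "role", "meta_pathway_count",
                 "median_abs_r", "direction", "key_gene"],
    )


def pathway_jaccard(db: PathwayDB) -> pd.DataFrame:
    """Pairwise Jaccard overlap of pathway gene sets (curation aid).

    Reported to assist a manual meta-pathway grouping; no automatic merge is
    performed.
    """
    ids = db.pathway_ids
    sets = {p.pathway_id: p.genes for p in db}
    rows = []
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            inter = len(sets[a] & sets[b])
            union = len(sets[a] | sets[b])
            rows.append(
                {"pathway_a": a, "pathway_b": b,
                 "jaccard": inter / union if union else 0.0}
            )
    return pd.DataFrame(rows, columns=["pathway_a", "pathway_b", "jaccard"])
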