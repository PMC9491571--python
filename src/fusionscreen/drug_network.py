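"""Direction-aware actionable-drug network construction and prioritization.

Component genes carrying evidence in the CIViC- or OncoKB-style knowledgebases
become gene nodes of a bipartite drug-gene graph; each evidence record becomes
one edge.  An edge is *prioritized* under the scenario that properly working
cancer drugs are inhibitors of activated (up-regulated) oncogenes or
activators of down-regulated tumor suppressors:

    prioritized  <=>  (inhibits AND oncogene AND up)
                   OR (activates AND tumor_suppressor AND down)

Gene roles come from the cancer-gene census when available; a knowledgebase
role is used only as a fallback, and census/knowledgebase conflicts are logged.
Evidence tiers are kept per source (CIViC A-E, OncoKB 1-4) and never unified
onto one scale; each drug node records its best tier per source.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from .io_formats import (
    CIVIC_TIERS,
    ONCOKB_TIERS,
    CancerGeneList,
    DrugEvidence,
)

__all__ = [
    "match_actionable",
    "prioritize",
    "DrugTargetNetwork",
    "build_network",
    "druggability_report",
]

logger = logging.getLogger(__name__)

_TIER_RANK = {
    "civic": {t: i for i, t in enumerate(CIVIC_TIERS)},    # A best
    "oncokb": {t: i for i, t in enumerate(ONCOKB_TIERS)},  # 1 best
}


def match_actionable(
    annotations: pd.DataFrame,
    civic: Sequence[DrugEvidence],
    oncokb: Sequence[DrugEvidence],
) -> tuple[list[DrugEvidence], pd.DataFrame]:
    """Inner-join annotated genes with knowledgebase evidence on gene symbol.

    ``annotations`` is the gene-annotation table of the enrichment stage
    (one row per component gene).  Returns the matched evidence records
    (both sources, provenance kept) and a side report listing the component
    genes with no actionable evidence.
    """
    genes = set(annotations.gene)
    matched = [e for e in (*civic, *oncokb) if e.gene in genes]
    matched_genes = {e.gene for e in matched}
    unmatched = annotations[~annotations.gene.isin(matched_genes)]
    report = unmatched[["gene", "direction", "meta_pathway_count"]].reset_index(
        drop=True
    )
    return matched, report


def prioritize(interaction: str, direction: str, role: str) -> tuple[bool, str]:
    """Apply the scenario rule to one (interaction, direction, role) premise.

    Returns the flag and a human-readable rationale; an unknown role or a
    flat direction never prioritizes and the rationale names the missing
    premise.
    """
    if role not in ("oncogene", "tumor_suppressor", "both", "unknown"):
        raise ValueError(f"unknown role {role!r}")
    if direction not in ("up", "down", "flat"):
        raise ValueError(f"unknown direction {direction!r}")
    if role == "unknown":
        return False, "gene role unknown; scenario rule needs oncogene/TSG status"
    if direction == "flat":
        return False, "no expression direction; scenario rule needs up/down"
    onco = role in ("oncogene", "both")
    tsg = role in ("tumor_suppressor", "both")
    if interaction == "inhibits" and onco and direction == "up":
        return True, "inhibitor of an up-regulated oncogene"
    if interaction == "activates" and tsg and direction == "down":
        return True, "activator of a down-regulated tumor suppressor"
    return False, (
        f"{interaction} / {role} / {direction} does not match the scenario "
        "(inhibitor+oncogene+up or activator+TSG+down)"
    )


@dataclass(frozen=True)
class DrugTargetNetwork:
    """Bipartite drug-gene graph with per-edge prioritization.

    ``graph`` is a networkx MultiDiGraph with drug -> gene edges; node
    attributes carry type, direction, role, meta-pathway count and best
    per-source tiers, edge attributes carry interaction, tier, source,
    prioritized flag and rationale.
    """

    graph: nx.MultiDiGraph

    @property
    def drug_nodes(self) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True)
                      if d["node_type"] == "drug")

    @property
    def gene_nodes(self) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True)
                      if d["node_type"] == "gene")

    def edges_frame(self) -> pd.DataFrame:
        rows = [
            {
                "drug": u,
                "interaction": d["interaction"],
                "gene": v,
                "tier": d["tier"],
                "source": d["source"],
                "prioritized": d["prioritized"],
                "rationale": d["rationale"],
            }
            for u, v, d in self.graph.edges(data=True)
        ]
        df = pd.DataFrame(
            rows,
            columns=["drug", "interaction", "gene", "tier", "source",
                     "prioritized", "rationale"],
        )
        return df.sort_values(
            ["drug", "gene", "source", "tier", "interaction"]
        ).reset_index(drop=True)

    def nodes_frame(self) -> pd.DataFrame:
        rows = []
        for n in sorted(self.graph.nodes):
            d = self.graph.nodes[n]
            rows.append(
                {
                    "node": n,
                    "node_type": d["node_type"],
                    "direction": d.get("direction", ""),
                    "role": d.get("role", ""),
                    "meta_pathway_count": d.get("meta_pathway_count", ""),
                    "best_tier_civic": d.get("best_tier_civic", ""),
                    "best_tier_oncokb": d.get("best_tier_oncokb", ""),
                }
            )
        return pd.DataFrame(
            rows,
            columns=["node", "node_type", "direction", "role",
                     "meta_pathway_count", "best_tier_civic", "best_tier_oncokb"],
        )

    @property
    def n_prioritized(self) -> int:
        return sum(1 for _, _, d in self.graph.edges(data=True) if d["prioritized"])


def _resolve_role(gene: str, kb_role: str, census: CancerGeneList | None) -> str:
    if census is not None and gene in census:
        census_role = census.role_of(gene)
        if kb_role not in ("unknown", census_role):
            logger.info(
                "gene %s: census role %r overrides knowledgebase role %r",
                gene, census_role, kb_role,
            )
        return census_role
    return kb_role


def build_network(
    matches: Sequence[DrugEvidence],
    annotations: pd.DataFrame,
    census: CancerGeneList | None = None,
) -> DrugTargetNetwork:
    """Assemble the prioritized drug-target network from matched evidence.

    One edge per evidence record (multi-drug rows were already expanded by the
    reader); gene direction and meta-pathway count come from ``annotations``;
    roles resolve census-first.  Node ordering in all exports is lexicographic,
    so the build is a pure function of its inputs.
    """
    ann = annotations.set_index("gene")
    g = nx.MultiDiGraph()
    for ev in sorted(matches, key=lambda e: (e.drug, e.gene, e.source, e.tier)):
        direction = str(ann.loc[ev.gene, "direction"]) if ev.gene in ann.index else "flat"
        count = int(ann.loc[ev.gene, "meta_pathway_count"]) if ev.gene in ann.index else 0
        role = _resolve_role(ev.gene, ev.gene_role, census)
        flag, rationale = prioritize(ev.interaction, direction, role)
        if ev.drug not in g:
            g.add_node(ev.drug, node_type="drug")
        if ev.gene not in g:
            g.add_node(ev.gene, node_type="gene", direction=direction,
                       role=role, meta_pathway_count=count)
        g.add_edge(
            ev.drug, ev.gene,
            interaction=ev.interaction, tier=ev.tier, source=ev.source,
            prioritized=flag, rationale=rationale,
        )
        best_key = f"best_tier_{ev.source}"
        rank = _TIER_RANK[ev.source]
        current = g.nodes[ev.drug].get(best_key)
        if current is None or rank[ev.tier] < rank[current]:
            g.nodes[ev.drug][best_key] = ev.tier
    return DrugTargetNetwork(g)


def druggability_report(network: DrugTargetNetwork) -> pd.DataFrame:
    """Per-gene summary: direction, multiplicity, drugs, tiers, prioritized count."""
    rows = []
    g = network.graph
    for gene in network.gene_nodes:
        d = g.nodes[gene]
        incoming = [
            (u, data) for u, v, data in g.in_edges(gene, data=True)
        ]
        drugs = sorted({u for u, _ in incoming})
        tiers = sorted({f"{data['source']}:{data['tier']}" for _, data in incoming})
        rows.append(
            {
                "gene": gene,
                "direction": d.get("direction", ""),
                "role": d.get("role", ""),
                "meta_pathway_count": d.get("meta_pathway_count", 0),
                "n_drugs": len(drugs),
                "drugs": ",".join(drugs),
                "tiers": ",".join(tiers),
                "n_prioritized": sum(data["prioritized"] for _, data in incoming),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["gene", "direction", "role", "meta_pathway_count",
                 "n_drugs", "drugs", "tiers", "n_prioritized"],
    )
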