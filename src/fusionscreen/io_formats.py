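"""Readers, writers and validated containers for every external format the pipeline touches.

All tabular formats are plain TSV; gene sets are GMT; networks are exported as
Cytoscape-style SIF plus node/edge attribute tables.  Gene identifiers are
opaque, case-sensitive strings.  TCGA-style composite ``SYMBOL|EntrezID``
identifiers are split on the first ``|`` and the symbol is kept as the primary
key.  Missing clinical values may be encoded as an empty string or ``NA``.

The drug-knowledgebase dialects are frozen, minimal schemas (the live CIViC and
OncoKB downloads drift between releases):

civic (tab-separated, header required)
    gene, drugs, drug_interaction_type, evidence_level, gene_role, disease
    ``drugs`` may hold several comma-separated drug names (one evidence row is
    expanded to one record per drug); ``evidence_level`` is one of A-E.

oncokb (tab-separated, header required)
    gene, drugs, drug_interaction_type, level, gene_role, cancer_type
    ``level`` is one of 1-4.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ExpressionMatrix",
    "SampleTable",
    "FusionCallSet",
    "Pathway",
    "PathwayDB",
    "DrugEvidence",
    "CancerGeneList",
    "read_expression",
    "write_expression",
    "read_metadata",
    "write_metadata",
    "read_fusions",
    "write_fusions",
    "read_gmt",
    "write_gmt",
    "read_meta_map",
    "write_meta_map",
    "read_gene_list",
    "write_gene_list",
    "read_drug_kb",
    "write_drug_kb",
    "write_network",
    "read_network",
]


class FormatError(ValueError):
    """A file violated its documented dialect; message carries the location."""


# ---------------------------------------------------------------------------
# controlled vocabularies
# ---------------------------------------------------------------------------

SAMPLE_TYPES = ("tumor", "normal", "metastasis")
SEX_VALUES = ("male", "female")
VITAL_VALUES = ("alive", "dead")
STAGE_VALUES = ("I", "II", "III", "IV")
MSI_VALUES = ("MSI-high", "MSI-low", "MSS")
HISTOLOGY_VALUES = ("adenocarcinoma", "mucinous_adenocarcinoma")
MUTATION_VALUES = ("mut", "wt")
MUTATION_FLAGS = ("tp53_mut", "kras_mut", "pik3ca_mut", "pten_mut", "braf_mut")

INTERACTIONS = ("inhibits", "activates", "other")
GENE_ROLES = ("oncogene", "tumor_suppressor", "both", "unknown")
CIVIC_TIERS = ("A", "B", "C", "D", "E")
ONCOKB_TIERS = ("1", "2", "3", "4")
DRUG_DELIMITER = ","

_MISSING = ("", "NA")

_METADATA_VOCAB = {
    "sample_type": SAMPLE_TYPES,
    "sex": SEX_VALUES,
    "vital_status": VITAL_VALUES,
    "stage": STAGE_VALUES,
    "msi_status": MSI_VALUES,
    "histology": HISTOLOGY_VALUES,
    **{flag: MUTATION_VALUES for flag in MUTATION_FLAGS},
}


def _is_missing(value) -> bool:
    return pd.isna(value) or (isinstance(value, str) and value.strip() in _MISSING)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpressionMatrix:
    """Gene x sample matrix of non-negative normalized expression values.

    ``data`` is a pandas DataFrame with unique gene identifiers in the index
    and unique sample identifiers in the columns; every value is finite and
    non-negative (RSEM-style normalized counts).
    """

    data: pd.DataFrame

    def __post_init__(self):
        df = self.data
        if df.index.has_duplicates:
            dups = sorted(df.index[df.index.duplicated()].unique())
            raise FormatError(f"duplicate gene IDs: {dups[:5]}")
        if df.columns.has_duplicates:
            dups = sorted(df.columns[df.columns.duplicated()].unique())
            raise FormatError(f"duplicate sample IDs: {dups[:5]}")
        values = df.to_numpy()
        if values.size == 0:
            raise FormatError("empty expression matrix")
        if not np.issubdtype(values.dtype, np.number):
            raise FormatError("non-numeric expression values")
        bad = ~np.isfinite(values) | (values < 0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise FormatError(
                f"negative or non-finite value at gene {df.index[i]!r}, "
                f"sample {df.columns[j]!r}: {values[i, j]}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def gene(self, gene_id: str) -> np.ndarray:
        """Expression vector of one gene across all samples."""
        if gene_id not in self.data.index:
            raise KeyError(f"gene {gene_id!r} not in expression matrix")
        return self.data.loc[gene_id].to_numpy(dtype=float)

    def subset(self, genes: Sequence[str] | None = None,
               samples: Sequence[str] | None = None) -> "ExpressionMatrix":
        df = self.data
        if genes is not None:
            missing = [g for g in genes if g not in df.index]
            if missing:
                raise KeyError(f"genes not in matrix: {missing[:5]}")
            df = df.loc[list(genes)]
        if samples is not None:
            missing = [s for s in samples if s not in df.columns]
            if missing:
                raise KeyError(f"samples not in matrix: {missing[:5]}")
            df = df[list(samples)]
        return ExpressionMatrix(df)


@dataclass(frozen=True)
class SampleTable:
    """Per-sample clinical metadata; any field other than the ID may be missing."""

    data: pd.DataFrame  # indexed by sample_id

    def __post_init__(self):
        df = self.data
        if df.index.has_duplicates:
            dups = sorted(df.index[df.index.duplicated()].unique())
            raise FormatError(f"duplicate sample IDs in metadata: {dups[:5]}")
        for col, vocab in _METADATA_VOCAB.items():
            if col not in df.columns:
                continue
            for sid, value in df[col].items():
                if _is_missing(value):
                    continue
                if str(value) not in vocab:
                    raise FormatError(
                        f"metadata column {col!r}, sample {sid!r}: value "
                        f"{value!r} not in vocabulary {vocab}"
                    )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def column(self, name: str) -> pd.Series:
        if name not in self.data.columns:
            raise KeyError(f"metadata has no column {name!r}")
        ser = self.data[name]
        mask = ser.map(_is_missing)
        return ser.mask(mask)


@dataclass(frozen=True)
class FusionCallSet:
    """Rows of (sample_id, gene_5prime, gene_3prime); duplicates rejected."""

    data: pd.DataFrame

    def __post_init__(self):
        df = self.data
        required = ["sample_id", "gene_5prime", "gene_3prime"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise FormatError(f"fusion table missing columns {missing}")
        if df.duplicated(subset=required).any():
            dup = df[df.duplicated(subset=required)].iloc[0]
            raise FormatError(
                "duplicate fusion row "
                f"({dup.sample_id}, {dup.gene_5prime}, {dup.gene_3prime})"
            )

    def samples_with_pair(self, pair: tuple[str, str]) -> list[str]:
        five, three = pair
        df = self.data
        hit = df[(df.gene_5prime == five) & (df.gene_3prime == three)]
        return list(dict.fromkeys(hit.sample_id))


@dataclass(frozen=True)
class Pathway:
    pathway_id: str
    source_label: str
    genes: frozenset[str]


@dataclass(frozen=True)
class PathwayDB:
    """Ordered collection of named gene sets with unique pathway IDs."""

    pathways: tuple[Pathway, ...]

    def __post_init__(self):
        seen = set()
        for p in self.pathways:
            if p.pathway_id in seen:
                raise FormatError(f"duplicate pathway ID {p.pathway_id!r}")
            seen.add(p.pathway_id)
            if not p.genes:
                raise FormatError(f"pathway {p.pathway_id!r} has an empty gene set")

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self):
        return iter(self.pathways)

    @property
    def pathway_ids(self) -> list[str]:
        return [p.pathway_id for p in self.pathways]

    def __getitem__(self, pathway_id: str) -> Pathway:
        for p in self.pathways:
            if p.pathway_id == pathway_id:
                return p
        raise KeyError(pathway_id)

    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for p in self.pathways:
            out |= p.genes
        return frozenset(out)


@dataclass(frozen=True)
class DrugEvidence:
    """One drug-gene relation from a knowledgebase, after multi-drug expansion."""

    gene: str
    drug: str
    interaction: str  # inhibits / activates / other
    tier: str         # CIViC A-E or OncoKB 1-4
    source: str       # "civic" or "oncokb"
    gene_role: str = "unknown"
    disease: str = ""

    def __post_init__(self):
        if not self.gene:
            raise FormatError("drug evidence with empty gene")
        if self.interaction not in INTERACTIONS:
            raise FormatError(
                f"gene {self.gene!r}: interaction {self.interaction!r} not in {INTERACTIONS}"
            )
        valid = CIVIC_TIERS if self.source == "civic" else ONCOKB_TIERS
        if self.source not in ("civic", "oncokb"):
            raise FormatError(f"unknown evidence source {self.source!r}")
        if self.tier not in valid:
            raise FormatError(
                f"gene {self.gene!r}: {self.source} tier {self.tier!r} not in {valid}"
            )
        if self.gene_role not in GENE_ROLES:
            raise FormatError(
                f"gene {self.gene!r}: role {self.gene_role!r} not in {GENE_ROLES}"
            )


@dataclass(frozen=True)
class CancerGeneList:
    """Census-style cancer gene list mapping gene symbol to role."""

    roles: Mapping[str, str]

    def __post_init__(self):
        for gene, role in self.roles.items():
            if role not in GENE_ROLES:
                raise FormatError(f"census gene {gene!r}: role {role!r} not in {GENE_ROLES}")

    def __contains__(self, gene: str) -> bool:
        return gene in self.roles

    def role_of(self, gene: str) -> str:
        return self.roles.get(gene, "unknown")

    @property
    def genes(self) -> list[str]:
        return list(self.roles)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def _split_composite_ids(index: pd.Index) -> pd.Index:
    # TCGA level-3 matrices use "SYMBOL|EntrezID"; keep the symbol.
    if not any("|" in str(g) for g in index):
        return index
    return pd.Index([str(g).split("|", 1)[0] for g in index], name=index.name)


def read_expression(path, genes_in_rows: bool = True) -> ExpressionMatrix:
    """Read a gene x sample TSV (first column gene IDs, header row of samples).

    ``genes_in_rows=False`` accepts the transposed, samples-in-rows layout.
    Composite ``SYMBOL|EntrezID`` gene identifiers are reduced to the symbol.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty expression file") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise FormatError(f"{path}: expression file has no data rows/columns")
    if not genes_in_rows:
        df = df.T
    df.index = _split_composite_ids(df.index.astype(str))
    df.columns = df.columns.astype(str)
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            gene = bad.index[0] if len(bad) else "?"
            raise FormatError(
                f"{path}: non-numeric value in sample column {col!r} at gene {gene!r}"
            )
    try:
        return ExpressionMatrix(df.astype(float))
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_expression(matrix: ExpressionMatrix, path) -> None:
    df = matrix.data.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.6f")


# ---------------------------------------------------------------------------
# metadata / fusions
# ---------------------------------------------------------------------------


def read_metadata(path) -> SampleTable:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty metadata file") from exc
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: metadata missing mandatory column 'sample_id'")
    df = df.set_index("sample_id")
    try:
        return SampleTable(df)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_metadata(table: SampleTable, path) -> None:
    df = table.data.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_fusions(path) -> FusionCallSet:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty fusion file") from exc
    try:
        return FusionCallSet(df)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_fusions(calls: FusionCallSet, path) -> None:
    calls.data.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------


def read_gmt(path) -> PathwayDB:
    """Read a GMT file: name <TAB> description <TAB> gene1 <TAB> gene2 ..."""
    path = Path(path)
    pathways: list[Pathway] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name, description and >=1 gene"
                )
            name, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if not genes:
                raise FormatError(f"{path}:{lineno}: pathway {name!r} has no genes")
            pathways.append(Pathway(name, desc, frozenset(genes)))
    if not pathways:
        raise FormatError(f"{path}: empty GMT file")
    try:
        return PathwayDB(tuple(pathways))
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_gmt(db: PathwayDB, path) -> None:
    with open(path, "w") as handle:
        for p in db:
            genes = "\t".join(sorted(p.genes))
            handle.write(f"{p.pathway_id}\t{p.source_label}\t{genes}\n")


def read_meta_map(path) -> dict[str, frozenset[str]]:
    """Read a two-column TSV (meta_pathway, pathway_id) into a mapping."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("meta_pathway", "pathway_id"):
        if col not in df.columns:
            raise FormatError(f"{path}: meta map missing column {col!r}")
    out: dict[str, set[str]] = {}
    for _, row in df.iterrows():
        out.setdefault(row.meta_pathway, set()).add(row.pathway_id)
    return {name: frozenset(ids) for name, ids in out.items()}


def write_meta_map(meta_map: Mapping[str, Iterable[str]], path) -> None:
    rows = [
        {"meta_pathway": name, "pathway_id": pid}
        for name in sorted(meta_map)
        for pid in sorted(meta_map[name])
    ]
    pd.DataFrame(rows, columns=["meta_pathway", "pathway_id"]).to_csv(
        path, sep="\t", index=False
    )


def read_gene_list(path) -> CancerGeneList:
    """Read a census-style TSV with columns gene, role."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("gene", "role"):
        if col not in df.columns:
            raise FormatError(f"{path}: gene list missing column {col!r}")
    if df.gene.duplicated().any():
        dup = df.gene[df.gene.duplicated()].iloc[0]
        raise FormatError(f"{path}: duplicate census gene {dup!r}")
    roles = {
        row.gene: (row.role if not _is_missing(row.role) else "unknown")
        for row in df.itertuples()
    }
    try:
        return CancerGeneList(roles)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_gene_list(census: CancerGeneList, path) -> None:
    df = pd.DataFrame(
        [{"gene": g, "role": census.roles[g]} for g in census.genes],
        columns=["gene", "role"],
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# drug knowledgebases
# ---------------------------------------------------------------------------

_KB_COLUMNS = {
    "civic": ("gene", "drugs", "drug_interaction_type", "evidence_level",
              "gene_role", "disease"),
    "oncokb": ("gene", "drugs", "drug_interaction_type", "level",
               "gene_role", "cancer_type"),
}


def read_drug_kb(path, dialect: str) -> list[DrugEvidence]:
    """Read a knowledgebase TSV in the 'civic' or 'oncokb' dialect.

    Multi-drug cells are split on commas, producing one evidence record per
    drug.  Tiers outside each source's controlled set are rejected.
    """
    if dialect not in _KB_COLUMNS:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'civic' or 'oncokb'")
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty knowledgebase file") from exc
    required = _KB_COLUMNS[dialect]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: {dialect} table missing columns {missing}")
    tier_col = "evidence_level" if dialect == "civic" else "level"
    disease_col = "disease" if dialect == "civic" else "cancer_type"
    records: list[DrugEvidence] = []
    for lineno, row in enumerate(df.itertuples(), start=2):
        drugs = [d.strip() for d in getattr(row, "drugs").split(DRUG_DELIMITER)]
        drugs = [d for d in drugs if d]
        if not drugs:
            raise FormatError(f"{path}:{lineno}: row for gene {row.gene!r} lists no drug")
        role = getattr(row, "gene_role")
        try:
            for drug in drugs:
                records.append(
                    DrugEvidence(
                        gene=row.gene,
                        drug=drug,
                        interaction=getattr(row, "drug_interaction_type"),
                        tier=getattr(row, tier_col),
                        source=dialect,
                        gene_role=role if not _is_missing(role) else "unknown",
                        disease=getattr(row, disease_col),
                    )
                )
        except FormatError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return records


def write_drug_kb(records: Sequence[DrugEvidence], path, dialect: str) -> None:
    """Write evidence records (one drug per record, not re-grouped) as TSV."""
    if dialect not in _KB_COLUMNS:
        raise ValueError(f"unknown dialect {dialect!r}")
    tier_col = "evidence_level" if dialect == "civic" else "level"
    disease_col = "disease" if dialect == "civic" else "cancer_type"
    rows = [
        {
            "gene": r.gene,
            "drugs": r.drug,
            "drug_interaction_type": r.interaction,
            tier_col: r.tier,
            "gene_role": r.gene_role,
            disease_col: r.disease,
        }
        for r in records
        if r.source == dialect
    ]
    pd.DataFrame(rows, columns=list(_KB_COLUMNS[dialect])).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# network export (SIF + attribute tables)
# ---------------------------------------------------------------------------

_NODE_COLUMNS = ["node", "node_type", "direction", "role", "meta_pathway_count",
                 "best_tier_civic", "best_tier_oncokb"]
_EDGE_COLUMNS = ["drug", "interaction", "gene", "tier", "source",
                 "prioritized", "rationale"]


def write_network(network, path_prefix) -> dict[str, Path]:
    """Write a drug-target network as SIF plus node/edge attribute TSVs.

    ``network`` is any object exposing ``nodes_frame()`` and ``edges_frame()``
    with the documented columns (see :class:`fusionscreen.drug_network.DrugTargetNetwork`).
    Returns the mapping of file kind to written path.
    """
    prefix = Path(path_prefix)
    nodes = network.nodes_frame().reindex(columns=_NODE_COLUMNS)
    edges = network.edges_frame().reindex(columns=_EDGE_COLUMNS)
    sif_path = prefix.with_name(prefix.name + ".sif")
    with open(sif_path, "w") as handle:
        for row in edges.itertuples():
            handle.write(f"{row.drug}\t{row.interaction}\t{row.gene}\n")
    nodes_path = prefix.with_name(prefix.name + "_nodes.tsv")
    edges_path = prefix.with_name(prefix.name + "_edges.tsv")
    nodes.to_csv(nodes_path, sep="\t", index=False)
    edges.to_csv(edges_path, sep="\t", index=False)
    return {"sif": sif_path, "nodes": nodes_path, "edges": edges_path}


def read_network(path_prefix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Re-read a written network; returns (edges, nodes) attribute frames."""
    prefix = Path(path_prefix)
    edges = pd.read_csv(prefix.with_name(prefix.name + "_edges.tsv"), sep="\t",
                        dtype={"prioritized": bool}, keep_default_na=False)
    nodes = pd.read_csv(prefix.with_name(prefix.name + "_nodes.tsv"), sep="\t",
                        keep_default_na=False)
    sif_path = prefix.with_name(prefix.name + ".sif")
    sif_edges = set()
    with open(sif_path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(f"{sif_path}: malformed SIF line {line!r}")
            sif_edges.add(tuple(parts))
    table_edges = {(r.drug, r.interaction, r.gene) for r in edges.itertuples()}
    if sif_edges != table_edges:
        raise FormatError(f"{sif_path}: SIF and edge-attribute table disagree")
    return edges, nodes
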