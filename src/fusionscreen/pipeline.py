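"""End-to-end orchestration: one config, deterministic seeding, run manifest.

``run_all`` executes cohort construction -> correlation screen -> permutation
calibration -> pathway enrichment -> drug network, writing every stage output
as TSV under the output directory plus a ``manifest.json`` recording the
package version, the derived stage seeds, SHA-256 checksums of every output
file, and the stage funnel counts (samples kept, cases, pool size, genes
selected, pathways significant, genes matched, edges prioritized).

Inputs come either from files (expression, metadata, fusions, GMT, meta map,
census, civic, oncokb) or from a ``simulate`` block holding synthetic-cohort
parameters; exactly one of the two must be present.  One master seed
deterministically derives all stage seeds, so two runs with the same config
are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from . import __version__
from . import cohort as cohort_mod
from . import correlation_screen as screen_mod
from . import drug_network as drug_mod
from . import enrichment as enrich_mod
from . import io_formats as io
from . import synthetic_data as sim_mod

__all__ = ["PipelineConfig", "ConfigError", "load_config", "run_all"]

logger = logging.getLogger(__name__)

_INPUT_KEYS = ("expression", "metadata", "fusions", "gmt", "meta_map",
               "census", "civic", "oncokb")
_STAGES = ("simulate", "cohort", "screen", "calibrate", "enrich", "drugs")


class ConfigError(ValueError):
    """The pipeline configuration is invalid; message names the field."""


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a full pipeline run needs.

    The fixed analysis constants live here as defaults and are never
    hard-coded in stage code: selection cutoff R = 0.2, key-gene cutoff
    R = 0.3, good-correlation tier report at R = 0.5, enrichment q < 0.05,
    100 resamples of 50 controls, 100,000 permutations in "full" mode.
    """

    seed: int = 0
    outdir: str = "out"
    reference_gene: str = "RSPO3"
    fusion_pair: tuple[str, str] = cohort_mod.DEFAULT_FUSION_PAIR
    transform: str = "none"
    selection_r: float = screen_mod.DEFAULT_CUTOFF
    key_r: float = enrich_mod.DEFAULT_KEY_R
    tier_r: float = 0.5
    q_threshold: float = enrich_mod.DEFAULT_Q_THRESHOLD
    n_resamples: int = 100
    control_size: int = 50
    n_permutations: int = 100_000
    permutation_mode: str = "full"
    cutoff_grid: tuple[float, ...] = screen_mod.DEFAULT_CUTOFF_GRID
    annotated_universe: bool = True
    inputs: Mapping[str, str] | None = None
    simulate: sim_mod.SimConfig | None = None

    def __post_init__(self):
        if (self.inputs is None) == (self.simulate is None):
            raise ConfigError(
                "config needs exactly one of 'inputs' (all file paths) or "
                "'simulate' (synthetic-cohort parameters)"
            )
        if self.inputs is not None:
            missing = [k for k in _INPUT_KEYS if k not in self.inputs]
            if missing:
                raise ConfigError(f"config 'inputs' missing paths: {missing}")
        for name in ("selection_r", "key_r", "tier_r", "q_threshold"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"config cutoff {name}={v} outside [0, 1]")
        if self.permutation_mode not in ("single", "full"):
            raise ConfigError(
                f"permutation_mode must be 'single' or 'full', got "
                f"{self.permutation_mode!r}"
            )

    def stage_seeds(self) -> dict[str, int]:
        """Derive one sub-seed per stage from the master seed."""
        ss = np.random.SeedSequence(self.seed)
        children = ss.spawn(len(_STAGES))
        return {
            stage: int(child.generate_state(1)[0] % (2**31))
            for stage, child in zip(_STAGES, children)
        }


def load_config(path) -> PipelineConfig:
    """Load a YAML pipeline config (documented schema, see README)."""
    with open(path) as handle:
        raw = yaml.safe_load(handle) or {}
    return config_from_dict(raw)


def config_from_dict(raw: Mapping[str, Any]) -> PipelineConfig:
    kwargs: dict[str, Any] = {}
    simple = {
        "seed", "outdir", "reference_gene", "transform", "selection_r",
        "key_r", "tier_r", "q_threshold", "n_resamples", "control_size",
        "n_permutations", "permutation_mode", "annotated_universe",
    }
    known = simple | {"fusion_pair", "cutoff_grid", "inputs", "simulate"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config fields: {sorted(unknown)}")
    for key in simple & set(raw):
        kwargs[key] = raw[key]
    if "fusion_pair" in raw:
        pair = tuple(raw["fusion_pair"])
        if len(pair) != 2:
            raise ConfigError("fusion_pair must list the 5' and 3' genes")
        kwargs["fusion_pair"] = pair
    if "cutoff_grid" in raw:
        kwargs["cutoff_grid"] = tuple(float(c) for c in raw["cutoff_grid"])
    if "inputs" in raw:
        kwargs["inputs"] = dict(raw["inputs"])
    if "simulate" in raw:
        sim_raw = dict(raw["simulate"] or {})
        for tup_key in ("module_sizes", "module_rhos", "cancer_gene_symbols"):
            if tup_key in sim_raw:
                sim_raw[tup_key] = tuple(sim_raw[tup_key])
        try:
            kwargs["simulate"] = sim_mod.SimConfig(**sim_raw)
        except TypeError as exc:
            raise ConfigError(f"bad simulate block: {exc}") from exc
    return PipelineConfig(**kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class StageError(RuntimeError):
    """A pipeline stage failed; message carries the stage name."""


def run_all(config: PipelineConfig) -> dict[str, Any]:
    """Run the whole pipeline; returns the manifest (also written to disk)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = config.stage_seeds()
    counts: dict[str, int] = {}
    outputs: dict[str, Path] = {}

    def emit(name: str, path: Path):
        outputs[name] = path

    stage = "inputs"
    try:
        if config.simulate is not None:
            stage = "simulate"
            sim_cfg = dataclasses.replace(config.simulate, seed=seeds["simulate"])
            cohort_data = sim_mod.generate_cohort(sim_cfg)
            expr = cohort_data.expression
            metadata = cohort_data.metadata
            fusions = cohort_data.fusion_calls
            planted = cohort_data.module_genes()
            pw = sim_mod.generate_pathway_db(
                n_pathways=50, genes=expr.gene_ids, planted=planted,
                seed=seeds["simulate"],
            )
            db, meta_map = pw.db, pw.meta_map
            civic, oncokb, census = sim_mod.generate_drug_kb(
                expr.gene_ids, seed=seeds["simulate"]
            )
            io.write_expression(expr, outdir / "expression.tsv")
            io.write_metadata(metadata, outdir / "metadata.tsv")
            io.write_fusions(fusions, outdir / "fusions.tsv")
            io.write_gmt(db, outdir / "pathways.gmt")
            io.write_meta_map(meta_map, outdir / "meta_map.tsv")
            io.write_gene_list(census, outdir / "census.tsv")
            io.write_drug_kb(civic, outdir / "civic.tsv", "civic")
            io.write_drug_kb(oncokb, outdir / "oncokb.tsv", "oncokb")
            cohort_data.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
            for name in ("expression", "metadata", "fusions", "truth"):
                emit(name, outdir / f"{name}.tsv")
            emit("pathways", outdir / "pathways.gmt")
            for name in ("meta_map", "census", "civic", "oncokb"):
                emit(name, outdir / f"{name}.tsv")
        else:
            paths = config.inputs
            expr = io.read_expression(paths["expression"])
            metadata = io.read_metadata(paths["metadata"])
            fusions = io.read_fusions(paths["fusions"])
            db = io.read_gmt(paths["gmt"])
            meta_map = io.read_meta_map(paths["meta_map"])
            census = io.read_gene_list(paths["census"])
            civic = io.read_drug_kb(paths["civic"], "civic")
            oncokb = io.read_drug_kb(paths["oncokb"], "oncokb")

        stage = "cohort"
        tumor_ids = cohort_mod.filter_tumor_samples(metadata)
        counts["samples_total"] = len(metadata.sample_ids)
        counts["tumor_samples"] = len(tumor_ids)
        case_ids = cohort_mod.select_cases(
            fusions, expr, config.reference_gene, tumor_ids,
            pair=config.fusion_pair,
        )
        counts["cases"] = len(case_ids)
        pool = cohort_mod.build_control_pool(
            expr, tumor_ids, case_ids, config.reference_gene
        )
        counts["control_pool"] = len(pool)
        design = cohort_mod.draw_resamples(
            case_ids, pool, n_resamples=config.n_resamples,
            control_size=config.control_size, seed=seeds["cohort"],
        )
        design.write(outdir / "cohort_design.tsv")
        emit("cohort_design", outdir / "cohort_design.tsv")
        clinical = cohort_mod.clinical_comparison(metadata, case_ids, pool)
        clinical.to_csv(outdir / "clinical_comparison.tsv", sep="\t", index=False)
        emit("clinical_comparison", outdir / "clinical_comparison.tsv")

        stage = "screen"
        result = screen_mod.run_screen(
            expr, design, config.reference_gene,
            transform=config.transform, cutoff=config.selection_r,
        )
        result.write(outdir / "screen.tsv")
        emit("screen", outdir / "screen.tsv")
        selected = screen_mod.select_genes(result.records, config.selection_r)
        counts["genes_screened"] = len(result.records)
        counts["genes_selected"] = len(selected)
        counts["genes_good_correlation"] = len(
            screen_mod.select_genes(result.records, config.tier_r)
        )
        z = screen_mod.zscore_matrix(
            expr, genes=selected, samples=list(design.case_ids) + list(pool)
        )
        z.to_csv(outdir / "zscores.tsv", sep="\t", float_format="%.4f")
        emit("zscores", outdir / "zscores.tsv")

        stage = "calibrate"
        curve = screen_mod.calibrate_cutoff(
            expr, design, config.reference_gene,
            n_permutations=config.n_permutations,
            cutoffs=config.cutoff_grid, mode=config.permutation_mode,
            seed=seeds["calibrate"], transform=config.transform,
        )
        curve.write(outdir / "calibration.tsv")
        emit("calibration", outdir / "calibration.tsv")

        stage = "enrich"
        universe = enrich_mod.build_universe(
            expr.gene_ids, db, annotated_only=config.annotated_universe
        )
        query = frozenset(selected) & universe
        records = enrich_mod.ora_hypergeometric(query, db, universe)
        collapse = enrich_mod.collapse_to_meta(
            records, meta_map, db, query, q_threshold=config.q_threshold
        )
        pathway_to_meta = {
            pid: name for name, pids in meta_map.items() for pid in pids
        }
        records["meta_pathway"] = records.pathway_id.map(pathway_to_meta)
        records.to_csv(outdir / "enrichment.tsv", sep="\t", index=False,
                       float_format="%.6g")
        emit("enrichment", outdir / "enrichment.tsv")
        counts["pathways_tested"] = len(records)
        counts["pathways_significant"] = len(collapse.significant_ids)
        counts["component_genes"] = len(collapse.component_genes)
        annotations = enrich_mod.annotate_genes(
            collapse.component_genes, census, result.records,
            collapse.meta_sets, key_r_threshold=config.key_r,
        )
        annotations.to_csv(outdir / "gene_annotations.tsv", sep="\t",
                           index=False, float_format="%.6f")
        emit("gene_annotations", outdir / "gene_annotations.tsv")
        counts["census_genes"] = int(annotations.is_cancer_gene.sum())
        counts["key_genes"] = int(annotations.key_gene.sum())
        long = collapse.long_table()
        direction_of = dict(zip(annotations.gene, annotations.direction))
        long["direction"] = long.gene.map(direction_of)
        long.to_csv(outdir / "meta_pathway_genes.tsv", sep="\t", index=False)
        emit("meta_pathway_genes", outdir / "meta_pathway_genes.tsv")
        colored = annotations[["gene", "direction"]]
        colored.to_csv(outdir / "colored_gene_list.tsv", sep="\t", index=False)
        emit("colored_gene_list", outdir / "colored_gene_list.tsv")

        stage = "drugs"
        matched, side_report = drug_mod.match_actionable(annotations, civic, oncokb)
        network = drug_mod.build_network(matched, annotations, census)
        written = io.write_network(network, outdir / "drug_network")
        for kind, path in written.items():
            emit(f"network_{kind}", path)
        side_report.to_csv(outdir / "undruggable_genes.tsv", sep="\t", index=False)
        emit("undruggable_genes", outdir / "undruggable_genes.tsv")
        report = drug_mod.druggability_report(network)
        report.to_csv(outdir / "druggability_report.tsv", sep="\t", index=False)
        emit("druggability_report", outdir / "druggability_report.tsv")
        counts["genes_matched"] = len(network.gene_nodes)
        counts["drugs"] = len(network.drug_nodes)
        counts["edges"] = network.graph.number_of_edges()
        counts["edges_prioritized"] = network.n_prioritized
    except (ConfigError,) as exc:
        raise
    except Exception as exc:
        raise StageError(f"stage {stage!r} failed: {exc}") from exc

    for name, value in counts.items():
        logger.info("%s = %d", name, value)
    manifest = {
        "package": "fusionscreen",
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "counts": counts,
        "outputs": {
            name: {"path": str(path.relative_to(outdir)), "sha256": _sha256(path)}
            for name, path in sorted(outputs.items())
        },
    }
    with open(outdir / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
        handle.write("\n")
    return manifest
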