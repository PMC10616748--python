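"""End-to-end orchestration: QC → normalization → imputation → SVA →
rank-product DE (two contrasts) → signature intersection → PPI disease
module → consensus miRNA targets → over-representation.

One YAML config is the single source of truth; every random stage records
its seed, and the machine-readable RunReport carries per-stage record
counts (the feature funnel), module statistics and target statistics.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .de_analysis import (
    estimate_surrogate_variables,
    fold_change_ct,
    intersect_signatures,
    rank_product_test,
    remove_unwanted_variation,
    significant_features,
    write_signature_tsv,
)
from .enrichment import hypergeometric_enrichment, attribute_enrichment, read_attribute_tsv, read_gmt
from .mirna_targets import aggregate_targets, map_targets_to_module, read_rank_tables, target_subnetwork
from .network_module import (
    extract_lcc,
    map_gene_set,
    module_coherence,
    node_centrality,
    ppi_enrichment,
    read_gene_list,
    read_interactome,
    write_components_tsv,
    write_module_graphml,
    write_module_stats_json,
)
from .qc_normalize import (
    apply_detection_filter,
    filter_by_missingness,
    hemolysis_assess,
    impute_bpca,
    quantile_normalize,
    read_ct_csv,
    read_metadata_tsv,
    write_qc_report,
)
from .synthetic_data import MIR23A_ID, MIR451A_ID

logger = logging.getLogger("premodmir")

__all__ = ["PipelineConfig", "RunReport", "PipelineError", "run_pipeline", "STAGES"]

STAGES = ("qc", "de", "module", "targets", "enrich")


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Paths, thresholds, sampling parameters and flags for a run."""

    # paths
    ct_matrix: str = ""
    metadata: str = ""
    interactome: str = ""
    rank_tables: str = ""
    gene_signature: str = ""
    gmt: str = ""
    attributes: str = ""
    output_dir: str = "premodmir_out"
    # thresholds
    detection_ct: float = 30.0
    max_missing_fraction: float = 0.20
    hemolysis_possible: float = 5.0
    hemolysis_high: float = 7.0
    fdr: float = 0.05
    string_score: float = 0.4
    min_sources: int = 2
    z_cutoff: float = -1.65
    # sampling
    n_perm: int = 1000
    n_random: int = 1000
    n_sv: int | str = "auto"
    bpca_components: int | None = None
    max_comparisons: int = 50
    seed: int = 0
    # reference features for the haemolysis ΔCq
    mir23a_id: str = MIR23A_ID
    mir451a_id: str = MIR451A_ID
    # flags
    include_hemolysed: bool = False
    degree_matched_null: bool = False
    full_network_centrality: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    def validate(self) -> None:
        if self.detection_ct <= 0:
            raise ValueError("detection_ct must be positive")
        if not 0 <= self.max_missing_fraction <= 1:
            raise ValueError("max_missing_fraction must be in [0, 1]")
        if not 0 < self.fdr < 1:
            raise ValueError("fdr must be in (0, 1)")
        if self.hemolysis_possible > self.hemolysis_high:
            raise ValueError("hemolysis thresholds must satisfy possible <= high")
        if not 0 <= self.string_score < 1:
            raise ValueError("string_score must be in [0, 1)")
        if self.min_sources < 1:
            raise ValueError("min_sources must be >= 1")


@dataclass
class RunReport:
    """Machine-readable run summary (per-stage counts, seeds, versions)."""

    config: dict = field(default_factory=dict)
    stages: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    artifacts: list[str] = field(default_factory=list)
    version: str = __version__
    wall_clock_s: float = 0.0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=_jsonify))


def _jsonify(o: Any):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (set, frozenset)):
        return sorted(o)
    raise TypeError(f"not JSON-serializable: {type(o)}")


def _require(paths: dict[str, str]) -> None:
    for label, p in paths.items():
        if not p:
            raise FileNotFoundError(f"config is missing the {label} path")
        if not Path(p).exists():
            raise FileNotFoundError(f"{label} file not found: {p}")


def run_pipeline(config: PipelineConfig, stages: Sequence[str] | None = None) -> RunReport:
    """Execute the analysis (or a prefix/subset of its stages).

    ``stages`` defaults to all of ``STAGES``; dependencies are resolved
    implicitly (``de`` implies ``qc``; ``targets`` implies everything up
    to ``module``). On failure a :class:`PipelineError` names the failed
    stage, and the partial run report is preserved with a ``.partial``
    suffix.
    """
    config.validate()
    requested = set(STAGES if stages is None else stages)
    unknown = requested - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    # dependency closure
    if "enrich" in requested:
        requested |= {"module"}
    if "targets" in requested:
        requested |= {"qc", "de", "module"}
    if "de" in requested:
        requested |= {"qc"}

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=asdict(config))
    report.seeds = {"pipeline": config.seed}
    t0 = time.perf_counter()

    state: dict[str, Any] = {}
    order = [s for s in STAGES if s in requested]
    try:
        for stage in order:
            logger.info("stage %s: start", stage)
            _STAGE_FUNCS[stage](config, state, report, out)
            logger.info("stage %s: done", stage)
    except Exception as exc:  # noqa: BLE001
        report.wall_clock_s = time.perf_counter() - t0
        report.to_json(out / "run_report.partial.json")
        raise PipelineError(stage, exc) from exc

    report.wall_clock_s = time.perf_counter() - t0
    report.to_json(out / "run_report.json")
    report.artifacts.append(str(out / "run_report.json"))
    return report


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_qc(config: PipelineConfig, state: dict, report: RunReport, out: Path) -> None:
    _require({"ct_matrix": config.ct_matrix, "metadata": config.metadata})
    meta = read_metadata_tsv(config.metadata)
    ct = read_ct_csv(config.ct_matrix, metadata=meta)
    n0 = ct.n_features

    ct = apply_detection_filter(ct, threshold=config.detection_ct)
    hem = hemolysis_assess(
        ct,
        config.mir23a_id,
        config.mir451a_id,
        possible_threshold=config.hemolysis_possible,
        high_threshold=config.hemolysis_high,
    )
    excluded = [] if config.include_hemolysed else hem.excluded_samples
    if excluded:
        ct = ct.drop_samples(excluded)
    miss = filter_by_missingness(ct, config.max_missing_fraction)
    ct = miss.matrix
    write_qc_report(out / "qc_report.json", hem, miss)

    ct = quantile_normalize(ct)
    ct = impute_bpca(ct, n_components=config.bpca_components, seed=config.seed)
    ct.to_csv(out / "processed_matrix.csv")

    state["ct"] = ct
    report.stages["qc"] = {
        "features_in": n0,
        "features_after_missingness": ct.n_features,
        "features_dropped": len(miss.dropped_ids),
        "samples_in": len(meta),
        "samples_excluded_hemolysis": len(excluded),
        "samples_out": ct.n_samples,
        "hemolysis_excluded_ids": excluded,
    }
    report.artifacts += [str(out / "qc_report.json"), str(out / "processed_matrix.csv")]


def _de_contrast(config: PipelineConfig, ct, labels: pd.Series, case_label: str,
                 protect: pd.DataFrame | None, seed: int):
    svs = estimate_surrogate_variables(
        ct, labels, protect=protect, n_sv=config.n_sv, seed=seed
    )
    adjusted_ct = remove_unwanted_variation(ct, svs, protect=protect, primary=labels)
    fc = fold_change_ct(adjusted_ct, labels, case_label=case_label)
    de = rank_product_test(
        -adjusted_ct,  # expression scale: lower Ct = higher abundance
        labels,
        n_perm=config.n_perm,
        seed=seed,
        case_label=case_label,
        max_comparisons=config.max_comparisons,
        fold_change=fc,
    )
    return svs, de, significant_features(de, fdr=config.fdr)


def _stage_de(config: PipelineConfig, state: dict, report: RunReport, out: Path) -> None:
    ct = state["ct"]
    meta = ct.metadata
    if meta is None or "group" not in meta.columns:
        raise ValueError("metadata must provide a 'group' column (case/control)")
    protect = meta[["arm"]] if "arm" in meta.columns else None

    svs_pe, de_pe, sig_pe = _de_contrast(
        config, ct, meta["group"], "case", protect, config.seed
    )
    report.seeds["de_pe"] = config.seed
    sig_vitd = None
    if "vitd" in meta.columns and meta["vitd"].nunique() == 2:
        svs_vd, de_vd, sig_vitd = _de_contrast(
            config, ct, meta["vitd"], "insufficient", protect, config.seed + 1
        )
        report.seeds["de_vitd"] = config.seed + 1
        intersection = intersect_signatures(sig_pe, sig_vitd)
    else:
        intersection = sig_pe.assign(direction_a=sig_pe.get("direction"))

    write_signature_tsv(sig_pe, out / "signature_pe.tsv")
    de_pe.to_json(out / "de_pe.json")
    if sig_vitd is not None:
        write_signature_tsv(sig_vitd, out / "signature_vitd.tsv")
        de_vd.to_json(out / "de_vitd.json")
    intersection.to_csv(out / "signature_intersection.tsv", sep="\t", index=False)

    state["sig_pe"] = sig_pe
    state["sig_vitd"] = sig_vitd
    state["intersection"] = intersection
    report.stages["de"] = {
        "n_sv_pe": svs_pe.n_sv,
        "n_de_pe": len(sig_pe),
        "n_de_vitd": None if sig_vitd is None else len(sig_vitd),
        "n_intersection": len(intersection),
        "n_permutations": config.n_perm,
    }
    report.artifacts += [str(out / "signature_pe.tsv"), str(out / "signature_intersection.tsv")]


def _stage_module(config: PipelineConfig, state: dict, report: RunReport, out: Path) -> None:
    _require({"interactome": config.interactome, "gene_signature": config.gene_signature})
    net = read_interactome(config.interactome, min_score=config.string_score)
    genes = read_gene_list(config.gene_signature)
    module = map_gene_set(net, genes)
    module.enrichment = ppi_enrichment(
        net, module.mapped_genes, n_random=config.n_random, seed=config.seed,
        degree_matched=config.degree_matched_null,
    )
    module = extract_lcc(net, module)
    module.coherence = module_coherence(
        net, module.mapped_genes, n_random=config.n_random, seed=config.seed,
        degree_matched=config.degree_matched_null,
    )
    scope = "network" if config.full_network_centrality else "module"
    module.centrality = node_centrality(net, module.mapped_genes, scope=scope)

    write_module_graphml(net, module, out / "module.graphml")
    write_components_tsv(module, out / "module_components.tsv")
    write_module_stats_json(module, out / "module_stats.json")

    state["net"] = net
    state["module"] = module
    report.seeds["module"] = config.seed
    report.stages["module"] = {
        "interactome_nodes": net.n_nodes,
        "interactome_edges": net.n_edges,
        "min_score": config.string_score,
        "n_query": len(module.query_genes),
        "n_mapped": len(module.mapped_genes),
        "n_lcc": len(module.lcc_members),
        "lcc_fraction": module.lcc_fraction,
        "n_peripheral_components": len(module.peripheral_components),
        "observed_edges": module.enrichment.observed_edges,
        "expected_edges": module.enrichment.expected_edges,
        "ppi_enrichment_p": module.enrichment.empirical_p,
        "coherence_z": module.coherence.z_score,
        "coherence_significant": module.coherence.significant,
    }
    report.artifacts += [
        str(out / "module.graphml"),
        str(out / "module_components.tsv"),
        str(out / "module_stats.json"),
    ]


def _stage_targets(config: PipelineConfig, state: dict, report: RunReport, out: Path) -> None:
    _require({"rank_tables": config.rank_tables})
    tables = read_rank_tables(config.rank_tables)
    targets = aggregate_targets(tables, min_sources=config.min_sources)
    targets.to_tsv(out / "consensus_targets.tsv")

    module = state["module"]
    intersection = state["intersection"]
    sig = intersection.rename(columns={"direction_a": "direction"})[["mirna", "direction"]] \
        if "direction_a" in intersection.columns else intersection[["mirna", "direction"]]
    mapped = map_targets_to_module(targets, module, sig)
    mapped.to_tsv(out / "module_targets.tsv")
    sub = target_subnetwork(
        state["net"], module, sorted(set(mapped.per_mirna["target"])) if len(mapped.per_mirna) else []
    )
    if sub.n_nodes:
        sub.write_graphml(out / "target_subnetwork.graphml")

    state["targets"] = targets
    state["module_targets"] = mapped
    state["target_subnetwork"] = sub
    report.stages["targets"] = {
        "n_consensus_pairs": len(targets.records),
        "n_signature_mirnas": len(sig),
        "n_missing_mirnas": len(mapped.missing_mirnas),
        **mapped.counts(),
        "subnetwork_size": sub.n_nodes,
        "subnetwork_hubs": sub.hubs[:5],
    }
    report.artifacts += [str(out / "consensus_targets.tsv"), str(out / "module_targets.tsv")]


def _stage_enrich(config: PipelineConfig, state: dict, report: RunReport, out: Path) -> None:
    _require({"gmt": config.gmt})
    module = state["module"]
    net = state["net"]
    universe = sorted(net.nodes)
    annotation = read_gmt(config.gmt)
    rows = hypergeometric_enrichment(
        module.lcc_members, annotation, universe, fdr_cutoff=config.fdr
    )
    rows.to_csv(out / "enrichment_lcc.tsv", sep="\t", index=False)
    stage: dict[str, Any] = {
        "n_sets_tested": len(rows),
        "n_significant": int(rows["significant"].sum()) if len(rows) else 0,
        "top_set": rows.iloc[0]["set_id"] if len(rows) else None,
    }
    if config.attributes:
        _require({"attributes": config.attributes})
        attr = read_attribute_tsv(config.attributes)
        frac, p = attribute_enrichment(module.mapped_genes, attr, universe)
        stage["attribute_fraction"] = frac
        stage["attribute_p"] = p
    report.stages["enrich"] = stage
    report.artifacts.append(str(out / "enrichment_lcc.tsv"))


_STAGE_FUNCS = {
    "qc": _stage_qc,
    "de": _stage_de,
    "module": _stage_module,
    "targets": _stage_targets,
    "enrich": _stage_enrich,
}
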