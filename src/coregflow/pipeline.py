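"""Pipeline orchestration: simulate -> infer -> integrate -> influence ->
differential -> enrich -> report, driven by one config mapping.

Every stage reads its inputs from, and writes its outputs to, a single
output directory, so stages are individually re-runnable and idempotent.
Identical config and seed produce byte-identical output directories: all
floats are serialized with a fixed format and no timestamps are written.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .differential import enrich_gene_sets, identify_degs, identify_dirs, read_gmt
from .evidence import IntegrationParams, evidence_enrichment_test, integrate_evidence
from .inference import infer_candidate_programs
from .influence import InfluenceMatrix, influence_matrix
from .io import (
    CoregflowError,
    EvidenceSet,
    ExpressionDataset,
    RegulatorCatalog,
    read_design,
    read_evidence,
    read_expression,
    read_network,
    read_regulators,
    write_evidence,
    write_expression,
    write_network,
)
from .reporting import (
    build_coreg_graph,
    export_graph,
    extract_regulatory_node,
    mean_group_influence,
    target_matrix,
)
from .simulate import SimulationConfig, simulate_dataset, simulate_reference

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineStageError", "run_pipeline"]

FLOAT_FMT = "%.10g"


class PipelineStageError(CoregflowError):
    """A stage failed; the message is prefixed with the stage name."""


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineStageError(f"[{name}] {exc}") from exc
            logger.info("stage=%s elapsed=%.2fs", name, time.perf_counter() - t0)
            return out

        wrapped.__name__ = fn.__name__
        return wrapped

    return deco


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------


def _from_mapping(cls, data: Mapping[str, Any], section: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise CoregflowError(f"unknown keys in section {section!r}: {sorted(unknown)}")
    kwargs = dict(data)
    for f in dataclasses.fields(cls):
        if f.name in kwargs and isinstance(kwargs[f.name], list) and isinstance(f.default, tuple):
            kwargs[f.name] = tuple(kwargs[f.name])
    return cls(**kwargs)


@dataclass(frozen=True)
class InferenceParams:
    min_support: float = 0.1
    max_set_size: int = 4
    z_threshold: float = 0.6
    max_programs_per_gene: int = 400
    fit_cutoff: float = 1.0
    allow_regulator_targets: bool = False
    min_coexpression: float = 0.09
    max_regulators_per_target: int = 6


@dataclass(frozen=True)
class InfluenceParams:
    min_targets: int = 5
    min_targets_mode: str = "combined"
    one_sided: str = "fallback"
    standardize: bool = True


@dataclass(frozen=True)
class DifferentialParams:
    adj_p_max: float = 0.05
    min_abs_delta: float = 0.5
    min_fold_change: float = 1.5


@dataclass(frozen=True)
class ReportParams:
    min_shared_targets: int = 1
    top_n_targets: int = 50


@dataclass(frozen=True)
class IoPaths:
    expression: str | None = None
    compendium: str | None = None
    design: str | None = None
    regulators: str | None = None
    tf_target_evidence: str | None = None
    ppi_evidence: str | None = None
    gene_sets: str | None = None  # GMT


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (unknown keys rejected)."""

    seed: int = 0
    simulate: bool = True
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    inference: InferenceParams = field(default_factory=InferenceParams)
    integration: IntegrationParams = field(default_factory=IntegrationParams)
    influence: InfluenceParams = field(default_factory=InfluenceParams)
    differential: DifferentialParams = field(default_factory=DifferentialParams)
    report: ReportParams = field(default_factory=ReportParams)
    contrasts: list[tuple[str, str]] = field(
        default_factory=lambda: [("baseline", "stimulated")]
    )
    io: IoPaths = field(default_factory=IoPaths)

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "PipelineConfig":
        allowed = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - allowed
        if unknown:
            raise CoregflowError(f"unknown config keys: {sorted(unknown)}")
        seed = int(data.get("seed", 0))
        sim_data = dict(data.get("simulation", {}))
        sim_data.setdefault("seed", seed)
        for k in ("edge_weight_range", "activators_per_target", "repressors_per_target"):
            if k in sim_data:
                sim_data[k] = tuple(sim_data[k])
        io_section = data.get("io", {}) or {}
        return cls(
            seed=seed,
            simulate=bool(data.get("simulate", io_section.get("expression") is None)),
            simulation=_from_mapping(SimulationConfig, sim_data, "simulation"),
            inference=_from_mapping(InferenceParams, data.get("inference", {}), "inference"),
            integration=_from_mapping(IntegrationParams, data.get("integration", {}), "integration"),
            influence=_from_mapping(InfluenceParams, data.get("influence", {}), "influence"),
            differential=_from_mapping(DifferentialParams, data.get("differential", {}), "differential"),
            report=_from_mapping(ReportParams, data.get("report", {}), "report"),
            contrasts=[tuple(c) for c in data.get("contrasts", [("baseline", "stimulated")])],
            io=_from_mapping(IoPaths, data.get("io", {}), "io"),
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["contrasts"] = [list(c) for c in self.contrasts]
        return d


# ---------------------------------------------------------------------------
# Stage functions (each reads/writes the output directory)
# ---------------------------------------------------------------------------


def _contrast_tag(cond_a: str, cond_b: str) -> str:
    safe = lambda s: s.replace("/", "_").replace(" ", "_")
    return f"{safe(cond_b)}_vs_{safe(cond_a)}"


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False, **kw) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT, index=index, **kw)


@_stage("simulate")
def stage_simulate(config: PipelineConfig, outdir: Path) -> None:
    ds, ev, truth = simulate_dataset(config.simulation)
    write_expression(ds, outdir / "expression.tsv")
    write_expression(simulate_reference(config.simulation), outdir / "compendium.tsv")
    design = pd.DataFrame(
        {"sample": ds.sample_ids, "condition": [ds.condition_of[s] for s in ds.sample_ids]}
    )
    _write_tsv(design, outdir / "design.tsv")
    (outdir / "regulators.txt").write_text(
        "".join(r + "\n" for r in truth.true_activity.index)
    )
    write_evidence(ev, outdir / "evidence_tf_target.tsv", outdir / "evidence_ppi.tsv")
    truth.to_json(outdir / "ground_truth.json")


def _load_inputs(
    config: PipelineConfig, outdir: Path
) -> tuple[ExpressionDataset, RegulatorCatalog, EvidenceSet]:
    io = config.io
    expr_path = io.expression or outdir / "expression.tsv"
    design_path = io.design or outdir / "design.tsv"
    reg_path = io.regulators or outdir / "regulators.txt"
    tf_path = io.tf_target_evidence or outdir / "evidence_tf_target.tsv"
    ppi_path = io.ppi_evidence or outdir / "evidence_ppi.tsv"
    expr = read_expression(expr_path, design_path, missing_policy="gene-mean")
    regulators = read_regulators(reg_path)
    evidence = read_evidence(
        tf_path if Path(tf_path).exists() else None,
        ppi_path if Path(ppi_path).exists() else None,
    )
    return expr, regulators, evidence


@_stage("infer")
def stage_infer(config: PipelineConfig, outdir: Path) -> None:
    # the reference network is inferred from the compendium when one is
    # available; the query dataset is only mapped onto it later
    expr, regulators, evidence = _load_inputs(config, outdir)
    comp_path = config.io.compendium or outdir / "compendium.tsv"
    if Path(comp_path).exists():
        expr = read_expression(comp_path, missing_policy="gene-mean")
    candidates = infer_candidate_programs(
        expr, regulators, **dataclasses.asdict(config.inference)
    )
    network = integrate_evidence(candidates, evidence, config.integration)
    write_network(network, outdir / "network.tsv")
    enrichment = {}
    for mode in ("ppi", "tfbs"):
        try:
            overlap, p = evidence_enrichment_test(network, evidence, mode)
            enrichment[mode] = {"overlap": overlap, "p_value": p}
        except CoregflowError as exc:
            enrichment[mode] = {"error": str(exc)}
    (outdir / "evidence_enrichment.json").write_text(
        json.dumps(enrichment, indent=1, sort_keys=True) + "\n"
    )


@_stage("influence")
def stage_influence(config: PipelineConfig, outdir: Path) -> None:
    expr, _, _ = _load_inputs(config, outdir)
    network = read_network(outdir / "network.tsv")
    infl = influence_matrix(expr, network, **dataclasses.asdict(config.influence))
    _write_tsv(infl.values, outdir / "influence.tsv", index=True, index_label="regulator")
    flags = pd.DataFrame(
        {"regulator": sorted(infl.flags), "flag": [infl.flags[r] for r in sorted(infl.flags)]}
    )
    _write_tsv(flags, outdir / "eligibility.tsv")


def _load_influence(outdir: Path) -> InfluenceMatrix:
    values = pd.read_csv(outdir / "influence.tsv", sep="\t", index_col=0)
    flags_df = pd.read_csv(outdir / "eligibility.tsv", sep="\t", dtype=str)
    flags = dict(zip(flags_df["regulator"], flags_df["flag"]))
    return InfluenceMatrix(values, flags)


@_stage("diff")
def stage_diff(config: PipelineConfig, outdir: Path) -> None:
    expr, _, _ = _load_inputs(config, outdir)
    infl = _load_influence(outdir)
    dp = config.differential
    for cond_a, cond_b in config.contrasts:
        tag = _contrast_tag(cond_a, cond_b)
        dirs = identify_dirs(
            infl, expr.condition_of, cond_a, cond_b,
            adj_p_max=dp.adj_p_max, min_abs_delta=dp.min_abs_delta,
        )
        _write_tsv(dirs, outdir / f"dirs_{tag}.tsv")
        degs = identify_degs(
            expr, cond_a, cond_b,
            adj_p_max=dp.adj_p_max, min_fold_change=dp.min_fold_change,
        )
        _write_tsv(degs, outdir / f"degs_{tag}.tsv")


@_stage("enrich")
def stage_enrich(config: PipelineConfig, outdir: Path) -> None:
    network = read_network(outdir / "network.tsv")
    if config.io.gene_sets:
        collections = read_gmt(config.io.gene_sets)
    else:
        # default: the network's own regulons as gene sets
        collections = {
            f"regulon:{r}": a | i
            for r, (a, i) in network.regulon_view().items()
            if len(a | i) >= 5
        }
    for cond_a, cond_b in config.contrasts:
        tag = _contrast_tag(cond_a, cond_b)
        degs = pd.read_csv(outdir / f"degs_{tag}.tsv", sep="\t")
        universe = set(degs["feature_id"])
        query = set(degs.loc[degs["class"].isin(("up", "down")), "feature_id"])
        if not query:
            _write_tsv(
                pd.DataFrame(
                    columns=["gene_set", "set_size", "overlap", "gene_ratio", "p_value", "adj_p"]
                ),
                outdir / f"enrichment_{tag}.tsv",
            )
            continue
        table = enrich_gene_sets(
            query, {k: v & universe for k, v in collections.items()}, universe
        )
        _write_tsv(table, outdir / f"enrichment_{tag}.tsv")


@_stage("report")
def stage_report(config: PipelineConfig, outdir: Path) -> None:
    expr, _, evidence = _load_inputs(config, outdir)
    network = read_network(outdir / "network.tsv")
    summary: dict[str, Any] = {"network": network.summary(), "contrasts": {}}
    for cond_a, cond_b in config.contrasts:
        tag = _contrast_tag(cond_a, cond_b)
        dirs = pd.read_csv(outdir / f"dirs_{tag}.tsv", sep="\t")
        degs = pd.read_csv(outdir / f"degs_{tag}.tsv", sep="\t")
        graph = build_coreg_graph(
            network, dirs, evidence, min_shared_targets=config.report.min_shared_targets
        )
        export_graph(graph, outdir / f"graph_{tag}.graphml", "graphml")
        export_graph(graph, outdir / f"graph_{tag}.sif", "sif")
        members, size = extract_regulatory_node(graph, "up")
        entry: dict[str, Any] = {
            "node_members": sorted(members),
            "node_size": size,
            "n_up": int((dirs["class"] == "up").sum()),
            "n_down": int((dirs["class"] == "down").sum()),
        }
        if members:
            entry["mean_group_influence"] = mean_group_influence(members, dirs)
            sub, directions = target_matrix(
                network, expr, degs, members, top_n=config.report.top_n_targets
            )
            _write_tsv(sub, outdir / f"target_matrix_{tag}.tsv", index=True, index_label="gene")
            _write_tsv(directions, outdir / f"target_directions_{tag}.tsv")
        summary["contrasts"][tag] = entry
    (outdir / "node_summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True) + "\n"
    )


STAGES = {
    "simulate": stage_simulate,
    "infer": stage_infer,
    "influence": stage_influence,
    "diff": stage_diff,
    "enrich": stage_enrich,
    "report": stage_report,
}


def run_pipeline(config: PipelineConfig, outdir) -> Path:
    """Run all stages into ``outdir`` and write the run manifest.

    Returns the output directory path.  Any stage failure raises
    :class:`PipelineStageError` carrying the stage name.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.yaml").write_text(
        yaml.safe_dump(config.to_dict(), sort_keys=True)
    )
    stage_names = list(STAGES)
    if not config.simulate:
        stage_names.remove("simulate")
    for name in stage_names:
        STAGES[name](config, outdir)
    manifest = {
        "package": "coregflow",
        "version": __version__,
        "seed": config.seed,
        "stages": stage_names,
        "config": config.to_dict(),
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n"
    )
    return outdir
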