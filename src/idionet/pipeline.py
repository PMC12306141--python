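"""One-command orchestration: EMA table in, treatment-target report out.

Runs the per-participant (idiographic) sequence — validation, completeness
and item summaries, node selection, lagged-pair construction, EBIC-selected
graphical VAR, centrality, target nomination — and writes every artifact
plus a run manifest with full provenance (config snapshot, diagnostics,
tie-break and low-data warnings, output inventory). Every convention the
protocol leaves open (centrality signs, self-loops, day-boundary policy,
EBIC gamma) is a config key so sensitivity can be probed.
"""

from __future__ import annotations

import json
import platform
import warnings
from datetime import datetime, timezone
from pathlib import Path
from typing import Literal

from pydantic import BaseModel, Field

from . import __version__
from .centrality import centrality_table
from .data import (
    Community,
    DayBoundary,
    EMADataset,
    Schedule,
    completeness_summary,
    load_ema_table,
    load_manifest_csv,
    to_lagged_pairs,
)
from .gvar import (
    default_grid,
    detrend_pairs,
    edge_list,
    extract_networks,
    select_model,
    standardize_pairs,
    write_graphml,
)
from .selection import item_summaries, select_top_k_per_community, summaries_frame
from .targets import (
    DEFAULT_STATISTICS,
    build_target_report,
    default_registry,
    load_registry,
    top_k_per_statistic,
)

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "run_pipeline_on_dataset"]


class ScheduleConfig(BaseModel):
    n_days: int = Field(21, ge=1)
    beeps_per_day: int = Field(5, ge=1)
    beep_interval_hours: float = Field(2.5, gt=0)
    response_window_hours: float = Field(2.0, gt=0)

    def to_schedule(self) -> Schedule:
        return Schedule(**self.model_dump())


class PipelineConfig(BaseModel):
    """Validated configuration; every default is the documented protocol choice."""

    data_path: str
    manifest_path: str | None = None
    registry_path: str | None = None
    output_dir: str = "idionet_output"
    participant_id: str | None = None
    schedule: ScheduleConfig = ScheduleConfig()
    k_per_community: int = Field(4, ge=1)
    day_boundary: Literal["within_day", "across_all"] = "within_day"
    detrend: bool = False
    n_lambda: int = Field(10, ge=1)
    lambda_ratio: float = Field(0.01, gt=0, le=1)
    gamma: float = Field(0.5, ge=0)
    signed_centrality: bool = False
    include_self_loops: bool = False
    nomination_statistics: list[str] = Field(default_factory=lambda: list(DEFAULT_STATISTICS))
    nomination_k: int = Field(2, ge=1)
    seed: int = 0

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls.model_validate_json(Path(path).read_text())


class RunManifest(BaseModel):
    """Provenance record sufficient to re-run the pipeline bit-identically."""

    config: PipelineConfig
    version: str
    python: str
    started: str
    finished: str
    diagnostics: dict
    warnings: list[str]
    outputs: list[str]


def _load_inputs(config: PipelineConfig) -> EMADataset:
    if config.manifest_path is not None:
        manifest = load_manifest_csv(config.manifest_path)
    else:
        from importlib import resources

        with resources.as_file(resources.files("idionet") / "default_manifest.csv") as p:
            manifest = load_manifest_csv(p)
    return load_ema_table(
        config.data_path, manifest, config.schedule.to_schedule(),
        participant_id=config.participant_id,
    )


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute all stages on the configured input file. See module docstring."""
    return run_pipeline_on_dataset(_load_inputs(config), config)


def run_pipeline_on_dataset(dataset: EMADataset, config: PipelineConfig) -> RunManifest:
    started = datetime.now(timezone.utc).isoformat()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[str] = []
    diagnostics: dict = {"participant_id": dataset.participant_id}
    captured: list[str] = []

    def _write(name: str, writer) -> None:
        path = out / name
        writer(path)
        outputs.append(str(path))

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        # stage 1: completeness + item summaries (availability-table analogue)
        completeness = completeness_summary(dataset)
        summaries = item_summaries(dataset)
        table1 = summaries_frame(summaries).merge(completeness, on="item_id")
        _write("item_summaries.csv", lambda p: table1.to_csv(p, index=False))
        diagnostics["n_completed_beeps"] = dataset.n_completed_beeps
        diagnostics["schedule_size"] = dataset.schedule.size

        # stage 2: node selection (k highest-mean items per community)
        partition = {it.item_id: it.community for it in dataset.manifest}
        node_set = select_top_k_per_community(summaries, partition, k=config.k_per_community)
        diagnostics["selected_nodes"] = node_set.items
        diagnostics["selection_notes"] = node_set.notes

        # stage 3: lag-1 pairs + standardization
        pairs = to_lagged_pairs(dataset, node_set.items, DayBoundary(config.day_boundary))
        diagnostics["n_pairs"] = len(pairs)
        p = len(node_set.items)
        if len(pairs) < 2 * p:
            warnings.warn(
                f"low data: only {len(pairs)} complete lagged pairs for {p} nodes; "
                "network estimates will be unstable"
            )
        if config.detrend:
            pairs = detrend_pairs(pairs)
        std_pairs, standardization = standardize_pairs(pairs, nodes=node_set.items)

        # stage 4: EBIC-selected graphical VAR
        grid = default_grid(std_pairs, n_lambda=config.n_lambda,
                            ratio=config.lambda_ratio, gamma=config.gamma)
        fit, score_table = select_model(std_pairs, grid, nodes=node_set.items)
        diagnostics["lambda_beta"] = fit.lambda_beta
        diagnostics["lambda_kappa"] = fit.lambda_kappa
        diagnostics["ebic"] = fit.ebic
        diagnostics["converged"] = fit.converged
        _write("ebic_table.csv", lambda p: score_table.to_csv(p, index=False))

        # stage 5: networks
        networks = extract_networks(fit)
        edges = edge_list(networks)
        _write("edges.csv", lambda p: edges.to_csv(p, index=False))
        write_graphml(networks, out / "contemporaneous.graphml", out / "temporal.graphml")
        outputs += [str(out / "contemporaneous.graphml"), str(out / "temporal.graphml")]

        # stage 6: centrality
        node_partition = {n: Community(partition[n]) for n in node_set.items}
        table = centrality_table(
            networks, node_partition,
            signed=config.signed_centrality,
            include_self_loops=config.include_self_loops,
        )
        _write("centrality.csv", lambda p: table.to_csv(p))

        # stage 7: treatment targets
        registry = (
            load_registry(config.registry_path) if config.registry_path else default_registry()
        )
        rankings = top_k_per_statistic(
            table, statistics=config.nomination_statistics, k=config.nomination_k
        )
        report = build_target_report(rankings, registry)
        _write("targets.json", lambda p: Path(p).write_text(report.to_json()))
        _write("targets.md", lambda p: Path(p).write_text(report.to_markdown()))
        diagnostics["n_targets"] = len(report.targets)
        diagnostics["target_notes"] = report.notes
        captured = [str(w.message) for w in caught]

    manifest = RunManifest(
        config=config,
        version=__version__,
        python=platform.python_version(),
        started=started,
        finished=datetime.now(timezone.utc).isoformat(),
        diagnostics=diagnostics,
        warnings=captured,
        outputs=outputs,
    )
    (out / "run_manifest.json").write_text(manifest.model_dump_json(indent=2))
    return manifest
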