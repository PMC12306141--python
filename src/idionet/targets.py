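"""Treatment-target nomination from centrality tables.

The clinical rule: for each centrality statistic of interest — by default
contemporaneous strength, contemporaneous bridge strength, temporal
OutStrength and temporal bridge OutStrength — take the top two nodes, pool
the nominations, deduplicate, and match each nominated symptom to
evidence-based intervention options from a configurable registry.
(InStrength variants are computed upstream but do not nominate: a symptom
that merely receives influence is a poor lever.) "Temporal strength" in the
four-statistic rule is read as OutStrength, the outgoing-influence sum.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .centrality import STATISTICS
from .data import EMAValidationError

__all__ = [
    "DEFAULT_STATISTICS",
    "StatisticRanking",
    "TargetReport",
    "default_registry",
    "top_k_per_statistic",
    "build_target_report",
]

DEFAULT_STATISTICS = [
    "contemporaneous_strength",
    "contemporaneous_bridge_strength",
    "out_strength",
    "bridge_out_strength",
]


@dataclass
class StatisticRanking:
    """Descending (node, value) ranking for one statistic; ties are flagged."""

    statistic: str
    ranking: list[tuple[str, float]]
    tie_flags: list[str] = field(default_factory=list)


@dataclass
class TargetReport:
    """Deduplicated treatment targets with nominations and matched options."""

    rankings: list[StatisticRanking]
    targets: list[dict]  # node, nominations [(statistic, value)...], interventions, matched
    notes: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "rankings": [
                    {"statistic": r.statistic, "top": r.ranking, "tie_flags": r.tie_flags}
                    for r in self.rankings
                ],
                "targets": self.targets,
                "notes": self.notes,
            },
            indent=2,
        )

    def to_markdown(self) -> str:
        lines = ["| Treatment target | Nominating statistics | Intervention options |",
                 "| --- | --- | --- |"]
        for t in self.targets:
            noms = "; ".join(f"{s} = {v:.2f}" for s, v in t["nominations"])
            options = "; ".join(t["interventions"]) if t["matched"] else "(no registry match)"
            lines.append(f"| {t['node']} | {noms} | {options} |")
        for note in self.notes:
            lines.append(f"\n> {note}")
        return "\n".join(lines)


def default_registry() -> dict[str, list[str]]:
    """The packaged symptom -> intervention-options mapping (editable data)."""
    text = resources.files("idionet").joinpath("default_registry.json").read_text()
    return json.loads(text)


def load_registry(path: str | Path) -> dict[str, list[str]]:
    registry = json.loads(Path(path).read_text())
    for key, options in registry.items():
        if not options:
            raise EMAValidationError(f"registry entry {key!r} has no intervention options")
    return registry


def top_k_per_statistic(
    table: pd.DataFrame,
    statistics: Sequence[str] = tuple(DEFAULT_STATISTICS),
    k: int = 2,
) -> list[StatisticRanking]:
    """Top-k nodes per statistic, descending, with deterministic tie-breaks.

    Ties on a statistic break by the node's aggregate centrality (sum over
    all six statistics), then lexicographic node id; every tie that k falls
    on is flagged for human review.
    """
    if k > len(table):
        raise EMAValidationError(f"k={k} exceeds the {len(table)} network nodes")
    unknown = [s for s in statistics if s not in STATISTICS]
    if unknown:
        raise EMAValidationError(f"unknown statistic(s) {unknown}; expected one of {STATISTICS}")
    aggregate = table[STATISTICS].sum(axis=1)
    rankings = []
    for stat in statistics:
        order = sorted(
            table.index,
            key=lambda node: (-table.loc[node, stat], -aggregate[node], node),
        )
        top = [(node, float(table.loc[node, stat])) for node in order[:k]]
        flags = []
        boundary_value = top[-1][1]
        tied = [n for n in table.index if float(table.loc[n, stat]) == boundary_value]
        if len(tied) > 1:
            flags.append(
                f"{stat}: value tie at rank {k} among {sorted(tied)}; broken by "
                "aggregate centrality then node id"
            )
        rankings.append(StatisticRanking(stat, top, flags))
    return rankings


def build_target_report(
    rankings: Sequence[StatisticRanking],
    registry: Mapping[str, Sequence[str]] | None = None,
) -> TargetReport:
    """Pool, deduplicate and registry-match the nominated symptoms.

    A node nominated by several statistics appears once, carrying every
    nomination. Targets absent from the registry are kept and flagged
    unmatched rather than dropped.
    """
    if not rankings:
        raise EMAValidationError("no rankings to build a target report from")
    registry = dict(registry) if registry is not None else {}
    notes: list[str] = []
    if not registry:
        notes.append("empty intervention registry: all targets unmatched")
    nominations: dict[str, list[tuple[str, float]]] = {}
    order: list[str] = []
    def _rank_key(r: StatisticRanking) -> tuple[int, str]:
        idx = (DEFAULT_STATISTICS.index(r.statistic)
               if r.statistic in DEFAULT_STATISTICS else len(DEFAULT_STATISTICS))
        return (idx, r.statistic)

    for ranking in sorted(rankings, key=_rank_key):
        notes.extend(ranking.tie_flags)
        for node, value in ranking.ranking:
            nominations.setdefault(node, []).append((ranking.statistic, value))
            if node not in order:
                order.append(node)
    targets = []
    for node in order:
        matched = node in registry
        targets.append(
            {
                "node": node,
                "nominations": nominations[node],
                "interventions": list(registry.get(node, [])),
                "matched": matched,
            }
        )
        if not matched and registry:
            notes.append(f"target {node!r} has no registry entry; flagged unmatched")
    return TargetReport(rankings=list(rankings), targets=targets, notes=notes)
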