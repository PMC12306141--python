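"""Node-set selection: the k highest-mean items from each symptom community.

Idiographic networks keep few nodes relative to the number of observations,
so the network is estimated over a small a-priori subset of the item pool:
the k items (default 4) with the highest across-study mean in each of the
two communities, giving a 4 ED + 4 SUI eight-node network by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import Community, EMADataset, EMAValidationError

__all__ = ["ItemSummary", "NodeSet", "item_summaries", "select_top_k_per_community"]


@dataclass(frozen=True)
class ItemSummary:
    """Observed-data mean/SD for one item (missing scores excluded)."""

    item_id: str
    mean: float
    sd: float
    n_observed: int


@dataclass
class NodeSet:
    """Selected network nodes, ordered by descending mean within community."""

    items: list[str]
    by_community: dict[Community, list[str]]
    notes: list[str] = field(default_factory=list)


def item_summaries(dataset: EMADataset) -> list[ItemSummary]:
    """Mean and sample SD (n-1 denominator) of each item's observed scores.

    Items with zero observations are excluded and reported via a warning.
    """
    summaries = []
    empty = []
    for item in dataset.manifest:
        values = np.array(
            [rec.scores[item.item_id] for rec in dataset.records if item.item_id in rec.scores]
        )
        if values.size == 0:
            empty.append(item.item_id)
            continue
        sd = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
        summaries.append(ItemSummary(item.item_id, float(np.mean(values)), sd, values.size))
    if empty:
        warnings.warn(f"items with no observations excluded from summaries: {empty}")
    return summaries


def summaries_frame(summaries: Sequence[ItemSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "item_id": [s.item_id for s in summaries],
            "mean": [s.mean for s in summaries],
            "sd": [s.sd for s in summaries],
            "n_observed": [s.n_observed for s in summaries],
        }
    )


def select_top_k_per_community(
    summaries: Sequence[ItemSummary],
    partition: Mapping[str, Community],
    k: int = 4,
    skip_zero_variance: bool = True,
) -> NodeSet:
    """Pick the k highest-mean items within each community.

    Ties at the k-th rank break deterministically: higher SD wins (more
    dynamic range carries more network information), then lexicographic
    item_id; any tie or zero-variance skip is recorded in ``NodeSet.notes``.
    Zero-variance items cannot carry edges after standardization, so by
    default they are skipped in favour of the next-ranked item.
    """
    notes: list[str] = []
    by_community: dict[Community, list[str]] = {}
    for community in (Community.ED, Community.SUI):
        members = [
            s for s in summaries if Community(partition[s.item_id]) is community and s.n_observed >= 1
        ]
        if skip_zero_variance:
            degenerate = [s.item_id for s in members if s.sd == 0.0]
            if degenerate:
                notes.append(
                    f"{community.value}: zero-variance items skipped: {sorted(degenerate)}"
                )
                members = [s for s in members if s.sd > 0.0]
        if len(members) < k:
            raise EMAValidationError(
                f"community {community.value} has only {len(members)} eligible items; need {k}"
            )
        ranked = sorted(members, key=lambda s: (-s.mean, -s.sd, s.item_id))
        boundary = ranked[k - 1]
        tied = [s.item_id for s in members if s.mean == boundary.mean]
        if len(tied) > 1:
            notes.append(
                f"{community.value}: mean tie at rank {k} among {sorted(tied)}; "
                "broken by higher SD then item_id"
            )
        by_community[community] = [s.item_id for s in ranked[:k]]
    items = by_community[Community.ED] + by_community[Community.SUI]
    return NodeSet(items=items, by_community=by_community, notes=notes)
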