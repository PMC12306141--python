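"""EMA symptom-series containers, validation, I/O and lagged-pair construction.

Ecological momentary assessment (EMA) delivers short surveys ("beeps") on a
fixed daily schedule; here each beep scores a set of symptom items on a 0-100
slider, and each item belongs to one of two clinically pre-defined
communities: eating-disorder (ED) or suicidality (SUI) symptoms.

The canonical time axis is the integer (day, beep) grid. Missing data are
explicit: a beep that was never answered simply has no observed scores, and a
score of 0 is a valid observation, never a missing marker. Lag-1 analysis
consumes complete consecutive-beep pairs only (listwise deletion at the pair
level, no imputation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Community",
    "SymptomItem",
    "Schedule",
    "EMARecord",
    "EMADataset",
    "LaggedPair",
    "DayBoundary",
    "EMAFormatError",
    "EMAValidationError",
    "schedule_size",
    "load_ema_table",
    "write_long_csv",
    "write_wide_csv",
    "completeness_summary",
    "to_lagged_pairs",
    "pairs_to_arrays",
]


class EMAFormatError(ValueError):
    """Raised when an input table does not match a recognised dialect."""


class EMAValidationError(ValueError):
    """Raised when table contents violate the EMA data contract."""


class Community(str, Enum):
    """The two pre-defined symptom communities."""

    ED = "ED"
    SUI = "SUI"


class DayBoundary(str, Enum):
    """Policy for lag-1 pairs at day boundaries.

    WITHIN_DAY: only consecutive beeps inside one waking day form pairs
    (overnight gaps break the equal-interval lag assumption).
    ACROSS_ALL: the last beep of day d and the first beep of day d+1 also
    form a pair.
    """

    WITHIN_DAY = "within_day"
    ACROSS_ALL = "across_all"


@dataclass(frozen=True)
class SymptomItem:
    """One EMA item: identifier, display label, full prompt, community tag."""

    item_id: str
    label: str
    prompt: str
    community: Community

    def __post_init__(self) -> None:
        object.__setattr__(self, "community", Community(self.community))


@dataclass(frozen=True)
class Schedule:
    """Fixed EMA sampling protocol.

    Defaults follow a 21-day protocol with five beeps per day, one every
    2.5 h inside a 12-h waking window, each open for 2 h.
    """

    n_days: int = 21
    beeps_per_day: int = 5
    beep_interval_hours: float = 2.5
    response_window_hours: float = 2.0

    def __post_init__(self) -> None:
        if self.n_days < 1 or self.beeps_per_day < 1:
            raise EMAValidationError("schedule requires n_days >= 1 and beeps_per_day >= 1")

    @property
    def size(self) -> int:
        return self.n_days * self.beeps_per_day


def schedule_size(schedule: Schedule) -> int:
    """Total number of scheduled assessment points, n_days * beeps_per_day."""
    return schedule.size


@dataclass(frozen=True)
class EMARecord:
    """Observed scores at one beep. Items absent from ``scores`` are missing."""

    day: int
    beep: int
    scores: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for item_id, value in self.scores.items():
            if not math.isfinite(value) or not (0.0 <= value <= 100.0):
                raise EMAValidationError(
                    f"score {value!r} for item {item_id!r} at (day {self.day}, "
                    f"beep {self.beep}) outside [0, 100]"
                )


@dataclass
class EMADataset:
    """Schedule-indexed, possibly-missing 0-100 item scores for one participant."""

    participant_id: str
    manifest: list[SymptomItem]
    schedule: Schedule
    records: list[EMARecord]

    def __post_init__(self) -> None:
        ids = [it.item_id for it in self.manifest]
        if len(set(ids)) != len(ids):
            raise EMAValidationError("duplicate item_id in manifest")
        known = set(ids)
        seen: set[tuple[int, int]] = set()
        for rec in self.records:
            if not (1 <= rec.day <= self.schedule.n_days):
                raise EMAValidationError(f"day {rec.day} outside schedule 1..{self.schedule.n_days}")
            if not (1 <= rec.beep <= self.schedule.beeps_per_day):
                raise EMAValidationError(
                    f"beep {rec.beep} outside schedule 1..{self.schedule.beeps_per_day}"
                )
            if (rec.day, rec.beep) in seen:
                raise EMAValidationError(f"duplicate record for (day {rec.day}, beep {rec.beep})")
            seen.add((rec.day, rec.beep))
            unknown = set(rec.scores) - known
            if unknown:
                raise EMAValidationError(
                    f"record (day {rec.day}, beep {rec.beep}) scores unknown items {sorted(unknown)}"
                )

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.manifest]

    def community_of(self, item_id: str) -> Community:
        for it in self.manifest:
            if it.item_id == item_id:
                return it.community
        raise KeyError(item_id)

    def to_frame(self) -> pd.DataFrame:
        """Wide frame over the full (day, beep) grid; NaN marks missing."""
        index = pd.MultiIndex.from_product(
            [range(1, self.schedule.n_days + 1), range(1, self.schedule.beeps_per_day + 1)],
            names=["day", "beep"],
        )
        frame = pd.DataFrame(np.nan, index=index, columns=self.item_ids, dtype=float)
        for rec in self.records:
            for item_id, value in rec.scores.items():
                frame.loc[(rec.day, rec.beep), item_id] = value
        return frame

    @property
    def n_completed_beeps(self) -> int:
        """Beeps with at least one observed item score."""
        return sum(1 for rec in self.records if rec.scores)


@dataclass(frozen=True)
class LaggedPair:
    """One complete (t-1, t) observation pair over the selected nodes."""

    predictor: np.ndarray
    outcome: np.ndarray
    day: int
    within_day: bool

    def __post_init__(self) -> None:
        if np.isnan(self.predictor).any() or np.isnan(self.outcome).any():
            raise EMAValidationError("lagged pair contains missing entries")


# ---------------------------------------------------------------------------
# I/O: long and wide CSV dialects
# ---------------------------------------------------------------------------

_LONG_COLUMNS = ["participant_id", "day", "beep", "item_id", "score"]
_WIDE_PREFIX = ["participant_id", "day", "beep"]


def load_manifest_csv(path: str | Path) -> list[SymptomItem]:
    """Read an item manifest (columns item_id, label, prompt, community)."""
    table = pd.read_csv(path, dtype=str)
    required = {"item_id", "label", "prompt", "community"}
    if not required.issubset(table.columns):
        raise EMAFormatError(f"manifest must have columns {sorted(required)}; got {list(table.columns)}")
    return [
        SymptomItem(row.item_id, row.label, row.prompt, Community(row.community))
        for row in table.itertuples()
    ]


def write_manifest_csv(manifest: Sequence[SymptomItem], path: str | Path) -> None:
    pd.DataFrame(
        {
            "item_id": [it.item_id for it in manifest],
            "label": [it.label for it in manifest],
            "prompt": [it.prompt for it in manifest],
            "community": [it.community.value for it in manifest],
        }
    ).to_csv(path, index=False)


def load_ema_table(
    path: str | Path,
    manifest: Sequence[SymptomItem],
    schedule: Schedule,
    participant_id: str | None = None,
) -> EMADataset:
    """Read an EMA score table (long or wide CSV dialect) into a dataset.

    Long dialect: participant_id, day, beep, item_id, score (one row per
    observed item score). Wide dialect: participant_id, day, beep, then one
    column per item_id; empty cells are missing. The dialect is detected from
    the header. Scheduled (day, beep) combinations absent from the file are
    recorded as fully missing.
    """
    table = pd.read_csv(path)
    columns = list(table.columns)
    if not columns[:3] == _WIDE_PREFIX:
        raise EMAFormatError(
            f"table must start with columns {_WIDE_PREFIX}; got {columns[:3]}"
        )
    is_long = columns == _LONG_COLUMNS
    item_ids = [it.item_id for it in manifest]

    if is_long:
        frame = table
    else:
        unknown = [c for c in columns[3:] if c not in item_ids]
        if unknown:
            raise EMAFormatError(f"wide table has columns not in the manifest: {unknown}")
        frame = table.melt(
            id_vars=_WIDE_PREFIX, var_name="item_id", value_name="score"
        ).dropna(subset=["score"])

    problems: list[str] = []
    for row in frame.itertuples():
        value = float(row.score)
        if not math.isfinite(value) or not (0.0 <= value <= 100.0):
            problems.append(
                f"row (day {row.day}, beep {row.beep}), item {row.item_id!r}: "
                f"score {row.score} outside [0, 100]"
            )
    if problems:
        raise EMAValidationError("; ".join(problems))
    duplicated = frame.duplicated(subset=["day", "beep", "item_id"], keep=False)
    if is_long and duplicated.any():
        cells = frame.loc[duplicated, ["day", "beep", "item_id"]].drop_duplicates()
        raise EMAValidationError(
            "duplicate (day, beep, item) cells: "
            + "; ".join(f"(day {r.day}, beep {r.beep}, {r.item_id})" for r in cells.itertuples())
        )
    if not is_long:
        dup_beeps = table.duplicated(subset=["day", "beep"], keep=False)
        if dup_beeps.any():
            cells = table.loc[dup_beeps, ["day", "beep"]].drop_duplicates()
            raise EMAValidationError(
                "duplicate (day, beep) rows: "
                + "; ".join(f"(day {r.day}, beep {r.beep})" for r in cells.itertuples())
            )

    pid = participant_id or str(frame["participant_id"].iloc[0]) if len(frame) else (participant_id or "unknown")
    records = []
    for (day, beep), group in frame.groupby(["day", "beep"], sort=True):
        scores = {str(r.item_id): float(r.score) for r in group.itertuples()}
        records.append(EMARecord(int(day), int(beep), scores))
    return EMADataset(pid, list(manifest), schedule, records)


def write_long_csv(dataset: EMADataset, path: str | Path) -> None:
    rows = [
        (dataset.participant_id, rec.day, rec.beep, item_id, value)
        for rec in sorted(dataset.records, key=lambda r: (r.day, r.beep))
        for item_id, value in sorted(rec.scores.items())
    ]
    pd.DataFrame(rows, columns=_LONG_COLUMNS).to_csv(path, index=False)


def write_wide_csv(dataset: EMADataset, path: str | Path) -> None:
    frame = dataset.to_frame().reset_index()
    frame.insert(0, "participant_id", dataset.participant_id)
    frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Completeness and lag structure
# ---------------------------------------------------------------------------


def _round_half_up(value: float, ndigits: int = 2) -> float:
    return float(Decimal(repr(value)).quantize(Decimal(10) ** -ndigits, rounding=ROUND_HALF_UP))


def completeness_summary(dataset: EMADataset) -> pd.DataFrame:
    """Per-item data availability over the scheduled assessment points.

    ``available_percent`` is 100 * n_observed / schedule_size rounded half-up
    to two decimals; ``n_days_observed`` counts days with at least one
    observation of the item.
    """
    if not dataset.manifest:
        raise EMAValidationError("empty manifest")
    total = dataset.schedule.size
    rows = []
    for item in dataset.manifest:
        observed = [rec.day for rec in dataset.records if item.item_id in rec.scores]
        rows.append(
            {
                "item_id": item.item_id,
                "n_observed": len(observed),
                "n_days_observed": len(set(observed)),
                "available_percent": _round_half_up(100.0 * len(observed) / total),
            }
        )
    return pd.DataFrame(rows)


def to_lagged_pairs(
    dataset: EMADataset,
    nodes: Sequence[str],
    day_boundary_policy: DayBoundary = DayBoundary.WITHIN_DAY,
) -> list[LaggedPair]:
    """Build complete lag-1 observation pairs over the selected nodes.

    A pair (t-1, t) is emitted only when both beeps are consecutive scheduled
    points and every selected node is observed at both; pairs touching a
    missing beep are dropped (no imputation). Under WITHIN_DAY the two beeps
    must fall in the same day; ACROSS_ALL also pairs the last beep of a day
    with the first beep of the next.
    """
    unknown = set(nodes) - set(dataset.item_ids)
    if unknown:
        raise EMAValidationError(f"nodes not in manifest: {sorted(unknown)}")
    if len(dataset.records) < 2:
        return []
    frame = dataset.to_frame()[list(nodes)]
    values = frame.to_numpy()
    index = frame.index.to_list()  # chronological (day, beep) grid
    policy = DayBoundary(day_boundary_policy)
    pairs: list[LaggedPair] = []
    for pos in range(1, len(index)):
        day_prev, _ = index[pos - 1]
        day_curr, _ = index[pos]
        same_day = day_prev == day_curr
        if not same_day and policy is DayBoundary.WITHIN_DAY:
            continue
        prev, curr = values[pos - 1], values[pos]
        if np.isnan(prev).any() or np.isnan(curr).any():
            continue
        pairs.append(LaggedPair(prev.copy(), curr.copy(), day=day_curr, within_day=same_day))
    return pairs


def pairs_to_arrays(pairs: Sequence[LaggedPair]) -> tuple[np.ndarray, np.ndarray]:
    """Stack pairs into predictor matrix X (t-1) and outcome matrix Y (t)."""
    if not pairs:
        raise EMAValidationError("no lagged pairs")
    X = np.stack([p.predictor for p in pairs])
    Y = np.stack([p.outcome for p in pairs])
    return X, Y
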