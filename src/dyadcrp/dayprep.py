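"""24-hour day segmentation, gap filling, normalization and discretization.

Index series are cut into day segments aligned to a 22:00 clock boundary
(1440 points on a 60 s grid), so that each segment spans one full
night-day cycle.  Days missing more than 20% of their points are excluded;
smaller gaps are mean-filled.  Values are then min-max normalized per
subject (pooled over that subject's days, so the within-subject
fluctuation range maps to [0, 1]) and discretized to 11 levels by rounding
to one decimal, which makes exact-match (ε = 0) recurrences meaningful.

Segments carry an explicit processing ``state`` (raw → filled → normalized
→ discrete); each operation asserts the state it requires, so the pipeline
order cannot silently be violated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime, time, timedelta
from typing import Iterable, Sequence

import numpy as np

from .hrv import IndexSeries

__all__ = [
    "POINTS_PER_DAY",
    "DAY_START",
    "DaySegment",
    "Rejection",
    "segment_days",
    "fill_or_reject",
    "normalize",
    "discretize",
    "prepare_days",
]

POINTS_PER_DAY = 1440  # 24 h on a 60 s grid
DAY_START = time(22, 0)  # segments run 22:00 -> 22:00


@dataclass
class DaySegment:
    """One subject's one index over one 22:00-aligned day (1440-point grid)."""

    subject_id: str
    kind: str
    day_index: int
    start: datetime
    values: np.ndarray
    missing: np.ndarray
    state: str = "raw"  # raw | filled | normalized | discrete
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.values.size == 0 or self.values.size != self.missing.size:
            raise ValueError("values and missing mask must align and be non-empty")

    @property
    def n_points(self) -> int:
        return self.values.size

    @property
    def levels(self) -> np.ndarray:
        """Integer levels 0..10; only defined once discretized."""
        if self.state != "discrete":
            raise ValueError("levels require state='discrete'")
        return np.rint(self.values * 10).astype(int)


@dataclass(frozen=True)
class Rejection:
    subject_id: str
    kind: str
    day_index: int
    reason: str


def _require_state(seg: DaySegment, state: str) -> None:
    if seg.state != state:
        raise ValueError(f"expected state {state!r}, got {seg.state!r}")


def segment_days(
    series: IndexSeries,
    recording_start: datetime,
    day_start: time = DAY_START,
) -> list[DaySegment]:
    """Cut a series into complete day segments starting at ``day_start``.

    ``series.grid`` holds seconds since ``recording_start``.  Only spans
    fully covered by the series' time range are kept; a recording shorter
    than 24 h yields no segments.  Grid slots with no sample or a NaN value
    are marked missing.
    """
    if series.grid.size >= 2 and not np.isclose(series.step, 60.0):
        raise ValueError("segment_days requires a 60 s grid")
    if series.grid.size < POINTS_PER_DAY:
        return []
    first = recording_start.replace(
        hour=day_start.hour, minute=day_start.minute, second=0, microsecond=0
    )
    if first < recording_start:
        first += timedelta(days=1)

    end_of_series = recording_start + timedelta(seconds=float(series.grid[-1]))
    segments: list[DaySegment] = []
    day = 0
    start = first
    while start + timedelta(days=1) <= end_of_series:
        offset_s = (start - recording_start).total_seconds()
        slot_times = offset_s + 60.0 * np.arange(POINTS_PER_DAY)
        idx = np.searchsorted(series.grid, slot_times)
        valid = (idx < series.grid.size) & np.isclose(
            series.grid[np.minimum(idx, series.grid.size - 1)], slot_times
        )
        values = np.full(POINTS_PER_DAY, np.nan)
        sel = idx[valid]
        values[valid] = series.values[sel]
        missing = np.isnan(values) | np.where(
            valid, series.missing[np.minimum(idx, series.grid.size - 1)], True
        )
        segments.append(
            DaySegment(
                subject_id=series.subject_id,
                kind=series.kind,
                day_index=day,
                start=start,
                values=values,
                missing=missing,
            )
        )
        day += 1
        start += timedelta(days=1)
    return segments


def fill_or_reject(
    seg: DaySegment, max_missing: float = 0.20, fill_value: float | None = None
) -> DaySegment | Rejection:
    """Mean-fill small gaps; reject days missing more than ``max_missing``.

    Exactly 20% missing is kept (the rule excludes days *exceeding* the
    threshold).  Gaps are set to the mean of the day's own observed values;
    pass ``fill_value`` (e.g. a subject-level mean) to fill with that
    instead.
    """
    _require_state(seg, "raw")
    frac = float(seg.missing.mean())
    if frac > max_missing:
        return Rejection(
            seg.subject_id, seg.kind, seg.day_index,
            f"missing {frac:.1%} exceeds {max_missing:.0%}",
        )
    observed = seg.values[~seg.missing]
    if observed.size == 0 and fill_value is None:
        return Rejection(seg.subject_id, seg.kind, seg.day_index, "all missing")
    values = seg.values.copy()
    values[seg.missing] = observed.mean() if fill_value is None else fill_value
    return replace(
        seg, values=values, missing=np.zeros_like(seg.missing), state="filled"
    )


def normalize(segments: Sequence[DaySegment]) -> list[DaySegment]:
    """Min-max scale one subject's segments of one kind to [0, 1], pooled.

    The minimum and maximum are taken over *all* of the subject's days of
    that kind, so day-to-day level differences survive normalization.  A
    zero range (constant subject) maps everything to 0.5 and flags the
    segments as degenerate.
    """
    if not segments:
        return []
    ids = {(s.subject_id, s.kind) for s in segments}
    if len(ids) > 1:
        raise ValueError(f"mixed subjects/kinds in normalize: {sorted(ids)}")
    for s in segments:
        _require_state(s, "filled")
    pooled = np.concatenate([s.values for s in segments])
    lo, hi = float(pooled.min()), float(pooled.max())
    out = []
    for s in segments:
        if hi > lo:
            vals = (s.values - lo) / (hi - lo)
            out.append(replace(s, values=vals, state="normalized"))
        else:
            out.append(
                replace(
                    s,
                    values=np.full(s.n_points, 0.5),
                    state="normalized",
                    degenerate=True,
                )
            )
    return out


def discretize(seg: DaySegment) -> DaySegment:
    """Round normalized values to one decimal (11 levels, half away from zero).

    Stored values are level/10 so the segment stays on the [0, 1] scale;
    integer codes are available via ``DaySegment.levels``.  Idempotent.
    """
    if seg.state == "discrete":
        return seg
    _require_state(seg, "normalized")
    # np.round ties to even; half-away-from-zero via floor(10x + 0.5) for x >= 0
    levels = np.floor(seg.values * 10 + 0.5).astype(int)
    levels = np.clip(levels, 0, 10)
    return replace(seg, values=levels / 10.0, state="discrete")


def prepare_days(
    segments_by_subject_kind: Iterable[Sequence[DaySegment]],
    max_missing: float = 0.20,
) -> tuple[list[DaySegment], list[Rejection]]:
    """Run fill → normalize → discretize over groups of raw segments.

    Each element of the iterable is one subject's raw segments of one kind.
    Returns the discretized segments and the rejection log.
    """
    kept: list[DaySegment] = []
    rejections: list[Rejection] = []
    for group in segments_by_subject_kind:
        filled = []
        for seg in group:
            res = fill_or_reject(seg, max_missing)
            if isinstance(res, Rejection):
                rejections.append(res)
            else:
                filled.append(res)
        for seg in normalize(filled):
            kept.append(discretize(seg))
    return kept, rejections
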