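"""Heart-rate-variability index extraction from R-R interval series.

Converts beat-to-beat interval recordings into artifact-gated N-N series
and sliding-window index series for three autonomic indices:

* SDNN — standard deviation of N-N intervals (global HRV),
* CSI  — cardiac sympathetic index, L/T from the Lorenz (Poincaré) plot,
* CVI  — cardiac vagal index, log10(L·T).

The Lorenz plot scatters each interval I_k against its successor I_{k+1};
T = 4·SD1 and L = 4·SD2 are the transverse and longitudinal cloud axes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "RRSeries",
    "NNSeries",
    "LorenzAxes",
    "IndexSeries",
    "INDEX_KINDS",
    "ARTIFACT_GATE",
    "clean_rr",
    "sdnn",
    "lorenz_axes",
    "csi_cvi",
    "sliding_indices",
]

INDEX_KINDS = ("SDNN", "CSI", "CVI")

#: Recordings whose artifact fraction exceeds this are flagged for exclusion.
ARTIFACT_GATE = 0.05


@dataclass
class RRSeries:
    """Raw R-R intervals: ``times`` in seconds since start, ``intervals`` in ms."""

    subject_id: str
    times: np.ndarray
    intervals: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intervals = np.asarray(self.intervals, dtype=float)
        if self.times.size != self.intervals.size:
            raise ValueError("times and intervals must have equal length")
        if self.times.size == 0:
            raise ValueError("empty series")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError(f"times not strictly increasing for {self.subject_id!r}")
        if np.any(self.intervals <= 0):
            raise ValueError("intervals must be positive")

    def __len__(self) -> int:
        return self.times.size


@dataclass
class NNSeries:
    """Artifact-filtered (normal-to-normal) intervals; subsequence of an RRSeries."""

    subject_id: str
    times: np.ndarray
    intervals: np.ndarray
    artifact_fraction: float = 0.0
    flagged: bool = False  # True when artifact_fraction exceeds the 5% gate

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class LorenzAxes:
    """Poincaré-cloud axis lengths. T = 4·sd1 (transverse), L = 4·sd2 (longitudinal)."""

    T: float
    L: float
    sd1: float
    sd2: float
    n_pairs: int


@dataclass
class IndexSeries:
    """One HRV index on a fixed-step time grid, with a missing mask."""

    subject_id: str
    kind: str
    grid: np.ndarray  # seconds since recording start, constant step
    values: np.ndarray
    missing: np.ndarray  # boolean, True where no value

    def __post_init__(self) -> None:
        if self.kind not in INDEX_KINDS:
            raise ValueError(f"unknown index kind {self.kind!r}")
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        if not (self.grid.size == self.values.size == self.missing.size):
            raise ValueError("grid, values and missing must align")
        steps = np.diff(self.grid)
        if steps.size and not np.allclose(steps, steps[0]):
            raise ValueError("grid step must be constant")

    @property
    def step(self) -> float:
        return float(self.grid[1] - self.grid[0]) if self.grid.size > 1 else float("nan")


def clean_rr(
    rr: RRSeries,
    min_ms: float = 300.0,
    max_ms: float = 2000.0,
    jump_frac: float = 0.3,
) -> NNSeries:
    """Remove artifact beats, producing an N-N series.

    An interval is rejected when it falls outside ``[min_ms, max_ms]`` or when
    it differs from the running median of the previous (up to) 5 *kept*
    intervals by more than ``jump_frac`` times that median.  Order is
    preserved; nothing is interpolated.  Series whose artifact fraction
    exceeds the 5% gate are flagged — the caller decides whether to exclude.
    """
    if not (0 < min_ms < max_ms):
        raise ValueError("require 0 < min_ms < max_ms")
    if not (0 < jump_frac < 1):
        raise ValueError("require 0 < jump_frac < 1")
    if len(rr) == 0:
        raise ValueError("empty series")

    kept_idx: list[int] = []
    recent: list[float] = []  # last <=5 kept intervals
    for i, iv in enumerate(rr.intervals):
        if iv < min_ms or iv > max_ms:
            continue
        if recent:
            med = float(np.median(recent))
            if abs(iv - med) > jump_frac * med:
                continue
        kept_idx.append(i)
        recent.append(float(iv))
        if len(recent) > 5:
            recent.pop(0)

    total = len(rr)
    frac = (total - len(kept_idx)) / total
    idx = np.asarray(kept_idx, dtype=int)
    return NNSeries(
        subject_id=rr.subject_id,
        times=rr.times[idx],
        intervals=rr.intervals[idx],
        artifact_fraction=frac,
        flagged=frac > ARTIFACT_GATE,
    )


def sdnn(intervals: Sequence[float] | np.ndarray) -> float:
    """Sample standard deviation (ddof=1) of the intervals, in ms; NaN if < 2 beats."""
    x = np.asarray(intervals, dtype=float)
    if x.size < 2:
        return float("nan")
    return float(np.std(x, ddof=1))


def lorenz_axes(intervals: Sequence[float] | np.ndarray) -> LorenzAxes:
    """Poincaré-plot axes over successive pairs (I_k, I_{k+1}).

    sd1 is the sample std of (I_k − I_{k+1})/√2 (dispersion across the
    identity line, short-term variability); sd2 the sample std of
    (I_k + I_{k+1})/√2 (dispersion along it, long-term variability).
    Requires at least 2 pairs (3 beats); otherwise all fields are NaN.
    """
    x = np.asarray(intervals, dtype=float)
    if x.size < 3:
        nan = float("nan")
        return LorenzAxes(nan, nan, nan, nan, max(x.size - 1, 0))
    a, b = x[:-1], x[1:]
    sd1 = float(np.std((a - b) / math.sqrt(2), ddof=1))
    sd2 = float(np.std((a + b) / math.sqrt(2), ddof=1))
    return LorenzAxes(T=4 * sd1, L=4 * sd2, sd1=sd1, sd2=sd2, n_pairs=x.size - 1)


def csi_cvi(axes: LorenzAxes) -> tuple[float, float]:
    """(CSI, CVI) = (L/T, log10(L·T)); both NaN for a degenerate cloud (T or L zero)."""
    if not (axes.T > 0 and axes.L > 0):  # also catches NaN
        return float("nan"), float("nan")
    return axes.L / axes.T, math.log10(axes.L * axes.T)


def sliding_indices(
    nn: NNSeries,
    width_s: float = 300.0,
    step_s: float = 60.0,
) -> dict[str, IndexSeries]:
    """Sliding-window SDNN/CSI/CVI on a fixed grid.

    Windows are trailing and half-open: the value at grid time t is computed
    from beats whose time lies in (t − width_s, t].  The grid runs from
    ``width_s`` to the last multiple of ``step_s`` not exceeding the final
    beat time.  Windows with too few beats yield missing values.
    """
    if width_s % step_s != 0:
        raise ValueError("width_s must be a multiple of step_s")
    t_end = nn.times[-1] if len(nn) else 0.0
    n_grid = int(t_end // step_s) - int(width_s // step_s) + 1
    if n_grid < 1:
        grid = np.array([width_s])
        n_grid = 1
    else:
        grid = width_s + step_s * np.arange(n_grid)

    out_vals = {k: np.full(n_grid, np.nan) for k in INDEX_KINDS}
    for gi, t in enumerate(grid):
        lo = np.searchsorted(nn.times, t - width_s, side="right")
        hi = np.searchsorted(nn.times, t, side="right")
        w = nn.intervals[lo:hi]
        out_vals["SDNN"][gi] = sdnn(w)
        csi, cvi = csi_cvi(lorenz_axes(w))
        out_vals["CSI"][gi] = csi
        out_vals["CVI"][gi] = cvi

    return {
        kind: IndexSeries(
            subject_id=nn.subject_id,
            kind=kind,
            grid=grid.astype(float),
            values=vals,
            missing=np.isnan(vals),
        )
        for kind, vals in out_vals.items()
    }
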