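"""Recurrence plots and cross-recurrence plots of day segments.

An RP of a series x marks the time pairs (i, j) where the series revisits
the same state: R_ij = 1 iff |x_i − x_j| ≤ ε.  A CRP marks state
coincidences between two different series (here child vs mother); its main
diagonal is the line of synchrony.  After discretization to 11 levels,
ε = 0 becomes exact level equality — no float comparisons are involved.

Axis convention for cross plots: mother runs along the horizontal axis
(columns), child along the vertical axis (rows).

Also provided: per-lag diagonal recurrence profiles (periodicity), the
overall recurrence rate, and block-mean downsampling to fixed-size images
for SOM input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dayprep import DaySegment

__all__ = [
    "RecurrenceConfig",
    "RecurrenceMatrix",
    "RecurrenceImage",
    "cross_recurrence",
    "build_rp",
    "build_crp",
    "recurrence_rate",
    "tau_profile",
    "diagonal_block_profile",
    "dominant_period",
    "to_image",
]


@dataclass(frozen=True)
class RecurrenceConfig:
    """Recurrence tolerance ε, on the normalized [0, 1] value scale."""

    epsilon: float = 0.0

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError("epsilon must be non-negative")


@dataclass
class RecurrenceMatrix:
    """Binary recurrence matrix with source metadata.

    For cross plots, rows index the child's time axis and columns the
    mother's (mother horizontal, child vertical).
    """

    entries: np.ndarray  # uint8, 0/1
    row_source: tuple
    col_source: tuple
    is_cross: bool

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.entries.shape


@dataclass
class RecurrenceImage:
    """Block-averaged plot, pixels in [0, 1]; the SOM's input unit."""

    pixels: np.ndarray
    source: tuple
    downsample_factor: int

    @property
    def flat(self) -> np.ndarray:
        return self.pixels.ravel()


def cross_recurrence(
    y: np.ndarray, x: np.ndarray, epsilon: float
) -> np.ndarray:
    """Raw recurrence entries R_ij = 1 iff |y_i − x_j| ≤ ε (rows = y, cols = x)."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    return (np.abs(y[:, None] - x[None, :]) <= epsilon + 1e-12).astype(np.uint8)


def _segment_levels(seg: DaySegment) -> np.ndarray:
    if seg.state != "discrete":
        raise ValueError(f"segment must be discrete, got state {seg.state!r}")
    return seg.levels


def build_rp(seg: DaySegment, cfg: RecurrenceConfig = RecurrenceConfig()) -> RecurrenceMatrix:
    """Recurrence plot of one discretized segment.

    ε is interpreted on the level scale: levels i, j recur when
    |level_i − level_j| ≤ 10·ε, so ε = 0 is exact level equality.
    """
    lv = _segment_levels(seg)
    entries = (np.abs(lv[:, None] - lv[None, :]) <= 10 * cfg.epsilon + 1e-9).astype(np.uint8)
    src = (seg.subject_id, seg.kind, seg.day_index)
    return RecurrenceMatrix(entries, row_source=src, col_source=src, is_cross=False)


def build_crp(
    mother: DaySegment,
    child: DaySegment,
    cfg: RecurrenceConfig = RecurrenceConfig(),
) -> RecurrenceMatrix:
    """Cross-recurrence plot of a dyad: rows = child time, columns = mother time."""
    if mother.kind != child.kind:
        raise ValueError(f"kind mismatch: {mother.kind} vs {child.kind}")
    lm = _segment_levels(mother)
    lc = _segment_levels(child)
    if lm.size != lc.size:
        raise ValueError("length mismatch between mother and child segments")
    entries = (np.abs(lc[:, None] - lm[None, :]) <= 10 * cfg.epsilon + 1e-9).astype(np.uint8)
    return RecurrenceMatrix(
        entries,
        row_source=(child.subject_id, child.kind, child.day_index),
        col_source=(mother.subject_id, mother.kind, mother.day_index),
        is_cross=True,
    )


def recurrence_rate(m: RecurrenceMatrix | np.ndarray) -> float:
    """Fraction of recurrent (one) entries, in [0, 1]."""
    e = m.entries if isinstance(m, RecurrenceMatrix) else np.asarray(m)
    if e.size == 0:
        raise ValueError("empty matrix")
    return float(e.mean())


def tau_profile(m: RecurrenceMatrix | np.ndarray) -> np.ndarray:
    """Mean recurrence on each superdiagonal (lag τ = 0 .. n−1).

    Peaks in the profile reveal periodicity: a period-T signal recurs on
    every diagonal at lag multiples of T.  For an RP, the lag-0 entry is 1.
    """
    e = m.entries if isinstance(m, RecurrenceMatrix) else np.asarray(m)
    n, mcols = e.shape
    if n != mcols:
        raise ValueError("tau profile requires a square matrix")
    return np.array([e.diagonal(tau).mean() for tau in range(n)])


def dominant_period(
    profile: np.ndarray, dt: float = 1.0, prominence: float = 0.1
) -> float:
    """Lag (in time units of ``dt``) of the first nonzero-lag maximum.

    The profile of a periodic signal dips away from lag 0 and rises back to
    a peak at one full period; that first prominent peak's lag is the
    period.  ``prominence`` (on the 0–1 recurrence-fraction scale) rejects
    the sampling jitter of finite profiles; plateau peaks report their
    midpoint.
    """
    from scipy.signal import find_peaks

    p = np.asarray(profile, dtype=float)
    if p.size < 3:
        raise ValueError("profile too short")
    peaks, _ = find_peaks(p, prominence=prominence)
    if peaks.size == 0:
        raise ValueError("no nonzero-lag maximum found")
    return float(peaks[0]) * dt


def diagonal_block_profile(
    m: RecurrenceMatrix | np.ndarray, block: int
) -> np.ndarray:
    """Main-diagonal recurrence fraction per consecutive block of ``block`` steps.

    Measures where the line of synchrony of a CRP is intact: blocks with a
    fraction near 1 are synchronized stretches.  Trailing entries not
    filling a block are dropped.
    """
    e = m.entries if isinstance(m, RecurrenceMatrix) else np.asarray(m)
    d = np.diagonal(e).astype(float)
    nb = d.size // block
    if nb == 0:
        raise ValueError("block larger than diagonal")
    return d[: nb * block].reshape(nb, block).mean(axis=1)


def to_image(m: RecurrenceMatrix, factor: int) -> RecurrenceImage:
    """Block-mean downsample by ``factor``; trailing partial blocks are truncated."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    n, c = m.shape
    h, w = n // factor, c // factor
    if h == 0 or w == 0:
        raise ValueError("factor larger than matrix")
    e = m.entries[: h * factor, : w * factor].astype(float)
    pixels = e.reshape(h, factor, w, factor).mean(axis=(1, 3))
    return RecurrenceImage(
        pixels=pixels,
        source=(m.row_source, m.col_source, m.is_cross),
        downsample_factor=factor,
    )
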