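"""CSV dialects and plot export.

Formats (all UTF-8, header required):

* R-R CSV:        ``subject_id,time_s,rr_ms``
* Index CSV:      ``subject_id,kind,time_s,value`` — empty value = missing
* Day-segment CSV: ``subject_id,kind,day_index,slot,level`` (slot 0–1439)
* Features CSV:   ``plot_id,d1..d16``
* Ground truth:   ``dyad_id,rho,psi_true``

Recurrence matrices export as grayscale PNG (1 = dark pixel, time origin
at the lower-left) or as a sparse ``i,j`` coordinate CSV.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .dayprep import DaySegment, Rejection
from .hrv import INDEX_KINDS, IndexSeries, RRSeries
from .recurrence import RecurrenceImage, RecurrenceMatrix

__all__ = [
    "read_rr_csv",
    "read_index_csv",
    "write_index_csv",
    "write_day_segments_csv",
    "write_features_csv",
    "write_rejections_csv",
    "matrix_to_png",
    "matrix_to_sparse_csv",
]


def read_rr_csv(path: str | Path) -> list[RRSeries]:
    """Parse an R-R CSV into one series per subject (order of appearance)."""
    df = pd.read_csv(path)
    required = {"subject_id", "time_s", "rr_ms"}
    if not required.issubset(df.columns):
        raise ValueError(f"R-R CSV must have columns {sorted(required)}")
    bad = df[df["rr_ms"].isna() | df["time_s"].isna()]
    if len(bad):
        lines = (bad.index + 2).tolist()  # +2: header + 1-based
        raise ValueError(f"malformed R-R rows at lines {lines}")
    out = []
    for sid, g in df.groupby("subject_id", sort=False):
        t = g["time_s"].to_numpy(float)
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"non-monotone times for subject {sid!r}")
        out.append(RRSeries(str(sid), t, g["rr_ms"].to_numpy(float)))
    return out


def read_index_csv(path: str | Path) -> list[IndexSeries]:
    """Parse an index CSV; an empty value field marks a missing grid point."""
    df = pd.read_csv(path)
    required = {"subject_id", "kind", "time_s", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"index CSV must have columns {sorted(required)}")
    out = []
    for (sid, kind), g in df.groupby(["subject_id", "kind"], sort=False):
        t = g["time_s"].to_numpy(float)
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"non-monotone times for subject {sid!r}")
        v = g["value"].to_numpy(float)  # empty cells parse to NaN
        out.append(
            IndexSeries(
                subject_id=str(sid), kind=str(kind), grid=t, values=v,
                missing=np.isnan(v),
            )
        )
    return out


def write_index_csv(path: str | Path, series: Iterable[IndexSeries]) -> None:
    frames = []
    for s in series:
        vals = s.values.astype(object)
        vals[s.missing] = None
        frames.append(
            pd.DataFrame(
                {"subject_id": s.subject_id, "kind": s.kind, "time_s": s.grid,
                 "value": vals}
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_day_segments_csv(path: str | Path, segments: Sequence[DaySegment]) -> None:
    frames = []
    for seg in segments:
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": seg.subject_id,
                    "kind": seg.kind,
                    "day_index": seg.day_index,
                    "slot": np.arange(seg.values.size),
                    "level": seg.levels,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_rejections_csv(path: str | Path, rejections: Sequence[Rejection]) -> None:
    pd.DataFrame(
        [
            {"subject_id": r.subject_id, "kind": r.kind,
             "day_index": r.day_index, "reason": r.reason}
            for r in rejections
        ],
        columns=["subject_id", "kind", "day_index", "reason"],
    ).to_csv(path, index=False)


def write_features_csv(
    path: str | Path, plot_ids: Sequence[str], activities: np.ndarray
) -> None:
    df = pd.DataFrame(activities, columns=[f"d{k}" for k in range(1, 17)])
    df.insert(0, "plot_id", list(plot_ids))
    df.to_csv(path, index=False)


def matrix_to_png(path: str | Path, m: RecurrenceMatrix | RecurrenceImage) -> None:
    """Grayscale PNG; recurrence = dark, time origin at the lower-left."""
    from PIL import Image

    a = m.entries.astype(float) if isinstance(m, RecurrenceMatrix) else m.pixels
    img = ((1.0 - a) * 255).astype(np.uint8)
    # row 0 is time origin; flip so it renders at the bottom of the image
    Image.fromarray(img[::-1, :], mode="L").save(path)


def matrix_to_sparse_csv(path: str | Path, m: RecurrenceMatrix) -> None:
    i, j = np.nonzero(m.entries)
    pd.DataFrame({"i": i, "j": j}).to_csv(path, index=False)
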