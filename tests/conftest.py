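from datetime import datetime

import numpy as np
import pytest

from dyadcrp.dayprep import DaySegment


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_discrete_segment(levels, subject="s1", kind="CVI", day=0):
    """A DaySegment in the discrete state from integer levels 0..10."""
    levels = np.asarray(levels, dtype=int)
    return DaySegment(
        subject_id=subject,
        kind=kind,
        day_index=day,
        start=datetime(2023, 1, 1, 22, 0),
        values=levels / 10.0,
        missing=np.zeros(levels.size, dtype=bool),
        state="discrete",
    )


def make_raw_segment(values, missing=None, subject="s1", kind="CVI", day=0):
    values = np.asarray(values, dtype=float)
    if missing is None:
        missing = np.isnan(values)
    return DaySegment(
        subject_id=subject,
        kind=kind,
        day_index=day,
        start=datetime(2023, 1, 1, 22, 0),
        values=values,
        missing=np.asarray(missing, dtype=bool),
        state="raw",
    )
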