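"""Parenting Stress Index (PSI) questionnaire scoring.

78 items rated 1–5.  Negatively worded items count as rated; positively
worded items are reverse-scored (6 − raw).  The total ranges 78–390; a
total of 221 or above flags excessively high stress (the instrument's
cut-off for specialist support).  Which items are reversed is proprietary
to the instrument and must be supplied by the caller; synthetic cohorts
use an empty reversed set.
"""

from __future__ import annotations

import numbers
from dataclasses import dataclass
from typing import Collection, Sequence

__all__ = ["N_ITEMS", "HIGH_RISK_CUTOFF", "PSIRecord", "score_psi"]

N_ITEMS = 78
HIGH_RISK_CUTOFF = 221


@dataclass(frozen=True)
class PSIRecord:
    total: int
    high_risk: bool


def score_psi(
    items: Sequence[int], reversed_items: Collection[int] = ()
) -> PSIRecord:
    """Score one 78-item response.

    ``reversed_items`` holds 0-based indices of positively worded items,
    scored as 6 − raw.  Raises on a wrong item count or out-of-range value,
    naming the offending item.
    """
    if len(items) != N_ITEMS:
        raise ValueError(f"expected {N_ITEMS} items, got {len(items)}")
    rev = set(reversed_items)
    if rev and (min(rev) < 0 or max(rev) >= N_ITEMS):
        raise ValueError("reversed item index out of range")
    total = 0
    for i, raw in enumerate(items):
        if not isinstance(raw, numbers.Integral) or isinstance(raw, bool):
            raise ValueError(f"item {i + 1}: value {raw!r} is not an integer")
        if not 1 <= raw <= 5:
            raise ValueError(f"item {i + 1}: value {raw} outside 1..5")
        total += (6 - raw) if i in rev else raw
    return PSIRecord(total=total, high_risk=total >= HIGH_RISK_CUTOFF)
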