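"""Small shared helpers: half-up rounding and interval arithmetic."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, List, Tuple

import numpy as np

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties going away from zero, the convention of printed tables
    (Python's built-in ``round`` uses banker's rounding)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent(x: float, ndigits: int = 2) -> float:
    """Express a fraction as a percentage rounded half-up."""
    return round_half_up(100.0 * x, ndigits)


def merge_intervals(intervals: Iterable[Tuple[int, int]]) -> List[Tuple[int, int]]:
    """Merge overlapping or touching half-open intervals into a sorted
    disjoint list."""
    ivs = sorted((s, e) for s, e in intervals if e > s)
    merged: List[Tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def union_length(intervals: Iterable[Tuple[int, int]]) -> int:
    return sum(e - s for s, e in merge_intervals(intervals))


def coverage_mask(intervals: Iterable[Tuple[int, int]], length: int) -> np.ndarray:
    """Boolean per-base mask of the union of half-open intervals."""
    mask = np.zeros(length, dtype=bool)
    for s, e in intervals:
        mask[max(s, 0) : min(e, length)] = True
    return mask
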