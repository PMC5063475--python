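"""Repeat landscape: long forward/palindromic repeats and tandem arrays.

Plant mitochondrial genomes carry large repeated tracts that mediate
recombination; the quantities of interest here are the maximal exact
repeated pairs of at least a minimum length (in direct and inverted
orientation) and maximal exact tandem arrays, plus the fraction of the
genome covered by repeats. Discovery is exact-match only: long-repeat
pairs are found by seeding on a shared k-mer index and extending each
seed to the maximal common run, tandem arrays by per-period match
scanning.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from ._util import merge_intervals, reverse_complement

__all__ = [
    "RepeatHit",
    "find_long_repeats",
    "find_tandem_repeats",
    "repeat_fraction",
]

_SEED_K = 21


@dataclass(frozen=True)
class RepeatHit:
    """One repeat: a pair of exact copies (forward/palindromic) or a
    tandem array (pos2 == pos1; length is the whole array)."""

    kind: str
    pos1: int
    pos2: int
    length: int
    period: Optional[int] = None
    copies: Optional[int] = None

    def intervals(self) -> List[Tuple[int, int]]:
        if self.kind == "tandem":
            return [(self.pos1, self.pos1 + self.length)]
        return [
            (self.pos1, self.pos1 + self.length),
            (self.pos2, self.pos2 + self.length),
        ]


def _kmer_index(s: str, k: int) -> Dict[str, List[int]]:
    index: Dict[str, List[int]] = defaultdict(list)
    for i in range(len(s) - k + 1):
        index[s[i : i + k]].append(i)
    return index


def _maximal_run(a: str, b: str, i: int, j: int, k: int) -> Tuple[int, int, int]:
    """Extend an exact k-mer match a[i:i+k]==b[j:j+k] to the maximal common
    run; returns (run_start_in_a, run_start_in_b, run_length)."""
    s, t = i, j
    while s > 0 and t > 0 and a[s - 1] == b[t - 1]:
        s -= 1
        t -= 1
    e, f = i + k, j + k
    while e < len(a) and f < len(b) and a[e] == b[f]:
        e += 1
        f += 1
    return s, t, e - s


def _paired_runs(a: str, b: str, k: int) -> Set[Tuple[int, int, int]]:
    """All maximal common runs of length >= k between two strings, as
    (start_in_a, start_in_b, length), found by seeding on shared k-mers."""
    index = _kmer_index(b, k)
    covered: Dict[int, List[Tuple[int, int]]] = defaultdict(list)  # diag -> a-spans
    runs: Set[Tuple[int, int, int]] = set()
    for i in range(len(a) - k + 1):
        for j in index.get(a[i : i + k], ()):
            diag = j - i
            if any(s <= i < e for s, e in covered[diag]):
                continue
            s, t, length = _maximal_run(a, b, i, j, k)
            covered[diag].append((s, s + length))
            runs.add((s, t, length))
    return runs


def find_long_repeats(seq: str, min_len: int = 100) -> List[RepeatHit]:
    """Maximal exact repeated pairs of length >= ``min_len``.

    Forward pairs are identical substrings at two positions; palindromic
    pairs are a substring and its reverse complement elsewhere. Each pair
    is reported once with ``pos1 < pos2``. Overlapping copies (as inside
    long tandem tracts) are legitimate pairs and are reported.
    """
    if min_len < 8:
        raise ValueError("min_len below 8 makes seeding infeasible")
    if len(seq) < min_len:
        raise ValueError("sequence shorter than min_len")
    seq = seq.upper()
    k = min(_SEED_K, min_len)
    n = len(seq)
    hits: Set[RepeatHit] = set()
    # forward: seq against itself, distinct positions only
    for s, t, length in _paired_runs(seq, seq, k):
        if length >= min_len and s < t:
            hits.add(RepeatHit("forward", s, t, length))
    # palindromic: seq against its reverse complement; a run starting at t
    # in rc(seq) corresponds to the seq interval [n - t - length, n - t)
    rc = reverse_complement(seq)
    for s, t, length in _paired_runs(seq, rc, k):
        if length < min_len:
            continue
        j = n - t - length
        p1, p2 = min(s, j), max(s, j)
        if p1 != p2:
            hits.add(RepeatHit("palindromic", p1, p2, length))
    return sorted(hits, key=lambda h: (h.pos1, h.pos2, h.kind))


def _true_runs(mask: np.ndarray) -> List[Tuple[int, int]]:
    """(start, end) half-open spans of consecutive True values."""
    padded = np.concatenate(([False], mask, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def find_tandem_repeats(
    seq: str,
    min_period: int = 2,
    min_copies: int = 3,
    min_array: int = 24,
    max_period: Optional[int] = None,
) -> List[RepeatHit]:
    """Maximal exact tandem arrays: a unit of ``period`` bases repeated
    contiguously at least ``min_copies`` times, spanning >= ``min_array``
    bases. Arrays are reported at their primitive period; reports wholly
    contained in a larger (or equal, smaller-period) array are collapsed.
    """
    if min_period < 1 or min_copies < 2 or min_array < 1:
        raise ValueError("thresholds must be positive (min_copies >= 2)")
    seq = seq.upper()
    n = len(seq)
    arr = np.frombuffer(seq.encode(), dtype="S1")
    if max_period is None:
        max_period = n // min_copies
    candidates: List[Tuple[int, int, int, int]] = []  # (start, end, period, copies)
    for p in range(min_period, max_period + 1):
        if n < p * min_copies:
            break
        match = arr[: n - p] == arr[p:]
        for s, e in _true_runs(match):
            array_len = (e - s) + p
            copies = array_len // p
            if array_len >= min_array and copies >= min_copies:
                candidates.append((s, s + array_len, p, copies))
    # collapse: keep the longest arrays; among equal intervals the smallest
    # (primitive) period wins; anything contained in a kept array is dropped
    candidates.sort(key=lambda c: (-(c[1] - c[0]), c[2]))
    kept: List[Tuple[int, int, int, int]] = []
    for s, e, p, c in candidates:
        if any(ks <= s and e <= ke for ks, ke, _, _ in kept):
            continue
        kept.append((s, e, p, c))
    return sorted(
        (RepeatHit("tandem", s, s, e - s, period=p, copies=c) for s, e, p, c in kept),
        key=lambda h: h.pos1,
    )


def repeat_fraction(hits: Sequence[RepeatHit], genome_len: int) -> float:
    """Fraction of the genome covered by repeats: the union of all copy
    intervals (both copies of a pair; the whole tandem array), overlaps
    counted once."""
    if genome_len <= 0:
        raise ValueError("genome_len must be positive")
    intervals = [iv for h in hits for iv in h.intervals()]
    for s, e in intervals:
        if s < 0 or e > genome_len:
            raise ValueError("repeat interval outside the genome")
    covered = sum(e - s for s, e in merge_intervals(intervals))
    return covered / genome_len
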