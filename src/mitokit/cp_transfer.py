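"""Detection of chloroplast-derived regions (MTPTs) in a mitochondrial genome.

Plant mitochondrial genomes accumulate segments of plastid DNA through
intracellular transfer. These are found here by local homology between the
mt genome and the plastid genome: exact word seeding followed by ungapped
X-drop extension, with hits retained when they pass identity, length and
E-value thresholds and then merged along the mitochondrial axis into
maximal regions. The scoring scheme is match +1 / mismatch -2 and the
E-value uses the Karlin-Altschul form E = K*m*n*exp(-lambda*S) with the
(lambda, K) pair tabulated for that scheme. Gapped extension is not
attempted: the retention thresholds are identity- and length-based, and at
the divergence levels of recent plastid transfers ungapped chains recover
the transferred segments.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ._util import merge_intervals, percent, reverse_complement
from .core import AnnotatedGenome, RegionSet, gc_content

__all__ = ["HomologyHit", "find_cp_derived", "cp_region_stats"]

# Karlin-Altschul parameters for ungapped scoring with reward +1/penalty -2.
_LAMBDA = 1.33
_K = 0.621

_WORD_SIZE = 11
_MATCH = 1
_MISMATCH = -2
_XDROP = 20


@dataclass(frozen=True)
class HomologyHit:
    """One ungapped local alignment between the mt and cp genomes.

    ``cp_start``/``cp_end`` are forward-strand cp coordinates; for a minus
    strand hit the mt interval aligns to the reverse complement of that cp
    interval.
    """

    mt_start: int
    mt_end: int
    cp_start: int
    cp_end: int
    strand: str
    identity: float
    aln_len: int
    score: int
    evalue: float


def _evalue(score: int, m: int, n: int) -> float:
    return _K * m * n * math.exp(-_LAMBDA * score)


def _extend(
    mt: str, cp: str, mt_pos: int, cp_pos: int, w: int
) -> Tuple[int, int, int, int]:
    """X-drop ungapped extension of an exact ``w``-mer seed.

    Returns (mt_start, mt_end, score, n_matches) with the seed interval
    extended to the best-scoring extents in both directions.
    """
    # right extension from the seed end
    best = cur = w * _MATCH
    best_right = mt_pos + w
    i, j = mt_pos + w, cp_pos + w
    while i < len(mt) and j < len(cp):
        cur += _MATCH if mt[i] == cp[j] else _MISMATCH
        i += 1
        j += 1
        if cur > best:
            best, best_right = cur, i
        elif cur <= best - _XDROP:
            break
    # left extension from the seed start
    cur = best
    best_left = mt_pos
    i, j = mt_pos - 1, cp_pos - 1
    while i >= 0 and j >= 0:
        cur += _MATCH if mt[i] == cp[j] else _MISMATCH
        if cur > best:
            best, best_left = cur, i
        elif cur <= best - _XDROP:
            break
        i -= 1
        j -= 1
    aln_len = best_right - best_left
    # score = matches*1 + mismatches*(-2)  =>  matches = (score + 2*len)/3
    n_matches = (best + 2 * aln_len) // 3
    return best_left, best_right, best, n_matches


def _scan_strand(
    mt: str, cp_oriented: str, strand: str, min_len: int
) -> List[Tuple[int, int, int, int, str, int, int]]:
    """All seeded ungapped extensions of one cp orientation against mt.

    Returns raw hits as (mt_start, mt_end, cp_start_or, cp_end_or, strand,
    score, n_matches) in the *oriented* cp frame.
    """
    index: Dict[str, List[int]] = defaultdict(list)
    for i in range(len(mt) - _WORD_SIZE + 1):
        index[mt[i : i + _WORD_SIZE]].append(i)
    seen: Dict[int, List[Tuple[int, int]]] = defaultdict(list)  # diag -> cp spans
    hits = []
    for j in range(len(cp_oriented) - _WORD_SIZE + 1):
        word = cp_oriented[j : j + _WORD_SIZE]
        for i in index.get(word, ()):
            diag = j - i
            if any(a <= j < b for a, b in seen[diag]):
                continue
            mt_s, mt_e, score, n_match = _extend(mt, cp_oriented, i, j, _WORD_SIZE)
            cp_s, cp_e = mt_s + diag, mt_e + diag
            seen[diag].append((cp_s, cp_e))
            if mt_e - mt_s >= min_len:
                hits.append((mt_s, mt_e, cp_s, cp_e, strand, score, n_match))
    return hits


def find_cp_derived(
    mt: AnnotatedGenome,
    cp: str,
    min_identity: float = 0.80,
    max_evalue: float = 1e-5,
    min_len: int = 50,
) -> Tuple[RegionSet, List[HomologyHit]]:
    """Find cp-derived regions of the mt genome by thresholded homology.

    Both strands of the plastid sequence are searched. Hits failing the
    identity, E-value or length threshold are discarded; the mt intervals
    of the survivors are merged into maximal disjoint regions labelled
    ``cp1``, ``cp2``, ... in genome order. Returns the merged region set
    together with the underlying hit list.
    """
    if not mt.seq or not cp:
        raise ValueError("both sequences must be non-empty")
    if not 0.0 < min_identity <= 1.0:
        raise ValueError("min_identity must lie in (0, 1]")
    if max_evalue <= 0 or min_len < _WORD_SIZE:
        raise ValueError(
            f"max_evalue must be positive and min_len >= word size {_WORD_SIZE}"
        )
    cp = cp.upper()
    m, n = mt.length, len(cp)
    hits: List[HomologyHit] = []
    for strand, oriented in (("+", cp), ("-", reverse_complement(cp))):
        for mt_s, mt_e, cp_s, cp_e, st, score, n_match in _scan_strand(
            mt.seq, oriented, strand, min_len
        ):
            aln_len = mt_e - mt_s
            identity = n_match / aln_len
            ev = _evalue(score, m, n)
            if identity < min_identity or ev > max_evalue:
                continue
            if strand == "-":  # map back to forward cp coordinates
                cp_s, cp_e = n - cp_e, n - cp_s
            hits.append(
                HomologyHit(
                    mt_start=mt_s,
                    mt_end=mt_e,
                    cp_start=cp_s,
                    cp_end=cp_e,
                    strand=strand,
                    identity=identity,
                    aln_len=aln_len,
                    score=score,
                    evalue=ev,
                )
            )
    hits = sorted(set(hits), key=lambda h: (h.mt_start, h.mt_end, h.strand))
    merged = merge_intervals((h.mt_start, h.mt_end) for h in hits)
    regions = RegionSet(
        regions=[(s, e, f"cp{i + 1}") for i, (s, e) in enumerate(merged)],
        frame=mt.id,
    )
    return regions, hits


def cp_region_stats(
    mt: AnnotatedGenome, regions: RegionSet, cp: str
) -> Dict[str, object]:
    """Composition summary of the cp-derived regions.

    GC contents of the plastid genome, of the detected regions, and of the
    mt remainder; plus the coding fraction inside the regions (union of
    coding feature bases over region length).
    """
    if len(regions) == 0:
        return {
            "total_len": 0,
            "fraction_of_genome": 0.0,
            "percent_of_genome": 0.0,
            "gc_cp": gc_content(cp),
            "gc_regions": 0.0,
            "gc_mt_remainder": gc_content(mt.seq),
            "coding_fraction_within_regions": 0.0,
            "empty": True,
        }
    mask = regions.mask(mt.length)
    total = int(mask.sum())
    seq_arr = np.frombuffer(mt.seq.encode(), dtype="S1")
    region_seq = seq_arr[mask].tobytes().decode()
    remainder = seq_arr[~mask].tobytes().decode()
    coding = np.zeros(mt.length, dtype=bool)
    for f in mt.features:
        if f.ftype in ("protein_coding", "orf", "tRNA", "rRNA", "pseudogene"):
            for a, b in f.intervals(mt.length):
                coding[a:b] = True
    return {
        "total_len": total,
        "fraction_of_genome": total / mt.length,
        "percent_of_genome": percent(total / mt.length),
        "gc_cp": gc_content(cp),
        "gc_regions": gc_content(region_seq),
        "gc_mt_remainder": gc_content(remainder) if remainder else 0.0,
        "coding_fraction_within_regions": float((coding & mask).sum()) / total,
        "empty": False,
    }
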