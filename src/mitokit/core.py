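"""Domain model for an annotated organelle genome.

The central object is :class:`AnnotatedGenome`: a (possibly circular) DNA
sequence plus a typed feature table. All coordinates are 0-based half-open
on the forward strand; format readers convert GFF3/VCF 1-based conventions
at the boundary. A feature on a circular genome may wrap the origin, in
which case ``end > length`` and the interval is interpreted modulo the
genome length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from ._util import coverage_mask, percent, reverse_complement

__all__ = [
    "Feature",
    "AnnotatedGenome",
    "RegionSet",
    "gc_content",
    "composition_report",
    "FEATURE_TYPES",
]

FEATURE_TYPES = frozenset(
    {"protein_coding", "pseudogene", "tRNA", "rRNA", "orf", "other"}
)

# Composition classes in precedence order; ORFs are hypothetical
# protein-coding genes and are pooled with them for content accounting.
_CLASS_OF_FTYPE = {
    "protein_coding": "protein_coding",
    "orf": "protein_coding",
    "pseudogene": "pseudogene",
    "tRNA": "tRNA",
    "rRNA": "rRNA",
}
CODING_CLASSES = ("protein_coding", "pseudogene", "tRNA", "rRNA")


@dataclass
class Feature:
    """A typed genomic interval (gene, pseudogene, tRNA, rRNA, ORF...).

    ``start``/``end`` are 0-based half-open. ``gene_family`` holds the
    functional family prefix (``nad``, ``rps``, ``trn``, ...). tRNA features
    may carry their three-letter anticodon (RNA alphabet).
    """

    id: str
    ftype: str
    start: int
    end: int
    strand: str = "+"
    gene_family: str = ""
    cp_derived: bool = False
    cds_phase: int = 0
    anticodon: Optional[str] = None

    def __post_init__(self) -> None:
        if self.ftype not in FEATURE_TYPES:
            raise ValueError(f"feature {self.id!r}: unknown ftype {self.ftype!r}")
        if self.start >= self.end:
            raise ValueError(f"feature {self.id!r}: start must precede end")
        if self.strand not in "+-":
            raise ValueError(f"feature {self.id!r}: strand must be '+' or '-'")
        if not 0 <= self.cds_phase <= 2:
            raise ValueError(f"feature {self.id!r}: cds_phase must be 0..2")

    @property
    def length(self) -> int:
        return self.end - self.start

    def intervals(self, genome_length: int) -> List[Tuple[int, int]]:
        """Linear pieces of the feature; two pieces if it wraps the origin."""
        if self.end <= genome_length:
            return [(self.start, self.end)]
        return [(self.start, genome_length), (0, self.end - genome_length)]


@dataclass
class AnnotatedGenome:
    id: str
    seq: str
    circular: bool = False
    features: List[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        bad = set(self.seq) - set("ACGTN")
        if bad:
            raise ValueError(f"genome {self.id!r}: non-DNA characters {sorted(bad)}")
        self.validate()

    @property
    def length(self) -> int:
        return len(self.seq)

    def validate(self) -> None:
        for f in self.features:
            if f.start < 0 or f.start >= self.length:
                raise ValueError(
                    f"feature {f.id!r} start {f.start} outside genome "
                    f"{self.id!r} of length {self.length}"
                )
            if f.end > self.length and not self.circular:
                raise ValueError(
                    f"feature {f.id!r} end {f.end} beyond linear genome "
                    f"{self.id!r} of length {self.length}"
                )
            if f.end - f.start > self.length:
                raise ValueError(f"feature {f.id!r} longer than the genome")

    def feature_seq(self, f: Feature) -> str:
        """Sense-strand sequence of a feature (wrap-aware)."""
        s = "".join(self.seq[a:b] for a, b in f.intervals(self.length))
        return reverse_complement(s) if f.strand == "-" else s


@dataclass
class RegionSet:
    """Labelled intervals in one genome's coordinate frame (cp-derived
    regions, repeat regions, exclusion masks...)."""

    regions: List[Tuple[int, int, str]] = field(default_factory=list)
    frame: str = ""

    def __post_init__(self) -> None:
        labels = [r[2] for r in self.regions]
        if len(labels) != len(set(labels)):
            raise ValueError("region labels must be unique")
        for s, e, lab in self.regions:
            if s >= e:
                raise ValueError(f"region {lab!r}: empty or inverted interval")

    def __len__(self) -> int:
        return len(self.regions)

    def intervals(self) -> List[Tuple[int, int]]:
        return [(s, e) for s, e, _ in self.regions]

    def union_length(self) -> int:
        from ._util import union_length

        return union_length(self.intervals())

    def contains(self, pos: int) -> bool:
        return any(s <= pos < e for s, e, _ in self.regions)

    def mask(self, length: int) -> np.ndarray:
        return coverage_mask(self.intervals(), length)


def gc_content(seq: str) -> float:
    """G+C fraction over unambiguous bases; N is excluded from both the
    numerator and the denominator."""
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    if gc + at == 0:
        raise ValueError("sequence contains no unambiguous bases")
    return gc / (gc + at)


def _class_masks(genome: AnnotatedGenome) -> Dict[str, np.ndarray]:
    masks = {c: np.zeros(genome.length, dtype=bool) for c in CODING_CLASSES}
    for f in genome.features:
        cls = _CLASS_OF_FTYPE.get(f.ftype)
        if cls is None:
            continue
        for a, b in f.intervals(genome.length):
            masks[cls][a:b] = True
    return masks


def composition_report(genome: AnnotatedGenome) -> dict:
    """Per-class base content of the genome.

    Classes are protein-coding (including hypothetical ORFs), pseudogene,
    tRNA, rRNA and the non-coding remainder. Overlaps within a class count
    once; bases claimed by more than one class are assigned by the
    precedence order above so that class fractions partition the genome
    exactly. The headline gene-content figure is the union of the four
    coding classes.
    """
    genome.validate()
    masks = _class_masks(genome)
    claimed = np.zeros(genome.length, dtype=bool)
    report_classes: Dict[str, dict] = {}
    seq_arr = np.frombuffer(genome.seq.encode(), dtype="S1")

    def _gc_of(mask: np.ndarray) -> Optional[float]:
        if not mask.any():
            return None
        sub = seq_arr[mask]
        gc = int(np.sum((sub == b"G") | (sub == b"C")))
        acgt = int(np.sum(sub != b"N"))
        return gc / acgt if acgt else None

    for cls in CODING_CLASSES:
        own = masks[cls] & ~claimed
        claimed |= masks[cls]
        report_classes[cls] = {
            "bases": int(own.sum()),
            "fraction": own.sum() / genome.length if genome.length else 0.0,
            "gc": _gc_of(own),
        }
    noncoding = ~claimed
    report_classes["noncoding"] = {
        "bases": int(noncoding.sum()),
        "fraction": noncoding.sum() / genome.length if genome.length else 1.0,
        "gc": _gc_of(noncoding),
    }

    gene_bases = int(claimed.sum())
    # Loci vs unique products: the feature table counts loci; unique gene
    # names collapse multi-copy genes.
    loci: Dict[str, int] = {c: 0 for c in CODING_CLASSES}
    names: Dict[str, set] = {c: set() for c in CODING_CLASSES}
    for f in genome.features:
        cls = _CLASS_OF_FTYPE.get(f.ftype)
        if cls is None:
            continue
        loci[cls] += 1
        names[cls].add(f.gene_family or f.id)
    return {
        "genome": {"length": genome.length, "gc": gc_content(genome.seq)},
        "classes": report_classes,
        "gene_content": {
            "bases": gene_bases,
            "percent": percent(gene_bases / genome.length) if genome.length else 0.0,
        },
        "loci": loci,
        "unique_genes": {c: len(names[c]) for c in CODING_CLASSES},
    }
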