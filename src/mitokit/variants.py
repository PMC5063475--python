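"""Dual-caller variant concordance, context classification, and Ti/Tv.

Organelle variant calls are noisy enough that a single caller is not
trusted: only sites recovered by both callers at an adequate alternative
allele fraction are kept. Retained variants are then classified against
the annotation (synonymous/nonsynonymous for coding SNPs) and against the
chloroplast-derived region mask, and transition/transversion ratios are
computed overall and with cp-derived regions excluded — the stratification
that separates intrinsic mitochondrial mutation spectra from collapsed
plastid paralogy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple

from Bio.Seq import Seq

from ._util import round_half_up, reverse_complement
from .core import AnnotatedGenome, Feature, RegionSet

__all__ = [
    "Variant",
    "intersect_callsets",
    "classify_variants",
    "titv",
    "variation_rate",
    "is_transition",
]

CONTEXTS = (
    "protein_coding_syn",
    "protein_coding_nonsyn",
    "tRNA",
    "rRNA",
    "noncoding",
)


@dataclass
class Variant:
    """A site-level DNA difference against the reference genome."""

    pos: int
    ref: str
    alt: str
    alt_fraction: float = 1.0
    callers: FrozenSet[str] = frozenset()
    context: Optional[str] = None
    cp_derived: bool = False
    genome_id: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.alt_fraction <= 1.0:
            raise ValueError("alt_fraction must lie in [0, 1]")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt alleles must be non-empty")

    @property
    def vclass(self) -> str:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return "snp"
        return "insertion" if len(self.alt) > len(self.ref) else "deletion"

    @property
    def key(self) -> Tuple[int, str, str]:
        return (self.pos, self.ref, self.alt)


def intersect_callsets(
    a: Sequence[Variant],
    b: Sequence[Variant],
    min_alt_fraction: float = 0.15,
    caller_names: Tuple[str, str] = ("A", "B"),
) -> List[Variant]:
    """Variants called identically (pos, ref, alt) by both callers, each
    with alternative allele fraction at or above the threshold.

    The retained record carries the smaller of the two allele fractions
    (the conservative support estimate) and ``callers`` set to both names.
    """
    if not 0.0 <= min_alt_fraction <= 1.0:
        raise ValueError("min_alt_fraction must lie in [0, 1]")
    frames_a = {v.genome_id for v in a if v.genome_id}
    frames_b = {v.genome_id for v in b if v.genome_id}
    if frames_a and frames_b and frames_a != frames_b:
        raise ValueError(f"callsets are on different genomes: {frames_a} vs {frames_b}")
    index_b = {v.key: v for v in b if v.alt_fraction >= min_alt_fraction}
    shared: List[Variant] = []
    for va in a:
        if va.alt_fraction < min_alt_fraction:
            continue
        vb = index_b.get(va.key)
        if vb is None:
            continue
        shared.append(
            replace(
                va,
                alt_fraction=min(va.alt_fraction, vb.alt_fraction),
                callers=frozenset(caller_names),
            )
        )
    return shared


def _coding_context(v: Variant, genome: AnnotatedGenome, f: Feature) -> Tuple[str, int]:
    """Classify a SNP inside a protein-coding feature; returns
    (context, warning_flag)."""
    if v.vclass != "snp":
        return "protein_coding_nonsyn", 0  # indel in CDS: frame-disrupting
    cds = genome.feature_seq(f)[f.cds_phase :]
    if f.strand == "+":
        off = v.pos - f.start - f.cds_phase
    else:
        off = (f.end - 1 - v.pos) - f.cds_phase
    if off < 0 or off + 1 > len(cds):
        return "noncoding", 1
    ci = off // 3
    codon = cds[3 * ci : 3 * ci + 3]
    if len(codon) < 3:
        return "noncoding", 1  # codon truncated at the feature edge
    alt_base = v.alt if f.strand == "+" else reverse_complement(v.alt)
    cp = off % 3
    codon_alt = codon[:cp] + alt_base + codon[cp + 1 :]
    syn = Seq(codon).translate() == Seq(codon_alt).translate()
    return ("protein_coding_syn" if syn else "protein_coding_nonsyn"), 0


def classify_variants(
    variants: Sequence[Variant],
    genome: AnnotatedGenome,
    cp_regions: Optional[RegionSet] = None,
) -> List[Variant]:
    """Attach genomic context and the cp-derived flag to each variant.

    Coding synonymy is decided by translating the containing codon on the
    feature strand with the reference versus the alternative base. A SNP
    whose codon is incomplete at a feature edge falls back to noncoding
    (with a warning counted in the feature's frame, not raised).
    """
    out: List[Variant] = []
    coding = [f for f in genome.features if f.ftype in ("protein_coding", "orf")]
    rnas = [f for f in genome.features if f.ftype in ("tRNA", "rRNA")]
    for v in variants:
        if v.pos < 0 or v.pos >= genome.length:
            raise ValueError(f"variant at {v.pos} outside genome of length {genome.length}")
        context = "noncoding"
        host = next((f for f in coding if f.start <= v.pos < f.end), None)
        if host is not None:
            context, _ = _coding_context(v, genome, host)
        else:
            rna = next((f for f in rnas if f.start <= v.pos < f.end), None)
            if rna is not None:
                context = rna.ftype
        cp_flag = bool(cp_regions.contains(v.pos)) if cp_regions is not None else False
        out.append(replace(v, context=context, cp_derived=cp_flag))
    return out


def is_transition(ref: str, alt: str) -> bool:
    return {ref.upper(), alt.upper()} in ({"A", "G"}, {"C", "T"})


def titv(
    variants: Sequence[Variant], exclude: Optional[RegionSet] = None
) -> Dict[str, object]:
    """Transition/transversion tally over SNPs, optionally dropping
    variants inside an exclusion region set first.

    With zero transversions the ratio is reported as ``None`` (undefined)
    rather than infinite — small stratified sets hit this routinely.
    """
    n_ti = n_tv = n_ignored = 0
    for v in variants:
        if exclude is not None and exclude.contains(v.pos):
            continue
        if v.vclass != "snp":
            n_ignored += 1
            continue
        if is_transition(v.ref, v.alt):
            n_ti += 1
        else:
            n_tv += 1
    ratio = round_half_up(n_ti / n_tv, 2) if n_tv else None
    return {"n_ti": n_ti, "n_tv": n_tv, "ratio": ratio, "n_ignored": n_ignored}


def variation_rate(
    n_snps: int, n_indels: int, denominator_bases: int
) -> Dict[str, float]:
    """Variations per kilobase, raw and rounded to the nearest integer."""
    if denominator_bases <= 0:
        raise ValueError("denominator_bases must be positive")
    raw = (n_snps + n_indels) / denominator_bases * 1000.0
    return {"per_kb": raw, "per_kb_rounded": int(round_half_up(raw, 0))}
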