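"""Pileup-based RNA-editing detection and downstream classification.

Plant mitochondrial transcripts are edited post-transcriptionally, almost
always cytidine-to-uridine, which appears in RNA-seq pileups as a C-to-T
mismatch against the genomic reference (G-to-A on the genome strand for
minus-strand genes). A site is called in a sample when some non-reference
base reaches both an absolute read-support floor and a minimum fraction of
the base calls at that position — the fraction threshold is what separates
editing (typically near-complete) from sequencing error and residual DNA
variation.

Called sites are classified against the annotation (codon, codon position,
amino-acid change, synonymy, all on the gene's sense strand), aggregated
across samples and cultivars, ranked by codon-change class, and compared
with externally predicted site lists.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd
from Bio.Seq import Seq

from ._util import percent, reverse_complement
from .core import AnnotatedGenome, Feature, RegionSet

__all__ = [
    "EditingSite",
    "call_editing_sites",
    "classify_edit",
    "aggregate_samples",
    "rank_codon_changes",
    "compare_editing_sets",
]

_BASES = ("A", "C", "G", "T")
_COUNT_COL = {"A": "countA", "C": "countC", "G": "countG", "T": "countT"}


@dataclass
class EditingSite:
    """A single editing site: genome position plus sense-strand edit typing
    and, for genic sites, the codon context."""

    pos: int
    gene: str = "."
    strand: str = "+"
    ref_sense: str = ""
    alt_sense: str = ""
    codon_ref: Optional[str] = None
    codon_alt: Optional[str] = None
    codon_pos: Optional[int] = None
    synonymy: Optional[str] = None
    aa_ref: Optional[str] = None
    aa_alt: Optional[str] = None
    support: Dict[str, Tuple[int, int, float]] = field(default_factory=dict)
    cp_derived: bool = False
    frame_broken: bool = False

    @property
    def edit_type(self) -> str:
        return f"{self.ref_sense}->{self.alt_sense}"

    @property
    def key(self) -> Tuple[int, str]:
        return (self.pos, self.alt_sense)


def classify_edit(
    site: EditingSite, genome: AnnotatedGenome, feature: Feature
) -> EditingSite:
    """Fill codon context and synonymy for a site inside a protein-coding
    feature, reading the codon on the feature's strand in feature frame.

    A feature whose CDS length (after phase) is not a codon multiple has a
    broken reading frame; classification is refused and the site flagged.
    """
    cds = genome.feature_seq(feature)[feature.cds_phase :]
    if len(cds) % 3 != 0:
        return replace(site, gene=feature.id, strand=feature.strand, frame_broken=True)
    if feature.strand == "+":
        off = site.pos - feature.start - feature.cds_phase
    else:
        off = (feature.end - 1 - site.pos) - feature.cds_phase
    if off < 0 or off >= len(cds):
        return replace(site, gene=feature.id, strand=feature.strand, frame_broken=True)
    ci, cp = divmod(off, 3)
    codon_ref = cds[3 * ci : 3 * ci + 3]
    codon_alt = codon_ref[:cp] + site.alt_sense + codon_ref[cp + 1 :]
    aa_ref = str(Seq(codon_ref).translate())
    aa_alt = str(Seq(codon_alt).translate())
    return replace(
        site,
        gene=feature.id,
        strand=feature.strand,
        codon_ref=codon_ref,
        codon_alt=codon_alt,
        codon_pos=cp + 1,
        aa_ref=aa_ref,
        aa_alt=aa_alt,
        synonymy="synonymous" if aa_ref == aa_alt else "nonsynonymous",
    )


def call_editing_sites(
    pileup: pd.DataFrame,
    genome: AnnotatedGenome,
    sample_id: str = "sample",
    min_alt_reads: int = 3,
    min_alt_frac: float = 0.5,
    cp_regions: Optional[RegionSet] = None,
) -> Tuple[List[EditingSite], int]:
    """Call editing sites from one sample's per-site base counts.

    A site is called when some non-reference base has at least
    ``min_alt_reads`` supporting reads AND a fraction of the base calls at
    or above ``min_alt_frac`` (both thresholds inclusive). Sites inside a
    protein-coding gene are typed on the gene's sense strand and given
    codon context; intergenic sites are typed on the plus strand with
    ``gene='.'``. Zero-depth rows are skipped and tallied.

    Returns (sites, n_skipped).
    """
    if min_alt_reads < 1 or not 0.0 < min_alt_frac <= 1.0:
        raise ValueError("min_alt_reads must be >= 1 and min_alt_frac in (0, 1]")
    coding = sorted(
        (f for f in genome.features if f.ftype in ("protein_coding", "orf")),
        key=lambda f: f.start,
    )
    sites: List[EditingSite] = []
    skipped = 0
    for row in pileup.itertuples(index=False):
        pos = int(row.pos)
        if pos < 0 or pos >= genome.length:
            raise ValueError(f"pileup position {pos} outside the genome")
        counts = {b: int(getattr(row, _COUNT_COL[b])) for b in _BASES}
        total = sum(counts.values())
        if total == 0:
            skipped += 1
            continue
        ref = genome.seq[pos]
        alt, alt_n = max(
            ((b, c) for b, c in counts.items() if b != ref),
            key=lambda bc: bc[1],
        )
        frac = alt_n / total
        if alt_n < min_alt_reads or frac < min_alt_frac:
            continue
        host = next((f for f in coding if f.start <= pos < f.end), None)
        if host is not None and host.strand == "-":
            ref_sense, alt_sense = reverse_complement(ref), reverse_complement(alt)
        else:
            ref_sense, alt_sense = ref, alt
        site = EditingSite(
            pos=pos,
            ref_sense=ref_sense,
            alt_sense=alt_sense,
            support={sample_id: (alt_n, total, frac)},
            cp_derived=bool(cp_regions.contains(pos)) if cp_regions else False,
        )
        if host is not None:
            site = classify_edit(site, genome, host)
        sites.append(site)
    return sites, skipped


def _merge_support(sites: Iterable[EditingSite]) -> EditingSite:
    merged = None
    for s in sites:
        if merged is None:
            merged = replace(s, support=dict(s.support))
        else:
            merged.support.update(s.support)
    assert merged is not None
    return merged


def aggregate_samples(
    per_sample: Sequence[Tuple[str, Sequence[EditingSite]]],
    cultivar_of: Optional[Mapping[str, str]] = None,
    min_datasets: int = 1,
) -> Dict[str, object]:
    """Merge per-sample editing calls into a union table with sharing stats.

    Sites are identified by (position, sense alternative base). The result
    carries, per sample, the site count, its percentage of the union and
    the number of sites private to that sample; the count of sites shared
    by every sample; and per-cultivar unions/intersections when a
    sample-to-cultivar map is given. ``min_datasets`` drops union sites
    supported by fewer samples before any statistic is computed.
    """
    ids = [sid for sid, _ in per_sample]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate sample ids")
    if not ids:
        raise ValueError("at least one sample is required")
    by_key: Dict[Tuple[int, str], List[EditingSite]] = defaultdict(list)
    carriers: Dict[Tuple[int, str], Set[str]] = defaultdict(set)
    for sid, sites in per_sample:
        for s in sites:
            by_key[s.key].append(s)
            carriers[s.key].add(sid)
    keys = {k for k in by_key if len(carriers[k]) >= min_datasets}
    union = [_merge_support(by_key[k]) for k in sorted(keys)]
    n_union = len(union)
    samples: Dict[str, dict] = {}
    for sid, _ in per_sample:
        own = {k for k in keys if sid in carriers[k]}
        unique = sum(1 for k in own if len(carriers[k]) == 1)
        samples[sid] = {
            "count": len(own),
            "percent_of_union": percent(len(own) / n_union) if n_union else 0.0,
            "unique": unique,
        }
    shared_by_all = sum(1 for k in keys if len(carriers[k]) == len(ids))
    result: Dict[str, object] = {
        "union": union,
        "union_size": n_union,
        "samples": samples,
        "shared_by_all": shared_by_all,
    }
    if cultivar_of:
        cultivars: Dict[str, Set[Tuple[int, str]]] = defaultdict(set)
        for k in keys:
            for sid in carriers[k]:
                cultivars[cultivar_of[sid]].add(k)
        result["cultivars"] = {
            name: {"union": len(sites)} for name, sites in cultivars.items()
        }
        if len(cultivars) == 2:
            a, b = cultivars.values()
            result["cultivar_shared"] = len(a & b)
    return result


def rank_codon_changes(
    sites: Sequence[EditingSite],
) -> Dict[str, List[Tuple[str, int, float]]]:
    """Rank codon-change classes and edited (alternative) codons.

    Percentages are of the classified (genic, frame-intact) sites, to two
    decimals. Ties are broken by codon lexicographic order.
    """
    classified = [s for s in sites if s.codon_ref is not None]
    total = len(classified)
    changes = Counter(f"{s.codon_ref}->{s.codon_alt}" for s in classified)
    edited = Counter(s.codon_alt for s in classified)

    def _ranked(counter: Counter) -> List[Tuple[str, int, float]]:
        items = sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
        return [
            (label, n, percent(n / total) if total else 0.0) for label, n in items
        ]

    return {
        "codon_changes": _ranked(changes),
        "edited_codons": _ranked(edited),
        "total_classified": total,
    }


def compare_editing_sets(
    observed: Iterable[int], predicted: Iterable[int]
) -> Dict[str, int]:
    """Exact-position comparison of an observed site set against an
    externally predicted list."""
    obs, pred = set(observed), set(predicted)
    return {
        "shared": len(obs & pred),
        "unique_observed": len(obs - pred),
        "unique_predicted": len(pred - obs),
    }
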