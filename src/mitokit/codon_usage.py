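"""Codon counting, relative synonymous codon usage, and anticodon mapping.

RSCU for codon c in a synonymous family F is

    RSCU(c) = |F| * count(c) / sum over F of counts,

i.e. the observed count relative to the expectation under uniform usage
within the family, so the family mean is 1 by construction. Families
follow the standard genetic code with the three stop codons pooled into
one family of degeneracy 3; the six-fold Leu/Ser/Arg families are kept
whole. Codons are keyed in the RNA alphabet (U, not T).

The codon-anticodon map is strict reverse-complement pairing: one
anticodon decodes exactly one codon. Wobble rules are deliberately not
modelled, so codons without a same-genome tRNA stay unassigned.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from Bio.Data import CodonTable

from ._util import round_half_up
from .core import AnnotatedGenome, Feature

__all__ = [
    "CODON_FAMILIES",
    "FAMILY_OF_CODON",
    "count_codons",
    "rscu",
    "build_anticodon_map",
    "codon_usage_table",
]

_RNA_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


def _build_families() -> Dict[str, Tuple[str, ...]]:
    table = CodonTable.unambiguous_rna_by_id[1]  # standard code
    fam: Dict[str, List[str]] = defaultdict(list)
    for codon, aa in table.forward_table.items():
        fam[aa].append(codon)
    fam["*"] = list(table.stop_codons)
    return {aa: tuple(sorted(codons)) for aa, codons in fam.items()}


CODON_FAMILIES: Dict[str, Tuple[str, ...]] = _build_families()
FAMILY_OF_CODON: Dict[str, str] = {
    c: aa for aa, codons in CODON_FAMILIES.items() for c in codons
}
ALL_CODONS: Tuple[str, ...] = tuple(sorted(FAMILY_OF_CODON))


def _to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def count_codons(cds_list: Sequence[str]) -> Dict[str, int]:
    """Tally codons over in-frame coding sequences (DNA or RNA alphabet);
    returns a full 64-codon table keyed by RNA codons."""
    counts = {c: 0 for c in ALL_CODONS}
    for idx, cds in enumerate(cds_list):
        rna = _to_rna(cds)
        if len(rna) % 3 != 0:
            raise ValueError(
                f"coding sequence #{idx} has length {len(rna)} not divisible by 3"
            )
        bad = set(rna) - set("ACGU")
        if bad:
            raise ValueError(f"coding sequence #{idx}: invalid characters {sorted(bad)}")
        for i in range(0, len(rna), 3):
            counts[rna[i : i + 3]] += 1
    return counts


def rscu(counts: Mapping[str, int], ndigits: Optional[int] = None) -> Dict[str, float]:
    """RSCU per codon; families with zero total are omitted (undefined).

    ``ndigits`` applies half-up rounding for table reporting; by default
    the exact values are returned (family sums then equal the degeneracy
    exactly).
    """
    out: Dict[str, float] = {}
    for aa, codons in CODON_FAMILIES.items():
        total = sum(counts.get(c, 0) for c in codons)
        if total == 0:
            continue
        deg = len(codons)
        for c in codons:
            val = deg * counts.get(c, 0) / total
            out[c] = round_half_up(val, ndigits) if ndigits is not None else val
    return out


def codon_of_anticodon(anticodon: str) -> str:
    """The codon decoded by strict reverse-complement pairing (RNA)."""
    ac = _to_rna(anticodon)
    if len(ac) != 3 or set(ac) - set("ACGU"):
        raise ValueError(f"invalid anticodon {anticodon!r}")
    return "".join(_RNA_COMPLEMENT[b] for b in reversed(ac))


def build_anticodon_map(
    trna_features: Iterable[Feature],
) -> Dict[str, List[Tuple[str, str, int, bool]]]:
    """Map codons to the tRNAs that decode them.

    tRNA gene copies are aggregated by (gene name, anticodon, cp origin);
    each map entry is (tRNA id, anticodon, copy_count, cp_derived). Codons
    with no tRNA are simply absent.
    """
    groups: Dict[Tuple[str, str, bool], int] = defaultdict(int)
    for f in trna_features:
        if f.anticodon is None:
            continue
        name = f.gene_family or f.id
        groups[(name, _to_rna(f.anticodon), f.cp_derived)] += 1
    out: Dict[str, List[Tuple[str, str, int, bool]]] = defaultdict(list)
    for (name, ac, cp), copies in sorted(groups.items()):
        out[codon_of_anticodon(ac)].append((name, ac, copies, cp))
    return dict(out)


def codon_usage_table(genome: AnnotatedGenome) -> "pandas.DataFrame":
    """Assemble the full usage table (AA, codon, count, RSCU, tRNAs) from
    an annotated genome's protein-coding genes (pseudogenes excluded)."""
    import pandas as pd

    cds = [
        genome.feature_seq(f)[f.cds_phase :]
        for f in genome.features
        if f.ftype == "protein_coding"
    ]
    counts = count_codons(cds)
    values = rscu(counts)
    acmap = build_anticodon_map(f for f in genome.features if f.ftype == "tRNA")
    rows = []
    for codon in ALL_CODONS:
        aa = FAMILY_OF_CODON[codon]
        trnas = ";".join(
            f"{name}({ac}x{copies}{'*' if cp else ''})"
            for name, ac, copies, cp in acmap.get(codon, [])
        )
        rows.append(
            {
                "aa": aa,
                "codon": codon,
                "count": counts[codon],
                "rscu": round_half_up(values[codon], 2) if codon in values else None,
                "tRNA": trnas,
            }
        )
    return pd.DataFrame(rows)
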