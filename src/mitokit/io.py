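"""Readers and writers for the standard formats the toolkit consumes.

All on-disk conventions are the usual ones (GFF3 and VCF 1-based, pileup
TSV 1-based positions); everything is converted to the internal 0-based
half-open frame on read and back on write, so the conversion lives only
here.
"""

from __future__ import annotations

import os
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import AnnotatedGenome, Feature
from .variants import Variant

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_genome",
    "read_gff3",
    "write_gff3",
    "read_vcf",
    "write_vcf",
    "read_pileup",
    "write_pileup",
    "PILEUP_COLUMNS",
]

PILEUP_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "countA",
    "countC",
    "countG",
    "countT",
    "countIns",
    "countDel",
]


# ---------------------------------------------------------------- FASTA

def read_fasta(path: str) -> List[Tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(path, "fasta")]


def write_fasta(path: str, records: Iterable[Tuple[str, str]]) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    SeqIO.write(recs, path, "fasta")


def read_genome(
    fasta_path: str, gff_path: Optional[str] = None, circular: bool = True
) -> AnnotatedGenome:
    """Load the first FASTA record, optionally attaching a GFF3 annotation."""
    records = read_fasta(fasta_path)
    if not records:
        raise ValueError(f"{fasta_path}: no FASTA records")
    name, seq = records[0]
    features = read_gff3(gff_path) if gff_path else []
    return AnnotatedGenome(id=name, seq=seq, circular=circular, features=features)


# ----------------------------------------------------------------- GFF3

_GFF_BOOL = {"true": True, "false": False, "1": True, "0": False}


def _parse_attributes(text: str) -> Dict[str, str]:
    attrs: Dict[str, str] = {}
    for item in text.strip().strip(";").split(";"):
        if not item:
            continue
        if "=" not in item:
            raise ValueError(f"attribute {item!r} lacks '='")
        k, v = item.split("=", 1)
        attrs[k.strip()] = v.strip()
    return attrs


def read_gff3(path: str) -> List[Feature]:
    """Parse a flat GFF3 feature table (1-based closed → 0-based half-open).

    The feature class is taken from column 3 and must be one of the
    internal feature types; ``gene_family``, ``cp_derived`` and
    ``anticodon`` are read from column 9 attributes.
    """
    features: List[Feature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, "
                    f"got {len(cols)}"
                )
            try:
                start1, end = int(cols[3]), int(cols[4])
                if start1 < 1 or end < start1:
                    raise ValueError("coordinates out of range")
                attrs = _parse_attributes(cols[8])
                phase = 0 if cols[7] == "." else int(cols[7])
                feat = Feature(
                    id=attrs.get("ID", f"feature{lineno}"),
                    ftype=cols[2],
                    start=start1 - 1,
                    end=end,
                    strand=cols[6] if cols[6] in "+-" else "+",
                    gene_family=attrs.get("gene_family", ""),
                    cp_derived=_GFF_BOOL.get(
                        attrs.get("cp_derived", "false").lower(), False
                    ),
                    cds_phase=phase,
                    anticodon=attrs.get("anticodon") or None,
                )
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: malformed GFF3 record: {err}")
            features.append(feat)
    return features


def write_gff3(path: str, features: Sequence[Feature], seqid: str = "genome") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = [f"ID={f.id}"]
            if f.gene_family:
                attrs.append(f"gene_family={f.gene_family}")
            if f.cp_derived:
                attrs.append("cp_derived=true")
            if f.anticodon:
                attrs.append(f"anticodon={f.anticodon}")
            phase = str(f.cds_phase) if f.ftype in ("protein_coding", "orf") else "."
            fh.write(
                "\t".join(
                    [
                        seqid,
                        "mitokit",
                        f.ftype,
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand,
                        phase,
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


# ------------------------------------------------------------------ VCF

def read_vcf(path: str) -> List[Variant]:
    """Read a VCF v4.x callset into Variant records (POS → 0-based).

    Allele fraction is taken from the ``AF`` INFO field when present.
    """
    variants: List[Variant] = []
    with pysam.VariantFile(path) as vf:
        for rec in vf:
            if rec.alts is None:
                continue
            for alt in rec.alts:
                af = rec.info.get("AF", 1.0)
                if isinstance(af, tuple):
                    af = af[0]
                variants.append(
                    Variant(
                        pos=rec.pos - 1,
                        ref=rec.ref,
                        alt=alt,
                        alt_fraction=float(af),
                        genome_id=rec.chrom,
                    )
                )
    return variants


def write_vcf(
    path: str, variants: Sequence[Variant], chrom: str, contig_length: int
) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom},length={contig_length}>\n")
        fh.write(
            '##INFO=<ID=AF,Number=A,Type=Float,'
            'Description="Alternative allele fraction">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(variants, key=lambda v: v.pos):
            fh.write(
                f"{chrom}\t{v.pos + 1}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t"
                f"AF={v.alt_fraction:.4f}\n"
            )


# ----------------------------------------------------------- pileup TSV

def read_pileup(path: str) -> pd.DataFrame:
    """Read a per-site base-count pileup TSV; positions become 0-based."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PILEUP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing pileup columns {missing}")
    df = df.copy()
    df["pos"] = df["pos"].astype(int) - 1
    if (df["pos"] < 0).any():
        raise ValueError(f"{path}: pileup positions must be 1-based and positive")
    return df


def write_pileup(path: str, df: pd.DataFrame) -> None:
    out = df.loc[:, PILEUP_COLUMNS].copy()
    out["pos"] = out["pos"].astype(int) + 1
    out.to_csv(path, sep="\t", index=False)
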