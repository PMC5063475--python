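"""Deterministic synthetic datasets with machine-readable ground truth.

The generator emulates the structure of a plant mitochondrial genome at
desk scale: a uniform-random circular background carrying protein-coding
genes on both strands (valid reading frames, no internal stops), segments
copied from a companion plastid genome under a controlled substitution
load, planted forward/palindromic/tandem repeats, planted DNA variants at
controlled allele fractions, and candidate C-to-U editing sites inside
genes. Every planted object is recorded in a :class:`TruthRecord` that
round-trips through JSON, so downstream callers can be scored against
known truth without any external data.

All randomness flows from one ``numpy`` generator seeded explicitly; the
same (parameters, seed) pair reproduces every output byte-for-byte.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._util import reverse_complement
from .core import AnnotatedGenome, Feature
from .variants import Variant, is_transition

__all__ = ["TruthRecord", "make_genome", "make_pileups", "make_callsets"]

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_RNA_ANTICODONS = ["GAA", "GUC", "UUC", "CAU", "UGG", "GCA", "UUU", "GUG"]


@dataclass
class TruthRecord:
    """Everything planted into a synthetic dataset, in final genome
    coordinates (0-based half-open)."""

    seed: int
    params: Dict[str, object] = field(default_factory=dict)
    genome_length: int = 0
    cp_length: int = 0
    genes: List[dict] = field(default_factory=list)
    cp_inserts: List[dict] = field(default_factory=list)
    repeats: List[dict] = field(default_factory=list)
    variants: List[dict] = field(default_factory=list)
    editing_sites: List[dict] = field(default_factory=list)
    samples: List[dict] = field(default_factory=list)

    def to_json(self, path: Optional[str] = None) -> str:
        text = json.dumps(asdict(self), indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, text_or_path: str) -> "TruthRecord":
        try:
            data = json.loads(text_or_path)
        except json.JSONDecodeError:
            with open(text_or_path) as fh:
                data = json.load(fh)
        return cls(**data)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + random non-stop codons + one stop codon."""
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = _random_seq(rng, 3)
        if c not in _STOPS:
            codons.append(c)
    codons.append("TAA")
    return "".join(codons)


class _Packer:
    """Greedy non-overlapping slot allocation with a safety margin."""

    def __init__(self, length: int, rng: np.random.Generator, margin: int = 30):
        self.length = length
        self.rng = rng
        self.margin = margin
        self.occupied: List[Tuple[int, int]] = []

    def place(self, size: int, what: str, tries: int = 200) -> int:
        if size + 2 * self.margin > self.length:
            raise ValueError(f"cannot place {what}: longer than the genome")
        for _ in range(tries):
            start = int(self.rng.integers(self.margin, self.length - size - self.margin))
            iv = (start - self.margin, start + size + self.margin)
            if all(e <= iv[0] or s >= iv[1] for s, e in self.occupied):
                self.occupied.append(iv)
                return start
        raise ValueError(
            f"infeasible packing: could not place {what} of {size} bp "
            f"in a genome of {self.length} bp"
        )


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> Tuple[str, int]:
    if rate <= 0:
        return seq, 0
    chars = list(seq)
    hits = np.flatnonzero(rng.random(len(chars)) < rate)
    for i in hits:
        others = [b for b in "ACGT" if b != chars[i]]
        chars[i] = others[int(rng.integers(0, 3))]
    return "".join(chars), len(hits)


def make_genome(
    length: int = 60_000,
    n_genes: int = 12,
    n_cp_inserts: int = 3,
    cp_insert_len_range: Tuple[int, int] = (200, 800),
    cp_mutation_rate: float = 0.02,
    repeat_spec: Optional[Sequence[dict]] = None,
    n_trnas: int = 4,
    n_variants: int = 100,
    ti_fraction: float = 0.5,
    indel_fraction: float = 0.02,
    alt_fraction_range: Tuple[float, float] = (0.2, 1.0),
    n_editing_sites: int = 60,
    cp_length: int = 30_000,
    seed: int = 0,
) -> Tuple[AnnotatedGenome, str, TruthRecord]:
    """Build a synthetic annotated mt genome, its plastid companion, and
    the truth record of everything planted.

    ``repeat_spec`` is a list of dicts: ``{"kind": "forward"|"palindromic",
    "length": int}`` or ``{"kind": "tandem", "period": int, "copies": int}``.
    DNA variants are planted genome-wide with transition probability
    ``ti_fraction`` and allele fractions uniform in ``alt_fraction_range``;
    candidate editing sites are sense-strand C positions inside genes.
    """
    rng = np.random.default_rng(seed)
    truth = TruthRecord(
        seed=int(seed),
        params={
            "length": length,
            "n_genes": n_genes,
            "n_cp_inserts": n_cp_inserts,
            "cp_insert_len_range": list(cp_insert_len_range),
            "cp_mutation_rate": cp_mutation_rate,
            "n_variants": n_variants,
            "ti_fraction": ti_fraction,
            "indel_fraction": indel_fraction,
            "n_editing_sites": n_editing_sites,
        },
        genome_length=length,
        cp_length=cp_length,
    )
    cp_seq = _random_seq(rng, cp_length)
    mt = list(_random_seq(rng, length))
    packer = _Packer(length, rng)

    # plastid-derived inserts: verbatim cp segments under a substitution load
    for i in range(n_cp_inserts):
        size = int(rng.integers(cp_insert_len_range[0], cp_insert_len_range[1] + 1))
        cp_start = int(rng.integers(0, cp_length - size))
        start = packer.place(size, f"cp insert {i}")
        segment, n_sub = _mutate(rng, cp_seq[cp_start : cp_start + size], cp_mutation_rate)
        mt[start : start + size] = list(segment)
        truth.cp_inserts.append(
            {
                "label": f"cp{i + 1}",
                "mt_start": start,
                "mt_end": start + size,
                "cp_start": cp_start,
                "cp_end": cp_start + size,
                "mutation_rate": cp_mutation_rate,
                "n_substitutions": n_sub,
            }
        )

    # planted repeats
    for i, spec in enumerate(repeat_spec or []):
        kind = spec["kind"]
        if kind in ("forward", "palindromic"):
            rlen = int(spec["length"])
            block = _random_seq(rng, rlen)
            p1 = packer.place(rlen, f"{kind} repeat {i} (copy 1)")
            p2 = packer.place(rlen, f"{kind} repeat {i} (copy 2)")
            p1, p2 = sorted((p1, p2))
            mt[p1 : p1 + rlen] = list(block)
            second = block if kind == "forward" else reverse_complement(block)
            mt[p2 : p2 + rlen] = list(second)
            truth.repeats.append(
                {"kind": kind, "pos1": p1, "pos2": p2, "length": rlen}
            )
        elif kind == "tandem":
            period, copies = int(spec["period"]), int(spec["copies"])
            unit = spec.get("unit") or _random_seq(rng, period)
            array = unit * copies
            start = packer.place(len(array), f"tandem repeat {i}")
            mt[start : start + len(array)] = list(array)
            truth.repeats.append(
                {
                    "kind": "tandem",
                    "pos1": start,
                    "pos2": start,
                    "length": len(array),
                    "period": period,
                    "copies": copies,
                }
            )
        else:
            raise ValueError(f"unknown repeat kind {kind!r}")

    # genes: valid frames, both strands
    features: List[Feature] = []
    for i in range(n_genes):
        n_codons = int(rng.integers(100, 400))
        cds = _random_cds(rng, n_codons)
        start = packer.place(len(cds), f"gene {i}")
        strand = "+" if rng.random() < 0.5 else "-"
        mt[start : start + len(cds)] = list(
            cds if strand == "+" else reverse_complement(cds)
        )
        feat = Feature(
            id=f"gene{i + 1}",
            ftype="protein_coding",
            start=start,
            end=start + len(cds),
            strand=strand,
            gene_family=f"fam{i % 4 + 1}",
        )
        features.append(feat)
        truth.genes.append(
            {
                "id": feat.id,
                "start": feat.start,
                "end": feat.end,
                "strand": strand,
                "n_codons": n_codons,
            }
        )
    for i in range(n_trnas):
        start = packer.place(72, f"tRNA {i}")
        features.append(
            Feature(
                id=f"trna{i + 1}",
                ftype="tRNA",
                start=start,
                end=start + 72,
                strand="+",
                gene_family=f"trn{i + 1}",
                anticodon=_RNA_ANTICODONS[i % len(_RNA_ANTICODONS)],
            )
        )

    seq = "".join(mt)

    # planted DNA variants (SNPs plus a few insertions), outside margins
    used = set()
    for i in range(n_variants):
        for _ in range(200):
            pos = int(rng.integers(0, length))
            if pos not in used:
                break
        else:
            raise ValueError("could not place all variants")
        used.add(pos)
        ref = seq[pos]
        if rng.random() < indel_fraction:
            alt = ref + _random_seq(rng, int(rng.integers(1, 4)))
        else:
            if rng.random() < ti_fraction:
                alt = {"A": "G", "G": "A", "C": "T", "T": "C"}[ref]
            else:
                tv = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}[ref]
                alt = tv[int(rng.integers(0, 2))]
        af = float(rng.uniform(*alt_fraction_range))
        truth.variants.append(
            {
                "pos": pos,
                "ref": ref,
                "alt": alt,
                "alt_fraction": round(af, 4),
                "transition": len(alt) == 1 and is_transition(ref, alt),
            }
        )
    truth.variants.sort(key=lambda v: v["pos"])

    # candidate C->U editing sites: sense-strand C inside genes
    candidates = []
    for g in truth.genes:
        strand = g["strand"]
        target = "C" if strand == "+" else "G"
        for pos in range(g["start"], g["end"]):
            if seq[pos] == target and pos not in used:
                candidates.append((pos, g["id"], strand))
    if len(candidates) < n_editing_sites:
        raise ValueError("not enough genic C positions for the requested sites")
    picks = rng.choice(len(candidates), size=n_editing_sites, replace=False)
    for k in sorted(picks.tolist()):
        pos, gene, strand = candidates[k]
        truth.editing_sites.append(
            {"pos": pos, "gene": gene, "strand": strand, "samples": []}
        )

    genome = AnnotatedGenome(id="synthetic_mt", seq=seq, circular=True, features=features)
    return genome, cp_seq, truth


def _pileup_row(
    rng: np.random.Generator,
    ref: str,
    depth: int,
    error_rate: float,
    alt: Optional[str] = None,
    alt_prob: float = 0.0,
) -> Dict[str, int]:
    counts = {b: 0 for b in "ACGT"}
    n_alt = int(rng.binomial(depth, alt_prob)) if alt is not None and alt_prob > 0 else 0
    if alt is not None:
        counts[alt] += n_alt
    n_ref = depth - n_alt
    n_err = int(rng.binomial(n_ref, error_rate)) if error_rate > 0 else 0
    counts[ref] += n_ref - n_err
    if n_err:
        others = [b for b in "ACGT" if b != ref]
        split = rng.multinomial(n_err, [1 / 3] * 3)
        for b, k in zip(others, split):
            counts[b] += int(k)
    return counts


def make_pileups(
    genome: AnnotatedGenome,
    truth: TruthRecord,
    depth: int = 30,
    error_rate: float = 0.005,
    samples: Sequence[Tuple[str, str, float]] = (("s1", "cultivarA", 0.0),),
    editing_efficiency: float = 0.9,
    core_fraction: float = 0.7,
    seed: int = 0,
) -> Tuple[Dict[str, pd.DataFrame], pd.DataFrame]:
    """Simulate per-sample RNA pileups over gene bodies plus a genome-wide
    DNA pileup.

    Each ``samples`` entry is (id, cultivar, private_editing_fraction). A
    shared core of ``core_fraction`` of the planted editing sites is
    carried by every sample; each sample additionally gets a private draw
    of fresh genic C positions sized by its private fraction. Carried
    sites show the alternative base at ``editing_efficiency``; every read
    errs uniformly onto the three other bases at ``error_rate``. The truth
    record's editing sites are updated in place with per-sample carriers.

    Returns ({sample_id: RNA pileup}, DNA pileup), pileup frames in the
    internal 0-based representation.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not 0.0 <= error_rate <= 0.1:
        raise ValueError("error_rate must lie in [0, 0.1]")
    ids = [s[0] for s in samples]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate sample ids")
    rng = np.random.default_rng(seed)

    n_core = int(round(core_fraction * len(truth.editing_sites)))
    order = rng.permutation(len(truth.editing_sites))
    core_idx = sorted(order[:n_core].tolist())
    pool_idx = sorted(order[n_core:].tolist())
    site_of_pos: Dict[int, dict] = {}
    for k in core_idx:
        site = truth.editing_sites[k]
        site["samples"] = list(ids)
        site_of_pos[site["pos"]] = site
    # private sites: drawn from the non-core pool, one owner each
    pool = list(pool_idx)
    for sid, _cultivar, private_frac in samples:
        n_private = int(round(private_frac * n_core))
        take, pool = pool[:n_private], pool[n_private:]
        for k in take:
            site = truth.editing_sites[k]
            site["samples"] = [sid]
            site_of_pos[site["pos"]] = site
    truth.samples = [
        {"id": sid, "cultivar": cv, "private_editing_fraction": pf}
        for sid, cv, pf in samples
    ]
    truth.params.update(
        {
            "depth": depth,
            "error_rate": error_rate,
            "editing_efficiency": editing_efficiency,
            "core_fraction": core_fraction,
        }
    )

    gene_positions = sorted(
        {
            pos
            for g in truth.genes
            for pos in range(g["start"], g["end"])
        }
    )
    rna: Dict[str, pd.DataFrame] = {}
    for sid, _cultivar, _pf in samples:
        rows = []
        for pos in gene_positions:
            ref = genome.seq[pos]
            site = site_of_pos.get(pos)
            if site is not None and sid in site["samples"]:
                alt = "T" if site["strand"] == "+" else "A"  # C->U on sense
                counts = _pileup_row(
                    rng, ref, depth, error_rate, alt=alt, alt_prob=editing_efficiency
                )
            else:
                counts = _pileup_row(rng, ref, depth, error_rate)
            rows.append(
                {
                    "chrom": genome.id,
                    "pos": pos,
                    "ref": ref,
                    "countA": counts["A"],
                    "countC": counts["C"],
                    "countG": counts["G"],
                    "countT": counts["T"],
                    "countIns": 0,
                    "countDel": 0,
                }
            )
        rna[sid] = pd.DataFrame(rows)

    variant_of_pos = {
        v["pos"]: v for v in truth.variants if len(v["ref"]) == len(v["alt"]) == 1
    }
    dna_rows = []
    for pos in range(genome.length):
        ref = genome.seq[pos]
        v = variant_of_pos.get(pos)
        if v is not None:
            counts = _pileup_row(
                rng, ref, depth, error_rate, alt=v["alt"], alt_prob=v["alt_fraction"]
            )
        else:
            counts = _pileup_row(rng, ref, depth, error_rate)
        dna_rows.append(
            {
                "chrom": genome.id,
                "pos": pos,
                "ref": ref,
                "countA": counts["A"],
                "countC": counts["C"],
                "countG": counts["G"],
                "countT": counts["T"],
                "countIns": 0,
                "countDel": 0,
            }
        )
    return rna, pd.DataFrame(dna_rows)


def make_callsets(
    genome: AnnotatedGenome,
    truth: TruthRecord,
    fp_a: float = 0.0,
    fn_a: float = 0.0,
    fp_b: float = 0.0,
    fn_b: float = 0.0,
    seed: int = 0,
) -> Tuple[List[Variant], List[Variant]]:
    """Derive two imperfect callsets from the planted variants.

    Each caller misses planted variants independently at its false-negative
    rate and adds ``round(fp * n_planted)`` novel false-positive sites at
    unused positions. Caller membership is recorded back into the truth
    record.
    """
    if not (0.0 <= fp_a < 1.0 and 0.0 <= fp_b < 1.0):
        raise ValueError("false-positive rates must lie in [0, 1)")
    if not (0.0 <= fn_a <= 1.0 and 0.0 <= fn_b <= 1.0):
        raise ValueError("false-negative rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    planted_pos = {v["pos"] for v in truth.variants}
    callsets: List[List[Variant]] = []
    for name, fp, fn in (("A", fp_a, fn_a), ("B", fp_b, fn_b)):
        calls: List[Variant] = []
        for v in truth.variants:
            if rng.random() < fn:
                continue
            v.setdefault("callers", []).append(name)
            calls.append(
                Variant(
                    pos=v["pos"],
                    ref=v["ref"],
                    alt=v["alt"],
                    alt_fraction=v["alt_fraction"],
                    callers=frozenset({name}),
                    genome_id=genome.id,
                )
            )
        n_fp = int(round(fp * len(truth.variants)))
        placed = 0
        while placed < n_fp:
            pos = int(rng.integers(0, genome.length))
            if pos in planted_pos:
                continue
            ref = genome.seq[pos]
            alt = [b for b in "ACGT" if b != ref][int(rng.integers(0, 3))]
            calls.append(
                Variant(
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    alt_fraction=float(rng.uniform(0.15, 1.0)),
                    callers=frozenset({name}),
                    genome_id=genome.id,
                )
            )
            placed += 1
        callsets.append(sorted(calls, key=lambda v: v.pos))
    return callsets[0], callsets[1]
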