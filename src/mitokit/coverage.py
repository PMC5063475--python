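"""Depth-based analytics: organelle copy number, mapping statistics,
coverage-bin profiles, expressed-gene calling, size-factor normalization,
and polycistron detection.

Relative sequencing depth of the nuclear, mitochondrial and plastid
compartments estimates their per-cell copy-number ratio, which in turn
bounds how much apparent mt variation can actually originate from nuclear
paralogs (1/(1+m) for mt:nuclear ratio m) and how likely a variant inside
a cp-derived region is to come from the plastid itself (c/(c+m)).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._util import percent, round_half_up
from .core import Feature

__all__ = [
    "CoverageProfile",
    "copy_ratio",
    "origin_attribution",
    "mapping_stats",
    "coverage_bins",
    "expression_profile",
    "size_factors",
    "polycistron_detect",
]

COVERAGE_BINS = ((0, 0), (1, 4), (5, 9), (10, 99), (100, 999), (1000, None))


@dataclass
class CoverageProfile:
    """Per-base read depth over the genome for one sample."""

    sample: str
    depth: np.ndarray
    platform: str = ""

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth)
        if (self.depth < 0).any():
            raise ValueError("depths must be non-negative")


def copy_ratio(
    platform_depths: Sequence[Tuple[float, float, float]]
) -> Tuple[int, int, int]:
    """Copy-number ratio (nuclear : mt : cp) from per-platform mean depths.

    Each platform's (nuclear, mt, cp) depths are scaled to nuclear = 1;
    components are then averaged across platforms and rounded half-up to
    integers. Scaling per platform makes the result invariant to each
    platform's total sequencing effort.
    """
    if not platform_depths:
        raise ValueError("at least one platform is required")
    scaled = []
    for nuc, mt, cp in platform_depths:
        if nuc <= 0:
            raise ValueError("nuclear depth must be positive")
        scaled.append((1.0, mt / nuc, cp / nuc))
    mean_mt = sum(s[1] for s in scaled) / len(scaled)
    mean_cp = sum(s[2] for s in scaled) / len(scaled)
    return (1, int(round_half_up(mean_mt, 0)), int(round_half_up(mean_cp, 0)))


def origin_attribution(ratio: Tuple[int, int, int]) -> Dict[str, float]:
    """Read-origin bounds implied by a (1, m, c) copy ratio, as percentages.

    ``nuclear_fraction_in_mt`` = 1/(1+m): the share of reads over
    mt-homologous sequence that could be nuclear. ``cp_fraction_in_cp_derived``
    = c/(c+m): the chance a read over a cp-derived region is truly plastid.
    """
    one, m, c = ratio
    if m < 1 or c < 1:
        raise ValueError("mt and cp ratio components must be >= 1")
    return {
        "nuclear_fraction_in_mt": percent(1.0 / (1.0 + m)),
        "cp_fraction_in_cp_derived": percent(c / (c + m)),
    }


def mapping_stats(
    original_fragments: int, hq_fragments: int, mt_fragments: int
) -> Dict[str, float]:
    """High-quality and mt-mapping percentages of a library, both relative
    to the original fragment count."""
    if not 0 <= mt_fragments <= hq_fragments <= original_fragments:
        raise ValueError(
            "expected 0 <= mt_fragments <= hq_fragments <= original_fragments"
        )
    if original_fragments == 0:
        raise ValueError("original fragment count must be positive")
    return {
        "hq_percent": percent(hq_fragments / original_fragments),
        "mt_percent": percent(mt_fragments / original_fragments),
    }


def coverage_bins(profile: CoverageProfile) -> Dict[str, object]:
    """Base counts and percentages in the depth bins
    0, 1-4, 5-9, 10-99, 100-999, >=1000, plus the covered (>=1) percent."""
    depth = profile.depth
    n = depth.size
    bins: Dict[str, Dict[str, float]] = {}
    for lo, hi in COVERAGE_BINS:
        label = "0" if (lo, hi) == (0, 0) else (f">={lo}" if hi is None else f"{lo}-{hi}")
        sel = depth >= lo if hi is None else (depth >= lo) & (depth <= hi)
        bases = int(sel.sum())
        bins[label] = {"bases": bases, "percent": percent(bases / n)}
    return {
        "bins": bins,
        "total_bases": n,
        "covered_percent": percent(int((depth >= 1).sum()) / n),
    }


def expression_profile(
    counts: pd.DataFrame, min_samples: int = 2
) -> Dict[str, object]:
    """Expressed-gene calling and expression tiers from a genes x samples
    fragment-count matrix.

    A gene is expressed in a sample iff its count is nonzero; the expressed
    set requires expression in at least ``min_samples`` samples. Tiers
    (high/moderate/low) are terciles of log1p size-factor-normalized mean
    counts over the expressed set — a reporting convention, not a model.
    """
    if (counts < 0).any().any():
        raise ValueError("counts must be non-negative")
    nonzero = counts > 0
    n_samples_expr = nonzero.sum(axis=1)
    expressed = counts.index[n_samples_expr >= min_samples].tolist()
    per_sample = nonzero.sum(axis=0).to_dict()
    tiers: Dict[str, str] = {}
    if expressed:
        try:
            factors = size_factors(counts)
            norm = counts.loc[expressed].div(pd.Series(factors), axis=1)
        except ValueError:  # no gene positive everywhere; tier on raw means
            norm = counts.loc[expressed]
        mean_log = np.log1p(norm).mean(axis=1)
        lo, hi = mean_log.quantile([1 / 3, 2 / 3])
        for gene, v in mean_log.items():
            tiers[gene] = "low" if v <= lo else ("moderate" if v <= hi else "high")
    return {
        "expressed_genes": expressed,
        "n_expressed": len(expressed),
        "per_sample_expressed": per_sample,
        "tiers": tiers,
    }


def size_factors(counts: pd.DataFrame) -> Dict[str, float]:
    """Median-of-ratios library size factors.

    For each gene with positive counts in every sample, the ratio of the
    sample's count to the gene's geometric mean across samples is formed;
    a sample's factor is the median of those ratios. This is the classic
    count-normalization estimator used by DESeq-style analyses.
    """
    eligible = counts[(counts > 0).all(axis=1)]
    if eligible.empty:
        raise ValueError("no gene has positive counts in every sample")
    log_gm = np.log(eligible).mean(axis=1)
    ratios = np.exp(np.log(eligible).sub(log_gm, axis=0))
    return {s: float(ratios[s].median()) for s in counts.columns}


def polycistron_detect(
    profile: CoverageProfile,
    features: Sequence[Feature],
    min_bridge_depth: int = 1,
    max_gap: int = 2000,
    ftypes: Tuple[str, ...] = ("protein_coding", "orf", "tRNA", "rRNA"),
) -> List[List[str]]:
    """Cluster adjacent same-strand genes joined by continuous transcription.

    Two neighbouring genes on the same strand join one transcription unit
    when every base of the intergenic gap reaches ``min_bridge_depth`` and
    the gap is at most ``max_gap`` bases. Clusters of at least two genes
    are returned in genome order.
    """
    genes = sorted((f for f in features if f.ftype in ftypes), key=lambda f: f.start)
    depth = profile.depth
    clusters: List[List[str]] = []
    current: List[Feature] = []
    for g in genes:
        if current:
            prev = current[-1]
            gap_s, gap_e = prev.end, g.start
            bridged = (
                g.strand == prev.strand
                and gap_e - gap_s <= max_gap
                and (
                    gap_e <= gap_s
                    or bool((depth[gap_s:gap_e] >= min_bridge_depth).all())
                )
            )
            if not bridged:
                if len(current) >= 2:
                    clusters.append([f.id for f in current])
                current = []
        current.append(g)
    if len(current) >= 2:
        clusters.append([f.id for f in current])
    return clusters
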