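"""Dual-caller intersection, context classification, and Ti/Tv."""

import numpy as np
import pytest

from mitokit import make_callsets, make_genome
from mitokit.core import RegionSet
from mitokit.variants import (
    Variant,
    classify_variants,
    intersect_callsets,
    is_transition,
    titv,
    variation_rate,
)


def _snp(pos, ref="A", alt="G", af=1.0, gid="g"):
    return Variant(pos=pos, ref=ref, alt=alt, alt_fraction=af, genome_id=gid)


class TestIntersectCallsets:
    def test_disjoint_callsets_empty(self):
        a = [_snp(1), _snp(5)]
        b = [_snp(2), _snp(9)]
        assert intersect_callsets(a, b) == []

    def test_inclusion_exclusion_on_published_sizes(self):
        # two callers reporting 202 and 157 sites with 102 in common imply
        # a union of 257
        shared = [_snp(i) for i in range(102)]
        a = shared + [_snp(1000 + i) for i in range(100)]
        b = shared + [_snp(2000 + i) for i in range(55)]
        inter = intersect_callsets(a, b)
        assert (len(a), len(b), len(inter)) == (202, 157, 102)
        assert len({v.key for v in a} | {v.key for v in b}) == 257

    def test_alt_fraction_filter_applies_to_both(self):
        a = [_snp(1, af=0.10), _snp(2, af=0.20)]
        b = [_snp(1, af=0.90), _snp(2, af=0.14)]
        assert intersect_callsets(a, b, min_alt_fraction=0.15) == []
        kept = intersect_callsets(a, b, min_alt_fraction=0.05)
        assert [v.pos for v in kept] == [1, 2]
        assert kept[0].callers == frozenset({"A", "B"})
        assert kept[0].alt_fraction == pytest.approx(0.10)

    def test_allele_mismatch_is_not_shared(self):
        assert intersect_callsets([_snp(3, alt="G")], [_snp(3, alt="T")]) == []

    def test_mismatched_genomes_rejected(self):
        with pytest.raises(ValueError, match="different genomes"):
            intersect_callsets([_snp(1, gid="x")], [_snp(1, gid="y")])

    def test_symmetric_and_bounded(self, synthetic_dataset):
        genome, truth = synthetic_dataset["genome"], synthetic_dataset["truth"]
        a, b = make_callsets(genome, truth, fp_a=0.1, fn_a=0.2, fp_b=0.05, fn_b=0.1, seed=5)
        ab = intersect_callsets(a, b, min_alt_fraction=0.0)
        ba = intersect_callsets(b, a, min_alt_fraction=0.0)
        assert {v.key for v in ab} == {v.key for v in ba}
        assert len(ab) <= min(len(a), len(b))

    def test_perfect_callers_recover_planted_set(self, synthetic_dataset):
        genome, truth = synthetic_dataset["genome"], synthetic_dataset["truth"]
        a, b = make_callsets(genome, truth, seed=6)
        inter = intersect_callsets(a, b, min_alt_fraction=0.0)
        assert {v.key for v in inter} == {
            (v["pos"], v["ref"], v["alt"]) for v in truth.variants
        }


class TestClassifyVariants:
    def test_coding_synonymy(self, toy_genome):
        # plus gene starts at 10: codons ATG GCC CGG TCA ...
        syn = _snp(15, ref="C", alt="T", gid="toy")  # GCC->GCT, Ala->Ala
        nonsyn = _snp(16, ref="C", alt="T", gid="toy")  # CGG->TGG, Arg->Trp
        out = classify_variants([syn, nonsyn], toy_genome)
        assert out[0].context == "protein_coding_syn"
        assert out[1].context == "protein_coding_nonsyn"

    def test_minus_strand_synonymy_uses_sense_codon(self, toy_genome):
        # minus gene occupies [60, 90); its sense codon 1 is ATG whose 'A'
        # sits at genome position 89 as 'T'
        v = _snp(89, ref="T", alt="C", gid="toy")  # ATG->GTG nonsyn (Met->Val)
        (out,) = classify_variants([v], toy_genome)
        assert out.context == "protein_coding_nonsyn"

    def test_contexts_match_generator_truth(self, synthetic_dataset):
        genome, truth = synthetic_dataset["genome"], synthetic_dataset["truth"]
        snps = [
            Variant(pos=v["pos"], ref=v["ref"], alt=v["alt"], genome_id=genome.id)
            for v in truth.variants
            if len(v["alt"]) == 1
        ]
        out = classify_variants(snps, genome)
        gene_ivs = [(g["start"], g["end"]) for g in truth.genes]
        trna_ivs = [
            (f.start, f.end) for f in genome.features if f.ftype == "tRNA"
        ]
        for v in out:
            in_gene = any(s <= v.pos < e for s, e in gene_ivs)
            in_trna = any(s <= v.pos < e for s, e in trna_ivs)
            if in_gene:
                assert v.context in ("protein_coding_syn", "protein_coding_nonsyn")
            elif in_trna:
                assert v.context == "tRNA"
            else:
                assert v.context == "noncoding"

    def test_cp_region_flag(self, toy_genome):
        rs = RegionSet(regions=[(0, 50, "cp1")], frame="toy")
        out = classify_variants([_snp(15, ref="C", alt="T"), _snp(95)], toy_genome, rs)
        assert out[0].cp_derived and not out[1].cp_derived


class TestTiTv:
    def test_published_ratios(self):
        overall = [_snp(i, ref="A", alt="G") for i in range(23)] + [
            _snp(100 + i, ref="A", alt="C") for i in range(77)
        ]
        res = titv(overall)
        assert (res["n_ti"], res["n_tv"], res["ratio"]) == (23, 77, 0.30)
        strat = [_snp(i, ref="C", alt="T") for i in range(3)] + [
            _snp(100 + i, ref="G", alt="T") for i in range(50)
        ]
        assert titv(strat)["ratio"] == 0.06

    def test_equal_counts_ratio_one(self):
        vs = [_snp(0, ref="A", alt="G"), _snp(1, ref="A", alt="T")]
        assert titv(vs)["ratio"] == 1.00

    def test_zero_transversions_undefined(self):
        res = titv([_snp(0, ref="C", alt="T")])
        assert res["ratio"] is None and res["n_ti"] == 1

    def test_indels_ignored_but_counted(self):
        vs = [_snp(0), Variant(pos=1, ref="A", alt="AT")]
        res = titv(vs)
        assert res["n_ti"] + res["n_tv"] == 1 and res["n_ignored"] == 1

    def test_empty_exclusion_equals_unstratified(self, synthetic_dataset):
        genome, truth = synthetic_dataset["genome"], synthetic_dataset["truth"]
        snps = [
            Variant(pos=v["pos"], ref=v["ref"], alt=v["alt"])
            for v in truth.variants
            if len(v["alt"]) == 1
        ]
        empty = RegionSet(frame=genome.id)
        assert titv(snps, exclude=empty) == titv(snps)

    def test_exclusion_drops_region_variants(self):
        vs = [_snp(5, ref="A", alt="G"), _snp(50, ref="A", alt="C")]
        rs = RegionSet(regions=[(0, 10, "r")])
        res = titv(vs, exclude=rs)
        assert res["n_ti"] == 0 and res["n_tv"] == 1

    def test_planted_ratio_recovered_at_scale(self):
        # 3:1 transition:transversion mix; the estimate should land within
        # 10% of ratio 3.0 at one thousand planted SNPs
        genome, _, truth = make_genome(
            length=80_000,
            n_genes=4,
            n_cp_inserts=0,
            n_editing_sites=0,
            n_variants=1000,
            ti_fraction=0.75,
            indel_fraction=0.0,
            seed=31,
        )
        snps = [Variant(pos=v["pos"], ref=v["ref"], alt=v["alt"]) for v in truth.variants]
        res = titv(snps)
        assert res["n_ti"] + res["n_tv"] == 1000
        assert res["ratio"] == pytest.approx(3.0, rel=0.10)


class TestVariationRate:
    def test_published_cross_species_rate(self):
        res = variation_rate(2_442, 1_122, 678_653)
        assert res["per_kb_rounded"] == 5
        assert res["per_kb"] == pytest.approx(5.2516, abs=1e-3)

    def test_zero_variants(self):
        assert variation_rate(0, 0, 1234)["per_kb"] == 0.0

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            variation_rate(1, 0, 0)

    def test_planted_density_recovered(self, synthetic_dataset):
        truth = synthetic_dataset["truth"]
        n_snp = sum(1 for v in truth.variants if len(v["alt"]) == 1)
        n_indel = len(truth.variants) - n_snp
        res = variation_rate(n_snp, n_indel, truth.genome_length)
        assert res["per_kb"] == pytest.approx(
            len(truth.variants) / truth.genome_length * 1000
        )


def test_transition_table():
    assert is_transition("A", "G") and is_transition("T", "C")
    assert not is_transition("A", "C") and not is_transition("G", "T")
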