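"""RNA-editing calling thresholds, classification, aggregation and set
comparison."""

import pandas as pd
import pytest

from mitokit import make_genome, make_pileups
from mitokit._util import percent, reverse_complement
from mitokit.core import AnnotatedGenome, Feature
from mitokit.rna_editing import (
    EditingSite,
    aggregate_samples,
    call_editing_sites,
    classify_edit,
    compare_editing_sets,
    rank_codon_changes,
)


def _pileup_row(pos, ref, **counts):
    row = {
        "chrom": "g",
        "pos": pos,
        "ref": ref,
        "countA": 0,
        "countC": 0,
        "countG": 0,
        "countT": 0,
        "countIns": 0,
        "countDel": 0,
    }
    for base, n in counts.items():
        row[f"count{base}"] = n
    return row


@pytest.fixture()
def editing_genome():
    # one plus-strand gene: ATG TCA CGG GCC TAA at [12, 27)
    cds = "ATGTCACGGGCCTAA"
    seq = "GATTACAGATTA" + cds + "CCGGTTAACCGGTTAA"
    return AnnotatedGenome(
        id="g",
        seq=seq,
        features=[
            Feature(id="gene1", ftype="protein_coding", start=12, end=27, strand="+")
        ],
    )


class TestCallingThresholds:
    def test_two_alt_reads_not_called(self, editing_genome):
        pileup = pd.DataFrame([_pileup_row(16, "C", C=1, T=2)])
        sites, _ = call_editing_sites(pileup, editing_genome)
        assert sites == []

    def test_three_alt_reads_called(self, editing_genome):
        pileup = pd.DataFrame([_pileup_row(16, "C", C=1, T=3)])
        sites, _ = call_editing_sites(pileup, editing_genome)
        assert len(sites) == 1 and sites[0].edit_type == "C->T"

    def test_fraction_boundary_inclusive(self, editing_genome):
        below = pd.DataFrame([_pileup_row(16, "C", C=51, T=49)])
        at = pd.DataFrame([_pileup_row(16, "C", C=50, T=50)])
        assert call_editing_sites(below, editing_genome)[0] == []
        assert len(call_editing_sites(at, editing_genome)[0]) == 1

    def test_zero_depth_skipped_and_tallied(self, editing_genome):
        pileup = pd.DataFrame(
            [_pileup_row(16, "C"), _pileup_row(17, "A", A=5, G=15)]
        )
        sites, skipped = call_editing_sites(pileup, editing_genome)
        assert skipped == 1 and len(sites) == 1

    def test_monotone_in_thresholds(self, synthetic_dataset):
        genome = synthetic_dataset["genome"]
        pileup = synthetic_dataset["rna"]["leaf1"]
        base = {
            s.pos
            for s in call_editing_sites(pileup, genome, min_alt_reads=3)[0]
        }
        for kwargs in ({"min_alt_reads": 6}, {"min_alt_frac": 0.8}):
            subset = {
                s.pos for s in call_editing_sites(pileup, genome, **kwargs)[0]
            }
            assert subset <= base


class TestClassification:
    @pytest.mark.parametrize(
        "pos,codon_ref,codon_alt,aa,synonymy,codon_pos",
        [
            (16, "TCA", "TTA", ("S", "L"), "nonsynonymous", 2),
            (18, "CGG", "TGG", ("R", "W"), "nonsynonymous", 1),
            (23, "GCC", "GCT", ("A", "A"), "synonymous", 3),
        ],
        ids=["TCA->TTA", "CGG->TGG", "GCC->GCT"],
    )
    def test_codon_change_classes(
        self, editing_genome, pos, codon_ref, codon_alt, aa, synonymy, codon_pos
    ):
        pileup = pd.DataFrame([_pileup_row(pos, editing_genome.seq[pos], T=20)])
        (site,), _ = call_editing_sites(pileup, editing_genome)
        assert (site.codon_ref, site.codon_alt) == (codon_ref, codon_alt)
        assert (site.aa_ref, site.aa_alt) == aa
        assert site.synonymy == synonymy
        assert site.codon_pos == codon_pos

    def test_minus_strand_gene_types_on_sense(self, editing_genome):
        # same gene sequence placed on the minus strand of a new genome
        cds = "ATGTCACGGGCCTAA"
        seq = "GATTACAGATTA" + reverse_complement(cds) + "CCGGTTAACCGGTTAA"
        minus = AnnotatedGenome(
            id="m",
            seq=seq,
            features=[
                Feature(id="g1", ftype="protein_coding", start=12, end=27, strand="-")
            ],
        )
        # sense TCA codon position 2 is genome 'G' (complement of sense C)
        # sense offset 4 -> genome pos = end - 1 - 4 = 22
        pileup = pd.DataFrame([_pileup_row(22, "G", A=20)])
        (site,), _ = call_editing_sites(pileup, minus)
        assert site.edit_type == "C->T"
        assert (site.codon_ref, site.codon_alt) == ("TCA", "TTA")

    def test_frame_broken_feature_refused(self, editing_genome):
        broken = AnnotatedGenome(
            id="b",
            seq=editing_genome.seq,
            features=[
                Feature(id="bad", ftype="protein_coding", start=12, end=26, strand="+")
            ],
        )
        site = EditingSite(pos=16, ref_sense="C", alt_sense="T")
        out = classify_edit(site, broken, broken.features[0])
        assert out.frame_broken and out.codon_ref is None

    def test_intergenic_site_has_no_codon_fields(self, editing_genome):
        pileup = pd.DataFrame([_pileup_row(2, "T", C=20)])
        (site,), _ = call_editing_sites(pileup, editing_genome)
        assert site.gene == "." and site.codon_ref is None


class TestPlantedRecovery:
    def test_noise_free_limit_exact(self):
        genome, _, truth = make_genome(
            length=20_000, n_genes=6, n_cp_inserts=0, n_variants=0,
            n_editing_sites=50, seed=41,
        )
        rna, _ = make_pileups(
            genome, truth, depth=30, error_rate=0.0,
            samples=[("s1", "A", 0.0)], editing_efficiency=1.0,
            core_fraction=1.0, seed=42,
        )
        sites, _ = call_editing_sites(rna["s1"], genome, sample_id="s1")
        assert {s.pos for s in sites} == {e["pos"] for e in truth.editing_sites}
        for s in sites:
            assert s.support["s1"][2] == 1.0
            assert s.edit_type == "C->T"

    def test_noisy_recovery_meets_precision_recall(self, synthetic_dataset):
        genome, truth = synthetic_dataset["genome"], synthetic_dataset["truth"]
        for sid, pileup in synthetic_dataset["rna"].items():
            called = {s.pos for s in call_editing_sites(pileup, genome, sample_id=sid)[0]}
            planted = {e["pos"] for e in truth.editing_sites if sid in e["samples"]}
            tp = len(called & planted)
            assert tp / len(called) >= 0.95
            assert tp / len(planted) >= 0.95


class TestAggregation:
    def test_published_sharing_percentages(self):
        assert percent(697 / 845) == 82.49
        assert percent(489 / 845) == 57.87

    def _sites(self, positions):
        return [EditingSite(pos=p, ref_sense="C", alt_sense="T") for p in positions]

    def test_union_unique_and_shared_counts(self):
        per_sample = [
            ("s1", self._sites([1, 2, 3, 4])),
            ("s2", self._sites([2, 3, 4, 9])),
            ("s3", self._sites([3, 4])),
        ]
        agg = aggregate_samples(per_sample)
        assert agg["union_size"] == 5
        assert agg["shared_by_all"] == 2
        assert agg["samples"]["s1"] == {
            "count": 4,
            "percent_of_union": 80.0,
            "unique": 1,
        }

    def test_identical_samples_have_no_uniques(self):
        sites = self._sites([5, 6, 7])
        agg = aggregate_samples([("a", sites), ("b", sites)])
        assert agg["shared_by_all"] == agg["union_size"] == 3
        assert all(s["unique"] == 0 for s in agg["samples"].values())

    def test_duplicate_sample_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            aggregate_samples([("a", []), ("a", [])])

    def test_min_datasets_filter(self):
        per_sample = [
            ("s1", self._sites([1, 2])),
            ("s2", self._sites([2, 3])),
        ]
        agg = aggregate_samples(per_sample, min_datasets=2)
        assert agg["union_size"] == 1 and agg["samples"]["s1"]["count"] == 1

    def test_cultivar_partition(self, synthetic_dataset):
        genome = synthetic_dataset["genome"]
        per_sample = [
            (sid, call_editing_sites(p, genome, sample_id=sid)[0])
            for sid, p in synthetic_dataset["rna"].items()
        ]
        cultivar_of = {s["id"]: s["cultivar"] for s in synthetic_dataset["truth"].samples}
        agg = aggregate_samples(per_sample, cultivar_of)
        assert set(agg["cultivars"]) == {"Tall", "Dwarf"}
        for stats in agg["cultivars"].values():
            assert stats["union"] <= agg["union_size"]
        assert agg["cultivar_shared"] <= min(
            s["union"] for s in agg["cultivars"].values()
        )

    def test_counts_bounded_by_union(self, synthetic_dataset):
        genome = synthetic_dataset["genome"]
        per_sample = [
            (sid, call_editing_sites(p, genome, sample_id=sid)[0])
            for sid, p in synthetic_dataset["rna"].items()
        ]
        agg = aggregate_samples(per_sample)
        for s in agg["samples"].values():
            assert s["count"] <= agg["union_size"]


class TestRanking:
    def test_published_class_percentages(self):
        assert percent(95 / 845) == 11.24
        assert percent(135 / 845) == 15.98

    def test_single_site_is_its_own_class(self):
        site = EditingSite(
            pos=1, ref_sense="C", alt_sense="T",
            codon_ref="TCA", codon_alt="TTA", codon_pos=2,
        )
        ranked = rank_codon_changes([site])
        assert ranked["codon_changes"] == [("TCA->TTA", 1, 100.0)]
        assert ranked["edited_codons"] == [("TTA", 1, 100.0)]

    def test_class_counts_sum_to_total(self, synthetic_dataset):
        genome = synthetic_dataset["genome"]
        sites = call_editing_sites(
            synthetic_dataset["rna"]["leaf1"], genome, sample_id="leaf1"
        )[0]
        ranked = rank_codon_changes(sites)
        assert (
            sum(n for _, n, _ in ranked["codon_changes"])
            == ranked["total_classified"]
        )

    def test_tie_break_is_lexicographic(self):
        sites = [
            EditingSite(pos=i, ref_sense="C", alt_sense="T",
                        codon_ref=cr, codon_alt=ca)
            for i, (cr, ca) in enumerate(
                [("TCA", "TTA"), ("CCA", "CTA"), ("CCA", "CTA"), ("TCA", "TTA")]
            )
        ]
        ranked = rank_codon_changes(sites)
        assert [label for label, _, _ in ranked["codon_changes"]] == [
            "CCA->CTA",
            "TCA->TTA",
        ]


class TestSetComparison:
    def test_identical_sets(self):
        res = compare_editing_sets({1, 2, 3}, {1, 2, 3})
        assert res == {"shared": 3, "unique_observed": 0, "unique_predicted": 0}

    def test_disjoint_sets(self):
        assert compare_editing_sets({1}, {2})["shared"] == 0

    def test_constructed_offsets(self):
        observed = set(range(100))
        predicted = (observed - set(range(10))) | {1000, 1001, 1002}
        res = compare_editing_sets(observed, predicted)
        assert res["shared"] == 90
        assert res["unique_observed"] == 10
        assert res["unique_predicted"] == 3
        assert res["shared"] + res["unique_predicted"] == len(predicted)
        assert res["shared"] + res["unique_observed"] == len(observed)
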