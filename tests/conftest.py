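import numpy as np
import pytest

from mitokit import make_genome, make_pileups
from mitokit.core import AnnotatedGenome, Feature

REPEAT_SPEC = [
    {"kind": "forward", "length": 150},
    {"kind": "palindromic", "length": 120},
    {"kind": "tandem", "period": 4, "copies": 30},
]

SAMPLES = [
    ("leaf1", "Tall", 0.10),
    ("leaf2", "Tall", 0.10),
    ("embryo", "Dwarf", 0.10),
    ("callus", "Dwarf", 0.10),
]


@pytest.fixture(scope="session")
def synthetic_dataset():
    """One shared synthetic genome with planted cp inserts, repeats,
    variants and editing sites, plus multi-sample pileups."""
    genome, cp_seq, truth = make_genome(
        length=40_000,
        n_genes=8,
        n_cp_inserts=3,
        cp_insert_len_range=(250, 600),
        cp_mutation_rate=0.02,
        repeat_spec=REPEAT_SPEC,
        n_variants=80,
        ti_fraction=0.5,
        n_editing_sites=50,
        cp_length=20_000,
        seed=101,
    )
    rna, dna = make_pileups(
        genome,
        truth,
        depth=30,
        error_rate=0.005,
        samples=SAMPLES,
        editing_efficiency=0.9,
        core_fraction=0.6,
        seed=102,
    )
    return {"genome": genome, "cp": cp_seq, "truth": truth, "rna": rna, "dna": dna}


@pytest.fixture()
def toy_genome():
    """A 120 bp genome with one plus-strand and one minus-strand gene."""
    rng = np.random.default_rng(3)
    # plus gene: ATG GCC CGG TCA ... TAA at [10, 40); minus gene at [60, 90)
    plus_cds = "ATGGCCCGGTCAGCTAAACTTGGGTCGTAA"
    minus_cds = "ATGTCATGCCGGAAGCTTGACCCAGGGTAA"
    from mitokit._util import reverse_complement

    bases = list("".join("ACGT"[i] for i in rng.integers(0, 4, 120)))
    bases[10:40] = list(plus_cds)
    bases[60:90] = list(reverse_complement(minus_cds))
    features = [
        Feature(id="gplus", ftype="protein_coding", start=10, end=40, strand="+"),
        Feature(id="gminus", ftype="protein_coding", start=60, end=90, strand="-"),
    ]
    return AnnotatedGenome(id="toy", seq="".join(bases), circular=False, features=features)
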