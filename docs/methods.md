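# Methods

This note documents the models and procedures implemented in mitokit, the
parameters that matter, the choices made where the design was genuinely
open, and what the synthetic-data tests do and do not demonstrate.

## Coordinate model

All internal coordinates are 0-based half-open on the forward strand;
GFF3/VCF/pileup readers and writers convert the 1-based on-disk
conventions at the boundary and nowhere else. A circular genome is stored
linearized; a single feature may wrap the origin (its `end` exceeds the
genome length and is interpreted modulo the length). All genome-wide
statistics are computed on the linearized sequence.

Printed percentages round half-up to two decimals (`decimal`-based, not
Python's banker's rounding), matching the convention of published
organelle tables; raw fractions are kept alongside wherever they feed
further arithmetic.

## Composition accounting

Per-class content uses per-base boolean masks, so overlapping features of
one class count once. Bases claimed by more than one class are assigned by
the fixed precedence protein-coding → pseudogene → tRNA → rRNA, which
makes the five class fractions (including the non-coding remainder) an
exact partition of the genome — the alternative (counting overlaps in both
classes) breaks the sum-to-one invariant that downstream sanity checks
rely on. Hypothetical ORFs are pooled with protein-coding genes. GC
content excludes N from numerator and denominator and refuses empty or
all-N input. Locus counts and unique gene names (collapsing multi-copy
genes via their family name) are reported separately, since gene-content
tables habitually mix the two.

## Chloroplast-derived region detection

Seed-and-extend local alignment: exact 11-mer seeds against an index of
the mt genome, ungapped extension with match +1 / mismatch −2 and X-drop
20, both strands of the plastid sequence. Significance uses the
Karlin–Altschul form E = K·m·n·e^(−λS) with (λ, K) = (1.33, 0.621), the
tabulated ungapped values for the +1/−2 scheme. Hits are kept when
identity ≥ 0.80, E ≤ 1e−5 and length ≥ 50 bp (all configurable), then
merged along the mt axis regardless of their plastid origin, because the
biological object of interest is the mt-side region.

Gapped extension is deliberately omitted: the retention thresholds are
identity- and length-based, and at the divergence of recent plastid
transfers ungapped chains recover the transferred segments; the planted
inserts in the synthetic data are substitution-mutated only, consistent
with this scope. A consequence worth knowing: a detected boundary can
drift a few bases beyond a planted insert when flanking background happens
to match the plastid flank, so recovery tests assert containment with a
small tolerance rather than exact ends.

## Repeat landscape

Long repeats are maximal exact repeated pairs ≥ `min_len` (default
100 bp): forward pairs from matching the sequence against itself,
palindromic pairs from matching against its reverse complement, each found
by 21-mer seeding plus maximal extension and reported once with
`pos1 < pos2`. Mismatch-tolerant repeat models are out of scope. Inside a
long tandem tract every lag that is a multiple of the unit produces a
legitimate maximal pair; these are reported, as repeat-pair finders do.

Tandem arrays are maximal exact runs satisfying `seq[i] == seq[i+p]`,
reported at their primitive period with defaults period ≥ 2, ≥ 3 copies,
array ≥ 24 bp (chosen in the spirit of common tandem-finder defaults;
fully configurable). Reports contained in a kept larger array, or the same
interval at a multiple of the period, are collapsed.

The repeat fraction is the union of covered bases (both copies of a pair,
the whole tandem array) over the genome length — the union convention is
stated here because published repeat percentages rarely say which they
use. Both finders are verified against brute-force oracles (all-diagonal
scanning; per-position period scanning) on kilobase-scale sequences.

## Codon usage

RSCU(c) = degeneracy(F) · n(c) / Σ_F n, over the standard genetic code
with the six-fold Leu/Ser/Arg families whole and the three stop codons as
one family of degeneracy 3. Families with zero total are reported as
missing rather than zero. The codon–anticodon map is strict
reverse-complement pairing: one anticodon, one codon. Wobble decoding is
intentionally not modelled — any wobble rule set would be speculative and
would break the one-row-per-codon table layout; codons whose tRNA is
absent simply have no entry.

## Variant concordance and Ti/Tv

Callset intersection matches on exact (position, ref, alt); indels are
assumed left-normalized upstream and no normalization pass is attempted.
Both callers must individually reach the allele-fraction threshold
(default 0.15); the retained record carries the smaller fraction. Coding
synonymy translates the containing codon on the feature strand with ref
versus alt; a SNP whose codon is truncated at a feature edge degrades to
non-coding rather than guessing a frame. Ti/Tv with zero transversions is
undefined (`None`), not infinite — stratified subsets hit this. The
per-kilobase variation rate is reported raw and rounded; the denominator
is the caller's choice and both the full genome length and any
alignable-length alternative can be passed explicitly.

## Copy number and origin attribution

Each platform's (nuclear, mt, cp) mean depths are scaled to nuclear = 1
before averaging across platforms, making the estimate invariant to
per-platform sequencing effort; components are rounded half-up to
integers *before* the attribution formulas, so the printed chain
(ratio → percentages) is internally consistent. Attribution treats
homologous loci as receiving reads proportionally to copy number:
nuclear share 1/(1+m), plastid share c/(c+m).

Mapping percentages use the original fragment count as denominator for
both the high-quality and the mt-mapped percentage — the convention that
reconciles with published profile tables. Coverage bins are the fixed set
{0, 1–4, 5–9, 10–99, 100–999, ≥1000}; bin bases always sum to the genome
length.

## Expression, size factors, polycistrons

A gene is expressed in a sample iff its fragment count is nonzero; the
expressed set requires ≥ 2 samples by default. Size factors are the
median-of-ratios estimator (median over genes, positive in all samples, of
count over the gene's geometric mean). Expression tiers (high / moderate /
low) are terciles of log1p normalized means — a labelling convention, not
a fitted model, and documented as such in the output. Polycistron
detection clusters adjacent same-strand genes whose intergenic gap
(≤ 2000 bp) is covered at depth ≥ 1 at every base; both thresholds are
conventions standing in for transcript assembly, which is out of scope.

## RNA editing

Calling thresholds are ≥ 3 reads for the alternative base and ≥ 50% of
base calls, both inclusive, per sample (an absolute floor of "more than
2 reads" is implemented strictly as ≥ 3 and is configurable). Edit types
are reported on the gene's sense strand; intergenic sites are typed on the
plus strand and carry no codon fields. Features whose CDS length is not a
codon multiple are refused classification and flagged rather than guessed.
Aggregation keys sites by (position, sense alternative base); a
`min_datasets` filter drops weakly supported union sites before any
statistic. Codon-change ranking breaks count ties lexicographically so the
ordering is deterministic.

## Synthetic data generator

The generator emulates the structural features the analyses consume: a
uniform-random background (realistic plant mt GC is near 45%, and uniform
ACGT gives 50% — close enough for threshold behaviour, and simpler to
reason about); genes as ATG + non-stop codons + stop on both strands;
plastid inserts copied verbatim from a generated cp genome under a
substitution load; planted repeat pairs and tandem arrays; SNPs/insertions
with controlled transition fraction and allele fractions; and candidate
C-to-U sites at sense-strand C positions inside genes, split into a shared
core plus per-sample private draws. Pileup counts are binomial: the
alternative base at the editing efficiency (or the variant's allele
fraction), sequencing errors uniform over the three non-reference bases.

Default study conditions used in the tests: depth 30, error rate 0.5%,
editing efficiency 0.9, 4 samples over 2 cultivars, genomes of 20–80 kb
with 4–12 genes — sizes at which every recovery test runs in seconds while
leaving genuine stochasticity in the pileups. All randomness flows from an
explicit seed through one `numpy` generator per call; identical inputs
reproduce byte-identical outputs.

What the generator does **not** emulate — and therefore what passing tests
do not show about real data: alignment artefacts (mapping bias, paralog
collapse, soft-clipping), platform error profiles and homopolymer errors,
indel-containing plastid transfers, partial/ambiguous editing below the
50% threshold, and RNA pileups reflecting underlying DNA variants.
Recovery at precision/recall ≥ 0.95 on this data demonstrates the
correctness of the calling logic and thresholds, not robustness to
real-world alignment noise.

## Known limitations

- The homology engine is ungapped and exact-seeded; highly diverged or
  indel-rich plastid transfers would be fragmented or missed.
- Repeat discovery is exact-match only; degenerate repeats are invisible.
- One wrapped feature per circular genome is supported; analyses treat
  the sequence as linear otherwise.
- Tandem scanning over all periods is O(n·p_max); for megabase genomes
  cap `max_period`.
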