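# Methods

## Scope and model

`hremeth` reimplements, at desk scale and with fully synthetic data, the
computational core of a bisulfite-methylome analysis of hypoxia-induced DNA
demethylation: per-CpG methylation calling from directional whole-genome
bisulfite sequencing (WGBS) reads, a coverage- and effect-size-based filter
for CpGs that lose methylation under hypoxia, a genome-wide scan for
CpG-containing hypoxia-response elements (HRE-CpGs), TSS-distance
annotation, and clone-based Na-bisulfite promoter profiling.

The underlying measurement model is binomial throughout. Sodium bisulfite
converts unmethylated cytosine to uracil (read as T) while 5-methylcytosine
is protected, so for a CpG with true methylation level *m* covered by *n*
informative reads, the methylated-read count is approximately
Bin(*n*, *m*) (exactly binomial when conversion is complete and sequencing
error is zero). Every quantitative expectation in the test suite — recovery
bounds, detection rates, false-positive rates — follows from this model via
binomial standard deviations or exact tail sums; no asymptotics are used.

## Synthetic data generator

The generator is first-class, tested code; it defines the study conditions
for everything downstream.

* **Genome.** I.i.d. background with configurable GC fraction (default
  0.41, the human genome-wide value) and a requested number of
  non-overlapping planted HRE 5-mers, each written as forward (G/A)CGTG or
  reverse-orientation CACG(C/T) at a recorded position. Planting positions
  are recorded as ground truth; the background can, and does, contain
  incidental HRE motifs, which is why scanner tests assert "all planted
  recovered" and use an independent regex oracle for the full match set.
* **Reads.** Directional (Lister-style) protocol only: original-top (OT)
  reads show C→T conversion, original-bottom (OB) reads appear as G→A
  relative to the forward reference. Fragment starts are uniform, read
  length fixed (default 100 bp), strand a fair coin, read count
  ceil(coverage × L / read length). Each cytosine on the sampled strand is
  methylated with its site probability (CpG) or with the non-CpG
  probability (default 0, matching somatic cells and enabling
  conversion-efficiency QC); unmethylated cytosines convert with
  probability *c* (default 0.99). Sequencing error is a uniform
  substitution at a configurable rate; qualities are constant Q40 because
  nothing downstream consumes them. Read names encode (contig, start,
  strand) so mapping accuracy is directly measurable.
* **Clones.** Independently converted top-strand copies of an amplicon with
  per-site methylation draws recorded in a truth matrix; imperfect
  conversion leaves residual non-CpG cytosines exactly as in real
  failed-conversion clones.
* **Not emulated:** paired-end reads, indels/structural variation, PBAT
  complementary strands, per-base quality error models, PCR duplicates,
  M-bias, CNV/aneuploidy, and real-genome repeat structure. Passing tests
  therefore demonstrate correctness of the algorithms under the binomial
  model, not robustness to every artefact of real libraries.

All randomness flows from explicit integer seeds (one RNG per simulation
call, seeded from the user seed plus the condition index), and seeded runs
are byte-identical.

## Read mapping and methylation extraction

Reads are mapped in three-letter space: the reference is collapsed C→T for
the OT hypothesis and G→A for the OB hypothesis, the read (or its reverse
complement) is collapsed the same way, and candidate loci from a pigeonhole
seed index (default seed length 20, up to mismatch-budget+1 seeds per read)
are verified by vectorised mismatch counting. The mismatch budget defaults
to 2 per 75 bp. Ties and misses return no alignment — ambiguous placements
are discarded rather than randomly placed, so methylation counts are
seed-independent. On genomes of a few kb the search provably equals
brute-force enumeration over every offset of both spaces (tested).

Extraction votes per CpG: OT reads through the base over the forward-strand
C (C methylated, T unmethylated), OB reads through the base over the G
(G methylated, A unmethylated); any other base (sequencing error) is
ignored, not counted as unmethylated. Strands are merged by default —
CpG methylation is symmetric — with a per-strand mode retained for QC.
Coordinates are 0-based half-open internally and 1-based in all text
reports.

## Differential filter and optional test

A CpG is classified demethylated under hypoxia when cov_N ≥ 5 **and**
cov_H ≥ 5 **and** methdiff = m_N − m_H **strictly** exceeds 0.2. The
coverage gate is applied to both conditions (the conservative reading;
configurable), and the threshold comparison is strict. Hypermethylated
sites (methdiff < −0.2) are tallied separately. An optional per-CpG
two-sided Fisher exact test with Benjamini–Hochberg correction is provided
for QC; it is off by default and never alters the filter classification.

The filter's operating characteristics have a closed form: with estimated
levels a/n_N and b/n_H, the detection (or false-positive) probability is
the exact double sum P(a/n_N − b/n_H > 0.2) over the two binomials
(`demethylation_tail_probability`). At coverage 30 and a planted 0.95→0.70
change this predicts ≈ 0.70 sensitivity, which the end-to-end pipeline
reproduces within Monte-Carlo error; under the null it predicts the
filter's false-positive rate (≈ 0.047 at m = 0.5, coverage 30/30).

A calibration caveat worth stating: the two-sided Fisher exact test is
conservative on discrete tables. At coverage 30/30 its exact achieved size
at α = 0.05 is at most ≈ 0.027 (maximised near m = 0.5), so empirical
rejection fractions near 0.03, not 0.05, are the correct behaviour.

## HRE-CpG scan and annotation

Every offset of every contig is tested against both orientation patterns by
vectorised base comparison (deliberately not a regex, so a regex can serve
as an independent oracle). Windows containing N never match; lowercase
(soft-masked) sequence is uppercased and masking ignored. The unit of
counting is the unique CpG: matches are grouped by (contig, CpG position),
so the palindromic E-box CACGTG — one forward and one reverse match over
the same CpG — counts once. A `unit="match"` flag exposes the alternative
tally. Nearest-TSS distance is the minimum absolute distance in kb (one
decimal), ties broken lexicographically by gene name for deterministic
reports; upstream/downstream is judged relative to the gene's strand.

## Clone analysis

Each clone is aligned globally (affine gaps: match +1, mismatch −1, open
−4, extend −0.5) against the converted reference in collapsed space, under
all four strand-product × read-orientation combinations; the best-scoring
one is kept, which makes calls invariant to reverse-complemented Sanger
reads. Residual mismatches in collapsed space plus unaligned reference
positions, as a fraction of the reference length, must not exceed 0.1 or
the clone is rejected. Conversion efficiency per clone is the converted
fraction of non-CpG cytosines; clones below the QC threshold (default
0.95) are excluded from per-site percentages. Ambiguous bases are excluded
from percentages rather than counted as unmethylated. Site labels are
TSS-relative signed positions from a user-supplied anchor (negative =
upstream). The default cross-condition comparison is a per-site Fisher test
on pooled clone counts; an experiment-grouped mean ± SD mode with Welch
t-tests is provided for the three-experiments presentation.

## Problem sizes and numerical choices

Test and acceptance runs use 2–50 kb genomes, coverages 15–200, 27–81
clones, and 1,000-CpG null panels — sizes at which every binomial
prediction is sharp and the whole suite runs in well under a minute.
Levels at zero coverage are NaN (never 0); percent tables round half-up to
integers; level strings trim a single trailing zero ("0.6", "1.0");
report sorting is by |methdiff| descending with ID tie-breaks. The
promoter scenario plants a published twelve-site proximal-promoter
methylation profile (86…78% normoxia, 70…100% hypoxia at sites −81…−242)
as simulation truth, and recovery is asserted within two binomial standard
errors per site.

## Known limitations

* The mapper is exact only at toy scale; it is not a replacement for a
  production bisulfite aligner on real genomes.
* Single-CpG resolution only; no region (DMR) segmentation.
* The demethylation filter is a thresholding rule, not an inference
  procedure; its error rates are coverage-dependent by construction.
* Clone analysis assumes amplicon-length Sanger reads without chromatogram
  ambiguity codes beyond single-base miscalls.
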