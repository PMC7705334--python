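# Methods

## The problem

TagSeq (3' tag-based RNA-seq) sequences one short read immediately upstream
of each transcript's poly(A) tail instead of covering the whole transcript.
That makes per-sample expression profiling cheap enough to replicate
heavily, but every analysis step then hinges on details that whole-transcript
RNA-seq can ignore: PCR duplicates must be removed using degenerate primer
bases (they can be half the library), tags must be aligned to a *de novo*
reference transcriptome rather than a genome, and only uniquely mapped tags
can be counted per locus. `tagref` implements that pipeline plus the
evaluation battery used to judge whether it works: locus-recovery saturation
curves, cross-reference specificity matrices, assembly summary statistics,
and MDS ordination of expression profiles.

## Read anatomy and the duplicate key

Each raw read (1 x 75 bp) is modeled as

    [4 degenerate bases][GGG][3'-proximal transcript fragment][poly(A)...]

The degenerate 4-mer labels the cDNA molecule (a UMI of 256 states). Two
reads identical over their first 57 bases — degenerate 4-mer, GGG, and 50
bases of insert — are treated as PCR copies of one molecule, and only the
first-encountered read survives. The key identifies a *molecule*, not a
genomic position: fragments from the same position with different degenerate
bases stay distinct. Consequences worth knowing:

* The key is exact. A sequencing error inside the first 57 bases splits a
  duplicate group (at error rate *e* per base, a fraction ~57·*e* of copies
  escape collapsing). The simulator reproduces this: duplicates inherit the
  4-mer and insert but receive independent errors, so exact-recovery tests
  run at `error_rate=0`.
* Two molecules that independently draw the same 4-mer, locus and fragment
  start are indistinguishable *in principle* under this protocol (a birthday
  collision, roughly 1e-5 per same-locus molecule pair). The truth manifest
  therefore records each molecule's error-free 57-base key, and exactness is
  asserted against distinct keys (`SimTruth.n_identifiable_molecules`), with
  the raw lineage count available separately.

Deduplication runs *before* trimming (the key includes bases that trimming
removes), and the first-encountered survivor rule keeps the operation
deterministic under any input order.

## Trimming

Applied per read, in this order, with qualities trimmed in lockstep:

1. Remove the 7-base 5' prefix (4 degenerate + GGG). The GGG is a
   template-switch artifact, not transcript sequence; trimming only the 4
   degenerate bases would leave it to mismatch against the reference. The
   prefix length is exposed (`--primer-prefix-len`) for users who disagree.
2. 3' quality trimming by the running-sum rule: subtract the threshold
   (default Q20) from each quality, accumulate partial sums from the 3' end,
   and cut at the position of the minimum. Unlike "cut at first low base",
   this tolerates isolated dips while removing genuinely degraded tails.
3. Remove a 3' adapter occurrence (leftmost match, minimum overlap 8 bases,
   up to 10% mismatches) and any terminal A-run of 8 or more bases. Runs of
   7 or fewer are kept: they are as likely genuine transcript sequence as
   tail, and an aligner handles a few trailing tail bases gracefully.
4. Discard anything shorter than 57 bases.

Whether quality trimming preceded poly(A) removal in the original protocol
order is not documented for the tool chain this mirrors; quality-first was
chosen because adapter/poly(A) recognition is more reliable on
quality-clipped sequence. The 57-base floor means a retained tag always
spans at least 57 informative bases, which in turn guarantees the aligner's
seeding bound below.

## Alignment

A seed-and-extend banded local aligner maps tags to contigs:

* **Scoring**: match +1, mismatch -4, gap open -6, gap extend -1 (a length-k
  gap costs 6 + k), report threshold 30 — the conventional short-read
  defaults. All are fields of `ScoringScheme`.
* **Band**: half-width 5 around each seed diagonal. Gaps relative to a
  transcriptome reference are not expected for genuine 3' tags, so a narrow
  band sacrifices nothing; when the optimal alignment is substitution-only
  it lies on the seed diagonal and the banded score equals the unbanded one
  (verified against an exhaustive Smith-Waterman oracle in the tests).
* **Seeding**: exact 14-mers, indexed over the forward strand of every
  locus; the query is reverse-complemented for the minus strand. Seed
  length 14 is a provable sensitivity floor rather than a tuning choice: a
  57-base tag carrying at most 3 substitutions always contains an intact
  run of at least ceil((57-3)/4) = 14 bases, so no such tag can be lost at
  the seeding stage. Longer seeds (19+ is common in genome mappers) do not
  carry this guarantee for tags this short.
* **Uniqueness**: a tag maps uniquely when exactly one locus attains its
  best score; `n_best_loci` counts loci tied at the maximum. Multiple
  equal-score placements *within* one locus collapse to the leftmost
  reference start and count once — uniqueness is about loci, not positions.
  Ties across loci are reported in lexicographic id order, which also makes
  output independent of reference insertion order.

The banded dynamic programming runs in a numba kernel that propagates
alignment-start coordinates alongside scores, so the leftmost-start
tie-break needs no traceback.

## Counting and filtering

Counting is unstranded (the reference assembly is unstranded) and
conservative: each uniquely mapped tag adds one to its locus; ambiguous
(multi-locus) tags are counted nowhere, mirroring standard htseq-count
"ambiguous" handling. Fractional allocation was rejected — nothing in this
protocol justifies a split. Per-sample vectors combine over the union of
observed loci, and loci with fewer than 5 hits summed across the *whole*
data set of a species (not per sample) are removed to suppress counts
caused by sequencing errors.

## Evaluation metrics

* **Recovery**: the proportion of reference loci with at least `min_hits`
  (default 5) counts, per sample and cumulatively over row sums. The
  denominator is the entire reference, with no attempt to exclude
  non-translating or erroneous contigs.
* **Saturation**: ordinary least squares of recovery proportion on
  ln(raw reads). The x-axis is *raw* sequencing effort, not post-dedup
  tags, because that is the quantity a study designer controls.
* **Specificity**: the proportion of a sample's cleaned tags aligning to
  each of several references, each reference indexed independently; the
  denominator is the number of tags entering alignment.
* **Assembly statistics**: contig count, N50 (descending cumulative-length
  walk, first length reaching half the total — always the length of an
  actual contig), maximum and total length.

## Ordination

Relative abundance (each sample column divided by its total) -> the
`top_n` loci with largest standard deviation across *all* samples (one
common set for every pair, ties broken by locus id) -> pairwise RMSD
`sqrt(mean_l (x_l - y_l)^2)` -> classical (Torgerson) scaling: double-center
-D²/2, eigendecompose, scale the top two eigenvectors by the square roots
of their eigenvalues. RMSD differs from plain Euclidean distance only by a
1/sqrt(n) factor, which classical scaling absorbs into the coordinate
scale. Negative eigenvalues are truncated; missing axes are zero-filled
with a warning; axis signs are fixed so each axis's largest-magnitude
loading is positive, making output invariant to sample order.

No log transform is applied by default — the distance is computed on the
relative abundance matrix itself — but `log2` with a pseudocount is
available. `top_n` defaults to the median number of observed loci among
samples (`suggest_top_n`); whether "observed" should be read pre- or
post-filter is genuinely ambiguous, so the helper takes whichever table it
is given. Outliers are excluded manually by sample id, never auto-detected:
an ordination outlier is a scientific judgment call.

## The simulator

`simulate` generates what the pipeline consumes, plus a manifest tying
every read to its molecule and locus. Defaults describe a realistic desk-
scale library:

| parameter | default | rationale |
| --- | --- | --- |
| `read_length` | 75 | single-end 1 x 75 bp libraries |
| `dup_rate` | 1.0 | expected extra PCR copies per molecule; duplicate fraction dup/(1+dup) = 50%, mid-range of the 42-61% seen in real libraries |
| `error_rate` | 0.001 | typical Illumina substitution rate |
| `locus_length_log_mean/sd` | 6.3 / 0.45 | lognormal contig lengths, median ~545 bp (real de novo assemblies show N50 575-895 bp), floor 200 bp |
| `expression_shape` | 1.5 | lognormal sigma of locus weights; expression spans ~3 orders of magnitude |
| `fragment_window` | 400 | fragment starts uniform in the last 400 bases (a 400-500 bp size selection); the true insert-length distribution is unknown and this stand-in makes no claim about it |
| `polya_min/max_len` | 10 / 30 | visible poly(A) tail length in reads |

Reads are built as degenerate 4-mer + GGG + fragment (+ poly(A) when the
fragment reaches the transcript end and room remains), errors are applied
per PCR copy *after* duplication, and qualities are drawn high (mean Q35)
with occasional low-quality 3' tails. A single RNG stream seeded once
drives all draws in a documented order, so outputs are byte-reproducible.
Multi-sample studies (`simulate_study`) share one transcriptome and
lognormal weight vector, shift a configurable fraction of loci by a fold
factor at the second location, and spread per-sample depth linearly so that
saturation fits have distinct effort values.

What the simulator does **not** model: rRNA contamination, adapter
read-through dimers, lane or batch effects, quality miscalibration,
transcript-end bias in priming chemistry, allelic variation between the
tag sample and the reference sample, and fragmented/partial reference
contigs (every simulated contig contains its full 3' end). Passing tests
therefore demonstrate algorithmic correctness of the pipeline under its
own assumptions — exact duplicate keys, 3'-anchored fragments, a reference
that contains the truth — not robustness to every artifact of real
libraries. In particular, real recovery fractions are dominated by
reference incompleteness at the 3' end, which is deliberately outside the
simulation.

## Numerical and scale choices

* Problem sizes in tests and `scripts/acceptance.py` (50,000-read dedup
  runs, a 1,000-locus / 200,000-read end-to-end run, 8-sample ordination
  studies) were chosen as the smallest sizes at which the statistical
  assertions have comfortable power; each completes in well under a minute
  on one CPU.
* Statistical tolerances follow the oracle, not the implementation: exact
  equality where the computation is deterministic (dedup counts, filter
  membership, N50), 1e-9/1e-12 for linear-algebra identities, and 3-4
  standard errors/deviations for sampled quantities.
* `run-all` reports are JSON with sorted keys and default float repr, which
  is what makes byte-identical rerun checks meaningful.
* Phred+33 is assumed everywhere; Phred+64 input is rejected rather than
  auto-detected.
* Degenerate counting: `N` bases never match in alignment and carry no
  special casing elsewhere.

## Known limitations

* The aligner reports all tied best-score loci but computes no mapping
  quality; the unique/multi dichotomy is a score-tie definition.
* Gaps wider than the 5-base band are unrepresentable by construction;
  this is intended for 3' tags but makes the aligner unsuitable as a
  general-purpose mapper.
* Adapter matching is ungapped (mismatches only), as in the common
  trimming tools' default mode.
* UMI error correction (clustering keys within small Hamming distance) is
  deliberately absent: the duplicate key is exact, so duplicate fractions
  are slightly underestimated at non-zero error rates.
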