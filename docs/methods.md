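# Methods

## The problem: allele drop-out in amplicon panels

Targeted resequencing panels (TruSeq Custom Amplicon and similar) amplify
each target with a locus-specific primer pair: the ULSO (upstream
locus-specific oligo) begins read 1 of every pair, the DLSO begins read 2.
When a germline variant falls inside a primer's genomic footprint, the
mutated allele hybridizes poorly and can amplify at up to 100-fold lower
yield — allele drop-out (ADO). Two artifacts follow:

1. The footprint variant itself is diluted. Reads from the affected
   amplicon carry the reference sequence in their primer bases, so if raw
   reads are aligned with primer bases feeding the pileup, the variant's
   allele fraction falls well below the heterozygous expectation and below
   typical caller thresholds (false homozygosity).
2. Any linked variant on the same haplotype — even one outside every
   footprint — is diluted too, because the ADO-affected amplicon
   contributes almost exclusively wild-type reads over that position.

`adotrim` implements the two-round remove-and-recall strategy against both
artifacts, a single-round soft-clip baseline emulating the vendor workflow,
and a synthetic-data generator that reproduces the two-amplicon worst case,
so the whole comparison runs from nothing in seconds.

## Pipelines

**Two-step pipeline** (`run_two_step`):

1. *Round 1.* Each read pair is assigned to the amplicon whose ULSO matches
   the start of read 1 and whose DLSO matches the start of read 2, allowing
   at most one mismatch per read and no gaps; unassignable pairs are
   discarded. Primers are cut off, trimmed reads are aligned to their
   amplicon's expected insert, and variants are called from the pileup.
2. *Footprint intersection.* Every round-1 variant whose reference span
   (anchor base, for insertions) intersects an amplicon's ULSO or DLSO
   footprint marks that amplicon as ADO-suspect.
3. *Round 2.* All read pairs of suspect amplicons are removed, the calling
   pass repeats over all targets, and the two call sets are merged by
   (chrom, pos, ref, alt) with round-1 precedence. Exactly one removal
   round runs; there is no fix-point iteration. If removal leaves target
   bases with no coverage, the loss is reported in the run statistics
   (regions covered by a single amplicon cannot be rescued).

**Single-round baselines** (`run_single_round`): `softclip` keeps primer
bases in the record as soft-clips (excluded from pileup) — the vendor
Custom Amplicon behaviour; `trimmed` is round 1 alone; `untrimmed` aligns
raw reads against ULSO + insert + DLSO with primer bases counted in the
pileup — the naive mode that produces artifact 1.

## Alignment

Reads are aligned only against their assigned amplicon's expected sequence
(no genome-wide search): amplicon assignment has already localized them, and
this replaces the general-purpose aligner of a BWA/GATK stack with an
equivalent, self-contained step. The aligner is a local Smith–Waterman
with affine gaps (match +2, mismatch −2, gap open −4, gap extend −1),
restricted to a diagonal band. Cumulative gap length is capped at one third
of the read length, read as cumulative I+D ≤ floor(len/3). The band is
twice the cap wide, so an optimum that overspends the cap is still found
and the read is then reported unaligned, rather than silently replaced by
an inferior in-band path. A read is also reported unaligned when its best
alignment covers less than two thirds of its bases (the rejection rule that
classifies, e.g., a read spanning a 60-base deletion as unalignable).

Two engineering choices matter for throughput and are behaviour-neutral:

- *Gapless fast path.* Every diagonal placement is scored with optimal
  terminal clipping (a vectorized maximum-subarray scan). The result is
  accepted only when it covers the read to within 4 bases with at most 2
  mismatches — under this scoring a gapped alignment cannot beat such a
  placement — otherwise the banded dynamic program runs.
- *Memoization.* Alignment results are cached per (amplicon, mode, mate,
  sequence). Amplicon data is massively duplicated, so cost is driven by
  distinct sequences, not read count.

N bases: in primer matching, N on either side matches for free; in
alignment scoring, N never counts as a match.

## Variant calling

The caller is a deterministic allele-fraction filter, not a genotype
likelihood model. Per target column the pileup records base counts,
insertions anchored after the preceding reference base, and deletions
(anchored left; deleted bases count toward depth, inserted bases do not).
A site is called when depth ≥ 30, the best non-reference allele has ≥ 5
reads and ≥ 25% of depth; fraction ≥ 75% is classified homozygous. One alt
per site (the configurations of interest are never multi-allelic). The 25%
floor mirrors the allele balance below which mainstream callers drop
heterozygotes — the regime ADO exploits — and 30× is the usual low-coverage
cutoff for amplicon panels. No variant quality score is emitted: the
original stacks' quality filtration is caller-internal and unspecifiable.
VCF 4.2 I/O goes through pysam (positions 1-based on disk; 0-based
half-open in memory everywhere else).

## Synthetic data generator

The generator emulates the two-amplicon ADO configuration with full
per-pair ground truth:

- Random 600 bp reference; amplicons A [100,310) and B [300,510)
  (insert coordinates), 20 bp primers, 250 bp amplicons, 2×150 bp pairs.
  B's ULSO footprint [280,300) lies inside A's insert.
- m1 at position 297, inside B's ULSO footprint: a substitution in SD1, a
  single-base insertion in SD2. m2, an SNV 5 bp downstream at 302, sits
  inside both inserts and outside every footprint.
- Amplicon A draws the mutated haplotype per pair with probability 0.5
  (`het_fraction`); amplicon B with odds wild:mutated = 1:0.01
  (`ado_yield_ratio`, the 100-fold yield reduction), i.e. ≈0.99% mutated.
  Mutated pairs carry m2 with probability 0.9 (`second_mut_prob`).
- Native composition: 3186 A pairs and 5484 B pairs (A:B ≈ 37:63).
  `mix_reads` resamples to any A-fraction at constant total (8670),
  without replacement when the pools allow, with replacement otherwise
  (flagged in the truth table).
- Qualities are constant `I` (Q40) and the base-error rate defaults to 0,
  so threshold arithmetic is exact; an error-rate knob exists for
  robustness tests. Byte-identical output under identical configs
  (fixed-mtime gzip).

The SD2 insertion site is chosen so the shifted primer prefix differs from
the ULSO at ≥ 2 positions (the no-gap, one-mismatch rule then discards
every mutated-B pair deterministically) and so the insertion left-aligns
uniquely.

What the generator does **not** emulate: sequencer error profiles and
quality distributions, GC/length amplification bias beyond the single ADO
ratio, multi-amplicon panels at production scale, or sample multiplexing.
Passing tests therefore demonstrate the pipeline logic — assignment,
trimming, removal, re-calling, merge arithmetic — under clean conditions,
not robustness to real error processes.

## Expected arithmetic (why the comparison behaves as it does)

With total N pairs and A-fraction f, only A read-2s cover m1 after
trimming, so m1's fraction is ≈ 0.5 at any f > 0 and m1 is called whenever
depth (= f·N) ≥ 30. In untrimmed mode B read-1s cover m1 with reference
primer bases, diluting it to ≈ (0.5·f + 0.0099·(1−f)) ≈ 19% at the native
f = 36.75% — under both the 25% calling floor and the ~20% the naive
alignment shows. m2 is covered by A read-2s and B read-1s, so a single
calling pass sees fraction ≈ 0.45·f: the 25% floor is cleared only when
f > 5/9 ≈ 55.6%, which on a 10%-step grid means 60% and above — the
threshold effect of the single-round baseline. After removing B, m2's
fraction is ≈ 0.45 at any f ≥ 10% (depth ≥ 867), so the two-step pipeline
recovers it across the grid.

A consequence of using a sharp 25% threshold: the single-round detection
boundary moves with `second_mut_prob` p (fraction ≈ 0.5·p·f). The
insensitivity of outcomes to p ∈ [0.7, 1.0] therefore holds away from the
boundary (tested at f = 20%, 36.75% and 80%) but not at f ∈ {60, 70}%,
where 0.5·p·f straddles 0.25. A likelihood-based caller with soft
thresholds would blur this edge; reproducing that behaviour is out of
scope. For the same reason the SD2 improvement of the vendor baseline at
f ∈ {30, 40}% (attributable to indel handling in the original caller) is
not reproduced: here SD2 tracks SD1 exactly.

## Numerical and convention choices

- Coordinates 0-based half-open internally; VCF converts to 1-based.
- Primer orientation: ULSO stored as read 1 begins with it, DLSO as read 2
  begins with it (reverse complement of the plus strand at the downstream
  footprint); the loader verifies both against the reference.
- Manifest: a minimal TSV dialect (`amplicon_id chrom insert_start
  insert_end ulso dlso`); the expected insert sequence is derived from the
  reference at load, so a manifest/reference disagreement surfaces as a
  primer-footprint mismatch error.
- Assignment ties (several amplicons' primer pairs matching): fewest total
  mismatches, then manifest order. Only the ULSO↔read1 / DLSO↔read2
  orientation is tried.
- Caller tie between equal-count alleles: SNV before insertion before
  deletion, then lexical.
- QC gate: reference statistics are means over the best ceil(0.2·n)
  samples (fewest uncovered regions, ties by id); a sample is excluded
  when quality < 0.30×reference or reads < 0.10×reference, both read
  literally. The alternative "30% below reference" reading is available
  as `interpretation="relative_drop"`.
- Sharing buckets: [0, 0.5), [0.5, 0.8), [0.8, 1] — "at least 80%" makes
  0.8 inclusive in the top bucket.
- All randomness lives in the generator and in mixture subsampling; the
  pipelines are deterministic functions of their input. Child seeds are
  derived from the user seed with `SeedSequence` and kept below 2³¹.

## Problem sizes

The shipped experiments run at the study's native scale — 8670 read pairs
per mixture, eleven grid fractions plus the native composition, both
dataset flavours — chosen because the threshold arithmetic above needs the
native depth to be exact and the whole grid still completes in well under
a minute per dataset flavour on one CPU. Unit tests use scaled-down
populations (120–200 pairs per amplicon) where depth does not matter.

## Known limitations

- Pileup arrays are allocated per chromosome, sized to the reference; fine
  for amplicon-panel references, wasteful for a whole genome.
- The caller reports one alt allele per site and no quality score.
- Reads are modelled as fitting entirely within their amplicon target
  (the TruSeq geometry); chimeras and adapter read-through are upstream
  concerns.
- Sample-level QC operates on externally supplied per-sample statistics;
  FastQC-style metrics beyond read count and mean base quality are not
  recomputed.
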