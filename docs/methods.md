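# Methods

This document describes the statistical and algorithmic model behind
`clusterhop`, the defaults it ships with and why, and the known limitations
of the synthetic-data generators used to validate it.

## Problem model

A haploid genome carries a contiguous multi-gene cluster at the right end of
one chromosome (the *donor* region). In some strains one or more extra copies
of the cluster have translocated into interior loci of other chromosomes
(*recipient* regions). Given paired-end sequencing of such a strain mapped to
the single-copy reference, the package answers three questions:

1. **Is the cluster duplicated?** Extra copies inflate read depth over the
   donor interval in proportion to copy number.
2. **Where did the copies land?** Reads that straddle an insertion junction
   fail to map against the donor sequence while their mates map inside it;
   realigning those mates to the whole genome piles them up in the flanks of
   every recipient locus. Assembled junction-spanning contigs pinpoint the
   coordinate at base resolution.
3. **Is the duplication reflected in array and expression data?** CGH
   log-ratios test per-gene DNA abundance per strain; expression log2
   fold-changes test transcriptional consequences; Spearman correlations test
   co-regulation and copy-number-to-expression dosage.

All internal coordinates are 0-based half-open; 1-based inclusive coordinates
appear only at I/O boundaries (`Region.from_1based` / `to_1based`).

## Coverage and copy number

* **Per-base depth** is computed from aligned blocks (CIGAR `M`-type
  operations) of records with MAPQ ≥ 30, via difference arrays and a
  cumulative sum.
* **Normalization** divides by the geometric mean of the *positive* per-base
  depths. The geometric mean matches the log2 domain used downstream and is
  insensitive to the heavy right tail a duplication itself creates;
  zero-depth positions are excluded so unsequencable stretches do not drag
  the baseline.
* **Windows**: non-overlapping 1 kb windows (terminal partial windows kept;
  all-zero windows marked missing). The window value is log2 of the mean
  normalized depth, so single-copy ≈ 0, a 3-copy segment ≈ log2 3 ≈ 1.585.
* **Segmentation** is circular binary segmentation (CBS). For each segment
  the statistic is the maximum over circular arcs of
  |mean_in − mean_out| / sqrt(1/k + 1/(n − k)); significance is assessed by
  permutation, p = (1 + b)/(nperm + 1), with early stopping once the α
  decision is forced. Accepted splits recurse; adjacent segments whose means
  differ by < 0.05 log2 are re-merged. Missing windows are excluded from the
  statistic and boundaries are mapped back through the index.
* **Calls**: a segment is *duplicated* if its mean log2 ≥ 0.3 (between the
  1-copy and 2-copy expectations, robust at 30× noise) and *deleted* below
  −0.5.

CBS has a structural limitation at small scale: with very few signal windows
on a short chromosome, the permutation null contains the signal values
themselves, and a 2-window elevation on a 60-window chromosome is correctly
judged non-significant. The method targets ≥ 4 signal windows per chromosome
of ≥ a few hundred windows.

## Discordant-mate localization

Alignments against a donor-only target are filtered with the SAM-flag mask
arithmetic *require 5, drop 77, drop 141* — i.e. paired and itself unmapped,
minus the two both-ends-unmapped masks. On well-formed paired records this
selects exactly "self unmapped, mate mapped". Surviving reads are realigned
single-ended to the whole genome; realignments with MAPQ ≥ 30 build a
per-base mate-depth track. Positions where mate depth ≥ 25% of the
chromosome's mean total depth are merged across gaps ≤ 500 bp into candidate
regions; runs within 500 bp of the donor itself are suppressed as self-hits,
and candidates spanning ≤ 100 bp are flagged as failing the length filter.
Insert-size geometry (500 ± 25 bp, 151 bp reads) puts the mate pile-ups in
the ~350 bp flanks of each junction, so true candidates comfortably exceed
100 bp.

**Junction contigs** are scanned against the donor sequence and the genome
with a 31-mer index: the longest exact donor match and the longest exact
outside-donor genome match must each be ≥ 100 bp and abut within 10 bp in
contig coordinates. The insertion coordinate is the genome-side anchor
boundary; both contig strands are scanned.

**Reconciliation** labels loci by evidence tier: *confirmed* (passing depth
candidate + junction within 500 bp), *depth-only*, or *junction-only*.
Depth-only evidence is treated as suggestive rather than positional.

## Mapping

The built-in mapper is a 31-mer index (2-bit packed, sorted-array lookup)
with three seed offsets per read per strand, ungapped extension, a mismatch
fraction cap of 0.15, and MAPQ 60 for unique placements or 0 when a
competitor is within one mismatch of the best. It is deliberately minimal:
exact on the synthetic data the package generates, not a general-purpose
aligner (no gapped alignment, no base-quality-aware scoring).

## Read QC

A read is dropped when > 30% of its bases are below Q20 (its mate goes with
it); otherwise 3′ bases are trimmed while the terminal base is below Q30. If
either mate ends up shorter than 50 bp the pair is dropped. Counts of
dropped reads and trimmed bases are exact and audited by the pipeline
report.

## CGH differential representation

Per (gene, strain), replicate log2(test/reference) ratios are tested against
0 with a one-sample Wilcoxon signed-rank test: zeros dropped, mid-ranks on
ties, and an **exact** null for n ≤ 25 computed by dynamic programming over
all 2^n sign assignments on the doubled mid-ranks (the null is symmetric, so
the two-sided p is the symmetric tail mass). Above n = 25 a normal
approximation with tie-corrected variance and the standard 0.5-rank
continuity correction is used; it matches scipy's corrected approximation on
tie-free data. Benjamini–Hochberg adjustment runs across all (gene, strain)
tests; a strain's call is *over*/*under* at q < 0.05 by the sign of the mean.

A gene is *differentially represented* when every resistant strain is called
in the same direction and at most 2 sensitive strains are concordant (a
fraction-based variant, > 75% of sensitive strains discordant, is also
provided; with typical panel sizes the two coincide).

**Why 12 replicate values per (gene, strain) in the simulator:** an exact
signed-rank test on n values has a two-sided p floor of 2^(1−n). After BH
correction across m tests with k true signals, any call requires
p ≤ 0.05·k/m, so the test has *zero* power — regardless of noise level —
unless 2^(1−n) ≤ 0.05·k/m, i.e. m/k ≤ 2^(n−1)/20. At n = 6 that bound is
1.6, unusable; at n = 12 it is ≈ 102, which accommodates realistic
panel-to-signal ratios. Twelve values per gene models several probes per
gene times two technical replicates. This was fixed from the closed-form
argument above, before any end-to-end results were inspected.

## Expression analysis

DEG calling is threshold-based per strain (|log2FC| ≥ 1 versus the
reference) with a group-consistency rule: every resistant strain in the same
direction, at most 1 sensitive strain concordant.

Spearman ρ is the Pearson correlation of mid-ranks. For n ≤ 8 complete pairs
the p-value is exact by full n! permutation enumeration; above that the
usual t approximation applies. Pairs are handled pairwise-complete; pairs
with < 4 complete observations or zero variance are undefined and excluded
from the BH adjustment rather than silently assigned p = 1.

**Why the simulator plants DEG effects at 2.0:** a planted effect exactly at
the 1.0 threshold is called per strain with probability ≈ 0.5, so the
all-resistant rule would recover it in ≈ 12% of runs — the rule would look
broken when the generator is at fault. With effect 2.0 and noise 0.25 the
per-strain call probability is Φ(4) ≈ 0.99997. Chosen a priori from this
power calculation.

## Variant overlay

A minimal VCF reader (via pysam) extracts per-sample genotype presence (any
non-reference allele). `resistant_specific_variants` keeps sites present in
every resistant strain (or any, optionally) and absent from all sensitive
strains.

## Synthetic generators: realism and limitations

* Genomes are i.i.d. nucleotides at a target GC — no repeats, so mapping is
  easier than on a real genome. The mapper's MAPQ-0 behavior is tested with
  explicitly planted repeats instead.
* Read pairs are FR-oriented with truncated-normal inserts (±2 sd), Poisson
  pair counts per chromosome, uniform error rate, constant Q37 — no quality
  decay along the read, no indels, no chimeras.
* Junction contigs are cut directly from the planted sample genome
  (300 bp flanks) rather than assembled from reads; assembly itself is out
  of scope.
* CGH and expression values are Gaussian around planted effects —
  no dye bias, no probe-affinity structure, no count noise.
* Coexpression blocks share one latent factor per block; a negative block
  loads the first gene + and the rest −, the only sign pattern making all
  its pairs mutually anti-correlated.

These choices keep every planted truth exactly known, which is what the test
oracles need; they are not claims about real data.

## Numerical and reproducibility choices

* All randomness flows through `numpy.random.default_rng` with explicit
  seeds; seeds stay below 2^31.
* Permutation p-values use the add-one estimator (1 + b)/(nperm + 1), never
  exactly 0.
* The pipeline report embeds a SHA-256 digest of the full configuration and
  the seed; identical inputs give bit-identical reports.
* Depth uses difference arrays (O(bases + records)); the k-mer index packs
  codes into uint64 and looks up with binary search — no hash tables, so
  iteration order is deterministic.
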