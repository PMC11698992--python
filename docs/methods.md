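# Methods

This note documents the models, conventions and numerical choices behind
tirscan, and what the synthetic benchmarks do and do not demonstrate.

## Coordinate and alphabet conventions

External coordinates are 1-based inclusive on the forward genomic strand
(GFF3 convention) and converted once at the I/O boundary. All offsets
relative to a start codon use the −1 convention: the base immediately 5'
of the start codon's first base is −1, so a 30-nt upstream window covers
offsets −30..−1 and the "−18 to −9" rule bounds are both inclusive. For
minus-strand genes the genomic segment 3' of the CDS end is
reverse-complemented so windows always read 5'→3' on the mRNA; a
property test asserts exact strand symmetry.

Sequences are held internally in the DNA alphabet; U is mapped to T on
input so motif matching is alphabet-agnostic (UGAGG ≡ TGAGG). N is
tolerated in genomes but never matches a motif position. Variant labels
from the rRNA junction classifier are reported back in the RNA alphabet.

## Leader classification

The 5'UTR length of a proximal cistron is the number of transcribed
nucleotides strictly 5' of the start codon's first base (0 when the TSS
coincides with it). Classes: leaderless ≤ 5 nt, short-leader 6–10 nt,
leadered ≥ 11 nt — a total partition of the non-negative integers with
boundaries at 5/6 and 10/11. The ≥ 11 threshold for "leadered" was
chosen over the alternative "> 11" reading so that no length is left
unclassified; length 11 is leadered. Distal cistrons have no 5'UTR of
their own and receive class NA; class percentages are computed over
proximal cistrons only.

## Positional SD rule

The scan reports every exact, possibly overlapping occurrence of each
motif in the upstream window (default width 30 nt; no fuzzy matching, no
position weight matrices). An occurrence is a *signal* when the offset
of its 5' base lies in [−18, −9] relative to the annotated start codon
or relative to any in-frame alternative start codon (ATG/GTG/TTG) whose
first base lies within ±30 nt of the annotated start (multiples of 3
only; the span is configurable since no canonical value exists). The
"5' base" anchor is the motif's first base whatever its identity, so the
rule applies uniformly to GGAGG and TGAGG. A gene counts at most once
per motif regardless of the number of passing hits — required for
gene-level fractions such as 9/169 to be well defined.

Windows are deliberately *not* clipped at the TSS: the scan covers a
fixed 30 nt upstream of every start codon, which for leaderless genes
extends past the TSS into untranscribed DNA. `respect_tss=True`
restricts the window to transcribed positions for sensitivity analyses.
Distal-cistron windows may overlap the upstream gene's CDS in real
annotations; they are scanned without masking.

Percentages are rounded half-up to one decimal. An empty stratum
reports NA, never 0.

## Anti-SD duplex

`longest_antiparallel_duplex` slides one sequence (read 3'→5') against
the other over all relative alignments and returns the longest
contiguous run of Watson–Crick pairs, optionally admitting G:U wobble.
It is a complementarity count, not a thermodynamic model —
nearest-neighbour ΔG calculation is out of scope. Enabling wobble can
only lengthen the best run (tested); the function is symmetric in its
arguments.

## 16S 3'-end typing

Circular-ligation reads are anchored on the 16S 5'-start motif (AAUCC).
If the anchor occurs more than once, the occurrence maximizing
position-wise agreement between the read and a 5'-region reference wins,
ties going leftmost; an absent anchor raises a distinct error rather
than an `other` call. The read suffix ending at the junction is matched
against the variant catalog ordered by length descending (CCUCC, CCUCA,
CCUC, CCU), so a read ending CCUCC can never be called CCUC or CCU; no
exact match yields `other`. No mismatch tolerance is applied by default
(clone/Sanger inputs); an optional allowance exists for the anchor only.
The classifier cannot distinguish genuinely intermediate 3' ends (CCUC,
CCU) from sequencing truncation; it classifies literally.

## Toeprint statistics

The lane statistic is 100·T/(T+RT), computed ratio-first so that it is
bounded in [0, 100] to the last ulp; lanes with T+RT = 0 are rejected as
unquantifiable. Normalization divides each lane's percentage by the
within-mRNA mean of the reference condition (monophosphorylated mRNA by
default) and multiplies by 100, making the reference mean exactly 100.
Condition summaries use the sample SD (n−1), reported as NA for a single
lane. No background subtraction is applied. A Welch/Student t-test
wrapper around scipy is provided as a convenience for condition
comparisons.

## Synthetic-data generator

The generator emulates the statistical structure of an archaeal
transcriptome annotation, not its sequence composition (no codon-usage
or GC-skew model). Study-condition defaults:

- leader-class proportions 0.73/0.11/0.16 (leaderless/short/leadered);
- SD-positive rates per motif and stratum: GGAGG 5.3% of leadered
  proximal and 8.2% of distal cistrons; UGAGG 4.1% and 5.3%;
- positional-decoy rate 0.25 per motif and stratum;
- junction-read variant mixture 27:1:3:1 over CCUCC/CCUCA/CCUC/CCU with
  32 reads, allocated exactly;
- toeprint condition means (T, RT) in arbitrary units: triphosphate
  (60, 40), monophosphate (40, 60), hydroxyl (20, 80); noise SD 5; three
  replicates per condition, matching the usual scale of independent
  toeprinting experiments.

Choices where the design was open, fixed once: CDS lengths are uniform
over 20–60 codons (desk scale; long enough that the ±30-nt
alternative-start span always lies inside the gene region); leadered
5'UTRs are capped at 50 nt; each alternative-start planting occurs with
probability 0.2 among SD-positive genes and places an in-frame
ATG/GTG/TTG at ±3/6/9 nt with the motif positioned to pass relative to
that start; 80% of annotated starts are ATG and 20% GTG. Truncated
Gaussian noise for toeprint intensities is implemented as clipping at 0,
which coincides with the untruncated draw whenever the noise SD is small
relative to the mean, and `noise_sd=0` reproduces the configured means
exactly.

Every gene region is composed as [pad | 30-nt window | CDS] and
rejection-sampled until it realizes exactly the planted truth: the
window contains precisely the planted motif occurrences (none for
background genes), and no in-frame start codon other than the annotated
one (plus any planted alternative) exists within the enumeration span.
Decoy offsets are drawn from [−30, −19] ∪ [−8, −5], i.e. outside the
rule window relative to every start the scan can enumerate. Intergenic
spacers of ≥ 10 nt plus the controlled window keep distal-cistron
windows inside composed sequence. A resampling cap (500 attempts per
gene) converts infeasible configurations into an explicit error.

With `exact_counts=True` (the default), class labels and per-motif
positive/decoy assignments are allocated by largest-remainder integer
counts and shuffled, so stratum compositions are exact and the benchmark
percentages are determined by pipeline correctness rather than sampling
noise; with `exact_counts=False` assignments are Bernoulli/multinomial
draws. A single root seed is split into per-component substreams
(genome, junctions, toeprint) so adding or reconfiguring one generator
does not perturb the others; a fixed seed reproduces all output files
byte-identically.

What passing the synthetic benchmarks shows: the scanner applies the
positional rule exactly (decoys are never counted, plantings always
are), the classifier tiles lengths correctly, the junction caller
honours longest-match precedence, and the statistics are computed as
specified. What it does not show: robustness to annotation errors,
overlapping genes, sequencing noise, compositional biases or TSS-calling
uncertainty in real transcriptome data — the generator's background is
deliberately clean in the scanned regions.

## Problem sizes

The validation fixtures use 169 single-gene transcription units (the
leadered-proximal stratum), 879 two-gene units (the distal stratum),
1,000 single-gene units (the leader partition), 32 junction reads and
9 toeprint lanes; the whole suite and the reproduction script each run
in a few seconds on one CPU.

## Known limitations

- Operon structures are linear, non-overlapping and single-contig in
  the generator; the analysis itself handles multi-contig input but
  assumes gene models do not straddle contig ends.
- The SD scan is exact-match only; degenerate or weighted motifs are
  out of scope.
- The duplex score counts contiguous pairs only; bulges and internal
  loops are not modelled.
- GenBank flat files are not parsed (FASTA + TSV/GFF3 are the input
  formats), and transcription units are inputs, not predictions.
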