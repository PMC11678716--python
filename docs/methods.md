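# Methods

This note records the models implemented by `loopblock`, the parameter
choices that matter, what the synthetic generator does and does not
emulate, and the numerical conventions the package commits to.

## Interval model and distance stratification

All coordinates are 0-based half-open (BED convention); GTF input
(1-based inclusive) is converted on read.  The distance between two
intervals is the **edge-to-edge gap**: 0 when they overlap *or abut*,
otherwise the number of bases strictly between them.  Bait–target
distance is measured edge to edge rather than midpoint to midpoint; for
the region sizes involved (hundreds of bases) against strata 10 kb wide
the difference is marginal, and the edge convention matches the
windowing semantics of standard interval tools.

Distance stratification is incremental: given strictly increasing bounds
(default 0, 10, 20, 30, 40, 50 kb), a pair is assigned to the *smallest*
bound whose window admits it, and pairs beyond the largest bound are
dropped.  Two properties follow by construction and are enforced by
tests: the strata are pairwise disjoint, and their union equals a single
window join at the largest bound.  "Direct overlap" anywhere in the
package means ≥ 1 shared base; no reciprocal-overlap requirement is
imposed.  Output ordering is always (chrom, start, end, name), so runs
are byte-reproducible.

## Peak anchors and location classes

A peak is anchored at its summit (narrowPeak column 10) when present,
else at its midpoint.  The anchor is tested against five mutually
exclusive categories in priority order:

| category | definition |
| --- | --- |
| promoter | −1000..+10 bp of the TSS (strand-oriented), or 5′ UTR |
| distal_enhancer | −2000..−1000 bp of the TSS, 3′ UTR, or ≤ 1 kb past the TES |
| other | exonic |
| intron | inside the gene body, not exonic |
| intergenic | none of the above |

The downstream extent (1 kb past the TES) is a package choice; the
class definitions themselves follow the conventional promoter/enhancer
bands above.  When several genes match, the highest-priority category
wins and ties are broken by distance to the TSS then gene id, making the
call independent of gene-file order.  Multi-transcript genes collapse to
the union of exons with the most upstream TSS.  Peak-to-gene association
reports the nearest TSS within 50 kb (the largest loop stratum), with
equidistant ties reported jointly.

## Loop candidates

A bait counts as bound when ≥ 1 anchor-TF peak overlaps it by ≥ 1 base,
once, regardless of peak multiplicity; likewise targets with partner-TF
peaks.  Candidates are the stratified (bound bait, bound target) pairs,
expanded cartesianly when several peaks cover one region, so every
(peak, peak) combination supporting a loop is retained.  Bound fractions
are raw region counts over catalogue size; no enrichment statistic is
attached to them.

## PSAM scanning

The affinity model is a max-normalised position × base matrix: every
position's best base has weight 1, so the consensus window scores
exactly 1 and every score is a *relative* affinity in (0, 1].  A window
score is the product of per-position weights — the standard
mononucleotide approximation; dinucleotide and shape terms are out of
scope, as is model fitting (any model file honouring the contract is
accepted, including externally trained ones).  Scanning evaluates every
offset on both strands, takes the per-offset maximum of forward and
reverse-complement scores (ties to +), and keeps the top-k windows
(default k = 10) ranked by score, then smaller offset.  Windows
containing N are masked and never ranked.  The per-region
`summary_score` is the mean of the top-k window scores; it is the
quantity compared across strata (two-sided rank-sum per pair, BH
adjustment within the comparison family, raw p-values retained) and
correlated with summit heights (Pearson, n ≥ 3, zero-variance inputs
rejected rather than silently returning NaN).

## Accessibility classes

Pseudo-bulk ATAC regions carry one aggregate count per condition.  The
class rule is `L = log2((mut + pc)/(wt + pc))`, gain if `L ≥ t`, loss if
`L ≤ −t`, else noDA, with defaults `t = 1` (two-fold) and `pc = 1`.
This transparent rule stands in for whatever statistics produced the
published pseudo-bulk clusters, which are not described alongside the
data; pre-labelled tables (a `klass` column) are therefore accepted
directly and bypass the rule.  Coverage profiling reuses the interval
engine's union coverage, so overlapping subject intervals are never
double-counted.

## Statistics

The two-sample Wilcoxon rank-sum test is exact (full permutation
distribution) when the combined sample size is ≤ 12 and the pooled data
are tie-free; otherwise the normal approximation with tie and continuity
corrections is used.  Ties always force the approximation — this keeps
the p-value well defined and the runtime bounded, and for identical
samples the corrected approximation still returns p = 1.  The reported
statistic is the rank sum of the first sample.  Two-sided exact p-values
follow the 2·min(P≤, P≥) convention, verified in tests against full
enumeration of all splits up to n₁+n₂ = 10.  Fisher's exact test is
two-sided by summing hypergeometric probabilities no larger than the
observed table's.  Benjamini–Hochberg is the standard step-up
adjustment; note that BH is *not* idempotent for arbitrary inputs (a
single small p among near-equal large ones is re-inflated on a second
pass), only for plateau-valued adjusted vectors.

## Synthetic bundles

The generator plants every signal the pipeline is meant to recover, at
the structural scale of the real inputs: 600 baits, 20,000 targets, 10%
bound on each side (planted deterministically at `round(n·fraction)` for
exact control), strata 0–50 kb, and a consensus-based affinity model
(12-mer, mismatch penalty 0.3).

*Geometry.*  Each bound bait occupies its own loop block: the bait plus
its bound targets, the first placed at a gap inside the bait's assigned
stratum (assigned round-robin so all strata are populated) and the rest
no closer.  Blocks are spaced further apart than the largest bound, so a
window join finds exactly the planted pairs; the ground-truth pair list
is nevertheless computed by an independent brute-force pass over all
bound regions, so recovery tests compare two independent routes.  The
default chromosome size is 2 × 5 Mb — large enough to hold 60 disjoint
50 kb loop neighbourhoods plus a free zone where decoy regions and genes
live, more than a window width from any planted peak.  The tiny test
profile (1 × 1 Mb, 20 baits, 200 targets, higher bound fractions) keeps
the same disjoint-block geometry.

*Affinity decay.*  Each bound bait region carries k = 10 planted sites,
each a consensus copy degraded by an integer number of mismatches
(score = penalty^m, m ≤ 3); the mismatch multiset per stratum is chosen
deterministically so the mean planted score is closest to the configured
decay sequence (0.90, 0.55, 0.35, 0.20, 0.12, 0.06).  With a 12-bp
consensus, an i.i.d. uniform background of a few hundred windows rarely
reaches 3 mismatches, so the planted sites dominate the top-k and
per-stratum medians separate cleanly.  Summit heights are
`50 + 400·(mean site score) + N(0, 60)` clipped at 1 — a positive,
deliberately noisy coupling, so the summit–affinity correlation is a
tunable effect size rather than an artefact.

*ATAC and histones.*  Every bound region gets an enclosing ATAC region
whose class is drawn from the configured proportions (0.70/0.15/0.15);
counts are then drawn so the classification rule reproduces the intended
class, and the recorded truth label *is* the rule's output on the
written integers, making label recovery exact by construction.  Histone
marks cover each bound region as active with probability
`open_fraction = 0.9`, else repressed — the "mostly open chromatin"
regime.

*What the generator does not emulate:* real genome base composition,
peak-width and signal distributions, correlated replicate noise,
read-level data (no FASTQ/BAM), or biologically structured gene
annotation.  Passing recovery tests therefore demonstrates correctness
of the pipeline's logic under known truth, not performance on real
embryonic data.

## Numerical and degenerate-input conventions

- Validation failures name the offending record and (for files) the
  line number; empty bait/target catalogues are configuration errors,
  while empty *bound* sets flow through and yield zero candidates.
- Affinity models with per-position maxima ≠ 1 are renormalised with a
  warning; non-positive weights are rejected.
- Groups with < 2 members are excluded from rank-sum comparisons with a
  warning; correlations require n ≥ 3 and non-zero variance.
- Peaks without a summit height are written to narrowPeak with
  signalValue −1, and negative signal values read back as absent, so
  round-trip I/O is lossless.
- All randomness flows from one `numpy` generator seeded per run; no
  timestamps are written, so identical configurations produce
  byte-identical output trees.

## Problem sizes used in the checks

The bundled verification runs use the default-scale bundle (2 × 5 Mb,
600 baits, 20,000 targets, 3,000 ATAC regions) for end-to-end recovery —
a few seconds on one core — and randomized instances of up to 200
intervals (1,000 of them) against brute-force oracles for the interval
engine, 100 regions up to 1 kb against exhaustive enumeration for the
scanner, and 10,000 null replicates for rank-sum calibration.

## Known limitations

- Candidate loops are built from proximity between bound baits and bound
  targets, not from per-record contact identities; a catalogue in which
  a specific bait–target pairing matters beyond distance is flattened to
  its interval geometry.
- Only mononucleotide PSAMs, only the N ambiguity code.
- The ATAC rule is a stand-in for unpublished clustering statistics (see
  above); conclusions about accessibility classes on real data should
  use the pre-labelled path.
- Gene-body classification ignores UTRs unless they are present in the
  annotation; none are inferred from CDS.
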