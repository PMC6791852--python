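# Methods

This note documents the models, conventions, parameter choices and known
limitations of crckit. It is the place where genuinely open design
decisions are recorded; empirical claims here are limited to what the
test suite and `scripts/acceptance.py` themselves compute.

## Coordinates and interval algebra

All internal coordinates are 0-based, half-open (BED convention);
1-based inputs (GTF, refFlat-style tables) are shifted on read. Overlap
always means at least one shared base, so bookended intervals do not
overlap and are not coalesced by `merge_union`. Chromosome-name dialects
("chr1" vs "1") are normalized to the attached assembly's spelling.
Transcripts are reduced to (TSS, strand, gene name); genes with several
TSSs keep all transcripts, and gene-level collapses take the transcript
with the larger assigned signal at the point of use.

## Read-density model

A fragment track stores read 5′ placements and a total mapped-read
count. Every read is extended to a fixed fragment length (default 200 bp)
in its strand direction; unstranded placements are treated as plus-strand
and logged once per track. Region occupancy (AUC) is the number of
extended reads overlapping the region divided by millions of mapped
reads (rpm) — read-level counting, so a read contributes once per region
regardless of the bases it covers. Gene-level occupancy sums the
full-extent AUC of landscape elements overlapping the ±50 kb TSS window;
elements are not clipped to the window, which matches assigning
occupancy per element rather than per base.

Sample similarity over the landscape normalizes each sample's region-AUC
vector to its median, then uses Pearson correlation and average-linkage
clustering on 1 − r. A zero median is treated as a degenerate track and
refused with the track named.

Fold changes everywhere are `log2((a + c)/(b + c))` with pseudocount
c = 1 rpm (configurable); replicates are combined by arithmetic mean of
AUC before the ratio. Rank orders break ties by gene name so output is
deterministic.

Binned profiles (100 genes per bin) report the bin mean with a 95%
bootstrap CI of the mean: 1000 resamples with replacement, percentile
bounds, seeded. The percentile bootstrap at n = 100 is very slightly
anticonservative; the acceptance run measures its realized coverage
(the 93–97% band check).

## Motif scanning

Scanning is FIMO-style. Frequencies are smoothed with a
background-weighted pseudocount (0.1): `p' = (p + 0.1·bg)/(1.1)`; scores
are log2 odds against a 0-order background estimated from the scanned
sequence and symmetrized with the complement so one null distribution is
valid on both strands (uniform fallback). Column scores are discretized
to 1e-3 bits; the scanner and the exact p-value table share the same
integer scores, so the dynamic-programming survival function is exact
for every score the scanner can emit (verified against exhaustive
enumeration for widths ≤ 6). `N` bases contribute zero score, and any
window containing `N` is excluded from hits.

Per motif, BH correction runs over every scanned offset on both strands;
occurrences with q < 1e-5 are reported. Overlapping same-motif hits are
all retained — downstream circuitry counts regions, not hits. The binary
occupancy matrix extends hits by 50 bp, merges across TFs into atomic
regions, and clusters TFs by Pearson correlation of their binary columns
(average linkage on 1 − r). Identical constant columns are defined to
correlate perfectly; a constant-vs-varying pair is defined as
uncorrelated.

## Circuitry

Candidate CRC TFs must be actively expressed, have a motif in the
database, be regulated by a distal element (a landscape region within
±50 kb of a TSS that does not overlap that TSS's ±1 kb promoter window),
and have at least one PPI edge with combined score > 0.400 to another
panel TF. "Any distal element" is used rather than requiring a
super-enhancer; elements are unstitched.

MCL runs on the column-stochastic PPI adjacency with unit self-loops:
expansion (matrix square), inflation (entrywise power 2.0, renormalize),
pruning below 1e-12, to a 1e-6 residual; clusters are connected
components of the converged support. Non-convergence raises with the
residual rather than returning a partial result.

A regulatory edge is one (TF, landscape region) pair where the TF has a
q-passing hit inside an ATAC peak contained in the region — one edge per
region regardless of hit count, preventing motif-count inflation. IN/OUT
regulatory connectivity counts unique partner TFs (self-binding counts
on both sides), so panel sums balance and each count is bounded by the
panel size. BRD4 OUT degree sums edge-region BRD4 AUC per condition;
the ranking statistic is the mean of per-edge log2 fold changes (the
ratio-of-sums variant is reported alongside), with a CI from resampling
edges with replacement (1000 draws, seeded). Edgeless TFs are excluded
from the ranking and flagged.

The one-sided Wilcoxon rank-sum comparison uses midranks and enumerates
the exact null over all C(n+m, n) assignments when n + m ≤ 16, else the
tie-corrected normal approximation.

## Target analysis

High-confidence TF peaks: merged engineered-replicate peaks kept iff
overlapped by a peak in *every* engineered replicate and by none in any
parental replicate ("absent" = no single shared base). The ATAC split is
an exhaustive, disjoint partition by ≥ 1-base overlap with any ATAC
sample. Per-peak signal is `max(0, chip_auc − input_auc)` in rpm (depth
scaling via rpm is the only normalization between chip and input).
Promoter and distal components follow the ±1 kb / ±50 kb windows; a
distal peak is dropped for a gene if it overlaps any *other* gene's ±1 kb
promoter window (a bare 1-bp TSS exclusion would be vacuous). A peak may
serve several genes' windows. Only genes with positive total are ranked.

Preranked enrichment is the classic unweighted KS running sum (weighted
mode available); the leading edge is the members at or before the
extremum (after it for negative ES). The permutation p is one-tailed
toward positive enrichment over uniformly drawn same-size gene sets with
the +1 correction, so it is uniform under the null and depletion
surfaces as p near 1. The expression contrast is a Welch two-sample
t-test (two-tailed) with box-plot quartiles returned; the degenerate
all-equal case is defined as t = 0, p = 1. Top-target list size defaults
to 100.

## Screen statistics

Counts are scaled to CPM per column; reagent log2 fold changes use
pseudocount 1 against the reference library (zero-reference reagents are
kept — dropout is the signal of interest). Z-scores standardize against
all reagents in the library (population SD); per-gene Q1/Q3 use linear
interpolation. RSA ranks reagents library-wide in the direction of
interest (midranks for ties, rounded to integers for the hypergeometric
draws) and reports `log10(min_j P[X ≥ j])` over the gene's j best ranks.
The min over j is not multiplicity-corrected, so it is an aggressive
ranking score rather than a calibrated p-value — measured empirically,
its null CDF deviates from uniform by ~0.3 at 5 reagents/gene. The
iterative threshold variant of the published algorithm is not
implemented; instead `rsa_empirical_pvalues` calibrates the statistic
against a label-permutation null (rank among permuted statistics per
reagent-set size), which is uniform under the null by construction and
is what the calibration check exercises.

## Synthetic data: what it emulates and what it does not

The generator is a pure function of (config, seed) and emits every input
format the pipeline reads. Defaults are the study conditions used
throughout the tests: one 5 Mb chromosome, 200 non-overlapping genes
(~15% inactive), a 20-TF panel, 1000 ATAC peaks placed 2–45 kb from
active TSSs, driver TF with 200 binding sites gaining 2× BRD4 in the
`lscp` condition, 30 sites per non-driver TF (disjoint assignments so
ground-truth edges are clean), 1e6 reads per track, log2 expression
noise SD 0.25, and a screen of 500 genes × 5 reagents with 25 planted
dropouts (log2fc −1.5) and 10 planted enrichments.

Choices worth calling out:

- **Motif widths default to 16–18.** A consensus site's exact p-value is
  bounded below by 4^-w, and BH over the default scan universe (~4×10^5
  offsets) needs p·N/k < 1e-5; widths below ~16 cannot clear that for a
  30-site TF, so narrower defaults would make planted sites undetectable
  at the pipeline's own q cutoff. Widths are configurable.
- **Region read counts are Poisson at the region level** (not per-base
  Markov reads): adequate for AUC-level statistics and fast. Reads place
  fragment midpoints uniformly in the region; 15% of reads are uniform
  genomic background, and the background absorbs planted extra signal so
  total depth — hence rpm normalization — is identical across
  conditions. Residual background overlap still dilutes the planted
  per-edge fold change slightly (the acceptance run measures ≈ 0.91
  rather than 1.0 for a 2× gain).
- **Driver sites are concentrated on a contiguous block of genes.**
  ±50 kb windows span several 25 kb gene slots, so scattering 200 sites
  genome-wide would make nearly every active gene a "target" and leave
  no contrast group.
- **Motif sites are implanted as consensus sequences** (not PWM draws),
  making scanner recovery deterministic at high information content.
- **Expression** couples log2 FPKM linearly to log2(promoter+proximal
  BRD4 rpm + 1) with the coefficient chosen per dataset so active genes
  stay ≥ 10 FPKM even at −4 SD of noise; inactive genes draw background
  FPKM in [0.2, 5].
- **PPI**: two planted cliques over the panel (within-cluster edge
  probability 0.9 at score 0.7, between 0.05 at 0.45), every TF
  guaranteed one within-cluster edge.
- **Screen counts** are negative-binomial (mean 500, dispersion 0.15);
  timepoint t scales planted-gene means by 2^(t·effect).

Not emulated: fragment-size and GC biases, duplicate reads, copy-number
effects, motif degeneracy/cooperative binding, correlated replicate
structure, and cell-population heterogeneity. Passing tests therefore
demonstrate correctness of the computations and recoverability of
planted effects at realistic desk-scale signal-to-noise — not robustness
to every artifact of real ChIP/ATAC/screen data.

## Orchestration and determinism

The pipeline stages (landscape → circuitry → targets; screen
independent) run from one flat config; all randomness flows from a
single seed, floating-point outputs are written at 6 significant digits
with fully specified sort orders, and the manifest records parameters
plus SHA-256 checksums of inputs and outputs, so identical config and
inputs give byte-identical numeric outputs. Exit codes: 0 success,
2 validation error, 3 dependency error.

Problem sizes in the default test and acceptance runs (20 seeded
datasets at the default config, 10 MCL seeds, 20 screen seeds, 1000
bootstrap bins, 2000 calibration shuffles) were chosen to give stable
pass/fail behavior at desk scale on a single CPU.

## Known limitations

- The exact-p DP assumes a 0-order background; higher-order backgrounds
  are out of scope.
- Gene-level AUC uses the element-sum reading of gene assignment (all
  landscape elements within ±50 kb); window-clipped variants will differ
  at elements straddling the window edge.
- The ENCODE-blacklist-style exclusion is exposed as an optional region
  subtraction on peak sets, not applied to reads.
- RSA's analytic p is intentionally the aggressive min-form statistic;
  use the empirical calibration when a uniform null is required.
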