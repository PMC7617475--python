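# Methods

`tikp` analyzes time-resolved transcription-factor induction
experiments: a nascent-RNA (chromatin-associated) count time course, an
accessibility/acetylation peak time course over the first hours of
induction, a regulatory-element landscape, and allele-level smFISH
burst tables. Every stage can also be driven end-to-end on synthetic
inputs with known ground truth, which is how the package verifies
itself.

## Differential count testing

All differential calls (genes between timepoints, peak accessibility,
element acetylation) use one engine: a per-feature negative-binomial
Wald test on median-of-ratios-normalized counts.

- Size factors are DESeq-style median-of-ratios; the geometric-mean
  reference excludes features with a zero in any sample. The estimator
  assumes a majority of features is invariant across samples; inputs
  violating that (for example a simulation where most genes respond)
  produce coherent per-sample distortions, which is why the synthetic
  designs always carry a stable background majority.
- The NB variance is `v = m + alpha * m^2`. Dispersion `alpha` is
  estimated per feature by method of moments, pooled across the two
  conditions, then shrunk halfway toward the across-feature median and
  floored at 1e-8. The shrinkage is load-bearing with duplicate
  libraries: the raw moment estimate has one or two degrees of freedom
  and its lower tail (`alpha_hat -> 0`) collapses the Wald standard
  error, which would flood the null with false calls; pulling every
  estimate halfway to the experiment-wide median bounds the statistic
  while leaving real per-feature overdispersion visible.
- The Wald statistic is `log2FC / SE` with the delta-method SE of a
  log2 NB mean (a 0.5 pseudocount stabilizes empty features), two-sided
  normal p-values, and Benjamini-Hochberg adjustment across features.
- Gene calls use padj < 0.01 and |log2FC| > 1. Peak accessibility
  classes: `decreased`/`increased` at padj < 0.01 with the matching
  sign, `unchanged` at padj > 0.05 and |log2FC| <= 0.2, `other`
  otherwise; the four classes partition every peak set. Element
  acetylation loss/gain uses padj < 0.01 and fold change 1.5.

Calibration and sensitivity are measured, not assumed: on a 2,000-peak
null simulation the decreased+increased call rate is well under 2% at
padj < 0.01, and 20% planted four-fold losses are recovered at ~99%
(`tikp.evaluation.accessibility_calibration`).

## Kinetic clustering and t-half

Differential genes are clustered on the *shape* of their response:
per-gene replicate-averaged `log2(normalized + 1)` trajectories are
min-max scaled to [0, 1] and K-means is run with `k = 5` by default
(25 restarts, fixed seed). Constant trajectories have no defined shape
and are dropped with a warning.

Each cluster's summary trajectory is the min-max-scaled **mean log
trajectory** of its members (scale after averaging). For multiplicative
kinetics — every member is `base_i * v(t)` — the mean log trajectory is
`const + log2 v(t)`, so scaling it recovers the shared shape exactly.
Averaging the per-gene scaled curves instead is biased: each gene's
noisy min and max compress its plateau and inflate mid-course values,
which we measured as a ~25% error on a 3 h half-response time before
switching conventions.

The half-response time (t-half) of a cluster is the first time its
summary trajectory crosses the midpoint of its range, linearly
interpolated between flanking timepoints; it is equivariant under
affine rescaling of the time axis.

Clusters are relabeled by behavior. A cluster is retained only if its
summary trajectory is monotone in time: |Spearman rho| >= 0.8,
computed after merging trajectory values into tie groups (adjacent
sorted values within 0.05 of each other share a rank). The tie-merge
exists because rank correlation treats tiny noise wiggles on a plateau
as full rank reversals; a slow response that is flat for the first
third of the course would otherwise be discarded as non-monotonic.
Retained clusters are split by the sign of their net change and ranked
by t-half: the fastest repressed cluster is `fast_repressed`, the rest
`slow_repressed`, and likewise `activated` / `slow_activated`;
non-monotone clusters are labeled `removed_non_monotonic` and excluded
downstream.

## Motif statistic

The motif count of a peak is the number of occurrences of the core
recognition 4-mers GGAA, TTCC, GGGA, TCCC, scanning every start
position so overlapping matches count (for example `GGGAA` contains
both GGGA and GGAA); `N` never matches. Density is count divided by
peak length in bp. The 4-mer set is closed under reverse complement,
so total counts are strand-symmetric; only the per-motif split depends
on strand. Class-wise density comparisons use the two-sided Wilcoxon
rank-sum test with midranks. Correctness is checked against a naive
position-by-position oracle by property-based fuzzing and on 1,000
random 1-kb sequences.

## Metaprofiles and summit offsets

Metaprofiles average a binned coverage track over windows
`[center - flank, center + flank)` split into uniform bins (defaults
±1 kb, 100 bins). Window values are two-bp midpoints
`(track[c+o] + track[c+o+1]) / 2`, which makes the profile of a signal
point-symmetric about a center exactly symmetric despite the half-open
window; the operator is linear in the track. Windows that would leave
the chromosome are dropped (or clipped on request). Peaks are
unstranded, so no strand flipping is applied. Summit centering reports,
per accessibility class, the median |summit − peak midpoint| over
TF-binding summits falling inside peaks of that class.

## Regulatory elements

An accessible site overlapping an H3K27ac peak is an active element:
`active_promoter` if its midpoint lies within ±1 kb of any TSS
(conventional choice; the window is a parameter and locked by boundary
tests), else `active_enhancer`; unmarked sites stay unclassified. All
TSS windows are closed intervals `[TSS - w, TSS + w]`; coordinates are
0-based half-open BED throughout and midpoints are `(start+end)//2`.

Super-enhancers follow the standard stitch-and-elbow recipe: enhancers
within 12.5 kb are merged, stitched regions are ranked by total
signal, both axes are scaled to [0, 1], and the cutoff is where the
tangent of the (convex) rank-signal curve reaches slope 1 — found as
the minimizer of (scaled signal − scaled rank). Regions strictly above
the cutoff signal are SEs. All-equal signals have no elbow and yield no
SEs. Stitching is idempotent.

Enhancer density per gene counts active enhancers within ±20 kb of the
TSS, compared between the fast-repressed class and every other class
by rank-sum tests with Bonferroni correction. SE association is the
fraction of genes per class with an SE within ±50 kb, plus a seeded
random-gene control class sized like the fast-repressed class. Change
fractions report, per class, the fraction of nearby enhancer elements
significantly losing or gaining acetylation, again with a seeded
random-gene control.

Enhancer-gene links require both Pearson activity correlation >= 0.5
across at least five shared contexts and contact frequency above a
threshold, for candidates within ±500 kb. When no explicit contact
threshold is given it is the 95th percentile of contact among
distance-matched candidate pairs (five quantile bins of pair
distance). Zero-variance activity vectors make the correlation
undefined; those pairs are skipped and flagged. The link decision is
monotone: raising either threshold never adds links.

## Burst statistics

Burst fraction is bursting alleles over total alleles (two per cell).
Burst size is the sum of the spot's maximum intensity and mean radius —
deliberately unit-heterogeneous, reported exactly as defined upstream
(CellProfiler feature names are kept as column names; image
segmentation is out of scope).

Fisher's exact test is implemented in-package: with margins fixed, the
two-sided p-value sums hypergeometric probabilities of all tables whose
probability does not exceed the observed table's (probability-ordering
convention). Factorials are evaluated with log-gamma, so counts in the
thousands are exact to float precision; a log-space tie tolerance of
1e-9 absorbs round-off on genuine ties without merging distinct
probabilities at the table sizes in scope. The implementation matches
an exact-rational enumeration oracle within 1e-12 on every 2x2 table
with total count <= 30, and scipy's implementation at larger counts.

Condition comparison runs Fisher on the burst/non-burst 2x2 and an
unpaired two-sided Student's t-test with pooled variance on burst sizes
(Welch by flag). Modulation at level alpha (default 0.01) is
`frequency` if only the Fisher test rejects, `size` if only the size
test does, `both` or `none` otherwise; with fewer than two bursts in a
condition the size test is undefined and reported as NaN
(non-significant). Measured type-I error of the Fisher route under the
null telegraph simulation at 700 cells is ~0.05, and detection of the
designed frequency-only and size-only scenarios exceeds 95%.

The two-state telegraph model's stationary active probability is
`k_on / (k_on + k_off)`; a Gillespie dwell-time path simulator is
provided for cross-checking the closed form but snapshot generation
uses the stationary Bernoulli directly, since fixed-time smFISH images
observe the stationary state.

## Synthetic-data generator

The generator encodes the study conditions once; its defaults are not
fitting knobs.

- **Time course**: 9 timepoints (0, 0.5, 1, 2, 4, 8, 12, 16, 24 h),
  duplicate libraries, NB dispersion 0.05 shared across genes (keeps
  recovery interpretable), log-normal baseline expression (ln-mean 6.2,
  ln-sd 1.0, i.e. ~500 counts — a modeling choice; nothing in the
  emulated design prescribes a baseline distribution). Class
  proportions: 8% fast-repressed, 12% slow-repressed, 5% activated, 8%
  slow-activated, 3% non-monotonic, 64% non-responding. The stable
  majority reflects a realistic transcriptome for induction of a single
  factor and is required by median-of-ratios normalization.
- **Kinetic family**: repressed genes follow a delayed-onset
  exponential `mu(t) = base * (f + (1-f) * 2^(-(max(0, t-d))/tau))`
  with floor `f = 0.125` (8-fold full response), mirrored upward for
  activated genes. Because the analysis scales log expression, the
  half-response time is the geometric-midpoint crossing; the onset
  delay `d = max(0, (4*t_half - T)/3)` and `tau` (solved numerically)
  place that crossing exactly at the design t-half of the min-max-
  scaled noiseless log trajectory over the sampled window. The delay is
  unavoidable: a pure exponential scaled over a finite window cannot
  cross its midpoint later than ~T/2, and two design classes (12 h,
  14.5 h) sit at or beyond that bound for a 24 h course. Design
  t-halves: 45 min, 12 h, 3 h, 14.5 h. The non-monotonic class rises
  ~2.5-fold to a mid-course peak and returns.
- **Peaks**: non-overlapping 400-bp peaks on a 10-Mb toy chromosome
  (`chrS`), genomic categories CTCF/promoter/intragenic/intergenic at
  8/25/37/30%. Motif counts are overdispersed around 6 per peak; the
  probability of true accessibility loss is logistic in motif density
  (motifs per 100 bp) with slope 1.0 log-odds, intercept calibrated so
  the marginal decreased fraction is 12.7% (3.4% increased) — the
  design targets this generator emulates. CTCF-site peaks are forced
  unchanged. Changed peaks move log-linearly to a 4-fold
  accessibility change, completing it at 2 h; enhancer peaks change
  `enhancer_speedup = 2`-fold faster, and their acetylation floor is
  deeper (5-fold vs 2-fold at promoters). TF summits sit at decreased-
  peak midpoints (sd 15 bp) and uniformly inside other peaks.
- **Landscape**: TSSs on a 100-kb grid (±20 kb jitter) so gene windows
  do not bleed into neighbors. Fast-repressed genes get Poisson(4)
  nearby enhancers vs Poisson(2) elsewhere; their enhancers lose
  acetylation with probability 0.65 vs 0.20 (the designed ~2x target
  against a random-gene control), and 26% vs 8% of genes receive an SE
  (five extra enhancers at ten-fold signal). Activities over eight
  pseudo-tissue contexts correlate for true enhancer-gene pairs;
  contact decays exponentially with distance (scale 100 kb) with a
  five-fold boost for true pairs.
- **smFISH**: two alleles per cell, burst states drawn from the
  stationary telegraph probability; uninduced `k_on = 1/h`,
  `k_off = 4/h` (burst fraction 0.2), induced `k_on` halved with the
  size distribution untouched — frequency, not size, modulation.
  Spot features are clipped normals around intensity 10 and radius 2.

What the generator does **not** emulate: read-level data, fragment-size
structure, sequence-dependent peak calling, gene-length or GC effects,
per-gene dispersion variation, cell-cycle or batch structure,
correlated replicates, and image segmentation noise. Passing the
verification suite therefore demonstrates that the estimators recover
the statistical structure they target at realistic effect sizes and
depths — not that they are robust to every artifact of real libraries.

## Reproducibility and numerics

All randomness flows from one integer seed through named substreams
(CRC32 of the stage name mixed into a `SeedSequence`), so stages are
independently reproducible and no code touches global random state.
Two same-seed pipeline runs are byte-identical file by file; floats in
reports are rounded to six decimals to keep bytes stable across
platforms. Verification experiments run at desk scale on one CPU:
2,000-5,000 genes, 2,000 peaks, ~1,500-gene landscapes, 700-cell FISH
tables, 100-1,000 repeats for rate estimates; the full suite runs in
under a minute and the acceptance script in well under a minute.

## Known limitations

- The NB Wald test with moment dispersion is a deliberately simple
  stand-in for a full GLM engine; it has no dispersion trend fitting,
  no outlier refitting, and its null calibration relies on the
  dispersion shrinkage described above.
- t-half is defined on the cluster summary trajectory, not per gene;
  within-cluster kinetic heterogeneity is summarized away.
- The monotonicity filter's tie tolerance (0.05 on scaled units) is a
  heuristic for plateau noise; trajectories with genuine sub-5%
  structure would be smoothed over.
- Enhancer-gene linking defaults (correlation 0.5, ±500 kb, 95th
  percentile distance-matched contact) are explicit stand-ins where the
  underlying study used external resources not reproduced here.
- Super-enhancer calling assumes a convex rank-signal curve; heavy-
  tailed but elbow-free signal distributions will call a cutoff wherever
  the tangent condition lands.
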