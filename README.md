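# tikp — TF-induction kinetics pipeline

`tikp` is a Python toolkit for time-resolved transcription-factor
induction studies in regulatory genomics. When a repressive TF is
acutely switched on (for example by tamoxifen-driven nuclear entry of
an ER-fusion construct), the first hours of the response carry the
mechanism: which genes respond and how fast, which accessible-chromatin
sites collapse and whether the TF's sequence motif predicts them, how
promoters and enhancers differ in the speed and depth of acetylation
loss, and whether transcription shuts down by bursting less often or by
bursting smaller. `tikp` implements that analysis chain for people who
have count matrices, peak tables and smFISH spot tables — and, because
the real deposited datasets are large, it ships a seeded synthetic-data
generator that reproduces the statistical structure of such a study so
every stage is verifiable offline against known ground truth.

## What it computes

- **Kinetic classification** (`tikp.kinetics`). Median-of-ratios
  normalization; per-gene negative-binomial Wald tests between
  timepoints (padj < 0.01, |log2FC| > 1, Benjamini–Hochberg); K-means
  clustering of min–max-scaled log trajectories; removal of
  non-monotonic clusters (|Spearman ρ| < 0.8 on the cluster summary
  trajectory); and the half-response time *t*½ — the first crossing of
  the midpoint of the scaled summary trajectory, linearly interpolated.
- **Differential accessibility** (`tikp.accessibility`). Four-way peak
  classification (decreased / increased / unchanged / other) with the
  same NB machinery; motif counts of the core 4-mers GGAA, TTCC, GGGA,
  TCCC with overlapping matches and density = count / peak length;
  rank-sum comparison of densities between classes; signal metaprofiles
  ±1 kb around peak centers; and summit-to-midpoint offset summaries.
- **Regulatory elements** (`tikp.enhancers`). Active promoter/enhancer
  classification from H3K27ac overlap and TSS distance; ROSE-style
  super-enhancer calling (12.5 kb stitching, rank-elbow cutoff);
  enhancer density within ±20 kb of the TSS per gene class with
  pairwise rank-sum tests; SE association within ±50 kb; acetylation
  loss/gain fractions (padj < 0.01, FC > 1.5) with a seeded random-gene
  control; and enhancer–gene linking by activity correlation
  (Pearson r ≥ 0.5) plus contact frequency.
- **Transcriptional bursting** (`tikp.bursting`). Burst fraction
  = bursts / (2 × cells); burst size = spot max-intensity + mean
  radius; an in-package two-sided Fisher's exact test
  (probability-ordering convention, log-space factorials, verified
  against exact enumeration); unpaired Student's *t* on sizes; and
  modulation calls (frequency / size / both / none). The two-state
  telegraph model backs the synthetic FISH tables: stationary active
  probability k_on / (k_on + k_off).
- **Synthetic data** (`tikp.simulate`) and an end-to-end driver
  (`tikp.pipeline`, CLI `tikp`) that chains
  simulate → kinetics → accessibility → enhancers → bursting and writes
  a manifest plus a JSON report; same seed ⇒ byte-identical outputs.

The analysis stages are sklearn-style estimators (`NBWaldTest`,
`KineticClusterer`, `AccessibilityClassifier`, `SuperEnhancerCaller`)
with `fit` and trailing-underscore attributes; the module-level
functions are thin wrappers over them. See `docs/methods.md` for the
models, assumptions, defaults and limitations.

## Worked example

Run the full pipeline on synthetic data (1,000 genes, 2,000 peaks,
700 cells by default):

```bash
tikp run --seed 1 --out-dir out
```

`out/report.json` then contains, among other sections (numbers below
are the actual seed-1 output):

```
kinetics.t_half_hours        {"fast_repressed": 0.81, "slow_repressed": 12.23,
                              "activated": 2.98, "slow_activated": 14.79}
kinetics.cluster_sizes       {"fast_repressed": 81, "slow_repressed": 120,
                              "activated": 50, "slow_activated": 81,
                              "removed_non_monotonic": 33}
accessibility.class_fractions{"decreased": 0.117, "increased": 0.035,
                              "unchanged": 0.380, "other": 0.468}
accessibility.motif_density_ranksum  p = 6.4e-41
accessibility.summit_median_offset_bp {"decreased": 11.0, "unchanged": 93.0}
bursting                     fraction 0.208 -> 0.100, fisher_p = 2.3e-15,
                              size_t_p = 0.42, modulation = "frequency"
```

Reading it: the four retained kinetic clusters recover the designed
half-response times (45 min, 12 h, 3 h, 14.5 h) and the rise-then-fall
cluster was removed; 11.7% of peaks lost accessibility within 2 h and
those peaks are strongly enriched for motif density relative to
unchanged peaks; TF summits sit ~11 bp from the midpoints of
decreased peaks versus ~93 bp for unchanged ones; and induction halved
the burst fraction while leaving burst size unchanged — frequency, not
size, modulation.

The same stages are available piecewise (`tikp simulate`,
`tikp kinetics`, `tikp accessibility`, `tikp bursting`, `tikp motifs`)
on files in the documented TSV/CSV/BED formats, and as library calls:

```python
from tikp import SimulationConfig, simulate_timecourse, normalize_counts
from tikp import call_differential_genes, cluster_kinetics

tc, truth = simulate_timecourse(SimulationConfig(seed=1, n_genes=2000))
tc = normalize_counts(tc)
de = call_differential_genes(tc, 0.0, 24.0)          # padj<0.01, |log2FC|>1
trajs = cluster_kinetics(tc, de.index[de.direction != "ns"], k=5, seed=1)
for tr in trajs:
    print(tr.cluster_label, len(tr.member_genes), round(tr.t_half, 2))
```

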