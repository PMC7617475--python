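"""Synthetic-data generators with known ground truth.

Every pipeline input can be generated here under a seeded random
stream: negative-binomial expression time courses with cluster-
structured kinetics, accessible-chromatin peaks whose probability of
losing accessibility rises with embedded motif density, acetylation
loss that is faster and deeper at enhancers than promoters, a
regulatory landscape (genes, enhancers, super-enhancers, activity and
contact matrices) biased toward fast-repressed genes, and two-state
telegraph bursting in which induction reduces burst frequency but not
burst size.

Kinetic family
--------------
Repressed trajectories follow a delayed-onset exponential approach to
a floor,

    mu(t) = base * (f + (1 - f) * 2**(-(max(0, t - d) / tau))),

mirrored upward for activated classes. Because the downstream kinetic
analysis scales *log* expression (as the half-response statistic is
defined on scaled normalized expression), the onset delay
``d = max(0, (4*t_half - T) / 3)`` and the decay scale ``tau``
(calibrated numerically) are chosen so that log2 of the noiseless
trajectory, min-max scaled over the sampled window [0, T], crosses 0.5
exactly at the configured half-response time. A pure exponential
cannot place that crossing later than ~T/2, so slow classes require
the onset delay.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from ._rng import substream
from .datatypes import (
    FishTable,
    GeneModel,
    PeakSet,
    SimulationConfig,
    TelegraphParams,
    TimeCourseMatrix,
)

__all__ = [
    "simulate_timecourse",
    "simulate_peaks",
    "simulate_fish",
    "simulate_regulatory_landscape",
    "class_trajectory",
    "nb_counts",
]


# ---------------------------------------------------------------------------
# kinetic trajectory family
# ---------------------------------------------------------------------------

def _relative_mean(t: np.ndarray, gene_class: str, delay: float, tau: float, floor: float) -> np.ndarray:
    """Relative expression v(t) with v(0) = 1 for the exponential classes."""
    decay = 2.0 ** (-np.maximum(0.0, t - delay) / tau)
    if gene_class in ("fast_repressed", "slow_repressed"):
        return floor + (1.0 - floor) * decay
    # activated classes mirror the approach upward to a 1/floor ceiling
    gain = 1.0 / floor
    return 1.0 + (gain - 1.0) * (1.0 - decay)


def _log_half_crossing(tau: float, delay: float, t_max: float, gene_class: str, floor: float) -> float:
    """Time at which the log-scaled trajectory reaches its window midpoint.

    The kinetic analysis scales log expression, so the half level of a
    trajectory over [0, T] is the geometric midpoint of its endpoint
    values; the crossing time has a closed form for the delayed
    exponential.
    """
    ends = _relative_mean(np.array([0.0, t_max]), gene_class, delay, tau, floor)
    v_star = float(np.sqrt(ends[0] * ends[1]))
    if gene_class in ("fast_repressed", "slow_repressed"):
        y = (v_star - floor) / (1.0 - floor)
    else:
        gain = 1.0 / floor
        y = 1.0 - (v_star - 1.0) / (gain - 1.0)
    return delay - tau * np.log2(y)


def _calibrate_kinetics(gene_class: str, t_half: float, t_max: float, floor: float) -> tuple[float, float]:
    """Onset delay and decay scale placing the scaled half-crossing at t_half.

    A pure exponential cannot cross the window midpoint later than
    ~T/2, so late classes get an onset delay d = max(0, (4*t_half-T)/3)
    and tau is then solved numerically.
    """
    if not 0 < t_half < t_max:
        raise ValueError(f"t_half must lie inside (0, {t_max})")
    delay = max(0.0, (4.0 * t_half - t_max) / 3.0)
    f = lambda tau: _log_half_crossing(tau, delay, t_max, gene_class, floor) - t_half
    lo, hi = 1e-6, 1e-5
    while f(hi) < 0 and hi < 1e6 * t_max:
        hi *= 2.0
    return delay, float(brentq(f, lo, hi, xtol=1e-12))


def class_trajectory(
    gene_class: str,
    t_half: float | None,
    timepoints: np.ndarray,
    floor: float = 0.125,
) -> np.ndarray:
    """Noiseless relative mean trajectory v(t) (v(0) = 1) for one class.

    Exponential classes are calibrated so that log2 of the trajectory,
    min-max scaled over the sampled window, crosses 0.5 exactly at the
    class t-half; ``non_monotonic`` rises and falls symmetrically;
    ``non_de`` is flat.
    """
    t = np.asarray(timepoints, dtype=float)
    T = t[-1]
    if gene_class == "non_de":
        return np.ones_like(t)
    if gene_class == "non_monotonic":
        u = t / T
        return 1.0 + 1.5 * (4.0 * u * (1.0 - u))
    if t_half is None:
        raise ValueError(f"class {gene_class!r} requires a t_half")
    if gene_class not in ("fast_repressed", "slow_repressed", "activated", "slow_activated"):
        raise ValueError(f"unknown gene class {gene_class!r}")
    delay, tau = _calibrate_kinetics(gene_class, t_half, T, floor)
    return _relative_mean(t, gene_class, delay, tau, floor)


def nb_counts(mean: np.ndarray, dispersion: float, rng: np.random.Generator) -> np.ndarray:
    """Negative-binomial draws with Var = m + dispersion * m**2.

    ``dispersion == 0`` is the declared zero-noise limit: counts equal
    the rounded means.
    """
    mean = np.asarray(mean, dtype=float)
    if np.any(mean < 0):
        raise ValueError("negative mean expression")
    if dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    if dispersion == 0:
        return np.rint(mean).astype(np.int64)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
    return rng.poisson(lam).astype(np.int64)


# ---------------------------------------------------------------------------
# expression time course
# ---------------------------------------------------------------------------

def _class_assignments(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Deterministic class counts (proportion * n, largest remainder), shuffled."""
    names = sorted(config.class_proportions)
    fracs = np.array([config.class_proportions[c] for c in names])
    raw = fracs * config.n_genes
    counts = np.floor(raw).astype(int)
    rema = raw - counts
    for i in np.argsort(-rema)[: config.n_genes - counts.sum()]:
        counts[i] += 1
    labels = np.repeat(names, counts)
    rng.shuffle(labels)
    return labels


def simulate_timecourse(config: SimulationConfig) -> tuple[TimeCourseMatrix, pd.Series]:
    """Simulate a nascent-RNA count time course with known kinetic classes.

    Returns the count matrix and the per-gene truth labels. Identical
    configs (including seed) give identical output.
    """
    rng = substream(config.seed, "timecourse")
    tps = np.asarray(config.timepoints, dtype=float)
    labels = _class_assignments(config, rng)

    base = rng.lognormal(config.base_log_mean, config.base_log_sd, size=config.n_genes)
    trajs = {
        c: class_trajectory(c, config.t_half_by_class.get(c), tps, config.repression_floor)
        for c in sorted(config.class_proportions)
    }
    means = np.empty((config.n_genes, len(tps)))
    for i, (cls, b) in enumerate(zip(labels, base)):
        means[i] = b * trajs[cls]

    cols = pd.MultiIndex.from_product(
        [tps, range(1, config.n_replicates + 1)], names=["timepoint", "replicate"]
    )
    counts = np.empty((config.n_genes, len(cols)), dtype=np.int64)
    for j in range(len(tps)):
        for r in range(config.n_replicates):
            counts[:, j * config.n_replicates + r] = nb_counts(
                means[:, j], config.nb_dispersion, rng
            )
    genes = pd.Index([f"gene_{i:05d}" for i in range(config.n_genes)], name="gene")
    tc = TimeCourseMatrix(pd.DataFrame(counts, index=genes, columns=cols))
    truth = pd.Series(labels, index=genes, name="gene_class")
    return tc, truth


# ---------------------------------------------------------------------------
# accessible-chromatin peaks
# ---------------------------------------------------------------------------

def _calibrate_intercept(density: np.ndarray, slope: float, target: float) -> float:
    """Intercept making mean logistic probability equal the target fraction."""
    g = lambda b0: expit(b0 + slope * density).mean() - target
    lo, hi = logit(target) - abs(slope) * density.max() - 5, logit(target) + 5
    return float(brentq(g, lo, hi))


def _signal_means(
    cls: str,
    depth: float,
    tps: np.ndarray,
    t_half: float,
    floor: float,
    speedup: float = 1.0,
) -> np.ndarray:
    """Per-timepoint mean signal for one peak class.

    Changed peaks move log-linearly to ``floor`` (or its reciprocal
    gain) and reach it at ``2 * t_half / speedup``, so the configured
    fold change is fully attained within the sampled window; t_half is
    the time at which half the log fold change has occurred.
    """
    frac = np.minimum(1.0, speedup * tps / (2.0 * t_half))
    if cls == "decreased":
        return depth * floor**frac
    if cls == "increased":
        return depth * (1.0 / floor) ** frac
    return np.full_like(tps, depth)


def simulate_peaks(config: SimulationConfig) -> PeakSet:
    """Simulate accessible sites with motif-coupled accessibility loss.

    The probability that a peak truly loses accessibility is a logistic
    function of its embedded motif density (motifs per 100 bp) with
    slope ``motif_density_effect``; the intercept is calibrated so the
    marginal decreased fraction matches the configured value. CTCF-site
    peaks are forced to stay unchanged. Acetylation at decreased
    enhancer peaks decays ``enhancer_speedup``-fold faster, and to a
    deeper floor, than at decreased promoter peaks.
    """
    rng = substream(config.seed, "peaks")
    n, width = config.n_peaks, config.peak_width
    spacing = config.chrom_length // n
    if spacing <= width:
        raise ValueError("peaks would overlap: chrom too short for n_peaks * width")
    offs = rng.integers(0, spacing - width, size=n)
    starts = np.arange(n) * spacing + offs
    ends = starts + width

    category = rng.choice(
        ["CTCF", "promoter", "intragenic", "intergenic"], size=n, p=[0.08, 0.25, 0.37, 0.30]
    )
    kind = np.where(
        category == "promoter",
        "promoter",
        np.where(
            (np.isin(category, ["intragenic", "intergenic"])) & (rng.random(n) < 0.6),
            "enhancer",
            "none",
        ),
    )

    # Motif content: overdispersed counts around ~6 per 400 bp peak.
    motif_count = nb_counts(np.full(n, 6.0), 0.25, rng)
    dens100 = motif_count / (width / 100.0)

    b0 = _calibrate_intercept(dens100, config.motif_density_effect, config.frac_decreased)
    p_dec = expit(b0 + config.motif_density_effect * dens100)
    u = rng.random(n)
    cls = np.full(n, "unchanged", dtype=object)
    cls[u < p_dec] = "decreased"
    p_inc = config.frac_increased / (1.0 - config.frac_decreased)
    inc = (cls == "unchanged") & (rng.random(n) < p_inc)
    cls[inc] = "increased"
    cls[category == "CTCF"] = "unchanged"

    depth = rng.lognormal(config.access_depth_log_mean, config.access_depth_log_sd, size=n)
    tps = np.asarray(config.access_timepoints, dtype=float)
    cols = pd.MultiIndex.from_product(
        [tps, range(1, config.n_replicates + 1)], names=["timepoint", "replicate"]
    )

    speed = np.where(kind == "enhancer", config.enhancer_speedup, 1.0)
    floor_h = np.where(kind == "enhancer", 0.2, 0.5)  # deeper acetylation loss at enhancers
    frac = np.minimum(1.0, speed[:, None] * tps[None, :] / (2.0 * config.access_t_half))
    fold_atac = np.select(
        [cls[:, None] == "decreased", cls[:, None] == "increased"],
        [0.25**frac, 4.0**frac],
        default=1.0,
    )
    fold_h3k = np.select(
        [cls[:, None] == "decreased", cls[:, None] == "increased"],
        [floor_h[:, None] ** frac, (1.0 / floor_h[:, None]) ** frac],
        default=1.0,
    )
    m_atac = np.repeat(depth[:, None] * fold_atac, config.n_replicates, axis=1)
    m_h3k = np.repeat(depth[:, None] * fold_h3k, config.n_replicates, axis=1)
    atac = nb_counts(m_atac, config.nb_dispersion, rng)
    h3k = nb_counts(m_h3k, config.nb_dispersion, rng)

    # TF-binding summits: centred (sd 15 bp) on truly-decreased peaks,
    # uniform elsewhere.
    mid = (starts + ends) // 2
    summit = np.where(
        cls == "decreased",
        np.clip(np.rint(mid + rng.normal(0, 15, size=n)), starts + 1, ends - 1),
        rng.integers(starts + 1, ends - 1),
    ).astype(np.int64)

    peaks = pd.DataFrame(
        {
            "chrom": config.chrom,
            "start": starts,
            "end": ends,
            "category": category,
            "kind": kind,
            "class_true": cls,
            "motif_count": motif_count,
            "summit": summit,
            "depth": depth,
        }
    )
    peaks.index.name = "peak"
    return PeakSet(
        peaks=peaks,
        atac=pd.DataFrame(atac, index=peaks.index, columns=cols),
        h3k27ac=pd.DataFrame(h3k, index=peaks.index, columns=cols),
    )


# ---------------------------------------------------------------------------
# smFISH bursting
# ---------------------------------------------------------------------------

def _fish_one(
    params: TelegraphParams, n_cells: int, rng: np.random.Generator, condition: str
) -> FishTable:
    n_alleles = 2 * n_cells
    denom = params.k_on + params.k_off
    if denom == 0:
        raise ValueError("k_on + k_off must be positive")
    p_on = params.k_on / denom
    burst = rng.random(n_alleles) < p_on
    intensity = np.full(n_alleles, np.nan)
    radius = np.full(n_alleles, np.nan)
    nb = int(burst.sum())
    if nb:
        intensity[burst] = np.clip(
            rng.normal(params.burst_intensity_mean, params.noise_sd, nb), 1e-6, None
        )
        radius_sd = params.noise_sd * params.burst_radius_mean / params.burst_intensity_mean
        radius[burst] = np.clip(
            rng.normal(params.burst_radius_mean, radius_sd, nb), 1e-6, None
        )
    table = pd.DataFrame(
        {
            "cell_id": np.repeat([f"cell_{i:05d}" for i in range(n_cells)], 2),
            "allele": np.tile([1, 2], n_cells),
            "burst": burst,
            "Intensity_MaxIntensity": intensity,
            "AreaShape_MeanRadius": radius,
        }
    )
    return FishTable(table=table, condition=condition)


def simulate_fish(
    params0: TelegraphParams,
    params1: TelegraphParams,
    n_cells: int,
    seed: int,
) -> tuple[FishTable, FishTable]:
    """Snapshot smFISH tables for two conditions (2 alleles per cell).

    Each allele's burst state is a Bernoulli draw of the telegraph
    model's stationary active probability k_on / (k_on + k_off);
    bursting alleles receive spot intensity and radius features.
    """
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    rng = substream(seed, "fish")
    t0 = _fish_one(params0, n_cells, rng, "uninduced")
    t1 = _fish_one(params1, n_cells, rng, "induced")
    return t0, t1


# ---------------------------------------------------------------------------
# regulatory landscape (genes, enhancers, SEs, linking inputs)
# ---------------------------------------------------------------------------

def simulate_regulatory_landscape(
    config: SimulationConfig,
    gene_classes: pd.Series,
    n_contexts: int = 8,
) -> dict:
    """Genes, enhancer/promoter elements and linking inputs with designed bias.

    Fast-repressed genes receive on average twice as many nearby
    enhancers (Poisson mean 4 vs 2 within +/-20 kb of the TSS), their
    enhancers lose acetylation with higher probability (0.65 vs 0.20),
    and a larger fraction of them (0.26 vs 0.08) is given a
    super-enhancer: a tight cluster of extra enhancers carrying
    ten-fold acetylation signal. Enhancer and gene activities across
    ``n_contexts`` pseudo-tissues are correlated for true enhancer-gene
    pairs, and contact frequency decays exponentially with distance
    with a boost for true pairs.

    Returns a dict with keys ``genes`` (GeneModel), ``elements``
    (PeakSet with H3K27ac counts and truth columns), ``element_activity``,
    ``gene_activity`` (DataFrames over contexts) and ``contacts``
    (elements x genes DataFrame).
    """
    rng = substream(config.seed, "landscape")
    genes = gene_classes.index.to_numpy()
    n_genes = len(genes)
    # 100 kb TSS spacing keeps each gene's +/-20 kb enhancer window and
    # +/-50 kb SE window from bleeding into its neighbours'; the
    # landscape spans as much of the toy chromosome as that needs.
    spacing = 100_000
    margin = 200_000
    tss = margin + np.arange(n_genes) * spacing + rng.integers(-20_000, 20_000, size=n_genes)
    genome_length = int(tss[-1] + margin)
    strand = rng.choice(["+", "-"], size=n_genes)
    gm = pd.DataFrame(
        {
            "gene": genes,
            "chrom": config.chrom,
            "tss": tss,
            "strand": strand,
            "gene_class": gene_classes.to_numpy(),
        }
    )

    is_fast = gm["gene_class"].to_numpy() == "fast_repressed"
    n_enh = rng.poisson(np.where(is_fast, 4.0, 2.0))
    se_gene = rng.random(n_genes) < np.where(is_fast, 0.26, 0.08)

    rows = []
    width = config.peak_width
    for gi in range(n_genes):
        # promoter element at the TSS
        rows.append((gm.tss[gi] - width // 2, "promoter", gi, False, 1.0))
        for _ in range(n_enh[gi]):
            off = rng.integers(2000, 20_000) * rng.choice([-1, 1])
            rows.append((gm.tss[gi] + off - width // 2, "enhancer", gi, True, 1.0))
        if se_gene[gi]:
            anchor = gm.tss[gi] + int(rng.integers(5000, 40_000)) * int(rng.choice([-1, 1]))
            for k in range(5):
                rows.append((anchor + k * 1500, "enhancer", gi, True, 10.0))

    el = pd.DataFrame(rows, columns=["start", "kind", "gene_idx", "is_enhancer", "boost"])
    el["start"] = el["start"].clip(0, genome_length - width)
    el["end"] = el["start"] + width
    el["chrom"] = config.chrom
    el = el.sort_values(["start", "end"], kind="mergesort").reset_index(drop=True)
    el.index.name = "element"

    gene_cls = gm["gene_class"].to_numpy()[el["gene_idx"].to_numpy()]
    p_loss = np.where(el["kind"] == "enhancer", np.where(gene_cls == "fast_repressed", 0.65, 0.20), 0.10)
    lost = rng.random(len(el)) < p_loss
    gained = (~lost) & (rng.random(len(el)) < 0.03)

    depth = rng.lognormal(config.access_depth_log_mean, 0.3, size=len(el)) * el["boost"].to_numpy()
    tps = np.asarray(config.access_timepoints, dtype=float)
    cols = pd.MultiIndex.from_product(
        [tps, range(1, config.n_replicates + 1)], names=["timepoint", "replicate"]
    )
    frac = np.minimum(1.0, tps[None, :] / (2.0 * config.access_t_half))
    fold = np.select(
        [lost[:, None], gained[:, None]], [0.25**frac, 4.0**frac], default=1.0
    )
    h3k = nb_counts(
        np.repeat(depth[:, None] * fold, config.n_replicates, axis=1),
        config.nb_dispersion, rng,
    )

    elements = el[["chrom", "start", "end", "kind", "gene_idx"]].copy()
    elements["lost_true"] = lost
    elements["gained_true"] = gained
    elements["signal"] = depth

    # Activity matrices over pseudo-tissue contexts: an element tracks
    # its target gene's latent profile, with noise.
    ctx = [f"ctx_{j}" for j in range(n_contexts)]
    gene_act = rng.normal(0.0, 1.0, size=(n_genes, n_contexts))
    elem_act = gene_act[el["gene_idx"].to_numpy()] + rng.normal(0.0, 0.5, size=(len(el), n_contexts))
    gene_activity = pd.DataFrame(gene_act, index=pd.Index(genes, name="gene"), columns=ctx)
    element_activity = pd.DataFrame(elem_act, index=el.index, columns=ctx)

    emid = ((el["start"] + el["end"]) // 2).to_numpy()
    dist = np.abs(emid[:, None] - tss[None, :]).astype(float)
    true_pair = np.zeros((len(el), n_genes), dtype=bool)
    true_pair[np.arange(len(el)), el["gene_idx"].to_numpy()] = True
    contacts = np.exp(-dist / 100_000.0) * (1.0 + 4.0 * true_pair)
    contacts *= rng.lognormal(0.0, 0.2, size=contacts.shape)
    contacts_df = pd.DataFrame(contacts, index=el.index, columns=pd.Index(genes, name="gene"))

    return {
        "genes": GeneModel(gm),
        "elements": PeakSet(peaks=elements, h3k27ac=pd.DataFrame(h3k, index=el.index, columns=cols)),
        "element_activity": element_activity,
        "gene_activity": gene_activity,
        "contacts": contacts_df,
    }
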