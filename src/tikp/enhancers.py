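"""Regulatory-element classification and enhancer-gene association.

Splits H3K27ac-marked accessible sites into active promoters and
enhancers, calls super-enhancers ROSE-style (stitch + rank-elbow),
quantifies enhancer density and super-enhancer association per kinetic
gene class, links enhancers to genes by activity correlation plus
contact frequency, and measures per-class fractions of nearby elements
losing or gaining acetylation.

All genomic windows around a TSS are closed intervals
[TSS - w, TSS + w]; coordinates are 0-based half-open BED intervals
and element positions are taken at the interval midpoint.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from ._rng import substream
from .datatypes import GeneModel
from .diffexp import NBWaldTest

__all__ = [
    "classify_elements",
    "SuperEnhancerCaller",
    "call_super_enhancers",
    "enhancer_density_by_gene_class",
    "se_association",
    "link_enhancers",
    "change_fraction_by_class",
]


def _overlaps_any(starts_a, ends_a, starts_b, ends_b) -> np.ndarray:
    """Boolean per interval in A: overlaps any interval in B (same chrom).

    B must be sorted by start and non-overlapping is not required;
    uses an event sweep over interval endpoints.
    """
    order = np.argsort(starts_b, kind="mergesort")
    sb, eb = np.asarray(starts_b)[order], np.asarray(ends_b)[order]
    # cumulative max of ends lets a single bisect decide overlap
    run_max_end = np.maximum.accumulate(eb)
    out = np.zeros(len(starts_a), dtype=bool)
    for i, (sa, ea) in enumerate(zip(starts_a, ends_a)):
        j = np.searchsorted(sb, ea, side="left")  # candidates start before a ends
        out[i] = j > 0 and run_max_end[j - 1] > sa
    return out


def classify_elements(
    h3k27ac_peaks: pd.DataFrame,
    atac_peaks: pd.DataFrame,
    gene_models: GeneModel,
    promoter_window: int = 1000,
) -> pd.DataFrame:
    """Label accessible sites as active promoter / active enhancer.

    A site overlapping an H3K27ac peak and whose midpoint lies within
    +/- promoter_window of any TSS is an ``active_promoter``; an
    H3K27ac-overlapping but TSS-distal site is an ``active_enhancer``;
    sites without H3K27ac overlap stay ``unclassified``.
    """
    gm = gene_models.genes
    out = atac_peaks.copy()
    out["element_kind"] = "unclassified"
    for chrom, sub in atac_peaks.groupby("chrom"):
        hk = h3k27ac_peaks[h3k27ac_peaks["chrom"] == chrom]
        marked = (
            _overlaps_any(
                sub["start"].to_numpy(), sub["end"].to_numpy(),
                hk["start"].to_numpy(), hk["end"].to_numpy(),
            )
            if len(hk)
            else np.zeros(len(sub), dtype=bool)
        )
        tss = np.sort(gm.loc[gm["chrom"] == chrom, "tss"].to_numpy())
        mids = (sub["start"].to_numpy() + sub["end"].to_numpy()) // 2
        if len(tss):
            j = np.searchsorted(tss, mids)
            d_lo = np.abs(mids - tss[np.clip(j - 1, 0, len(tss) - 1)])
            d_hi = np.abs(tss[np.clip(j, 0, len(tss) - 1)] - mids)
            near_tss = np.minimum(d_lo, d_hi) <= promoter_window
        else:
            near_tss = np.zeros(len(sub), dtype=bool)
        kind = np.where(
            marked, np.where(near_tss, "active_promoter", "active_enhancer"), "unclassified"
        )
        out.loc[sub.index, "element_kind"] = kind
    return out


class SuperEnhancerCaller(BaseEstimator):
    """ROSE-style super-enhancer caller: stitch, rank, elbow cutoff.

    Enhancers within ``stitch_distance`` bp are merged; stitched regions
    are ranked by total signal, both axes are scaled to [0, 1], and the
    cutoff is the point where the tangent slope of the (convex) curve
    reaches 1 - equivalently the minimizer of (scaled signal - scaled
    rank). Regions with signal strictly above the cutoff value are
    super-enhancers. If all signals are equal, there is no elbow and no
    SEs are called.

    Fitted attributes: ``stitched_`` (regions with total signal),
    ``is_super_`` (boolean per stitched region), ``threshold_``.
    """

    def __init__(self, stitch_distance: int = 12_500):
        self.stitch_distance = stitch_distance

    def fit(self, enhancers: pd.DataFrame, signal=None):
        if len(enhancers) < 3:
            raise ValueError("need at least 3 enhancers")
        df = enhancers.copy()
        if signal is not None:
            df["signal"] = np.asarray(signal, dtype=float)
        if "signal" not in df.columns:
            raise ValueError("enhancers need a 'signal' column or an explicit signal array")
        df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)

        regions = []
        cur = None
        for row in df.itertuples(index=False):
            if (
                cur is not None
                and row.chrom == cur["chrom"]
                and row.start - cur["end"] <= self.stitch_distance
            ):
                cur["end"] = max(cur["end"], row.end)
                cur["signal"] += row.signal
                cur["n_enhancers"] += 1
            else:
                if cur is not None:
                    regions.append(cur)
                cur = {
                    "chrom": row.chrom,
                    "start": row.start,
                    "end": row.end,
                    "signal": row.signal,
                    "n_enhancers": 1,
                }
        regions.append(cur)
        stitched = pd.DataFrame(regions)

        sig = np.sort(stitched["signal"].to_numpy())
        span = sig[-1] - sig[0]
        if span == 0:
            self.threshold_ = float("nan")
            self.is_super_ = np.zeros(len(stitched), dtype=bool)
        else:
            y = (sig - sig[0]) / span
            x = np.linspace(0.0, 1.0, len(sig))
            cut = int(np.argmin(y - x))
            self.threshold_ = float(sig[cut])
            self.is_super_ = stitched["signal"].to_numpy() > self.threshold_
        stitched["is_super"] = self.is_super_
        self.stitched_ = stitched
        return self


def call_super_enhancers(
    enhancers: pd.DataFrame, signal=None, stitch_distance: int = 12_500
) -> pd.DataFrame:
    """Stitched enhancer regions with an ``is_super`` flag."""
    return SuperEnhancerCaller(stitch_distance=stitch_distance).fit(enhancers, signal).stitched_


def _counts_in_window(positions: np.ndarray, tss: np.ndarray, window: int) -> np.ndarray:
    """Per-TSS count of positions within the closed window [tss-w, tss+w]."""
    pos = np.sort(np.asarray(positions))
    lo = np.searchsorted(pos, tss - window, side="left")
    hi = np.searchsorted(pos, tss + window, side="right")
    return hi - lo


def enhancer_density_by_gene_class(
    gene_models: GeneModel,
    elements: pd.DataFrame,
    window: int = 20_000,
    reference_class: str = "fast_repressed",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Active-enhancer counts near each gene, compared across classes.

    Counts accessible active-enhancer elements whose midpoint lies in
    the closed +/- window around the TSS. Returns the per-gene table and
    pairwise Wilcoxon rank-sum tests of the reference class against
    every other class, Bonferroni-corrected.
    """
    gm = gene_models.genes
    enh = elements[elements["element_kind"] == "active_enhancer"]
    counts = np.zeros(len(gm), dtype=int)
    for chrom, sub in gm.groupby("chrom"):
        e = enh[enh["chrom"] == chrom]
        mids = (e["start"].to_numpy() + e["end"].to_numpy()) // 2
        counts[np.asarray(gm["chrom"] == chrom)] = _counts_in_window(
            mids, sub["tss"].to_numpy(), window
        )
    per_gene = gm[["gene", "gene_class"]].copy()
    per_gene["n_enhancers"] = counts

    ref = per_gene.loc[per_gene["gene_class"] == reference_class, "n_enhancers"]
    if ref.empty:
        raise ValueError(f"no genes in reference class {reference_class!r}")
    others = [c for c in per_gene["gene_class"].unique() if c != reference_class]
    rows = []
    for cls in others:
        vals = per_gene.loc[per_gene["gene_class"] == cls, "n_enhancers"]
        if vals.empty:
            raise ValueError(f"gene class {cls!r} is empty")
        res = stats.mannwhitneyu(ref, vals, alternative="two-sided")
        rows.append({"vs_class": cls, "statistic": res.statistic, "p_value": res.pvalue})
    tests = pd.DataFrame(rows)
    tests["p_adjusted"] = np.minimum(tests["p_value"] * len(tests), 1.0)
    return per_gene, tests


def _random_control_classes(gm: pd.DataFrame, size: int, seed: int) -> np.ndarray:
    rng = substream(seed, "gene-control")
    return rng.choice(gm.index.to_numpy(), size=size, replace=False)


def se_association(
    gene_models: GeneModel,
    se_regions: pd.DataFrame,
    window: int = 50_000,
    seed: int = 0,
) -> pd.Series:
    """Fraction of genes per class with a super-enhancer within +/- window.

    A gene is SE-associated when any SE region intersects the closed
    window [TSS - w, TSS + w]. A ``random_control`` class of seeded
    randomly-sampled genes (size of the fast-repressed class, or 100)
    is appended.
    """
    gm = gene_models.genes
    ses = (
        se_regions[se_regions["is_super"].astype(bool)]
        if "is_super" in se_regions.columns
        else se_regions
    )
    hit = np.zeros(len(gm), dtype=bool)
    for chrom, sub in gm.groupby("chrom"):
        s = ses[ses["chrom"] == chrom].sort_values("start")
        if s.empty:
            continue
        tss = sub["tss"].to_numpy()
        hit[np.asarray(gm["chrom"] == chrom)] = _overlaps_any(
            tss - window, tss + window + 1, s["start"].to_numpy(), s["end"].to_numpy()
        )
    frac = pd.Series(hit, index=gm.index).groupby(gm["gene_class"]).mean()
    n_ctl = int((gm["gene_class"] == "fast_repressed").sum()) or min(100, len(gm))
    ctl_idx = _random_control_classes(gm, n_ctl, seed)
    frac["random_control"] = float(hit[gm.index.get_indexer(ctl_idx)].mean())
    return frac


def link_enhancers(
    element_activity: pd.DataFrame,
    gene_activity: pd.DataFrame,
    contacts: pd.DataFrame,
    element_pos: np.ndarray,
    gene_pos: np.ndarray,
    r_min: float = 0.5,
    c_min: float | None = None,
    max_distance: int = 500_000,
    n_distance_bins: int = 5,
) -> pd.DataFrame:
    """Enhancer-gene links from activity correlation plus contact.

    Candidate pairs are element/gene combinations within
    ``max_distance``. A pair is linked when the Pearson correlation of
    activities across shared contexts is >= r_min AND the contact
    frequency is >= the threshold. When ``c_min`` is None the threshold
    is the 95th percentile of contact among distance-matched candidate
    pairs (quantile bins of pair distance). Zero-variance activity
    vectors make the correlation undefined; such pairs are skipped and
    flagged.
    """
    shared = element_activity.columns.intersection(gene_activity.columns)
    if len(shared) < 5:
        raise ValueError("need at least 5 shared contexts for correlation")
    ea = element_activity[shared].to_numpy(dtype=float)
    ga = gene_activity[shared].to_numpy(dtype=float)

    epos = np.asarray(element_pos, dtype=np.int64)
    gpos = np.asarray(gene_pos, dtype=np.int64)
    ei, gi = np.nonzero(np.abs(epos[:, None] - gpos[None, :]) <= max_distance)
    dist = np.abs(epos[ei] - gpos[gi])
    contact = contacts.to_numpy(dtype=float)[ei, gi]

    ez = ea[ei] - ea[ei].mean(axis=1, keepdims=True)
    gz = ga[gi] - ga[gi].mean(axis=1, keepdims=True)
    es = np.sqrt((ez**2).sum(axis=1))
    gs = np.sqrt((gz**2).sum(axis=1))
    degenerate = (es == 0) | (gs == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (ez * gz).sum(axis=1) / (es * gs)
    r = np.where(degenerate, np.nan, r)

    if c_min is None:
        edges = np.quantile(dist, np.linspace(0, 1, n_distance_bins + 1))
        which = np.clip(np.searchsorted(edges, dist, side="right") - 1, 0, n_distance_bins - 1)
        thr = np.array(
            [np.quantile(contact[which == b], 0.95) if (which == b).any() else np.inf
             for b in range(n_distance_bins)]
        )
        c_thr = thr[which]
    else:
        c_thr = np.full(len(ei), float(c_min))

    linked = (~degenerate) & (r >= r_min) & (contact >= c_thr)
    return pd.DataFrame(
        {
            "element": element_activity.index.to_numpy()[ei],
            "gene": gene_activity.index.to_numpy()[gi],
            "distance": dist,
            "activity_correlation": r,
            "contact_frequency": contact,
            "contact_threshold": c_thr,
            "skipped_zero_variance": degenerate,
            "linked": linked,
        }
    )


def change_fraction_by_class(
    gene_models: GeneModel,
    elements: pd.DataFrame,
    element_counts: pd.DataFrame,
    t_ref: float,
    t: float,
    alpha: float = 0.01,
    min_fc: float = 1.5,
    window: int = 20_000,
    seed: int = 0,
    element_kind: str | None = "enhancer",
) -> pd.DataFrame:
    """Per-class fractions of nearby elements losing / gaining signal.

    Elements (optionally restricted by ``kind``) are tested with the NB
    machinery between the two timepoints; loss means padj < alpha and
    FC <= 1/min_fc, gain padj < alpha and FC >= min_fc. Each element is
    attributed to every gene class whose genes have a TSS within the
    closed +/- window of the element midpoint; a seeded random-gene
    control class is appended.
    """
    tps = element_counts.columns.get_level_values("timepoint")
    X_ref = element_counts.loc[:, tps == t_ref].to_numpy(dtype=float)
    X_alt = element_counts.loc[:, tps == t].to_numpy(dtype=float)
    test = NBWaldTest().fit(X_ref, X_alt)
    lfc, padj = test.log2_fold_change_, test.p_adjusted_
    lg2 = np.log2(min_fc)
    lost = (padj < alpha) & (lfc <= -lg2)
    gained = (padj < alpha) & (lfc >= lg2)

    el = elements.reset_index(drop=True)
    if element_kind is not None and "kind" in el.columns:
        keep = (el["kind"] == element_kind).to_numpy()
    else:
        keep = np.ones(len(el), dtype=bool)
    mids = ((el["start"] + el["end"]) // 2).to_numpy()

    gm = gene_models.genes
    classes = list(pd.unique(gm["gene_class"]))
    n_ctl = int((gm["gene_class"] == "fast_repressed").sum()) or min(100, len(gm))
    ctl_genes = set(_random_control_classes(gm, n_ctl, seed))
    rows = []
    for cls in classes + ["random_control"]:
        if cls == "random_control":
            sub = gm.loc[gm.index.isin(ctl_genes)]
        else:
            sub = gm[gm["gene_class"] == cls]
        if sub.empty:
            raise ValueError(f"gene class {cls!r} is empty")
        near = np.zeros(len(el), dtype=bool)
        for chrom, g in sub.groupby("chrom"):
            tss = np.sort(g["tss"].to_numpy())
            onchrom = (el["chrom"] == chrom).to_numpy()
            j = np.searchsorted(tss, mids[onchrom])
            d_lo = np.abs(mids[onchrom] - tss[np.clip(j - 1, 0, len(tss) - 1)])
            d_hi = np.abs(tss[np.clip(j, 0, len(tss) - 1)] - mids[onchrom])
            near[onchrom] = np.minimum(d_lo, d_hi) <= window
        sel = near & keep
        n = int(sel.sum())
        rows.append(
            {
                "gene_class": cls,
                "n_elements": n,
                "loss_fraction": float(lost[sel].mean()) if n else float("nan"),
                "gain_fraction": float(gained[sel].mean()) if n else float("nan"),
            }
        )
    return pd.DataFrame(rows).set_index("gene_class")
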