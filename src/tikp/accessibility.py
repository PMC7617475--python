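"""Early chromatin-accessibility changes at accessible sites.

Classifies peaks by differential accessibility between two timepoints,
counts short TF-recognition motifs (GGAA, TTCC, GGGA, TCCC by default)
with overlapping matches, computes motif density per bp, compares
densities between peak classes by rank-sum test, builds signal
metaprofiles around peak centers, and summarizes how precisely
TF-binding summits sit at peak midpoints per accessibility class.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .datatypes import PeakSet
from .diffexp import NBWaldTest

__all__ = [
    "IKZF_MOTIFS",
    "AccessibilityClassifier",
    "classify_accessibility",
    "count_motifs",
    "motif_density",
    "compare_motif_density",
    "metaprofile",
    "summit_centering",
    "Metaprofile",
]

#: Core recognition 4-mers; the set is closed under reverse complement
#: (GGAA<->TTCC, GGGA<->TCCC), so total counts are strand-symmetric.
IKZF_MOTIFS = ("GGAA", "TTCC", "GGGA", "TCCC")


class AccessibilityClassifier(BaseEstimator):
    """Four-way accessibility classification of peaks between timepoints.

    fit(X_ref, X_alt) takes raw peak-count matrices (peaks x
    replicates). Classes: ``decreased`` (padj < alpha, log2FC < 0),
    ``increased`` (padj < alpha, log2FC > 0), ``unchanged``
    (padj > unchanged_alpha and |log2FC| <= unchanged_lfc), ``other``.

    Fitted attributes: ``classes_``, ``log2_fold_change_``,
    ``p_value_``, ``p_adjusted_``.
    """

    def __init__(
        self,
        alpha: float = 0.01,
        unchanged_alpha: float = 0.05,
        unchanged_lfc: float = 0.2,
    ):
        self.alpha = alpha
        self.unchanged_alpha = unchanged_alpha
        self.unchanged_lfc = unchanged_lfc

    def fit(self, X_ref, X_alt, sf_ref=None, sf_alt=None):
        test = NBWaldTest().fit(X_ref, X_alt, sf_ref=sf_ref, sf_alt=sf_alt)
        lfc, padj = test.log2_fold_change_, test.p_adjusted_
        cls = np.full(test.n_features_, "other", dtype=object)
        cls[(padj < self.alpha) & (lfc < 0)] = "decreased"
        cls[(padj < self.alpha) & (lfc > 0)] = "increased"
        cls[(padj > self.unchanged_alpha) & (np.abs(lfc) <= self.unchanged_lfc)] = "unchanged"
        self.classes_ = cls
        self.log2_fold_change_ = lfc
        self.p_value_ = test.p_value_
        self.p_adjusted_ = padj
        return self

    def results(self, index=None) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class": self.classes_,
                "log2_fold_change": self.log2_fold_change_,
                "p_value": self.p_value_,
                "p_adjusted": self.p_adjusted_,
            },
            index=index,
        )


def classify_accessibility(
    peaks: PeakSet, t_ref: float, t: float, alpha: float = 0.01
) -> pd.DataFrame:
    """Classify every peak's accessibility change between two timepoints."""
    if peaks.atac is None:
        raise ValueError("PeakSet carries no accessibility counts")
    tps = peaks.atac.columns.get_level_values("timepoint")
    X_ref = peaks.atac.loc[:, tps == t_ref].to_numpy(dtype=float)
    X_alt = peaks.atac.loc[:, tps == t].to_numpy(dtype=float)
    if X_ref.shape[1] == 0 or X_alt.shape[1] == 0:
        raise ValueError(f"timepoint {t_ref} or {t} missing from accessibility counts")
    clf = AccessibilityClassifier(alpha=alpha).fit(X_ref, X_alt)
    return clf.results(index=peaks.peaks.index)


def count_motifs(sequence: str, motifs=IKZF_MOTIFS) -> tuple[dict, int]:
    """Count possibly-overlapping motif occurrences on the given strand.

    Scans every start position; ``N`` never matches. Returns the
    per-motif map and the total.
    """
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    if set(seq) - set("ACGTN"):
        raise ValueError("sequence must be over A, C, G, T, N")
    counts = {}
    for m in motifs:
        k, c, start = len(m), 0, 0
        while True:
            i = seq.find(m, start)
            if i < 0:
                break
            c += 1
            start = i + 1  # overlapping occurrences count
        counts[m] = c
    return counts, sum(counts.values())


def motif_density(total_count: int, start: int, end: int) -> float:
    """Motif density per bp: count / (end - start)."""
    length = end - start
    if length <= 0:
        raise ValueError("zero-length peak")
    return total_count / length


def compare_motif_density(densities_a, densities_b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test on per-peak motif densities."""
    a = np.asarray(densities_a, dtype=float)
    b = np.asarray(densities_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both peak groups must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


class Metaprofile:
    """Mean signal in uniform bins around a set of centers."""

    def __init__(self, bin_centers: np.ndarray, mean_signal: np.ndarray, n_intervals: int):
        self.bin_centers = bin_centers
        self.mean_signal = mean_signal
        self.n_intervals = n_intervals

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bin_center": self.bin_centers, "mean_signal": self.mean_signal})


def metaprofile(
    signal: np.ndarray,
    centers,
    flank: int = 1000,
    n_bins: int = 100,
    bin_size: int = 1,
    drop_out_of_bounds: bool = True,
) -> Metaprofile:
    """Average a binned coverage track in windows around centers.

    ``signal`` is per-bin coverage with ``bin_size`` bp bins covering
    the chromosome from 0. Each window spans [center - flank,
    center + flank) split into ``n_bins`` uniform bins; windows
    extending past the track are dropped (or clipped to the edge value
    when ``drop_out_of_bounds`` is False). Peaks are unstranded, so no
    strand flipping is applied.
    """
    signal = np.asarray(signal, dtype=float)
    centers = np.asarray(centers, dtype=np.int64)
    if centers.size == 0:
        raise ValueError("empty center list")
    if (2 * flank) % n_bins != 0:
        raise ValueError("2*flank must be divisible by n_bins")
    chrom_len = signal.size * bin_size
    in_bounds = (centers - flank >= 0) & (centers + flank <= chrom_len)
    if drop_out_of_bounds:
        centers = centers[in_bounds]
        if centers.size == 0:
            raise ValueError("no window lies fully within the track")
    offsets = np.arange(-flank, flank)
    pos = centers[:, None] + offsets[None, :]
    np.clip(pos, 0, chrom_len - 1, out=pos)
    # two-cell midpoint values: profiles of signals point-symmetric
    # about a center are then exactly symmetric despite the half-open
    # window convention
    pos2 = np.minimum(pos + 1, chrom_len - 1)
    values = (signal[pos // bin_size] + signal[pos2 // bin_size]) / 2.0
    w = 2 * flank // n_bins
    per_bin = values.reshape(len(centers), n_bins, w).mean(axis=(0, 2))
    bin_centers = -flank + w * np.arange(n_bins) + w / 2.0
    return Metaprofile(bin_centers, per_bin, n_intervals=len(centers))


def summit_centering(
    tf_peaks: pd.DataFrame, atac_peaks: pd.DataFrame, class_column: str = "class"
) -> pd.DataFrame:
    """Median |summit - peak midpoint| per accessibility class.

    ``tf_peaks`` needs ``chrom`` and ``summit`` columns; ``atac_peaks``
    needs ``chrom``, ``start``, ``end`` and the class column. A TF peak
    pairs with every accessible peak whose interval contains its summit.
    Returns per-class median offset and pair count; classes without
    overlapping pairs are flagged with ``n_pairs == 0``.
    """
    if "summit" not in tf_peaks.columns:
        raise ValueError("TF peaks must carry a 'summit' column")
    out = []
    for cls, grp in atac_peaks.groupby(class_column):
        offsets = []
        for chrom, sub in grp.groupby("chrom"):
            sub = sub.sort_values("start")
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            mids = (starts + ends) // 2
            summits = tf_peaks.loc[tf_peaks["chrom"] == chrom, "summit"].to_numpy()
            # peaks are non-overlapping within a class group after sorting;
            # locate the candidate interval for each summit and keep hits
            idx = np.searchsorted(starts, summits, side="right") - 1
            ok = (idx >= 0) & (summits < ends[np.clip(idx, 0, len(ends) - 1)])
            offsets.append(np.abs(summits[ok] - mids[idx[ok]]))
        offs = np.concatenate(offsets) if offsets else np.array([])
        out.append(
            {
                "class": cls,
                "n_pairs": len(offs),
                "median_offset": float(np.median(offs)) if len(offs) else float("nan"),
            }
        )
    return pd.DataFrame(out).set_index("class")
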