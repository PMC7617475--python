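"""Kinetic classification of induction time courses.

Normalizes count time courses (median-of-ratios), calls differential
genes between two timepoints with the shared negative-binomial Wald
test, clusters differential genes by the shape of their scaled
trajectories, removes non-monotonic clusters, and annotates each
retained cluster with its half-maximal response time (t-half).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans

from .datatypes import TimeCourseMatrix
from .diffexp import NBWaldTest, size_factors_median_of_ratios

__all__ = [
    "normalize_counts",
    "call_differential_genes",
    "cluster_kinetics",
    "estimate_t_half",
    "scale_minmax",
    "KineticClusterer",
    "ClusterTrajectory",
]


def normalize_counts(tc: TimeCourseMatrix) -> TimeCourseMatrix:
    """Populate median-of-ratios size factors on a copy of the matrix."""
    sf = size_factors_median_of_ratios(tc.counts.to_numpy())
    return TimeCourseMatrix(
        counts=tc.counts.copy(),
        size_factors=pd.Series(sf, index=tc.counts.columns),
    )


def call_differential_genes(
    tc: TimeCourseMatrix,
    t_ref: float,
    t: float,
    alpha: float = 0.01,
    min_abs_log2fc: float = 1.0,
) -> pd.DataFrame:
    """Differential genes between two timepoints (NB Wald + BH).

    Direction is ``down`` when padj < alpha and log2FC < -min_abs_log2fc,
    ``up`` when padj < alpha and log2FC > +min_abs_log2fc, else ``ns``.
    """
    if tc.size_factors is None:
        tc = normalize_counts(tc)
    X_ref = tc.counts_at(t_ref).to_numpy(dtype=float)
    X_alt = tc.counts_at(t).to_numpy(dtype=float)
    if X_ref.shape[1] < 2 or X_alt.shape[1] < 2:
        raise ValueError("need at least 2 replicates at each timepoint")
    res = NBWaldTest().fit(
        X_ref, X_alt, sf_ref=tc.size_factors_at(t_ref), sf_alt=tc.size_factors_at(t)
    ).results(index=tc.genes)
    sig = res["p_adjusted"] < alpha
    res["direction"] = np.where(
        sig & (res["log2_fold_change"] < -min_abs_log2fc),
        "down",
        np.where(sig & (res["log2_fold_change"] > min_abs_log2fc), "up", "ns"),
    )
    return res


def scale_minmax(values: np.ndarray) -> np.ndarray:
    """Per-row min-max scaling to [0, 1]; constant rows become NaN."""
    values = np.asarray(values, dtype=float)
    lo = values.min(axis=-1, keepdims=True)
    hi = values.max(axis=-1, keepdims=True)
    span = hi - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (values - lo) / span
    return np.where(span == 0, np.nan, out)


def estimate_t_half(values, timepoints) -> float:
    """First time the trajectory crosses the midpoint of its range.

    Linear interpolation between the flanking samples; returns NaN if
    the half level is never crossed (degenerate constant input).
    """
    v = np.asarray(values, dtype=float)
    t = np.asarray(timepoints, dtype=float)
    if v.shape != t.shape or v.ndim != 1:
        raise ValueError("values and timepoints must be 1-D and aligned")
    half = (v.min() + v.max()) / 2.0
    d = v - half
    if np.all(d == 0):
        return float("nan")
    for i in range(len(v)):
        if d[i] == 0:
            return float(t[i])
        if i + 1 < len(v) and d[i] * d[i + 1] < 0:
            return float(t[i] + (half - v[i]) * (t[i + 1] - t[i]) / (v[i + 1] - v[i]))
    return float("nan")


def _tie_groups(values: np.ndarray, tol: float) -> np.ndarray:
    """Replace values by single-linkage group indices (gap > tol splits)."""
    order = np.argsort(values, kind="mergesort")
    sorted_vals = values[order]
    group = np.zeros(len(values), dtype=int)
    group[order] = np.concatenate([[0], np.cumsum(np.diff(sorted_vals) > tol)])
    return group


@dataclass
class ClusterTrajectory:
    """One kinetic cluster: behavior label, members, scaled mean and t-half."""

    cluster_label: str
    member_genes: list = field(default_factory=list)
    mean_scaled: np.ndarray | None = None
    ci95_low: np.ndarray | None = None
    ci95_high: np.ndarray | None = None
    t_half: float = float("nan")
    spearman_rho: float = float("nan")
    removed: bool = False


class KineticClusterer(ClusterMixin, BaseEstimator):
    """K-means clustering of kinetic trajectories with behavior labels.

    fit(X, timepoints) expects per-gene replicate-averaged
    log-expression trajectories (rows: genes, columns: ordered
    timepoints). Genes are clustered on their per-gene min-max-scaled
    trajectories (shape, not level). Each cluster's summary trajectory
    is the min-max-scaled *mean log trajectory* of its members -
    scaling after averaging, which for multiplicative kinetics recovers
    the shared shape exactly, whereas averaging per-gene scaled curves
    compresses plateaus and biases the half-crossing. Clusters whose
    summary trajectory is not monotone in time (|Spearman rho| <
    ``monotonicity_threshold`` after snapping plateaus to a
    ``plateau_tolerance`` grid) are flagged ``removed_non_monotonic``;
    the remainder are split by the sign of their net change and ranked
    by t-half into fast_repressed / slow_repressed and activated /
    slow_activated.

    Fitted attributes: ``labels_`` (integer cluster per gene),
    ``cluster_names_`` (behavior label per cluster), ``trajectories_``
    (list of :class:`ClusterTrajectory` in cluster order), ``t_half_``
    (behavior label -> hours for retained clusters).
    """

    def __init__(
        self,
        n_clusters: int = 5,
        n_init: int = 25,
        monotonicity_threshold: float = 0.8,
        plateau_tolerance: float = 0.05,
        random_state: int | None = 0,
    ):
        self.n_clusters = n_clusters
        self.n_init = n_init
        self.monotonicity_threshold = monotonicity_threshold
        self.plateau_tolerance = plateau_tolerance
        self.random_state = random_state

    def fit(self, X, timepoints=None):
        X = np.asarray(X, dtype=float)
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")
        if X.shape[0] < self.n_clusters:
            raise ValueError("need at least n_clusters trajectories")
        if timepoints is None:
            timepoints = np.arange(X.shape[1], dtype=float)
        t = np.asarray(timepoints, dtype=float)

        scaled = scale_minmax(X)
        if np.isnan(scaled).any():
            raise ValueError("constant trajectories have undefined scaling; drop them first")
        km = KMeans(
            n_clusters=self.n_clusters, n_init=self.n_init, random_state=self.random_state
        ).fit(scaled)
        labels = km.labels_

        trajs: list[ClusterTrajectory] = []
        for c in range(self.n_clusters):
            member_scaled = scaled[labels == c]
            if len(member_scaled) == 0:  # duplicate inputs can starve a cluster
                mean = np.full(len(t), 0.5)
            else:
                mean = scale_minmax(X[labels == c].mean(axis=0))
            if np.isnan(mean).any():  # flat cluster mean: no kinetic signal
                mean = np.full(len(t), 0.5)
            sem = (
                member_scaled.std(axis=0, ddof=1) / np.sqrt(len(member_scaled))
                if len(member_scaled) > 1
                else np.zeros_like(mean)
            )
            # Rank correlation treats noise wiggles on a plateau as full
            # rank reversals; merging values into tie groups (adjacent
            # sorted gaps within tolerance) makes |rho| measure the
            # trend only.
            snapped = _tie_groups(mean, self.plateau_tolerance)
            if len(np.unique(snapped)) > 1:
                rho = stats.spearmanr(snapped, t).statistic
            else:
                rho = 0.0
            trajs.append(
                ClusterTrajectory(
                    cluster_label="",
                    mean_scaled=mean,
                    ci95_low=mean - 1.96 * sem,
                    ci95_high=mean + 1.96 * sem,
                    t_half=estimate_t_half(mean, t),
                    spearman_rho=float(rho),
                    removed=abs(rho) < self.monotonicity_threshold,
                )
            )

        t_quarter = t[-1] / 4.0
        for direction, fast_name, slow_name in (
            (-1, "fast_repressed", "slow_repressed"),
            (+1, "activated", "slow_activated"),
        ):
            idx = [
                i
                for i, tr in enumerate(trajs)
                if not tr.removed
                and np.sign(tr.mean_scaled[-1] - tr.mean_scaled[0]) == direction
            ]
            idx.sort(key=lambda i: trajs[i].t_half)
            if len(idx) == 1:
                only = trajs[idx[0]]
                only.cluster_label = fast_name if only.t_half <= t_quarter else slow_name
            elif idx:
                trajs[idx[0]].cluster_label = fast_name
                for i in idx[1:]:
                    trajs[i].cluster_label = slow_name
        for tr in trajs:
            if tr.removed:
                tr.cluster_label = "removed_non_monotonic"
            elif not tr.cluster_label:  # flat retained cluster (no net change)
                tr.cluster_label = "removed_non_monotonic"
                tr.removed = True

        self.labels_ = labels
        self.trajectories_ = trajs
        self.cluster_names_ = [tr.cluster_label for tr in trajs]
        self.t_half_ = {
            tr.cluster_label: tr.t_half for tr in trajs if not tr.removed
        }
        self.timepoints_ = t
        return self

    def fit_predict(self, X, timepoints=None):
        return self.fit(X, timepoints=timepoints).labels_


def _log_trajectories(tc: TimeCourseMatrix, genes) -> tuple[pd.DataFrame, np.ndarray]:
    """Replicate-averaged log2(normalized + 1) trajectories per gene.

    Constant trajectories (undefined min-max scaling) are dropped with
    a warning.
    """
    if tc.size_factors is None:
        tc = normalize_counts(tc)
    norm = tc.counts.to_numpy(dtype=float) / tc.size_factors.to_numpy()[None, :]
    logn = np.log2(norm + 1.0)
    df = pd.DataFrame(logn, index=tc.genes, columns=tc.counts.columns)
    avg = df.T.groupby(level="timepoint").mean().T  # genes x timepoints
    avg = avg.loc[list(genes)]
    keep = avg.to_numpy().min(axis=1) < avg.to_numpy().max(axis=1)
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} constant trajectories")
    avg = avg.loc[keep]
    return avg, avg.columns.to_numpy(dtype=float)


def cluster_kinetics(
    tc: TimeCourseMatrix,
    de_genes,
    k: int = 5,
    seed: int = 0,
    monotonicity_threshold: float = 0.8,
) -> list[ClusterTrajectory]:
    """Cluster differential genes by kinetic behavior.

    Returns one :class:`ClusterTrajectory` per cluster with members
    filled in; clusters failing the monotonicity filter carry the
    ``removed_non_monotonic`` label and are excluded downstream.
    """
    logtraj, tps = _log_trajectories(tc, de_genes)
    model = KineticClusterer(n_clusters=k, random_state=seed,
                             monotonicity_threshold=monotonicity_threshold)
    model.fit(logtraj.to_numpy(), timepoints=tps)
    for c, tr in enumerate(model.trajectories_):
        tr.member_genes = list(logtraj.index[model.labels_ == c])
    return model.trajectories_
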