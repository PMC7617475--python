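"""Kinetic clustering, scaling and half-response estimation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from tikp.datatypes import SimulationConfig, TimeCourseMatrix
from tikp.kinetics import (
    KineticClusterer,
    call_differential_genes,
    cluster_kinetics,
    estimate_t_half,
    normalize_counts,
    scale_minmax,
)
from tikp.simulate import simulate_timecourse


def _tc_from_means(means, timepoints, n_rep=2, noise=None, rng=None):
    cols = pd.MultiIndex.from_product(
        [timepoints, range(1, n_rep + 1)], names=["timepoint", "replicate"]
    )
    reps = np.repeat(means, n_rep, axis=1).astype(float)
    if noise is not None and rng is not None:
        reps = rng.poisson(reps).astype(float)
    genes = pd.Index([f"g{i}" for i in range(means.shape[0])], name="gene")
    return TimeCourseMatrix(pd.DataFrame(reps.astype(np.int64), index=genes, columns=cols))


class TestTHalf:
    def test_half_level_met_exactly_at_a_sample(self):
        assert estimate_t_half([1.0, 0.9, 0.5, 0.1, 0.0], [0, 0.5, 1, 2, 6]) == 1.0

    def test_linear_decay_crosses_at_midtime(self):
        t = np.linspace(0, 2, 5)
        assert estimate_t_half(1 - t / 2, t) == pytest.approx(1.0)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.floats(min_value=0.1, max_value=10.0))
    def test_equivariant_under_time_rescaling(self, factor):
        t = np.array([0.0, 1.0, 2.0, 4.0, 8.0])
        v = np.array([1.0, 0.8, 0.45, 0.2, 0.05])
        base = estimate_t_half(v, t)
        assert estimate_t_half(v, factor * t) == pytest.approx(factor * base)

    def test_constant_trajectory_undefined(self):
        assert np.isnan(estimate_t_half([0.5] * 4, [0, 1, 2, 3]))


class TestScaling:
    def test_idempotent_on_unit_interval(self, rng):
        x = scale_minmax(rng.random((10, 6)))
        assert np.allclose(scale_minmax(x), x)

    def test_constant_rows_become_nan(self):
        out = scale_minmax(np.array([[1.0, 1.0, 1.0], [0.0, 1.0, 2.0]]))
        assert np.isnan(out[0]).all() and np.allclose(out[1], [0, 0.5, 1])


class TestDifferentialCalling:
    def test_null_course_flags_no_genes(self, rng):
        means = np.full((150, 4), 400.0)
        tc = _tc_from_means(means, [0.0, 2.0, 8.0, 24.0])
        tc = normalize_counts(tc)
        res = call_differential_genes(tc, 0.0, 24.0)
        assert (res["direction"] == "ns").all()

    def test_thresholds_applied_as_printed(self, rng):
        """padj < 0.01 AND |log2FC| > 1; a strong but small change stays ns."""
        sim = SimulationConfig(seed=3, n_genes=800)
        tc, truth = simulate_timecourse(sim)
        tc = normalize_counts(tc)
        res = call_differential_genes(tc, 0.0, 24.0, alpha=0.01, min_abs_log2fc=1.0)
        flagged = res["direction"] != "ns"
        assert (res.loc[flagged, "p_adjusted"] < 0.01).all()
        assert (res.loc[flagged, "log2_fold_change"].abs() > 1.0).all()
        # every fast-repressed gene is 8-fold down by 24 h
        fast = truth == "fast_repressed"
        assert (res.loc[fast.to_numpy(), "direction"] == "down").mean() > 0.95

    def test_missing_timepoint_raises(self):
        tc = _tc_from_means(np.full((20, 2), 100.0), [0.0, 2.0])
        with pytest.raises(KeyError):
            call_differential_genes(normalize_counts(tc), 0.0, 5.0)


class TestClustering:
    def test_recovers_well_separated_families(self):
        sim = SimulationConfig(seed=5, n_genes=2000)
        tc, truth = simulate_timecourse(sim)
        tc = normalize_counts(tc)
        de = set()
        for t in tc.timepoints[1:]:
            r = call_differential_genes(tc, 0.0, t)
            de.update(r.index[r["direction"] != "ns"])
        trajs = cluster_kinetics(tc, sorted(de), k=5, seed=5)
        labels = {g: tr.cluster_label for tr in trajs for g in tr.member_genes}
        pred = pd.Series(labels)
        designed = truth.index[truth != "non_de"].intersection(pred.index)
        assert adjusted_rand_score(truth.loc[designed], pred.loc[designed]) >= 0.9

    def test_rise_then_fall_cluster_removed(self):
        sim = SimulationConfig(seed=5, n_genes=2000)
        tc, truth = simulate_timecourse(sim)
        tc = normalize_counts(tc)
        de = set()
        for t in tc.timepoints[1:]:
            r = call_differential_genes(tc, 0.0, t)
            de.update(r.index[r["direction"] != "ns"])
        trajs = cluster_kinetics(tc, sorted(de), k=5, seed=5)
        removed = [tr for tr in trajs if tr.removed]
        assert len(removed) == 1
        members = truth.loc[removed[0].member_genes]
        assert (members == "non_monotonic").mean() > 0.8

    def test_single_family_gives_identical_cluster_means(self):
        traj = np.array([1.0, 0.7, 0.4, 0.2, 0.1]) * 1000
        X = np.log2(np.tile(traj, (60, 1)) + 1)
        model = KineticClusterer(n_clusters=3, random_state=0).fit(
            X, timepoints=[0, 1, 2, 4, 8]
        )
        # identical inputs may leave some clusters empty; every
        # populated cluster must carry the same (exact) mean trajectory
        populated = [
            tr.mean_scaled
            for c, tr in enumerate(model.trajectories_)
            if (model.labels_ == c).any()
        ]
        assert populated
        for tr in populated[1:]:
            assert np.allclose(tr, populated[0], atol=1e-12)

    def test_partition_invariant_to_gene_order(self):
        sim = SimulationConfig(seed=9, n_genes=1200)
        tc, truth = simulate_timecourse(sim)
        tc = normalize_counts(tc)
        genes = list(tc.genes)
        trajs_a = cluster_kinetics(tc, genes, k=4, seed=0)
        perm = TimeCourseMatrix(tc.counts.iloc[::-1], size_factors=tc.size_factors)
        trajs_b = cluster_kinetics(perm, genes[::-1], k=4, seed=0)
        part_a = {frozenset(tr.member_genes) for tr in trajs_a if tr.member_genes}
        part_b = {frozenset(tr.member_genes) for tr in trajs_b if tr.member_genes}
        assert part_a == part_b

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            KineticClusterer(n_clusters=1).fit(np.random.default_rng(0).random((10, 5)))

    def test_constant_trajectories_dropped_with_warning(self):
        means = np.vstack([np.full(5, 100.0), [100, 80, 60, 40, 20], [10, 20, 40, 80, 160],
                           [100, 50, 25, 12, 6]])
        tc = _tc_from_means(means, [0.0, 1.0, 2.0, 4.0, 8.0])
        tc = TimeCourseMatrix(tc.counts, size_factors=pd.Series(1.0, index=tc.counts.columns))
        with pytest.warns(UserWarning, match="constant"):
            trajs = cluster_kinetics(tc, list(tc.genes), k=2, seed=0)
        assert sum(len(tr.member_genes) for tr in trajs) == 3
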