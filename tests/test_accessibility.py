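"""Accessibility classification, motif statistics, metaprofiles, summits."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tikp.accessibility import (
    compare_motif_density,
    count_motifs,
    classify_accessibility,
    metaprofile,
    motif_density,
    summit_centering,
)
from tikp.datatypes import PeakSet, SimulationConfig
from tikp.simulate import simulate_peaks

dna = st.text(alphabet="ACGTN", min_size=4, max_size=300)


def naive_scan(seq, motifs=("GGAA", "TTCC", "GGGA", "TCCC")):
    return sum(
        1
        for m in motifs
        for i in range(len(seq) - len(m) + 1)
        if seq[i : i + len(m)] == m
    )


def revcomp(seq):
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


class TestCountMotifs:
    def test_exact_tiling(self):
        counts, total = count_motifs("GGAAGGAA")
        assert counts["GGAA"] == 2 and total == 2
        assert counts["TTCC"] == counts["GGGA"] == counts["TCCC"] == 0

    def test_overlapping_occurrences_counted(self):
        counts, total = count_motifs("GGGAA")
        assert counts["GGGA"] == 1 and counts["GGAA"] == 1 and total == 2

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(dna)
    def test_matches_naive_scan(self, seq):
        _, total = count_motifs(seq)
        assert total == naive_scan(seq)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(dna)
    def test_total_invariant_under_reverse_complement(self, seq):
        # the motif set is closed under reverse complement
        assert count_motifs(seq)[1] == count_motifs(revcomp(seq))[1]

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            count_motifs("")

    def test_invalid_alphabet_rejected(self):
        with pytest.raises(ValueError):
            count_motifs("GGXA")


class TestMotifDensity:
    def test_arithmetic(self):
        assert motif_density(5, 0, 250) == pytest.approx(0.02)
        assert motif_density(0, 100, 400) == 0.0

    def test_halves_when_length_doubles(self):
        assert motif_density(4, 0, 400) == 2 * motif_density(4, 0, 800)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            motif_density(1, 100, 100)


class TestCompareMotifDensity:
    def test_identical_groups_not_significant(self):
        stat, p = compare_motif_density([1, 2, 3, 4], [1, 2, 3, 4])
        assert p > 0.9

    def test_fully_separated_small_groups_match_enumeration(self):
        # U = 0 for {1,2,3} vs {10,20,30}: the most extreme of the
        # C(6,3) = 20 rank assignments, two-sided exact p = 2/20
        stat, p = compare_motif_density([1, 2, 3], [10, 20, 30])
        assert stat == 0.0
        assert p == pytest.approx(0.1)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_motif_density([], [1.0])


class TestClassification:
    def test_identical_counts_no_calls(self, rng):
        counts = rng.poisson(300, size=(200, 2)).astype(np.int64)
        cols = pd.MultiIndex.from_product([[0.0, 2.0], [1, 2]],
                                          names=["timepoint", "replicate"])
        atac = pd.DataFrame(np.hstack([counts, counts]), columns=cols)
        peaks = pd.DataFrame({"chrom": "chrS", "start": np.arange(200) * 1000,
                              "end": np.arange(200) * 1000 + 400})
        res = classify_accessibility(PeakSet(peaks=peaks, atac=atac), 0.0, 2.0)
        assert not ((res["class"] == "decreased") | (res["class"] == "increased")).any()

    def test_classes_partition_all_peaks(self, small_config):
        ps = simulate_peaks(small_config)
        res = classify_accessibility(ps, 0.0, 2.0)
        assert res["class"].isin(["decreased", "increased", "unchanged", "other"]).all()
        assert len(res) == len(ps)

    def test_class_rules_respected(self, small_config):
        ps = simulate_peaks(small_config)
        res = classify_accessibility(ps, 0.0, 2.0, alpha=0.01)
        dec = res[res["class"] == "decreased"]
        assert ((dec["p_adjusted"] < 0.01) & (dec["log2_fold_change"] < 0)).all()
        unch = res[res["class"] == "unchanged"]
        assert ((unch["p_adjusted"] > 0.05) & (unch["log2_fold_change"].abs() <= 0.2)).all()

    def test_missing_timepoint_rejected(self, small_config):
        ps = simulate_peaks(small_config)
        with pytest.raises(ValueError):
            classify_accessibility(ps, 0.0, 9.0)


class TestMetaprofile:
    def test_constant_track_gives_flat_profile(self):
        prof = metaprofile(np.full(10_000, 7.0), [20_000, 50_000], flank=1000,
                           n_bins=100, bin_size=10)
        assert np.allclose(prof.mean_signal, 7.0)

    def test_two_centers_average_hand_computed(self):
        track = np.arange(1000, dtype=float)
        prof = metaprofile(track, [300, 700], flank=100, n_bins=10, bin_size=1)
        # window value at offset o is the two-bp midpoint (track[c+o] +
        # track[c+o+1]) / 2; the profile averages both windows per bin
        w = np.arange(-100, 100)
        expected = ((300.5 + w) + (700.5 + w)) / 2
        assert np.allclose(prof.mean_signal, expected.reshape(10, 20).mean(axis=1))

    def test_symmetric_signal_gives_symmetric_profile(self):
        track = np.zeros(2001)
        center = 1000
        track[center - 500 : center + 501] = 500 - np.abs(np.arange(-500, 501))
        prof = metaprofile(track, [center], flank=500, n_bins=50, bin_size=1)
        assert np.allclose(prof.mean_signal, prof.mean_signal[::-1], atol=1e-9)

    def test_linearity(self, rng):
        s1, s2 = rng.random(5000), rng.random(5000)
        centers = [1000, 2500, 4000]
        f = lambda s: metaprofile(s, centers, flank=200, n_bins=20, bin_size=1).mean_signal
        assert np.allclose(f(3 * s1 + 2 * s2), 3 * f(s1) + 2 * f(s2))

    def test_empty_centers_rejected(self):
        with pytest.raises(ValueError):
            metaprofile(np.zeros(100), [], flank=10, n_bins=2)


class TestSummitCentering:
    def test_summit_at_midpoint_gives_zero_offset(self):
        atac = pd.DataFrame({"chrom": "chrS", "start": [1000], "end": [1400],
                             "class": ["decreased"]})
        tf = pd.DataFrame({"chrom": ["chrS"], "summit": [1200]})
        out = summit_centering(tf, atac)
        assert out.loc["decreased", "median_offset"] == 0.0

    def test_decreased_peaks_more_centered_by_construction(self, small_config):
        ps = simulate_peaks(small_config)
        atac = ps.peaks[["chrom", "start", "end"]].copy()
        atac["class"] = ps.peaks["class_true"]
        out = summit_centering(ps.peaks[["chrom", "summit"]], atac)
        assert out.loc["decreased", "median_offset"] < out.loc["unchanged", "median_offset"]

    def test_no_overlap_flagged_not_raised(self):
        atac = pd.DataFrame({"chrom": "chrS", "start": [0], "end": [100], "class": ["x"]})
        tf = pd.DataFrame({"chrom": ["chrS"], "summit": [5000]})
        out = summit_centering(tf, atac)
        assert out.loc["x", "n_pairs"] == 0 and np.isnan(out.loc["x", "median_offset"])
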