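"""Element classification, super-enhancers, association and linking."""

import numpy as np
import pandas as pd
import pytest

from tikp.datatypes import GeneModel, SimulationConfig
from tikp.enhancers import (
    call_super_enhancers,
    change_fraction_by_class,
    classify_elements,
    enhancer_density_by_gene_class,
    link_enhancers,
    se_association,
)
from tikp.simulate import simulate_regulatory_landscape, simulate_timecourse


@pytest.fixture
def toy_genes():
    return GeneModel(pd.DataFrame({
        "gene": ["gA", "gB"],
        "chrom": "chrS",
        "tss": [100_000, 500_000],
        "strand": ["+", "-"],
        "gene_class": ["fast_repressed", "non_de"],
    }))


class TestClassifyElements:
    def test_tss_site_with_mark_is_promoter(self, toy_genes):
        atac = pd.DataFrame({"chrom": "chrS", "start": [99_900], "end": [100_300]})
        h3k = atac.copy()
        out = classify_elements(h3k, atac, toy_genes)
        assert out["element_kind"].iloc[0] == "active_promoter"

    def test_distal_site_with_mark_is_enhancer(self, toy_genes):
        atac = pd.DataFrame({"chrom": "chrS", "start": [150_000], "end": [150_400]})
        out = classify_elements(atac.copy(), atac, toy_genes)
        assert out["element_kind"].iloc[0] == "active_enhancer"

    def test_unmarked_site_stays_unclassified(self, toy_genes):
        atac = pd.DataFrame({"chrom": "chrS", "start": [99_900], "end": [100_300]})
        h3k = pd.DataFrame({"chrom": ["chrS"], "start": [900_000], "end": [900_400]})
        out = classify_elements(h3k, atac, toy_genes)
        assert out["element_kind"].iloc[0] == "unclassified"


class TestSuperEnhancers:
    def _enh(self, starts, signals):
        starts = np.asarray(starts)
        return pd.DataFrame({"chrom": "chrS", "start": starts, "end": starts + 400,
                             "signal": signals})

    def test_nearby_enhancers_stitched(self):
        out = call_super_enhancers(self._enh([0, 5000, 100_000], [10, 10, 10]))
        assert len(out) == 2
        assert out.iloc[0]["n_enhancers"] == 2

    def test_equal_signals_give_no_superenhancers(self):
        out = call_super_enhancers(self._enh(np.arange(10) * 50_000, np.full(10, 5.0)))
        assert out["is_super"].sum() == 0

    def test_planted_top5_recovered_exactly(self, rng):
        n = 100
        sig = np.concatenate([rng.uniform(80, 120, 95), rng.uniform(900, 1100, 5)])
        enh = self._enh(np.arange(n) * 50_000, sig)
        out = call_super_enhancers(enh)
        called = set(out.loc[out["is_super"], "start"])
        assert called == set(enh.nlargest(5, "signal")["start"])
        # brute-force tangent scan: slide a slope-1 line over every
        # point of the scaled rank-signal curve; the tangent point (the
        # lowest intercept) is the cutoff and SEs lie strictly above it
        y = np.sort(sig)
        ys = (y - y[0]) / (y[-1] - y[0])
        xs = np.linspace(0, 1, n)
        best = min(range(n), key=lambda i: ys[i] - xs[i])
        assert out["is_super"].sum() == np.sum(sig > y[best]) == 5

    def test_stitching_idempotent(self, rng):
        starts = np.sort(rng.choice(np.arange(0, 2_000_000, 1000), 50, replace=False))
        enh = self._enh(starts, rng.uniform(1, 100, 50))
        once = call_super_enhancers(enh)
        twice = call_super_enhancers(once[["chrom", "start", "end", "signal"]])
        assert once[["chrom", "start", "end"]].equals(twice[["chrom", "start", "end"]])

    def test_needs_three_enhancers(self):
        with pytest.raises(ValueError):
            call_super_enhancers(self._enh([0, 5000], [1, 2]))


class TestDensityAndAssociation:
    def test_gene_without_enhancers_counts_zero(self, toy_genes):
        elements = pd.DataFrame({
            "chrom": "chrS", "start": [150_000], "end": [150_400],
            "element_kind": ["active_enhancer"],
        })
        per_gene, _ = enhancer_density_by_gene_class(toy_genes, elements, window=20_000)
        assert per_gene.set_index("gene").loc["gB", "n_enhancers"] == 0

    def test_window_boundary_is_closed(self, toy_genes):
        # midpoint exactly at TSS + window must be included
        mid = 100_000 + 20_000
        elements = pd.DataFrame({
            "chrom": "chrS", "start": [mid - 200], "end": [mid + 200],
            "element_kind": ["active_enhancer"],
        })
        per_gene, _ = enhancer_density_by_gene_class(toy_genes, elements, window=20_000)
        assert per_gene.set_index("gene").loc["gA", "n_enhancers"] == 1
        beyond = elements.assign(start=elements["start"] + 2, end=elements["end"] + 2)
        per_gene2, _ = enhancer_density_by_gene_class(toy_genes, beyond, window=20_000)
        assert per_gene2.set_index("gene").loc["gA", "n_enhancers"] == 0

    def test_designed_density_bias_recovered(self):
        sim = SimulationConfig(seed=21, n_genes=1500)
        _, truth = simulate_timecourse(sim)
        land = simulate_regulatory_landscape(sim, truth)
        el = land["elements"].peaks
        classified = classify_elements(el[["chrom", "start", "end"]], el, land["genes"])
        per_gene, tests = enhancer_density_by_gene_class(land["genes"], classified)
        means = per_gene.groupby("gene_class")["n_enhancers"].mean()
        assert means["fast_repressed"] == means.max()
        assert (tests["p_adjusted"] < 0.01).all()

    def test_no_superenhancers_gives_zero_fractions(self, toy_genes):
        ses = pd.DataFrame({"chrom": [], "start": [], "end": [], "is_super": []})
        frac = se_association(toy_genes, ses, seed=0)
        assert (frac == 0).all()

    def test_blanket_superenhancer_gives_fraction_one(self, toy_genes):
        ses = pd.DataFrame({"chrom": ["chrS"], "start": [0], "end": [600_000],
                            "is_super": [True]})
        frac = se_association(toy_genes, ses, seed=0)
        assert (frac == 1).all()


class TestLinking:
    def _inputs(self, r=1.0):
        ctx = [f"c{i}" for i in range(6)]
        g = pd.DataFrame([[1.0, 2, 3, 4, 5, 6]], index=["gA"], columns=ctx)
        e_act = np.array([[1.0, 2, 3, 4, 5, 6]]) if r == 1.0 else np.zeros((1, 6))
        e = pd.DataFrame(e_act, index=["e0"], columns=ctx)
        contacts = pd.DataFrame([[10.0]], index=["e0"], columns=["gA"])
        return e, g, contacts

    def test_identical_activity_links_when_contact_passes(self):
        e, g, c = self._inputs()
        out = link_enhancers(e, g, c, [1000], [2000], c_min=1.0)
        assert out["activity_correlation"].iloc[0] == pytest.approx(1.0)
        assert bool(out["linked"].iloc[0])

    def test_zero_variance_pair_skipped_and_flagged(self):
        e, g, c = self._inputs(r=0.0)
        out = link_enhancers(e, g, c, [1000], [2000], c_min=1.0)
        assert bool(out["skipped_zero_variance"].iloc[0])
        assert not bool(out["linked"].iloc[0])

    def test_correlation_matches_direct_formula(self, rng):
        ctx = [f"c{i}" for i in range(6)]
        ev, gv = rng.random(6), rng.random(6)
        e = pd.DataFrame([ev], index=["e0"], columns=ctx)
        g = pd.DataFrame([gv], index=["gA"], columns=ctx)
        c = pd.DataFrame([[5.0]], index=["e0"], columns=["gA"])
        out = link_enhancers(e, g, c, [0], [100], c_min=0.0)
        expected = np.cov(ev, gv, ddof=0)[0, 1] / (ev.std() * gv.std())
        assert out["activity_correlation"].iloc[0] == pytest.approx(expected)

    def test_raising_thresholds_never_adds_links(self, rng):
        ctx = [f"c{i}" for i in range(8)]
        e = pd.DataFrame(rng.normal(size=(30, 8)), columns=ctx,
                         index=[f"e{i}" for i in range(30)])
        g = pd.DataFrame(rng.normal(size=(10, 8)), columns=ctx,
                         index=[f"g{i}" for i in range(10)])
        c = pd.DataFrame(rng.random((30, 10)), index=e.index, columns=g.index)
        epos = rng.integers(0, 400_000, 30)
        gpos = rng.integers(0, 400_000, 10)
        loose = link_enhancers(e, g, c, epos, gpos, r_min=0.2, c_min=0.1)
        tight = link_enhancers(e, g, c, epos, gpos, r_min=0.6, c_min=0.5)
        assert set(map(tuple, tight.loc[tight["linked"], ["element", "gene"]].values)) <= \
               set(map(tuple, loose.loc[loose["linked"], ["element", "gene"]].values))

    def test_requires_five_contexts(self):
        ctx = [f"c{i}" for i in range(4)]
        e = pd.DataFrame(np.ones((1, 4)), index=["e0"], columns=ctx)
        g = pd.DataFrame(np.ones((1, 4)), index=["gA"], columns=ctx)
        c = pd.DataFrame([[1.0]], index=["e0"], columns=["gA"])
        with pytest.raises(ValueError, match="contexts"):
            link_enhancers(e, g, c, [0], [0])


class TestChangeFractions:
    def _counts(self, n, fold, rng, depth=500.0, disp=0.001):
        cols = pd.MultiIndex.from_product([[0.0, 2.0], [1, 2]],
                                          names=["timepoint", "replicate"])
        m = np.hstack([np.full((n, 2), depth), np.full((n, 2), depth * fold)])
        lam = rng.gamma(1 / disp, m * disp)
        return pd.DataFrame(rng.poisson(lam).astype(np.int64), columns=cols)

    def test_saturated_loss_detected_everywhere(self, toy_genes, rng):
        el = pd.DataFrame({"chrom": "chrS",
                           "start": [95_000, 110_000, 495_000, 510_000],
                           "end": [95_400, 110_400, 495_400, 510_400],
                           "kind": "enhancer"})
        counts = self._counts(4, 0.5, rng)
        out = change_fraction_by_class(toy_genes, el, counts, 0.0, 2.0, seed=0)
        assert out.loc["fast_repressed", "loss_fraction"] == 1.0
        assert out.loc["non_de", "loss_fraction"] == 1.0

    def test_null_fractions_stay_small(self, toy_genes, rng):
        n = 400
        starts = np.concatenate([
            rng.integers(80_000, 120_000, n // 2),
            rng.integers(480_000, 520_000, n // 2),
        ])
        el = pd.DataFrame({"chrom": "chrS", "start": starts, "end": starts + 400,
                           "kind": "enhancer"})
        counts = self._counts(n, 1.0, rng, disp=0.05)
        out = change_fraction_by_class(toy_genes, el, counts, 0.0, 2.0, alpha=0.01, seed=0)
        assert (out["loss_fraction"] < 0.02).all()
        assert (out["gain_fraction"] < 0.02).all()

    def test_designed_loss_concentration(self):
        sim = SimulationConfig(seed=23, n_genes=1200)
        _, truth = simulate_timecourse(sim)
        land = simulate_regulatory_landscape(sim, truth)
        out = change_fraction_by_class(
            land["genes"], land["elements"].peaks, land["elements"].h3k27ac,
            0.0, 2.0, seed=23,
        )
        ratio = out.loc["fast_repressed", "loss_fraction"] / out.loc["random_control",
                                                                     "loss_fraction"]
        assert ratio >= 2.0
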