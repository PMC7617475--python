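"""Verification experiments on synthetic ground truth.

Each function runs one stage of the pipeline on data generated with
known truth and measures how well the analysis recovers the design:
kinetic-class assignment and half-response times, accessibility-
classification calibration and sensitivity, the motif statistic against
a naive scan oracle, Fisher's exact test against full enumeration,
type-I error and modulation power of the burst comparison, the
telegraph closed form against sampling, super-enhancer recovery, the
designed enhancer-association ordering, and end-to-end determinism.

Everything is seeded and runs at desk scale (seconds to a couple of
minutes per experiment on one CPU).
"""

from __future__ import annotations

import hashlib
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from ._rng import substream
from .accessibility import classify_accessibility, compare_motif_density, count_motifs
from .bursting import compare_conditions, fisher_exact, telegraph_stationary_fraction
from .datatypes import SimulationConfig, TelegraphParams
from .enhancers import (
    call_super_enhancers,
    change_fraction_by_class,
    classify_elements,
    enhancer_density_by_gene_class,
    se_association,
)
from .io import PipelineConfig
from .kinetics import call_differential_genes, cluster_kinetics, normalize_counts
from .pipeline import run_pipeline
from .simulate import (
    simulate_fish,
    simulate_peaks,
    simulate_regulatory_landscape,
    simulate_timecourse,
)

__all__ = [
    "kinetics_recovery",
    "accessibility_calibration",
    "motif_scan_agreement",
    "motif_enrichment_power",
    "fisher_enumeration_agreement",
    "burst_type_i_error",
    "modulation_detection",
    "telegraph_stationary_deviation",
    "super_enhancer_recovery",
    "enhancer_design_recovery",
    "pipeline_determinism",
]

DESIGN_T_HALF = {
    "fast_repressed": 0.75,
    "slow_repressed": 12.0,
    "activated": 3.0,
    "slow_activated": 14.5,
}


def kinetics_recovery(seed: int, n_per_class: int = 500) -> dict:
    """Full kinetics stage on four designed classes + stable background.

    Simulates ``n_per_class`` genes per kinetic class with the design
    half-response times plus a 60% non-responding background (the
    median-of-ratios normalization assumes a majority-stable gene set),
    runs normalization, per-timepoint differential calling, clustering
    and t-half estimation, and reports the adjusted Rand index against
    truth (over designed-class genes) and the per-class recovered
    t-half with its percent error.
    """
    n_genes = int(4 * n_per_class / 0.4)
    props = {c: n_per_class / n_genes for c in DESIGN_T_HALF}
    props["non_de"] = 1.0 - sum(props.values())
    sim = SimulationConfig(seed=seed, n_genes=n_genes, class_proportions=props)
    tc, truth = simulate_timecourse(sim)
    tc = normalize_counts(tc)
    de: set = set()
    for t in tc.timepoints[1:]:
        res = call_differential_genes(tc, tc.timepoints[0], t)
        de.update(res.index[res["direction"] != "ns"])
    trajs = cluster_kinetics(tc, sorted(de), k=4, seed=seed)
    labels = {g: tr.cluster_label for tr in trajs for g in tr.member_genes}
    pred = pd.Series(labels)
    designed = truth.index[truth != "non_de"].intersection(pred.index)
    ari = adjusted_rand_score(truth.loc[designed], pred.loc[designed])
    t_half = {tr.cluster_label: tr.t_half for tr in trajs if not tr.removed}
    err = {
        c: 100.0 * (t_half[c] - d) / d if c in t_half else float("nan")
        for c, d in DESIGN_T_HALF.items()
    }
    return {"ari": float(ari), "t_half": t_half, "t_half_error_pct": err}


def accessibility_calibration(seed: int, n_peaks: int = 2000) -> dict:
    """Null false-call rate and sensitivity of accessibility classification.

    Null: no true changes; reports the fraction of decreased+increased
    calls at padj < 0.01. Signal: 20% of peaks truly lose accessibility
    four-fold; reports the fraction of true-decreased peaks recovered.
    """
    null_cfg = SimulationConfig(
        seed=seed, n_peaks=n_peaks, frac_decreased=1e-9, frac_increased=0.0
    )
    res = classify_accessibility(simulate_peaks(null_cfg), 0.0, 2.0)
    cls = res["class"].to_numpy()
    false_rate = float(np.mean((cls == "decreased") | (cls == "increased")))

    sig_cfg = SimulationConfig(
        seed=seed + 1, n_peaks=n_peaks, frac_decreased=0.2, frac_increased=0.0
    )
    ps = simulate_peaks(sig_cfg)
    res = classify_accessibility(ps, 0.0, 2.0)
    truth = ps.peaks["class_true"].to_numpy()
    dec = truth == "decreased"
    sensitivity = float(np.mean(res["class"].to_numpy()[dec] == "decreased"))
    return {"null_false_call_rate": false_rate, "sensitivity": sensitivity}


def _naive_motif_scan(seq: str, motifs) -> int:
    """Position-by-position O(L * |m|) oracle for overlapping matches."""
    total = 0
    for m in motifs:
        k = len(m)
        for i in range(len(seq) - k + 1):
            if seq[i : i + k] == m:
                total += 1
    return total


def motif_scan_agreement(seed: int, n_sequences: int = 1000, length: int = 1000) -> int:
    """Number of random sequences where count_motifs differs from the oracle."""
    rng = substream(seed, "motif-check")
    mismatches = 0
    for _ in range(n_sequences):
        seq = "".join(rng.choice(list("ACGTN"), size=length, p=[0.24, 0.24, 0.24, 0.24, 0.04]))
        _, total = count_motifs(seq)
        if total != _naive_motif_scan(seq, ("GGAA", "TTCC", "GGGA", "TCCC")):
            mismatches += 1
    return mismatches


def motif_enrichment_power(seed: int, n_repeats: int = 100, n_peaks: int = 2000) -> dict:
    """Rank-sum rejection rates under positive and zero motif coupling."""
    reject = {"positive_coupling": 0, "zero_coupling": 0}
    for r in range(n_repeats):
        for key, effect in (("positive_coupling", 1.0), ("zero_coupling", 0.0)):
            cfg = SimulationConfig(
                seed=seed + 7919 * r + (0 if effect else 104729),
                n_peaks=n_peaks,
                motif_density_effect=effect,
            )
            ps = simulate_peaks(cfg)
            dens = ps.peaks["motif_count"].to_numpy() / ps.lengths
            ct = ps.peaks["class_true"].to_numpy()
            _, p = compare_motif_density(dens[ct == "decreased"], dens[ct == "unchanged"])
            reject[key] += p < 0.01
    return {k: v / n_repeats for k, v in reject.items()}


def fisher_enumeration_agreement(max_n: int = 30) -> float:
    """Worst |p - p_exact| over all 2x2 tables with total count <= max_n.

    The oracle enumerates every admissible table with the observed
    margins in exact rational arithmetic.
    """

    def exact_p(a, b, c, d):
        r1, r2, c1 = a + b, c + d, a + c
        denom = comb(r1 + r2, c1) if r1 + r2 else 1
        probs = [
            Fraction(comb(r1, k) * comb(r2, c1 - k), denom)
            for k in range(max(0, c1 - r2), min(r1, c1) + 1)
        ]
        p_obs = probs[a - max(0, c1 - r2)]
        return float(sum(p for p in probs if p <= p_obs))

    worst = 0.0
    for n in range(max_n + 1):
        for a in range(n + 1):
            for b in range(n + 1 - a):
                for c in range(n + 1 - a - b):
                    d = n - a - b - c
                    worst = max(worst, abs(fisher_exact([[a, b], [c, d]]) - exact_p(a, b, c, d)))
    return worst


def burst_type_i_error(seed: int, n_repeats: int = 1000, n_cells: int = 700) -> float:
    """Fisher rejection rate at alpha = 0.05 under the null telegraph model."""
    params = TelegraphParams(k_on=1.0, k_off=4.0)
    rejected = 0
    for r in range(n_repeats):
        t0, t1 = simulate_fish(params, params, n_cells, seed=seed + r)
        rejected += compare_conditions(t0, t1)["fisher_p"] < 0.05
    return rejected / n_repeats


def modulation_detection(seed: int, n_repeats: int = 200, n_cells: int = 700) -> dict:
    """Detection rates of frequency-only and size-only modulation.

    Frequency scenario: induction halves k_on, size distribution
    unchanged. Size scenario: k_on unchanged, burst intensity doubled.
    """
    base = TelegraphParams(k_on=1.0, k_off=4.0)
    freq = TelegraphParams(k_on=0.5, k_off=4.0)
    size = TelegraphParams(k_on=1.0, k_off=4.0, burst_intensity_mean=20.0)
    hits = {"frequency": 0, "size": 0}
    for r in range(n_repeats):
        t0, t1 = simulate_fish(base, freq, n_cells, seed=seed + r)
        hits["frequency"] += compare_conditions(t0, t1)["modulation"] == "frequency"
        t0, t1 = simulate_fish(base, size, n_cells, seed=seed + 60013 + r)
        hits["size"] += compare_conditions(t0, t1)["modulation"] == "size"
    return {k: v / n_repeats for k, v in hits.items()}


def telegraph_stationary_deviation(seed: int, n_alleles: int = 10_000) -> float:
    """Worst |empirical - k_on/(k_on+k_off)| in SE units over 5 parameter sets."""
    param_sets = [
        TelegraphParams(k_on=1.0, k_off=4.0),
        TelegraphParams(k_on=0.5, k_off=4.0),
        TelegraphParams(k_on=2.0, k_off=2.0),
        TelegraphParams(k_on=3.0, k_off=1.0),
        TelegraphParams(k_on=0.2, k_off=1.8),
    ]
    worst = 0.0
    for i, pars in enumerate(param_sets):
        t0, _ = simulate_fish(pars, pars, n_alleles // 2, seed=seed + i)
        p = telegraph_stationary_fraction(pars)
        emp = t0.table["burst"].mean()
        se = np.sqrt(p * (1 - p) / n_alleles)
        worst = max(worst, abs(emp - p) / se)
    return worst


def super_enhancer_recovery(seed: int, n_regions: int = 100, n_planted: int = 5) -> dict:
    """Elbow caller on a toy with planted ten-fold high-signal regions."""
    rng = substream(seed, "se-toy")
    signal = np.concatenate(
        [rng.uniform(80, 120, n_regions - n_planted), rng.uniform(900, 1100, n_planted)]
    )
    df = pd.DataFrame(
        {
            "chrom": "chrS",
            "start": np.arange(n_regions) * 50_000,
            "end": np.arange(n_regions) * 50_000 + 400,
            "signal": signal,
        }
    )
    ses = call_super_enhancers(df)
    called = set(ses.loc[ses["is_super"], "start"])
    planted = set(df.nlargest(n_planted, "signal")["start"])
    return {"n_called": int(ses["is_super"].sum()), "exact_recovery": called == planted}


def enhancer_design_recovery(seed: int, n_genes: int = 1500) -> dict:
    """Enhancer-density ordering and loss-fraction ratio on the designed landscape."""
    sim = SimulationConfig(seed=seed, n_genes=n_genes)
    _, truth = simulate_timecourse(sim)
    land = simulate_regulatory_landscape(sim, truth)
    gm = land["genes"]
    el = land["elements"].peaks
    classified = classify_elements(el[["chrom", "start", "end"]], el, gm)
    per_gene, tests = enhancer_density_by_gene_class(gm, classified)
    means = per_gene.groupby("gene_class")["n_enhancers"].mean()
    fast_greatest = means["fast_repressed"] == means.max()
    enh = classified[classified["element_kind"] == "active_enhancer"]
    ses = call_super_enhancers(enh.assign(signal=el.loc[enh.index, "signal"]))
    se_frac = se_association(gm, ses, seed=seed)
    change = change_fraction_by_class(
        gm, el, land["elements"].h3k27ac, 0.0, 2.0, seed=seed
    )
    loss_ratio = (
        change.loc["fast_repressed", "loss_fraction"]
        / change.loc["random_control", "loss_fraction"]
    )
    return {
        "density_fast_greatest": bool(fast_greatest),
        "density_max_padj": float(tests["p_adjusted"].max()),
        "se_fraction_fast_greatest": bool(
            se_frac["fast_repressed"] == se_frac.max()
        ),
        "loss_ratio_vs_control": float(loss_ratio),
    }


def pipeline_determinism(seed: int, base_dir: str = "scratch/determinism") -> bool:
    """True iff two same-seed pipeline runs are byte-identical file by file."""
    outs = []
    for tag in ("a", "b"):
        cfg = PipelineConfig(
            seed=seed, out_dir=f"{base_dir}_{tag}", n_genes=400, n_peaks=600, n_cells=200
        )
        outs.append(run_pipeline(cfg))

    def digest(d):
        return {
            f.name: hashlib.sha256(f.read_bytes()).hexdigest() for f in sorted(d.iterdir())
        }

    return digest(outs[0]) == digest(outs[1])
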