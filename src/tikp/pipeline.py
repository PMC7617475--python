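"""End-to-end pipeline driver.

Chains simulate -> kinetics -> accessibility -> enhancers -> bursting
on fully synthetic inputs with known ground truth, writing per-stage
output files, a manifest (stages, seed, thresholds, config hash) and a
JSON summary report. Re-running with the same configuration produces
byte-identical outputs: all randomness flows from the single config
seed through named substreams and no stage touches global random state.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .accessibility import (
    classify_accessibility,
    compare_motif_density,
    metaprofile,
    summit_centering,
)
from .bursting import compare_conditions
from .datatypes import SimulationConfig
from .enhancers import (
    call_super_enhancers,
    change_fraction_by_class,
    classify_elements,
    enhancer_density_by_gene_class,
    link_enhancers,
    se_association,
)
from .io import (
    PipelineConfig,
    config_hash,
    write_bed,
    write_fish,
    write_peakset,
    write_table,
    write_timecourse,
)
from .kinetics import call_differential_genes, cluster_kinetics, normalize_counts
from .simulate import (
    simulate_fish,
    simulate_peaks,
    simulate_regulatory_landscape,
    simulate_timecourse,
)

__all__ = ["run_pipeline"]

log = logging.getLogger("tikp")


def _coverage_track(starts, ends, values, chrom_length: int, bin_size: int = 10) -> np.ndarray:
    """Binned coverage: each interval contributes its value over its bins."""
    n_bins = int(np.ceil(chrom_length / bin_size))
    track = np.zeros(n_bins)
    for s, e, v in zip(starts, ends, values):
        track[s // bin_size : max(s // bin_size + 1, -(-e // bin_size))] += v
    return track


def _round_floats(obj, ndigits: int = 6):
    """Coerce numpy scalars and round floats so report bytes are stable."""
    if isinstance(obj, (float, np.floating)):
        # significant digits, not decimals: keeps small p-values meaningful
        return float(f"{float(obj):.{ndigits}g}")
    if isinstance(obj, (bool, np.bool_)):
        return bool(obj)
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, dict):
        return {_round_floats(k, ndigits): _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, np.ndarray)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run all enabled stages; return the report directory.

    Any stage failure aborts with the stage name and the underlying
    cause. The manifest lists every enabled stage with its status and
    in/out counts at each filter.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(cfg)
    sim = SimulationConfig(seed=cfg.seed, n_genes=cfg.n_genes, n_peaks=cfg.n_peaks,
                           n_cells=cfg.n_cells)
    report: dict = {"config_hash": chash, "seed": cfg.seed}
    cfg_record = asdict(cfg)
    cfg_record.pop("out_dir")  # location-independent: identical runs stay byte-identical
    manifest: dict = {
        "tool": "tikp",
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": chash,
        "config": cfg_record,
        "stages": {},
    }
    state: dict = {}

    stage_fns = {
        "simulate": _stage_simulate,
        "kinetics": _stage_kinetics,
        "accessibility": _stage_accessibility,
        "enhancers": _stage_enhancers,
        "bursting": _stage_bursting,
    }
    for name in cfg.stages:
        if name not in stage_fns:
            raise ValueError(f"unknown stage {name!r}")
        log.info("stage %s: starting", name)
        try:
            section = stage_fns[name](cfg, sim, state, out, chash)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        report[name] = section
        manifest["stages"][name] = {"status": "ok"}
        log.info("stage %s: ok", name)

    report = _round_floats(report)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(out / "manifest.json", "w") as fh:
        json.dump(_round_floats(manifest), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(cfg, sim, state, out, chash):
    tc, truth = simulate_timecourse(sim)
    peaks = simulate_peaks(sim)
    land = simulate_regulatory_landscape(sim, truth)
    pars = sim.telegraph_params_by_condition
    fish0, fish1 = simulate_fish(pars["uninduced"], pars["induced"], sim.n_cells, sim.seed)

    state.update(tc=tc, truth=truth, peaks=peaks, land=land, fish0=fish0, fish1=fish1)
    write_timecourse(tc, out / "counts.tsv", "simulate", chash)
    write_table(truth.to_frame(), out / "truth_classes.tsv", "simulate", chash)
    write_peakset(peaks, out / "peaks", "simulate", chash)
    write_fish(fish0, out / "fish_uninduced.csv", "simulate", chash)
    write_fish(fish1, out / "fish_induced.csv", "simulate", chash)
    return {
        "n_genes": len(tc.genes),
        "n_peaks": len(peaks),
        "n_cells": sim.n_cells,
        "class_counts": truth.value_counts().sort_index().to_dict(),
    }


def _stage_kinetics(cfg, sim, state, out, chash):
    tc = normalize_counts(state["tc"])
    state["tc"] = tc
    tps = tc.timepoints
    de_union: set = set()
    per_tp = {}
    for t in tps[1:]:
        res = call_differential_genes(tc, tps[0], t, alpha=cfg.de_alpha,
                                      min_abs_log2fc=cfg.min_abs_log2fc)
        hits = res.index[res["direction"] != "ns"]
        per_tp[float(t)] = len(hits)
        de_union.update(hits)
        if t == tps[-1]:
            write_table(res, out / "de_final_timepoint.tsv", "kinetics", chash)
    de_genes = sorted(de_union)
    log.info("kinetics: %d/%d genes differential in at least one timepoint",
             len(de_genes), len(tc.genes))

    trajs = cluster_kinetics(tc, de_genes, k=cfg.n_clusters, seed=cfg.seed,
                             monotonicity_threshold=cfg.monotonicity_threshold)
    state["trajectories"] = trajs
    state["de_genes"] = de_genes

    members = pd.DataFrame(
        [(g, i, tr.cluster_label) for i, tr in enumerate(trajs) for g in tr.member_genes],
        columns=["gene", "cluster", "cluster_label"],
    )
    write_table(members, out / "cluster_membership.tsv", "kinetics", chash, index=False)
    traj_rows = []
    for i, tr in enumerate(trajs):
        for t, m, lo, hi in zip(tc.timepoints, tr.mean_scaled, tr.ci95_low, tr.ci95_high):
            traj_rows.append((i, tr.cluster_label, t, m, lo, hi))
    write_table(
        pd.DataFrame(traj_rows, columns=["cluster", "label", "timepoint", "mean_scaled",
                                         "ci95_low", "ci95_high"]),
        out / "cluster_trajectories.tsv", "kinetics", chash, index=False,
    )
    return {
        "n_differential": len(de_genes),
        "n_differential_by_timepoint": per_tp,
        "cluster_sizes": {tr.cluster_label: len(tr.member_genes) for tr in trajs},
        "t_half_hours": {tr.cluster_label: tr.t_half for tr in trajs if not tr.removed},
        "removed_clusters": sum(tr.removed for tr in trajs),
    }


def _stage_accessibility(cfg, sim, state, out, chash):
    peaks = state["peaks"]
    res = classify_accessibility(peaks, cfg.access_t_ref, cfg.access_t, alpha=cfg.access_alpha)
    state["access"] = res
    bed = peaks.peaks[["chrom", "start", "end"]].copy()
    bed["name"] = res["class"].to_numpy()
    with np.errstate(divide="ignore"):
        bed["score"] = np.round(-np.log10(np.maximum(res["p_adjusted"].to_numpy(), 1e-300)), 3)
    write_bed(bed, out / "accessibility_classes.bed", "accessibility", chash)

    dens = peaks.peaks["motif_count"].to_numpy() / peaks.lengths
    cls = res["class"].to_numpy()
    stat, pval = compare_motif_density(dens[cls == "decreased"], dens[cls == "unchanged"])

    # metaprofiles of accessibility before/after induction around peak midpoints
    bin_size = 10
    t_axis = peaks.atac.columns.get_level_values("timepoint")
    cov0 = peaks.atac.loc[:, t_axis == cfg.access_t_ref].mean(axis=1).to_numpy()
    cov1 = peaks.atac.loc[:, t_axis == cfg.access_t].mean(axis=1).to_numpy()
    p = peaks.peaks
    profiles = {}
    for label in ("decreased", "unchanged"):
        sel = cls == label
        if not sel.any():
            continue
        centers = peaks.midpoints[sel]
        track0 = _coverage_track(p["start"].to_numpy()[sel], p["end"].to_numpy()[sel],
                                 cov0[sel], sim.chrom_length, bin_size)
        track1 = _coverage_track(p["start"].to_numpy()[sel], p["end"].to_numpy()[sel],
                                 cov1[sel], sim.chrom_length, bin_size)
        prof0 = metaprofile(track0, centers, flank=cfg.flank, n_bins=cfg.n_bins,
                            bin_size=bin_size)
        prof1 = metaprofile(track1, centers, flank=cfg.flank, n_bins=cfg.n_bins,
                            bin_size=bin_size)
        df = prof0.to_frame().rename(columns={"mean_signal": "mean_t_ref"})
        df["mean_t"] = prof1.mean_signal
        write_table(df, out / f"metaprofile_{label}.tsv", "accessibility", chash, index=False)
        mid = slice(cfg.n_bins // 2 - 5, cfg.n_bins // 2 + 5)
        profiles[label] = {
            "center_signal_t_ref": float(prof0.mean_signal[mid].mean()),
            "center_signal_t": float(prof1.mean_signal[mid].mean()),
        }

    tf = p[["chrom", "summit"]]
    atac_cls = p[["chrom", "start", "end"]].copy()
    atac_cls["class"] = cls
    offsets = summit_centering(tf, atac_cls)

    counts = pd.Series(cls).value_counts().to_dict()
    return {
        "class_counts": counts,
        "class_fractions": {k: v / len(cls) for k, v in counts.items()},
        "motif_density_ranksum": {"statistic": stat, "p_value": pval},
        "metaprofile_center": profiles,
        "summit_median_offset_bp": offsets["median_offset"].to_dict(),
        "category_by_class": p.groupby(cls)["category"].value_counts().unstack(fill_value=0)
                              .to_dict("index"),
    }


def _stage_enhancers(cfg, sim, state, out, chash):
    land = state["land"]
    gm = land["genes"]
    el = land["elements"].peaks
    h3k = land["elements"].h3k27ac

    # element-kind classification from H3K27ac overlap + TSS distance
    h3k_bed = el[["chrom", "start", "end"]]
    classified = classify_elements(h3k_bed, el, gm, promoter_window=cfg.promoter_window)
    state["elements"] = classified
    write_bed(
        classified.assign(name=classified["element_kind"])[["chrom", "start", "end", "name"]],
        out / "elements.bed", "enhancers", chash,
    )

    enh = classified[classified["element_kind"] == "active_enhancer"]
    ses = call_super_enhancers(enh.assign(signal=el.loc[enh.index, "signal"]),
                               stitch_distance=cfg.stitch_distance)
    write_table(ses, out / "super_enhancers.tsv", "enhancers", chash, index=False)

    per_gene, dens_tests = enhancer_density_by_gene_class(gm, classified,
                                                          window=cfg.enhancer_window)
    write_table(per_gene, out / "enhancer_density.tsv", "enhancers", chash, index=False)
    se_frac = se_association(gm, ses, window=cfg.se_window, seed=cfg.seed)

    change = change_fraction_by_class(
        gm, el, h3k, sim.access_timepoints[0], sim.access_timepoints[-1],
        alpha=cfg.access_alpha, min_fc=cfg.min_fc, window=cfg.enhancer_window, seed=cfg.seed,
    )
    write_table(change, out / "change_fractions.tsv", "enhancers", chash)

    emid = (el["start"].to_numpy() + el["end"].to_numpy()) // 2
    links = link_enhancers(
        land["element_activity"], land["gene_activity"], land["contacts"],
        emid, gm.genes["tss"].to_numpy(), r_min=cfg.r_min,
    )
    write_table(links, out / "enhancer_gene_links.tsv", "enhancers", chash, index=False)
    linked = links[links["linked"]]
    links_per_class = (
        linked.merge(gm.genes[["gene", "gene_class"]], on="gene")
        .groupby("gene_class")["element"].count()
        .reindex(pd.unique(gm.genes["gene_class"]), fill_value=0)
    )
    n_per_class = gm.genes["gene_class"].value_counts()

    return {
        "n_elements": len(classified),
        "element_kind_counts": classified["element_kind"].value_counts().to_dict(),
        "n_stitched_regions": len(ses),
        "n_super_enhancers": int(ses["is_super"].sum()),
        "enhancer_density_mean": per_gene.groupby("gene_class")["n_enhancers"].mean().to_dict(),
        "enhancer_density_tests": dens_tests.to_dict("records"),
        "se_association_fraction": se_frac.to_dict(),
        "change_fractions": change.to_dict("index"),
        "links_per_gene_by_class": (links_per_class / n_per_class).to_dict(),
    }


def _stage_bursting(cfg, sim, state, out, chash):
    rep = compare_conditions(state["fish0"], state["fish1"],
                             alpha=cfg.burst_alpha, size_test=cfg.size_test)
    write_table(pd.DataFrame([rep]), out / "burst_comparison.tsv", "bursting", chash,
                index=False)
    return rep
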