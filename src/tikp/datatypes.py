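"""Core data containers.

Count matrices and tables are thin dataclass wrappers around pandas
objects; genomic coordinates are 0-based half-open (BED convention)
everywhere, and midpoints are ``(start + end) // 2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Kinetic gene classes, in the order used for reporting.
GENE_CLASSES = (
    "fast_repressed",
    "slow_repressed",
    "activated",
    "slow_activated",
)

#: Genomic categories for accessible sites, in precedence order.
PEAK_CATEGORIES = ("CTCF", "promoter", "intragenic", "intergenic")

#: Accessibility classes.
ACCESS_CLASSES = ("decreased", "increased", "unchanged", "other")


@dataclass
class TimeCourseMatrix:
    """Per-gene counts over ordered timepoints with replicates.

    ``counts`` is genes x samples with a 2-level column MultiIndex
    ``(timepoint_hours, replicate)``; timepoints must be strictly
    increasing along the columns.
    """

    counts: pd.DataFrame
    size_factors: pd.Series | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.counts.columns, pd.MultiIndex):
            raise ValueError("counts columns must be a (timepoint, replicate) MultiIndex")
        tps = self.timepoints
        if np.any(np.diff(tps) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if self.size_factors is not None and (self.size_factors <= 0).any():
            raise ValueError("size factors must be positive")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def timepoints(self) -> np.ndarray:
        return np.array(sorted(self.counts.columns.unique(level=0), key=float), dtype=float)

    def replicates_at(self, t: float) -> int:
        return int((self.counts.columns.get_level_values(0) == t).sum())

    def counts_at(self, t: float) -> pd.DataFrame:
        """Raw counts for one timepoint (genes x replicates)."""
        sel = self.counts.columns.get_level_values(0) == t
        if not sel.any():
            raise KeyError(f"timepoint {t} not present")
        return self.counts.loc[:, sel]

    def size_factors_at(self, t: float) -> np.ndarray:
        if self.size_factors is None:
            raise ValueError("size factors not computed; call normalize_counts first")
        sel = self.counts.columns.get_level_values(0) == t
        return self.size_factors.to_numpy()[np.asarray(sel)]


@dataclass
class PeakSet:
    """Genomic intervals with per-timepoint signal and motif counts.

    ``peaks`` holds one row per interval with at least ``chrom``,
    ``start``, ``end`` and optionally ``category`` (CTCF/promoter/
    intragenic/intergenic), ``kind`` (promoter/enhancer element),
    ``motif_count``, ``summit`` and simulation truth columns.
    ``atac`` / ``h3k27ac`` are peak x sample count matrices with the
    same (timepoint, replicate) column convention as TimeCourseMatrix.
    """

    peaks: pd.DataFrame
    atac: pd.DataFrame | None = None
    h3k27ac: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        p = self.peaks
        for col in ("chrom", "start", "end"):
            if col not in p.columns:
                raise ValueError(f"peaks table missing column {col!r}")
        if (p["start"] >= p["end"]).any():
            raise ValueError("peak intervals must satisfy start < end")

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def midpoints(self) -> np.ndarray:
        return ((self.peaks["start"].to_numpy() + self.peaks["end"].to_numpy()) // 2)

    @property
    def lengths(self) -> np.ndarray:
        return self.peaks["end"].to_numpy() - self.peaks["start"].to_numpy()


@dataclass
class GeneModel:
    """TSS-level gene annotation with kinetic class labels."""

    genes: pd.DataFrame  # columns: gene, chrom, tss, strand, gene_class

    def __post_init__(self) -> None:
        for col in ("gene", "chrom", "tss", "strand"):
            if col not in self.genes.columns:
                raise ValueError(f"gene table missing column {col!r}")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class TelegraphParams:
    """Two-state (telegraph) promoter model parameters.

    Rates are per hour; the stationary active probability is
    k_on / (k_on + k_off). Spot features of bursting alleles are drawn
    as Normal(mean, noise_sd) clipped at zero.
    """

    k_on: float
    k_off: float
    burst_intensity_mean: float = 10.0
    burst_radius_mean: float = 2.0
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.k_on < 0 or self.k_off < 0:
            raise ValueError("telegraph rates must be non-negative")
        if self.burst_intensity_mean <= 0 or self.burst_radius_mean <= 0:
            raise ValueError("feature means must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class FishTable:
    """Allele-level smFISH spot table (two alleles per cell).

    CellProfiler feature names are preserved as column names; intensity
    and radius are NaN for non-bursting alleles.
    """

    table: pd.DataFrame  # cell_id, allele, burst, Intensity_MaxIntensity, AreaShape_MeanRadius
    condition: str = ""
    gene: str = ""

    REQUIRED = ("cell_id", "allele", "burst", "Intensity_MaxIntensity", "AreaShape_MeanRadius")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValueError(f"FISH table missing column {col!r}")
        per_cell = self.table.groupby("cell_id")["allele"].count()
        if (per_cell != 2).any():
            bad = per_cell.index[per_cell != 2][0]
            raise ValueError(f"cell {bad!r} does not have exactly 2 allele rows")

    def __len__(self) -> int:
        return len(self.table)


# Most genes do not respond to induction of one TF; a majority-stable
# background is also what median-of-ratios normalization assumes.
_DEFAULT_PROPORTIONS = {
    "fast_repressed": 0.08,
    "slow_repressed": 0.12,
    "activated": 0.05,
    "slow_activated": 0.08,
    "non_monotonic": 0.03,
    "non_de": 0.64,
}

_DEFAULT_T_HALF = {
    "fast_repressed": 0.75,
    "slow_repressed": 12.0,
    "activated": 3.0,
    "slow_activated": 14.5,
}


def _default_telegraph() -> dict:
    # Induction halves the on-rate and leaves burst size untouched:
    # frequency modulation with unchanged intensity distribution.
    return {
        "uninduced": TelegraphParams(k_on=1.0, k_off=4.0),
        "induced": TelegraphParams(k_on=0.5, k_off=4.0),
    }


@dataclass
class SimulationConfig:
    """Ground-truth design of the synthetic study.

    Defaults encode the study conditions: duplicate libraries over a
    24 h time course, half-response times of 45 min / 12 h / 3 h /
    14.5 h for the four kinetic classes, 12.7% / 3.4% of accessible
    sites losing / gaining accessibility within 2 h, motif-coupled loss
    probability, faster acetylation loss at enhancers than promoters,
    and telegraph bursting whose frequency (not size) drops on
    induction.
    """

    seed: int = 0
    n_genes: int = 2000
    class_proportions: dict = field(default_factory=lambda: dict(_DEFAULT_PROPORTIONS))
    t_half_by_class: dict = field(default_factory=lambda: dict(_DEFAULT_T_HALF))
    timepoints: tuple = (0.0, 0.5, 1.0, 2.0, 4.0, 8.0, 12.0, 16.0, 24.0)
    n_replicates: int = 2
    nb_dispersion: float = 0.05
    base_log_mean: float = 6.2  # ln scale, ~500 counts
    base_log_sd: float = 1.0
    repression_floor: float = 0.125  # 8-fold full repression / activation
    n_peaks: int = 2000
    peak_width: int = 400
    chrom: str = "chrS"
    chrom_length: int = 10_000_000
    frac_decreased: float = 0.127
    frac_increased: float = 0.034
    motif_density_effect: float = 1.0  # log-odds per motif / 100 bp
    enhancer_speedup: float = 2.0
    access_timepoints: tuple = (0.0, 0.5, 1.0, 2.0)
    access_t_half: float = 1.0
    access_depth_log_mean: float = 6.2
    access_depth_log_sd: float = 0.5
    telegraph_params_by_condition: dict = field(default_factory=_default_telegraph)
    n_cells: int = 700

    def __post_init__(self) -> None:
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions sum to {total}, expected 1")
        tps = np.asarray(self.timepoints, dtype=float)
        if tps[0] != 0 or np.any(np.diff(tps) <= 0):
            raise ValueError("timepoints must be strictly increasing and include 0")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be non-negative")
        if not 0 < self.repression_floor < 1:
            raise ValueError("repression_floor must be in (0, 1)")
        unknown = set(self.t_half_by_class) - set(self.class_proportions)
        if unknown:
            raise ValueError(f"t_half given for unknown classes: {sorted(unknown)}")
        if self.enhancer_speedup <= 0:
            raise ValueError("enhancer_speedup must be positive")
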