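"""File formats and configuration.

Plain-text formats only: BED6 for intervals, TSV for count matrices and
statistics, CSV for smFISH tables, YAML for pipeline configuration.
Every file written by a pipeline stage starts with a comment header
naming the producing stage and the configuration hash, so outputs are
traceable to the run that made them.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import FishTable, PeakSet, TimeCourseMatrix

__all__ = [
    "read_bed",
    "write_bed",
    "write_table",
    "read_table",
    "write_timecourse",
    "read_timecourse",
    "write_fish",
    "read_fish",
    "write_peakset",
    "PipelineConfig",
    "load_config",
    "config_hash",
]


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path) -> pd.DataFrame:
    """Read BED3/BED6 into a sorted interval table (0-based half-open).

    Track and comment lines are tolerated and skipped; malformed lines
    raise with their line number.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected at least 3 BED fields")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            name = parts[3] if len(parts) > 3 else "."
            score = float(parts[4]) if len(parts) > 4 and parts[4] != "." else np.nan
            strand = parts[5] if len(parts) > 5 else "."
            rows.append((chrom, start, end, name, score, strand))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])
    return df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def write_bed(df: pd.DataFrame, path, stage: str = "", cfg_hash: str = "") -> None:
    """Write a BED6 file (sorted); optional columns default to ./0/."""
    out = df.copy()
    for col, default in (("name", "."), ("score", 0), ("strand", ".")):
        if col not in out.columns:
            out[col] = default
    out = out.sort_values(["chrom", "start"], kind="mergesort")
    with open(path, "w") as fh:
        if stage:
            fh.write(f"# stage={stage} config_hash={cfg_hash}\n")
        for r in out.itertuples(index=False):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t{r.score}\t{r.strand}\n")


# ---------------------------------------------------------------------------
# TSV / CSV tables
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path, stage: str, cfg_hash: str, index: bool = True) -> None:
    """TSV with a stage/config-hash comment header."""
    with open(path, "w") as fh:
        fh.write(f"# stage={stage} config_hash={cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=index, lineterminator="\n")


def read_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def write_timecourse(tc: TimeCourseMatrix, path, stage: str = "simulate", cfg_hash: str = "") -> None:
    """Long-format counts TSV: gene, timepoint, replicate, count."""
    long = (
        tc.counts.stack(["timepoint", "replicate"], future_stack=True)
        .rename("count")
        .reset_index()
    )
    write_table(long, path, stage, cfg_hash, index=False)


def read_timecourse(path) -> TimeCourseMatrix:
    long = read_table(path)
    wide = long.pivot_table(
        index="gene", columns=["timepoint", "replicate"], values="count", aggfunc="first"
    ).astype(np.int64)
    wide = wide.sort_index(axis=1)
    return TimeCourseMatrix(counts=wide)


def write_fish(table: FishTable, path, stage: str = "simulate", cfg_hash: str = "") -> None:
    with open(path, "w") as fh:
        fh.write(f"# stage={stage} config_hash={cfg_hash} condition={table.condition}\n")
        table.table.to_csv(fh, index=False, lineterminator="\n")


def read_fish(path, condition: str = "") -> FishTable:
    df = pd.read_csv(path, comment="#")
    return FishTable(table=df, condition=condition)


def write_peakset(ps: PeakSet, prefix: Path, stage: str, cfg_hash: str) -> None:
    """BED6 (name=category/kind, score=0) plus sidecar TSVs of signals."""
    bed = ps.peaks[["chrom", "start", "end"]].copy()
    bed["name"] = ps.peaks.get("category", pd.Series(".", index=ps.peaks.index)).astype(str)
    write_bed(bed, f"{prefix}.bed", stage, cfg_hash)
    write_table(ps.peaks, f"{prefix}.peaks.tsv", stage, cfg_hash)
    if ps.atac is not None:
        write_table(ps.atac, f"{prefix}.atac.tsv", stage, cfg_hash)
    if ps.h3k27ac is not None:
        write_table(ps.h3k27ac, f"{prefix}.h3k27ac.tsv", stage, cfg_hash)


# ---------------------------------------------------------------------------
# pipeline configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Thresholds, windows and toggles for the end-to-end driver."""

    seed: int = 0
    out_dir: str = "tikp_out"
    # simulation size
    n_genes: int = 1000
    n_peaks: int = 2000
    n_cells: int = 700
    # kinetics
    de_alpha: float = 0.01
    min_abs_log2fc: float = 1.0
    n_clusters: int = 5
    monotonicity_threshold: float = 0.8
    # accessibility
    access_alpha: float = 0.01
    access_t_ref: float = 0.0
    access_t: float = 2.0
    flank: int = 1000
    n_bins: int = 100
    # regulatory elements
    promoter_window: int = 1000
    stitch_distance: int = 12_500
    enhancer_window: int = 20_000
    se_window: int = 50_000
    min_fc: float = 1.5
    r_min: float = 0.5
    # bursting
    burst_alpha: float = 0.01
    size_test: str = "student"
    # stage toggles
    stages: tuple = ("simulate", "kinetics", "accessibility", "enhancers", "bursting")

    def __post_init__(self) -> None:
        for name in ("de_alpha", "access_alpha", "burst_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.min_fc <= 1:
            raise ValueError("min_fc must exceed 1")
        if not -1 <= self.r_min <= 1:
            raise ValueError("r_min must be in [-1, 1]")
        if self.seed is None:
            raise ValueError("a seed is mandatory: every stochastic stage derives from it")


def load_config(path) -> PipelineConfig:
    """Load a YAML pipeline config; unknown keys raise."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    valid = {f.name for f in PipelineConfig.__dataclass_fields__.values()}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "stages" in data:
        data["stages"] = tuple(data["stages"])
    return PipelineConfig(**data)


def config_hash(cfg: PipelineConfig) -> str:
    """Stable short hash of the analysis configuration.

    Output paths are excluded: two runs with the same seed and
    thresholds produce identical results wherever they are written.
    """
    payload = asdict(cfg)
    payload.pop("out_dir")
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]
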