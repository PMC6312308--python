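"""Occurrence records and the quality-control cascade.

Raw occurrence compilations mix precise and imprecise coordinates, exact
duplicates, and spatial clusters denser than the analysis grid.  The cleaning
chain applied before model calibration is:

    raw -> precise (drop low-precision coordinates)
        -> unique  (drop exact duplicates)
        -> thinned (one record per grid cell per species)
        -> calibration / evaluation (random 50/50 split)

Each stage records before/after counts in ``counts_log`` so the cascade can be
reported like a data-cleaning table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import RasterGrid

__all__ = [
    "OccurrenceSet",
    "filter_precision",
    "deduplicate",
    "thin_to_grid",
    "split_calibration",
]

STAGES = (
    "raw",
    "precise",
    "unique",
    "thinned",
    "calibration",
    "evaluation",
    "independent",
)

#: DataFrame columns every OccurrenceSet carries.
COLUMNS = ["species", "longitude", "latitude", "precision_flag", "source_id"]


@dataclass
class OccurrenceSet:
    """Species-labeled point records at one stage of the cleaning cascade."""

    df: pd.DataFrame
    stage_tag: str = "raw"
    counts_log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.stage_tag not in STAGES:
            raise ValueError(f"unknown stage {self.stage_tag!r}")
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"occurrence frame missing columns: {missing}")
        lat = self.df["latitude"].to_numpy(dtype=float)
        lon = self.df["longitude"].to_numpy(dtype=float)
        if len(lat) and (np.abs(lat) > 90).any():
            raise ValueError("latitude outside [-90, 90]")
        if len(lon) and ((lon < -180) | (lon >= 180)).any():
            raise ValueError("longitude outside [-180, 180)")
        self.counts_log = dict(self.counts_log)
        self.counts_log.setdefault(self.stage_tag, len(self.df))

    def __len__(self) -> int:
        return len(self.df)

    @property
    def lons(self) -> np.ndarray:
        return self.df["longitude"].to_numpy(dtype=float)

    @property
    def lats(self) -> np.ndarray:
        return self.df["latitude"].to_numpy(dtype=float)

    @property
    def species(self) -> list[str]:
        return sorted(self.df["species"].unique())

    def for_species(self, name: str) -> "OccurrenceSet":
        sub = self.df[self.df["species"] == name].reset_index(drop=True)
        return OccurrenceSet(sub, self.stage_tag, dict(self.counts_log))

    def _advance(self, df: pd.DataFrame, stage: str, **log) -> "OccurrenceSet":
        counts = dict(self.counts_log)
        counts[stage] = len(df)
        counts.update(log)
        return OccurrenceSet(df.reset_index(drop=True), stage, counts)


def _require_stage(occ: OccurrenceSet, stage: str, op: str) -> None:
    if occ.stage_tag != stage:
        raise ValueError(f"{op} expects a {stage!r} occurrence set, got {occ.stage_tag!r}")


def filter_precision(occ: OccurrenceSet) -> OccurrenceSet:
    """Keep only records with exact coordinates (precision_flag == 'exact')."""
    _require_stage(occ, "raw", "filter_precision")
    keep = occ.df["precision_flag"] == "exact"
    out = occ._advance(occ.df[keep], "precise", removed_low_precision=int((~keep).sum()))
    return out


def deduplicate(occ: OccurrenceSet) -> OccurrenceSet:
    """Collapse exact (species, longitude, latitude) duplicates, keeping the
    first record in input order."""
    _require_stage(occ, "precise", "deduplicate")
    df = occ.df.drop_duplicates(subset=["species", "longitude", "latitude"], keep="first")
    return occ._advance(df, "unique", removed_duplicates=len(occ.df) - len(df))


def thin_to_grid(
    occ: OccurrenceSet,
    grid: RasterGrid,
    valid_mask: np.ndarray | None = None,
) -> OccurrenceSet:
    """Keep one record per occupied grid cell per species (first in order).

    Records falling outside the grid, or on nodata cells when ``valid_mask``
    is supplied, are dropped and counted in the log.
    """
    _require_stage(occ, "unique", "thin_to_grid")
    rows, cols, inside = grid.cells_of(occ.lons, occ.lats)
    if valid_mask is not None:
        on_valid = inside.copy()
        on_valid[inside] = valid_mask[rows[inside], cols[inside]]
    else:
        on_valid = inside
    df = occ.df[on_valid].copy()
    df["_cell"] = rows[on_valid] * grid.n_cols + cols[on_valid]
    df = df.drop_duplicates(subset=["species", "_cell"], keep="first").drop(columns="_cell")
    return occ._advance(
        df,
        "thinned",
        dropped_off_grid=int((~on_valid).sum()),
        removed_same_cell=int(on_valid.sum()) - len(df),
    )


def split_calibration(
    occ: OccurrenceSet, fraction: float = 0.5, seed: int = 0
) -> tuple[OccurrenceSet, OccurrenceSet]:
    """Random disjoint partition into calibration and evaluation halves.

    The calibration part receives ``ceil(fraction * n)`` records; the split is
    a partition without replacement, reproducible from ``seed``.
    """
    _require_stage(occ, "thinned", "split_calibration")
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    n = len(occ)
    if n < 2:
        raise ValueError("need at least 2 records to split")
    n_cal = math.ceil(fraction * n)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    cal_idx = np.sort(perm[:n_cal])
    eva_idx = np.sort(perm[n_cal:])
    cal = occ._advance(occ.df.iloc[cal_idx], "calibration")
    eva = occ._advance(occ.df.iloc[eva_idx], "evaluation")
    return cal, eva
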