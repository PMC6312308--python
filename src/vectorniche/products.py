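"""Post-processing of continuous predictions into decision products.

Covers the E%-omission threshold and binary maps, the medians-of-medians
future ensemble with its per-RCP uncertainty range, present/future stability
categories, and area-change bookkeeping.  Area is measured in cell counts;
the change percentages are ratios and do not depend on that choice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .grids import Layer
from .maxent import SuitabilityMap, median_of, range_of
from .occurrences import OccurrenceSet

__all__ = [
    "ThresholdSpec",
    "EnsembleProduct",
    "StabilityMap",
    "threshold_E",
    "ensemble_future",
    "area_change",
    "stability_map",
    "STABILITY_CODES",
]

#: Stability-map category codes.
STABILITY_CODES = {
    0: "unsuitable in present and future",
    1: "stable: suitable in present and ensemble future",
    2: "future gain agreed by all GCMs",
    3: "future gain with partial GCM agreement",
    4: "present-only (future loss)",
}


@dataclass(frozen=True)
class ThresholdSpec:
    """Suitability cutoff tolerating at most E calibration omission.

    ``tau`` is the largest calibration-point suitability value whose omission
    (fraction of calibration points strictly below it) does not exceed E.
    """

    E: float
    tau: float
    omission: float
    n_points: int


@dataclass
class EnsembleProduct:
    """Per-(RCP, period) summary across GCM median predictions."""

    rcp: str
    period: str
    per_gcm_medians: list[SuitabilityMap]
    ensemble_median: SuitabilityMap
    uncertainty_range: Layer
    binary: Layer


@dataclass
class StabilityMap:
    """Categorical present/future agreement map (codes in STABILITY_CODES)."""

    layer: Layer
    counts: dict[int, int]


def threshold_E(
    median_map: SuitabilityMap,
    calibration: OccurrenceSet,
    E: float = 0.05,
) -> tuple[ThresholdSpec, Layer]:
    """Threshold a suitability map at the E%-allowable-omission cutoff.

    Up to a fraction E of calibration records is assumed to carry coordinate
    or environmental error, so the cutoff is pushed as high as possible while
    leaving at most E of the calibration points below it.  The binary map is
    suitability >= tau.
    """
    if not 0 <= E < 1:
        raise ValueError("E must be in [0, 1)")
    grid = median_map.grid
    rows, cols, inside = grid.cells_of(calibration.lons, calibration.lats)
    ok = inside.copy()
    vals = median_map.values
    ok[inside] = ~np.isnan(vals[rows[inside], cols[inside]])
    n_dropped = int((~ok).sum())
    if n_dropped:
        warnings.warn(f"{n_dropped} calibration points off-grid or on nodata cells")
    suits = vals[rows[ok], cols[ok]]
    if suits.size == 0:
        raise ValueError("no calibration points fall on valid cells")

    candidates = np.unique(suits)
    n = suits.size
    tau = candidates[0]
    for v in candidates:
        if np.mean(suits < v) <= E:
            tau = v
        else:
            break
    omission = float(np.mean(suits < tau))
    binary = Layer(grid, "binary", np.where(np.isnan(vals), np.nan, (vals >= tau) * 1.0))
    return ThresholdSpec(E=E, tau=float(tau), omission=omission, n_points=n), binary


def apply_threshold(smap: SuitabilityMap, tau: float, name: str = "binary") -> Layer:
    vals = smap.values
    return Layer(smap.grid, name, np.where(np.isnan(vals), np.nan, (vals >= tau) * 1.0))


def ensemble_future(
    per_gcm_medians: list[SuitabilityMap],
    tau: float,
    rcp: str = "",
    period: str = "",
) -> EnsembleProduct:
    """Median-of-GCM-medians ensemble for one (RCP, period).

    The binary map applies the present-day threshold ``tau`` to the ensemble
    median (future scenarios have no calibration occurrences of their own);
    the uncertainty range is the per-cell max - min across GCM medians.
    """
    if not per_gcm_medians:
        raise ValueError("need at least one GCM median map")
    grid = per_gcm_medians[0].grid
    for m in per_gcm_medians[1:]:
        if m.grid != grid:
            raise ValueError("GCM maps are on different grids")
    ens = median_of(per_gcm_medians)
    ens.layer.name = f"ensemble_{rcp}_{period}" if rcp else "ensemble_median"
    return EnsembleProduct(
        rcp=rcp,
        period=period,
        per_gcm_medians=per_gcm_medians,
        ensemble_median=ens,
        uncertainty_range=range_of(per_gcm_medians, name="gcm_range"),
        binary=apply_threshold(ens, tau),
    )


def area_change(present_binary: Layer, future_binary: Layer) -> tuple[float | None, float]:
    """Suitable-area change from present to future, two conventions.

    Returns ``(percent_relative, percent_of_total)``: change relative to the
    present suitable area, and change relative to all analyzed cells.  The
    relative version is None when no cell is suitable at present.
    """
    if present_binary.grid != future_binary.grid:
        raise ValueError("binary maps are on different grids")
    pv, fv = present_binary.values, future_binary.values
    valid = ~np.isnan(pv) & ~np.isnan(fv)
    a_p = float(np.nansum(pv[valid]))
    a_f = float(np.nansum(fv[valid]))
    n_valid = int(valid.sum())
    pct_total = 100.0 * (a_f - a_p) / n_valid if n_valid else 0.0
    pct_rel = 100.0 * (a_f - a_p) / a_p if a_p > 0 else None
    return pct_rel, pct_total


def stability_map(
    present_binary: Layer,
    per_gcm_binaries: list[Layer],
    ensemble_binary: Layer,
) -> StabilityMap:
    """Classify each valid cell by present/future agreement.

    With G = number of GCMs predicting suitable:
      1  present-suitable and ensemble-future-suitable (stable)
      4  present-suitable but ensemble-future-unsuitable (loss)
      2  present-unsuitable, all GCMs agree on future suitability
      3  present-unsuitable, partial GCM agreement (0 < G < all)
      0  otherwise (unsuitable throughout)
    """
    grid = present_binary.grid
    for l in per_gcm_binaries + [ensemble_binary]:
        if l.grid != grid:
            raise ValueError("stability inputs are on different grids")
    pv = present_binary.values
    ev = ensemble_binary.values
    G = np.sum([np.nan_to_num(l.values) for l in per_gcm_binaries], axis=0)
    n_gcms = len(per_gcm_binaries)
    valid = ~np.isnan(pv) & ~np.isnan(ev)

    codes = np.zeros(grid.shape)
    present = valid & (pv == 1)
    codes[present & (ev == 1)] = 1
    codes[present & (ev == 0)] = 4
    absent = valid & (pv == 0)
    codes[absent & (G == n_gcms)] = 2
    codes[absent & (G > 0) & (G < n_gcms)] = 3
    codes[~valid] = np.nan

    counts = {
        k: int(np.sum(codes[valid] == k)) for k in STABILITY_CODES
    }
    return StabilityMap(Layer(grid, "stability", codes), counts)
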