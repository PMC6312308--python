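"""Niche overlap metrics and the background similarity randomization test.

Two suitability surfaces are compared after normalizing each to a discrete
probability distribution over a shared cell mask:

* Schoener's D  = 1 - 0.5 * sum_i |p1_i - p2_i|
* Hellinger's I = 1 - 0.5 * sum_i (sqrt(p1_i) - sqrt(p2_i))^2
                = sum_i sqrt(p1_i * p2_i)   (the Bhattacharyya coefficient)

Both lie in [0, 1]; 1 means identical surfaces, 0 disjoint support, and
I >= D always.  The background similarity test asks whether the observed
overlap between two species' models is lower than the overlap achieved by
models fitted to random points from one species' accessible area: the null
hypothesis of niche similarity is rejected when the observed D (or I) falls
below the 5th percentile of the null distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import CalibrationRegion, EnvStack
from .maxent import (
    FeatureSpec,
    FitError,
    SuitabilityMap,
    fit_model,
    predict,
)
from .occurrences import OccurrenceSet

__all__ = [
    "OverlapResult",
    "normalize_surface",
    "schoener_D",
    "hellinger_I",
    "overlap_statistics",
    "background_similarity_test",
]


@dataclass
class OverlapResult:
    """Observed D/I, null distributions, and the 5th-percentile decision."""

    D_observed: float
    I_observed: float
    direction: str
    null_D: np.ndarray
    null_I: np.ndarray
    percentile_5_D: float
    percentile_5_I: float
    reject_D: bool
    reject_I: bool
    percentile_rank_D: float  # auxiliary: empirical rank of the observed D
    percentile_rank_I: float
    n_skipped: int = 0

    def summary(self) -> dict:
        return {
            "direction": self.direction,
            "D_observed": self.D_observed,
            "I_observed": self.I_observed,
            "percentile_5_D": self.percentile_5_D,
            "percentile_5_I": self.percentile_5_I,
            "reject_D": self.reject_D,
            "reject_I": self.reject_I,
            "percentile_rank_D": self.percentile_rank_D,
            "percentile_rank_I": self.percentile_rank_I,
            "n_replicates": int(self.null_D.size),
            "n_skipped": self.n_skipped,
        }


def normalize_surface(smap: SuitabilityMap, mask: np.ndarray) -> np.ndarray:
    """Suitability over ``mask`` cells rescaled to a probability vector.

    Cells of the mask where the surface is nodata contribute zero.
    """
    vals = np.nan_to_num(smap.values, nan=0.0)[mask]
    total = vals.sum()
    if not total > 0:
        raise ValueError("surface has no positive suitability on the mask")
    return vals / total


def schoener_D(p1: np.ndarray, p2: np.ndarray) -> float:
    """Schoener's D between two probability surfaces on a shared mask."""
    _check_pair(p1, p2)
    return float(1.0 - 0.5 * np.abs(p1 - p2).sum())


def hellinger_I(p1: np.ndarray, p2: np.ndarray) -> float:
    """Hellinger-derived I (Bhattacharyya coefficient) between two surfaces."""
    _check_pair(p1, p2)
    return float(1.0 - 0.5 * ((np.sqrt(p1) - np.sqrt(p2)) ** 2).sum())


def _check_pair(p1: np.ndarray, p2: np.ndarray) -> None:
    if p1.shape != p2.shape:
        raise ValueError("probability surfaces are on different masks")
    for p in (p1, p2):
        if not np.isclose(p.sum(), 1.0, atol=1e-8):
            raise ValueError("surface is not normalized to sum 1")


def overlap_statistics(
    map1: SuitabilityMap, map2: SuitabilityMap
) -> tuple[float, float]:
    """D and I between two suitability maps over their shared valid mask."""
    mask = ~np.isnan(map1.values) | ~np.isnan(map2.values)
    p1 = normalize_surface(map1, mask)
    p2 = normalize_surface(map2, mask)
    return schoener_D(p1, p2), hellinger_I(p1, p2)


def background_similarity_test(
    model_a_map: SuitabilityMap,
    model_b_map: SuitabilityMap,
    m_b: CalibrationRegion | None,
    n_points_b: int,
    pc_stack: EnvStack,
    background: np.ndarray,
    n_replicates: int = 100,
    seed: int = 0,
    spec_classes: tuple[str, ...] = ("linear", "quadratic"),
    beta: float = 2.0,
    direction: str = "A-vs-backgroundB",
) -> OverlapResult:
    """Background similarity randomization test (one direction).

    Per replicate, ``n_points_b`` points are drawn uniformly from the valid
    cells of species B's accessible area (matching B's real occurrence
    count), a model with the shared settings is fitted to them against the
    shared background, and its predicted surface is compared to species A's
    surface.  The observed D/I come from the two species' real models.
    Replicates whose fit fails are skipped and counted; more than 20% skipped
    aborts the test.
    """
    D_obs, I_obs = overlap_statistics(model_a_map, model_b_map)
    mask_a = ~np.isnan(model_a_map.values)

    region_mask = pc_stack.valid_mask.copy()
    if m_b is not None:
        region_mask &= m_b.mask(pc_stack.grid)
    rows, cols = np.nonzero(region_mask)
    if rows.size == 0:
        raise ValueError("species B's accessible area has no valid cells")

    root = np.random.SeedSequence(seed)
    null_D, null_I = [], []
    n_skipped = 0
    for ss in root.spawn(n_replicates):
        rng = np.random.default_rng(ss)
        idx = rng.choice(rows.size, size=n_points_b, replace=True)
        lon, lat = pc_stack.grid.cell_center(rows[idx], cols[idx])
        occ = OccurrenceSet(
            pd.DataFrame(
                {
                    "species": "background",
                    "longitude": lon,
                    "latitude": lat,
                    "precision_flag": "exact",
                    "source_id": [f"bg{i}" for i in range(n_points_b)],
                }
            ),
            "independent",
        )
        try:
            model = fit_model(
                occ,
                background,
                pc_stack,
                spec=FeatureSpec(classes=spec_classes),
                beta=beta,
            )
        except (FitError, ValueError):
            n_skipped += 1
            continue
        rep_map = predict(model, pc_stack)
        mask = mask_a | ~np.isnan(rep_map.values)
        pa = normalize_surface(model_a_map, mask)
        pr = normalize_surface(rep_map, mask)
        null_D.append(schoener_D(pa, pr))
        null_I.append(hellinger_I(pa, pr))

    if n_skipped > 0.2 * n_replicates:
        raise RuntimeError(
            f"background similarity test: {n_skipped}/{n_replicates} replicates failed"
        )
    null_D = np.asarray(null_D)
    null_I = np.asarray(null_I)
    p5_D = float(np.percentile(null_D, 5.0))
    p5_I = float(np.percentile(null_I, 5.0))
    return OverlapResult(
        D_observed=D_obs,
        I_observed=I_obs,
        direction=direction,
        null_D=null_D,
        null_I=null_I,
        percentile_5_D=p5_D,
        percentile_5_I=p5_I,
        reject_D=D_obs < p5_D,
        reject_I=I_obs < p5_I,
        percentile_rank_D=float(np.mean(null_D < D_obs)),
        percentile_rank_I=float(np.mean(null_I < I_obs)),
        n_skipped=n_skipped,
    )
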