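"""Model significance tests: bootstrap partial ROC and the cumulative
binomial test on independent records.

Partial ROC evaluates the model only in the high-sensitivity region
(sensitivity >= 1 - E, matching the E% omission tolerance).  With no true
absences, proportional predicted area (PPA) stands in for 1 - specificity.
The statistic is the ratio of the model's partial AUC to the null (diagonal)
partial AUC over the same PPA range; ratios above 1 indicate
better-than-random prediction, and the p-value is the fraction of bootstrap
iterations with ratio <= 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .grids import Layer
from .maxent import SuitabilityMap
from .occurrences import OccurrenceSet

__all__ = ["PROCResult", "BinomialResult", "partial_roc", "binomial_test"]


@dataclass
class PROCResult:
    """Bootstrap partial-ROC summary."""

    E: float
    n_iterations: int
    ratios: np.ndarray
    minimum: float
    maximum: float
    mean: float
    median: float
    n_ns: int  # iterations with AUC ratio <= 1 (non-significant)
    p_value: float
    auc_full: float  # traditional AUC, debug only

    def summary(self) -> dict:
        return {
            "E": self.E,
            "n_iterations": self.n_iterations,
            "min_ratio": self.minimum,
            "max_ratio": self.maximum,
            "mean_ratio": self.mean,
            "median_ratio": self.median,
            "n_ns": self.n_ns,
            "p_value": self.p_value,
        }


@dataclass
class BinomialResult:
    """One-tailed cumulative binomial test of independent records."""

    n: int
    s: int
    p: float
    p_value: float
    n_off_grid: int


def _point_suitabilities(
    smap: SuitabilityMap, occ: OccurrenceSet
) -> tuple[np.ndarray, int]:
    rows, cols, inside = smap.grid.cells_of(occ.lons, occ.lats)
    vals = smap.values
    ok = inside.copy()
    ok[inside] = ~np.isnan(vals[rows[inside], cols[inside]])
    return vals[rows[ok], cols[ok]], int((~ok).sum())


def _partial_aucs(
    point_suits: np.ndarray, ppa: np.ndarray, cutoffs: np.ndarray, E: float
) -> tuple[float, float]:
    """(model, null) partial AUCs of one curve over the sensitivity >= 1-E region."""
    srt = np.sort(point_suits)
    n = srt.size
    # sensitivity(t) = fraction of points with suitability >= t
    sens = (n - np.searchsorted(srt, cutoffs, side="left")) / n
    keep = sens >= 1.0 - E
    sens_k, ppa_k = sens[keep], ppa[keep]
    order = np.argsort(ppa_k)
    sens_k, ppa_k = sens_k[order], ppa_k[order]
    span = ppa_k[-1] - ppa_k[0]
    if span < 1e-12:
        # degenerate single-point region: compare heights directly
        h = float(sens_k[-1] / ppa_k[-1]) if ppa_k[-1] > 0 else 1.0
        return h, 1.0
    pauc_model = float(np.trapezoid(sens_k, ppa_k))
    pauc_null = float(0.5 * (ppa_k[-1] ** 2 - ppa_k[0] ** 2))
    return pauc_model, pauc_null


def _partial_auc_ratio(
    point_suits: np.ndarray, ppa: np.ndarray, cutoffs: np.ndarray, E: float
) -> float:
    model, null = _partial_aucs(point_suits, ppa, cutoffs, E)
    return model / null


def partial_roc(
    median_map: SuitabilityMap,
    test_occ: OccurrenceSet,
    E: float = 0.05,
    n_iterations: int = 1000,
    resample_fraction: float = 0.5,
    n_bins: int = 100,
    seed: int = 0,
) -> PROCResult:
    """Bootstrap partial-ROC test of a suitability map on withheld records.

    Each iteration resamples ``ceil(resample_fraction * n)`` test points with
    replacement and computes the AUC ratio over ``n_bins`` equal-width
    suitability cutoffs restricted to sensitivity >= 1 - E.
    """
    suits, _ = _point_suitabilities(median_map, test_occ)
    if suits.size < 10:
        raise ValueError(f"need at least 10 test points on valid cells, got {suits.size}")
    vals = median_map.values
    cell_vals = vals[~np.isnan(vals)]
    cutoffs = np.linspace(0.0, 1.0, n_bins + 1)
    # PPA(t) = fraction of valid cells predicted suitable at cutoff t
    srt_cells = np.sort(cell_vals)
    ppa = (srt_cells.size - np.searchsorted(srt_cells, cutoffs, side="left")) / srt_cells.size

    rng = np.random.default_rng(seed)
    k = int(np.ceil(resample_fraction * suits.size))
    ratios = np.empty(n_iterations)
    for i in range(n_iterations):
        sample = suits[rng.integers(0, suits.size, size=k)]
        ratios[i] = _partial_auc_ratio(sample, ppa, cutoffs, E)

    n_ns = int(np.sum(ratios <= 1.0))
    # traditional AUC for reference: P(point suit > random cell suit)
    auc_full = float(
        (np.searchsorted(srt_cells, suits, side="left")
         + 0.5 * (np.searchsorted(srt_cells, suits, side="right")
                  - np.searchsorted(srt_cells, suits, side="left"))).mean()
        / srt_cells.size
    )
    return PROCResult(
        E=E,
        n_iterations=n_iterations,
        ratios=ratios,
        minimum=float(ratios.min()),
        maximum=float(ratios.max()),
        mean=float(ratios.mean()),
        median=float(np.median(ratios)),
        n_ns=n_ns,
        p_value=n_ns / n_iterations,
        auc_full=auc_full,
    )


def binomial_test(binary: Layer, independent_occ: OccurrenceSet) -> BinomialResult:
    """Exact one-tailed cumulative binomial test of a binary map.

    Success probability is the proportional suitable coverage of the valid
    area; the p-value is P(X >= s) for X ~ Binomial(n, p), the chance of the
    observed number of correctly predicted independent records arising by
    chance alone.
    """
    vals = binary.values
    valid = ~np.isnan(vals)
    p = float(np.mean(vals[valid] == 1))
    rows, cols, inside = binary.grid.cells_of(independent_occ.lons, independent_occ.lats)
    ok = inside.copy()
    ok[inside] = valid[rows[inside], cols[inside]]
    n = int(ok.sum())
    if n == 0:
        raise ValueError("no independent records fall on valid cells")
    s = int(np.sum(vals[rows[ok], cols[ok]] == 1))
    p_value = float(stats.binom.sf(s - 1, n, p))
    return BinomialResult(n=n, s=s, p=p, p_value=p_value, n_off_grid=int((~ok).sum()))
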