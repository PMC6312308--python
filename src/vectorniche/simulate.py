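"""Virtual-species world generator.

Everything downstream of raw data — occurrence cleaning, PCA, niche model
fitting, scenario ensembles, overlap tests — is exercised on a synthetic world
with known ground truth:

* a small number of *latent* environmental gradients: smooth, spatially
  autocorrelated surfaces (kernel-smoothed white noise, standardized);
* an observed climate-like stack: each layer is a fixed random linear mixture
  of the latent gradients plus small independent noise, then given a
  layer-specific scale and offset, so layers are mutually correlated and a
  correlation-matrix PCA recovers the latent dimensionality;
* species whose true suitability is an axis-aligned Gaussian in latent space
  — smooth, unimodal, and representable by quadratic features, so niche
  recovery can be scored against an exact truth map;
* occurrence samples drawn proportionally to true suitability and then
  contaminated with exact duplicates and coordinate-rounded low-precision
  records — the artifacts the cleaning cascade must remove;
* pseudo-GCM future stacks: the latent gradients receive a shared directional
  shift whose magnitude grows with scenario intensity (RCP) and time horizon,
  plus smooth GCM-specific perturbations, and are mixed through the *same*
  mixing matrix as the present-day stack.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .grids import EnvStack, Layer, RasterGrid
from .occurrences import OccurrenceSet

__all__ = [
    "TrueNiche",
    "ScenarioSpec",
    "LatentEnvironment",
    "make_environment",
    "make_species",
    "sample_occurrences",
    "make_future",
    "default_grid",
]


def default_grid(n_rows: int = 100, n_cols: int = 120) -> RasterGrid:
    """Desk-scale analysis grid (half-degree cells over a mid-latitude window)."""
    return RasterGrid(
        n_rows=n_rows, n_cols=n_cols, x_min=-30.0, y_max=30.0, resolution=0.5
    )


@dataclass(frozen=True)
class TrueNiche:
    """Axis-aligned Gaussian response in latent-environment space.

    true_suitability(x) = max_suitability * exp(-0.5 * sum_j ((x_j - center_j) / widths_j)^2)
    """

    center: tuple[float, ...]
    widths: tuple[float, ...]
    max_suitability: float = 1.0

    def __post_init__(self) -> None:
        if len(self.center) != len(self.widths):
            raise ValueError("center and widths must have the same dimension")
        if any(w <= 0 for w in self.widths):
            raise ValueError("widths must be positive")
        if not 0 < self.max_suitability <= 1:
            raise ValueError("max_suitability must be in (0, 1]")

    @property
    def dim(self) -> int:
        return len(self.center)

    def suitability(self, latent_values: np.ndarray) -> np.ndarray:
        """Evaluate the niche on an array of latent vectors.

        ``latent_values`` has the latent axis first: shape (dim, ...).
        """
        x = np.asarray(latent_values, dtype=float)
        if x.shape[0] != self.dim:
            raise ValueError(
                f"niche has dimension {self.dim}, got {x.shape[0]} latent fields"
            )
        c = np.asarray(self.center, dtype=float).reshape((-1,) + (1,) * (x.ndim - 1))
        w = np.asarray(self.widths, dtype=float).reshape((-1,) + (1,) * (x.ndim - 1))
        z2 = np.sum(((x - c) / w) ** 2, axis=0)
        return self.max_suitability * np.exp(-0.5 * z2)


@dataclass(frozen=True)
class ScenarioSpec:
    """Future-scenario grid: GCM count, RCP shift magnitudes, time periods.

    Shift magnitudes are in latent-gradient standard deviations and must
    increase strictly with RCP intensity; period multipliers grow with the
    time horizon (climate drifts further by 2070 than by 2050).
    """

    n_gcms: int = 9
    rcp_shifts: tuple[tuple[str, float], ...] = (
        ("rcp26", 0.25),
        ("rcp45", 0.50),
        ("rcp60", 0.75),
        ("rcp85", 1.00),
    )
    periods: tuple[tuple[str, float], ...] = (("2050", 1.0), ("2070", 1.5))

    def __post_init__(self) -> None:
        if self.n_gcms < 2:
            raise ValueError("need at least 2 GCMs")
        shifts = [s for _, s in self.rcp_shifts]
        if any(b <= a for a, b in zip(shifts, shifts[1:])):
            raise ValueError("RCP shift magnitudes must strictly increase")
        mults = [m for _, m in self.periods]
        if any(b <= a for a, b in zip(mults, mults[1:])):
            raise ValueError("period multipliers must strictly increase")

    @property
    def gcm_ids(self) -> list[str]:
        return [f"gcm{i + 1}" for i in range(self.n_gcms)]

    @property
    def n_stacks(self) -> int:
        return self.n_gcms * len(self.rcp_shifts) * len(self.periods)


@dataclass
class LatentEnvironment:
    """Ground-truth state of the virtual world.

    Holds the latent gradient fields together with the fixed mixing matrix,
    per-layer scales/offsets and per-layer noise fields, so that future stacks
    can be produced by shifting the latent fields and re-mixing with the
    *identical* observation model as the present-day stack.
    """

    grid: RasterGrid
    fields: np.ndarray  # (n_latent, n_rows, n_cols), NaN on masked cells
    mixing: np.ndarray  # (n_layers, n_latent)
    scales: np.ndarray  # (n_layers,)
    offsets: np.ndarray  # (n_layers,)
    layer_noise: np.ndarray  # (n_layers, n_rows, n_cols)
    smooth_sigma: float
    layer_names: list[str] = field(default_factory=list)

    @property
    def n_latent(self) -> int:
        return self.fields.shape[0]

    def mix(self, fields: np.ndarray, scenario_tag: object) -> EnvStack:
        """Apply the fixed observation model to a set of latent fields."""
        layers = []
        for k, name in enumerate(self.layer_names):
            raw = np.tensordot(self.mixing[k], fields, axes=(0, 0)) + self.layer_noise[k]
            layers.append(Layer(self.grid, name, self.scales[k] * raw + self.offsets[k]))
        return EnvStack(self.grid, layers, scenario_tag)


def _smooth_standard_field(
    rng: np.random.Generator, shape: tuple[int, int], sigma: float
) -> np.ndarray:
    """Spatially autocorrelated surface with zero mean and unit variance."""
    f = gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")
    f -= f.mean()
    sd = f.std()
    if sd == 0:  # pathological tiny grid; keep the flat field
        return f
    return f / sd


def make_environment(
    grid: RasterGrid,
    n_latent: int = 2,
    n_layers: int = 15,
    seed: int = 0,
    smooth_sigma: float = 8.0,
    noise_sd: float = 0.05,
    mask: np.ndarray | None = None,
) -> tuple[EnvStack, LatentEnvironment]:
    """Generate the present-day climate-like stack and its latent ground truth.

    Fifteen layers from two latent gradients is the default: it mirrors a
    reduced bioclimatic set whose variation lives on a low-dimensional
    manifold, so downstream PCA keeps a couple of meaningful components.
    ``mask`` (True = analyzed cell) introduces nodata cells, e.g. ocean.
    """
    if n_latent < 1:
        raise ValueError("n_latent must be at least 1")
    if n_latent > n_layers:
        raise ValueError("n_latent cannot exceed n_layers")
    rng = np.random.default_rng(seed)
    fields = np.stack(
        [_smooth_standard_field(rng, grid.shape, smooth_sigma) for _ in range(n_latent)]
    )
    # Fixed observation model: well-conditioned mixture with per-layer units.
    mixing = rng.normal(size=(n_layers, n_latent))
    mixing /= np.linalg.norm(mixing, axis=1, keepdims=True)
    scales = rng.uniform(0.5, 20.0, size=n_layers)
    offsets = rng.uniform(-10.0, 30.0, size=n_layers)
    layer_noise = noise_sd * rng.standard_normal((n_layers,) + grid.shape)

    if mask is not None:
        fields = fields.copy()
        fields[:, ~mask] = np.nan

    latent = LatentEnvironment(
        grid=grid,
        fields=fields,
        mixing=mixing,
        scales=scales,
        offsets=offsets,
        layer_noise=layer_noise,
        smooth_sigma=smooth_sigma,
        layer_names=[f"env{k + 1:02d}" for k in range(n_layers)],
    )
    return latent.mix(fields, "present"), latent


def make_species(latent: LatentEnvironment, niche: TrueNiche, name: str = "truth") -> Layer:
    """True suitability surface: the niche evaluated on the latent fields."""
    if niche.dim != latent.n_latent:
        raise ValueError(
            f"niche dimension {niche.dim} does not match {latent.n_latent} latent fields"
        )
    return Layer(latent.grid, name, niche.suitability(latent.fields))


def sample_occurrences(
    truth: Layer,
    n: int = 400,
    dup_rate: float = 0.1,
    lowprec_rate: float = 0.1,
    seed: int = 0,
    species: str = "species",
) -> OccurrenceSet:
    """Draw a contaminated raw occurrence sample from a truth map.

    ``n`` base records are drawn from cells with probability proportional to
    true suitability and placed uniformly within their cell.  A fraction
    ``dup_rate`` is then duplicated exactly, and a fraction ``lowprec_rate``
    of the base records is rounded to one decimal place and flagged
    low-precision.  The result is a stage='raw' set.
    """
    rng = np.random.default_rng(seed)
    grid = truth.grid
    vals = truth.values
    valid = ~np.isnan(vals)
    weights = np.where(valid, vals, 0.0).ravel()
    total = weights.sum()
    if not total > 0:
        raise ValueError("truth map has no cell with positive suitability")
    cells = rng.choice(weights.size, size=n, replace=True, p=weights / total)
    rows, cols = np.unravel_index(cells, grid.shape)
    lon = grid.x_min + (cols + rng.uniform(0, 1, size=n)) * grid.resolution
    lat = grid.y_max - (rows + rng.uniform(0, 1, size=n)) * grid.resolution

    df = pd.DataFrame(
        {
            "species": species,
            "longitude": lon,
            "latitude": lat,
            "precision_flag": "exact",
            "source_id": [f"{species}-{i}" for i in range(n)],
        }
    )

    n_low = int(round(lowprec_rate * n))
    low_idx = rng.choice(n, size=n_low, replace=False) if n_low else np.array([], int)
    df.loc[low_idx, "longitude"] = df.loc[low_idx, "longitude"].round(1)
    df.loc[low_idx, "latitude"] = df.loc[low_idx, "latitude"].round(1)
    df.loc[low_idx, "precision_flag"] = "low"

    n_dup = int(round(dup_rate * n))
    dup_idx = rng.choice(n, size=n_dup, replace=False) if n_dup else np.array([], int)
    dups = df.iloc[dup_idx].copy()
    dups["source_id"] = [f"{s}-dup" for s in dups["source_id"]]
    df = pd.concat([df, dups], ignore_index=True)

    log = {
        "base_records": n,
        "injected_duplicates": n_dup,
        "injected_low_precision": n_low,
    }
    return OccurrenceSet(df, "raw", log)


def make_future(
    latent: LatentEnvironment,
    spec: ScenarioSpec = ScenarioSpec(),
    seed: int = 0,
    gcm_sigma: float | None = None,
    gcm_amplitude: float = 0.15,
) -> dict[tuple[str, str, str], EnvStack]:
    """Generate one future stack per (GCM, RCP, period) combination.

    Each latent gradient is shifted by ``rcp_shift * period_multiplier`` along
    a shared direction (equal weight on every gradient), plus a smooth
    GCM-specific perturbation generated from a per-GCM subseed; the shifted
    fields are mixed through the same observation model as the present stack.
    """
    if gcm_sigma is None:
        gcm_sigma = latent.smooth_sigma
    n_latent = latent.n_latent
    direction = np.ones(n_latent) / np.sqrt(n_latent)

    # One perturbation field set per GCM, reused across RCPs and periods:
    # a GCM is one climate simulator's systematic realization.
    gcm_seeds = np.random.SeedSequence(seed).spawn(spec.n_gcms)
    perturbations = {}
    for gcm_id, ss in zip(spec.gcm_ids, gcm_seeds):
        rng = np.random.default_rng(ss)
        perturbations[gcm_id] = gcm_amplitude * np.stack(
            [_smooth_standard_field(rng, latent.grid.shape, gcm_sigma) for _ in range(n_latent)]
        )

    stacks: dict[tuple[str, str, str], EnvStack] = {}
    for gcm_id in spec.gcm_ids:
        for rcp_id, shift in spec.rcp_shifts:
            for period_id, mult in spec.periods:
                delta = (shift * mult) * direction
                fields = (
                    latent.fields
                    + delta.reshape(-1, 1, 1)
                    + perturbations[gcm_id]
                )
                tag = (gcm_id, rcp_id, period_id)
                stacks[tag] = latent.mix(fields, tag)
    return stacks
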