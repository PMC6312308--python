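"""Maximum-entropy presence-background niche model.

The model is the Gibbs density at the heart of MaxEnt-style species
distribution modeling: over a background sample of the accessible area M it
estimates weights lambda minimizing

    -(1/m) sum_presences eta(x_i) + log[(1/B) sum_background exp(eta(x_b))]
        + sum_j beta * (s_j / sqrt(m)) * |lambda_j|

where eta(x) = sum_j lambda_j f_j(x) over linear, quadratic and (optionally)
pairwise-product features standardized to unit variance on the background,
and s_j is feature j's standard deviation over the presence sample — the
regularization form used by MaxEnt, which penalizes each feature roughly by
the sampling uncertainty of the presence constraint it enforces.
The objective is convex; it is solved exactly by splitting each weight into
its positive and negative parts, which turns the L1 penalty into smooth
bound-constrained minimization (L-BFGS-B).

Predictions are the Gibbs intensity exp(eta) rescaled by its maximum to
[0, 1].  Extrapolation is deactivated: any cell whose component values fall
outside the per-layer training ranges is assigned suitability zero and
flagged in a novelty mask, rather than clamped into range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp, softmax

from .grids import CalibrationRegion, EnvStack, Layer, RasterGrid
from .occurrences import OccurrenceSet

__all__ = [
    "FeatureSpec",
    "NicheModel",
    "SuitabilityMap",
    "ReplicateSet",
    "FitError",
    "sample_background",
    "fit_model",
    "predict",
    "fit_replicates",
]


class FitError(RuntimeError):
    """Raised when the convex solver fails to reach the gradient tolerance."""


@dataclass
class FeatureSpec:
    """Feature expansion of the component layers.

    ``classes`` is an ordered subset of {linear, quadratic, product}; linear
    is always included.  Inputs are smooth principal components, so hinge and
    threshold features are unnecessary: a quadratic-with-products expansion
    already represents any Gaussian (log-quadratic) response surface.
    Standardization constants (mean, sd per feature over the background) are
    filled in at fit time.
    """

    classes: tuple[str, ...] = ("linear", "quadratic")
    feature_names: list[str] = field(default_factory=list)
    means: np.ndarray | None = None
    sds: np.ndarray | None = None

    def __post_init__(self) -> None:
        allowed = {"linear", "quadratic", "product"}
        unknown = set(self.classes) - allowed
        if unknown:
            raise ValueError(f"unknown feature classes: {sorted(unknown)}")
        if "linear" not in self.classes:
            raise ValueError("the linear feature class is always required")

    def expand(self, X: np.ndarray, names: list[str] | None = None) -> np.ndarray:
        """Raw (unstandardized) feature matrix for a (n, d) layer-value matrix."""
        cols = [X]
        if names is not None:
            self.feature_names = list(names)
        if "quadratic" in self.classes:
            cols.append(X**2)
            if names is not None:
                self.feature_names += [f"{n}^2" for n in names]
        if "product" in self.classes:
            d = X.shape[1]
            iu, ju = np.triu_indices(d, k=1)
            if iu.size:
                cols.append(X[:, iu] * X[:, ju])
                if names is not None:
                    self.feature_names += [f"{names[i]}*{names[j]}" for i, j in zip(iu, ju)]
        return np.column_stack(cols)

    def fit_scaling(self, F_background: np.ndarray) -> None:
        self.means = F_background.mean(axis=0)
        sds = F_background.std(axis=0)
        sds[sds < 1e-12] = 1.0  # constant feature carries no information
        self.sds = sds

    def standardize(self, F: np.ndarray) -> np.ndarray:
        if self.means is None or self.sds is None:
            raise ValueError("feature scaling not fitted")
        return (F - self.means) / self.sds


@dataclass
class NicheModel:
    """Fitted maximum-entropy model.

    ``weights`` apply to background-standardized features; ``log_normalizer``
    is log of the mean Gibbs factor over the training background, so that
    exp(eta - log_normalizer) averages to 1 over the background (Gibbs
    normalization).  ``calib_ranges`` are per-layer (min, max) over training
    presence+background cells and drive the no-extrapolation rule.
    """

    feature_spec: FeatureSpec
    weights: np.ndarray
    log_normalizer: float
    calib_ranges: np.ndarray  # (n_layers, 2)
    layer_names: list[str]
    m_region: CalibrationRegion | None = None
    replicate_id: str = "full"
    beta: float = 2.0

    def eta(self, X: np.ndarray) -> np.ndarray:
        F = self.feature_spec.standardize(self.feature_spec.expand(X))
        return F @ self.weights


@dataclass
class SuitabilityMap:
    """Continuous suitability in [0, 1] plus the novelty (truncation) mask."""

    layer: Layer
    novelty: np.ndarray

    @property
    def grid(self) -> RasterGrid:
        return self.layer.grid

    @property
    def values(self) -> np.ndarray:
        return self.layer.values


@dataclass
class ReplicateSet:
    """Bootstrapped prediction ensemble with per-cell median and range."""

    replicates: list[SuitabilityMap]
    median_map: SuitabilityMap
    range_map: Layer


def sample_background(
    pc_stack: EnvStack,
    m: CalibrationRegion | None,
    n: int = 10_000,
    seed: int = 0,
) -> np.ndarray:
    """Draw ``n`` distinct non-nodata cells uniformly from the accessible area.

    Returns an (n, 2) array of (row, col) indices.  If M holds fewer than
    ``n`` valid cells, all of them are returned.
    """
    mask = pc_stack.valid_mask.copy()
    if m is not None:
        mask &= m.mask(pc_stack.grid)
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("accessible area does not intersect any valid cell")
    rng = np.random.default_rng(seed)
    if rows.size <= n:
        idx = np.arange(rows.size)
    else:
        idx = rng.choice(rows.size, size=n, replace=False)
    return np.column_stack([rows[idx], cols[idx]])


def _presence_cells(
    presences: OccurrenceSet, pc_stack: EnvStack
) -> tuple[np.ndarray, np.ndarray]:
    rows, cols, inside = pc_stack.grid.cells_of(presences.lons, presences.lats)
    ok = inside.copy()
    ok[inside] = pc_stack.valid_mask[rows[inside], cols[inside]]
    return rows[ok], cols[ok]


def fit_model(
    presences: OccurrenceSet,
    background: np.ndarray,
    pc_stack: EnvStack,
    spec: FeatureSpec | None = None,
    beta: float = 2.0,
    m_region: CalibrationRegion | None = None,
    replicate_id: str = "full",
    max_iter: int = 10_000,
    grad_tol: float = 1e-6,
    init_weights: np.ndarray | None = None,
) -> NicheModel:
    """Fit the L1-regularized maximum-entropy model.

    ``background`` is an (B, 2) array of cell indices (presence cells may
    recur in it).  ``beta`` multiplies the L1 penalty on standardized-feature
    weights; larger values shrink toward the flat (uninformative) model.
    """
    if spec is None:
        spec = FeatureSpec()
    rows, cols = _presence_cells(presences, pc_stack)
    if rows.size < 10:
        raise ValueError(f"need at least 10 presences on valid cells, got {rows.size}")
    Xp = pc_stack.values_at(rows, cols)
    Xb = pc_stack.values_at(background[:, 0], background[:, 1])

    Fb = spec.expand(Xb, names=pc_stack.layer_names)
    spec.fit_scaling(Fb)
    Fb = spec.standardize(Fb)
    Fp = spec.standardize(spec.expand(Xp))
    mean_fp = Fp.mean(axis=0)
    p = Fb.shape[1]
    logB = np.log(Fb.shape[0])
    # MaxEnt-style regularization: each feature's L1 weight is its sampling
    # uncertainty — the feature's standard deviation over the presence sample
    # divided by sqrt(m) — so features whose presence distribution is tightly
    # concentrated (informative responses) are penalized little, while
    # features as dispersed at presences as at background are shrunk hard.
    reg = beta * np.maximum(Fp.std(axis=0), 1e-3) / np.sqrt(Fp.shape[0])

    def objective(ab: np.ndarray) -> tuple[float, np.ndarray]:
        lam = ab[:p] - ab[p:]
        eta_b = Fb @ lam
        lse = logsumexp(eta_b)
        loss = -mean_fp @ lam + (lse - logB) + reg @ ab[:p] + reg @ ab[p:]
        w = softmax(eta_b)
        g = -mean_fp + w @ Fb
        return loss, np.concatenate([g + reg, -g + reg])

    if init_weights is None:
        x0 = np.zeros(2 * p)
    else:  # split initialization into positive/negative parts
        x0 = np.concatenate([np.clip(init_weights, 0, None), np.clip(-init_weights, 0, None)])
    res = minimize(
        objective,
        x0,
        jac=True,
        method="L-BFGS-B",
        bounds=[(0.0, None)] * (2 * p),
        options={"maxiter": max_iter, "ftol": 1e-14, "gtol": grad_tol},
    )
    # projected-gradient convergence check (KKT residual of the L1 problem)
    _, g_final = objective(res.x)
    proj = np.where(res.x > 0, np.abs(g_final), np.minimum(g_final, 0.0))
    pg_norm = float(np.max(np.abs(proj))) if proj.size else 0.0
    if not res.success and pg_norm > 1e-4:
        raise FitError(
            f"maxent solver did not converge (projected gradient {pg_norm:.2e})"
        )
    lam = res.x[:p] - res.x[p:]
    lam[np.abs(lam) < 1e-12] = 0.0

    eta_b = Fb @ lam
    log_normalizer = float(logsumexp(eta_b) - logB)
    Xtrain = np.vstack([Xp, Xb])
    calib_ranges = np.column_stack([Xtrain.min(axis=0), Xtrain.max(axis=0)])
    return NicheModel(
        feature_spec=spec,
        weights=lam,
        log_normalizer=log_normalizer,
        calib_ranges=calib_ranges,
        layer_names=list(pc_stack.layer_names),
        m_region=m_region,
        replicate_id=replicate_id,
        beta=beta,
    )


def predict(model: NicheModel, pc_stack: EnvStack) -> SuitabilityMap:
    """Predict suitability on any scenario stack, extrapolation disabled.

    Output is exp(eta) divided by its maximum over valid in-range cells, so
    the best cell scores exactly 1.  Cells with any layer value outside the
    training range get suitability 0 and a True novelty flag.
    """
    if model.layer_names != pc_stack.layer_names:
        raise ValueError(
            f"stack layers {pc_stack.layer_names} do not match model layers "
            f"{model.layer_names}"
        )
    mask = pc_stack.valid_mask
    X = pc_stack.table(mask)
    lo, hi = model.calib_ranges[:, 0], model.calib_ranges[:, 1]
    in_range = np.all((X >= lo) & (X <= hi), axis=1)

    eta = model.eta(X)
    vals = np.full(pc_stack.grid.shape, np.nan)
    novelty = np.zeros(pc_stack.grid.shape, dtype=bool)
    if not in_range.any():
        # wholly novel scenario: nothing predictable, all valid cells zero
        vals[mask] = 0.0
        novelty[mask] = True
        return SuitabilityMap(Layer(pc_stack.grid, "suitability", vals), novelty)

    eta_max = eta[in_range].max()
    suit = np.where(in_range, np.exp(eta - eta_max), 0.0)
    vals[mask] = suit
    nv = np.zeros(mask.sum(), dtype=bool)
    nv[~in_range] = True
    novelty[mask] = nv
    return SuitabilityMap(Layer(pc_stack.grid, "suitability", vals), novelty)


def median_of(maps: list[SuitabilityMap]) -> SuitabilityMap:
    stack = np.stack([m.values for m in maps])
    med = np.median(stack, axis=0)
    novelty = np.logical_and.reduce([m.novelty for m in maps])
    return SuitabilityMap(Layer(maps[0].grid, "median_suitability", med), novelty)


def range_of(maps: list[SuitabilityMap], name: str = "uncertainty_range") -> Layer:
    stack = np.stack([m.values for m in maps])
    return Layer(maps[0].grid, name, stack.max(axis=0) - stack.min(axis=0))


def fit_replicates(
    calibration: OccurrenceSet,
    pc_stack: EnvStack,
    n_replicates: int = 10,
    train_fraction: float = 0.5,
    seed: int = 0,
    background: np.ndarray | None = None,
    background_n: int = 10_000,
    m_region: CalibrationRegion | None = None,
    spec_classes: tuple[str, ...] = ("linear", "quadratic"),
    beta: float = 2.0,
) -> tuple[list[NicheModel], ReplicateSet]:
    """Bootstrap-replicate fits sharing one background sample.

    Each replicate draws ``ceil(train_fraction * n)`` calibration presences
    with replacement under a replicate-specific subseed, fits, and predicts
    on the training stack; replicate spread therefore reflects occurrence
    resampling only.  Returns the models plus per-cell median and range maps.
    """
    if len(calibration) == 0:
        raise ValueError("calibration set is empty")
    root = np.random.SeedSequence(seed)
    bg_seed, *rep_seeds = root.spawn(n_replicates + 1)
    if background is None:
        background = sample_background(
            pc_stack, m_region, background_n, seed=_seed_int(bg_seed)
        )
    n_draw = int(np.ceil(train_fraction * len(calibration)))
    models: list[NicheModel] = []
    maps: list[SuitabilityMap] = []
    for i, ss in enumerate(rep_seeds):
        rng = np.random.default_rng(ss)
        idx = rng.choice(len(calibration), size=n_draw, replace=True)
        boot = OccurrenceSet(
            calibration.df.iloc[idx].reset_index(drop=True),
            calibration.stage_tag,
            dict(calibration.counts_log),
        )
        try:
            model = fit_model(
                boot,
                background,
                pc_stack,
                spec=FeatureSpec(classes=spec_classes),
                beta=beta,
                m_region=m_region,
                replicate_id=f"rep{i + 1}",
            )
        except (FitError, ValueError) as exc:
            raise FitError(f"replicate {i + 1} failed: {exc}") from exc
        models.append(model)
        maps.append(predict(model, pc_stack))
    rep_set = ReplicateSet(
        replicates=maps, median_map=median_of(maps), range_map=range_of(maps)
    )
    return models, rep_set


def _seed_int(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1, np.uint32)[0])
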