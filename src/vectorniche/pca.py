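"""Correlation-matrix PCA of the environmental stack.

Bioclimatic layers carry incommensurate units (degrees, millimetres), so each
layer is z-scored over its non-nodata cells before the eigen-decomposition.
The transform fitted on present-day data — its means, standard deviations and
loadings — is applied unchanged to every future stack, so present and future
cells live in one common component space.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np

from .grids import EnvStack, Layer

__all__ = [
    "PCATransform",
    "DEFAULT_EXCLUDED",
    "exclude_layers",
    "fit_pca",
    "transform",
    "select_components",
]

#: Bioclimatic layers conventionally dropped for their spatial artifacts.
DEFAULT_EXCLUDED = frozenset({"bio8", "bio9", "bio18", "bio19"})


@dataclass
class PCATransform:
    """Fitted standardization + orthonormal loadings.

    ``loadings`` has shape (n_layers, n_components) with orthonormal columns;
    ``variance_fraction`` is non-increasing and sums to 1.
    """

    layer_names: list[str]
    means: np.ndarray
    sds: np.ndarray
    loadings: np.ndarray
    variance_fraction: np.ndarray
    eigenvalues: np.ndarray

    def project(self, X: np.ndarray, n_components: int | None = None) -> np.ndarray:
        """Center/scale rows by the fitted statistics, then project."""
        k = self.loadings.shape[1] if n_components is None else n_components
        Z = (X - self.means) / self.sds
        return Z @ self.loadings[:, :k]

    def reconstruct(self, scores: np.ndarray) -> np.ndarray:
        """Inverse-project component scores and undo the standardization."""
        k = scores.shape[1]
        return scores @ self.loadings[:, :k].T * self.sds + self.means

    def to_json(self, path: str | os.PathLike) -> None:
        payload = {
            "layer_names": self.layer_names,
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "loadings": self.loadings.tolist(),
            "variance_fraction": self.variance_fraction.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "PCATransform":
        with open(path) as fh:
            p = json.load(fh)
        return cls(
            layer_names=list(p["layer_names"]),
            means=np.asarray(p["means"], dtype=float),
            sds=np.asarray(p["sds"], dtype=float),
            loadings=np.asarray(p["loadings"], dtype=float),
            variance_fraction=np.asarray(p["variance_fraction"], dtype=float),
            eigenvalues=np.asarray(p["eigenvalues"], dtype=float),
        )


def exclude_layers(stack: EnvStack, excluded: frozenset | set | None = None) -> EnvStack:
    """Drop the named layers (default: the artifact-prone bioclim set)."""
    if excluded is None:
        excluded = DEFAULT_EXCLUDED & set(stack.layer_names)
    unknown = set(excluded) - set(stack.layer_names)
    if unknown:
        raise ValueError(f"cannot exclude unknown layers: {sorted(unknown)}")
    kept = [n for n in stack.layer_names if n not in excluded]
    if not kept:
        raise ValueError("excluding all layers leaves an empty stack")
    return stack.subset(kept)


def fit_pca(stack: EnvStack) -> PCATransform:
    """Fit correlation-matrix PCA over the stack's non-nodata cells.

    Components are ordered by decreasing variance.  The sign of each loading
    column is fixed so its largest-magnitude entry is positive, making the
    decomposition reproducible across linear-algebra backends.
    """
    if stack.n_layers < 2:
        raise ValueError("PCA needs at least 2 layers")
    X = stack.table()
    if X.shape[0] < stack.n_layers + 1:
        raise ValueError("not enough non-nodata cells to fit a PCA")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    zero = np.flatnonzero(sds == 0)
    if zero.size:
        raise ValueError(
            f"constant layer(s) cannot be standardized: "
            f"{[stack.layer_names[i] for i in zero]}"
        )
    Z = (X - means) / sds
    corr = Z.T @ Z / (Z.shape[0] - 1)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    # deterministic sign: largest-|loading| entry of each column positive
    flips = np.sign(eigvecs[np.abs(eigvecs).argmax(axis=0), np.arange(eigvecs.shape[1])])
    flips[flips == 0] = 1.0
    eigvecs = eigvecs * flips
    return PCATransform(
        layer_names=list(stack.layer_names),
        means=means,
        sds=sds,
        loadings=eigvecs,
        variance_fraction=eigvals / eigvals.sum(),
        eigenvalues=eigvals,
    )


def transform(stack: EnvStack, pca: PCATransform, n_components: int = 8) -> EnvStack:
    """Project a stack onto the fitted components using present-day statistics.

    The stack must carry exactly the fitted layer names (any order); each cell
    vector is standardized with the *fitted* means/sds — never statistics of
    the stack being transformed — and projected on the loadings.
    """
    if sorted(stack.layer_names) != sorted(pca.layer_names):
        raise ValueError(
            f"stack layers {stack.layer_names} do not match fitted layers "
            f"{pca.layer_names}"
        )
    if not 1 <= n_components <= pca.loadings.shape[1]:
        raise ValueError(f"n_components must be in [1, {pca.loadings.shape[1]}]")
    ordered = stack.subset(pca.layer_names)
    mask = ordered.valid_mask
    scores = pca.project(ordered.table(mask), n_components)
    layers = []
    for j in range(n_components):
        vals = np.full(stack.grid.shape, np.nan)
        vals[mask] = scores[:, j]
        layers.append(Layer(stack.grid, f"PC{j + 1}", vals))
    return EnvStack(stack.grid, layers, stack.scenario_tag)


def select_components(pca: PCATransform, variance_target: float) -> int:
    """Smallest component count whose cumulative variance meets the target."""
    if not 0 < variance_target <= 1:
        raise ValueError("variance_target must be in (0, 1]")
    cum = np.cumsum(pca.variance_fraction)
    # guard against float round-off at target 1.0
    cum[-1] = max(cum[-1], 1.0)
    return int(np.searchsorted(cum, variance_target - 1e-12) + 1)
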