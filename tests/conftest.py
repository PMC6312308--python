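import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import vectorniche as vn

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_grid():
    """10x10 one-degree grid for hand-enumerable geometry tests."""
    return vn.RasterGrid(n_rows=10, n_cols=10, x_min=0.0, y_max=10.0, resolution=1.0)


@pytest.fixture(scope="session")
def default_world():
    """The desk-scale virtual world: 100x120 grid, 15 layers from 2 latent
    gradients, one species with an isotropic Gaussian niche, 400 presences
    put through the full cleaning cascade and the 50/50 split."""
    grid = vn.default_grid()
    env, latent = vn.make_environment(grid, seed=42)
    truth = vn.make_species(latent, vn.TrueNiche((0.0, 0.0), (1.0, 1.0)))
    raw = vn.sample_occurrences(truth, n=400, seed=1, species="a")
    thinned = vn.thin_to_grid(
        vn.deduplicate(vn.filter_precision(raw)), grid, env.valid_mask
    )
    cal, eva = vn.split_calibration(thinned, 0.5, seed=2)
    pca = vn.fit_pca(env)
    pcs = vn.transform(env, pca, 8)
    return {
        "grid": grid,
        "env": env,
        "latent": latent,
        "truth": truth,
        "raw": raw,
        "thinned": thinned,
        "calibration": cal,
        "evaluation": eva,
        "pca": pca,
        "pcs": pcs,
    }


@pytest.fixture(scope="session")
def small_world():
    """A faster 50x60 world with 4 PCs for model-mechanics tests."""
    grid = vn.RasterGrid(50, 60, -30.0, 25.0, 0.5)
    env, latent = vn.make_environment(grid, n_latent=2, n_layers=8, seed=7, smooth_sigma=5.0)
    truth = vn.make_species(latent, vn.TrueNiche((0.0, 0.0), (1.0, 1.0)))
    raw = vn.sample_occurrences(truth, n=200, dup_rate=0.0, lowprec_rate=0.0, seed=3, species="s")
    thinned = vn.thin_to_grid(vn.deduplicate(vn.filter_precision(raw)), grid, env.valid_mask)
    cal, eva = vn.split_calibration(thinned, 0.5, seed=4)
    pca = vn.fit_pca(env)
    pcs = vn.transform(env, pca, 4)
    bg = vn.sample_background(pcs, None, 2000, seed=5)
    return {
        "grid": grid,
        "env": env,
        "latent": latent,
        "truth": truth,
        "calibration": cal,
        "evaluation": eva,
        "pcs": pcs,
        "background": bg,
    }


def make_occurrences(points, species="sp", stage="raw", flags=None):
    """Build an OccurrenceSet from (lon, lat) pairs."""
    lons = [p[0] for p in points]
    lats = [p[1] for p in points]
    n = len(points)
    flags = flags or ["exact"] * n
    df = pd.DataFrame(
        {
            "species": species if isinstance(species, list) else [species] * n,
            "longitude": lons,
            "latitude": lats,
            "precision_flag": flags,
            "source_id": [f"r{i}" for i in range(n)],
        }
    )
    return vn.OccurrenceSet(df, stage)


@pytest.fixture
def occ_factory():
    return make_occurrences


def constant_suitability_map(grid, value=0.5, mask=None):
    vals = np.full(grid.shape, float(value))
    if mask is not None:
        vals[~mask] = np.nan
    return vn.SuitabilityMap(vn.Layer(grid, "s", vals), np.zeros(grid.shape, bool))


@pytest.fixture
def suit_map_factory():
    def make(grid, values):
        return vn.SuitabilityMap(
            vn.Layer(grid, "s", np.asarray(values, dtype=float)),
            np.zeros(grid.shape, bool),
        )

    return make
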