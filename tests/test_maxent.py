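import numpy as np
import pytest
from scipy import stats
from scipy.stats import spearmanr

import vectorniche as vn
from vectorniche.maxent import (
    FeatureSpec,
    fit_model,
    fit_replicates,
    predict,
    sample_background,
)


class TestSampleBackground:
    def test_draws_distinct_valid_cells(self, small_world):
        bg = sample_background(small_world["pcs"], None, 1000, seed=0)
        assert bg.shape == (1000, 2)
        assert len({(r, c) for r, c in bg}) == 1000

    def test_restricted_to_latitude_band(self, small_world):
        pcs = small_world["pcs"]
        grid = pcs.grid
        band = vn.CalibrationRegion(lat_max=10.0, lat_min=5.0)
        bg = sample_background(pcs, band, 200, seed=1)
        _, lats = grid.cell_center(bg[:, 0], bg[:, 1])
        assert ((lats >= 5.0) & (lats <= 10.0)).all()

    def test_uniform_over_region(self, small_world):
        # chi-square on row marginals of a large uniform draw
        pcs = small_world["pcs"]
        rng_draws = sample_background(pcs, None, 2500, seed=3)
        counts = np.bincount(rng_draws[:, 0], minlength=pcs.grid.n_rows)
        expected = np.full(pcs.grid.n_rows, 2500 / pcs.grid.n_rows)
        assert stats.chisquare(counts, expected).pvalue > 0.01

    def test_empty_region_rejected(self, small_world):
        pcs = small_world["pcs"]
        far = vn.CalibrationRegion(lat_max=-80.0, lat_min=-85.0)
        with pytest.raises(ValueError):
            sample_background(pcs, far, 10, seed=0)


class TestFitModel:
    def test_null_presences_give_flat_model(self, small_world, occ_factory):
        # presences drawn uniformly from background cells carry no signal
        pcs = small_world["pcs"]
        bg = small_world["background"]
        rng = np.random.default_rng(0)
        idx = rng.choice(len(bg), 200, replace=False)
        lon, lat = pcs.grid.cell_center(bg[idx, 0], bg[idx, 1])
        occ = occ_factory(list(zip(lon, lat)), stage="independent")
        model = fit_model(occ, bg, pcs)
        assert np.all(np.abs(model.weights) <= 0.05)
        smap = predict(model, pcs)
        vals = smap.values[~np.isnan(smap.values) & ~smap.novelty]
        assert vals.std() / vals.mean() < 0.05

    def test_presences_in_top_pc1_decile_get_positive_weight(self, small_world, occ_factory):
        pcs = small_world["pcs"]
        bg = small_world["background"]
        pc1 = pcs.layers[0].values
        thresh = np.nanquantile(pc1, 0.9)
        rows, cols = np.nonzero(pc1 >= thresh)
        rng = np.random.default_rng(1)
        pick = rng.choice(rows.size, 100, replace=False)
        lon, lat = pcs.grid.cell_center(rows[pick], cols[pick])
        occ = occ_factory(list(zip(lon, lat)), stage="independent")
        model = fit_model(occ, bg, pcs, spec=FeatureSpec(classes=("linear",)))
        assert model.weights[0] > 0

    def test_huge_penalty_zeroes_all_weights(self, small_world):
        model = fit_model(
            small_world["calibration"], small_world["background"],
            small_world["pcs"], beta=1e6,
        )
        assert np.all(model.weights == 0.0)

    def test_gibbs_normalization_invariant(self, small_world):
        model = fit_model(
            small_world["calibration"], small_world["background"], small_world["pcs"]
        )
        pcs = small_world["pcs"]
        bg = small_world["background"]
        Xb = pcs.values_at(bg[:, 0], bg[:, 1])
        mean_gibbs = np.mean(np.exp(model.eta(Xb) - model.log_normalizer))
        assert mean_gibbs == pytest.approx(1.0, abs=1e-6)

    def test_too_few_presences_rejected(self, small_world, occ_factory):
        occ = occ_factory([(0.0, 0.0)] * 5, stage="independent")
        with pytest.raises(ValueError, match="10"):
            fit_model(occ, small_world["background"], small_world["pcs"])

    def test_convexity_restarts_agree(self, small_world):
        cal, bg, pcs = (
            small_world["calibration"],
            small_world["background"],
            small_world["pcs"],
        )
        m0 = fit_model(cal, bg, pcs)
        rng = np.random.default_rng(5)
        m1 = fit_model(cal, bg, pcs, init_weights=rng.normal(scale=0.5, size=m0.weights.size))
        p0, p1 = predict(m0, pcs), predict(m1, pcs)
        np.testing.assert_allclose(p1.values, p0.values, atol=1e-4)


class TestPredict:
    def test_training_stack_max_is_exactly_one(self, small_world):
        model = fit_model(
            small_world["calibration"], small_world["background"], small_world["pcs"]
        )
        smap = predict(model, small_world["pcs"])
        assert np.nanmax(smap.values) == 1.0

    def test_out_of_range_cells_are_zero_and_flagged(self, small_world):
        pcs = small_world["pcs"]
        model = fit_model(small_world["calibration"], small_world["background"], pcs)
        shifted_layers = [
            vn.Layer(pcs.grid, l.name, l.values + (100.0 if i == 0 else 0.0))
            for i, l in enumerate(pcs.layers)
        ]
        shifted = vn.EnvStack(pcs.grid, shifted_layers, "future")
        smap = predict(model, shifted)
        valid = ~np.isnan(smap.values)
        assert (smap.values[valid] == 0.0).all()
        assert smap.novelty[valid].all()

    def test_zero_weight_model_predicts_one_everywhere_in_range(self, small_world):
        model = fit_model(
            small_world["calibration"], small_world["background"],
            small_world["pcs"], beta=1e6,
        )
        smap = predict(model, small_world["pcs"])
        vals = smap.values[~np.isnan(smap.values) & ~smap.novelty]
        assert (vals == 1.0).all()

    def test_layer_mismatch_rejected(self, small_world):
        model = fit_model(
            small_world["calibration"], small_world["background"], small_world["pcs"]
        )
        renamed = vn.EnvStack(
            small_world["pcs"].grid,
            [vn.Layer(l.grid, f"other_{l.name}", l.values) for l in small_world["pcs"].layers],
        )
        with pytest.raises(ValueError, match="match"):
            predict(model, renamed)


class TestFitReplicates:
    def test_single_replicate_has_zero_range(self, small_world):
        _, reps = fit_replicates(
            small_world["calibration"], small_world["pcs"], n_replicates=1,
            seed=0, background=small_world["background"],
        )
        np.testing.assert_array_equal(
            reps.median_map.values, reps.replicates[0].values
        )
        assert np.nanmax(reps.range_map.values) == 0.0

    def test_median_lies_within_replicate_envelope(self, small_world):
        _, reps = fit_replicates(
            small_world["calibration"], small_world["pcs"], n_replicates=5,
            seed=1, background=small_world["background"],
        )
        stack = np.stack([m.values for m in reps.replicates])
        med = reps.median_map.values
        valid = ~np.isnan(med)
        assert (med[valid] >= stack.min(axis=0)[valid] - 1e-12).all()
        assert (med[valid] <= stack.max(axis=0)[valid] + 1e-12).all()
        assert np.nanmin(reps.range_map.values) >= 0.0

    def test_reproducible_from_seed(self, small_world):
        _, r1 = fit_replicates(
            small_world["calibration"], small_world["pcs"], n_replicates=3,
            seed=9, background=small_world["background"],
        )
        _, r2 = fit_replicates(
            small_world["calibration"], small_world["pcs"], n_replicates=3,
            seed=9, background=small_world["background"],
        )
        np.testing.assert_array_equal(r1.median_map.values, r2.median_map.values)


class TestNicheRecovery:
    def test_predictions_rank_cells_like_the_true_niche(self, small_world):
        # scaled-down recovery check; the full-size version runs in the
        # acceptance suite
        models, reps = fit_replicates(
            small_world["calibration"], small_world["pcs"], n_replicates=5,
            seed=2, background=small_world["background"],
        )
        mask = small_world["env"].valid_mask
        rho = spearmanr(
            reps.median_map.values[mask], small_world["truth"].values[mask]
        ).statistic
        assert rho >= 0.85

    def test_irrelevant_noise_layer_barely_changes_ranking(self, small_world):
        pcs = small_world["pcs"]
        cal, bg = small_world["calibration"], small_world["background"]
        base = predict(fit_model(cal, bg, pcs), pcs)
        rng = np.random.default_rng(3)
        noise_vals = np.where(
            np.isnan(pcs.layers[0].values), np.nan, rng.normal(size=pcs.grid.shape)
        )
        widened = vn.EnvStack(
            pcs.grid, pcs.layers + [vn.Layer(pcs.grid, "PCnoise", noise_vals)]
        )
        noisy = predict(fit_model(cal, bg, widened), widened)
        mask = ~np.isnan(base.values)
        rho = spearmanr(base.values[mask], noisy.values[mask]).statistic
        assert rho >= 0.95
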