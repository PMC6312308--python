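import numpy as np
import pytest

import vectorniche as vn
from vectorniche.products import (
    apply_threshold,
    area_change,
    ensemble_future,
    stability_map,
    threshold_E,
)


def grid_for(n_cells):
    return vn.RasterGrid(1, n_cells, 0.0, 1.0, 1.0)


def suit_map(values, grid=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    g = grid or vn.RasterGrid(values.shape[0], values.shape[1], 0.0, float(values.shape[0]), 1.0)
    return vn.SuitabilityMap(vn.Layer(g, "s", values), np.zeros(g.shape, bool))


def points_at_cells(grid, cols, occ_factory, rows=None):
    rows = rows if rows is not None else np.zeros(len(cols), int)
    lon, lat = grid.cell_center(np.asarray(rows), np.asarray(cols))
    return occ_factory(list(zip(lon, lat)), stage="calibration")


def brute_force_tau(suits, E):
    """Oracle: scan every candidate cutoff for the maximal one with
    omission (fraction strictly below) <= E."""
    best = None
    for v in sorted(set(suits)):
        if np.mean(np.asarray(suits) < v) <= E:
            best = v
    return best


class TestThresholdE:
    def test_ten_equally_spaced_points_keep_lowest_cutoff(self, occ_factory):
        suits = [0.1 * k for k in range(1, 11)]
        g = grid_for(10)
        smap = suit_map([suits], g)
        occ = points_at_cells(g, np.arange(10), occ_factory)
        spec, binary = threshold_E(smap, occ, E=0.05)
        # removing even one of ten points is 10% > 5% omission
        assert spec.tau == pytest.approx(0.1)
        assert spec.omission == 0.0
        assert np.nansum(binary.values) == 10

    def test_hundred_points_cutoff_at_sixth_order_statistic(self, occ_factory):
        suits = [0.01 * k for k in range(1, 101)]
        g = grid_for(100)
        smap = suit_map([suits], g)
        occ = points_at_cells(g, np.arange(100), occ_factory)
        spec, _ = threshold_E(smap, occ, E=0.05)
        assert spec.tau == pytest.approx(0.06)
        assert spec.omission == pytest.approx(0.05)

    def test_zero_tolerance_keeps_minimum(self, occ_factory):
        suits = [0.37, 0.2, 0.9, 0.55]
        g = grid_for(4)
        smap = suit_map([suits], g)
        occ = points_at_cells(g, np.arange(4), occ_factory)
        spec, _ = threshold_E(smap, occ, E=0.0)
        assert spec.tau == pytest.approx(0.2)
        assert spec.omission == 0.0

    def test_maximality_against_brute_force_scan(self, occ_factory):
        rng = np.random.default_rng(0)
        for trial in range(200):
            n = int(rng.integers(5, 60))
            suits = np.round(rng.uniform(0, 1, n), 3)
            g = grid_for(n)
            smap = suit_map([suits], g)
            occ = points_at_cells(g, np.arange(n), occ_factory)
            spec, _ = threshold_E(smap, occ, E=0.05)
            assert spec.tau == pytest.approx(brute_force_tau(suits, 0.05))
            assert spec.omission <= 0.05

    def test_binary_area_is_antitone_in_tau(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(0, 1, (10, 10))
        smap = suit_map(vals)
        areas = [np.nansum(apply_threshold(smap, t).values) for t in np.linspace(0, 1, 21)]
        assert (np.diff(areas) <= 0).all()

    def test_empty_calibration_rejected(self, occ_factory):
        smap = suit_map([[0.5, 0.6]])
        occ = occ_factory([(50.0, 50.0)], stage="calibration")  # off-grid
        with pytest.raises(ValueError):
            with pytest.warns(UserWarning):
                threshold_E(smap, occ, E=0.05)


class TestEnsembleFuture:
    def test_identical_gcms_have_zero_range(self):
        m = suit_map([[0.2, 0.8], [0.5, 0.1]])
        ens = ensemble_future([m, m, m], tau=0.3)
        np.testing.assert_array_equal(ens.ensemble_median.values, m.values)
        assert np.nanmax(ens.uncertainty_range.values) == 0.0

    def test_median_and_range_arithmetic(self):
        maps = [suit_map([[v]]) for v in (0.2, 0.5, 0.8)]
        ens = ensemble_future(maps, tau=0.4)
        assert ens.ensemble_median.values[0, 0] == pytest.approx(0.5)
        assert ens.uncertainty_range.values[0, 0] == pytest.approx(0.6)
        assert ens.binary.values[0, 0] == 1.0

    def test_single_gcm_passthrough(self):
        m = suit_map([[0.3, 0.9]])
        ens = ensemble_future([m], tau=0.5)
        np.testing.assert_array_equal(ens.ensemble_median.values, m.values)

    def test_median_bounded_by_gcm_envelope(self):
        rng = np.random.default_rng(2)
        maps = [suit_map(rng.uniform(0, 1, (6, 7))) for _ in range(5)]
        ens = ensemble_future(maps, tau=0.5)
        stack = np.stack([m.values for m in maps])
        assert (ens.ensemble_median.values >= stack.min(axis=0)).all()
        assert (ens.ensemble_median.values <= stack.max(axis=0)).all()

    def test_grid_mismatch_rejected(self):
        a = suit_map([[0.1]])
        b = vn.SuitabilityMap(
            vn.Layer(vn.RasterGrid(1, 1, 5.0, 5.0, 1.0), "s", np.array([[0.1]])),
            np.zeros((1, 1), bool),
        )
        with pytest.raises(ValueError):
            ensemble_future([a, b], tau=0.5)


class TestAreaChange:
    def test_both_conventions(self):
        g = vn.RasterGrid(10, 100, 0.0, 10.0, 1.0)
        pv = np.zeros(g.shape)
        pv.ravel()[:100] = 1.0
        fv = np.zeros(g.shape)
        fv.ravel()[:103] = 1.0
        rel, tot = area_change(vn.Layer(g, "p", pv), vn.Layer(g, "f", fv))
        assert rel == pytest.approx(3.0)
        assert tot == pytest.approx(0.3)

    def test_identical_maps_have_zero_change(self):
        g = vn.RasterGrid(2, 2, 0.0, 2.0, 1.0)
        v = np.array([[1.0, 0.0], [0.0, 1.0]])
        rel, tot = area_change(vn.Layer(g, "p", v), vn.Layer(g, "f", v.copy()))
        assert rel == 0.0 and tot == 0.0

    def test_contraction_gives_negative_change(self):
        g = vn.RasterGrid(1, 4, 0.0, 1.0, 1.0)
        p = vn.Layer(g, "p", np.array([[1.0, 1.0, 1.0, 0.0]]))
        f = vn.Layer(g, "f", np.array([[1.0, 0.0, 0.0, 0.0]]))
        rel, tot = area_change(p, f)
        assert rel == pytest.approx(-200.0 / 3)
        assert tot == pytest.approx(-50.0)

    def test_empty_present_area_reported_as_undefined(self):
        g = vn.RasterGrid(1, 2, 0.0, 1.0, 1.0)
        p = vn.Layer(g, "p", np.zeros(g.shape))
        f = vn.Layer(g, "f", np.ones(g.shape))
        rel, tot = area_change(p, f)
        assert rel is None
        assert tot == pytest.approx(100.0)


class TestStabilityMap:
    def grid(self):
        return vn.RasterGrid(1, 6, 0.0, 1.0, 1.0)

    def test_rule_table(self):
        g = self.grid()
        # cells: stable, loss, gain-all, gain-partial, never, nodata
        present = vn.Layer(g, "p", np.array([[1, 1, 0, 0, 0, np.nan]], dtype=float))
        ensemble = vn.Layer(g, "e", np.array([[1, 0, 1, 0, 0, np.nan]], dtype=float))
        gcms = [
            vn.Layer(g, f"g{i}", np.array([[1, 0, 1, b, 0, np.nan]], dtype=float))
            for i, b in enumerate([1, 0, 1])  # partial agreement at cell 3
        ]
        stab = stability_map(present, gcms, ensemble)
        np.testing.assert_array_equal(stab.layer.values[0, :5], [1, 4, 2, 3, 0])
        assert np.isnan(stab.layer.values[0, 5])

    def test_all_zero_inputs_give_code_zero(self):
        g = self.grid()
        z = vn.Layer(g, "z", np.zeros(g.shape))
        stab = stability_map(z, [z, z], z)
        assert (stab.layer.values == 0).all()

    def test_codes_partition_valid_cells(self):
        rng = np.random.default_rng(3)
        g = vn.RasterGrid(20, 20, 0.0, 20.0, 1.0)
        mk = lambda: vn.Layer(g, "b", (rng.uniform(size=g.shape) > 0.5) * 1.0)
        present, ensemble = mk(), mk()
        gcms = [mk() for _ in range(9)]
        stab = stability_map(present, gcms, ensemble)
        assert sum(stab.counts.values()) == g.n_rows * g.n_cols

    def test_full_gcm_agreement_is_code_two_in_nine_of_nine(self):
        g = self.grid()
        present = vn.Layer(g, "p", np.zeros(g.shape))
        ensemble = vn.Layer(g, "e", np.ones(g.shape))
        all_on = [vn.Layer(g, f"g{i}", np.ones(g.shape)) for i in range(9)]
        stab = stability_map(present, all_on, ensemble)
        assert (stab.layer.values == 2).all()
        partial = all_on[:4] + [vn.Layer(g, f"h{i}", np.zeros(g.shape)) for i in range(5)]
        stab2 = stability_map(present, partial, ensemble)
        assert (stab2.layer.values == 3).all()
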