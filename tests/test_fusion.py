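"""Ratio computation, temporal fill, clipped IDW, and the fused field."""

import numpy as np
import pandas as pd
import pytest

import airfusion as af
from airfusion.errors import InsufficientDataError, UndefinedRatioError
from airfusion.fusion import (RatioPointSet, build_cell_ratio_matrix,
                              idw_interpolate)
from airfusion.grid import haversine_km
from airfusion.regression import build_annual_pairs, merge_monitors_to_cells

PARAMS = af.RegressionParams("pm25", 2011, alpha=3.0, beta=0.5, r2=1.0)


class TestPointRatio:
    def test_self_normalization(self):
        assert af.compute_point_ratio(5.0, 5.0, 2.0, 2.0, PARAMS) == pytest.approx(1.0)

    def test_obs_scaling(self):
        assert af.compute_point_ratio(10.0, 5.0, 2.0, 2.0, PARAMS) == pytest.approx(2.0)

    def test_worked_example(self):
        # obs/obs_mean = 2; alpha*model_mean^beta = 3*2; alpha*model^beta = 3*3
        r = af.compute_point_ratio(4.0, 2.0, 9.0, 4.0, PARAMS)
        assert r == pytest.approx(4.0 / 3.0, rel=1e-12)

    def test_alpha_cancels(self):
        other = af.RegressionParams("pm25", 2011, alpha=300.0, beta=0.5, r2=1.0)
        assert af.compute_point_ratio(4.0, 2.0, 9.0, 4.0, other) == \
            pytest.approx(af.compute_point_ratio(4.0, 2.0, 9.0, 4.0, PARAMS))

    @pytest.mark.parametrize("obs_mean,model,model_mean", [
        (0.0, 2.0, 2.0), (2.0, 0.0, 2.0), (2.0, 2.0, -1.0)])
    def test_undefined_ratio(self, obs_mean, model, model_mean):
        with pytest.raises(UndefinedRatioError):
            af.compute_point_ratio(1.0, obs_mean, model, model_mean, PARAMS)


class TestTemporalFill:
    def test_linear_between_samples(self):
        out = af.interpolate_ratio_series([1, 4], [1.0, 2.0], np.arange(1, 5))
        assert out == pytest.approx([1.0, 4.0 / 3.0, 5.0 / 3.0, 2.0])

    def test_edges_hold_nearest(self):
        out = af.interpolate_ratio_series([3], [1.5], np.arange(10))
        assert out == pytest.approx(np.full(10, 1.5))

    def test_dense_series_is_identity(self, rng):
        vals = rng.uniform(0.5, 2.0, 20)
        out = af.interpolate_ratio_series(np.arange(20), vals, np.arange(20))
        assert out == pytest.approx(vals)

    def test_empty_raises(self):
        with pytest.raises(InsufficientDataError):
            af.interpolate_ratio_series([], [], np.arange(5))


def test_clip_ratios_examples():
    out = af.clip_ratios(np.array([25.0, 0.01, 3.0]))
    assert out == pytest.approx([10.0, 0.1, 3.0])


def brute_force_idw(grid, lat, lon, vals, power=2.0, eps=0.001):
    out = np.empty(grid.n_cells)
    for c in range(grid.n_cells):
        num = den = 0.0
        exact = None
        for la, lo, v in zip(lat, lon, vals):
            d = float(haversine_km(grid.lat[c], grid.lon[c], la, lo))
            if d < eps:
                exact = v
            else:
                w = d ** -power
                num += w * v
                den += w
        out[c] = exact if exact is not None else num / den
    return out


def points(grid, cells, ratios):
    cells = np.asarray(cells, dtype=int)
    return RatioPointSet(date="2011-01-01", cell_ids=cells,
                         lat=grid.lat[cells], lon=grid.lon[cells],
                         ratios=np.asarray(ratios, dtype=float))


class TestIdw:
    def test_single_point_fills_domain(self, small_grid):
        out = idw_interpolate(points(small_grid, [7], [3.0]), small_grid, af.IdwSettings())
        assert out == pytest.approx(np.full(small_grid.n_cells, 3.0))

    def test_exact_at_nodes(self, small_grid, rng):
        cells = [0, 17, 55, 99]
        ratios = rng.uniform(0.5, 2.0, 4)
        out = idw_interpolate(points(small_grid, cells, ratios), small_grid, af.IdwSettings())
        assert out[cells] == pytest.approx(ratios, rel=1e-12)

    def test_equidistant_pair_averages(self):
        grid = af.GridDefinition(1, 3, np.full(3, 35.0), np.array([-0.1, 0.0, 0.1]))
        pts = RatioPointSet("d", np.array([0, 2]), grid.lat[[0, 2]],
                            np.array([-0.1, 0.1]), np.array([1.0, 3.0]))
        out = idw_interpolate(pts, grid, af.IdwSettings())
        assert out[1] == pytest.approx(2.0, rel=1e-12)

    def test_matches_bruteforce_on_random_instances(self, rng):
        for trial in range(10):
            grid = af.GridDefinition.regular(10, 10, 30 + trial, -100.0, 0.13, 0.11)
            n_pts = rng.integers(1, 12)
            cells = rng.choice(grid.n_cells, size=n_pts, replace=False)
            ratios = rng.uniform(0.1, 10.0, n_pts)
            out = idw_interpolate(points(grid, cells, ratios), grid, af.IdwSettings())
            ref = brute_force_idw(grid, grid.lat[cells], grid.lon[cells], ratios)
            np.testing.assert_allclose(out, ref, rtol=1e-12)

    def test_duplicate_locations_merged(self, small_grid):
        pts = RatioPointSet("d", np.array([4, 4]), small_grid.lat[[4, 4]],
                            small_grid.lon[[4, 4]], np.array([1.0, 3.0]))
        out = idw_interpolate(pts, small_grid, af.IdwSettings())
        assert out[4] == pytest.approx(2.0)

    def test_convex_combination_of_inputs(self, small_grid, rng):
        cells = rng.choice(small_grid.n_cells, 6, replace=False)
        ratios = rng.uniform(0.1, 10.0, 6)
        out = idw_interpolate(points(small_grid, cells, ratios), small_grid, af.IdwSettings())
        assert out.min() >= ratios.min() - 1e-12
        assert out.max() <= ratios.max() + 1e-12

    def test_no_points_raises(self, small_grid):
        with pytest.raises(InsufficientDataError):
            idw_interpolate(points(small_grid, [], []), small_grid, af.IdwSettings())


def test_fuse_day_examples(rng):
    corrected = rng.uniform(1, 10, 12)
    assert af.fuse_day(np.ones(12), corrected) == pytest.approx(corrected)
    assert af.fuse_day(np.full(12, 2.0), np.full(12, 5.0)) == pytest.approx(np.full(12, 10.0))
    assert af.fuse_day(np.full(12, 2.0), np.zeros(12)) == pytest.approx(np.zeros(12))
    with pytest.raises(ValueError):
        af.fuse_day(np.ones(12), np.ones(11))


class TestRunFusionYear:
    def test_monitor_cell_closed_form(self, scenario_small):
        """At a cell with one reporting monitor, the fused value collapses to
        obs * (alpha * model_mean**beta) / obs_mean."""
        data = scenario_small
        res = af.run_fusion_year(data.monitors, data.model, data.grid)
        pairs = build_annual_pairs(data.monitors, data.model, data.grid).set_index("cell_id")
        cell_obs = merge_monitors_to_cells(data.monitors, data.grid)
        fused = res.fused.to_pandas()
        p = res.params
        for _, row in cell_obs.iterrows():
            cell = row["cell_id"]
            expected = row["obs"] * (p.alpha * pairs.at[cell, "model_mean"] ** p.beta) \
                / pairs.at[cell, "obs_mean"]
            assert fused.at[row["date"], cell] == pytest.approx(expected, rel=1e-10)

    def test_sparse_monitor_gives_complete_fields(self, scenario_small):
        data = scenario_small
        sparse = data.monitors[data.monitors["sampling_freq"] == "1-in-3"]
        res = af.run_fusion_year(sparse, data.model, data.grid)
        assert res.fused.shape == data.model.shape
        assert np.all(np.isfinite(res.fused.values))

    def test_monitor_order_invariance(self, scenario_small):
        data = scenario_small
        shuffled = data.monitors.sample(frac=1.0, random_state=9)
        a = af.run_fusion_year(data.monitors, data.model, data.grid)
        b = af.run_fusion_year(shuffled, data.model, data.grid)
        np.testing.assert_array_equal(a.fused.values, b.fused.values)

    def test_bounded_correction_with_outlier(self, scenario_small):
        data = scenario_small
        poisoned = data.monitors.copy()
        victim = poisoned["site_id"].iloc[0]
        poisoned.loc[poisoned["site_id"] == victim, "value"] *= 1e3
        res = af.run_fusion_year(poisoned, data.model, data.grid)
        ratio = res.fused.values / res.corrected.values
        assert ratio.min() >= 0.1 - 1e-12
        assert ratio.max() <= 10.0 + 1e-12

    def test_no_monitors_returns_corrected(self, scenario_small):
        data = scenario_small
        params = af.RegressionParams("pm25", 2011, alpha=1.2, beta=0.9, r2=0.5)
        empty = data.monitors.iloc[0:0]
        with pytest.warns(UserWarning, match="no usable monitor"):
            res = af.run_fusion_year(empty, data.model, data.grid, params=params)
        np.testing.assert_array_equal(res.fused.values, res.corrected.values)

    def test_withheld_site_closer_to_truth_than_raw_model(self):
        """Smooth model bias: the fused field at a withheld monitor should beat
        the raw model against truth on most days."""
        scn = af.SyntheticScenario(n_rows=15, n_cols=20, n_days=90, n_sites=20, seed=3)
        data = af.generate_scenario(scn)
        withheld = data.monitors["site_id"].unique()[0]
        train = data.monitors[data.monitors["site_id"] != withheld]
        row = data.monitors[data.monitors["site_id"] == withheld].iloc[0]
        cell = af.assign_monitor_to_cell(row["lat"], row["lon"], data.grid)
        res = af.run_fusion_year(train, data.model, data.grid)
        truth = data.truth.values[:, cell]
        err_fused = np.abs(res.fused.values[:, cell] - truth)
        err_raw = np.abs(data.model.values[:, cell] - truth)
        assert np.mean(err_fused < err_raw) >= 0.8

    def test_provenance_recorded(self, scenario_small):
        res = af.run_fusion_year(scenario_small.monitors, scenario_small.model,
                                 scenario_small.grid, pollutant="pm25")
        assert res.provenance["regression"]["alpha"] == res.params.alpha
        assert res.provenance["n_monitor_cells"] == res.n_monitor_cells
        assert res.fused.attrs["idw_power"] == 2.0


def test_cell_ratio_matrix_interpolates_schedule(scenario_small):
    data = scenario_small
    pairs = build_annual_pairs(data.monitors, data.model, data.grid)
    params = af.fit_power_regression(pairs)
    cells, R = build_cell_ratio_matrix(data.monitors, data.model, data.grid,
                                       params, pairs)
    assert R.shape == (len(cells), data.scenario.n_days)
    assert np.all(np.isfinite(R)) and np.all(R > 0)
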