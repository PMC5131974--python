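"""Temperature correction, bootstrap comparison, regressions, generators."""

import itertools

import numpy as np
import pandas as pd
import pytest

import thermodrift as td
from thermodrift.compare import _metric


def toy_atlas(dtopt_value=3.2, tloc_value=20.0, n=10):
    """Flat single-rate atlas on an n×n all-ocean grid."""
    grid = td.OceanGrid(2.0 * np.arange(n + 1), 10.0 + 2.0 * np.arange(n + 1))
    atlas = td.DifferentialAtlas(grid)
    full = np.full((n, n), float)
    layer = {name: np.full((n, n), np.nan) for name in
             ("TOPTA", "TOPTNA", "DTOPT", "THISTG", "THISTS", "DTHISTS", "TLOC", "VPOL")}
    layer["TLOC"][:] = tloc_value
    layer["DTOPT"][:] = dtopt_value
    layer["TOPTA"][:] = tloc_value + dtopt_value + 1.0
    layer["TOPTNA"][:] = tloc_value + 1.0
    layer["THISTG"][:] = tloc_value
    layer["THISTS"][:] = tloc_value + dtopt_value
    layer["DTHISTS"][:] = dtopt_value
    layer["VPOL"][:] = 0.1
    atlas.add_layer(0.14, layer)
    return atlas


class TestCorrectTemperatures:
    def test_zero_differential_corrected_equals_local(self):
        atlas = toy_atlas(dtopt_value=0.0)
        obs = td.ObservationTable(pd.DataFrame(
            {"lon": [5.0, 9.0], "lat": [15.0, 21.0], "kind": "topt_iso",
             "value": [21.0, 22.0]}))
        out = td.correct_temperatures(obs, atlas, 0.14)
        assert np.allclose(out.table["t_corrected"], out.table["t_loc"])

    def test_direct_addition(self):
        atlas = toy_atlas(dtopt_value=3.2, tloc_value=20.0)
        obs = td.ObservationTable(pd.DataFrame(
            {"lon": [5.0], "lat": [15.0], "kind": "topt_iso", "value": [25.0]}))
        out = td.correct_temperatures(obs, atlas, 0.14)
        assert out.table["t_corrected"].iloc[0] == pytest.approx(23.2)

    def test_unmappable_observation_excluded_and_counted(self):
        atlas = toy_atlas()
        obs = td.ObservationTable(pd.DataFrame(
            {"lon": [5.0, 150.0], "lat": [15.0, 15.0], "kind": "topt_iso",
             "value": [1.0, 2.0]}))
        out = td.correct_temperatures(obs, atlas, 0.14)
        assert out.n == 1
        assert out.n_excluded == 1


class TestPairedBootstrap:
    def test_identical_predictions_give_zero_diff_p_one(self):
        rng = np.random.default_rng(0)
        obs = rng.normal(size=30)
        pred = obs + rng.normal(0, 0.5, 30)
        rep = td.paired_metric_bootstrap(obs, pred, pred, "rmse", 200, rng)
        assert rep.diff == 0.0
        assert rep.p_value == 1.0

    def test_perfect_vs_noisy_prediction_separates(self):
        rng = np.random.default_rng(1)
        obs = rng.normal(10, 3, 50)
        noisy = obs + rng.normal(0, 2.0, 50)
        rep = td.paired_metric_bootstrap(obs, obs, noisy, "rmse", 1000, rng)
        assert rep.diff < 0  # RMSE(A)=0 below RMSE(B)
        assert rep.p_value < 0.01

    def test_matches_enumerated_resample_oracle(self):
        """Tiny case: regenerate the generator's index draws and verify the
        bootstrap distribution against explicitly computed metrics."""
        obs = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        a = obs + np.array([0.1, -0.2, 0.3, 0.0, -0.1])
        b = obs + np.array([1.0, 1.0, -1.0, 0.5, -0.5])
        seed, n_boot = 7, 10
        rep = td.paired_metric_bootstrap(obs, a, b, "rmse", n_boot,
                                         np.random.default_rng(seed))
        rng2 = np.random.default_rng(seed)
        diffs = []
        for k in range(n_boot):
            idx = rng2.integers(0, 5, size=5)
            rm_a = np.sqrt(np.mean((obs[idx] - a[idx]) ** 2))
            rm_b = np.sqrt(np.mean((obs[idx] - b[idx]) ** 2))
            diffs.append(rm_a - rm_b)
        point = _metric(obs, a, "rmse") - _metric(obs, b, "rmse")
        expect_p = min(1.0, 2 * np.mean(np.sign(diffs) != np.sign(point)))
        assert rep.p_value == pytest.approx(expect_p)
        assert rep.metric_sd == pytest.approx(np.std(diffs))

    def test_zero_variance_observations_rejected_for_r2(self):
        with pytest.raises(ValueError, match="zero-variance"):
            td.paired_metric_bootstrap(np.ones(10), np.arange(10.0),
                                       np.arange(10.0), "r2", 10,
                                       np.random.default_rng(0))

    def test_null_p_values_calibrated(self):
        """Equally noisy predictions: p < 0.05 in ≈5% of repetitions."""
        rng = np.random.default_rng(42)
        hits = 0
        n_rep = 200
        for k in range(n_rep):
            obs = rng.normal(0, 1, 40)
            a = obs + rng.normal(0, 1, 40)
            b = obs + rng.normal(0, 1, 40)
            rep = td.paired_metric_bootstrap(obs, a, b, "rmse", 200, rng)
            hits += rep.p_value < 0.05
        # binomial(200, 0.05): central 99.9% within [1, 21]
        assert 1 <= hits <= 21


class TestEcotypeRegression:
    def test_perfect_line_r2_one(self):
        T = np.linspace(10, 30, 20)
        rep = td.ecotype_ratio_regression(-2.0 + 0.12 * T, T, n_boot=0)
        assert rep.r2 == pytest.approx(1.0)
        assert rep.slope == pytest.approx(0.12)

    def test_corrected_temperature_regression_improves_r2(self):
        """Log(R) generated from advection-shifted temperatures regresses
        better on corrected than on raw temperatures."""
        rng = np.random.default_rng(3)
        n = 80
        tloc = rng.uniform(10, 28, n)
        dtopt = rng.normal(0, 2.5, n)
        logr = -2.0 + 0.12 * (tloc + dtopt) + rng.normal(0, 0.05, n)
        raw = td.ecotype_ratio_regression(logr, tloc, n_boot=0)
        corr = td.ecotype_ratio_regression(logr, tloc + dtopt, n_boot=0)
        assert corr.r2 > raw.r2

    def test_slope_recovery_within_ci(self):
        """Generator slope inside the 95% CI in ≥90% of 100 seeds."""
        hits = 0
        beta = 0.12
        for seed in range(100):
            rng = np.random.default_rng(seed)
            T = rng.uniform(5, 30, 60)
            y = -2.0 + beta * T + rng.normal(0, 0.3, 60)
            rep = td.ecotype_ratio_regression(y, T, n_boot=0)
            half = 1.96 * rep.extras["stderr"]
            hits += abs(rep.slope - beta) <= half
        assert hits >= 90

    def test_r2_invariant_under_affine_predictor_rescaling(self):
        rng = np.random.default_rng(9)
        T = rng.uniform(0, 30, 50)
        y = 1.0 + 0.2 * T + rng.normal(0, 0.5, 50)
        r1 = td.ecotype_ratio_regression(y, T, n_boot=0).r2
        r2 = td.ecotype_ratio_regression(y, 3.7 * T - 11.0, n_boot=0).r2
        assert r1 == pytest.approx(r2, rel=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            td.ecotype_ratio_regression([1.0, 2.0], [1.0, 2.0])


class TestSeasonalSine:
    def test_pure_sine_exact_recovery(self):
        t = np.arange(0.0, 730.0, 3.0)
        y = 5.0 + 2.0 * np.sin(2 * np.pi * (t - 80.0) / 365.0)
        m, A, phi = td.fit_seasonal_sine(t, y)
        assert m == pytest.approx(5.0, abs=1e-6)
        assert A == pytest.approx(2.0, abs=1e-6)
        assert phi == pytest.approx(80.0, abs=1e-4)

    def test_48_day_offset_recovered_as_lag(self):
        t = np.arange(0.0, 730.0, 3.0)
        a = np.sin(2 * np.pi * (t - 10.0) / 365.0)
        b = np.sin(2 * np.pi * (t - 58.0) / 365.0)
        assert td.seasonal_lag(t, a, t, b) == pytest.approx(48.0, abs=1e-6)

    def test_noisy_amplitude_recovery(self):
        """SNR 5: amplitude within 10% in the large majority of seeds."""
        t = np.arange(0.0, 1095.0, 3.0)
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            y = 3.0 * np.sin(2 * np.pi * t / 365.0) + rng.normal(0, 0.6, t.size)
            _, A, _ = td.fit_seasonal_sine(t, y)
            hits += abs(A - 3.0) / 3.0 < 0.1
        assert hits >= 90

    def test_short_series_rejected(self):
        t = np.arange(0.0, 100.0, 3.0)
        with pytest.raises(ValueError):
            td.fit_seasonal_sine(t, np.sin(t))


class TestANDRegression:
    def test_constructed_linear_signal_recovered(self):
        rng = np.random.default_rng(5)
        n = 40
        T = rng.uniform(0, 30, n)
        c = 0.004
        m = c * np.abs(T[:, None] - T[None, :])
        rep = td.and_temperature_regression(m, T, n_boot=0)
        assert rep.slope == pytest.approx(c, rel=1e-9)
        assert rep.r2 == pytest.approx(1.0)
        assert rep.extras["n_pairs_ordered"] == n * (n - 1)
        assert rep.n == n * (n - 1) // 2

    def test_constant_and_gives_zero_slope(self):
        T = np.linspace(0, 30, 10)
        m = np.full((10, 10), 0.3)
        np.fill_diagonal(m, 0.0)
        # keep symmetric with zero diagonal but constant off-diagonal
        rep = td.and_temperature_regression(m, T, n_boot=0)
        assert rep.slope == pytest.approx(0.0, abs=1e-12)

    def test_asymmetric_matrix_rejected(self):
        m = np.zeros((4, 4))
        m[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            td.and_temperature_regression(m, np.arange(4.0))

    def test_corrected_temperatures_improve_r2(self):
        rng = np.random.default_rng(8)
        n = 30
        tloc = rng.uniform(5, 28, n)
        dt = rng.normal(0, 3, n)
        corr = tloc + dt
        m = 0.004 * np.abs(corr[:, None] - corr[None, :])
        noise = rng.normal(0, 0.004, (n, n))
        m = np.clip(m + 0.5 * (noise + noise.T), 0, 1)
        np.fill_diagonal(m, 0)
        raw = td.and_temperature_regression(m, tloc, n_boot=0)
        cor = td.and_temperature_regression(m, corr, n_boot=0)
        assert cor.r2 > raw.r2


class TestSyntheticObservations:
    def test_zero_noise_topt_equals_atlas(self):
        atlas = toy_atlas()
        obs = td.generate_synthetic_observations(atlas, "topt_iso", 20, 0.0,
                                                 np.random.default_rng(0))
        assert np.allclose(obs.table["value"], 24.2)  # TOPTA of the toy atlas

    def test_seeded_run_reproducible(self):
        atlas = toy_atlas()
        a = td.generate_synthetic_observations(atlas, "ecotype_logratio", 15, 1.0,
                                               np.random.default_rng(5))
        b = td.generate_synthetic_observations(atlas, "ecotype_logratio", 15, 1.0,
                                               np.random.default_rng(5))
        assert np.array_equal(a.table["value"], b.table["value"])

    def test_too_many_locations_rejected(self):
        atlas = toy_atlas(n=10)
        with pytest.raises(ValueError):
            td.generate_synthetic_observations(atlas, "topt_iso", 101, 0.0,
                                               np.random.default_rng(0))

    def test_detection_power_decreases_with_noise(self, bacteria_atlas):
        """The built-in advection signal is detected (p < 0.05) at low
        noise, and detection weakens monotonically as noise grows."""
        rate = bacteria_atlas.rates[0]
        p_by_noise = []
        for noise in (0.5, 2.0, 8.0):
            ps = []
            for seed in range(10):
                rng = np.random.default_rng(seed)
                obs = td.generate_synthetic_observations(
                    bacteria_atlas, "ecotype_logratio", 150, noise, rng, rate=rate)
                mapped = td.correct_temperatures(obs, bacteria_atlas, rate)
                y = mapped.table["value"].values
                raw = td.ecotype_ratio_regression(y, mapped.table["t_loc"].values, 0)
                cor = td.ecotype_ratio_regression(y, mapped.table["t_corrected"].values, 0)
                rep = td.paired_metric_bootstrap(
                    y,
                    raw.intercept + raw.slope * mapped.table["t_loc"].values,
                    cor.intercept + cor.slope * mapped.table["t_corrected"].values,
                    "rmse", 400, rng)
                ps.append(rep.p_value)
            p_by_noise.append(np.mean(ps))
        assert p_by_noise[0] < 0.05
        assert p_by_noise[0] <= p_by_noise[1] <= p_by_noise[2]


class TestImprovementTable:
    def test_formula_arithmetic(self):
        df = td.improvement_table({"metagenomes": (0.42, 0.43)})
        assert df["improvement_pct"].iloc[0] == pytest.approx(2.380952, abs=1e-4)

    def test_identical_r2_zero_improvement(self):
        df = td.improvement_table({"x": (0.5, 0.5)})
        assert df["improvement_pct"].iloc[0] == 0.0

    def test_average_is_mean_of_rows(self):
        df = td.improvement_table({"a": (0.4, 0.44), "b": (0.2, 0.21), "c": (0.5, 0.5)})
        rows = df[df["dataset"] != "Average"]["improvement_pct"]
        avg = df[df["dataset"] == "Average"]["improvement_pct"].iloc[0]
        assert avg == pytest.approx(rows.mean())

    def test_zero_baseline_reported_missing(self):
        df = td.improvement_table({"deg": (0.0, 0.3)})
        assert np.isnan(df["improvement_pct"].iloc[0])


class TestDirectEcotypeSimulation:
    def test_identical_curves_give_symmetric_ratio(self, small_forcing):
        cfg = td.SimConfig(duration_years=1.0, n_agents_target=40_000,
                           target_mean_growth=None, rng_seed=2)
        pair = [{"t_opt": 20.0}, {"t_opt": 20.0 + 1e-9}]
        times, logr, _ = td.direct_ecotype_simulation(cfg, small_forcing, pair,
                                                      engine="ibm")
        tail = logr[times > 180.0]
        assert np.nanmean(np.abs(tail)) < 0.25  # demographic noise only

    def test_warm_ecotype_wins_toward_warm_boundary(self, small_forcing):
        """Log(warm/cool) increases toward the warm (equatorward) side."""
        cfg = td.SimConfig(duration_years=2.0, n_agents_target=1,
                           carrying_capacity=500.0, target_mean_growth=None,
                           rng_seed=2)
        pair = [{"t_opt": 25.0}, {"t_opt": 13.0}]
        times, logr, out = td.direct_ecotype_simulation(cfg, small_forcing, pair,
                                                        engine="eulerian")
        mean_logr = np.nanmean(logr[times > 365.0], axis=0)
        lat = out.grid.lat_centers[out.cell_iy]
        south = mean_logr[lat < np.percentile(lat, 30)]
        north = mean_logr[lat > np.percentile(lat, 70)]
        assert np.nanmean(south) > np.nanmean(north) + 1.0

    def test_advection_changes_seasonal_lag_at_boundary_current(self, small_forcing):
        """With advection the ecotype ratio lags the local temperature
        longer at a western-boundary cell than without."""
        pair = [{"t_opt": 24.0}, {"t_opt": 14.0}]
        lags = {}
        for adv in (True, False):
            cfg = td.SimConfig(duration_years=3.0, n_agents_target=1,
                               carrying_capacity=500.0, target_mean_growth=None,
                               advection_enabled=adv, rng_seed=2)
            times, logr, out = td.direct_ecotype_simulation(
                cfg, small_forcing, pair, engine="eulerian")
            # western-boundary mid-latitude cell
            sel = (out.cell_ix == 1) & (out.cell_iy == out.grid.nlat // 2)
            cell = np.nonzero(sel)[0][0]
            keep = times > 365.0
            tser = out.t_loc[keep, cell]
            lser = logr[keep, cell]
            lags[adv] = td.seasonal_lag(times[keep], tser, times[keep], lser)
        assert lags[True] > lags[False]
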