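"""Validation metrics, dosing protocols, synthetic study fixtures and CLI."""

import json

import numpy as np
import pytest
from click.testing import CliRunner

from ketsim import (
    Scenario,
    StudySeries,
    generate_fixture_study,
    normalize_to_baseline,
    run_coupled_simulation,
    study_protocol,
    tccc_regimen,
    validation_metrics,
)
from ketsim.cli import main as cli_main


def series(times, mean, sem, vital="MAP"):
    return StudySeries(np.asarray(times, float), np.asarray(mean, float),
                       np.asarray(sem, float), vital, float(mean[0]))


class TestNormalize:
    def test_equal_baselines_leave_series_unchanged(self):
        pred = np.array([100.0, 120.0])
        assert np.array_equal(normalize_to_baseline(pred, 100.0, 100.0), pred)

    def test_rescales_by_baseline_ratio(self):
        got = normalize_to_baseline([100.0, 120.0], 100.0, 85.0)
        assert np.allclose(got, [85.0, 102.0])

    def test_zero_series_stays_zero(self):
        assert np.all(normalize_to_baseline([0.0, 0.0], 50.0, 100.0) == 0.0)

    def test_zero_predicted_baseline_rejected(self):
        with pytest.raises(ZeroDivisionError):
            normalize_to_baseline([1.0], 0.0, 1.0)


class TestMetrics:
    def test_perfect_prediction(self):
        obs = series([0, 1, 2], [100, 101, 99], [1, 1, 1])
        rep = validation_metrics([0, 1, 2], [100, 101, 99], obs)
        assert (rep.rmse, rep.mbe, rep.pct_within_2sem) == (0.0, 0.0, 100.0)

    def test_constant_shift(self):
        obs = series([0, 1, 2], [100, 100, 100], [5, 5, 5])
        rep = validation_metrics([0, 1, 2], [103, 103, 103], obs)
        assert rep.rmse == pytest.approx(3.0)
        assert rep.mbe == pytest.approx(3.0)

    def test_hand_computed_case(self):
        obs = series([0, 1], [100, 100], [1.0, 0.4])
        rep = validation_metrics([0, 1], [101, 99], obs)
        assert rep.rmse == pytest.approx(1.0)
        assert rep.mbe == pytest.approx(0.0)
        assert rep.pct_within_2sem == pytest.approx(50.0)

    def test_rmse_decomposition_identity(self):
        rng = np.random.default_rng(0)
        obs_mean = rng.normal(100, 5, 50)
        pred = obs_mean + rng.normal(1, 2, 50)
        obs = series(np.arange(50), obs_mean, np.ones(50))
        rep = validation_metrics(np.arange(50), pred, obs)
        resid = pred - obs_mean
        assert rep.rmse**2 == pytest.approx(rep.mbe**2 + resid.var(), rel=1e-9)
        assert rep.rmse >= abs(rep.mbe)

    def test_interpolation_alignment(self):
        obs = series([0.5], [10.0], [1.0])
        rep = validation_metrics([0.0, 1.0], [8.0, 12.0], obs)
        assert rep.rmse == pytest.approx(0.0, abs=1e-12)

    def test_empty_series_rejected(self):
        obs = series([0.0], [1.0], [0.1])
        with pytest.raises(ValueError):
            validation_metrics([], [], obs)

    def test_normalized_metrics_use_baseline_ratio(self):
        obs = series([0, 1], [85.0, 102.0], [1, 1])
        rep = validation_metrics([0, 1], [100.0, 120.0], obs, normalize=True)
        assert rep.rmse == pytest.approx(0.0, abs=1e-12)


class TestProtocols:
    def test_study_2_is_single_bolus(self):
        reg = study_protocol(2, 70.0)
        assert len(reg) == 1
        assert reg.events[0].dose == pytest.approx(17.5)
        assert reg.events[0].duration == 1.0

    def test_study_1_bolus_plus_slow_infusion(self):
        reg = study_protocol(1, 70.0)
        assert len(reg) == 2
        assert reg.events[0].dose == pytest.approx(16.1)
        assert reg.events[1].dose == pytest.approx(40.6)
        assert reg.events[1].start == 1.0
        assert reg.events[1].duration == 60.0

    def test_study_3_scales_with_mass(self):
        reg = study_protocol(3, 100.0)
        assert reg.events[0].dose == pytest.approx(26.0)
        assert reg.events[1].dose == pytest.approx(65.0)

    def test_unknown_study_rejected(self):
        with pytest.raises(KeyError):
            study_protocol(4)

    def test_tccc_default_timing(self):
        reg = tccc_regimen()
        starts = [e.start for e in reg.events]
        assert starts == [32.0, 57.0, 82.0, 107.0, 132.0]
        assert all(e.dose == pytest.approx(17.5) for e in reg.events)

    def test_tccc_single_dose_and_errors(self):
        assert len(tccc_regimen(n_doses=1)) == 1
        with pytest.raises(ValueError):
            tccc_regimen(interval_min=0.5)  # shorter than the 1-min infusion
        with pytest.raises(ValueError):
            tccc_regimen(dose_mg_per_kg=0.6)


class TestFixtureStudy:
    def _scenario(self):
        return Scenario(regimen=study_protocol(2), t_end=20.0, dt=0.02)

    def test_zero_noise_reproduces_model(self):
        sc = self._scenario()
        fx = generate_fixture_study(sc, noise_sd=0.0, n_subjects=5, seed=0,
                                    record_every=10)
        assert np.all(fx.sem == 0.0)
        rep = validation_metrics(fx.times, fx.mean, fx)
        assert (rep.rmse, rep.mbe, rep.pct_within_2sem) == (0.0, 0.0, 100.0)

    def test_seed_determinism(self):
        sc = self._scenario()
        a = generate_fixture_study(sc, noise_sd=2.0, seed=9, record_every=10)
        b = generate_fixture_study(sc, noise_sd=2.0, seed=9, record_every=10)
        assert np.array_equal(a.mean, b.mean) and np.array_equal(a.sem, b.sem)

    def test_model_rmse_against_own_noisy_fixture_is_bounded(self):
        """Sampling theory: RMSE of the generator against its own fixture
        stays below noise_sd * (1 + 2/sqrt(n)) (checked over seeds)."""
        sc = self._scenario()
        trace = run_coupled_simulation(sc, record_every=10)
        noise, n = 3.0, 10
        bound = noise * (1.0 + 2.0 / np.sqrt(n))
        for seed in range(5):
            fx = generate_fixture_study(sc, noise_sd=noise, n_subjects=n,
                                        seed=seed, record_every=10)
            rep = validation_metrics(trace.time_min, trace.map_mmHg, fx)
            assert rep.rmse < bound

    def test_rejects_bad_arguments(self):
        with pytest.raises(ValueError):
            generate_fixture_study(self._scenario(), noise_sd=-1.0)
        with pytest.raises(ValueError):
            generate_fixture_study(self._scenario(), n_subjects=1)


class TestStudySeries:
    def test_validation(self):
        with pytest.raises(ValueError):
            series([0, 1], [1, 2], [-0.1, 0.0])
        with pytest.raises(ValueError):
            series([1, 1], [1, 2], [0, 0])
        with pytest.raises(ValueError):
            StudySeries(np.array([0.0]), np.array([1.0]), np.array([0.0]),
                        "SBP", 1.0)

    def test_csv_round_trip(self, tmp_path):
        s = series([0, 1, 2], [100, 105, 99], [1, 2, 1], vital="HR")
        path = tmp_path / "study.csv"
        s.to_csv(path)
        back = StudySeries.from_csv(path)
        assert back.vital == "HR"
        assert np.allclose(back.mean, s.mean) and np.allclose(back.sem, s.sem)


class TestCLI:
    def test_simulate_and_validate_round_trip(self, tmp_path):
        scenario = tmp_path / "sc.yaml"
        scenario.write_text(
            "body_mass_kg: 70\nt_end_min: 10\ndt_min: 0.01\n"
            "doses:\n  - {start_min: 0, duration_min: 1, dose_mg_per_kg: 0.25}\n"
        )
        trace_csv = tmp_path / "trace.csv"
        runner = CliRunner()
        res = runner.invoke(cli_main, ["simulate", "--scenario", str(scenario),
                                       "--out", str(trace_csv),
                                       "--record-every", "50"])
        assert res.exit_code == 0, res.output
        assert trace_csv.exists()

        sc = Scenario.from_yaml(scenario)
        fx = generate_fixture_study(sc, noise_sd=1.0, seed=0, record_every=50)
        obs_csv = tmp_path / "obs.csv"
        fx.to_csv(obs_csv)
        res = runner.invoke(cli_main, ["validate", "--pred", str(trace_csv),
                                       "--obs", str(obs_csv), "--vital", "map"])
        assert res.exit_code == 0, res.output
        rep = json.loads(res.output)
        assert rep["rmse"] < 2.0

    def test_calibrate_writes_coefficients(self, tmp_path):
        out = tmp_path / "coeffs.json"
        runner = CliRunner()
        res = runner.invoke(cli_main, ["calibrate", "--out", str(out),
                                       "--n-map", "10", "--n-co", "10"])
        assert res.exit_code == 0, res.output
        data = json.loads(out.read_text())
        assert {"a0", "a_map", "a_co", "b0", "b_map", "b_co"} <= set(data)
        assert data["r2_map"] > 0.97
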