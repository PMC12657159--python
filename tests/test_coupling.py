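"""Offset transformation, grid calibration and the coupled simulation loop."""

import numpy as np
import pytest

from ketsim import (
    DoseEvent,
    DoseRegimen,
    InjuryProtocol,
    OffsetCoefficients,
    Scenario,
    calibrate_offsets,
    compute_offsets,
    run_coupled_simulation,
    simulate_cardio,
    steady_state,
)
from ketsim.coupling import SURROGATE_COEFFS
from ketsim.evaluation import tccc_regimen


class TestComputeOffsets:
    nominal = OffsetCoefficients.table_nominal()

    def test_homeostasis_point_near_zero(self):
        dm, dc = compute_offsets(100.0, 5.0, self.nominal)
        assert dm == pytest.approx(-0.85, abs=1e-9)
        assert dc == pytest.approx(-0.108, abs=1e-9)
        assert abs(dm) <= 1.0 and abs(dc) <= 0.15

    def test_elevated_targets(self):
        dm, dc = compute_offsets(140.0, 6.0, self.nominal)
        assert dm == pytest.approx(71.96, abs=1e-9)
        assert dc == pytest.approx(2.7008, abs=1e-9)

    def test_zero_coefficients_map_to_zero(self):
        zero = OffsetCoefficients(0, 0, 0, 0, 0, 0)
        assert compute_offsets(123.0, 4.5, zero) == (0.0, 0.0)

    def test_printed_sign_variant_breaks_homeostasis(self):
        """With the minus sign exactly as displayed in the source equation,
        the offsets at (100, 5) are hundreds of mmHg from zero — the
        motivation for the positive-sign resolution."""
        strict = OffsetCoefficients.table_nominal(strict_printed_sign=True)
        dm, _ = compute_offsets(100.0, 5.0, strict)
        assert abs(dm) > 100.0

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            compute_offsets(np.nan, 5.0, self.nominal)


@pytest.fixture(scope="module")
def calibration(cardio_params):
    return calibrate_offsets(cardio_params, n_map=25, n_co=25, dt=0.01)


class TestCalibration:
    def test_goodness_of_fit(self, calibration):
        assert calibration.r2_map >= 0.98
        assert calibration.r2_co >= 0.98
        assert calibration.n_excluded == 0

    def test_fitted_offsets_vanish_at_homeostasis(self, calibration):
        dm, dc = calibration.coefficients.homeostasis_residual(100.0, 5.0)
        assert abs(dm) <= 1.0
        assert abs(dc) <= 0.15

    def test_round_trip_tracking(self, calibration, cardio_params):
        """Offsets from the fitted inverse drive the closed loop to the
        requested targets within 2% (MAP) and 5% (CO)."""
        for map_t, co_t in ((130.0, 6.0), (120.0, 5.5)):
            off = compute_offsets(map_t, co_t, calibration.coefficients)
            m, c, ok = steady_state(cardio_params, off)
            assert ok
            assert abs(m - map_t) / map_t <= 0.02
            assert abs(c - co_t) / co_t <= 0.05

    def test_summary_mentions_fit(self, calibration):
        s = calibration.summary()
        assert "R2" in s and "delta_map" in s

    def test_rejects_tiny_grid(self, cardio_params):
        with pytest.raises(ValueError):
            calibrate_offsets(cardio_params, n_map=3, n_co=3)


class TestCoupledLoop:
    def test_drug_free_trace_matches_plain_cardio_bitwise(self, cardio_params):
        prot = InjuryProtocol.hemorrhage_scenario(0.2, hem_duration=5.0)
        sc = Scenario(regimen=DoseRegimen(), protocol=prot, t_end=15.0, dt=0.01)
        coupled = run_coupled_simulation(sc, record_every=10)
        plain = simulate_cardio(cardio_params, prot, offsets=None,
                                t_end=15.0, dt=0.01, record_every=10)
        assert np.array_equal(coupled["map_mmHg"], plain["map_mmHg"])
        assert np.array_equal(coupled["co_Lmin"], plain["co_Lmin"])
        assert np.array_equal(coupled["hr_bpm"], plain["hr_bpm"])
        assert np.all(coupled["delta_map_mmHg"] == 0.0)

    def test_drug_free_homeostasis(self):
        sc = Scenario(regimen=DoseRegimen(), t_end=60.0, dt=0.01)
        df = run_coupled_simulation(sc, record_every=100)
        assert df.map_mmHg.between(99.5, 100.5).all()
        assert df.co_Lmin.between(4.95, 5.05).all()

    def test_bolus_raises_vitals_then_returns(self, bolus_17p5):
        """Vitals rise within 5 min of a 0.25 mg/kg bolus; MAP is back
        within 1% of baseline by 60 min post-dose. CO retains a small
        (<2%) metabolite-driven deficit at that time."""
        sc = Scenario(regimen=bolus_17p5, t_end=61.0, dt=0.005)
        df = run_coupled_simulation(sc, record_every=20)
        early = df[df.time_min <= 5.0]
        assert early.map_mmHg.max() > 100.2
        assert early.co_Lmin.max() > 5.05
        end = df.iloc[-1]
        assert abs(end.map_mmHg - 100.0) / 100.0 < 0.01
        assert abs(end.co_Lmin - 5.0) / 5.0 < 0.02

    def test_trace_mass_balance(self, fast_scenario):
        df = run_coupled_simulation(fast_scenario, record_every=50)
        assert df.attrs["mass_balance_error_mg"] < 1e-6 * 17.5

    def test_recorded_deltas_follow_affine_map(self, fast_scenario):
        df = run_coupled_simulation(fast_scenario, record_every=50)
        c = SURROGATE_COEFFS
        dm0, dc0 = c.homeostasis_residual(100.0, 5.0)
        expect = (c.a0 + c.a_map * df.map_pd_mmHg + c.a_co * df.co_pd_Lmin) - dm0
        assert np.allclose(df.delta_map_mmHg, expect, atol=1e-12)

    def test_hemorrhage_attenuates_ketamine_increment(self):
        """Peak ketamine-attributable MAP and CO increments (first dose,
        given 2 min after hemorrhage ends) fall strictly with severity."""
        configs = [(0.0, 0.0), (0.15, 0.0), (0.30, 0.15), (0.45, 0.23)]
        inc_map, inc_co = [], []
        for hem, resus in configs:
            prot = (InjuryProtocol.hemorrhage_scenario(hem, resus)
                    if hem else InjuryProtocol())
            reg = tccc_regimen(n_doses=1)
            base = run_coupled_simulation(
                Scenario(regimen=DoseRegimen(), protocol=prot, t_end=57.0, dt=0.01),
                record_every=10)
            ket = run_coupled_simulation(
                Scenario(regimen=reg, protocol=prot, t_end=57.0, dt=0.01),
                record_every=10)
            w = base.time_min >= 32.0
            inc_map.append((ket.map_mmHg - base.map_mmHg)[w].max())
            inc_co.append((ket.co_Lmin - base.co_Lmin)[w].max())
        assert all(a > b for a, b in zip(inc_map, inc_map[1:]))
        assert all(a > b for a, b in zip(inc_co, inc_co[1:]))
        assert inc_map[0] > 0 and inc_co[-1] > 0


def test_scenario_yaml_round_trip(tmp_path):
    path = tmp_path / "scenario.yaml"
    path.write_text(
        "body_mass_kg: 80\n"
        "t_end_min: 20\n"
        "dt_min: 0.01\n"
        "doses:\n"
        "  - {start_min: 0, duration_min: 1, dose_mg_per_kg: 0.25}\n"
        "hemorrhage:\n"
        "  - {start_min: 2, duration_min: 10, fraction: 0.2}\n"
    )
    sc = Scenario.from_yaml(path)
    assert sc.body_mass_kg == 80.0
    assert sc.regimen.total_dose == pytest.approx(20.0)
    assert sc.protocol.hemorrhage[0].fraction == 0.2
    df = run_coupled_simulation(sc, record_every=100)
    assert not df.attrs["nonviable"]
    assert len(df) > 10
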