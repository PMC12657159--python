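"""The offset-coupling layer: affine transformation from PD targets to
controller-input offsets, its grid-simulation calibration, and the fully
coupled PK -> PD -> offsets -> cardiovascular simulation loop.

The pharmacodynamic models prescribe target vitals (MAP_PD, CO_PD); the
cardiovascular controllers, however, accept only their own inputs. The
bridge is an affine map

    delta_map = a0 + a_map * MAP_PD + a_co * CO_PD
    delta_co  = b0 + b_map * MAP_PD + b_co * CO_PD

whose coefficients are calibrated by sweeping constant offsets over a grid,
recording the steady-state (MAP, CO) each offset produces, and regressing
the offsets on the steady-state outcomes by ordinary least squares — i.e.
fitting the inverse of the forward offset->vitals map. At run time the
controllers then see (MAP - delta_map, CO - delta_co) at every Euler step,
which drives the closed loop toward the PD targets.

Offsets are applied baseline-corrected: the stepper subtracts the map's
evaluation at the drug-free baseline so that with no drug the offsets are
exactly zero and the coupled trace coincides bitwise with the plain
cardiovascular simulation (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cardio as _cardio
from .cardio import CardioParameters, InjuryProtocol, cardio_derivatives, cardio_outputs
from .parameters import (
    CoPDParameters,
    MapPDParameters,
    OffsetCoefficients,
    PKParameters,
)
from .pd_effects import co_pd as _co_pd
from .pd_effects import ke0, map_pd as _map_pd
from .pk import CONC_COLUMNS, DoseEvent, DoseRegimen, PKSolver, split_racemic

__all__ = [
    "compute_offsets",
    "CalibrationResult",
    "calibrate_offsets",
    "SURROGATE_COEFFS",
    "Scenario",
    "run_coupled_simulation",
    "TRACE_COLUMNS",
]

TRACE_COLUMNS = CONC_COLUMNS + [
    "ce_ket_gL",
    "ce_norket_gL",
    "map_pd_mmHg",
    "co_pd_Lmin",
    "delta_map_mmHg",
    "delta_co_Lmin",
    "map_mmHg",
    "co_Lmin",
    "ci_Lminm2",
    "hr_bpm",
    "blood_volume_L",
]


def compute_offsets(map_pd_value, co_pd_value, coeffs: OffsetCoefficients):
    """Evaluate the affine offset transformation (delta_map, delta_co)."""
    mp = np.asarray(map_pd_value, dtype=float)
    cp = np.asarray(co_pd_value, dtype=float)
    if not (np.all(np.isfinite(mp)) and np.all(np.isfinite(cp))):
        raise ValueError("PD targets must be finite")
    dm = coeffs.a0 + coeffs.a_map * mp + coeffs.a_co * cp
    dc = coeffs.b0 + coeffs.b_map * mp + coeffs.b_co * cp
    if dm.ndim == 0:
        return float(dm), float(dc)
    return dm, dc


@dataclass
class CalibrationResult:
    """Fitted offset coefficients with goodness-of-fit diagnostics.

    ``grid_records`` holds one row per converged grid point:
    (delta_map, delta_co, map_ss, co_ss).
    """

    coefficients: OffsetCoefficients
    r2_map: float
    r2_co: float
    grid_records: pd.DataFrame
    n_excluded: int = 0

    def summary(self) -> str:
        c = self.coefficients
        lines = [
            "Offset-coupling calibration (OLS on steady-state grid)",
            "=" * 56,
            f"grid points used      {len(self.grid_records):6d}   excluded {self.n_excluded}",
            f"delta_map = {c.a0:+10.4f} {c.a_map:+8.4f}*MAP_ss {c.a_co:+8.4f}*CO_ss   R2 = {self.r2_map:.4f}",
            f"delta_co  = {c.b0:+10.4f} {c.b_map:+8.4f}*MAP_ss {c.b_co:+8.4f}*CO_ss   R2 = {self.r2_co:.4f}",
        ]
        dm0, dc0 = c.homeostasis_residual()
        lines.append(
            f"homeostasis residual  delta_map(100,5) = {dm0:+.4f} mmHg, "
            f"delta_co(100,5) = {dc0:+.4f} L/min"
        )
        return "\n".join(lines)

    def to_json(self, path: str | Path) -> None:
        import json

        c = self.coefficients
        Path(path).write_text(json.dumps({
            "a0": c.a0, "a_map": c.a_map, "a_co": c.a_co,
            "b0": c.b0, "b_map": c.b_map, "b_co": c.b_co,
            "r2_map": self.r2_map, "r2_co": self.r2_co,
            "n_grid": len(self.grid_records), "n_excluded": self.n_excluded,
        }, indent=2))


class CalibrationError(RuntimeError):
    pass


def calibrate_offsets(
    cardio_params: CardioParameters | None = None,
    map_range: tuple[float, float] = (-20.0, 80.0),
    co_range: tuple[float, float] = (-2.0, 4.0),
    n_map: int = 100,
    n_co: int = 100,
    dt: float = 0.01,
    max_excluded_fraction: float = 0.05,
) -> CalibrationResult:
    """Calibrate the offset coefficients on the implemented cardiovascular core.

    Sweeps an ``n_map`` x ``n_co`` uniform grid of constant offsets over the
    given ranges, runs each to steady state (vectorised), and regresses each
    offset on (MAP_ss, CO_ss) by ordinary least squares. Non-converged grid
    points are excluded; more than ``max_excluded_fraction`` of them raises.
    """
    if n_map < 5 or n_co < 5:
        raise ValueError("need at least a 5 x 5 grid")
    params = cardio_params or CardioParameters()
    dm = np.linspace(*map_range, n_map)
    dc = np.linspace(*co_range, n_co)
    DM, DC = np.meshgrid(dm, dc, indexing="ij")
    map_ss, co_ss, ok = _cardio.steady_state(params, (DM.ravel(), DC.ravel()), dt=dt)
    n_excl = int((~ok).sum())
    if n_excl > max_excluded_fraction * ok.size:
        raise CalibrationError(
            f"{n_excl}/{ok.size} grid points failed to converge"
        )
    m, c = map_ss[ok], co_ss[ok]
    y_dm, y_dc = DM.ravel()[ok], DC.ravel()[ok]
    X = np.column_stack([np.ones(m.size), m, c])
    beta_m, *_ = np.linalg.lstsq(X, y_dm, rcond=None)
    beta_c, *_ = np.linalg.lstsq(X, y_dc, rcond=None)

    def r2(y, beta):
        resid = y - X @ beta
        return float(1.0 - resid.var() / y.var())

    coeffs = OffsetCoefficients(
        a0=float(beta_m[0]), a_map=float(beta_m[1]), a_co=float(beta_m[2]),
        b0=float(beta_c[0]), b_map=float(beta_c[1]), b_co=float(beta_c[2]),
    )
    records = pd.DataFrame({
        "delta_map": y_dm, "delta_co": y_dc, "map_ss": m, "co_ss": c,
    })
    return CalibrationResult(coeffs, r2(y_dm, beta_m), r2(y_dc, beta_c),
                             records, n_excluded=n_excl)


# Default runtime coefficients for the surrogate core, obtained by running
# calibrate_offsets(CardioParameters(), n_map=100, n_co=100, dt=0.01).
# Regenerate with `ketsim calibrate` after changing any cardiovascular
# parameter. The published Table-1 coefficients belong to the original
# 104-equation core and are available via OffsetCoefficients.table_nominal().
SURROGATE_COEFFS = OffsetCoefficients(
    a0=-120.2789457283909,
    a_map=1.0530475298574664,
    a_co=2.958434535581245,
    b0=-6.11116653509692,
    b_map=-0.011957836576573948,
    b_co=1.4876109494656828,
)


@dataclass
class Scenario:
    """A complete simulation scenario.

    Doses are supplied as a :class:`DoseRegimen` of total racemic mg events
    (helpers in :mod:`ketsim.evaluation` build them from mg/kg protocols).
    """

    body_mass_kg: float = 70.0
    regimen: DoseRegimen = field(default_factory=DoseRegimen)
    protocol: InjuryProtocol = field(default_factory=InjuryProtocol)
    t_end: float = 60.0
    dt: float = 4.17e-4

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Scenario":
        raw = yaml.safe_load(Path(path).read_text())
        mass = float(raw.get("body_mass_kg", 70.0))
        events = []
        for d in raw.get("doses", []):
            dose_mg = float(d["dose_mg_per_kg"]) * mass if "dose_mg_per_kg" in d \
                else float(d["dose_mg"])
            events.append(DoseEvent(float(d["start_min"]),
                                    float(d.get("duration_min", 1.0)), dose_mg))
        from ._events import VolumeEvent

        hem = [VolumeEvent(float(h["start_min"]), float(h["duration_min"]),
                           float(h["fraction"])) for h in raw.get("hemorrhage", [])]
        inf = [VolumeEvent(float(h["start_min"]), float(h["duration_min"]),
                           float(h["fraction"])) for h in raw.get("infusion", [])]
        return cls(
            body_mass_kg=mass,
            regimen=DoseRegimen(events),
            protocol=InjuryProtocol(hem, inf, label=raw.get("label", "none")),
            t_end=float(raw.get("t_end_min", 60.0)),
            dt=float(raw.get("dt_min", 4.17e-4)),
        )


def run_coupled_simulation(
    scenario: Scenario,
    pk_params: PKParameters | None = None,
    map_pd_params: MapPDParameters | None = None,
    co_pd_params: CoPDParameters | None = None,
    cardio_params: CardioParameters | None = None,
    coeffs: OffsetCoefficients | None = None,
    baseline_correction: bool = True,
    record_every: int = 1,
) -> pd.DataFrame:
    """Run the fully coupled simulation loop.

    Per Euler step: PK state -> plasma concentrations -> effect-site state ->
    (MAP_PD, CO_PD) -> offsets -> cardiovascular step with controller inputs
    (MAP - delta_map, CO - delta_co). Returns a trace DataFrame with columns
    ``TRACE_COLUMNS``; ``df.attrs['nonviable']`` flags early termination on
    blood-volume collapse.

    PD baselines default to the cardiovascular setpoints (the drug-free
    steady state of the core at simulation start). Numeric fields of the PD
    parameter objects may be NumPy arrays to run a batch of parameter sets
    in lockstep, in which case per-column arrays are returned.
    """
    pk_params = pk_params or PKParameters()
    cp = cardio_params or CardioParameters()
    map_p = map_pd_params or MapPDParameters(map_baseline=cp.map_setpoint)
    co_p = co_pd_params or CoPDParameters(co_baseline=cp.co_setpoint)
    coeffs = coeffs or SURROGATE_COEFFS

    dt = scenario.dt
    if scenario.t_end <= 0 or dt <= 0:
        raise ValueError("t_end and dt must be positive")
    n_steps = int(round(scenario.t_end / dt))
    rates = scenario.regimen.rate_steps(n_steps, dt)

    batch_shape = np.broadcast(
        np.asarray(map_p.emax), np.asarray(co_p.c25_ket),
        np.asarray(co_p.thalf_ket), np.asarray(pk_params.v_central_ket),
    ).shape

    pk = PKSolver(pk_params, dt, batch_shape)
    ce_k = np.zeros(batch_shape)
    ce_nk = np.zeros(batch_shape)
    ke_k = ke0(co_p.thalf_ket)
    ke_nk = ke0(co_p.thalf_norket)
    state = cp.baseline_state(batch_shape)

    # baseline offsets, subtracted so drug-free offsets are exactly zero
    if baseline_correction:
        dm0, dc0 = compute_offsets(map_p.map_baseline, co_p.co_baseline, coeffs)
    else:
        dm0, dc0 = 0.0, 0.0

    floor = cp.nonviable_fraction * cp.blood_volume_baseline
    times: list[float] = []
    rows: list[tuple] = []
    nonviable = False

    def record(t, conc, mp_v, cp_v, dm, dc, out):
        times.append(t)
        rows.append((
            conc["c_s_ket_gL"], conc["c_r_ket_gL"], conc["c_s_norket_gL"],
            conc["c_r_norket_gL"], conc["c_total_ket_gL"], ce_k, ce_nk,
            mp_v, cp_v, dm, dc,
            out["map"], out["co"], out["ci"], out["hr"], out["blood_volume"],
        ))

    def pd_and_offsets(conc):
        c_drive = conc["c_total_ket_gL"] if map_p.driving == "total" else conc["c_s_ket_gL"]
        mp_v = _map_pd(c_drive, map_p)
        cp_v = _co_pd((ce_k, ce_nk), co_p)
        dm, dc = compute_offsets(mp_v, cp_v, coeffs)
        return mp_v, cp_v, dm - dm0, dc - dc0

    for k in range(n_steps):
        t = k * dt
        conc = pk.concentrations()
        mp_v, cp_v, dm, dc = pd_and_offsets(conc)
        out = cardio_outputs(state, cp)
        if k % record_every == 0:
            record(t, conc, mp_v, cp_v, dm, dc, out)
        hem, inf = scenario.protocol.rates_at(t, cp.blood_volume_baseline)
        d = cardio_derivatives(state, cp, out["map"] - dm, out["co"] - dc, hem, inf)
        state = state + dt * d

        s_rate, r_rate = split_racemic(rates[k])
        cs_plasma = conc["c_s_ket_gL"]
        cnk_plasma = conc["c_s_norket_gL"]
        pk.step(s_rate, r_rate)
        ce_k = ce_k + dt * ke_k * (cs_plasma - ce_k)
        ce_nk = ce_nk + dt * ke_nk * (cnk_plasma - ce_nk)

        bv = state[..., 0] + state[..., 1]
        if batch_shape == () and float(bv) <= floor:
            nonviable = True
            break

    conc = pk.concentrations()
    mp_v, cp_v, dm, dc = pd_and_offsets(conc)
    record((k + 1) * dt if n_steps else 0.0, conc, mp_v, cp_v, dm, dc,
           cardio_outputs(state, cp))

    mass_err = float(np.max(np.abs(
        pk.state.sum(axis=-1) - (pk.infused_s + pk.infused_r)
    )))
    if batch_shape == ():
        df = pd.DataFrame([[float(v) for v in row] for row in rows],
                          columns=TRACE_COLUMNS[1:])
        df.insert(0, "time_min", times)
        df.attrs["nonviable"] = nonviable
        df.attrs["mass_balance_error_mg"] = mass_err
        return df
    # batch mode: dict of arrays shaped (n_records, *batch)
    out_arrays = {
        c: np.stack([np.broadcast_to(np.asarray(row[i], float), batch_shape)
                     for row in rows])
        for i, c in enumerate(TRACE_COLUMNS[1:])
    }
    out_arrays["time_min"] = np.asarray(times)
    return out_arrays
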