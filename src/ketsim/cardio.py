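"""Surrogate lumped-parameter cardiovascular core with baroreflex and
local-flow control, hemorrhage and fluid infusion.

The circulation is reduced to two compliant compartments (arterial, venous)
with a flow-source heart: CO = heart_gain * contractility * venous filling
pressure (a linearised Frank-Starling law). Two feedback controllers act on
the plant:

* a neuronal (baroreflex) controller, driven by the fractional MAP error,
  whose low-pass-filtered, saturating activation x_n raises heart rate,
  systemic resistance, cardiac contractility and venous tone (unstressed-
  volume recruitment);
* a local flow-autoregulation controller, driven by the fractional CO
  error, whose activation x_l raises peripheral conductance.

Both activations pass through an odd soft-clip saturation; its amplitude
and knee sharpness set the physiological ceiling of compensation. Under
severe hypovolemia the baroreflex activation x_n sits on its plateau, so
further controller-input offsets (e.g. ketamine-driven ones) yield little
additional response — the mechanism behind the attenuation of ketamine
effects with hemorrhage severity.

With zero offsets and no injury the plant is constructed to rest exactly at
the homeostasis point MAP = map_setpoint, CO = co_setpoint: the baseline
geometry (volumes, compliances, resistance, heart gain) is derived from the
setpoints so the drug-free error — and hence every controller state — is
identically zero.

State vector: [V_arterial (L), V_venous (L), x_n, x_l].
HR is an algebraic controller output, hr_baseline * (1 + w_hr * x_n).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._events import VolumeEvent, events_rate_at, validate_events

__all__ = [
    "CardioParameters",
    "CardioState",
    "InjuryProtocol",
    "cardio_derivatives",
    "cardio_outputs",
    "simulate_cardio",
    "steady_state",
    "SteadyStateError",
    "CARDIO_COLUMNS",
]

CARDIO_COLUMNS = [
    "time_min",
    "map_mmHg",
    "co_Lmin",
    "ci_Lminm2",
    "hr_bpm",
    "blood_volume_L",
]

N_STATE = 4
_IVA, _IVV, _IXN, _IXL = 0, 1, 2, 3


@dataclass
class CardioParameters:
    """Parameters of the surrogate cardiovascular core.

    The baseline hemodynamic geometry (compartment volumes, resistance and
    heart gain) is derived from the setpoints so homeostasis is an exact
    fixed point; the controller gains, saturation amplitudes and time
    constants are the tuning surface and were chosen so that (i) a 30%
    blood-volume hemorrhage drops MAP by roughly a third of baseline,
    (ii) the offset -> steady-state map is near-affine over the calibration
    grid, and (iii) baroreflex activation saturates under severe (45%)
    hemorrhage.
    """

    map_setpoint: float = 100.0        # mmHg
    co_setpoint: float = 5.0           # L/min
    hr_baseline: float = 70.0          # beats/min
    blood_volume_baseline: float = 5.0  # L
    bsa: float = 1.9                   # m^2, for CI = CO / BSA

    arterial_compliance: float = 0.004  # L/mmHg
    venous_compliance: float = 0.25     # L/mmHg
    venous_pressure_baseline: float = 5.0  # mmHg
    arterial_fraction: float = 0.2     # fraction of blood volume arterial side

    # neuronal (baroreflex) branch
    gain_neuronal: float = 6.0         # activation per unit fractional MAP error
    sat_neuronal: float = 1.2          # saturation amplitude of x_n
    tau_neuronal: float = 0.5          # min
    w_hr: float = 0.45                 # HR weight
    w_contractility: float = 0.6
    w_resistance: float = 0.8
    w_venous_tone: float = 0.25        # unstressed-volume recruitment weight

    # local (flow autoregulation) branch
    gain_local: float = 4.0
    sat_local: float = 1.6
    tau_local: float = 2.0             # min
    w_conductance: float = 0.8

    clip_neuronal: float = 2.0         # saturation knee exponent, baroreflex
    clip_local: float = 4.0            # saturation knee exponent, autoregulation
    nonviable_fraction: float = 0.2    # blood volume floor (fraction of baseline)

    # ---- derived baseline geometry ----
    @property
    def systemic_resistance_baseline(self) -> float:
        return (self.map_setpoint - self.venous_pressure_baseline) / self.co_setpoint

    @property
    def heart_gain(self) -> float:
        # CO = heart_gain * contractility * Pv; baseline contractility = 1
        return self.co_setpoint / self.venous_pressure_baseline

    @property
    def arterial_volume_baseline(self) -> float:
        return self.arterial_fraction * self.blood_volume_baseline

    @property
    def venous_volume_baseline(self) -> float:
        return (1.0 - self.arterial_fraction) * self.blood_volume_baseline

    @property
    def arterial_unstressed(self) -> float:
        return self.arterial_volume_baseline - self.arterial_compliance * self.map_setpoint

    @property
    def venous_unstressed(self) -> float:
        return (
            self.venous_volume_baseline
            - self.venous_compliance * self.venous_pressure_baseline
        )

    def baseline_state(self, batch_shape: tuple = ()) -> np.ndarray:
        s = np.zeros(batch_shape + (N_STATE,))
        s[..., _IVA] = self.arterial_volume_baseline
        s[..., _IVV] = self.venous_volume_baseline
        return s


@dataclass
class CardioState:
    """Convenience scalar view of the cardiovascular state with derived vitals."""

    arterial_volume: float
    venous_volume: float
    x_neuronal: float
    x_local: float
    map: float
    co: float
    ci: float
    hr: float

    @classmethod
    def from_vector(cls, vec: np.ndarray, params: CardioParameters) -> "CardioState":
        out = cardio_outputs(vec, params)
        return cls(
            float(vec[_IVA]), float(vec[_IVV]), float(vec[_IXN]), float(vec[_IXL]),
            float(out["map"]), float(out["co"]), float(out["ci"]), float(out["hr"]),
        )


class InjuryProtocol:
    """Timed hemorrhage and fluid-infusion events.

    Volumes are expressed as fractions of the baseline blood volume (in
    [0, 0.6]); events of the same kind must not overlap. ``label`` tags the
    canonical severities (none / moderate / severe).
    """

    def __init__(self, hemorrhage: list[VolumeEvent] | None = None,
                 infusion: list[VolumeEvent] | None = None, label: str = "none"):
        self.hemorrhage = validate_events(hemorrhage or [], "hemorrhage")
        self.infusion = validate_events(infusion or [], "infusion")
        if label not in ("none", "moderate", "severe"):
            raise ValueError("label must be none|moderate|severe")
        self.label = label

    def rates_at(self, t: float, blood_volume_baseline: float) -> tuple[float, float]:
        """(hemorrhage_rate, infusion_rate) in L/min at time t."""
        hem = events_rate_at(self.hemorrhage, t) * blood_volume_baseline
        inf = events_rate_at(self.infusion, t) * blood_volume_baseline
        return hem, inf

    @classmethod
    def hemorrhage_scenario(cls, hem_fraction: float, resus_fraction: float = 0.0,
                            hem_start: float = 0.0, hem_duration: float = 30.0,
                            monitoring: float = 2.0, resus_duration: float = 30.0,
                            resus_delay: float | None = None,
                            label: str = "none") -> "InjuryProtocol":
        """Canonical hemorrhage (+ optional resuscitation) timeline.

        Hemorrhage over ``hem_duration`` min, a monitoring gap, then fluid
        resuscitation over ``resus_duration`` min. ``resus_delay`` overrides
        the monitoring gap between hemorrhage end and resuscitation start.
        """
        hem = [VolumeEvent(hem_start, hem_duration, hem_fraction)] if hem_fraction else []
        inf = []
        if resus_fraction:
            delay = monitoring if resus_delay is None else resus_delay
            inf = [VolumeEvent(hem_start + hem_duration + delay,
                               resus_duration, resus_fraction)]
        return cls(hem, inf, label=label)


def _softclip(z, amplitude: float, sharpness: float):
    """Odd, strictly increasing soft saturation: ~identity for |z| << amplitude,
    plateauing at +/- amplitude with a knee sharpness set by the exponent."""
    z = np.asarray(z, dtype=float)
    return z / np.power(1.0 + np.power(np.abs(z) / amplitude, sharpness),
                        1.0 / sharpness)


def _activations(params: CardioParameters, eps_n, eps_l):
    a_n = _softclip(params.gain_neuronal * eps_n, params.sat_neuronal,
                    params.clip_neuronal)
    a_l = _softclip(params.gain_local * eps_l, params.sat_local,
                    params.clip_local)
    return a_n, a_l


def cardio_outputs(state: np.ndarray, params: CardioParameters) -> dict[str, np.ndarray]:
    """Derived hemodynamics (MAP, CO, CI, HR, pressures, resistance)."""
    state = np.asarray(state, dtype=float)
    va = state[..., _IVA]
    vv = state[..., _IVV]
    x_n = state[..., _IXN]
    x_l = state[..., _IXL]

    pa = (va - params.arterial_unstressed) / params.arterial_compliance
    vv_unstressed = params.venous_unstressed * (1.0 - params.w_venous_tone * x_n)
    pv = (vv - vv_unstressed) / params.venous_compliance
    contractility = 1.0 + params.w_contractility * x_n
    resistance = (
        params.systemic_resistance_baseline
        * (1.0 + params.w_resistance * x_n)
        / (1.0 + params.w_conductance * x_l)
    )
    co = params.heart_gain * contractility * np.maximum(pv, 0.0)
    hr = params.hr_baseline * (1.0 + params.w_hr * x_n)
    return {
        "map": pa,
        "co": co,
        "ci": co / params.bsa,
        "hr": hr,
        "venous_pressure": pv,
        "resistance": resistance,
        "blood_volume": va + vv,
    }


def cardio_derivatives(state: np.ndarray, params: CardioParameters,
                       controller_input_map, controller_input_co,
                       hemorrhage_rate=0.0, infusion_rate=0.0) -> np.ndarray:
    """State rate of change given (possibly offset) controller inputs.

    The neuronal branch is driven by the fractional error of
    ``controller_input_map`` against ``map_setpoint``, the local branch by
    the fractional error of ``controller_input_co`` against ``co_setpoint``.
    Blood volume changes at infusion_rate - hemorrhage_rate (applied to the
    venous compartment).
    """
    state = np.asarray(state, dtype=float)
    out = cardio_outputs(state, params)
    q_systemic = (out["map"] - out["venous_pressure"]) / out["resistance"]

    eps_n = (params.map_setpoint - np.asarray(controller_input_map, float)) / params.map_setpoint
    eps_l = (params.co_setpoint - np.asarray(controller_input_co, float)) / params.co_setpoint
    a_n, a_l = _activations(params, eps_n, eps_l)

    d = np.empty_like(state)
    d[..., _IVA] = out["co"] - q_systemic
    d[..., _IVV] = (
        q_systemic - out["co"]
        + np.asarray(infusion_rate, float) - np.asarray(hemorrhage_rate, float)
    )
    d[..., _IXN] = (a_n - state[..., _IXN]) / params.tau_neuronal
    d[..., _IXL] = (a_l - state[..., _IXL]) / params.tau_local
    return d


def _resolve_offsets(offsets, n_steps: int, dt: float):
    """Normalise the offsets argument to a per-step (dm, dc) callable."""
    if offsets is None:
        return lambda k: (0.0, 0.0)
    if callable(offsets):
        return lambda k: offsets(k * dt)
    arr = np.asarray(offsets, dtype=float)
    if arr.ndim == 1 and arr.shape == (2,):
        dm, dc = float(arr[0]), float(arr[1])
        return lambda k: (dm, dc)
    if arr.ndim == 2 and arr.shape[1] == 2:
        if arr.shape[0] < n_steps:
            raise ValueError("offsets series shorter than the number of steps")
        return lambda k: (arr[k, 0], arr[k, 1])
    raise ValueError("offsets must be None, (dm, dc), an (n_steps, 2) array or callable")


def simulate_cardio(params: CardioParameters, protocol: InjuryProtocol | None = None,
                    offsets=None, t_end: float = 60.0, dt: float = 0.01,
                    record_every: int = 1, initial_state: np.ndarray | None = None,
                    ) -> pd.DataFrame:
    """Euler simulation of the cardiovascular core alone.

    ``offsets`` supplies the controller-input offsets (delta_map, delta_co):
    the controllers see (MAP - delta_map, CO - delta_co). The trace carries
    ``df.attrs['nonviable']`` = True if blood volume fell to
    ``nonviable_fraction`` of baseline, at which point the simulation halts.
    """
    if t_end <= 0 or dt <= 0:
        raise ValueError("t_end and dt must be positive")
    protocol = protocol or InjuryProtocol()
    n_steps = int(round(t_end / dt))
    off = _resolve_offsets(offsets, n_steps, dt)
    state = params.baseline_state() if initial_state is None else np.array(initial_state, float)

    floor = params.nonviable_fraction * params.blood_volume_baseline
    times, rows = [], []
    nonviable = False

    def record(t):
        o = cardio_outputs(state, params)
        times.append(t)
        rows.append((float(o["map"]), float(o["co"]), float(o["ci"]),
                     float(o["hr"]), float(o["blood_volume"])))

    record(0.0)
    for k in range(n_steps):
        t = k * dt
        dm, dc = off(k)
        o = cardio_outputs(state, params)
        hem, inf = protocol.rates_at(t, params.blood_volume_baseline)
        d = cardio_derivatives(state, params, o["map"] - dm, o["co"] - dc, hem, inf)
        state = state + dt * d
        if float(state[_IVA] + state[_IVV]) <= floor:
            nonviable = True
            record((k + 1) * dt)
            break
        if (k + 1) % record_every == 0 or k == n_steps - 1:
            record((k + 1) * dt)

    df = pd.DataFrame(rows, columns=CARDIO_COLUMNS[1:])
    df.insert(0, "time_min", times)
    df.attrs["nonviable"] = nonviable
    df.attrs["final_state"] = state
    return df


class SteadyStateError(RuntimeError):
    """Raised when the core fails to settle; carries the last values."""

    def __init__(self, message: str, map_last=None, co_last=None):
        super().__init__(message)
        self.map_last = map_last
        self.co_last = co_last


def steady_state(params: CardioParameters, offsets, dt: float = 0.01,
                 tol: float = 1e-4, window: float = 1.0, t_cap: float = 120.0,
                 raise_on_fail: bool = True):
    """Steady-state (MAP, CO) under constant controller-input offsets.

    ``offsets`` is (delta_map, delta_co) with scalar or array entries; array
    entries are run as a batch in lockstep. Convergence requires the maximum
    state derivative over one simulated minute to fall below ``tol`` relative
    to per-state scales. Returns (map, co, converged_mask); scalar inputs
    give scalar map/co and a bool.
    """
    dm = np.asarray(offsets[0], dtype=float)
    dc = np.asarray(offsets[1], dtype=float)
    batch_shape = np.broadcast(dm, dc).shape
    scalar = batch_shape == ()
    state = params.baseline_state(batch_shape)
    scales = np.array([
        params.arterial_volume_baseline, params.venous_volume_baseline, 1.0, 1.0,
    ])

    n_window = max(1, int(round(window / dt)))
    n_cap = int(round(t_cap / dt))
    converged = np.zeros(batch_shape, dtype=bool)
    window_max = np.zeros(batch_shape)
    k = 0
    while k < n_cap:
        o = cardio_outputs(state, params)
        d = cardio_derivatives(state, params, o["map"] - dm, o["co"] - dc)
        state = state + dt * d
        rel = np.max(np.abs(d) / scales, axis=-1)
        window_max = np.maximum(window_max, rel)
        k += 1
        if k % n_window == 0:
            converged = converged | (window_max < tol)
            if np.all(converged):
                break
            window_max = np.zeros(batch_shape)

    o = cardio_outputs(state, params)
    map_out, co_out = o["map"], o["co"]
    if scalar:
        map_out, co_out = float(map_out), float(co_out)
        ok = bool(converged)
        if not ok and raise_on_fail:
            raise SteadyStateError(
                f"no steady state within {t_cap} min", map_out, co_out
            )
        return map_out, co_out, ok
    return map_out, co_out, converged
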