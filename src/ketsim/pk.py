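"""Enantiomer-resolved compartmental pharmacokinetics of intravenous
racemic ketamine and its metabolite norketamine.

Each enantiomer (S, R) is modelled with a central and a peripheral ketamine
compartment; eliminated parent drug passes through a transit chain (mean
transit time ``mtt_norket``) into a central/peripheral norketamine pair and
is finally cleared to a terminal sink, so total mass is conserved exactly:

    infused = central + peripheral + transit + norket(central + peripheral)
              + eliminated-to-sink          (per enantiomer, in mg)

Concentrations are reported in g/L (amount in mg / 1000 / volume in L).
Integration is fixed-step explicit Euler; every parameter may be a scalar
or a NumPy array, in which case a whole batch of parameter sets is
integrated in lockstep (used by the sensitivity machinery).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import PKParameters

__all__ = [
    "DoseEvent",
    "DoseRegimen",
    "split_racemic",
    "pk_derivatives",
    "simulate_pk",
    "PKSolver",
    "CONC_COLUMNS",
]

CONC_COLUMNS = [
    "time_min",
    "c_s_ket_gL",
    "c_r_ket_gL",
    "c_s_norket_gL",
    "c_r_norket_gL",
    "c_total_ket_gL",
]


@dataclass(frozen=True)
class DoseEvent:
    """A timed intravenous infusion of total racemic ketamine.

    ``dose`` is the total racemic mass in mg, delivered at constant rate
    over ``duration`` minutes starting at ``start`` minutes.
    """

    start: float
    duration: float
    dose: float

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("dose duration must be positive")
        if self.dose < 0:
            raise ValueError("dose must be nonnegative")
        if self.start < 0:
            raise ValueError("dose start must be nonnegative")

    @property
    def end(self) -> float:
        return self.start + self.duration

    @property
    def rate(self) -> float:
        """Total racemic infusion rate in mg/min."""
        return self.dose / self.duration


class DoseRegimen:
    """An ordered, non-overlapping collection of :class:`DoseEvent`."""

    def __init__(self, events: list[DoseEvent] | None = None):
        events = sorted(events or [], key=lambda e: e.start)
        for a, b in zip(events, events[1:]):
            if b.start < a.end - 1e-12:
                raise ValueError(
                    f"dose events overlap: [{a.start}, {a.end}) and [{b.start}, {b.end})"
                )
        self.events = events

    def __iter__(self):
        return iter(self.events)

    def __len__(self) -> int:
        return len(self.events)

    @property
    def total_dose(self) -> float:
        return sum(e.dose for e in self.events)

    @property
    def min_duration(self) -> float:
        return min((e.duration for e in self.events), default=np.inf)

    def rate_at(self, t: float) -> float:
        """Total racemic infusion rate (mg/min) at time t (left-closed events)."""
        for e in self.events:
            if e.start <= t < e.end:
                return e.rate
        return 0.0

    def rate_steps(self, n_steps: int, dt: float) -> np.ndarray:
        """Per-step total infusion rate for an Euler grid t_k = k*dt.

        The rate applied on step k moves the state from t_k to t_{k+1}; a dose
        event is mapped onto whole steps so that the infused mass is exact
        (rate = dose / (#steps * dt) over the steps it covers).
        """
        rates = np.zeros(n_steps)
        for e in self.events:
            k0 = int(round(e.start / dt))
            k1 = int(round(e.end / dt))
            k1 = min(k1, n_steps)
            if k1 <= k0:
                continue
            rates[k0:k1] += e.dose / ((k1 - k0) * dt)
        return rates

    def scaled(self, factor: float) -> "DoseRegimen":
        return DoseRegimen(
            [DoseEvent(e.start, e.duration, e.dose * factor) for e in self.events]
        )


def split_racemic(dose):
    """Split a total racemic dose (mg) into equal S- and R-enantiomer doses."""
    dose = np.asarray(dose, dtype=float)
    if np.any(dose < 0):
        raise ValueError("dose must be nonnegative")
    half = dose / 2.0
    if half.ndim == 0:
        h = float(half)
        return h, h
    return half, half


# State layout per enantiomer: [central_ket, periph_ket, transit_1..transit_n,
# central_norket, periph_norket, eliminated]; S block then R block.
def _width(n_transit: int) -> int:
    return 5 + n_transit


def state_width(params: PKParameters) -> int:
    return 2 * _width(params.n_transit)


def zero_state(params: PKParameters, batch_shape: tuple = ()) -> np.ndarray:
    return np.zeros(batch_shape + (state_width(params),))


def _enantiomer_rates(amounts, inf_rate, cl_elim, v_c, q, v_p,
                      cl_nk, q_nk, v_c_nk, v_p_nk, mtt, frac_met, n_transit):
    """Rates of change for one enantiomer block; shapes broadcast."""
    c_central = amounts[..., 0] / v_c            # mg/L
    c_periph = amounts[..., 1] / v_p
    c_c_nk = amounts[..., 2 + n_transit] / v_c_nk
    c_p_nk = amounts[..., 3 + n_transit] / v_p_nk

    elim_flux = cl_elim * c_central              # mg/min out of central
    exch = q * (c_central - c_periph)
    exch_nk = q_nk * (c_c_nk - c_p_nk)
    elim_nk = cl_nk * c_c_nk
    k_tr = n_transit / mtt

    d = np.empty_like(amounts)
    d[..., 0] = inf_rate - elim_flux - exch
    d[..., 1] = exch
    inflow = frac_met * elim_flux
    for i in range(n_transit):
        out = k_tr * amounts[..., 2 + i]
        d[..., 2 + i] = inflow - out
        inflow = out
    d[..., 2 + n_transit] = inflow - elim_nk - exch_nk
    d[..., 3 + n_transit] = exch_nk
    # terminal sink: cleared norketamine plus the unmetabolised parent fraction
    d[..., 4 + n_transit] = elim_nk + (1.0 - frac_met) * elim_flux
    return d


def pk_derivatives(state: np.ndarray, params: PKParameters,
                   infusion_rate_s, infusion_rate_r) -> np.ndarray:
    """Rate of change of the full PK state (mg/min per compartment).

    ``state`` has trailing dimension ``state_width(params)``; infusion rates
    are in mg/min per enantiomer. Raises on negative amounts or rates.
    """
    state = np.asarray(state, dtype=float)
    if np.any(state < -1e-12):
        raise ValueError("PK state amounts must be nonnegative")
    if np.any(np.asarray(infusion_rate_s) < 0) or np.any(np.asarray(infusion_rate_r) < 0):
        raise ValueError("infusion rates must be nonnegative")
    n = params.n_transit
    w = _width(n)
    d = np.empty_like(state)
    d[..., :w] = _enantiomer_rates(
        state[..., :w], infusion_rate_s,
        params.cl_elim_s_ket, params.v_central_ket, params.q_inter_ket,
        params.v_periph_ket, params.cl_elim_s_norket, params.q_inter_s_norket,
        params.v_central_norket, params.v_periph_norket, params.mtt_norket,
        params.frac_metabolized, n,
    )
    d[..., w:] = _enantiomer_rates(
        state[..., w:], infusion_rate_r,
        params.cl_elim_r_ket, params.v_central_ket, params.q_inter_ket,
        params.v_periph_ket, params.cl_central_r_norket, params.q_inter_r_norket,
        params.v_central_norket, params.v_periph_norket, params.mtt_norket,
        params.frac_metabolized, n,
    )
    return d


def concentrations(state: np.ndarray, params: PKParameters) -> dict[str, np.ndarray]:
    """Plasma concentrations (g/L) from a PK state (amounts in mg)."""
    n = params.n_transit
    w = _width(n)
    c_s = state[..., 0] / params.v_central_ket / 1000.0
    c_r = state[..., w + 0] / params.v_central_ket / 1000.0
    c_s_nk = state[..., 2 + n] / params.v_central_norket / 1000.0
    c_r_nk = state[..., w + 2 + n] / params.v_central_norket / 1000.0
    return {
        "c_s_ket_gL": c_s,
        "c_r_ket_gL": c_r,
        "c_s_norket_gL": c_s_nk,
        "c_r_norket_gL": c_r_nk,
        "c_total_ket_gL": c_s + c_r,
    }


def mass_balance_error(state: np.ndarray, params: PKParameters,
                       infused_s, infused_r) -> np.ndarray:
    """(compartments + sink) - infused, per enantiomer, summed (mg)."""
    w = _width(params.n_transit)
    tot_s = state[..., :w].sum(axis=-1)
    tot_r = state[..., w:].sum(axis=-1)
    return (tot_s - infused_s) + (tot_r - infused_r)


class PKSolver:
    """Fixed-step Euler integrator for the PK system, batch-capable.

    Create once per (params, dt); ``step`` advances one Euler step given the
    per-enantiomer infusion rates (mg/min).
    """

    def __init__(self, params: PKParameters, dt: float, batch_shape: tuple = ()):
        if dt <= 0:
            raise ValueError("dt must be positive")
        self.params = params
        self.dt = dt
        self.state = zero_state(params, batch_shape)
        self.infused_s = np.zeros(batch_shape)
        self.infused_r = np.zeros(batch_shape)

    def step(self, infusion_rate_s, infusion_rate_r) -> None:
        d = pk_derivatives(self.state, self.params, infusion_rate_s, infusion_rate_r)
        self.state = self.state + self.dt * d
        self.infused_s = self.infused_s + self.dt * np.asarray(infusion_rate_s, float)
        self.infused_r = self.infused_r + self.dt * np.asarray(infusion_rate_r, float)

    def concentrations(self) -> dict[str, np.ndarray]:
        return concentrations(self.state, self.params)


def simulate_pk(params: PKParameters, regimen: DoseRegimen, t_end: float,
                dt: float = 4.17e-4, record_every: int = 1) -> pd.DataFrame:
    """Simulate plasma concentrations for a dosing regimen.

    Returns a DataFrame with columns ``CONC_COLUMNS`` recorded every
    ``record_every`` Euler steps (plus the initial time 0 row), and the
    final mass-balance error in ``df.attrs['mass_balance_error_mg']``.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if len(regimen) and dt > regimen.min_duration:
        raise ValueError("dt must not exceed the shortest dose duration")
    n_steps = int(round(t_end / dt))
    rates = regimen.rate_steps(n_steps, dt)
    s_rates, r_rates = split_racemic(rates)

    solver = PKSolver(params, dt)
    times = [0.0]
    recs = [solver.concentrations()]
    for k in range(n_steps):
        solver.step(s_rates[k], r_rates[k])
        if (k + 1) % record_every == 0 or k == n_steps - 1:
            times.append((k + 1) * dt)
            recs.append(solver.concentrations())

    df = pd.DataFrame(
        {
            "time_min": np.asarray(times),
            **{c: np.asarray([r[c] for r in recs]) for c in CONC_COLUMNS[1:]},
        }
    )
    df.attrs["mass_balance_error_mg"] = float(
        mass_balance_error(solver.state, params, solver.infused_s, solver.infused_r)
    )
    df.attrs["total_infused_mg"] = float(solver.infused_s + solver.infused_r)
    return df


def peak_s_ketamine(params: PKParameters, regimen: DoseRegimen, t_end: float,
                    dt: float = 0.01) -> np.ndarray:
    """Peak S-ketamine plasma concentration (g/L) over [0, t_end].

    Vectorised over batched parameter arrays: pass a :class:`PKParameters`
    whose numeric fields are NumPy arrays of a common shape and the peak is
    returned with that shape. Only the running maximum is kept, so large
    batches stay memory-light.
    """
    n_steps = int(round(t_end / dt))
    rates = regimen.rate_steps(n_steps, dt)
    batch_shape = np.broadcast(
        np.asarray(params.v_central_ket), np.asarray(params.cl_elim_s_ket)
    ).shape
    solver = PKSolver(params, dt, batch_shape)
    peak = np.zeros(batch_shape)
    for k in range(n_steps):
        half = rates[k] / 2.0
        solver.step(half, half)
        c_s = solver.state[..., 0] / params.v_central_ket / 1000.0
        np.maximum(peak, c_s, out=peak)
    return peak
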