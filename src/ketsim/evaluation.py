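"""Validation metrics, baseline normalisation, the canonical dosing
protocols, and a synthetic study-series generator.

The three validation studies administered a 1-min racemic ketamine bolus
(0.23-0.26 mg/kg) to healthy volunteers, two of them followed by a 60-min
constant-rate infusion (0.58-0.65 mg/kg); doses here are per kg body mass
and scaled at construction. The battlefield analgesia regimen is a 1-min
infusion of 0.2-0.3 mg/kg repeated at 25-min intervals.

Model-to-study comparison follows the standard recipe: predictions are
rescaled so their baseline matches the observed baseline, interpolated to
the observation times, and summarised by RMSE, mean bias error, and the
percentage of predictions falling within +/-2 SEM of the observed mean.

No experimental time series ship with the package (the originals exist
only as published figures); :func:`generate_fixture_study` fabricates a
synthetic study — mean and SEM trajectories from noisy samples of the
model's own output — so the whole validation pipeline is exercisable
end to end. Anything it produces is synthetic by construction.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cardio import InjuryProtocol
from .coupling import Scenario, run_coupled_simulation
from .pk import DoseEvent, DoseRegimen

__all__ = [
    "StudySeries",
    "ValidationReport",
    "normalize_to_baseline",
    "validation_metrics",
    "study_protocol",
    "tccc_regimen",
    "generate_fixture_study",
    "STUDY_DOSES",
]

# study id -> (n_subjects, bolus mg/kg over 1 min, slow mg/kg over 60 min or None)
STUDY_DOSES: dict[int, tuple[int, float, float | None]] = {
    1: (10, 0.23, 0.58),
    2: (10, 0.25, None),
    3: (8, 0.26, 0.65),
}


@dataclass
class StudySeries:
    """An observed (or synthetic) vital-sign series: mean +/- SEM over time."""

    times: np.ndarray         # min, strictly increasing
    mean: np.ndarray          # vital units
    sem: np.ndarray           # same units, >= 0
    vital: str                # MAP | HR | CI
    baseline_value: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        self.sem = np.asarray(self.sem, dtype=float)
        if not (self.times.size == self.mean.size == self.sem.size):
            raise ValueError("times/mean/sem must have equal length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.sem < 0):
            raise ValueError("sem must be nonnegative")
        if self.vital not in ("MAP", "HR", "CI"):
            raise ValueError("vital must be MAP, HR or CI")

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# vital={self.vital} baseline={self.baseline_value}\n")
            pd.DataFrame({"time_min": self.times, "mean": self.mean,
                          "sem": self.sem}).to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "StudySeries":
        text = Path(path).read_text().splitlines()
        meta = {}
        if text and text[0].startswith("#"):
            for tok in text[0].lstrip("# ").split():
                k, _, v = tok.partition("=")
                meta[k] = v
            text = text[1:]
        df = pd.read_csv(io.StringIO("\n".join(text)))
        return cls(df["time_min"].to_numpy(), df["mean"].to_numpy(),
                   df["sem"].to_numpy(), meta.get("vital", "MAP"),
                   float(meta.get("baseline", df["mean"].iloc[0])))


@dataclass
class ValidationReport:
    """RMSE / mean-bias-error / %-within-2-SEM agreement summary."""

    rmse: float
    mbe: float
    pct_within_2sem: float

    def to_dict(self) -> dict[str, float]:
        return {"rmse": self.rmse, "mbe": self.mbe,
                "pct_within_2sem": self.pct_within_2sem}


def normalize_to_baseline(pred, pred_baseline: float, obs_baseline: float):
    """Rescale predictions by the observed/predicted baseline ratio."""
    if pred_baseline == 0:
        raise ZeroDivisionError("predicted baseline must be nonzero")
    return np.asarray(pred, dtype=float) * (obs_baseline / pred_baseline)


def validation_metrics(pred_times, pred_values, obs: StudySeries,
                       normalize: bool = False,
                       pred_baseline: float | None = None) -> ValidationReport:
    """Agreement metrics between a predicted trajectory and a study series.

    Predictions are linearly interpolated to the observation times. With
    ``normalize=True`` they are first baseline-rescaled (predicted baseline
    defaults to the first predicted value).
    """
    pred_times = np.asarray(pred_times, dtype=float)
    pred_values = np.asarray(pred_values, dtype=float)
    if pred_times.size == 0 or obs.times.size == 0:
        raise ValueError("empty series")
    if normalize:
        pb = pred_values[0] if pred_baseline is None else pred_baseline
        pred_values = normalize_to_baseline(pred_values, pb, obs.baseline_value)
    aligned = np.interp(obs.times, pred_times, pred_values)
    resid = aligned - obs.mean
    rmse = float(np.sqrt(np.mean(resid**2)))
    mbe = float(np.mean(resid))
    pct = float(100.0 * np.mean(np.abs(resid) <= 2.0 * obs.sem))
    return ValidationReport(rmse, mbe, pct)


def study_protocol(study_id: int, body_mass_kg: float = 70.0) -> DoseRegimen:
    """Dose regimen of one of the three validation studies, scaled to mass."""
    if study_id not in STUDY_DOSES:
        raise KeyError(f"unknown study id {study_id!r}; valid: 1, 2, 3")
    _, bolus, slow = STUDY_DOSES[study_id]
    events = [DoseEvent(0.0, 1.0, bolus * body_mass_kg)]
    if slow is not None:
        events.append(DoseEvent(1.0, 60.0, slow * body_mass_kg))
    return DoseRegimen(events)


def tccc_regimen(dose_mg_per_kg: float = 0.25, body_mass_kg: float = 70.0,
                 n_doses: int = 5, start_min: float = 32.0,
                 interval_min: float = 25.0,
                 duration_min: float = 1.0) -> DoseRegimen:
    """Repeated-bolus battlefield analgesia regimen.

    ``n_doses`` 1-min infusions of ``dose_mg_per_kg`` at ``interval_min``
    spacing, the first at ``start_min`` (default 32 min: hemorrhage over
    30 min plus a 2-min monitoring gap).
    """
    if not (0.1 <= dose_mg_per_kg <= 0.5):
        raise ValueError("dose must lie in [0.1, 0.5] mg/kg")
    if n_doses < 1:
        raise ValueError("n_doses must be >= 1")
    if interval_min < duration_min and n_doses > 1:
        raise ValueError("interval shorter than infusion duration")
    dose_mg = dose_mg_per_kg * body_mass_kg
    return DoseRegimen([
        DoseEvent(start_min + i * interval_min, duration_min, dose_mg)
        for i in range(n_doses)
    ])


def generate_fixture_study(scenario: Scenario, vital: str = "MAP",
                           noise_sd: float = 3.0, n_subjects: int = 10,
                           seed: int = 0, grid_min: float = 1.0,
                           **sim_kwargs) -> StudySeries:
    """Synthetic study series from the model's own output (test fixture).

    Runs the coupled simulation, samples ``n_subjects`` trajectories with
    additive i.i.d. Gaussian noise, and returns mean and SEM (= sd/sqrt(n))
    on a ``grid_min``-minute grid. Purely synthetic; stands in for digitised
    experimental curves that are not redistributable.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    col = {"MAP": "map_mmHg", "HR": "hr_bpm", "CI": "ci_Lminm2"}[vital]
    trace = run_coupled_simulation(scenario, **sim_kwargs)
    grid = np.arange(0.0, scenario.t_end + 1e-9, grid_min)
    truth = np.interp(grid, trace["time_min"], trace[col])
    rng = np.random.default_rng(seed)
    samples = truth[None, :] + rng.normal(0.0, noise_sd, size=(n_subjects, grid.size))
    mean = samples.mean(axis=0)
    sem = samples.std(axis=0, ddof=1) / np.sqrt(n_subjects)
    if noise_sd == 0:
        mean, sem = truth.copy(), np.zeros_like(truth)
    return StudySeries(grid, mean, sem, vital, baseline_value=float(mean[0]))
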