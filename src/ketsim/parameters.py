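"""Nominal parameter tables and parameter containers.

The 24 "new" parameters of the extended model are conventionally numbered
P1-P24: P1-P11 are the enantiomer-resolved ketamine/norketamine
pharmacokinetic parameters, P12-P15 the cardiac-output effect-compartment
pharmacodynamics, P16-P18 the sigmoid-Emax MAP pharmacodynamics, and
P19-P24 the six coefficients of the affine offset transformation.

Overrides may be supplied as YAML or JSON files keyed either by the P#
labels (``P3: 30.0``) or by field names (``v_central_ket: 30.0``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, fields, replace
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "PKParameters",
    "MapPDParameters",
    "CoPDParameters",
    "OffsetCoefficients",
    "TABLE_NOMINAL",
    "PNUM_TO_FIELD",
    "nominal_parameter_vector",
    "load_overrides",
    "apply_overrides",
]


@dataclass
class PKParameters:
    """Enantiomer-resolved two-compartment ketamine PK with a transit-delayed
    norketamine metabolite (amounts in mg, volumes in L, clearances in L/min).

    ``v_central_norket`` is not separately identifiable in the source data and
    defaults to the ketamine central volume; ``frac_metabolized`` routes that
    fraction of eliminated parent drug into norketamine formation.
    """

    cl_elim_s_ket: float = 1.78
    cl_elim_r_ket: float = 1.58
    v_central_ket: float = 25.80
    q_inter_ket: float = 2.10
    v_periph_ket: float = 115.00
    v_periph_norket: float = 240.00
    cl_elim_s_norket: float = 1.00
    q_inter_s_norket: float = 3.27
    mtt_norket: float = 26.60
    cl_central_r_norket: float = 0.73
    q_inter_r_norket: float = 2.55
    v_central_norket: float | None = None
    frac_metabolized: float = 1.0
    n_transit: int = 1

    def __post_init__(self) -> None:
        if self.v_central_norket is None:
            self.v_central_norket = self.v_central_ket
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name == "n_transit":
                if int(v) < 1:
                    raise ValueError("n_transit must be >= 1")
                continue
            if f.name == "frac_metabolized":
                import numpy as _np

                if _np.any(_np.asarray(v) < 0) or _np.any(_np.asarray(v) > 1):
                    raise ValueError("frac_metabolized must lie in [0, 1]")
                continue
            import numpy as _np

            if _np.any(_np.asarray(v, dtype=float) <= 0):
                raise ValueError(f"PK parameter {f.name} must be strictly positive")


@dataclass
class MapPDParameters:
    """Sigmoid Emax model of the ketamine-induced MAP rise.

    ``driving`` selects the plasma species driving the effect (total racemic
    ketamine by default). ``concentration_scale`` multiplies the driving
    concentration before the Emax evaluation; the nominal C50 sits far above
    plasma levels reached at analgesic doses, a documented inconsistency of
    the source parameterisation, and this knob lets users explore it without
    silently rescaling anything (default 1.0 = use the table as printed).
    """

    emax: float = 51.60           # mmHg
    c50: float = 4.68e-3          # g/L
    gamma: float = 2.04
    map_baseline: float = 100.0   # mmHg
    driving: str = "total"        # "total" (S+R) or "s_only"
    concentration_scale: float = 1.0

    def __post_init__(self) -> None:
        import numpy as _np

        for name in ("emax", "c50", "gamma"):
            if _np.any(_np.asarray(getattr(self, name)) <= 0):
                raise ValueError(f"MAP PD parameter {name} must be positive")
        if self.driving not in ("total", "s_only"):
            raise ValueError("driving must be 'total' or 's_only'")


@dataclass
class CoPDParameters:
    """Effect-compartment model of the ketamine-induced CO change.

    S-ketamine raises CO by 25% at ``c25_ket`` while S-norketamine opposes it
    (25% reduction at ``c25_norket``); both act through first-order effect
    compartments parameterised by half-lives. The fractional effects combine
    linearly and the result is floored at ``floor_fraction`` of baseline as a
    numerical guard against extreme parameter draws.
    """

    c25_ket: float = 4.00e-4      # g/L
    c25_norket: float = 1.60e-4   # g/L
    thalf_ket: float = 2.28       # min
    thalf_norket: float = 29.30   # min
    co_baseline: float = 5.0      # L/min
    norket_sign: float = -1.0     # -1: norketamine opposes ketamine
    linear: bool = True
    floor_fraction: float = 0.1

    def __post_init__(self) -> None:
        import numpy as _np

        for name in ("c25_ket", "c25_norket", "thalf_ket", "thalf_norket", "co_baseline"):
            if _np.any(_np.asarray(getattr(self, name)) <= 0):
                raise ValueError(f"CO PD parameter {name} must be positive")


@dataclass
class OffsetCoefficients:
    """Affine transformation from PD targets to controller offsets.

    delta_map = a0 + a_map * map_pd + a_co * co_pd
    delta_co  = b0 + b_map * map_pd + b_co * co_pd

    The nominal table prints the magnitude 1.47 for the MAP_PD coefficient of
    delta_map while the displayed equation carries a minus sign; only +1.47
    is consistent with near-zero offsets at the (100 mmHg, 5 L/min)
    homeostasis point, so the positive sign is the default resolution.
    """

    a0: float = -217.90
    a_map: float = 1.47
    a_co: float = 14.01
    b0: float = -14.68
    b_map: float = -5.28e-3
    b_co: float = 3.02

    @classmethod
    def table_nominal(cls, strict_printed_sign: bool = False) -> "OffsetCoefficients":
        """Nominal published coefficients; ``strict_printed_sign`` keeps the
        minus sign exactly as displayed in the source equation (audit mode)."""
        c = cls()
        if strict_printed_sign:
            c = replace(c, a_map=-1.47)
        return c

    def homeostasis_residual(self, map_setpoint: float = 100.0, co_setpoint: float = 5.0):
        dm = self.a0 + self.a_map * map_setpoint + self.a_co * co_setpoint
        dc = self.b0 + self.b_map * map_setpoint + self.b_co * co_setpoint
        return dm, dc


# P# -> (parameter group, field name). Groups: pk / co_pd / map_pd / coupling.
PNUM_TO_FIELD: dict[str, tuple[str, str]] = {
    "P1": ("pk", "cl_elim_s_ket"),
    "P2": ("pk", "cl_elim_r_ket"),
    "P3": ("pk", "v_central_ket"),
    "P4": ("pk", "q_inter_ket"),
    "P5": ("pk", "v_periph_ket"),
    "P6": ("pk", "v_periph_norket"),
    "P7": ("pk", "cl_elim_s_norket"),
    "P8": ("pk", "q_inter_s_norket"),
    "P9": ("pk", "mtt_norket"),
    "P10": ("pk", "cl_central_r_norket"),
    "P11": ("pk", "q_inter_r_norket"),
    "P12": ("co_pd", "c25_ket"),
    "P13": ("co_pd", "c25_norket"),
    "P14": ("co_pd", "thalf_ket"),
    "P15": ("co_pd", "thalf_norket"),
    "P16": ("map_pd", "emax"),
    "P17": ("map_pd", "c50"),
    "P18": ("map_pd", "gamma"),
    "P19": ("coupling", "a0"),
    "P20": ("coupling", "a_map"),
    "P21": ("coupling", "a_co"),
    "P22": ("coupling", "b0"),
    "P23": ("coupling", "b_map"),
    "P24": ("coupling", "b_co"),
}

TABLE_NOMINAL: dict[str, float] = {
    "P1": 1.78, "P2": 1.58, "P3": 25.80, "P4": 2.10, "P5": 115.00,
    "P6": 240.00, "P7": 1.00, "P8": 3.27, "P9": 26.60, "P10": 0.73,
    "P11": 2.55, "P12": 4.00e-4, "P13": 1.60e-4, "P14": 2.28, "P15": 29.30,
    "P16": 51.60, "P17": 4.68e-3, "P18": 2.04, "P19": -217.90, "P20": 1.47,
    "P21": 14.01, "P22": -14.68, "P23": -5.28e-3, "P24": 3.02,
}


def nominal_parameter_vector() -> tuple[list[str], list[float]]:
    """The 24 parameters in table order, as (names, nominal values)."""
    names = [f"P{i}" for i in range(1, 25)]
    return names, [TABLE_NOMINAL[n] for n in names]


_FIELD_TO_PNUM = {v: k for k, v in PNUM_TO_FIELD.items()}


def load_overrides(path: str | Path) -> dict[str, float]:
    """Load a YAML/JSON parameter-override file to a ``{P#: value}`` dict.

    Keys may be P# labels or field names; field names are translated.
    """
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(raw, Mapping):
        raise ValueError("override file must contain a mapping")
    out: dict[str, float] = {}
    for key, val in raw.items():
        if key in TABLE_NOMINAL:
            out[key] = float(val)
        else:
            hit = [p for p, (g, f) in PNUM_TO_FIELD.items() if f == key]
            if not hit:
                raise KeyError(f"unknown parameter key {key!r}")
            out[hit[0]] = float(val)
    return out


def apply_overrides(
    overrides: Mapping[str, float],
    pk: PKParameters | None = None,
    map_pd: MapPDParameters | None = None,
    co_pd: CoPDParameters | None = None,
    coupling: OffsetCoefficients | None = None,
) -> tuple[PKParameters, MapPDParameters, CoPDParameters, OffsetCoefficients]:
    """Return fresh parameter objects with P#-keyed overrides applied."""
    pk = pk or PKParameters()
    map_pd = map_pd or MapPDParameters()
    co_pd = co_pd or CoPDParameters()
    coupling = coupling or OffsetCoefficients()
    groups = {"pk": pk, "map_pd": map_pd, "co_pd": co_pd, "coupling": coupling}
    updates: dict[str, dict[str, float]] = {g: {} for g in groups}
    for pnum, value in overrides.items():
        grp, fname = PNUM_TO_FIELD[pnum]
        updates[grp][fname] = float(value)
    return (
        replace(pk, **updates["pk"]),
        replace(map_pd, **updates["map_pd"]),
        replace(co_pd, **updates["co_pd"]),
        replace(coupling, **updates["coupling"]),
    )
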