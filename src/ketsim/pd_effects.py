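"""Pharmacodynamic translation of ketamine concentrations into MAP and CO
targets.

The MAP effect is a sigmoid Emax (Hill) function of the plasma ketamine
concentration; the CO effect combines S-ketamine (stimulating) and
S-norketamine (opposing) fractional effects, each driven through a
first-order effect compartment whose rate constant is ke0 = ln 2 / t_half.
All functions broadcast over NumPy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import CoPDParameters, MapPDParameters

__all__ = [
    "EffectSiteState",
    "map_pd",
    "effect_site_derivative",
    "co_pd",
    "ke0",
]


@dataclass
class EffectSiteState:
    """Effect-site concentrations (g/L) for the CO model."""

    ce_ket: float = 0.0
    ce_norket: float = 0.0

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.ce_ket) < 0) or np.any(np.asarray(self.ce_norket) < 0):
            raise ValueError("effect-site concentrations must be nonnegative")


def ke0(thalf):
    """Effect-compartment rate constant (1/min) from a half-life (min)."""
    thalf = np.asarray(thalf, dtype=float)
    if np.any(thalf <= 0):
        raise ValueError("half-life must be positive")
    out = np.log(2.0) / thalf
    return float(out) if out.ndim == 0 else out


def map_pd(c, params: MapPDParameters):
    """MAP target (mmHg) for a driving plasma concentration c (g/L).

    map_baseline + emax * c**gamma / (c50**gamma + c**gamma); strictly
    increasing in c and saturating at map_baseline + emax.
    """
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be nonnegative")
    c = c * params.concentration_scale
    cg = np.power(c, params.gamma)
    effect = params.emax * cg / (np.power(params.c50, params.gamma) + cg)
    out = params.map_baseline + effect
    return float(out) if np.ndim(out) == 0 else out


def effect_site_derivative(ce, cp, thalf):
    """d(ce)/dt = ke0 * (cp - ce) with ke0 = ln2 / thalf (g/(L*min))."""
    k = ke0(thalf)
    out = k * (np.asarray(cp, float) - np.asarray(ce, float))
    return float(out) if np.ndim(out) == 0 else out


def co_pd(state: EffectSiteState | tuple, params: CoPDParameters):
    """CO target (L/min) from effect-site S-ketamine / S-norketamine levels.

    co_baseline * (1 + 0.25*ce_ket/c25_ket + sign*0.25*ce_norket/c25_norket),
    floored at floor_fraction * co_baseline. ``linear=False`` applies the
    same fractional effects multiplicatively instead.
    """
    if isinstance(state, EffectSiteState):
        ce_k, ce_nk = state.ce_ket, state.ce_norket
    else:
        ce_k, ce_nk = state
    f_ket = 0.25 * np.asarray(ce_k, float) / params.c25_ket
    f_nk = 0.25 * np.asarray(ce_nk, float) / params.c25_norket
    if params.linear:
        factor = 1.0 + f_ket + params.norket_sign * f_nk
    else:
        factor = (1.0 + f_ket) * (1.0 + params.norket_sign * f_nk)
    out = params.co_baseline * np.maximum(factor, params.floor_fraction)
    return float(out) if np.ndim(out) == 0 else out
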