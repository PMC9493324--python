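"""Van't Hoff thermodynamics of ligand-protein association.

The apparent binding constant Ka measured at several temperatures is
decomposed by the linear van't Hoff model

    ln Ka = -dH/(R T) + dS/R

(ordinary least squares of ln Ka on 1/T; dH assumed temperature
independent), and the Gibbs free energy follows as dG(T) = dH - T dS.
Sign-based Ross-Subramanian rules map (dH, dS) to the dominant
non-covalent driving force, and dG < 0 marks spontaneous binding.

All energies are in J/mol throughout; R = 8.314 J mol^-1 K^-1.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

GAS_CONSTANT = 8.314  # J mol^-1 K^-1

__all__ = [
    "GAS_CONSTANT",
    "ForceCall",
    "ThermoResult",
    "vant_hoff_fit",
    "gibbs_free_energy",
    "classify_driving_force",
    "spontaneity",
    "analyze_thermodynamics",
]


class ForceCall(str, enum.Enum):
    """Dominant non-covalent interaction inferred from (dH, dS) signs."""

    HYDROPHOBIC = "hydrophobic"  # dH > 0 and dS > 0
    VDW_AND_HBOND = "vdw_and_hbond"  # dH < 0 and dS < 0
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class ThermoResult:
    """Van't Hoff decomposition with per-temperature Gibbs energies."""

    delta_H: float  # J/mol
    delta_S: float  # J mol^-1 K^-1
    r_squared: float
    gibbs: dict  # temperature K -> dG J/mol
    force_call: ForceCall
    spontaneous: dict  # temperature K -> bool
    gas_constant: float = GAS_CONSTANT
    # diagnostic: dG from -RT ln Ka directly, which need not agree with
    # the van't Hoff route when the Ka set is internally inconsistent
    gibbs_from_lnKa: dict = field(default_factory=dict)


def vant_hoff_fit(ka_by_temperature: dict) -> tuple[float, float, float]:
    """OLS of ln Ka against 1/T; returns (delta_H, delta_S, r_squared).

    delta_H = -slope * R and delta_S = intercept * R, J-based.  With
    exactly two temperatures the line is exact and r_squared is 1.
    """
    temps = np.array(sorted(ka_by_temperature), dtype=float)
    if len(temps) < 2:
        raise ValueError("need >= 2 temperatures")
    if len(np.unique(temps)) != len(temps):
        raise ValueError("duplicate temperatures")
    if np.any(temps <= 0):
        raise ValueError("temperatures must be positive kelvin")
    ka = np.array([ka_by_temperature[t] for t in temps], dtype=float)
    if np.any(ka <= 0):
        raise ValueError("all Ka must be positive")
    x = 1.0 / temps
    y = np.log(ka)
    if len(temps) == 2:
        slope = (y[1] - y[0]) / (x[1] - x[0])
        intercept = y[0] - slope * x[0]
        r2 = 1.0
    else:
        res = stats.linregress(x, y)
        slope, intercept = float(res.slope), float(res.intercept)
        r2 = min(max(float(res.rvalue**2), 0.0), 1.0)
    return (-slope * GAS_CONSTANT, intercept * GAS_CONSTANT, r2)


def gibbs_free_energy(delta_H: float, delta_S: float, temperatures) -> dict:
    """dG(T) = dH - T dS for each temperature, J/mol."""
    out = {}
    for t in temperatures:
        if t <= 0:
            raise ValueError("temperatures must be positive kelvin")
        out[float(t)] = delta_H - t * delta_S
    return out


def classify_driving_force(delta_H: float, delta_S: float) -> ForceCall:
    """Ross-Subramanian sign rules: (+,+) hydrophobic, (-,-) van der
    Waals + hydrogen bonding, anything else (including zeros)
    indeterminate."""
    if not (math.isfinite(delta_H) and math.isfinite(delta_S)):
        raise ValueError("delta_H and delta_S must be finite")
    if delta_H > 0 and delta_S > 0:
        return ForceCall.HYDROPHOBIC
    if delta_H < 0 and delta_S < 0:
        return ForceCall.VDW_AND_HBOND
    return ForceCall.INDETERMINATE


def spontaneity(gibbs: dict) -> dict:
    """True at a temperature iff dG < 0 there."""
    return {float(t): bool(dg < 0) for t, dg in gibbs.items()}


def analyze_thermodynamics(ka_by_temperature: dict) -> ThermoResult:
    """Full van't Hoff analysis of a Ka(T) map.

    Fits (dH, dS), evaluates dG at the measured temperatures, classifies
    the driving force and spontaneity, and carries the direct
    -RT ln Ka values as a diagnostic column.
    """
    dh, ds, r2 = vant_hoff_fit(ka_by_temperature)
    gibbs = gibbs_free_energy(dh, ds, sorted(ka_by_temperature))
    diag = {
        float(t): -GAS_CONSTANT * t * math.log(ka)
        for t, ka in sorted(ka_by_temperature.items())
    }
    return ThermoResult(
        delta_H=dh,
        delta_S=ds,
        r_squared=r2,
        gibbs=gibbs,
        force_call=classify_driving_force(dh, ds),
        spontaneous=spontaneity(gibbs),
        gibbs_from_lnKa=diag,
    )
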