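"""Stern-Volmer quenching and double-logarithmic binding fits.

The quench-ratio table produced by :mod:`quenchbind.spectra` (or read
from a user CSV) is fitted two ways:

* Stern-Volmer: F0/F = 1 + K_SV [Q], a straight line in quencher
  concentration whose slope is the quenching constant K_SV; the
  bimolecular quenching rate constant is kq = K_SV / tau0 with tau0 the
  unquenched fluorophore lifetime (default 1e-8 s).
* Double-log: log10((F0-F)/F) = log10(Ka) + n log10([Q]) yields the
  apparent binding constant Ka and the binding-site number n.

A mechanism classifier combines the two textbook criteria: apparent kq
above the diffusion-controlled collision limit (~2e10 L mol^-1 s^-1)
and K_SV decreasing with temperature both point to static quenching
(ground-state complex); the opposite pattern to dynamic (collisional)
quenching; any disagreement is reported as ambiguous.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DIFFUSION_LIMIT = 2e10  # L mol^-1 s^-1, diffusion-controlled collision limit
DEFAULT_TAU0 = 1e-8  # s, unquenched fluorophore lifetime

__all__ = [
    "QuenchingFit",
    "BindingFit",
    "MechanismCall",
    "Verdict",
    "Trend",
    "stern_volmer_fit",
    "classify_mechanism",
    "double_log_fit",
    "DIFFUSION_LIMIT",
    "DEFAULT_TAU0",
]


@dataclass(frozen=True)
class QuenchingFit:
    """Result of the Stern-Volmer regression at one temperature."""

    K_SV: float  # L/mol
    intercept: float
    kq: float  # L mol^-1 s^-1, == K_SV / tau0
    tau0: float  # s
    r_squared: float
    stderr_K_SV: float
    temperature: float  # K
    intercept_warning: bool = False  # |intercept - 1| > 0.1


@dataclass(frozen=True)
class BindingFit:
    """Result of the double-log binding regression at one temperature."""

    Ka: float  # L/mol
    n: float  # binding-site number
    r_squared: float
    temperature: float  # K


class Verdict(str, enum.Enum):
    STATIC = "static"
    DYNAMIC = "dynamic"
    AMBIGUOUS = "ambiguous"


class Trend(str, enum.Enum):
    DECREASING = "decreasing"
    INCREASING = "increasing"
    FLAT = "flat"


@dataclass(frozen=True)
class MechanismCall:
    """Quenching-mechanism verdict with the evidence behind it."""

    verdict: Verdict
    kq_exceeds_diffusion_limit: dict  # temperature K -> bool
    ksv_temperature_trend: Trend
    diffusion_limit: float = DIFFUSION_LIMIT


def _usable(ratios: pd.DataFrame) -> pd.DataFrame:
    if "enhancement" in ratios.columns:
        dropped = ratios["enhancement"].sum()
        if dropped:
            warnings.warn(f"excluding {int(dropped)} enhancement row(s) (F > F0)", stacklevel=3)
        return ratios.loc[~ratios["enhancement"]]
    return ratios


def stern_volmer_fit(
    ratios: pd.DataFrame,
    tau0: float = DEFAULT_TAU0,
    temperature: float | None = None,
    through_unity: bool = False,
) -> QuenchingFit:
    """Fit F0/F = intercept + K_SV [Q] by ordinary least squares.

    ``ratios`` needs columns ``quencher_conc_M`` and ``F0_over_F`` (the
    table from :func:`quenchbind.spectra.quench_ratios` works directly;
    enhancement rows are excluded).  The intercept is free by default —
    the Stern-Volmer model forces it to 1, so a fitted intercept away
    from 1 (beyond 0.1) raises a warning flag that diagnoses curvature.
    ``through_unity=True`` instead constrains the line through (0, 1).
    """
    table = _usable(ratios)
    q = table["quencher_conc_M"].to_numpy(dtype=float)
    y = table["F0_over_F"].to_numpy(dtype=float)
    if len(np.unique(q)) < 3:
        raise ValueError("underdetermined: need >= 3 distinct concentrations")
    if np.ptp(q) == 0:
        raise ValueError("zero concentration spread")
    if temperature is None:
        temperature = float(table["temperature_K"].iloc[0]) if "temperature_K" in table else float("nan")

    if through_unity:
        # least squares of (y - 1) on q with no intercept
        slope = float(np.dot(q, y - 1.0) / np.dot(q, q))
        intercept = 1.0
        resid = y - (1.0 + slope * q)
        ss_res = float(np.dot(resid, resid))
        ss_tot = float(np.dot(y - y.mean(), y - y.mean()))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        dof = len(q) - 1
        stderr = float(np.sqrt(ss_res / dof / np.dot(q, q))) if dof > 0 else 0.0
    else:
        res = stats.linregress(q, y)
        slope, intercept = float(res.slope), float(res.intercept)
        r2 = float(res.rvalue**2)
        stderr = float(res.stderr)
    return QuenchingFit(
        K_SV=slope,
        intercept=intercept,
        kq=slope / tau0,
        tau0=tau0,
        r_squared=min(max(r2, 0.0), 1.0),
        stderr_K_SV=stderr,
        temperature=temperature,
        intercept_warning=abs(intercept - 1.0) > 0.1,
    )


def double_log_fit(ratios: pd.DataFrame, temperature: float | None = None) -> BindingFit:
    """Fit log10((F0-F)/F) = log10(Ka) + n log10([Q]) by OLS.

    Rows with zero concentration or non-positive (F0-F)/F carry no
    information on the log scale and are dropped (with a warning for the
    latter); at least 3 usable rows are required.
    """
    table = _usable(ratios)
    q = table["quencher_conc_M"].to_numpy(dtype=float)
    r = table["F0_minus_F_over_F"].to_numpy(dtype=float)
    nonzero = q > 0
    bad = nonzero & (r <= 0)
    if bad.any():
        warnings.warn(
            f"dropping {int(bad.sum())} row(s) with non-positive (F0-F)/F", stacklevel=2
        )
    keep = nonzero & (r > 0)
    if keep.sum() < 3:
        raise ValueError("underdetermined: need >= 3 usable nonzero-concentration rows")
    if temperature is None:
        temperature = float(table["temperature_K"].iloc[0]) if "temperature_K" in table else float("nan")
    res = stats.linregress(np.log10(q[keep]), np.log10(r[keep]))
    return BindingFit(
        Ka=float(10.0 ** res.intercept),
        n=float(res.slope),
        r_squared=min(max(float(res.rvalue**2), 0.0), 1.0),
        temperature=temperature,
    )


def classify_mechanism(
    fits: list[QuenchingFit], diffusion_limit: float = DIFFUSION_LIMIT
) -> MechanismCall:
    """Classify quenching as static, dynamic or ambiguous.

    Criterion A (rate): every apparent kq above ``diffusion_limit`` is
    static evidence; every kq at or below it is dynamic evidence.
    Criterion B (trend): K_SV non-increasing with temperature (ties
    allowed within one pooled standard error) is static evidence; an
    increasing trend is dynamic evidence.  The reported trend is the
    sign of the OLS slope of K_SV against T (sign of the difference for
    two points), with changes smaller than the pooled standard error
    treated as flat.  The verdict is static or dynamic only when both
    criteria agree; otherwise ambiguous.
    """
    if len(fits) < 2:
        raise ValueError("trend undefined: need >= 2 temperatures")
    fits = sorted(fits, key=lambda f: f.temperature)
    temps = np.array([f.temperature for f in fits])
    if len(np.unique(temps)) != len(temps):
        raise ValueError("duplicate temperatures")
    ksv = np.array([f.K_SV for f in fits])
    stderrs = np.array([f.stderr_K_SV for f in fits])
    pooled_se = float(np.sqrt(np.mean(np.square(np.nan_to_num(stderrs)))))

    if len(fits) == 2:
        slope = (ksv[1] - ksv[0]) / (temps[1] - temps[0])
        predicted_change = ksv[1] - ksv[0]
    else:
        res = stats.linregress(temps, ksv)
        slope = float(res.slope)
        predicted_change = slope * float(np.ptp(temps))
    if abs(predicted_change) <= pooled_se:
        trend = Trend.FLAT
    else:
        trend = Trend.DECREASING if slope < 0 else Trend.INCREASING

    exceeds = {float(f.temperature): bool(f.kq > diffusion_limit) for f in fits}
    all_exceed = all(exceeds.values())
    none_exceed = not any(exceeds.values())
    # non-increasing stepwise, ties allowed within one pooled standard error
    non_increasing = bool(np.all(np.diff(ksv) <= pooled_se))

    if all_exceed and non_increasing and trend is not Trend.INCREASING:
        verdict = Verdict.STATIC
    elif none_exceed and trend is Trend.INCREASING:
        verdict = Verdict.DYNAMIC
    else:
        verdict = Verdict.AMBIGUOUS
    return MechanismCall(
        verdict=verdict,
        kq_exceeds_diffusion_limit=exceeds,
        ksv_temperature_trend=trend,
        diffusion_limit=diffusion_limit,
    )
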