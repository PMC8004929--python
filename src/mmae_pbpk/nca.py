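"""Noncompartmental analysis: AUC, moments, partition coefficients, IVIVE.

AUCs use the linear/log trapezoidal rule: linear trapezoids on rising or
flat segments (and wherever a concentration is zero), logarithmic trapezoids
on strictly declining positive segments. The terminal slope lambda_z comes
from a log-linear regression of the last positive points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "NCAError",
    "NCASummary",
    "auc_linlog",
    "aumc_linlog",
    "lambda_z",
    "kp",
    "adjust_kp",
    "moment_analysis",
    "percent_pe",
    "ivive",
    "scale_ps",
]


class NCAError(ValueError):
    """Insufficient or invalid data for a noncompartmental quantity."""


@dataclass
class NCASummary:
    """Moment-analysis outputs for a plasma profile.

    ``AUC_0_t``/``AUC_0_inf`` in h·nM, ``CL`` in mL/h, ``Vss`` in mL,
    ``t_half`` in h, ``lambda_z`` in 1/h. Fields that could not be estimated
    (no terminal slope) are NaN and ``flagged`` is True.
    """

    AUC_0_t: float
    AUC_0_inf: float
    AUMC_0_inf: float
    CL: float
    Vss: float
    MRT: float
    t_half: float
    lambda_z: float
    flagged: bool = False


def _validate_profile(times, concs):
    t = np.asarray(times, dtype=float)
    c = np.asarray(concs, dtype=float)
    if t.size != c.size:
        raise NCAError("times and concentrations differ in length")
    if t.size < 2:
        raise NCAError(f"need at least 2 points, got {t.size}")
    if np.any(np.diff(t) <= 0):
        raise NCAError("times must be strictly increasing")
    if np.any(c < 0):
        raise NCAError("concentrations must be nonnegative")
    return t, c


def lambda_z(times, concs, n_points: int = 3) -> float:
    """Terminal slope (1/h) from log-linear regression of the last
    ``n_points`` positive concentrations."""
    t, c = _validate_profile(times, concs)
    pos = c > 0
    t, c = t[pos], c[pos]
    if t.size < n_points or n_points < 2:
        raise NCAError(
            f"terminal regression needs {max(n_points, 2)} positive points, got {t.size}"
        )
    tt, cc = t[-n_points:], np.log(c[-n_points:])
    slope = np.polyfit(tt, cc, 1)[0]
    lam = -slope
    if lam <= 0:
        raise NCAError(f"non-declining terminal phase (lambda_z={lam:.4g})")
    return float(lam)


def _segment_auc(t1, t2, c1, c2):
    dt = t2 - t1
    if c1 > 0 and 0 < c2 < c1:
        k = math.log(c1 / c2)
        return (c1 - c2) / k * dt
    return 0.5 * (c1 + c2) * dt


def _segment_aumc(t1, t2, c1, c2):
    dt = t2 - t1
    if c1 > 0 and 0 < c2 < c1:
        k = math.log(c1 / c2) / dt
        return (t1 * c1 - t2 * c2) / k + (c1 - c2) / k**2
    return 0.5 * (t1 * c1 + t2 * c2) * dt


def auc_linlog(times, concs, extrapolate: bool = False, n_terminal: int = 3) -> float:
    """AUC (h·nM) by the linear/log trapezoidal method.

    With ``extrapolate`` the tail C_last/lambda_z is added (AUC to infinity);
    lambda_z uses the last ``n_terminal`` positive points.
    """
    t, c = _validate_profile(times, concs)
    auc = sum(_segment_auc(t[i], t[i + 1], c[i], c[i + 1]) for i in range(t.size - 1))
    if extrapolate:
        lam = lambda_z(t, c, n_terminal)
        c_last = c[c > 0][-1]
        auc += c_last / lam
    return float(auc)


def aumc_linlog(times, concs, extrapolate: bool = False, n_terminal: int = 3) -> float:
    """Area under the first-moment curve (h²·nM), linear/log trapezoids."""
    t, c = _validate_profile(times, concs)
    aumc = sum(_segment_aumc(t[i], t[i + 1], c[i], c[i + 1]) for i in range(t.size - 1))
    if extrapolate:
        lam = lambda_z(t, c, n_terminal)
        pos = c > 0
        c_last, t_last = c[pos][-1], t[pos][-1]
        aumc += c_last * t_last / lam + c_last / lam**2
    return float(aumc)


def kp(AUC_matrix: float, AUC_plasma: float) -> float:
    """Partition coefficient: ratio of tissue (or blood-cell) to plasma AUC."""
    if AUC_plasma <= 0:
        raise NCAError(f"plasma AUC must be positive, got {AUC_plasma}")
    return AUC_matrix / AUC_plasma


def adjust_kp(Kp: float, f_cellular: float) -> float:
    """Adjust an apparent Kp to the cellular-space basis: Kp / f_cellular."""
    if not 0.0 < f_cellular <= 1.0:
        raise NCAError(f"cellular fraction must be in (0, 1], got {f_cellular}")
    return Kp / f_cellular


def moment_analysis(
    times, concs, dose_amount: float, n_terminal: int = 3
) -> NCASummary:
    """Clearance, Vss, and half-life from statistical moments.

    CL = dose/AUC_inf, MRT = AUMC_inf/AUC_inf, Vss = CL·MRT,
    t_half = ln2/lambda_z. If no terminal slope is estimable, the summary
    carries AUC_0_t and is flagged partial.
    """
    t, c = _validate_profile(times, concs)
    if dose_amount <= 0:
        raise NCAError("dose amount must be positive")
    auc_t = auc_linlog(t, c)
    try:
        lam = lambda_z(t, c, n_terminal)
    except NCAError:
        return NCASummary(
            AUC_0_t=auc_t,
            AUC_0_inf=math.nan,
            AUMC_0_inf=math.nan,
            CL=math.nan,
            Vss=math.nan,
            MRT=math.nan,
            t_half=math.nan,
            lambda_z=math.nan,
            flagged=True,
        )
    auc_inf = auc_linlog(t, c, extrapolate=True, n_terminal=n_terminal)
    aumc_inf = aumc_linlog(t, c, extrapolate=True, n_terminal=n_terminal)
    cl = dose_amount / auc_inf
    mrt = aumc_inf / auc_inf
    return NCASummary(
        AUC_0_t=auc_t,
        AUC_0_inf=auc_inf,
        AUMC_0_inf=aumc_inf,
        CL=cl,
        Vss=cl * mrt,
        MRT=mrt,
        t_half=math.log(2.0) / lam,
        lambda_z=lam,
    )


def percent_pe(AUC_pred: float, AUC_obs: float, signed: bool = False) -> float:
    """Percent predictive error: |pred − obs| / obs x 100 (signed by flag)."""
    if AUC_obs <= 0:
        raise NCAError(f"observed AUC must be positive, got {AUC_obs}")
    pe = (AUC_pred - AUC_obs) / AUC_obs * 100.0
    return pe if signed else abs(pe)


_IVIVE_BASES = {
    # clint basis -> required scaling-factor basis
    "hepatocyte": "cells_per_g",  # uL/min per 10^6 cells; SF in 10^6 cells/g
    "microsome": "mg_per_g",  # uL/min per mg protein; SF in mg protein/g
}


def ivive(
    CLint_vitro: float,
    scaling_factor: float,
    liver_weight: float,
    f_metabolic: float = 0.4,
    clint_basis: str = "hepatocyte",
    sf_basis: str | None = None,
) -> dict[str, float]:
    """In vitro-in vivo extrapolation of intrinsic clearance.

    Metabolic CL (mL/h) = CLint_vitro x SF x liver weight, unit-converted
    from uL/min; the whole-liver intrinsic clearance divides by the
    metabolic fraction of total elimination (0.4 by default, the rest being
    mostly biliary). ``clint_basis`` and ``sf_basis`` must agree
    ('hepatocyte' with 'cells_per_g', 'microsome' with 'mg_per_g').
    """
    if CLint_vitro <= 0 or scaling_factor <= 0 or liver_weight <= 0:
        raise NCAError("IVIVE inputs must be positive")
    if not 0.0 < f_metabolic <= 1.0:
        raise NCAError(f"f_metabolic must be in (0, 1], got {f_metabolic}")
    if clint_basis not in _IVIVE_BASES:
        raise NCAError(f"unknown CLint basis {clint_basis!r}")
    expected_sf = _IVIVE_BASES[clint_basis]
    if sf_basis is not None and sf_basis != expected_sf:
        raise NCAError(
            f"scaling-factor basis {sf_basis!r} does not match CLint basis"
            f" {clint_basis!r} (expected {expected_sf!r})"
        )
    ul_per_min = CLint_vitro * scaling_factor * liver_weight
    metabolic = ul_per_min * 60.0 / 1000.0  # -> mL/h
    return {
        "CL_metabolic": metabolic,
        "CL_int_total": metabolic / f_metabolic,
    }


def scale_ps(PS_mouse: float, bw_source: float, bw_target: float, exponent: float = 0.67) -> float:
    """Allometric scaling of a permeability-surface-area coefficient."""
    if bw_source <= 0 or bw_target <= 0:
        raise NCAError("body weights must be positive")
    return PS_mouse * (bw_target / bw_source) ** exponent
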