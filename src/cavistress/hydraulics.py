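"""Biophysics of leaf hydraulic supply and runaway cavitation.

The leaf is modelled as a single hydraulic compartment fed from an upstream
source (stem/soil) through a conductance that collapses sigmoidally as water
potential falls, and drained by cuticular transpiration after stomatal
closure.  Runaway cavitation is the point at which the steady-state water
balance ceases to exist: the maximum rate at which the (partly embolised)
xylem can deliver water falls below the cuticular demand, so leaf water
potential goes into free fall and embolism self-amplifies.

Closed-form results
-------------------
With the vulnerability curve

    K(psi) = kmax / (1 + exp((p50 - psi) / alpha)),   alpha > 0,

cuticular demand ``ec`` and supply ``K(psi_leaf) * (psi_source - psi_leaf)``,
the leaf water potential at runaway onset is

    psi_runaway = p50 - alpha * ln(alpha * kmax / ec)

and the percent loss of conductance at that point is

    plc_runaway = 100 * x / (1 + x),   x = alpha * kmax / ec.

Both are exposed through :func:`runaway_point`; an independent numerical
route (:func:`runaway_point_numeric`) locates the same point by bisection on
the source potential, and :func:`simulate_drydown` integrates the dynamic
water balance to exhibit the runaway feedback.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.optimize import brentq, minimize_scalar

__all__ = [
    "VulnerabilityCurve",
    "Environment",
    "RunawayResult",
    "DrydownTrace",
    "conductance",
    "plc_at_psi",
    "vpd_arden_buck",
    "cuticular_transpiration",
    "supply_rate",
    "max_supply",
    "runaway_point",
    "runaway_point_numeric",
    "simulate_drydown",
]


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class VulnerabilityCurve:
    """Sigmoidal xylem vulnerability curve.

    Parameters
    ----------
    kmax : float
        Maximum hydraulic conductance, mmol s-1 m-2 MPa-1.
    p50 : float
        Water potential at 50% conductance loss, MPa (negative).
    alpha : float
        Slope parameter of the sigmoid, MPa (strictly positive; larger
        values give a shallower curve).

    Notes
    -----
    The curve is ``K(psi) = kmax / (1 + exp((p50 - psi)/alpha))``, which is
    strictly increasing in ``psi`` (conductance is lost as the leaf dries)
    and satisfies ``K(p50) = kmax / 2`` exactly.
    """

    kmax: float
    p50: float
    alpha: float

    def __post_init__(self) -> None:
        if not (self.kmax > 0):
            raise ValueError(f"kmax must be > 0, got {self.kmax}")
        if not (self.alpha > 0):
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if not (self.p50 < 0):
            raise ValueError(f"p50 must be < 0 (MPa), got {self.p50}")

    def conductance(self, psi):
        return conductance(self, psi)

    def plc(self, psi):
        return plc_at_psi(self, psi)


@dataclass
class Environment:
    """Laboratory environment driving cuticular water loss.

    ``vpd_kpa`` may be supplied directly; otherwise it is derived from
    temperature and relative humidity with the Arden–Buck saturation
    vapour-pressure formula.  ``ec`` (cuticular transpiration) is always
    derived as ``gmin * vpd / patm``.
    """

    temp_c: float = 20.0
    rh_pct: float = 35.86
    patm_kpa: float = 101.3
    gmin: float = 10.02
    vpd_kpa: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.rh_pct <= 100.0):
            raise ValueError(f"rh_pct must be in [0, 100], got {self.rh_pct}")
        if not (self.patm_kpa > 0):
            raise ValueError("patm_kpa must be > 0")
        if self.gmin < 0:
            raise ValueError("gmin must be >= 0")
        if self.vpd_kpa is None:
            self.vpd_kpa = vpd_arden_buck(self.temp_c, self.rh_pct)
        elif self.vpd_kpa < 0:
            raise ValueError("vpd_kpa must be >= 0")

    @property
    def ec(self) -> float:
        """Cuticular transpiration, mmol m-2 s-1."""
        return cuticular_transpiration(self.gmin, self.vpd_kpa, self.patm_kpa)


@dataclass(frozen=True)
class RunawayResult:
    """Runaway-cavitation onset point.

    Attributes
    ----------
    psi_runaway : float
        Leaf water potential at runaway onset, MPa.
    plc_runaway : float
        Percent loss of conductance at onset, in (0, 100).
    k_at_runaway : float
        Conductance at onset, mmol s-1 m-2 MPa-1.
    psi_source_critical : float or None
        Source water potential at which the steady state vanishes (only
        populated by the numerical route).
    """

    psi_runaway: float
    plc_runaway: float
    k_at_runaway: float
    psi_source_critical: float | None = None


@dataclass
class DrydownTrace:
    """Output of :func:`simulate_drydown`: time series plus onset marker."""

    time_min: np.ndarray
    psi_leaf: np.ndarray
    psi_source: np.ndarray
    onset_time_min: float | None
    onset_psi_leaf: float | None
    onset_psi_source: float | None


# --------------------------------------------------------------------------
# static relations
# --------------------------------------------------------------------------

def conductance(curve: VulnerabilityCurve, psi):
    """Hydraulic conductance at water potential ``psi`` (MPa).

    ``K(psi) = kmax / (1 + exp((p50 - psi)/alpha))``; monotone increasing
    in ``psi``.  Accepts scalars or arrays.
    """
    psi = np.asarray(psi, dtype=float)
    if not np.all(np.isfinite(psi)):
        raise ValueError("psi must be finite")
    z = (curve.p50 - psi) / curve.alpha
    # clip to avoid overflow in exp; K underflows to 0 far below p50 anyway
    out = curve.kmax / (1.0 + np.exp(np.clip(z, -700.0, 700.0)))
    return float(out) if out.ndim == 0 else out


def plc_at_psi(curve: VulnerabilityCurve, psi):
    """Percent loss of conductance at ``psi``: ``100 * (1 - K(psi)/kmax)``."""
    k = conductance(curve, psi)
    return 100.0 * (1.0 - k / curve.kmax)


def vpd_arden_buck(temp_c: float, rh_pct: float) -> float:
    """Vapour-pressure deficit (kPa) from the Arden–Buck saturation formula.

    ``VPD = (1 - RH/100) * 0.61121 * exp(17.502 T / (240.97 + T))`` with T in
    degrees Celsius, assuming saturated internal leaf airspaces.
    """
    if not (0.0 <= rh_pct <= 100.0):
        raise ValueError(f"rh_pct must be in [0, 100], got {rh_pct}")
    if temp_c <= -240.97:
        raise ValueError("temp_c out of range for the Arden-Buck formula")
    es = 0.61121 * math.exp(17.502 * temp_c / (240.97 + temp_c))
    return (1.0 - rh_pct / 100.0) * es


def cuticular_transpiration(gmin: float, vpd_kpa: float, patm_kpa: float) -> float:
    """Cuticular transpiration ``E_c = gmin * VPD / P_atm`` (mmol m-2 s-1)."""
    if patm_kpa <= 0:
        raise ValueError("patm_kpa must be > 0")
    if gmin < 0 or vpd_kpa < 0:
        raise ValueError("gmin and vpd_kpa must be >= 0")
    return gmin * vpd_kpa / patm_kpa


def supply_rate(curve: VulnerabilityCurve, psi_leaf, psi_source):
    """Steady water supply through the xylem, mmol m-2 s-1.

    ``K(psi_leaf) * (psi_source - psi_leaf)``: the downstream conductance
    times the driving gradient.  Requires ``psi_leaf <= psi_source``.
    """
    pl = np.asarray(psi_leaf, dtype=float)
    ps = np.asarray(psi_source, dtype=float)
    if np.any(pl > ps + 1e-12):
        raise ValueError("psi_leaf must not exceed psi_source")
    out = conductance(curve, pl) * (ps - pl)
    return float(out) if np.ndim(out) == 0 else out


def max_supply(curve: VulnerabilityCurve, psi_source: float) -> tuple[float, float]:
    """Maximum of ``supply_rate`` over ``psi_leaf`` for a fixed source.

    Returns ``(psi_leaf_at_max, supply_max)``.  The supply is unimodal in
    ``psi_leaf`` on ``(-inf, psi_source]``: zero at equality, rising as the
    gradient grows, then collapsing as the conductance vanishes.
    """
    span = max(10.0 * curve.alpha + abs(curve.p50) + abs(psi_source) + 5.0, 20.0)
    lo = psi_source - span
    res = minimize_scalar(
        lambda p: -supply_rate(curve, p, psi_source),
        bounds=(lo, psi_source),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x), float(-res.fun)


# --------------------------------------------------------------------------
# runaway point
# --------------------------------------------------------------------------

def runaway_point(curve: VulnerabilityCurve, ec: float) -> RunawayResult:
    """Closed-form runaway-cavitation onset.

    Parameters
    ----------
    curve : VulnerabilityCurve
    ec : float
        Cuticular transpiration, mmol m-2 s-1 (> 0).

    Returns
    -------
    RunawayResult
        ``psi_runaway = p50 - alpha * ln(alpha * kmax / ec)`` and
        ``plc_runaway = 100 * x / (1 + x)`` with ``x = alpha * kmax / ec``.
    """
    if ec <= 0:
        raise ValueError(f"ec must be > 0, got {ec}")
    x = curve.alpha * curve.kmax / ec
    psi = curve.p50 - curve.alpha * math.log(x)
    plc = 100.0 * x / (1.0 + x)
    k = curve.kmax / (1.0 + x)
    return RunawayResult(psi_runaway=psi, plc_runaway=plc, k_at_runaway=k)


def runaway_point_numeric(
    curve: VulnerabilityCurve,
    ec: float,
    psi_source_start: float = -0.2,
) -> RunawayResult:
    """Runaway onset found numerically, independent of the closed form.

    Lowers the source water potential until the maximum achievable supply
    (over all leaf water potentials) just equals the cuticular demand: below
    that source potential no steady state exists.  The maximiser at the
    critical source potential is the leaf water potential at runaway onset.

    Raises
    ------
    ValueError
        If demand already exceeds the maximum supply at
        ``psi_source_start`` (runaway has already passed), or if no
        bracketing interval can be found.
    """
    if ec <= 0:
        raise ValueError(f"ec must be > 0, got {ec}")

    def excess(ps: float) -> float:
        return max_supply(curve, ps)[1] - ec

    hi = psi_source_start
    if excess(hi) <= 0:
        raise ValueError(
            f"max supply at psi_source_start={psi_source_start} is below "
            f"ec={ec}: runaway already passed at the starting source potential"
        )
    lo = hi
    step = max(1.0, 2.0 * curve.alpha)
    for _ in range(200):
        lo -= step
        if excess(lo) < 0:
            break
    else:
        raise ValueError(
            f"could not bracket the critical source potential in "
            f"[{lo}, {psi_source_start}]"
        )
    ps_crit = brentq(excess, lo, hi, xtol=1e-12)
    psi_leaf, _ = max_supply(curve, ps_crit)
    return RunawayResult(
        psi_runaway=psi_leaf,
        plc_runaway=plc_at_psi(curve, psi_leaf),
        k_at_runaway=conductance(curve, psi_leaf),
        psi_source_critical=float(ps_crit),
    )


# --------------------------------------------------------------------------
# dynamic drydown
# --------------------------------------------------------------------------

def simulate_drydown(
    curve: VulnerabilityCurve,
    ec: float,
    psi0: float = -0.5,
    source_ramp: float = -5.5 / (5 * 1440),
    capacitance: float = 40.0,
    dt_min: float = 1.0,
    t_end_min: float = 5 * 1440.0,
) -> DrydownTrace:
    """Integrate the leaf water balance through a linear source-drying ramp.

    ``capacitance * dPsi_leaf/dt = supply_rate(psi_leaf, psi_source(t)) - ec``
    with ``psi_source(t) = psi0 + source_ramp * t`` (ramp in MPa/min,
    capacitance in mmol m-2 MPa-1, fluxes in mmol m-2 s-1).

    Runaway onset is flagged at the first time the quasi-steady solution
    ceases to exist, i.e. when ``max_supply(psi_source(t)) < ec``; a slope
    heuristic is unnecessary because loss of existence is checked directly.

    Integration uses classical RK4 with fixed step ``dt_min`` (the system is
    non-stiff before onset and the post-onset collapse is resolved at the
    default step).
    """
    if capacitance <= 0:
        raise ValueError("capacitance must be > 0")
    if dt_min <= 0 or dt_min > 5.0:
        raise ValueError("dt_min must be in (0, 5] minutes")
    if ec < 0:
        raise ValueError("ec must be >= 0")

    n = int(math.floor(t_end_min / dt_min)) + 1
    t = np.arange(n) * dt_min
    psi_source = psi0 + source_ramp * t
    psi_leaf = np.empty(n)
    psi_leaf[0] = psi0

    # Existence boundary of the quasi-steady root: the source potential at
    # which max supply equals demand.  Found once; onset is the first step
    # whose source potential falls below it.
    ps_crit: float | None = None
    if ec > 0 and max_supply(curve, psi_source[0])[1] > ec:
        try:
            ps_crit = runaway_point_numeric(
                curve, ec, psi_source_start=float(psi_source[0])
            ).psi_source_critical
        except ValueError:
            ps_crit = None

    def deriv(pl: float, ps: float) -> float:
        pl = min(pl, ps)
        # 60: fluxes are per second, time marched in minutes
        return 60.0 * (supply_rate(curve, pl, ps) - ec) / capacitance

    onset_idx: int | None = None
    for i in range(n - 1):
        ps0 = psi_source[i]
        ps1 = psi_source[i + 1]
        psm = 0.5 * (ps0 + ps1)
        y = psi_leaf[i]
        h = dt_min
        k1 = deriv(y, ps0)
        k2 = deriv(y + 0.5 * h * k1, psm)
        k3 = deriv(y + 0.5 * h * k2, psm)
        k4 = deriv(y + h * k3, ps1)
        y1 = y + h / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        psi_leaf[i + 1] = min(y1, ps1)
        if onset_idx is None and ps_crit is not None and ps1 < ps_crit:
            onset_idx = i + 1

    if onset_idx is None:
        return DrydownTrace(t, psi_leaf, psi_source, None, None, None)
    return DrydownTrace(
        t,
        psi_leaf,
        psi_source,
        onset_time_min=float(t[onset_idx]),
        onset_psi_leaf=float(psi_leaf[onset_idx]),
        onset_psi_source=float(psi_source[onset_idx]),
    )
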