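"""Statistical estimators for dehydration experiments.

Covers the fits the analysis pipeline needs: cumulative-cavitation sigmoid
(and a monotone-smoother alternative) with P-level extraction, two-segment
breakpoint regression in the Muggeo style with a grid-search fallback and
bootstrap standard errors, ordinary least squares, rehydration-kinetics
K_leaf estimation with the four-parameter sigmoid, minimum cuticular
conductance from leaf mass-loss traces, and turgor loss point from
pressure-volume curves.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.interpolate import PchipInterpolator
from sklearn.isotonic import IsotonicRegression

from .hydraulics import vpd_arden_buck

__all__ = [
    "SigmoidFit",
    "SmootherFit",
    "BreakpointFit",
    "LinearFit",
    "KleafInstance",
    "fit_cavitation_curve",
    "extract_px",
    "fit_breakpoint",
    "fit_linear",
    "kleaf_instance",
    "fit_kleaf_curve",
    "gmin_from_trace",
    "tlp_from_pv",
    "water_viscosity_ratio",
]

MOLAR_MASS_WATER = 18.0153  # g/mol


# --------------------------------------------------------------------------
# fit result containers
# --------------------------------------------------------------------------

@dataclass
class SigmoidFit:
    """Fitted sigmoid.

    For cumulative cavitation curves this is the two-parameter form
    ``F(psi) = 1 / (1 + exp((psi - p50)/alpha))``; for K_leaf vulnerability
    it is the four-parameter form ``y = y0 + a / (1 + exp(-(psi - x0)/b))``
    with the (kmax, p50, alpha) reduction stored alongside.
    """

    p50: float
    alpha: float
    y0: float | None = None
    a: float | None = None
    x0: float | None = None
    b: float | None = None
    residual_sd: float = 0.0
    n: int = 0

    @property
    def kmax(self) -> float | None:
        """Plateau of the four-parameter form (``y0 + a``)."""
        if self.y0 is None or self.a is None:
            return None
        return self.y0 + self.a

    def cumulative(self, psi):
        """Cumulative cavitated fraction at ``psi`` (two-parameter form)."""
        psi = np.asarray(psi, dtype=float)
        return 1.0 / (1.0 + np.exp(np.clip((psi - self.p50) / self.alpha, -700, 700)))


@dataclass
class SmootherFit:
    """Monotone-spline smoother for a cumulative cavitation curve."""

    psi_grid: np.ndarray
    frac_grid: np.ndarray
    _interp: PchipInterpolator = field(repr=False, default=None)

    def cumulative(self, psi):
        psi = np.asarray(psi, dtype=float)
        lo, hi = self.psi_grid.min(), self.psi_grid.max()
        out = self._interp(np.clip(psi, lo, hi))
        return np.clip(out, 0.0, 1.0)

    @property
    def p50(self) -> float:
        return self.inverse(0.5)

    def inverse(self, frac: float) -> float:
        """Psi at a given cumulative fraction, by bisection on the smoother."""
        g = np.linspace(self.psi_grid.min(), self.psi_grid.max(), 2001)
        v = self.cumulative(g)
        if frac < v.min() or frac > v.max():
            raise ValueError(
                f"fraction {frac} outside smoothed range [{v.min():.3f}, {v.max():.3f}]"
            )
        # v decreases with increasing psi; find crossing
        idx = np.nonzero(np.diff(np.signbit(v - frac)))[0]
        i = idx[0]
        x0, x1, y0_, y1_ = g[i], g[i + 1], v[i], v[i + 1]
        if y1_ == y0_:
            return float(0.5 * (x0 + x1))
        return float(x0 + (frac - y0_) * (x1 - x0) / (y1_ - y0_))


@dataclass
class BreakpointFit:
    """Two-segment continuous regression result.

    ``breakpoint`` is in the units of ``x`` (MPa or minutes).  ``converged``
    reports whether the Muggeo iteration converged; when it diverges the
    grid-search estimate is used and ``method`` says so.  ``has_breakpoint``
    is False when no slope change is statistically detectable, in which case
    the slopes collapse to a single line.
    """

    breakpoint: float | None
    slope_before: float
    slope_after: float
    intercept: float
    breakpoint_se: float | None
    has_breakpoint: bool
    converged: bool
    iterations: int
    method: str = "muggeo"

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        if not self.has_breakpoint or self.breakpoint is None:
            return self.intercept + self.slope_before * x
        return (
            self.intercept
            + self.slope_before * x
            + (self.slope_after - self.slope_before) * np.maximum(x - self.breakpoint, 0.0)
        )


@dataclass(frozen=True)
class LinearFit:
    slope: float
    intercept: float
    r2: float
    p_value: float
    stderr: float


@dataclass(frozen=True)
class KleafInstance:
    """One rehydration-kinetics K_leaf measurement (two implied values)."""

    k_init: float
    k_fin: float
    k_mean: float
    flagged: bool
    rel_difference: float


# --------------------------------------------------------------------------
# cumulative cavitation curves
# --------------------------------------------------------------------------

def fit_cavitation_curve(psi, frac, method: str = "sigmoid"):
    """Fit a cumulative cavitation curve.

    Parameters
    ----------
    psi, frac : array-like
        Stem water potentials (MPa) and cumulative cavitated fractions in
        [0, 1]; the fraction must be (weakly) increasing as psi declines.
    method : {"sigmoid", "smoother"}
        ``"sigmoid"`` fits ``F = 1/(1+exp((psi-p50)/alpha))`` by least
        squares; ``"smoother"`` fits a monotone spline (isotonic regression
        followed by shape-preserving interpolation).
    """
    psi = np.asarray(psi, dtype=float)
    frac = np.asarray(frac, dtype=float)
    if psi.size != frac.size:
        raise ValueError("psi and frac must have equal length")
    if np.unique(psi).size < 6:
        raise ValueError("need at least 6 distinct psi levels")
    order = np.argsort(psi)  # increasing psi -> decreasing frac
    psi_s, frac_s = psi[order], frac[order]
    # monotonicity check: frac should not increase with psi beyond tolerance
    viol = np.maximum(np.diff(frac_s), 0.0)
    if viol.size and viol.max() > 0.25:
        raise ValueError("cumulative curve is non-monotone beyond tolerance")

    if method == "smoother":
        iso = IsotonicRegression(increasing=False, y_min=0.0, y_max=1.0)
        fitted = iso.fit_transform(psi_s, frac_s)
        # collapse duplicate psi for interpolation
        gx, inv = np.unique(psi_s, return_inverse=True)
        gy = np.bincount(inv, weights=fitted) / np.bincount(inv)
        interp = PchipInterpolator(gx, gy)
        return SmootherFit(psi_grid=gx, frac_grid=gy, _interp=interp)
    if method != "sigmoid":
        raise ValueError(f"unknown method {method!r}")

    def model(x, p50, alpha):
        return 1.0 / (1.0 + np.exp(np.clip((x - p50) / alpha, -700, 700)))

    # initial guess: 50% crossing and logistic scale from the 25-75 span
    p50_0 = float(np.interp(0.5, frac_s[::-1], psi_s[::-1]))
    try:
        q25 = float(np.interp(0.25, frac_s[::-1], psi_s[::-1]))
        q75 = float(np.interp(0.75, frac_s[::-1], psi_s[::-1]))
        alpha_0 = max((q25 - q75) / (2 * math.log(3)), 1e-3)
    except Exception:
        alpha_0 = 0.3
    popt, _ = optimize.curve_fit(
        model, psi_s, frac_s, p0=[p50_0, alpha_0],
        bounds=([psi_s.min() - 1.0, 1e-6], [psi_s.max() + 1.0, 10.0]),
        maxfev=20000,
    )
    resid = frac_s - model(psi_s, *popt)
    return SigmoidFit(
        p50=float(popt[0]), alpha=float(popt[1]),
        residual_sd=float(np.std(resid, ddof=2)) if psi_s.size > 2 else 0.0,
        n=int(psi_s.size),
    )


def extract_px(fit, p: float) -> float:
    """Water potential at ``p`` percent cumulative cavitation.

    For the two-parameter sigmoid the inverse is analytic:
    ``psi_p = p50 + alpha * ln((100 - p)/p)`` (so ``extract_px(fit, 50)``
    returns p50 exactly).  Smoother fits are inverted numerically and raise
    outside their fitted range.
    """
    if not (0.0 < p < 100.0):
        raise ValueError(f"p must be in (0, 100), got {p}")
    if isinstance(fit, SmootherFit):
        return fit.inverse(p / 100.0)
    return fit.p50 + fit.alpha * math.log((100.0 - p) / p)


# --------------------------------------------------------------------------
# breakpoint regression
# --------------------------------------------------------------------------

def _segmented_ols(x, y, bp):
    """OLS of the continuous two-segment model at a fixed breakpoint."""
    X = np.column_stack([np.ones_like(x), x, np.maximum(x - bp, 0.0)])
    beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    sse = float(np.sum((y - fitted) ** 2))
    return beta, sse


def _grid_breakpoint(x, y):
    """SSE profile over candidate breakpoints at interior x values."""
    xs = np.unique(x)
    cands = xs[2:-2]
    if cands.size == 0:
        cands = np.array([np.median(x)])
    best_bp, best_sse, best_beta = None, np.inf, None
    for bp in cands:
        beta, sse = _segmented_ols(x, y, bp)
        if sse < best_sse:
            best_bp, best_sse, best_beta = float(bp), sse, beta
    return best_bp, best_beta, best_sse


def fit_breakpoint(
    x,
    y,
    init: float | None = None,
    max_iter: int = 50,
    tol: float = 1e-8,
    n_boot: int = 0,
    seed: int | None = None,
    alpha_level: float = 0.05,
) -> BreakpointFit:
    """Two-segment continuous ("broken-stick") regression.

    Implements the iterative scheme of segmented regression: fit
    ``y = b0 + b1 x + b2 (x - bp)_+ + g * I(x > bp)`` by OLS and update
    ``bp <- bp + g / b2`` until the shift term vanishes.  When the iteration
    diverges or leaves the data range, an SSE grid search over interior x
    values is used instead.  Breakpoint standard error is estimated by a
    seeded nonparametric bootstrap when ``n_boot > 0``.

    Returns ``has_breakpoint=False`` (with a single-line fit) when the
    two-segment model does not improve significantly on a straight line
    (F-test at ``alpha_level``) or the slope change is negligible.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 8:
        raise ValueError("need matched x, y with n >= 8")

    lo, hi = np.quantile(x, 0.05), np.quantile(x, 0.95)
    lin = stats.linregress(x, y)
    sse_line = float(np.sum((y - (lin.intercept + lin.slope * x)) ** 2))

    bp = float(init) if init is not None else float(np.median(x))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        U = np.maximum(x - bp, 0.0)
        V = (x > bp).astype(float)
        X = np.column_stack([np.ones_like(x), x, U, V])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        b2, g = beta[2], beta[3]
        if abs(b2) < 1e-12:
            break
        # first-order expansion of (x - bp)_+ in bp gives g = -b2 * d_bp
        new_bp = bp - g / b2
        if not (lo <= new_bp <= hi):
            break
        if abs(new_bp - bp) < tol:
            bp = new_bp
            converged = True
            break
        bp = new_bp
    method = "muggeo"
    if not converged:
        bp, _, _ = _grid_breakpoint(x, y)
        method = "grid"

    beta, sse_seg = _segmented_ols(x, y, bp)
    # significance of the slope change: F-test vs the single line
    df_den = x.size - 4  # intercept, slope, slope change, breakpoint
    if df_den <= 0 or sse_seg <= 0:
        f_p = 0.0
    else:
        f_stat = max(sse_line - sse_seg, 0.0) / 2.0 / (sse_seg / df_den)
        f_p = float(stats.f.sf(f_stat, 2, df_den))
    slope_change = float(beta[2])
    if f_p > alpha_level or abs(slope_change) < 1e-10:
        return BreakpointFit(
            breakpoint=None,
            slope_before=float(lin.slope),
            slope_after=float(lin.slope),
            intercept=float(lin.intercept),
            breakpoint_se=None,
            has_breakpoint=False,
            converged=converged,
            iterations=it,
            method=method,
        )

    se = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        boots = []
        n = x.size
        for _ in range(n_boot):
            idx = rng.integers(0, n, n)
            try:
                b = fit_breakpoint(x[idx], y[idx], init=bp, n_boot=0)
            except ValueError:
                continue
            if b.has_breakpoint:
                boots.append(b.breakpoint)
        if len(boots) >= 10:
            se = float(np.std(boots, ddof=1))

    return BreakpointFit(
        breakpoint=float(bp),
        slope_before=float(beta[1]),
        slope_after=float(beta[1] + beta[2]),
        intercept=float(beta[0]),
        breakpoint_se=se,
        has_breakpoint=True,
        converged=converged,
        iterations=it,
        method=method,
    )


def fit_linear(x, y) -> LinearFit:
    """Ordinary least squares line fit (closed form)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    res = stats.linregress(x, y)
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        p_value=float(res.pvalue),
        stderr=float(res.stderr),
    )


# --------------------------------------------------------------------------
# K_leaf rehydration kinetics
# --------------------------------------------------------------------------

def water_viscosity_ratio(temp_c: float, ref_c: float = 20.0) -> float:
    """``eta(T)/eta(ref)`` for liquid water from the Vogel equation.

    Vogel form ``eta = A * exp(B / (T_K - C))`` with the standard water
    coefficients; only the ratio matters for conductance standardisation.
    """
    B, C = 507.88, 149.3  # K (prefactor cancels in the ratio)
    tk, rk = temp_c + 273.15, ref_c + 273.15
    return math.exp(B / (tk - C) - B / (rk - C))


def kleaf_instance(
    fmax: float,
    f2: float,
    psi_init: float,
    psi_fin: float,
    area: float,
    temp_c: float = 20.0,
    flag_threshold: float = 0.10,
) -> KleafInstance:
    """K_leaf from one rehydration record.

    ``K = F / (area * |psi|)`` for the (Fmax, psi_init) and (F2, psi_fin)
    pairs, each standardised to the viscosity of water at 20 C.  When the
    two values differ by more than ``flag_threshold`` (relative to their
    mean) the record is flagged; the mean is still reported.
    """
    if psi_init >= 0 or psi_fin >= 0:
        raise ValueError("psi_init and psi_fin must be negative")
    if area <= 0:
        raise ValueError("area must be > 0")
    visc = water_viscosity_ratio(temp_c)
    k1 = fmax / (area * abs(psi_init)) * visc
    k2 = f2 / (area * abs(psi_fin)) * visc
    mean = 0.5 * (k1 + k2)
    rel = abs(k1 - k2) / mean if mean > 0 else 0.0
    return KleafInstance(
        k_init=k1, k_fin=k2, k_mean=mean,
        flagged=rel > flag_threshold, rel_difference=rel,
    )


def fit_kleaf_curve(psi, k, n_starts: int = 8, seed: int = 0) -> SigmoidFit:
    """Four-parameter sigmoid fit of K_leaf against water potential.

    ``y = y0 + a / (1 + exp(-(psi - x0)/b))`` fitted by nonlinear least
    squares from ``n_starts`` seeded multistarts.  The reduction to the
    (kmax, p50, alpha) parametrisation used by the runaway formulas is:
    ``kmax = y0 + a`` (the wet plateau), ``p50`` the psi where the fitted
    curve crosses ``kmax / 2`` (solved numerically), and ``alpha = |b|``.
    """
    psi = np.asarray(psi, dtype=float)
    k = np.asarray(k, dtype=float)
    if psi.size < 6:
        raise ValueError("need at least 6 records")

    def model(x, y0, a, x0, b):
        return y0 + a / (1.0 + np.exp(np.clip(-(x - x0) / b, -700, 700)))

    kspan = max(k.max() - k.min(), 1e-6)
    rng = np.random.default_rng(seed)
    best, best_sse = None, np.inf
    for i in range(n_starts):
        if i == 0:
            p0 = [0.0, k.max(), float(np.median(psi)), 0.3]
        else:
            p0 = [
                rng.uniform(-0.1 * kspan, 0.3 * kspan),
                kspan * rng.uniform(0.5, 1.5),
                rng.uniform(psi.min(), psi.max()),
                rng.uniform(0.05, 1.5),
            ]
        try:
            popt, _ = optimize.curve_fit(
                model, psi, k, p0=p0, maxfev=20000,
                bounds=([-np.inf, 1e-9, psi.min() - 2, 1e-4],
                        [np.inf, np.inf, psi.max() + 2, 10.0]),
            )
        except RuntimeError:
            continue
        sse = float(np.sum((k - model(psi, *popt)) ** 2))
        if sse < best_sse:
            best, best_sse = popt, sse
    if best is None:
        raise RuntimeError(
            f"K_leaf sigmoid fit failed to converge from {n_starts} multistarts"
        )
    y0, a, x0, b = (float(v) for v in best)
    kmax = y0 + a
    half = kmax / 2.0

    def crossing(x):
        return model(np.asarray([x]), y0, a, x0, b)[0] - half

    span = 20.0 * abs(b) + 5.0
    try:
        p50 = float(optimize.brentq(crossing, x0 - span, x0 + span))
    except ValueError:
        p50 = x0  # degenerate y0: half-plateau crossing is at x0
    resid = k - model(psi, y0, a, x0, b)
    return SigmoidFit(
        p50=p50, alpha=abs(b), y0=y0, a=a, x0=x0, b=b,
        residual_sd=float(np.std(resid, ddof=min(4, psi.size - 1))),
        n=int(psi.size),
    )


# --------------------------------------------------------------------------
# g_min from mass loss
# --------------------------------------------------------------------------

def gmin_from_trace(
    time_s,
    mass_g,
    area_m2: float,
    temp_c: float,
    rh_pct: float,
    patm_kpa: float = 101.3,
    window: int = 10,
    slope_tol: float = 0.05,
):
    """Minimum cuticular conductance from a leaf mass-loss trace.

    Finds the steady (post-stomatal-closure) phase as the longest terminal
    window over which the rolling mass-loss slope varies by less than
    ``slope_tol`` (relative), fits the slope there, converts it to a water
    loss rate ``WL = -slope / 18.0153 * 1000 / area`` (mmol m-2 s-1) and
    returns ``gmin = WL * P_atm / VPD`` with VPD from the Arden-Buck
    formula.

    Returns
    -------
    (gmin, phase_start_index) : tuple of float and int
    """
    t = np.asarray(time_s, dtype=float)
    m = np.asarray(mass_g, dtype=float)
    if t.size != m.size or t.size < window + 2:
        raise ValueError("trace too short")
    if t[-1] - t[0] < 1800:
        raise ValueError("need at least 30 minutes of trace")
    if area_m2 <= 0:
        raise ValueError("area must be > 0")

    # rolling slopes over `window`-point windows
    n = t.size
    slopes = np.array([
        stats.linregress(t[i: i + window], m[i: i + window]).slope
        for i in range(0, n - window + 1)
    ])
    final = slopes[-1]
    scale = max(abs(final), 1e-15)
    ok = np.abs(slopes - final) <= slope_tol * scale
    # longest terminal run of stable windows
    start_w = len(ok)
    for i in range(len(ok) - 1, -1, -1):
        if ok[i]:
            start_w = i
        else:
            break
    if start_w >= len(ok):
        raise ValueError("no stable terminal phase detected in mass trace")
    i0 = start_w
    slope = stats.linregress(t[i0:], m[i0:]).slope  # g/s, negative
    wl = -slope / MOLAR_MASS_WATER * 1000.0 / area_m2  # mmol m-2 s-1
    vpd = vpd_arden_buck(temp_c, rh_pct)
    if vpd <= 0:
        return 0.0 if abs(wl) < 1e-12 else float("nan"), i0
    return wl * patm_kpa / vpd, i0


# --------------------------------------------------------------------------
# pressure-volume curve
# --------------------------------------------------------------------------

def tlp_from_pv(
    psi,
    mass_g,
    saturated_mass_g: float,
    min_points: int = 4,
    r2_criterion: float = 0.995,
):
    """Turgor loss point from a pressure-volume curve.

    Plots ``1/psi`` against water deficit (fraction of saturated mass lost)
    and grows the terminal (driest-end) linear segment point by point toward
    full hydration while its OLS fit keeps ``r2 >= r2_criterion``.  The TLP
    is the water potential of the wettest point retained in that segment;
    the osmotic potential at full turgor is ``-1/intercept`` of the segment
    extrapolated to zero deficit.

    Returns
    -------
    dict with keys ``tlp``, ``osmotic_potential_ft``, ``n_linear``,
    ``r2``, ``slope``, ``degenerate`` (True when the whole curve is linear,
    i.e. no turgid phase was present).
    """
    psi = np.asarray(psi, dtype=float)
    m = np.asarray(mass_g, dtype=float)
    if psi.size != m.size or psi.size < 10:
        raise ValueError("need >= 10 paired points")
    if np.any(psi >= 0):
        raise ValueError("all psi must be negative")
    deficit = (saturated_mass_g - m) / saturated_mass_g
    order = np.argsort(psi)  # most negative (driest) first
    x = deficit[order]
    y = 1.0 / psi[order]

    # the largest dry-end segment that still satisfies the linearity
    # criterion; small-k dips from noise do not abort the scan
    best_k = None
    for k in range(min_points, psi.size + 1):
        res = stats.linregress(x[:k], y[:k])
        if res.rvalue**2 >= r2_criterion:
            best_k = k
    if best_k is None:
        raise ValueError("no linear post-turgor tail found in PV curve")
    res = stats.linregress(x[:best_k], y[:best_k])
    tlp = float(psi[order][best_k - 1])
    degenerate = best_k == psi.size
    if degenerate:
        warnings.warn(
            "PV curve is linear throughout: no turgid phase; TLP reported at "
            "the wettest point", stacklevel=2,
        )
    osm_ft = 1.0 / res.intercept if res.intercept != 0 else float("nan")
    return {
        "tlp": tlp,
        "osmotic_potential_ft": float(osm_ft),
        "n_linear": int(best_k),
        "r2": float(res.rvalue**2),
        "slope": float(res.slope),
        "degenerate": bool(degenerate),
    }
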