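"""Dose-response calibration of the correlation curve.

The curve of mean ZNCC versus concentration is fitted two ways, matching
standard immunoassay practice: a four-parameter logistic (4PL) over the
full 1-1000 ng/mL panel (log10 concentration axis, since the panel spans
three decades) and an ordinary least-squares line over the quasi-linear
1-50 ng/mL sub-range, whose absolute slope is the surface sensitivity in
(ng/mL)^-1.  Both fits invert in closed form to estimate concentration
from a measured ZNCC value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "CalibrationError",
    "LogisticFit",
    "LinearFit",
    "fit_logistic",
    "fit_linear_sensitivity",
    "invert_concentration",
]


class CalibrationError(RuntimeError):
    pass


def _four_pl(c, lower, upper, log10_mid, slope_factor):
    x = np.log10(c)
    return lower + (upper - lower) / (1.0 + 10.0 ** (slope_factor * (x - log10_mid)))


@dataclass(frozen=True)
class LogisticFit:
    """4PL fit z(c) = lower + (upper - lower) / (1 + (c / midpoint)**slope_factor).

    With slope_factor > 0 the curve falls from ``upper`` at c -> 0 to
    ``lower`` at c -> inf (the decorrelating sensor); negative
    slope_factor describes a rising response.
    """

    lower_asymptote: float
    upper_asymptote: float
    midpoint: float  # ng/mL
    slope_factor: float
    residual_sd: float
    r_squared: float
    c_min: float
    c_max: float

    def predict(self, c):
        return _four_pl(
            np.asarray(c, dtype=float),
            self.lower_asymptote,
            self.upper_asymptote,
            np.log10(self.midpoint),
            self.slope_factor,
        )

    @property
    def span(self) -> float:
        return self.upper_asymptote - self.lower_asymptote


@dataclass(frozen=True)
class LinearFit:
    """OLS line z = slope * c + intercept over ``fit_range``; the surface
    sensitivity is |slope| in (ng/mL)^-1 (ZNCC is dimensionless)."""

    slope: float
    intercept: float
    fit_range: tuple[float, float]
    r_squared: float

    @property
    def sensitivity(self) -> float:
        return abs(self.slope)

    def predict(self, c):
        return self.slope * np.asarray(c, dtype=float) + self.intercept


def _curve_arrays(curve: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    c = np.asarray(curve["concentration_ng_per_ml"], dtype=float)
    z = np.asarray(curve["mean_zncc"], dtype=float)
    if np.any(~np.isfinite(z)) or np.any(c <= 0):
        raise CalibrationError("curve must have finite means and positive concentrations")
    order = np.argsort(c)
    return c[order], z[order]


def fit_logistic(curve: pd.DataFrame) -> LogisticFit:
    """Least-squares 4PL fit of mean ZNCC vs log10(concentration).

    Initialisation from data quantiles (asymptotes from the extreme
    means, midpoint from the half-range crossing); a few restarts over
    slope factors guard against a bad basin.  Raises ``CalibrationError``
    on fewer than 4 distinct concentrations, a flat (degenerate) curve,
    or non-convergence.
    """
    c, z = _curve_arrays(curve)
    if np.unique(c).size < 4:
        raise CalibrationError("logistic fit needs >= 4 distinct concentrations")
    zspan = float(z.max() - z.min())
    if zspan == 0.0:
        raise CalibrationError("degenerate flat curve: zero response span")

    decreasing = z[0] >= z[-1]
    upper0 = float(z.max())
    lower0 = float(z.min())
    half = (upper0 + lower0) / 2.0
    # midpoint guess: concentration whose mean is nearest the half-range
    x0 = float(np.log10(c[np.argmin(np.abs(z - half))]))

    best = None
    for b0 in (1.0, 0.5, 2.0):
        sgn = 1.0 if decreasing else -1.0
        p0 = (lower0, upper0, x0, sgn * b0)
        try:
            popt, _ = curve_fit(
                _four_pl, c, z, p0=p0, maxfev=20000, xtol=1e-14, ftol=1e-14
            )
        except RuntimeError:
            continue
        resid = z - _four_pl(c, *popt)
        sse = float(np.sum(resid**2))
        if best is None or sse < best[1]:
            best = (popt, sse)
    if best is None:
        raise CalibrationError(
            f"4PL fit failed to converge on {c.size} points (span {zspan:.3g})"
        )
    (lower, upper, log10_mid, slope_factor), sse = best
    if upper < lower:
        # relabel so upper_asymptote >= lower_asymptote
        lower, upper = upper, lower
        slope_factor = -slope_factor
    sst = float(np.sum((z - z.mean()) ** 2))
    dof = max(c.size - 4, 1)
    return LogisticFit(
        lower_asymptote=float(lower),
        upper_asymptote=float(upper),
        midpoint=float(10.0**log10_mid),
        slope_factor=float(slope_factor),
        residual_sd=float(np.sqrt(sse / dof)),
        r_squared=1.0 - sse / sst if sst > 0 else np.nan,
        c_min=float(c.min()),
        c_max=float(c.max()),
    )


def fit_linear_sensitivity(
    curve: pd.DataFrame,
    c_min: float = 1.0,
    c_max: float = 50.0,
    weighted: bool = False,
) -> LinearFit:
    """Least squares of mean ZNCC vs concentration restricted to
    [c_min, c_max]; unweighted by default (replicate counts are equal by
    construction), with inverse-variance weighting of the per-
    concentration means (``n / sd**2``) as an option."""
    if c_min >= c_max:
        raise ValueError("c_min must be < c_max")
    c, z = _curve_arrays(curve)
    mask = (c >= c_min) & (c <= c_max)
    if mask.sum() < 2:
        raise CalibrationError(
            f"linear sensitivity fit needs >= 2 points in [{c_min}, {c_max}]"
        )
    cs, zs = c[mask], z[mask]
    w = None
    if weighted:
        order = np.argsort(np.asarray(curve["concentration_ng_per_ml"], dtype=float))
        sd = np.asarray(curve["sd_zncc"], dtype=float)[order][mask]
        n = np.asarray(curve["n"], dtype=float)[order][mask]
        if np.any(sd <= 0):
            raise CalibrationError("inverse-variance weights need sd_zncc > 0")
        # np.polyfit weights multiply the residuals, so pass 1/sigma
        w = np.sqrt(n) / sd
    slope, intercept = np.polyfit(cs, zs, 1, w=w)
    resid = zs - (slope * cs + intercept)
    sst = float(np.sum((zs - zs.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / sst if sst > 0 else 1.0
    return LinearFit(
        slope=float(slope),
        intercept=float(intercept),
        fit_range=(c_min, c_max),
        r_squared=r2,
    )


def invert_concentration(
    fit: LogisticFit | LinearFit, z: float
) -> tuple[float, bool]:
    """Closed-form inverse of a fitted curve.

    Returns ``(concentration ng/mL, extrapolated)``; a ZNCC outside the
    fitted response span maps to the nearest fit-range boundary with the
    extrapolation flag set.
    """
    if not np.isfinite(z):
        raise ValueError("ZNCC value must be finite")
    if isinstance(fit, LinearFit):
        if fit.slope == 0.0:
            raise CalibrationError("zero-slope line is not invertible")
        c = (z - fit.intercept) / fit.slope
        lo, hi = fit.fit_range
        if c < lo:
            return lo, True
        if c > hi:
            return hi, True
        return float(c), False
    if fit.span == 0.0 or fit.slope_factor == 0.0:
        raise CalibrationError("degenerate logistic fit is not invertible")
    z_lo = float(fit.predict(fit.c_min))
    z_hi = float(fit.predict(fit.c_max))
    z_at = {fit.c_min: z_lo, fit.c_max: z_hi}
    inner = (fit.upper_asymptote - z) / (z - fit.lower_asymptote) if z != fit.lower_asymptote else np.inf
    if inner <= 0 or not np.isfinite(inner):
        # outside the open asymptote interval: report the boundary whose
        # fitted response is nearest
        c_b = min(z_at, key=lambda k: abs(z_at[k] - z))
        return float(c_b), True
    c = fit.midpoint * inner ** (1.0 / fit.slope_factor)
    if c < fit.c_min:
        return float(fit.c_min), True
    if c > fit.c_max:
        return float(fit.c_max), True
    return float(c), False
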