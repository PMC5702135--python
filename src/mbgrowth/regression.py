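"""Growth-rate regression: weighted linear fit of ln(biomass) vs time, and
a non-linear exponential cross-check.

The exponential growth model dc_X/dt = mu * c_X linearizes under the natural
logarithm, so mu is the slope of ln(c_X) against time. Because the
backscatter error is additive, the log-transformed errors scale as 1/c_X and
the weighted fit uses their inverse squares as weights. Non-linear
regression (NLR) of c0 * exp(mu t) on the untransformed signal is the
reference method; it is seeded from the linear fit since it is iterative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import optimize, stats

from .errors import ConvergenceError, DegenerateFitError

__all__ = ["FitResult", "weighted_linear_fit", "adjusted_r2",
           "nonlinear_exp_fit"]


@dataclass(frozen=True)
class FitResult:
    """Summary of one exponential-phase fit.

    Attributes
    ----------
    mu : float
        Growth rate (slope of ln biomass vs time), 1/h.
    intercept : float
        ln(a.u.) at t = 0 — for NLR, ``ln(c0)``.
    mu_se : float
        Standard error of the slope, 1/h.
    ci95 : (float, float)
        Student-t 95% confidence interval for mu (n - 2 dof).
    adj_r2 : float
        Weighted adjusted coefficient of determination.
    n : int
        Number of points in the fit.
    method : str
        ``"WLR"`` or ``"NLR"``.
    c0 : float or None
        Fitted initial biomass (NLR only), a.u.
    """

    mu: float
    intercept: float
    mu_se: float
    ci95: Tuple[float, float]
    adj_r2: float
    n: int
    method: str = "WLR"
    c0: Optional[float] = None


def adjusted_r2(y, yhat, w, p: int = 2) -> float:
    """Weighted adjusted R-squared.

    R2_w = 1 - SSE_w / SST_w with weighted sums of squares about the
    weighted mean; adjusted = 1 - (1 - R2_w) (n-1)/(n-p). Reduces to the
    ordinary adjusted R2 at equal weights.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    w = np.asarray(w, dtype=float)
    n = len(y)
    if n < 3:
        raise DegenerateFitError("window too short for adjusted R2")
    ybar = np.sum(w * y) / np.sum(w)
    sst = np.sum(w * (y - ybar) ** 2)
    if sst == 0:
        raise DegenerateFitError("undefined R2: constant response")
    sse = np.sum(w * (y - yhat) ** 2)
    r2 = 1.0 - sse / sst
    return float(1.0 - (1.0 - r2) * (n - 1) / (n - p))


def weighted_linear_fit(t, y, w) -> FitResult:
    """Weighted least-squares line through (t, y) with weights w.

    Closed-form weighted normal equations in centered coordinates. The
    slope standard error uses the weighted residual variance with n - 2
    degrees of freedom; the 95% CI is mu +/- t(0.975, n-2) * se.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    n = len(t)
    if n < 3:
        raise DegenerateFitError("window too short: need >= 3 points")
    if np.any(w <= 0):
        raise DegenerateFitError("weights must be strictly positive")
    sw = np.sum(w)
    tbar = np.sum(w * t) / sw
    ybar = np.sum(w * y) / sw
    sxx = np.sum(w * (t - tbar) ** 2)
    if sxx == 0:
        raise DegenerateFitError("degenerate time vector: all time stamps equal")
    sxy = np.sum(w * (t - tbar) * (y - ybar))
    mu = sxy / sxx
    intercept = ybar - mu * tbar
    resid = y - intercept - mu * t
    s2 = np.sum(w * resid**2) / (n - 2)
    mu_se = float(np.sqrt(s2 / sxx))
    tq = stats.t.ppf(0.975, n - 2)
    ar2 = adjusted_r2(y, intercept + mu * t, w)
    return FitResult(mu=float(mu), intercept=float(intercept), mu_se=mu_se,
                     ci95=(float(mu - tq * mu_se), float(mu + tq * mu_se)),
                     adj_r2=ar2, n=n, method="WLR")


def nonlinear_exp_fit(t, c, delta, init: FitResult,
                      weighted: bool = True,
                      max_iter: int = 500) -> FitResult:
    """Fit c(t) = c0 * exp(mu t) to the untransformed blanked signal.

    Minimizes sum((c_i - c0 exp(mu t_i))^2 / delta_i^2) from the linear-fit
    seed (c0 = exp(intercept), mu). Convergence: relative parameter change
    below 1e-10 (or ``max_iter`` iterations -> ConvergenceError carrying the
    seed fit as fallback). The CI comes from the local curvature of the
    objective (Gauss-Newton covariance) with n - 2 dof.

    Set ``weighted=False`` to drop the 1/delta^2 weighting.
    """
    t = np.asarray(t, dtype=float)
    c = np.asarray(c, dtype=float)
    n = len(t)
    if n < 3:
        raise DegenerateFitError("window too short: need >= 3 points")
    if np.any(c <= 0):
        raise DegenerateFitError("NLR requires strictly positive biomass")
    delta = np.asarray(delta, dtype=float)
    if delta.ndim == 0:
        delta = np.full(n, float(delta))
    if not weighted or np.all(delta == 0):
        scale = np.ones(n)
    else:
        scale = delta.copy()
        scale[scale == 0] = np.min(scale[scale > 0]) if np.any(scale > 0) else 1.0

    def resid(params):
        c0, mu = params
        return (c - c0 * np.exp(mu * t)) / scale

    x0 = np.array([np.exp(init.intercept), init.mu])
    sol = optimize.least_squares(resid, x0, method="lm",
                                 xtol=1e-12, ftol=1e-12, gtol=1e-12,
                                 max_nfev=max_iter * 4)
    if not sol.success:
        raise ConvergenceError("NLR failed to converge", fallback=init)
    c0, mu = sol.x
    if c0 <= 0:
        raise ConvergenceError("NLR converged to non-positive c0",
                               fallback=init)
    # Gauss-Newton covariance from the Jacobian at the optimum
    jtj = sol.jac.T @ sol.jac
    try:
        cov = np.linalg.inv(jtj)
    except np.linalg.LinAlgError:
        raise ConvergenceError("NLR curvature singular", fallback=init)
    s2 = 2.0 * sol.cost / (n - 2)
    mu_se = float(np.sqrt(s2 * cov[1, 1]))
    tq = stats.t.ppf(0.975, n - 2)
    yhat = c0 * np.exp(mu * t)
    w = 1.0 / scale**2
    ar2 = adjusted_r2(c, yhat, w)
    return FitResult(mu=float(mu), intercept=float(np.log(c0)), mu_se=mu_se,
                     ci95=(float(mu - tq * mu_se), float(mu + tq * mu_se)),
                     adj_r2=ar2, n=n, method="NLR", c0=float(c0))
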