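"""scikit-learn style estimator tying the whole single-well chain together.

``GrowthRateEstimator.fit(t, bs)`` takes one well's time stamps (hours) and
raw backscatter readings, estimates blank and measurement error from the
pre-growth cycles, locates the LOQ crossing, runs the iterative
exponential-phase detection with weighted linear regression, and (optionally)
cross-checks with a non-linear exponential fit. Fitted attributes follow the
sklearn trailing-underscore convention; the estimator clones and composes
with sklearn model-selection utilities.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .errors import ConvergenceError, NoExponentialPhaseError
from .phase_detection import detect_exponential_phase
from .preprocessing import RawWell, apply_blank, estimate_blank, log_transform
from .regression import nonlinear_exp_fit

__all__ = ["GrowthRateEstimator"]


class GrowthRateEstimator(BaseEstimator, RegressorMixin):
    """Automated growth-rate determination for one backscatter trace.

    Parameters
    ----------
    loq : float or None
        Limit of quantification (a.u., on the blanked scale). ``None``
        defaults to ``10 * sigma`` of the blank window — a conventional
        quantification limit — and records that in ``defaulted_loq_``.
    r2_min : float
        Adjusted-R2 acceptance threshold for the window search
        (default 0.99).
    blank_policy : int or "adaptive"
        Pre-growth cycle selection for blank/error estimation: an int k
        uses the first k cycles; "adaptive" grows the window inside
        blank +/- 3 sigma.
    nlr : bool
        Also run the non-linear exponential regression seeded by the
        linear fit.
    nlr_weighted : bool
        Weight the NLR residuals by the inverse squared measurement error.

    Attributes
    ----------
    mu_ : float
        Growth rate, 1/h (WLR).
    ci95_ : (float, float)
        95% confidence interval for ``mu_``.
    adj_r2_ : float
        Adjusted R2 of the accepted window fit.
    blank_, sigma_, error_ : float
        Blank value, per-reading error and propagated per-point error (a.u.).
    loq_ : float
        LOQ actually applied (user value or the 10-sigma default).
    window_ : (int, int)
        Accepted window, inclusive cycle indices.
    detection_ : DetectionResult
        Full iterative-search record.
    nlr_fit_ : FitResult or None
        Non-linear regression result when ``nlr=True``.
    converged_ : bool
        Whether the three stopping criteria were met.
    """

    def __init__(self, loq: Optional[float] = None, r2_min: float = 0.99,
                 blank_policy=5, nlr: bool = False,
                 nlr_weighted: bool = True):
        self.loq = loq
        self.r2_min = r2_min
        self.blank_policy = blank_policy
        self.nlr = nlr
        self.nlr_weighted = nlr_weighted

    def fit(self, t, bs=None, well_id: str = "well"):
        """Fit on time stamps ``t`` (hours) and raw backscatter ``bs``.

        ``t`` may also be a ``RawWell`` (then ``bs`` is ignored), or a
        2-column array ``[time, backscatter]`` for pipeline compatibility.
        """
        if isinstance(t, RawWell):
            raw = t
        else:
            t = np.asarray(t, dtype=float)
            if bs is None:
                if t.ndim != 2 or t.shape[1] != 2:
                    raise ValueError(
                        "without bs, t must be an (n, 2) [time, backscatter] array"
                    )
                t, bs = t[:, 0], t[:, 1]
            else:
                t = np.ravel(t)
            raw = RawWell(well_id=well_id, time=t, backscatter=np.ravel(bs))

        stats = estimate_blank(raw, self.blank_policy)
        self.blank_ = stats.blank
        self.sigma_ = stats.sigma
        self.n_pre_ = stats.n_pre
        self.lod_ = stats.lod

        self.defaulted_loq_ = self.loq is None
        loq = 10.0 * stats.sigma if self.loq is None else float(self.loq)
        if not loq > 0:
            raise ValueError("LOQ must be positive; supply loq explicitly "
                             "for noiseless data")
        self.loq_ = loq

        curve = apply_blank(raw, stats, loq=loq)
        self.error_ = curve.error
        self.curve_ = curve

        det = detect_exponential_phase(curve, loq, self.r2_min)
        self.detection_ = det
        self.converged_ = det.converged
        self.window_ = (det.start_index, det.end_index)
        self.n_iter_ = det.iterations
        if not det.converged:
            raise NoExponentialPhaseError(
                f"{raw.well_id}: no exponential phase found "
                f"(window shrank to {det.end_index - det.start_index + 1} points)"
            )
        fit = det.fit
        self.fit_ = fit
        self.mu_ = fit.mu
        self.intercept_ = fit.intercept
        self.mu_se_ = fit.mu_se
        self.ci95_ = fit.ci95
        self.adj_r2_ = fit.adj_r2
        self.n_points_ = fit.n

        self.nlr_fit_ = None
        if self.nlr:
            s, e = self.window_
            try:
                self.nlr_fit_ = nonlinear_exp_fit(
                    curve.time[s:e + 1], curve.value[s:e + 1], curve.error,
                    init=fit, weighted=self.nlr_weighted)
            except ConvergenceError as exc:
                self.nlr_fit_ = exc.fallback
        return self

    def predict(self, t):
        """Predicted blanked biomass ``exp(intercept_ + mu_ t)`` (a.u.)."""
        check_is_fitted(self, "mu_")
        t = np.ravel(np.asarray(t, dtype=float))
        return np.exp(self.intercept_ + self.mu_ * t)

    def score(self, t=None, bs=None):
        """Adjusted R2 of the accepted exponential-window fit."""
        check_is_fitted(self, "adj_r2_")
        return self.adj_r2_
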