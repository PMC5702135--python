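"""Exponential-phase detection by iterative trailing-point removal.

Starting from the window [first LOQ crossing ... last cycle], a weighted
linear fit of ln(biomass) vs time is evaluated against three stopping
criteria; while any fails, the final measurement is dropped and the fit
repeated. The criteria are:

1. the adjusted R-squared of the fit exceeds a threshold (default 0.99);
2. the biomass increase over the last measurement cycle is strictly larger
   than over the previous one (exponential convexity — rules out trailing
   stationary-phase points that an R-squared test alone would tolerate at
   high temporal resolution);
3. neither of those two increases is negative (rules out the transient
   signal dips sometimes seen at the exponential-to-stationary transition).

Criteria 2-3 act on the blanked linear-scale signal of the *current*
window, since the loop removes the final measurement of the evaluated
subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .errors import DegenerateFitError, NoQuantifiableGrowthError
from .preprocessing import BlankedCurve, find_loq_crossing, log_transform
from .regression import FitResult, weighted_linear_fit

__all__ = ["DetectionResult", "stopping_criteria", "detect_exponential_phase"]

MIN_WINDOW = 4  # regression needs >= 3; one extra so both increases are inside


@dataclass(frozen=True)
class DetectionResult:
    """Outcome of the iterative exponential-phase search.

    ``start_index``/``end_index`` delimit the accepted window (inclusive);
    ``iterations`` counts trailing-point removals; ``criteria_trace`` holds
    one ``(adj_r2, d_last, d_prev, c1, c2, c3)`` record per iteration for
    diagnostics.
    """

    start_index: int
    end_index: int
    fit: Optional[FitResult]
    iterations: int
    converged: bool
    criteria_trace: List[tuple] = field(default_factory=list)
    diagnostic: str = ""


def stopping_criteria(window_values: np.ndarray, fit: FitResult,
                      r2_min: float) -> Tuple[bool, bool, bool]:
    """Evaluate the three acceptance criteria on the current window.

    With v the blanked values, d_last = v[-1] - v[-2] and
    d_prev = v[-2] - v[-3]:
    c1 = adj_r2 > r2_min; c2 = d_last > d_prev; c3 = both increases >= 0.
    """
    v = np.asarray(window_values, dtype=float)
    d_last = v[-1] - v[-2]
    d_prev = v[-2] - v[-3]
    c1 = fit.adj_r2 > r2_min
    c2 = d_last > d_prev
    c3 = (d_last >= 0) and (d_prev >= 0)
    return c1, c2, c3


def detect_exponential_phase(curve: BlankedCurve, loq: float,
                             r2_min: float = 0.99) -> DetectionResult:
    """Find the exponential window and its growth rate.

    Raises ``NoQuantifiableGrowthError`` if the signal never exceeds
    ``loq``. A window that shrinks below 4 points returns
    ``converged=False`` with the last fit and a diagnostic, so a plate run
    can flag the well and continue.
    """
    if not 0 < r2_min < 1:
        raise ValueError("r2_min must lie in (0, 1)")
    start = find_loq_crossing(curve, loq)
    end = len(curve.value) - 1  # inclusive
    trace: List[tuple] = []
    last_fit: Optional[FitResult] = None
    iterations = 0
    while end - start + 1 >= MIN_WINDOW:
        t, y, w = log_transform(curve, start, end + 1)
        try:
            fit = weighted_linear_fit(t, y, w)
        except DegenerateFitError:
            # e.g. a perfectly constant plateau window; treat as a failed
            # iteration and keep shrinking
            trace.append((float("nan"), float("nan"), float("nan"),
                          False, False, False))
            end -= 1
            iterations += 1
            continue
        last_fit = fit
        v = curve.value[start:end + 1]
        c1, c2, c3 = stopping_criteria(v, fit, r2_min)
        d_last = v[-1] - v[-2]
        d_prev = v[-2] - v[-3]
        trace.append((fit.adj_r2, d_last, d_prev, c1, c2, c3))
        if c1 and c2 and c3:
            return DetectionResult(start_index=start, end_index=end,
                                   fit=fit, iterations=iterations,
                                   converged=True, criteria_trace=trace)
        end -= 1
        iterations += 1
    return DetectionResult(start_index=start, end_index=end, fit=last_fit,
                           iterations=iterations, converged=False,
                           criteria_trace=trace,
                           diagnostic="no exponential phase found")
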