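"""Blank estimation, error propagation and quantification-limit handling.

A microbioreactor well reports backscatter (BS, arbitrary units) as an
online biomass proxy. Before any rate can be fitted, the raw trace must be
(i) blanked — the pre-growth signal offset subtracted, (ii) annotated with
a per-point measurement error, which is treated as additive and therefore
constant across the trace, and (iii) restricted to readings above a
user-defined limit of quantification (LOQ), below which the blanked signal
is too close to the noise floor to carry rate information.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from .errors import (
    InsufficientBlankWindowError,
    NonPositiveBiomassError,
    NoQuantifiableGrowthError,
)

__all__ = [
    "RawWell",
    "BlankStats",
    "BlankedCurve",
    "estimate_blank",
    "apply_blank",
    "find_loq_crossing",
    "log_transform",
]


@dataclass(frozen=True)
class RawWell:
    """One well's raw time series plus metadata.

    Parameters
    ----------
    well_id : str
        Plate coordinate label, e.g. ``"A01"``.
    time : ndarray
        Strictly increasing time stamps in hours.
    backscatter : ndarray
        Raw backscatter readings, arbitrary units (a.u.).
    dissolved_oxygen : ndarray, optional
        Dissolved-oxygen trace in % saturation; stored and plotted only.
    cycle_time : float
        Measurement cycle time in minutes (BioLector default here: 9 min).
    """

    well_id: str
    time: np.ndarray
    backscatter: np.ndarray
    dissolved_oxygen: Optional[np.ndarray] = None
    cycle_time: float = 9.0

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        bs = np.asarray(self.backscatter, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "backscatter", bs)
        if t.ndim != 1 or bs.ndim != 1:
            raise ValueError("time and backscatter must be 1-D vectors")
        if len(t) != len(bs):
            raise ValueError("time and backscatter length mismatch")
        if len(t) < 4:
            raise ValueError("a well needs at least 4 measurement cycles")
        if not np.all(np.diff(t) > 0):
            raise ValueError("time stamps must be strictly increasing")
        if self.dissolved_oxygen is not None:
            do = np.asarray(self.dissolved_oxygen, dtype=float)
            if len(do) != len(t):
                raise ValueError("dissolved_oxygen length mismatch")
            object.__setattr__(self, "dissolved_oxygen", do)

    def __len__(self) -> int:
        return len(self.time)


@dataclass(frozen=True)
class BlankStats:
    """Blank value and additive per-reading measurement error.

    ``blank`` is the mean of the selected pre-growth readings, ``sigma``
    their sample standard deviation (the per-reading error delta_cX), and
    ``n_pre`` the number of readings used. ``lod`` (blank + 3 sigma) is a
    diagnostic limit of detection reported by the adaptive policy.
    """

    blank: float
    sigma: float
    n_pre: int
    lod: float = field(default=float("nan"))

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.n_pre < 2:
            raise ValueError("n_pre must be >= 2")


@dataclass(frozen=True)
class BlankedCurve:
    """Blanked backscatter c_X with a constant propagated per-point error.

    The additive-error model makes the propagated error a single positive
    constant replicated per point. ``loq_index`` is the first cycle whose
    blanked value strictly exceeds ``loq`` (``None`` if never exceeded —
    the well is a non-grower).
    """

    time: np.ndarray
    value: np.ndarray
    error: float
    loq: float = float("nan")
    loq_index: Optional[int] = None


def estimate_blank(raw: RawWell, policy: Union[int, str] = 5) -> BlankStats:
    """Estimate the blank (zero) value and measurement error from the
    pre-growth plateau at the start of the trace.

    Parameters
    ----------
    raw : RawWell
    policy : int or "adaptive"
        An integer ``k`` selects the fixed-count policy: the first ``k``
        cycles are the blank window (default 5). ``"adaptive"`` grows the
        window from 2 cycles while each next reading stays within
        ``blank +/- 3 sigma`` of the running estimate, which approximates
        "all readings below the limit of detection".

    Returns
    -------
    BlankStats
        blank = mean, sigma = sample standard deviation (ddof=1) of the
        window, n_pre = window length, lod = blank + 3 sigma.
    """
    bs = raw.backscatter
    if policy == "adaptive":
        n = 2
        while n < len(bs):
            mean = float(np.mean(bs[:n]))
            sd = float(np.std(bs[:n], ddof=1))
            if abs(bs[n] - mean) <= 3.0 * sd:
                n += 1
            else:
                break
        n_pre = n
    else:
        k = int(policy)
        if k < 2:
            raise InsufficientBlankWindowError(
                "insufficient blank window: need at least 2 pre-growth cycles"
            )
        if k > len(bs):
            raise InsufficientBlankWindowError(
                f"insufficient blank window: {k} cycles requested, "
                f"trace has {len(bs)}"
            )
        n_pre = k
    window = bs[:n_pre]
    blank = float(np.mean(window))
    sigma = float(np.std(window, ddof=1))
    return BlankStats(blank=blank, sigma=sigma, n_pre=n_pre,
                      lod=blank + 3.0 * sigma)


def propagated_error(stats: BlankStats) -> float:
    """Constant per-point error of the blanked signal.

    Subtracting the blank (a mean of ``n_pre`` readings) from each reading
    adds the blank-mean variance to the reading variance:
    ``sqrt(sigma^2 + sigma^2 / n_pre)``. For large blank windows this
    approaches the per-reading error itself.
    """
    return float(np.sqrt(stats.sigma**2 + stats.sigma**2 / stats.n_pre))


def apply_blank(raw: RawWell, stats: BlankStats,
                loq: float = float("nan")) -> BlankedCurve:
    """Subtract the blank and attach the propagated per-point error.

    Negative blanked values are permitted here; they are excluded later by
    the LOQ cut. If ``loq`` is given the crossing index is located too.
    """
    value = raw.backscatter - stats.blank
    err = propagated_error(stats)
    loq_index = None
    if np.isfinite(loq):
        try:
            loq_index = find_loq_crossing_values(value, loq)
        except NoQuantifiableGrowthError:
            loq_index = None
    return BlankedCurve(time=raw.time, value=value, error=err,
                        loq=loq, loq_index=loq_index)


def find_loq_crossing_values(values: np.ndarray, loq: float) -> int:
    """Smallest index ``i`` with ``values[i] > loq`` (strict)."""
    if not loq > 0:
        raise ValueError("loq must be > 0")
    above = np.nonzero(np.asarray(values) > loq)[0]
    if len(above) == 0:
        raise NoQuantifiableGrowthError(
            f"no quantifiable growth: signal never exceeds LOQ = {loq}"
        )
    return int(above[0])


def find_loq_crossing(curve: BlankedCurve, loq: float) -> int:
    """Locate the first measurement cycle whose blanked signal exceeds the
    user-defined limit of quantification.

    Raises
    ------
    NoQuantifiableGrowthError
        If no value ever exceeds ``loq`` (well reported as non-grower).
    """
    return find_loq_crossing_values(curve.value, loq)


def log_transform(curve: BlankedCurve, start: int, stop: int):
    """Natural-log transform of a window, with error propagation and
    regression weights.

    For each blanked value c with additive error d, the transformed
    coordinate is ``y = ln c`` with transformed error ``d/c``; the weight is
    the inverse squared transformed error ``(c/d)^2``, so later (larger)
    exponential points carry more weight. For an exactly noiseless trace
    (``error == 0``) unit weights are used.

    Parameters
    ----------
    curve : BlankedCurve
    start, stop : int
        Half-open index window ``[start, stop)``.

    Returns
    -------
    (t, y, w) : three ndarrays — time (h), ln(value), weights.
    """
    v = curve.value[start:stop]
    t = curve.time[start:stop]
    if np.any(v <= 0):
        raise NonPositiveBiomassError(
            "log of non-positive biomass inside fitting window "
            "(windowing bug: window must start at the LOQ crossing)"
        )
    y = np.log(v)
    if curve.error == 0:
        w = np.ones_like(v)
    else:
        w = (v / curve.error) ** 2
    return t, y, w
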