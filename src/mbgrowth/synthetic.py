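"""Synthetic microbioreactor growth curves with known ground truth.

Emulates a BioLector-style backscatter trace: a pre-growth blank plateau, a
lag phase, one exponential phase, an optional second retarded (diauxic)
phase, and a stationary plateau, with additive Gaussian measurement noise.
Every other module is testable against these curves without any download.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .preprocessing import RawWell

__all__ = ["CurveSpec", "TruthRecord", "simulate_curve", "simulate_plate",
           "cglutamicum_like", "ecoli_like", "truth_table"]


def cglutamicum_like(**overrides) -> "CurveSpec":
    """Single-exponential-phase preset: C. glutamicum on glucose.

    Growth at 0.46 1/h reaching a ~35 a.u. stationary plateau; additive
    noise sd 0.36 a.u. so that a 5-cycle blank window propagates to a
    ~0.39 a.u. per-point error.
    """
    spec = dict(blank_level=40.0, noise_sd=0.36, c0=0.5, mu1=0.46,
                t_lag=5.0, t_phase1_end=20.0, mu2=None, plateau=35.0,
                cycle_min=9.0, t_total=30.0)
    spec.update(overrides)
    return CurveSpec(**spec)


def ecoli_like(**overrides) -> "CurveSpec":
    """Diauxic preset: E. coli on glucose with overflow-metabolite reuse.

    A fast exponential phase at 0.61 1/h until ~7 h (reaching ~25 a.u.),
    then a visibly retarded second phase toward the 35 a.u. plateau;
    noise sd 0.31 a.u. propagates to ~0.34 a.u. with a 5-cycle blank.
    """
    spec = dict(blank_level=40.0, noise_sd=0.31, c0=0.4, mu1=0.61,
                t_lag=0.2, t_phase1_end=7.0, mu2=0.04, plateau=35.0,
                cycle_min=9.0, t_total=24.0)
    spec.update(overrides)
    return CurveSpec(**spec)


@dataclass(frozen=True)
class CurveSpec:
    """Parameters of one simulated well.

    Magnitudes default to a C. glutamicum-like BioLector batch: blank near
    40 a.u., additive noise sd 0.3 a.u., growth at 0.46 1/h from a 0.5 a.u.
    inoculum after a 5 h lag, plateau at 40 a.u. above blank, 9-min cycles.
    """

    blank_level: float = 40.0
    noise_sd: float = 0.36
    c0: float = 0.5
    mu1: float = 0.46
    t_lag: float = 5.0
    t_phase1_end: float = 20.0
    mu2: Optional[float] = None
    plateau: float = 35.0
    cycle_min: float = 9.0
    t_total: float = 30.0
    seed: int = 0
    smooth_transition: bool = False
    simulate_do: bool = False

    def __post_init__(self):
        if not self.mu1 > 0:
            raise ValueError("mu1 must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (self.t_lag < self.t_phase1_end < self.t_total):
            raise ValueError("need t_lag < t_phase1_end < t_total")
        if self.mu2 is not None and not self.mu2 < self.mu1:
            raise ValueError("second phase must be retarded: mu2 < mu1")


@dataclass(frozen=True)
class TruthRecord:
    """Noise-free latent signal and true phase boundaries for one well."""

    spec: CurveSpec
    time: np.ndarray
    latent: np.ndarray  # blanked, noise-free signal
    t_lag: float
    t_phase1_end: float
    mu1: float
    mu2: Optional[float]


def _latent_signal(spec: CurveSpec, t: np.ndarray) -> np.ndarray:
    x = np.full_like(t, spec.c0, dtype=float)
    in1 = (t >= spec.t_lag) & (t <= spec.t_phase1_end)
    x[in1] = spec.c0 * np.exp(spec.mu1 * (t[in1] - spec.t_lag))
    x1_end = min(spec.c0 * np.exp(spec.mu1 * (spec.t_phase1_end - spec.t_lag)),
                 spec.plateau)
    after = t > spec.t_phase1_end
    if spec.mu2 is not None:
        x[after] = x1_end * np.exp(spec.mu2 * (t[after] - spec.t_phase1_end))
    elif spec.smooth_transition:
        # exponential approach to the plateau with the phase-1 end slope
        gap = spec.plateau - x1_end
        if gap > 0:
            rate = spec.mu1 * x1_end / gap
            x[after] = spec.plateau - gap * np.exp(
                -rate * (t[after] - spec.t_phase1_end))
        else:
            x[after] = x1_end
    else:
        x[after] = x1_end
    return np.minimum(x, spec.plateau)


def simulate_curve(spec: CurveSpec) -> Tuple[RawWell, TruthRecord]:
    """Sample one well at ``cycle_min`` intervals over ``[0, t_total]``.

    Observed backscatter is ``blank_level + latent + Normal(0, noise_sd^2)``
    i.i.d. per cycle, fully reproducible from ``spec.seed``.
    """
    dt = spec.cycle_min / 60.0
    n = int(np.floor(spec.t_total / dt)) + 1
    t = np.arange(n) * dt
    latent = _latent_signal(spec, t)
    rng = np.random.default_rng(spec.seed)
    bs = spec.blank_level + latent + rng.normal(0.0, spec.noise_sd, size=n)
    do = None
    if spec.simulate_do:
        # cosmetic mirror of biomass: DO sinks as the culture grows
        do = 100.0 - 60.0 * latent / max(spec.plateau, 1e-9)
    raw = RawWell(well_id="S01", time=t, backscatter=bs,
                  dissolved_oxygen=do, cycle_time=spec.cycle_min)
    truth = TruthRecord(spec=spec, time=t, latent=latent, t_lag=spec.t_lag,
                        t_phase1_end=spec.t_phase1_end, mu1=spec.mu1,
                        mu2=spec.mu2)
    return raw, truth


def simulate_plate(
    n_wells: int,
    spec_generator: Optional[Callable[[int], CurveSpec]] = None,
    seed: int = 0,
    groups: Optional[List[str]] = None,
    n_blank_wells: int = 0,
):
    """Simulate a whole plate with per-well seeds derived from ``seed``.

    Parameters
    ----------
    n_wells : int
        Number of growing wells (>= 1).
    spec_generator : callable(int) -> CurveSpec, optional
        Maps the well index to its spec; defaults to the ``CurveSpec``
        defaults. The spec's own ``seed`` field is overwritten by the
        derived per-well seed.
    seed : int
        Master seed; per-well seeds come from ``np.random.SeedSequence``.
    groups : list of str, optional
        Strain label per growing well (cycled if shorter).
    n_blank_wells : int
        Extra wells containing blank medium only (non-growers).

    Returns
    -------
    (wells, truth, groups_map) :
        list of RawWell, dict well_id -> TruthRecord (growers only), and
        dict well_id -> strain label.
    """
    if n_wells < 1:
        raise ValueError("n_wells must be >= 1")
    total = n_wells + n_blank_wells
    child_seeds = np.random.SeedSequence(seed).generate_state(total) % (2**31)
    wells: List[RawWell] = []
    truth: Dict[str, TruthRecord] = {}
    groups_map: Dict[str, str] = {}
    for i in range(total):
        row, col = divmod(i, 8)
        well_id = f"{chr(ord('A') + row)}{col + 1:02d}"
        if i < n_wells:
            spec = spec_generator(i) if spec_generator else CurveSpec()
            spec = replace(spec, seed=int(child_seeds[i]))
            raw, rec = simulate_curve(spec)
            raw = RawWell(well_id=well_id, time=raw.time,
                          backscatter=raw.backscatter,
                          dissolved_oxygen=raw.dissolved_oxygen,
                          cycle_time=raw.cycle_time)
            truth[well_id] = rec
            groups_map[well_id] = (groups[i % len(groups)]
                                   if groups else "strainA")
        else:
            base = spec_generator(0) if spec_generator else CurveSpec()
            rng = np.random.default_rng(int(child_seeds[i]))
            dt = base.cycle_min / 60.0
            n = int(np.floor(base.t_total / dt)) + 1
            t = np.arange(n) * dt
            bs = base.blank_level + rng.normal(0.0, base.noise_sd, size=n)
            raw = RawWell(well_id=well_id, time=t, backscatter=bs,
                          cycle_time=base.cycle_min)
            groups_map[well_id] = "blank"
        wells.append(raw)
    return wells, truth, groups_map


def truth_table(truth: Dict[str, TruthRecord]) -> pd.DataFrame:
    """Flatten the per-well ground truth for joining with a results table."""
    rows = [{"well_id": wid, "mu1": rec.mu1, "mu2": rec.mu2,
             "t_lag": rec.t_lag, "t_phase1_end": rec.t_phase1_end,
             "noise_sd": rec.spec.noise_sd, "blank_level": rec.spec.blank_level}
            for wid, rec in truth.items()]
    return pd.DataFrame(rows)
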