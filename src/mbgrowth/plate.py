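"""Plate-scale batch processing: ingest, per-well detection, aggregation.

A 48-well microbioreactor plate yields one backscatter trace per well; each
well is processed independently (the task is embarrassingly parallel), so
results are identical regardless of execution order or degree of
parallelism. Failing wells (non-growers, no detectable exponential phase)
are flagged, never fatal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .errors import (
    MBGrowthError,
    NoExponentialPhaseError,
    NoQuantifiableGrowthError,
)
from .estimator import GrowthRateEstimator
from .phase_detection import DetectionResult
from .preprocessing import RawWell

__all__ = [
    "Plate",
    "WellResult",
    "StrainSummary",
    "read_plate_table",
    "write_plate_csv",
    "process_plate",
    "aggregate_replicates",
    "deviation_percent",
    "write_results",
]

RESULT_COLUMNS = [
    "well_id", "strain", "status", "mu_h-1", "ci_low", "ci_high", "adj_r2",
    "n_points", "window_start_h", "window_end_h", "iterations", "blank",
    "sigma", "propagated_error", "loq",
]
SUMMARY_COLUMNS = ["strain", "n", "mu_mean", "dev_pct"]


@dataclass(frozen=True)
class Plate:
    """A collection of wells read from one source file."""

    wells: List[RawWell]
    channel: str = "backscatter"
    source: str = ""
    groups: Optional[Dict[str, str]] = None

    def __post_init__(self):
        ids = [w.well_id for w in self.wells]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate well ids in plate")

    def __len__(self) -> int:
        return len(self.wells)


@dataclass(frozen=True)
class WellResult:
    """Per-well outcome; ``status`` is ``ok`` iff detection converged."""

    well_id: str
    strain: str
    status: str  # ok | no_growth | no_exponential_phase
    mu: float = float("nan")
    ci95: tuple = (float("nan"), float("nan"))
    adj_r2: float = float("nan")
    n_points: int = 0
    window_start_h: float = float("nan")
    window_end_h: float = float("nan")
    iterations: int = 0
    blank: float = float("nan")
    sigma: float = float("nan")
    propagated_error: float = float("nan")
    loq: float = float("nan")
    detection: Optional[DetectionResult] = None
    nlr_mu: float = float("nan")


@dataclass(frozen=True)
class StrainSummary:
    """Replicate aggregation: plain arithmetic mean of per-well rates."""

    strain: str
    n_replicates: int
    mu_mean: float
    replicate_mus: tuple = ()
    dev_pct: float = float("nan")
    status: str = "ok"


def deviation_percent(mu_auto: float, mu_lit: float) -> float:
    """Scale-free deviation of an automated rate from a literature rate:
    ``|1 - mu_auto / mu_lit| * 100`` (%)."""
    if not mu_lit > 0:
        raise ValueError("literature growth rate must be > 0")
    return abs(1.0 - mu_auto / mu_lit) * 100.0


def _truncate_at_first_bad(col: pd.Series, well_id: str) -> np.ndarray:
    vals = pd.to_numeric(col, errors="coerce").to_numpy(dtype=float)
    bad = np.nonzero(~np.isfinite(vals))[0]
    if len(bad):
        warnings.warn(
            f"well {well_id}: unparseable value at row {bad[0]}; "
            f"truncating well at that row")
        vals = vals[:bad[0]]
    return vals


def read_plate_table(path, dialect: str = "wide_csv",
                     config: Optional[dict] = None) -> Plate:
    """Read a plate file into a :class:`Plate`.

    Dialects
    --------
    ``wide_csv``
        First column ``time_h`` (hours), one column per well, header row
        required. ``config["time_unit"] = "min"`` divides times by 60.
    ``biolector_xlsx``
        Spreadsheet with one sheet per channel; ``config`` keys ``sheet``,
        ``time_column``, ``wells`` (list or ``"all"``), ``channel``.
    """
    config = dict(config or {})
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "wide_csv":
        df = pd.read_csv(path)
        time_col = config.get("time_column", "time_h")
        if time_col not in df.columns:
            raise ValueError(f"missing time column '{time_col}' in {path}")
        well_cols = [c for c in df.columns if c != time_col]
    elif dialect == "biolector_xlsx":
        sheet = config.get("sheet", 0)
        df = pd.read_excel(path, sheet_name=sheet)
        time_col = config.get("time_column", "time_h")
        if time_col not in df.columns:
            raise ValueError(f"missing time column '{time_col}' in {path}")
        wanted = config.get("wells", "all")
        well_cols = ([c for c in df.columns if c != time_col]
                     if wanted == "all" else list(wanted))
        missing = [c for c in well_cols if c not in df.columns]
        if missing:
            raise ValueError(f"wells not found in sheet: {missing}")
    else:
        raise ValueError(f"unknown dialect '{dialect}'")
    if len(set(well_cols)) != len(well_cols):
        raise ValueError("duplicate well ids in plate file")
    if len(df) < 4:
        raise ValueError("plate file has fewer than 4 rows")
    time = pd.to_numeric(df[time_col], errors="coerce").to_numpy(dtype=float)
    if config.get("time_unit", "h") == "min":
        time = time / 60.0
    cycle_min = float(np.median(np.diff(time)) * 60.0)
    wells = []
    for c in well_cols:
        vals = _truncate_at_first_bad(df[c], c)
        if len(vals) < 4:
            raise ValueError(f"well {c}: fewer than 4 usable rows")
        wells.append(RawWell(well_id=str(c), time=time[:len(vals)],
                             backscatter=vals, cycle_time=cycle_min))
    return Plate(wells=wells, channel=config.get("channel", "backscatter"),
                 source=str(path))


def write_plate_csv(wells: Sequence[RawWell], path) -> None:
    """Write wells in the wide-CSV dialect the reader consumes."""
    df = pd.DataFrame({"time_h": wells[0].time})
    for w in wells:
        if len(w) != len(wells[0]):
            raise ValueError("wide CSV requires a shared time grid")
        df[w.well_id] = w.backscatter
    df.to_csv(path, index=False)


def _process_well(raw: RawWell, strain: str, loq, r2_min, blank_policy,
                  nlr) -> WellResult:
    est = GrowthRateEstimator(loq=loq, r2_min=r2_min,
                              blank_policy=blank_policy, nlr=nlr)
    try:
        est.fit(raw)
    except NoQuantifiableGrowthError:
        return WellResult(well_id=raw.well_id, strain=strain,
                          status="no_growth",
                          blank=est.blank_, sigma=est.sigma_,
                          loq=getattr(est, "loq_", float("nan")))
    except NoExponentialPhaseError:
        det = est.detection_
        return WellResult(well_id=raw.well_id, strain=strain,
                          status="no_exponential_phase",
                          iterations=det.iterations, blank=est.blank_,
                          sigma=est.sigma_, propagated_error=est.error_,
                          loq=est.loq_, detection=det)
    s, e = est.window_
    return WellResult(
        well_id=raw.well_id, strain=strain, status="ok", mu=est.mu_,
        ci95=est.ci95_, adj_r2=est.adj_r2_, n_points=est.n_points_,
        window_start_h=float(raw.time[s]), window_end_h=float(raw.time[e]),
        iterations=est.n_iter_, blank=est.blank_, sigma=est.sigma_,
        propagated_error=est.error_, loq=est.loq_, detection=est.detection_,
        nlr_mu=est.nlr_fit_.mu if est.nlr_fit_ is not None else float("nan"),
    )


def process_plate(plate: Plate, loq: Optional[float] = None,
                  r2_min: float = 0.99, blank_policy=5, nlr: bool = False,
                  n_jobs: int = 1) -> List[WellResult]:
    """Run exponential-phase detection for every well.

    Wells are independent; with ``n_jobs > 1`` they are processed in
    parallel (joblib), and the output order and values are identical to a
    serial run.
    """
    groups = plate.groups or {}
    tasks = [(w, groups.get(w.well_id, "")) for w in plate.wells]
    if n_jobs == 1:
        return [_process_well(w, s, loq, r2_min, blank_policy, nlr)
                for w, s in tasks]
    return Parallel(n_jobs=n_jobs)(
        delayed(_process_well)(w, s, loq, r2_min, blank_policy, nlr)
        for w, s in tasks)


def aggregate_replicates(results: Sequence[WellResult],
                         groups: Optional[Dict[str, str]] = None,
                         lit_rates: Optional[Dict[str, float]] = None
                         ) -> List[StrainSummary]:
    """Arithmetic mean of replicate growth rates per strain group.

    ``groups`` maps well_id -> strain (falls back to each result's own
    strain label); ``lit_rates`` maps strain -> literature mu for the
    deviation column. Groups with zero converged wells get a flagged
    summary with no mean.
    """
    by_strain: Dict[str, List[WellResult]] = {}
    for r in results:
        strain = (groups or {}).get(r.well_id, r.strain) or "ungrouped"
        by_strain.setdefault(strain, []).append(r)
    summaries = []
    for strain in sorted(by_strain):
        ok = [r for r in by_strain[strain] if r.status == "ok"]
        if not ok:
            summaries.append(StrainSummary(strain=strain, n_replicates=0,
                                           mu_mean=float("nan"),
                                           status="no_converged_replicates"))
            continue
        mus = tuple(r.mu for r in ok)
        mean = float(np.mean(mus))
        dev = float("nan")
        if lit_rates and strain in lit_rates:
            dev = deviation_percent(mean, lit_rates[strain])
        summaries.append(StrainSummary(strain=strain, n_replicates=len(ok),
                                       mu_mean=mean, replicate_mus=mus,
                                       dev_pct=dev))
    return summaries


def _fmt(x) -> str:
    if isinstance(x, float):
        return "" if not np.isfinite(x) else f"{x:.6g}"
    return str(x)


def results_frame(results: Sequence[WellResult]) -> pd.DataFrame:
    rows = [{
        "well_id": r.well_id, "strain": r.strain, "status": r.status,
        "mu_h-1": r.mu, "ci_low": r.ci95[0], "ci_high": r.ci95[1],
        "adj_r2": r.adj_r2, "n_points": r.n_points,
        "window_start_h": r.window_start_h, "window_end_h": r.window_end_h,
        "iterations": r.iterations, "blank": r.blank, "sigma": r.sigma,
        "propagated_error": r.propagated_error, "loq": r.loq,
    } for r in results]
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def write_results(results: Sequence[WellResult],
                  summaries: Sequence[StrainSummary],
                  results_path, summary_path) -> None:
    """Write the per-well results CSV and the per-strain summary CSV.

    Fixed column order; numbers at 6 significant digits, plus a
    2-decimal presentation column for the mean rate in the summary.
    """
    if not results:
        raise ValueError("results must be non-empty")
    rdf = results_frame(results)
    for c in rdf.columns:
        rdf[c] = rdf[c].map(_fmt)
    rdf.to_csv(results_path, index=False)
    srows = [{"strain": s.strain, "n": s.n_replicates,
              "mu_mean": _fmt(s.mu_mean),
              "dev_pct": _fmt(s.dev_pct),
              "mu_mean_2dp": ("" if not np.isfinite(s.mu_mean)
                              else f"{s.mu_mean:.2f}")}
             for s in summaries]
    sdf = pd.DataFrame(srows, columns=SUMMARY_COLUMNS + ["mu_mean_2dp"])
    sdf.to_csv(summary_path, index=False)
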