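"""Indirect-calorimetry trace processing: from minute-level gas exchange to
measured resting energy expenditure (mREE).

Processing order, mirroring how a canopy measurement is analysed:

1. discard the acclimation period (default first 10 min);
2. find the earliest steady state: a sliding window (default 5 min) in
   which the coefficient of variation of RQ is below 5% and of VO2 and of
   minute ventilation below 10% (all strict);
3. average VO2 and VCO2 from the start of that window to the end of the
   recording, requiring at least 20 min of data;
4. convert the mean gas exchange to kcal/day with the abbreviated
   (protein-free) Weir equation and compute RQ from the same means.

The Weir coefficients are the protein-free form, 3.941 kcal/L O2 and
1.106 kcal/L CO2, forced by the fact that only O2 and CO2 are recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import DomainError, QCFailureError, SchemaError, ValidationError

#: abbreviated Weir coefficients, kcal per litre
WEIR_O2_KCAL_L = 3.941
WEIR_CO2_KCAL_L = 1.106
MINUTES_PER_DAY = 1440.0

DEFAULT_ACCLIMATION_MIN = 10
DEFAULT_SS_WINDOW_MIN = 5
DEFAULT_RQ_CV_MAX_PCT = 5.0
DEFAULT_VO2_CV_MAX_PCT = 10.0
DEFAULT_VE_CV_MAX_PCT = 10.0
MIN_AVERAGING_MINUTES = 20

TRACE_COLUMNS = ("subject_id", "minute", "vo2_l_min", "vco2_l_min", "ve_l_min")


@dataclass(frozen=True)
class CalorimetryTrace:
    """Minute-indexed VO2/VCO2/VE series for one measurement session."""

    subject_id: str
    minutes: np.ndarray        # integer minute index, strictly increasing
    vo2_l_min: np.ndarray
    vco2_l_min: np.ndarray
    ve_l_min: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.minutes)
        arrays = {
            "minutes": m,
            "vo2_l_min": np.asarray(self.vo2_l_min, float),
            "vco2_l_min": np.asarray(self.vco2_l_min, float),
            "ve_l_min": np.asarray(self.ve_l_min, float),
        }
        n = len(m)
        for name, a in arrays.items():
            object.__setattr__(self, name, a)
            if len(a) != n:
                raise ValidationError("trace channels must have equal length")
        if n == 0:
            raise ValidationError("empty trace")
        if np.any(np.diff(m) <= 0):
            raise ValidationError("minute indices must be strictly increasing")
        for name in ("vo2_l_min", "vco2_l_min", "ve_l_min"):
            if np.any(arrays[name] <= 0):
                raise ValidationError(f"{name} must be strictly positive")

    def __len__(self) -> int:
        return len(self.minutes)


@dataclass(frozen=True)
class SteadyStateResult:
    """Outcome of steady-state detection on a post-acclimation trace.

    start_minute is an offset on the post-acclimation clock (0 = first
    minute after acclimation).  diagnostics holds, per candidate window
    start, the CV (%) of RQ, VO2 and VE.
    """

    achieved: bool
    start_minute: int | None
    window_minutes: int
    diagnostics: pd.DataFrame = field(repr=False)


@dataclass(frozen=True)
class MeasurementResult:
    mree_kcal_d: float
    rq: float
    steady_state: SteadyStateResult
    minutes_averaged: int


# --------------------------------------------------------------------------
# trace I/O
# --------------------------------------------------------------------------

def load_traces(path: str | Path) -> dict[str, CalorimetryTrace]:
    """Read long-format trace CSV into one CalorimetryTrace per subject."""
    frame = pd.read_csv(Path(path), dtype={"subject_id": str})
    missing = [c for c in TRACE_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing trace column(s) {', '.join(missing)}")
    out: dict[str, CalorimetryTrace] = {}
    for sid, grp in frame.groupby("subject_id", sort=False):
        grp = grp.sort_values("minute")
        out[str(sid)] = CalorimetryTrace(
            subject_id=str(sid),
            minutes=grp["minute"].to_numpy(int),
            vo2_l_min=grp["vo2_l_min"].to_numpy(float),
            vco2_l_min=grp["vco2_l_min"].to_numpy(float),
            ve_l_min=grp["ve_l_min"].to_numpy(float),
        )
    return out


def write_traces(traces: Sequence[CalorimetryTrace], path: str | Path) -> Path:
    frames = [
        pd.DataFrame({
            "subject_id": t.subject_id,
            "minute": t.minutes,
            "vo2_l_min": t.vo2_l_min,
            "vco2_l_min": t.vco2_l_min,
            "ve_l_min": t.ve_l_min,
        })
        for t in traces
    ]
    pd.concat(frames, ignore_index=True).to_csv(Path(path), index=False)
    return Path(path)


# --------------------------------------------------------------------------
# processing steps
# --------------------------------------------------------------------------

def discard_acclimation(
    trace: CalorimetryTrace, acclimation_min: int = DEFAULT_ACCLIMATION_MIN
) -> CalorimetryTrace:
    """Drop the first acclimation_min minutes (their data are discarded)."""
    if acclimation_min < 0:
        raise ValidationError("acclimation_min must be >= 0")
    if len(trace) <= acclimation_min:
        raise QCFailureError(
            "short_recording",
            f"trace has {len(trace)} min, no data beyond {acclimation_min}-min acclimation",
        )
    if acclimation_min == 0:
        return trace
    return CalorimetryTrace(
        subject_id=trace.subject_id,
        minutes=trace.minutes[acclimation_min:],
        vo2_l_min=trace.vo2_l_min[acclimation_min:],
        vco2_l_min=trace.vco2_l_min[acclimation_min:],
        ve_l_min=trace.ve_l_min[acclimation_min:],
    )


def _cv_pct(values: np.ndarray) -> float:
    # sample (ddof=1) coefficient of variation as a percentage
    mean = values.mean()
    if mean <= 0:
        return float("inf")
    return 100.0 * values.std(ddof=1) / mean


def detect_steady_state(
    trace: CalorimetryTrace,
    window_min: int = DEFAULT_SS_WINDOW_MIN,
    rq_cv_max_pct: float = DEFAULT_RQ_CV_MAX_PCT,
    vo2_cv_max_pct: float = DEFAULT_VO2_CV_MAX_PCT,
    ve_cv_max_pct: float = DEFAULT_VE_CV_MAX_PCT,
) -> SteadyStateResult:
    """Earliest window of window_min consecutive minutes whose per-minute
    RQ, VO2 and VE coefficients of variation are all strictly below their
    thresholds.

    The trace is assumed already acclimation-stripped; window starts are
    reported on that clock.  If no window qualifies the result carries
    achieved=False and the per-window diagnostics.
    """
    if window_min < 2:
        raise ValidationError("window_min must be >= 2")
    n = len(trace)
    if n < window_min:
        raise QCFailureError("short_recording", f"trace has {n} < {window_min} min")
    rq = trace.vco2_l_min / trace.vo2_l_min
    starts = range(n - window_min + 1)
    diag_rows = []
    found: int | None = None
    for s in starts:
        sl = slice(s, s + window_min)
        cvs = (_cv_pct(rq[sl]), _cv_pct(trace.vo2_l_min[sl]), _cv_pct(trace.ve_l_min[sl]))
        ok = cvs[0] < rq_cv_max_pct and cvs[1] < vo2_cv_max_pct and cvs[2] < ve_cv_max_pct
        diag_rows.append((s, *cvs, ok))
        if ok and found is None:
            found = s
    diagnostics = pd.DataFrame(
        diag_rows, columns=["start", "rq_cv_pct", "vo2_cv_pct", "ve_cv_pct", "qualifies"]
    )
    return SteadyStateResult(
        achieved=found is not None,
        start_minute=found,
        window_minutes=window_min,
        diagnostics=diagnostics,
    )


def weir_ree(mean_vo2_l_min: float, mean_vco2_l_min: float) -> float:
    """Energy expenditure, kcal/day, from mean gas exchange (protein-free Weir)."""
    if mean_vo2_l_min <= 0 or mean_vco2_l_min <= 0:
        raise DomainError("gas exchange rates must be positive")
    kcal_min = WEIR_O2_KCAL_L * mean_vo2_l_min + WEIR_CO2_KCAL_L * mean_vco2_l_min
    return kcal_min * MINUTES_PER_DAY


def respiratory_quotient(mean_vco2_l_min: float, mean_vo2_l_min: float) -> float:
    """RQ = VCO2/VO2."""
    if mean_vo2_l_min <= 0:
        raise DomainError("VO2 must be positive")
    return mean_vco2_l_min / mean_vo2_l_min


def measure_ree(
    trace: CalorimetryTrace,
    acclimation_min: int = DEFAULT_ACCLIMATION_MIN,
    window_min: int = DEFAULT_SS_WINDOW_MIN,
    rq_cv_max_pct: float = DEFAULT_RQ_CV_MAX_PCT,
    vo2_cv_max_pct: float = DEFAULT_VO2_CV_MAX_PCT,
    ve_cv_max_pct: float = DEFAULT_VE_CV_MAX_PCT,
    min_minutes: int = MIN_AVERAGING_MINUTES,
) -> MeasurementResult:
    """Full measurement pipeline on a raw trace (acclimation included).

    Raises QCFailureError with reason ``no_steady_state`` if no window
    qualifies, or ``short_recording`` if fewer than min_minutes remain from
    the start of the steady-state window to the end of the trace.
    """
    usable = discard_acclimation(trace, acclimation_min)
    ss = detect_steady_state(usable, window_min, rq_cv_max_pct, vo2_cv_max_pct, ve_cv_max_pct)
    if not ss.achieved:
        raise QCFailureError("no_steady_state", f"subject {trace.subject_id}: no steady state")
    start = ss.start_minute
    n_avg = len(usable) - start
    if n_avg < min_minutes:
        raise QCFailureError(
            "short_recording",
            f"subject {trace.subject_id}: only {n_avg} min from steady state, need {min_minutes}",
        )
    mean_vo2 = float(usable.vo2_l_min[start:].mean())
    mean_vco2 = float(usable.vco2_l_min[start:].mean())
    return MeasurementResult(
        mree_kcal_d=weir_ree(mean_vo2, mean_vco2),
        rq=respiratory_quotient(mean_vco2, mean_vo2),
        steady_state=ss,
        minutes_averaged=n_avg,
    )
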