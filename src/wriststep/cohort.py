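"""Cohort deployment: QC screening, non-wear imputation and daily metrics.

Multi-day recordings are summarised on a day x minute-of-day step grid.
Participants failing any quality rule (less than 72 h of wear, incomplete
diurnal coverage, failed device calibration, mean acceleration above
100 mg) are excluded with flags.  Minutes missing through non-wear are
imputed with the mean of the same minute-of-day over all other valid days;
daily step count is the per-day minute sum, summarised as the median over
valid days; one-minute peak cadence is the highest single calendar-minute
count per day, summarised as the median over valid days (a rolling-60 s
variant is provided for sub-minute step series).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MINUTES_PER_DAY = 1440

WEAR_MIN_HOURS = 72.0
MEAN_ACC_MAX_MG = 100.0

FLAG_WEAR = "wear_lt_72h"
FLAG_DIURNAL = "incomplete_diurnal_coverage"
FLAG_CALIBRATION = "calibration_failure"
FLAG_ACCELERATION = "mean_acc_gt_100mg"


@dataclass
class QCResult:
    include: bool
    flags: list[str]


def qc_screen(wear_hours: float, hours_covered,
              mean_acc_mg: float, calibration_ok: bool = True) -> QCResult:
    """Apply the cohort exclusion rules to one participant's summary stats.

    ``hours_covered`` is an iterable of hour-of-day values (0-23) with at
    least one valid wear epoch anywhere in the recording; diurnal coverage
    requires all 24.  Device calibration is an upstream tool's verdict,
    passed in as a boolean.
    """
    flags = []
    if wear_hours < WEAR_MIN_HOURS:
        flags.append(FLAG_WEAR)
    if set(int(h) for h in hours_covered) != set(range(24)):
        flags.append(FLAG_DIURNAL)
    if not calibration_ok:
        flags.append(FLAG_CALIBRATION)
    if mean_acc_mg > MEAN_ACC_MAX_MG:
        flags.append(FLAG_ACCELERATION)
    return QCResult(include=not flags, flags=flags)


def impute_nonwear(minute_steps: np.ndarray, valid: np.ndarray,
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fill missing minutes from the same minute-of-day on other valid days.

    Parameters
    ----------
    minute_steps : ndarray, shape (n_days, 1440)
        Step counts per calendar minute.
    valid : ndarray of bool, same shape
        False where the minute was non-wear.

    Returns
    -------
    completed, imputed_mask, all_missing_mask
        ``completed`` equals the input where valid; missing minutes hold the
        cross-day mean, or 0 (flagged in ``all_missing_mask``) when the
        minute is missing on every day.
    """
    steps = np.asarray(minute_steps, dtype=float)
    valid = np.asarray(valid, dtype=bool)
    if steps.shape != valid.shape or steps.ndim != 2:
        raise ValueError("minute_steps and valid must share shape (n_days, 1440)")
    if steps.shape[0] < 2:
        raise ValueError("imputation needs at least 2 days")
    n_valid = valid.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        col_mean = np.where(n_valid > 0,
                            np.where(valid, steps, 0.0).sum(axis=0)
                            / np.maximum(n_valid, 1), 0.0)
    completed = np.where(valid, steps, col_mean[None, :])
    imputed = ~valid
    all_missing = np.broadcast_to(n_valid == 0, steps.shape) & imputed
    return completed, imputed, all_missing


def daily_steps(completed: np.ndarray,
                valid_days: np.ndarray | None = None,
                ) -> tuple[np.ndarray, float]:
    """Per-day totals and their median over valid days.

    The median of an even number of days is the mean of the middle two.
    Returns NaN for the summary when no day is valid.
    """
    grid = np.asarray(completed, dtype=float)
    totals = grid.sum(axis=1)
    if valid_days is None:
        valid_days = np.ones(len(totals), dtype=bool)
    vd = totals[np.asarray(valid_days, dtype=bool)]
    return totals, (float(np.median(vd)) if len(vd) else float("nan"))


def peak_1min_cadence(completed: np.ndarray,
                      valid_days: np.ndarray | None = None) -> float:
    """Median over valid days of each day's highest single-minute step count."""
    grid = np.asarray(completed, dtype=float)
    day_max = grid.max(axis=1)
    if valid_days is None:
        valid_days = np.ones(len(day_max), dtype=bool)
    vd = day_max[np.asarray(valid_days, dtype=bool)]
    return float(np.median(vd)) if len(vd) else float("nan")


def rolling_peak_1min(step_times: np.ndarray) -> int:
    """Maximum number of steps in any 60 s window of a step-event series.

    Config-switchable alternative to the calendar-minute peak cadence when
    sub-minute step timing is available.
    """
    t = np.sort(np.asarray(step_times, dtype=float))
    if len(t) == 0:
        return 0
    # two-pointer sweep over windows [t[i], t[i] + 60)
    j = 0
    best = 0
    for i in range(len(t)):
        if j < i:
            j = i
        while j < len(t) and t[j] < t[i] + 60.0:
            j += 1
        best = max(best, j - i)
    return best


def minute_grid_from_steps(step_times: np.ndarray, n_days: int,
                           wear_mask_minutes: np.ndarray | None = None,
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Bin step-event times (s from midnight of day 0) onto a day x minute grid."""
    steps = np.zeros((n_days, MINUTES_PER_DAY))
    t = np.asarray(step_times, dtype=float)
    day = (t // 86400).astype(int)
    minute = ((t % 86400) // 60).astype(int)
    ok = (day >= 0) & (day < n_days)
    np.add.at(steps, (day[ok], minute[ok]), 1)
    valid = (np.ones_like(steps, dtype=bool) if wear_mask_minutes is None
             else np.asarray(wear_mask_minutes, dtype=bool))
    return steps, valid


@dataclass
class DailySummary:
    """Per-participant deployment summary."""

    participant_id: str
    day_totals: np.ndarray
    median_daily_steps: float
    peak_cadence: float
    imputed_minutes: int
    qc: QCResult
    valid_days: np.ndarray = field(default=None)  # type: ignore

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "participant_id": self.participant_id,
            "day": np.arange(len(self.day_totals)),
            "steps": self.day_totals,
            "median_daily_steps": self.median_daily_steps,
            "peak_cadence": self.peak_cadence,
            "imputed_minutes": self.imputed_minutes,
            "qc_include": self.qc.include,
            "qc_flags": ";".join(self.qc.flags) or "",
        })


def summarize_participant(participant_id: str, minute_steps: np.ndarray,
                          valid: np.ndarray, wear_hours: float,
                          hours_covered, mean_acc_mg: float,
                          calibration_ok: bool = True,
                          valid_days: np.ndarray | None = None,
                          ) -> DailySummary:
    """QC screen + impute + summarise one participant's minute grid."""
    qc = qc_screen(wear_hours, hours_covered, mean_acc_mg, calibration_ok)
    completed, imputed, _ = impute_nonwear(minute_steps, valid)
    totals, med = daily_steps(completed, valid_days)
    cadence = peak_1min_cadence(completed, valid_days)
    if valid_days is None:
        valid_days = np.ones(len(totals), dtype=bool)
    return DailySummary(participant_id, totals, med, cadence,
                        int(imputed.sum()), qc, np.asarray(valid_days, bool))
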