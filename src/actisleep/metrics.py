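"""Per-night sleep parameters and per-participant aggregation.

Clock times that straddle midnight are averaged with the pivot trick:
values below a pivot are shifted forward by 24 h, the ordinary mean is
taken, and 24 h is removed again if needed.  Bed and midpoint times pivot
at 12:00, rise times at 0:00.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .chronotype import msfsc, sjl
from .types import NightRecord, ParticipantSummary, SleepPeriod, SleepWakeSeries

log = logging.getLogger(__name__)

PIVOT_BEDTIME = 12.0
PIVOT_RISETIME = 0.0
WEEKEND_WEEKDAYS = (5, 6)  # rise on Saturday or Sunday


def pivot_mean(times: Sequence[float], pivot: float) -> float:
    """Circular-safe mean of clock times in [0, 24) around a pivot."""
    arr = np.asarray(list(times), dtype=float)
    if arr.size == 0:
        raise ValueError("pivot_mean of an empty list")
    mean = np.mean(unwrap_times(arr, pivot))
    return float(mean - 24.0 if mean >= 24.0 else mean)


def unwrap_times(times, pivot: float) -> np.ndarray:
    """Shift clock times below the pivot forward by 24 h."""
    arr = np.asarray(times, dtype=float)
    return np.where(arr < pivot, arr + 24.0, arr)


def day_type_of(night_date) -> str:
    return "weekend" if pd.Timestamp(night_date).weekday() in WEEKEND_WEEKDAYS else "workday"


def night_metrics(period: SleepPeriod, sw: SleepWakeSeries) -> NightRecord:
    """Compute TIB, TST, efficiency and the sleep midpoint for one night.

    TST counts sleep-labelled epochs in [onset, offset); efficiency is
    TST/TIB.  A night with non-positive time in bed is invalid.
    """
    tib = period.risetime_abs - period.bedtime_abs
    if tib <= 0:
        raise ValueError(
            f"{period.participant_id} {period.night_date}: non-positive time in bed ({tib:.2f} h)"
        )
    i0 = max(sw.index_at(period.onset_abs), 0)
    i1 = min(sw.index_at(period.offset_abs), sw.n_epochs)
    tst = float(np.sum(sw.sleep[i0:i1])) / 60.0
    tst = min(tst, tib)
    midpoint_abs = 0.5 * (period.onset_abs + period.offset_abs)
    return NightRecord(
        participant_id=period.participant_id,
        night_date=period.night_date,
        day_type=day_type_of(period.night_date),
        bedtime_abs=period.bedtime_abs,
        risetime_abs=period.risetime_abs,
        midpoint_abs=midpoint_abs,
        tib_h=tib,
        tst_h=tst,
        efficiency=tst / tib,
    )


def _mean_or_nan(values) -> float:
    vals = [v for v in values]
    return float(np.mean(vals)) if vals else np.nan


def _clock_mean_or_nan(values, pivot) -> float:
    vals = [v for v in values]
    return pivot_mean(vals, pivot) if vals else np.nan


def aggregate_participant(
    nights: Iterable[NightRecord],
    demographics: Optional[dict] = None,
    pivot_bed: float = PIVOT_BEDTIME,
    pivot_rise: float = PIVOT_RISETIME,
) -> ParticipantSummary:
    """Aggregate one participant's nights into day-type means and SDs.

    Requires at least one workday night; weekend aggregates (and hence the
    chronotype measures MSFsc and SJL) are defined only when a weekend
    night is present.  Timing SDs use pivot-unwrapped values over all
    nights.
    """
    nights = list(nights)
    if not nights:
        raise ValueError("participant has no valid nights")
    pid = nights[0].participant_id
    by_type = {
        "workday": [n for n in nights if n.day_type == "workday"],
        "weekend": [n for n in nights if n.day_type == "weekend"],
    }
    if not by_type["workday"]:
        raise ValueError(f"{pid}: no workday nights; aggregates undefined")

    def block(sub):
        return dict(
            bedtime=_clock_mean_or_nan([n.bedtime for n in sub], pivot_bed),
            risetime=_clock_mean_or_nan([n.risetime for n in sub], pivot_rise),
            midpoint=_clock_mean_or_nan([n.midpoint for n in sub], pivot_bed),
            tib=_mean_or_nan([n.tib_h for n in sub]),
            tst=_mean_or_nan([n.tst_h for n in sub]),
            efficiency=_mean_or_nan([n.efficiency for n in sub]),
        )

    wk = block(by_type["workday"])
    we = block(by_type["weekend"])
    al = block(nights)

    bed_unwrapped = unwrap_times([n.bedtime for n in nights], pivot_bed)
    rise_unwrapped = unwrap_times([n.risetime for n in nights], pivot_rise)
    bed_sd = float(np.std(bed_unwrapped, ddof=1)) if len(nights) > 1 else 0.0
    rise_sd = float(np.std(rise_unwrapped, ddof=1)) if len(nights) > 1 else 0.0

    msfsc_val = np.nan
    sjl_val = np.nan
    if by_type["weekend"] and np.isfinite(we["tst"]) and we["tst"] > 0 and wk["tst"] > 0:
        msfsc_val = msfsc(we["midpoint"], we["tst"], wk["tst"])
        sjl_val = sjl(we["midpoint"], wk["midpoint"])

    return ParticipantSummary(
        participant_id=pid,
        n_nights=len(nights),
        n_workday_nights=len(by_type["workday"]),
        n_weekend_nights=len(by_type["weekend"]),
        bedtime_workdays=wk["bedtime"],
        bedtime_weekend=we["bedtime"],
        bedtime_all=al["bedtime"],
        risetime_workdays=wk["risetime"],
        risetime_weekend=we["risetime"],
        risetime_all=al["risetime"],
        midpoint_workdays=wk["midpoint"],
        midpoint_weekend=we["midpoint"],
        midpoint_all=al["midpoint"],
        tib_workdays=wk["tib"],
        tib_weekend=we["tib"],
        tib_all=al["tib"],
        tst_workdays=wk["tst"],
        tst_weekend=we["tst"],
        tst_all=al["tst"],
        efficiency_workdays=wk["efficiency"],
        efficiency_weekend=we["efficiency"],
        efficiency_all=al["efficiency"],
        bedtime_sd=bed_sd,
        risetime_sd=rise_sd,
        msfsc=msfsc_val,
        sjl=sjl_val,
        demographics=demographics,
    )


SUMMARY_METRICS = [
    "bedtime_workdays",
    "bedtime_weekend",
    "bedtime_all",
    "risetime_workdays",
    "risetime_weekend",
    "risetime_all",
    "midpoint_workdays",
    "midpoint_weekend",
    "midpoint_all",
    "tib_workdays",
    "tib_weekend",
    "tib_all",
    "tst_workdays",
    "tst_weekend",
    "tst_all",
    "efficiency_workdays",
    "efficiency_weekend",
    "efficiency_all",
    "bedtime_sd",
    "risetime_sd",
    "msfsc",
    "sjl",
]


def summaries_to_frame(summaries: Iterable[ParticipantSummary]) -> pd.DataFrame:
    """Flatten ParticipantSummary records (plus demographics) to a table."""
    rows = []
    for s in summaries:
        row = {"participant_id": s.participant_id, "n_nights": s.n_nights}
        for m in SUMMARY_METRICS:
            row[m] = getattr(s, m)
        if s.demographics:
            row.update(s.demographics)
        rows.append(row)
    return pd.DataFrame(rows)


def group_variability(frame: pd.DataFrame) -> pd.DataFrame:
    """Group-level mean/SD/min/max of the participant timing SDs.

    The group mean of per-participant bed/rise-time SDs is the group's
    sleep-timing variability.
    """
    out = []
    for col in ("bedtime_sd", "risetime_sd"):
        stats = frame.groupby("group")[col].agg(["mean", "std", "min", "max"])
        for group, row in stats.iterrows():
            out.append(
                {
                    "metric": col,
                    "group": group,
                    "mean": row["mean"],
                    "sd": row["std"],
                    "min": row["min"],
                    "max": row["max"],
                }
            )
    return pd.DataFrame(out)
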