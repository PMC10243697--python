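"""Sleep/wake scoring and nightly sleep-period delimitation.

Epochs are classified with the 1-min Cole--Kripke weighted moving sum;
night edges come from the diary, reconciled against the activity trace:
a diary edge disagreeing with the activity-based candidate by more than
30 min is replaced by the candidate (the deterministic surrogate for
visual rescoring).
"""

from __future__ import annotations

import logging

import numpy as np

from .types import ActivitySeries, DiaryEntry, SleepPeriod, SleepWakeSeries

log = logging.getLogger(__name__)

# 1-min "overall best" kernel: weights for epochs t-4 .. t+2, applied to
# counts scaled by 1/100 and capped at 300, overall scale 0.001.
CK_WEIGHTS = np.array([106.0, 54.0, 58.0, 76.0, 230.0, 74.0, 67.0])
CK_SCALE = 0.001
CK_COUNT_DIVISOR = 100.0
CK_COUNT_CAP = 300.0
CK_THRESHOLD = 1.0

MIN_SLEEP_RUN_MIN = 10
DISCREPANCY_LIMIT_MIN = 30.0
SEARCH_PAD_H = 3.0


class UnscorableNight(RuntimeError):
    """No sustained sleep run was found in the night's search window."""


def cole_kripke(series: ActivitySeries) -> SleepWakeSeries:
    """Score each epoch sleep/wake with the 1-min Cole--Kripke kernel.

    D(t) = 0.001 * (106 a(t-4) + 54 a(t-3) + 58 a(t-2) + 76 a(t-1)
                    + 230 a(t) + 74 a(t+1) + 67 a(t+2)),
    with a = min(counts/100, 300) and zero padding at the boundaries;
    an epoch is sleep iff D < 1.
    """
    counts = np.asarray(series.counts, dtype=float)
    if len(counts) < len(CK_WEIGHTS):
        raise ValueError(f"series too short for scoring: {len(counts)} < {len(CK_WEIGHTS)} epochs")
    a = np.minimum(counts / CK_COUNT_DIVISOR, CK_COUNT_CAP)
    padded = np.pad(a, (4, 2))
    # correlation: D[t] = sum_k w[k] * a[t + k - 4]
    d = CK_SCALE * np.correlate(padded, CK_WEIGHTS, mode="valid")
    sleep = d < CK_THRESHOLD
    return SleepWakeSeries(
        participant_id=series.participant_id,
        sleep=sleep,
        d=d,
        start=series.start,
        epoch_seconds=series.epoch_seconds,
    )


def _sleep_runs(sleep: np.ndarray, min_run: int):
    """(start, end) index pairs (inclusive) of sleep runs >= min_run epochs."""
    if len(sleep) == 0:
        return []
    padded = np.concatenate(([False], sleep, [False])).astype(int)
    diff = np.diff(padded)
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1) - 1
    return [(s, e) for s, e in zip(starts, ends) if e - s + 1 >= min_run]


def detect_sleep_period(
    sw: SleepWakeSeries,
    diary: DiaryEntry,
    min_sleep_run_min: int = MIN_SLEEP_RUN_MIN,
    discrepancy_limit_min: float = DISCREPANCY_LIMIT_MIN,
    search_pad_h: float = SEARCH_PAD_H,
) -> SleepPeriod:
    """Delimit the main sleep period of one night.

    The activity-based onset candidate is the start of the first run of at
    least ``min_sleep_run_min`` consecutive sleep epochs inside the window
    [diary bedtime - pad, diary rise time + pad]; the offset candidate is
    the end of the last such run.  Each diary edge is kept when it agrees
    with its candidate to within ``discrepancy_limit_min`` minutes and is
    otherwise replaced by the candidate.
    """
    start_date = sw.start.date()
    bed_diary = diary.bedtime_unwrapped(start_date)
    rise_diary = diary.risetime_unwrapped(start_date)
    lo = max(sw.index_at(bed_diary - search_pad_h), 0)
    hi = min(sw.index_at(rise_diary + search_pad_h) + 1, sw.n_epochs)
    if hi <= lo:
        raise UnscorableNight(f"{diary.participant_id} {diary.night_date}: search window outside recording")
    runs = _sleep_runs(sw.sleep[lo:hi], min_sleep_run_min)
    if not runs:
        raise UnscorableNight(f"{diary.participant_id} {diary.night_date}: no sleep run of >= {min_sleep_run_min} min")
    onset_cand = sw.hour_of_epoch(lo + runs[0][0])
    offset_cand = sw.hour_of_epoch(lo + runs[-1][1] + 1)  # end boundary of the last run

    disc_bed = (onset_cand - bed_diary) * 60.0
    disc_rise = (offset_cand - rise_diary) * 60.0
    bed_ok = abs(disc_bed) <= discrepancy_limit_min
    rise_ok = abs(disc_rise) <= discrepancy_limit_min

    bedtime = bed_diary if bed_ok else onset_cand
    risetime = rise_diary if rise_ok else offset_cand
    bedtime = min(bedtime, onset_cand)
    risetime = max(risetime, offset_cand)
    source = "diary_anchored" if (bed_ok and rise_ok) else "activity_anchored"
    return SleepPeriod(
        participant_id=diary.participant_id,
        night_date=diary.night_date,
        bedtime_abs=bedtime,
        onset_abs=onset_cand,
        offset_abs=offset_cand,
        risetime_abs=risetime,
        source=source,
        discrepancy_bed_min=disc_bed,
        discrepancy_rise_min=disc_rise,
    )
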