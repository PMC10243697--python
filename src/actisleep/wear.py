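"""Non-wear detection, recording validity and age-outlier exclusion.

Non-wear uses the 60-min zero-run rule of Troiano et al. (window 60 min,
up to 2 interior spike minutes below 100 counts tolerated).  An epoch is
non-worn iff it lies inside *some* qualifying window; this union-of-windows
reading makes the rule monotone — raising any count can only shrink the
non-worn set.
"""

from __future__ import annotations

import datetime as _dt
import logging

import numpy as np
import pandas as pd

from .types import ActivitySeries, WearMask

log = logging.getLogger(__name__)

TROIANO_WINDOW_MIN = 60
TROIANO_SPIKE_TOLERANCE = 2
TROIANO_SPIKE_LEVEL = 100

WAKING_WINDOW = (6.0, 24.0)  # local clock hours counted toward the 10-h rule
MIN_WORN_WAKING_MINUTES = 600
MIN_VALID_DAYS = 4


def detect_nonwear(
    series: ActivitySeries,
    window_min: int = TROIANO_WINDOW_MIN,
    spike_tolerance: int = TROIANO_SPIKE_TOLERANCE,
    spike_level: int = TROIANO_SPIKE_LEVEL,
) -> WearMask:
    """Flag epochs as non-worn under the sustained-zero-run rule.

    A qualifying window starts and ends on a zero-count epoch, spans at
    least ``window_min`` minutes, contains no count >= ``spike_level`` and
    at most ``spike_tolerance`` nonzero interior minutes.
    """
    counts = np.asarray(series.counts)
    n = len(counts)
    nonworn = np.zeros(n, dtype=bool)
    zero = counts == 0
    big = counts >= spike_level
    i = 0
    while i < n:
        if not zero[i] or (i > 0 and zero[i - 1]):
            i += 1
            continue
        # i starts a maximal candidate window: extend past up to
        # `spike_tolerance` sub-level spikes, stopping at a big count.
        spikes = 0
        last_zero = i
        j = i + 1
        while j < n:
            if zero[j]:
                last_zero = j
            elif big[j] or spikes >= spike_tolerance:
                break
            else:
                spikes += 1
            j += 1
        if last_zero - i + 1 >= window_min:
            nonworn[i : last_zero + 1] = True
        i += 1
    return WearMask(
        participant_id=series.participant_id,
        worn=~nonworn,
        start=series.start,
        epoch_seconds=series.epoch_seconds,
    )


def apply_diary_offwrist(mask: WearMask, off_wrist_intervals) -> WearMask:
    """OR diary-declared off-wrist spells into the non-wear mask.

    Where the diary says the device was off, the diary wins regardless of
    what the count trace looks like.
    """
    worn = mask.worn.copy()
    n = len(worn)
    for a, b in off_wrist_intervals:
        i0 = int(np.floor((pd.Timestamp(a) - mask.start).total_seconds() / 60.0))
        i1 = int(np.ceil((pd.Timestamp(b) - mask.start).total_seconds() / 60.0))
        worn[max(i0, 0) : min(i1, n)] = False
    return WearMask(mask.participant_id, worn, mask.start, mask.epoch_seconds)


def valid_day(
    mask: WearMask,
    day: _dt.date,
    waking_window=WAKING_WINDOW,
    min_worn_minutes: int = MIN_WORN_WAKING_MINUTES,
) -> bool:
    """True iff the day has >= ``min_worn_minutes`` worn within waking hours.

    The day must lie entirely inside the recording; partial edge days are
    the caller's job to skip (see :func:`count_valid_days`).
    """
    start_midnight = mask.start.normalize()
    day_start_min = int((pd.Timestamp(day) - start_midnight).total_seconds() / 60.0)
    lo = day_start_min + int(waking_window[0] * 60)
    hi = day_start_min + int(waking_window[1] * 60)
    start_off = int(round(mask.start_hour * 60))
    lo_idx, hi_idx = lo - start_off, hi - start_off
    if lo_idx < 0 or hi_idx > len(mask.worn):
        raise ValueError(f"day {day} is not fully inside the recording")
    return int(mask.worn[lo_idx:hi_idx].sum()) >= min_worn_minutes


def count_valid_days(mask: WearMask, **kwargs) -> int:
    """Number of valid days, skipping (and logging) partial edge days."""
    start_midnight = mask.start.normalize()
    end = mask.start + pd.Timedelta(minutes=len(mask.worn))
    n_valid = 0
    day = start_midnight
    while day < end:
        try:
            if valid_day(mask, day.date(), **kwargs):
                n_valid += 1
        except ValueError:
            log.debug("partial day %s excluded from validity counting for %s", day.date(), mask.participant_id)
        day += pd.Timedelta(days=1)
    return n_valid


def valid_participant(n_valid_days: int, min_days: int = MIN_VALID_DAYS) -> bool:
    """Recording passes iff it contributes at least ``min_days`` valid days."""
    return n_valid_days >= min_days


def exclude_age_outliers(
    demographics: pd.DataFrame,
    n_sd: float = 3.0,
    per_group: bool = True,
) -> pd.DataFrame:
    """Drop participants whose age is beyond ``n_sd`` SDs from the mean.

    A single pass using per-group moments by default (a pooled-sample
    variant is available via ``per_group=False``).  Zero-SD groups keep
    everyone.
    """
    frame = demographics.copy()

    def keep(sub: pd.DataFrame) -> pd.Series:
        mu, sd = sub["age"].mean(), sub["age"].std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            return pd.Series(True, index=sub.index)
        return (sub["age"] - mu).abs() <= n_sd * sd

    if per_group:
        kept = frame.groupby("group", group_keys=False).apply(keep, include_groups=False)
        kept = kept.reindex(frame.index)
    else:
        kept = keep(frame)
    dropped = frame.loc[~kept, "participant_id"].tolist()
    if dropped:
        log.info("age-outlier exclusion removed %d participant(s): %s", len(dropped), dropped)
    return frame.loc[kept].reset_index(drop=True)


def validity_report(rows) -> pd.DataFrame:
    """Assemble the per-participant validity report table."""
    return pd.DataFrame(rows, columns=["participant_id", "valid_days", "included", "exclusion_reason"])
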