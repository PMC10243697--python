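"""Core domain containers shared by all pipeline stages.

Clock times are decimal hours in [0, 24).  Night-level processing uses an
*unwrapped* axis: hours since midnight of the recording's first day, so a
bedtime of 23:28 on night 3 sits at 3*24 + 23.467 and ordering constraints
(bedtime <= onset < offset <= rise time) hold as plain inequalities.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd


def parse_clock(text: str) -> float:
    """Parse "HH:MM" (or "H:MM") into decimal hours in [0, 24)."""
    parts = str(text).strip().split(":")
    if len(parts) not in (2, 3):
        raise ValueError(f"unparseable clock time: {text!r}")
    try:
        h, m = int(parts[0]), int(parts[1])
        s = int(parts[2]) if len(parts) == 3 else 0
    except ValueError as exc:
        raise ValueError(f"unparseable clock time: {text!r}") from exc
    if not (0 <= h < 24 and 0 <= m < 60 and 0 <= s < 60):
        raise ValueError(f"clock time out of range: {text!r}")
    return h + m / 60.0 + s / 3600.0


def format_clock(hours: float) -> str:
    """Render decimal hours as "H:MM", rounding to the nearest minute."""
    total = int(round((hours % 24.0) * 60.0)) % (24 * 60)
    return f"{total // 60}:{total % 60:02d}"


@dataclass
class ActivitySeries:
    """One participant's contiguous 1-min epoch activity counts.

    Non-wear shows up as zeros, never as missing epochs: ``counts[i]``
    covers the minute starting at ``start + i`` minutes.
    """

    participant_id: str
    start: pd.Timestamp
    counts: np.ndarray
    epoch_seconds: int = 60

    def __post_init__(self) -> None:
        self.start = pd.Timestamp(self.start)
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if np.any(self.counts < 0):
            raise ValueError("activity counts must be non-negative")
        if self.epoch_seconds != 60:
            raise ValueError("this pipeline requires 60-s epochs")

    @property
    def n_epochs(self) -> int:
        return len(self.counts)

    @property
    def start_date(self) -> _dt.date:
        return self.start.date()

    @property
    def start_hour(self) -> float:
        """Hours from midnight of the start date to the first epoch."""
        midnight = self.start.normalize()
        return (self.start - midnight).total_seconds() / 3600.0

    def timestamps(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start, periods=self.n_epochs, freq="60s")

    def hour_of_epoch(self, index: int) -> float:
        """Unwrapped hour (since start-date midnight) of epoch ``index``."""
        return self.start_hour + index / 60.0

    def index_at(self, hour: float) -> int:
        """Epoch index covering the given unwrapped hour (floor)."""
        return int(np.floor((hour - self.start_hour) * 60.0 + 1e-9))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ActivitySeries):
            return NotImplemented
        return (
            self.participant_id == other.participant_id
            and self.start == other.start
            and self.epoch_seconds == other.epoch_seconds
            and np.array_equal(self.counts, other.counts)
        )


@dataclass
class DiaryEntry:
    """One night's self-report: bed/rise times plus naps and off-wrist spells.

    ``night_date`` is the calendar date of the rise time; a reported bedtime
    later than the rise time belongs to the previous evening.
    """

    participant_id: str
    night_date: _dt.date
    reported_bedtime: float
    reported_risetime: float
    naps: list = field(default_factory=list)
    awakenings_count: int = 0
    off_wrist: list = field(default_factory=list)

    def bedtime_unwrapped(self, start_date: _dt.date) -> float:
        """Reported bedtime on the unwrapped axis anchored at start_date."""
        day = (self.night_date - start_date).days
        bed = self.reported_bedtime
        if bed > self.reported_risetime:
            day -= 1
        return day * 24.0 + bed

    def risetime_unwrapped(self, start_date: _dt.date) -> float:
        day = (self.night_date - start_date).days
        return day * 24.0 + self.reported_risetime


@dataclass
class WearMask:
    """Boolean worn/not-worn per epoch, aligned to an ActivitySeries."""

    participant_id: str
    worn: np.ndarray
    start: pd.Timestamp
    epoch_seconds: int = 60

    def __post_init__(self) -> None:
        self.worn = np.asarray(self.worn, dtype=bool)
        self.start = pd.Timestamp(self.start)

    @property
    def start_hour(self) -> float:
        return (self.start - self.start.normalize()).total_seconds() / 3600.0


@dataclass
class SleepWakeSeries:
    """Per-epoch sleep/wake labels with the underlying classifier score.

    ``sleep[i]`` is True iff the score ``d[i] < 1``.
    """

    participant_id: str
    sleep: np.ndarray
    d: np.ndarray
    start: pd.Timestamp
    epoch_seconds: int = 60

    def __post_init__(self) -> None:
        self.sleep = np.asarray(self.sleep, dtype=bool)
        self.d = np.asarray(self.d, dtype=float)
        self.start = pd.Timestamp(self.start)

    @property
    def n_epochs(self) -> int:
        return len(self.sleep)

    @property
    def start_hour(self) -> float:
        return (self.start - self.start.normalize()).total_seconds() / 3600.0

    def hour_of_epoch(self, index: int) -> float:
        return self.start_hour + index / 60.0

    def index_at(self, hour: float) -> int:
        return int(np.floor((hour - self.start_hour) * 60.0 + 1e-9))


@dataclass
class SleepPeriod:
    """One scored night.  All ``*_abs`` times are unwrapped hours.

    ``source`` records whether the diary report survived reconciliation
    (``diary_anchored``) or an edge was replaced by the activity-based
    candidate because it disagreed by more than the discrepancy limit
    (``activity_anchored``).
    """

    participant_id: str
    night_date: _dt.date
    bedtime_abs: float
    onset_abs: float
    offset_abs: float
    risetime_abs: float
    source: str
    discrepancy_bed_min: float
    discrepancy_rise_min: float

    @property
    def bedtime(self) -> float:
        return self.bedtime_abs % 24.0

    @property
    def onset(self) -> float:
        return self.onset_abs % 24.0

    @property
    def offset(self) -> float:
        return self.offset_abs % 24.0

    @property
    def risetime(self) -> float:
        return self.risetime_abs % 24.0


@dataclass
class NightRecord:
    """Per-night sleep parameters derived from a scored SleepPeriod."""

    participant_id: str
    night_date: _dt.date
    day_type: str  # "workday" | "weekend"
    bedtime_abs: float
    risetime_abs: float
    midpoint_abs: float
    tib_h: float
    tst_h: float
    efficiency: float

    @property
    def bedtime(self) -> float:
        return self.bedtime_abs % 24.0

    @property
    def risetime(self) -> float:
        return self.risetime_abs % 24.0

    @property
    def midpoint(self) -> float:
        return self.midpoint_abs % 24.0


@dataclass
class ParticipantSummary:
    """Per-participant aggregates by day type, plus chronotype measures.

    Clock-time means are stored as decimal hours in [0, 24); the timing
    standard deviations are computed on pivot-unwrapped values so a spread
    straddling midnight is not inflated.
    """

    participant_id: str
    n_nights: int
    n_workday_nights: int
    n_weekend_nights: int
    bedtime_workdays: float = np.nan
    bedtime_weekend: float = np.nan
    bedtime_all: float = np.nan
    risetime_workdays: float = np.nan
    risetime_weekend: float = np.nan
    risetime_all: float = np.nan
    midpoint_workdays: float = np.nan
    midpoint_weekend: float = np.nan
    midpoint_all: float = np.nan
    tib_workdays: float = np.nan
    tib_weekend: float = np.nan
    tib_all: float = np.nan
    tst_workdays: float = np.nan
    tst_weekend: float = np.nan
    tst_all: float = np.nan
    efficiency_workdays: float = np.nan
    efficiency_weekend: float = np.nan
    efficiency_all: float = np.nan
    bedtime_sd: float = np.nan
    risetime_sd: float = np.nan
    msfsc: float = np.nan
    sjl: float = np.nan
    demographics: Optional[dict] = None


@dataclass
class StatResult:
    """One statistical comparison: statistic, df, p and optional extras."""

    test_name: str
    statistic: float
    df: float
    p: float
    estimate: Optional[float] = None
    se: Optional[float] = None
    emms: Optional[dict] = None
    extra: Optional[dict] = None

    @property
    def significant(self) -> bool:
        return bool(self.p < 0.05)

    def as_dict(self) -> dict:
        out = {
            "test_name": self.test_name,
            "statistic": _round(self.statistic),
            "df": _round(self.df),
            "p": _round(self.p),
            "significant": self.significant,
        }
        if self.estimate is not None:
            out["estimate"] = _round(self.estimate)
        if self.se is not None:
            out["se"] = _round(self.se)
        if self.emms is not None:
            out["emms"] = {
                k: {kk: _round(vv) for kk, vv in v.items()} if isinstance(v, dict) else _round(v)
                for k, v in self.emms.items()
            }
        if self.extra is not None:
            out["extra"] = {k: _round(v) if isinstance(v, float) else v for k, v in self.extra.items()}
        return out


def _round(x, ndigits: int = 10):
    if x is None:
        return None
    try:
        xf = float(x)
    except (TypeError, ValueError):
        return x
    if np.isnan(xf):
        return None
    return round(xf, ndigits)
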