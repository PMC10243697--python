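"""Ground-truthed synthetic two-group actigraphy cohort.

Emulates a one-week (7 x 24 h, 1-min epochs) wrist-actigraphy study of an
onsite-working and a home-office group: per-night true bed/rise times with
between- and within-person variation, sleep-onset latency, brief nocturnal
awakenings (WASO), overdispersed activity counts (gamma-mixed Poisson,
high mean awake / low mean asleep), diary reports with minute-level noise
and occasional gross (>30 min) errors, and optional daytime non-wear gaps.

Default timing parameters are the two groups' printed workday/weekend
bed- and rise-time means and SDs; recovery of those group contrasts by the
full pipeline is the generator's reason to exist.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import ActivitySeries, DiaryEntry

WEEK_EPOCHS = 7 * 24 * 60
DEFAULT_START = "2021-03-01 12:00"  # a Monday noon: 5 workday + 2 weekend nights


def _signed_evening(clock_h: float) -> float:
    """Map a bedtime clock hour to a signed offset around midnight."""
    return clock_h - 24.0 if clock_h >= 12.0 else clock_h


@dataclass
class GroupParams:
    """Timing, noise and demographic parameters for one study arm.

    Clock means are decimal hours in [0, 24); the ``*_sd`` values are
    between-person SDs of the personal mean times, while ``night_sd`` is
    the within-person night-to-night SD shared by all edges.
    """

    name: str
    workday_bedtime_mean: float
    workday_bedtime_sd: float
    workday_risetime_mean: float
    workday_risetime_sd: float
    weekend_bedtime_mean: float
    weekend_bedtime_sd: float
    weekend_risetime_mean: float
    weekend_risetime_sd: float
    night_sd: float = 0.75
    sleep_onset_latency_mean_min: float = 15.0
    waso_rate_min_per_h: float = 4.0
    wake_activity_mean: float = 300.0
    sleep_activity_mean: float = 3.0
    activity_dispersion: float | None = 2.0  # gamma shape; None = deterministic counts
    age_mean: float = 28.0
    age_sd: float = 7.0
    p_male: float = 0.32
    p_student: float = 0.45
    p_employee: float = 0.45
    p_children: float = 0.07
    messi_means: tuple = (3.37, 3.01, 3.31)  # MA, EV, DI
    messi_sd: float = 0.8

    def validate(self) -> None:
        for name in ("workday_bedtime_sd", "workday_risetime_sd", "weekend_bedtime_sd",
                     "weekend_risetime_sd", "night_sd", "age_sd", "messi_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{self.name}: {name} must be >= 0")
        for name in ("p_male", "p_student", "p_employee", "p_children"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{self.name}: {name} must be in [0, 1]")
        if self.p_student + self.p_employee > 1.0 + 1e-9:
            raise ValueError(f"{self.name}: profession probabilities exceed 1")
        for name in ("workday_bedtime_mean", "weekend_bedtime_mean",
                     "workday_risetime_mean", "weekend_risetime_mean"):
            if not 0.0 <= getattr(self, name) < 24.0:
                raise ValueError(f"{self.name}: {name} must be a clock hour in [0, 24)")
        if self.sleep_activity_mean >= self.wake_activity_mean:
            raise ValueError(f"{self.name}: sleep activity level must be below wake level")
        if self.sleep_onset_latency_mean_min < 0 or self.waso_rate_min_per_h < 0:
            raise ValueError(f"{self.name}: latency and WASO rate must be >= 0")


def default_onsite() -> GroupParams:
    """Onsite arm: earlier workday timing, older, more employees."""
    return GroupParams(
        name="onsite",
        workday_bedtime_mean=23.0 + 28.0 / 60.0,  # 23:28
        workday_bedtime_sd=0.98,
        workday_risetime_mean=7.0 + 5.0 / 60.0,  # 7:05
        workday_risetime_sd=1.18,
        weekend_bedtime_mean=21.0 / 60.0,  # 0:21
        weekend_bedtime_sd=1.30,
        weekend_risetime_mean=8.0 + 17.0 / 60.0,  # 8:17
        weekend_risetime_sd=1.12,
        age_mean=30.3,
        age_sd=8.7,
        p_male=0.375,
        p_student=0.225,
        p_employee=0.625,
        p_children=0.10,
        messi_means=(3.41, 2.97, 3.35),
    )


def default_home_office() -> GroupParams:
    """Home-office arm: later workday timing, younger, more students."""
    return GroupParams(
        name="home_office",
        workday_bedtime_mean=7.0 / 60.0,  # 0:07
        workday_bedtime_sd=1.05,
        workday_risetime_mean=7.0 + 44.0 / 60.0,  # 7:44
        workday_risetime_sd=1.13,
        weekend_bedtime_mean=45.0 / 60.0,  # 0:45
        weekend_bedtime_sd=1.33,
        weekend_risetime_mean=8.0 + 47.0 / 60.0,  # 8:47
        weekend_risetime_sd=1.20,
        age_mean=25.8,
        age_sd=5.6,
        p_male=0.257,
        p_student=0.657,
        p_employee=0.343,
        p_children=0.029,
        messi_means=(3.32, 3.07, 3.27),
    )


@dataclass
class CohortConfig:
    """Cohort-level knobs: arm sizes, diary noise, non-wear, seed."""

    n_per_group: int = 40
    onsite: GroupParams = field(default_factory=default_onsite)
    home_office: GroupParams = field(default_factory=default_home_office)
    diary_error_sd_min: float = 10.0
    p_diary_gross_error: float = 0.05  # per edge
    p_nonwear_day: float = 0.05
    weekend_phase_correlation: float = 0.7
    seed: int = 0
    start: str = DEFAULT_START

    def validate(self) -> None:
        if self.n_per_group <= 0:
            raise ValueError("n_per_group must be positive")
        if self.diary_error_sd_min < 0:
            raise ValueError("diary_error_sd_min must be >= 0")
        for name in ("p_diary_gross_error", "p_nonwear_day"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not -1.0 <= self.weekend_phase_correlation <= 1.0:
            raise ValueError("weekend_phase_correlation must be in [-1, 1]")
        self.onsite.validate()
        self.home_office.validate()

    def replace(self, **kwargs) -> "CohortConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class GroundTruth:
    """True per-night edges and the true per-epoch sleep state."""

    nights: pd.DataFrame  # participant_id, night_date, day_type, true_* columns
    states: dict  # participant_id -> bool array (True = asleep), week grid

    def write_csv(self, path) -> None:
        self.nights.to_csv(path, index=False)


@dataclass
class CohortData:
    activity: list
    diaries: dict  # participant_id -> list[DiaryEntry]
    demographics: pd.DataFrame
    ground_truth: GroundTruth


def _counts(rng, mean: float, dispersion, n: int) -> np.ndarray:
    if mean <= 0:
        return np.zeros(n, dtype=np.int64)
    if dispersion is None:
        return np.full(n, int(round(mean)), dtype=np.int64)
    lam = rng.gamma(shape=dispersion, scale=mean / dispersion, size=n)
    return rng.poisson(lam).astype(np.int64)


def _simulate_participant(rng, pid: str, params: GroupParams, config: CohortConfig, start: pd.Timestamp):
    start_date = start.date()
    start_hour = (start - start.normalize()).total_seconds() / 3600.0
    rho = config.weekend_phase_correlation

    u_work = rng.standard_normal()
    u_wkend = rho * u_work + np.sqrt(max(1.0 - rho**2, 0.0)) * rng.standard_normal()
    person = {
        "workday": (
            _signed_evening(params.workday_bedtime_mean) + params.workday_bedtime_sd * u_work,
            params.workday_risetime_mean + params.workday_risetime_sd * u_work,
        ),
        "weekend": (
            _signed_evening(params.weekend_bedtime_mean) + params.weekend_bedtime_sd * u_wkend,
            params.weekend_risetime_mean + params.weekend_risetime_sd * u_wkend,
        ),
    }

    sleep_state = np.zeros(WEEK_EPOCHS, dtype=bool)
    nights = []
    diary_entries = []
    for k in range(7):
        rise_day = k + 1
        night_date = start_date + _dt.timedelta(days=rise_day)
        day_type = "weekend" if night_date.weekday() in (5, 6) else "workday"
        bed_mu, rise_mu = person[day_type]
        bed_abs = 24.0 * rise_day + bed_mu + params.night_sd * rng.standard_normal()
        rise_abs = 24.0 * rise_day + rise_mu + params.night_sd * rng.standard_normal()
        rise_abs = max(rise_abs, bed_abs + 4.0)  # floor TIB at 4 h
        latency_h = (
            rng.exponential(params.sleep_onset_latency_mean_min) / 60.0
            if params.sleep_onset_latency_mean_min > 0
            else 0.0
        )
        onset_abs = min(bed_abs + latency_h, bed_abs + (rise_abs - bed_abs) - 1.0)
        offset_abs = rise_abs

        i0 = int(round((onset_abs - start_hour) * 60.0))
        i1 = int(round((offset_abs - start_hour) * 60.0))
        sleep_state[max(i0, 0) : min(i1, WEEK_EPOCHS)] = True

        # WASO: short wake bursts inside the sleep span
        if params.waso_rate_min_per_h > 0:
            sleep_h = offset_abs - onset_abs
            n_bursts = rng.poisson(params.waso_rate_min_per_h * sleep_h / 3.0)
            for _ in range(n_bursts):
                b0 = rng.uniform(onset_abs + 0.5, offset_abs - 0.5)
                blen = min(int(rng.geometric(1.0 / 3.0)), 10)
                j0 = int(round((b0 - start_hour) * 60.0))
                sleep_state[max(j0, 0) : min(j0 + blen, WEEK_EPOCHS)] = False

        # diary report: minute noise plus occasional gross errors per edge
        def report(true_abs: float) -> float:
            err = rng.normal(0.0, config.diary_error_sd_min) / 60.0
            if rng.uniform() < config.p_diary_gross_error:
                err += rng.choice([-1.0, 1.0]) * rng.uniform(31.0, 120.0) / 60.0
            return true_abs + err

        rep_bed_abs = report(bed_abs)
        rep_rise_abs = report(rise_abs)
        nights.append(
            {
                "participant_id": pid,
                "night_index": k,
                "night_date": night_date,
                "day_type": day_type,
                "true_bedtime_abs": bed_abs,
                "true_onset_abs": onset_abs,
                "true_offset_abs": offset_abs,
                "true_risetime_abs": rise_abs,
            }
        )
        diary_entries.append(
            DiaryEntry(
                participant_id=pid,
                night_date=night_date,
                reported_bedtime=rep_bed_abs % 24.0,
                reported_risetime=rep_rise_abs % 24.0,
                naps=[],
                awakenings_count=0,
                off_wrist=[],
            )
        )

    counts = np.where(
        sleep_state,
        _counts(rng, params.sleep_activity_mean, params.activity_dispersion, WEEK_EPOCHS),
        _counts(rng, params.wake_activity_mean, params.activity_dispersion, WEEK_EPOCHS),
    )
    series = ActivitySeries(participant_id=pid, start=start, counts=counts)

    # daytime non-wear gaps, mirrored into the diary off-wrist column
    if config.p_nonwear_day > 0:
        for day in range(1, 7):
            if rng.uniform() < config.p_nonwear_day:
                length_min = int(rng.uniform(60, 180))
                start_min = rng.uniform(9.0, 17.0 - length_min / 60.0)
                a = start.normalize() + pd.Timedelta(days=day, minutes=int(start_min * 60))
                b = a + pd.Timedelta(minutes=length_min)
                series = inject_nonwear(series, [(a, b)])
                night = [e for e in diary_entries if e.night_date == (start_date + _dt.timedelta(days=day))]
                if night:
                    night[0].off_wrist.append((a, b))

    demo = {
        "participant_id": pid,
        "group": params.name,
        "age": round(float(np.clip(rng.normal(params.age_mean, params.age_sd), 18.0, 67.0)), 1),
        "sex": "male" if rng.uniform() < params.p_male else "female",
        "profession": str(
            rng.choice(
                ["student", "employee", "not_specified"],
                p=[params.p_student, params.p_employee, max(1.0 - params.p_student - params.p_employee, 0.0)],
            )
        ),
        "children": "yes" if rng.uniform() < params.p_children else "no",
        "MA": round(float(np.clip(rng.normal(params.messi_means[0], params.messi_sd), 1, 5)), 2),
        "EV": round(float(np.clip(rng.normal(params.messi_means[1], params.messi_sd), 1, 5)), 2),
        "DI": round(float(np.clip(rng.normal(params.messi_means[2], params.messi_sd), 1, 5)), 2),
    }
    return series, diary_entries, demo, nights, sleep_state


def generate_cohort(config: CohortConfig) -> CohortData:
    """Simulate the full two-arm cohort; identical config+seed is bit-stable."""
    config.validate()
    start = pd.Timestamp(config.start)
    root = np.random.SeedSequence(config.seed)
    group_seeds = root.spawn(2)

    activity, diaries, demo_rows, night_rows, states = [], {}, [], [], {}
    for params, gseed, prefix in (
        (config.onsite, group_seeds[0], "on"),
        (config.home_office, group_seeds[1], "ho"),
    ):
        child_seeds = gseed.spawn(config.n_per_group)
        for i, cs in enumerate(child_seeds):
            pid = f"{prefix}{i + 1:03d}"
            rng = np.random.default_rng(cs)
            series, entries, demo, nights, state = _simulate_participant(rng, pid, params, config, start)
            activity.append(series)
            diaries[pid] = entries
            demo_rows.append(demo)
            night_rows.extend(nights)
            states[pid] = state
    truth = GroundTruth(nights=pd.DataFrame(night_rows), states=states)
    return CohortData(
        activity=activity,
        diaries=diaries,
        demographics=pd.DataFrame(demo_rows),
        ground_truth=truth,
    )


def inject_nonwear(series: ActivitySeries, intervals) -> ActivitySeries:
    """Zero the counts inside each (start, end) timestamp interval."""
    counts = series.counts.copy()
    end_ts = series.start + pd.Timedelta(minutes=series.n_epochs)
    for a, b in intervals:
        a, b = pd.Timestamp(a), pd.Timestamp(b)
        if a < series.start or b > end_ts or b <= a:
            raise ValueError(f"interval ({a}, {b}) outside recording span ({series.start}, {end_ts})")
        i0 = int((a - series.start).total_seconds() / 60.0)
        i1 = int((b - series.start).total_seconds() / 60.0)
        counts[i0:i1] = 0
    return ActivitySeries(series.participant_id, series.start, counts, series.epoch_seconds)
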