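import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from actisleep import night_metrics, pivot_mean, aggregate_participant, group_variability
from actisleep.metrics import day_type_of, summaries_to_frame, unwrap_times
from actisleep.types import NightRecord, SleepPeriod, SleepWakeSeries


def make_sw(sleep, start="2021-03-01 12:00"):
    sleep = np.asarray(sleep, dtype=bool)
    return SleepWakeSeries("p", sleep, np.where(sleep, 0.0, 2.0), pd.Timestamp(start))


def make_period(bed, onset, offset, rise, night_date=dt.date(2021, 3, 2)):
    return SleepPeriod("p", night_date, bed, onset, offset, rise, "diary_anchored", 0.0, 0.0)


class TestPivotMean:
    def test_symmetric_straddle_of_midnight(self):
        assert pivot_mean([23.0, 1.0], 12.0) == pytest.approx(0.0)

    def test_no_wrap_reduces_to_arithmetic_mean(self):
        assert pivot_mean([7.0, 8.0], 12.0) == pytest.approx(7.5)

    def test_mixed_values_around_midnight(self):
        assert pivot_mean([22.5, 23.5, 0.5], 12.0) == pytest.approx(23.5)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            pivot_mean([], 12.0)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        st.lists(st.floats(0.0, 24.0, exclude_max=True), min_size=1, max_size=12),
        st.floats(-6.0, 6.0),
    )
    def test_circular_shift_invariance(self, times, shift):
        """Shifting every clock time by a constant shifts the mean by the
        same constant (mod 24) as long as the sample stays inside one
        12-h window around the pivot."""
        base = [6.0 + 12.0 * t / 24.0 for t in times]  # squeeze into [6, 18)
        shifted = [(t + shift) % 24.0 for t in base]
        m0 = pivot_mean(base, 12.0)
        m1 = pivot_mean(shifted, (12.0 + shift) % 24.0)
        diff = (m1 - m0 - shift) % 24.0
        assert min(diff, 24.0 - diff) == pytest.approx(0.0, abs=1e-6)


def test_perfect_night_metrics():
    # bed 23:00 -> rise 07:00, fully asleep: series covers noon to noon
    sleep = np.zeros(1440, dtype=bool)
    sleep[int(11 * 60) : int(19 * 60)] = True  # 23:00..07:00 on the noon axis
    sw = make_sw(sleep)
    rec = night_metrics(make_period(23.0, 23.0, 31.0, 31.0), sw)
    assert rec.tib_h == pytest.approx(8.0)
    assert rec.tst_h == pytest.approx(8.0)
    assert rec.efficiency == pytest.approx(1.0)
    assert rec.midpoint == pytest.approx(3.0)


def test_efficiency_table_scale_arithmetic():
    # TST 6.92 h over TIB 7.65 h -> 0.9046
    assert 6.92 / 7.65 == pytest.approx(0.9046, abs=5e-5)
    sleep = np.zeros(1440, dtype=bool)
    i0 = int(11.35 * 60)
    sleep[i0 : i0 + int(round(6.92 * 60))] = True
    sw = make_sw(sleep)
    rec = night_metrics(make_period(23.35, 23.35, 31.0, 31.0), sw)
    assert rec.efficiency == pytest.approx(6.92 / 7.65, abs=2e-3)


def test_tib_across_midnight():
    rec_period = make_period(23.0 + 28 / 60, 23.5, 30.5, 24.0 + 7.0 + 5 / 60)
    sleep = np.ones(1440, dtype=bool)
    rec = night_metrics(rec_period, make_sw(sleep))
    assert rec.tib_h == pytest.approx(7.617, abs=1e-3)


def test_nonpositive_tib_invalid():
    with pytest.raises(ValueError, match="non-positive"):
        night_metrics(make_period(31.0, 31.0, 32.0, 30.0), make_sw(np.ones(1440, dtype=bool)))


def test_day_type_weekend_rule():
    assert day_type_of(dt.date(2021, 3, 6)) == "weekend"  # Saturday
    assert day_type_of(dt.date(2021, 3, 7)) == "weekend"  # Sunday
    assert day_type_of(dt.date(2021, 3, 8)) == "workday"  # Monday
    assert day_type_of(dt.date(2021, 3, 5)) == "workday"  # Friday


def night(night_date, bed, rise, midpoint, tib, tst):
    return NightRecord(
        "p", night_date, day_type_of(night_date),
        bedtime_abs=bed, risetime_abs=rise, midpoint_abs=midpoint,
        tib_h=tib, tst_h=tst, efficiency=tst / tib,
    )


def week_nights(bed_clock=23.5, rise_clock=7.5, weekend_shift=1.0, jitter=None):
    """Five workday + two weekend nights anchored to the first week of
    March 2021 (Monday start)."""
    nights = []
    rng = np.random.default_rng(0)
    for k in range(7):
        date = dt.date(2021, 3, 2) + dt.timedelta(days=k)
        shift = weekend_shift if day_type_of(date) == "weekend" else 0.0
        eps = float(rng.normal(0, jitter)) if jitter else 0.0
        bed = 24.0 * k + (bed_clock - 24.0) + shift + eps
        rise = 24.0 * k + rise_clock + shift + eps
        onset, offset = bed + 0.25, rise
        nights.append(
            night(date, bed, rise, 0.5 * (onset + offset), rise - bed, rise - bed - 0.25)
        )
    return nights


def test_identical_nights_have_zero_sd_and_mean_equal_value():
    nights = week_nights(weekend_shift=0.0)
    s = aggregate_participant(nights)
    assert s.bedtime_sd == pytest.approx(0.0, abs=1e-12)
    assert s.risetime_sd == pytest.approx(0.0, abs=1e-12)
    assert s.bedtime_all == pytest.approx(23.5)
    assert s.risetime_all == pytest.approx(7.5)
    assert s.sjl == pytest.approx(0.0, abs=1e-12)
    assert s.msfsc == pytest.approx(s.midpoint_weekend)


def test_weekend_shift_feeds_sjl_inputs():
    s = aggregate_participant(week_nights(weekend_shift=1.0))
    assert s.n_workday_nights == 5 and s.n_weekend_nights == 2
    assert s.midpoint_weekend - s.midpoint_workdays == pytest.approx(1.0)
    assert s.sjl == pytest.approx(1.0)


def test_aggregation_permutation_invariant():
    nights = week_nights(jitter=0.3)
    s1 = aggregate_participant(nights)
    s2 = aggregate_participant(list(reversed(nights)))
    for attr in ("bedtime_all", "risetime_all", "bedtime_sd", "risetime_sd", "msfsc", "sjl"):
        assert getattr(s1, attr) == pytest.approx(getattr(s2, attr), abs=1e-12)


def test_shifting_bedtimes_shifts_mean_not_sd():
    nights = week_nights(jitter=0.3)
    shifted = [
        NightRecord(
            n.participant_id, n.night_date, n.day_type,
            n.bedtime_abs + 1.0, n.risetime_abs, n.midpoint_abs,
            n.tib_h, n.tst_h, n.efficiency,
        )
        for n in nights
    ]
    s0, s1 = aggregate_participant(nights), aggregate_participant(shifted)
    assert (s1.bedtime_all - s0.bedtime_all) % 24.0 == pytest.approx(1.0, abs=1e-9)
    assert s1.bedtime_sd == pytest.approx(s0.bedtime_sd, abs=1e-9)


def test_no_workday_nights_rejected():
    weekend_only = [n for n in week_nights() if n.day_type == "weekend"]
    with pytest.raises(ValueError, match="workday"):
        aggregate_participant(weekend_only)


def test_group_variability_mean_min_max():
    summaries = [
        aggregate_participant(week_nights(jitter=j), demographics={"group": "onsite"})
        for j in (0.2, 0.8)
    ]
    frame = summaries_to_frame(summaries)
    # exact two-level oracle: group mean of the two participant SDs
    expect = np.mean(frame["bedtime_sd"])
    table = group_variability(frame)
    row = table[(table["metric"] == "bedtime_sd") & (table["group"] == "onsite")].iloc[0]
    assert row["mean"] == pytest.approx(expect)
    assert row["min"] == pytest.approx(frame["bedtime_sd"].min())
    assert row["max"] == pytest.approx(frame["bedtime_sd"].max())


def test_group_variability_simple_numbers():
    frame = pd.DataFrame(
        {"group": ["onsite", "onsite"], "bedtime_sd": [0.2, 2.32], "risetime_sd": [0.2, 2.32]}
    )
    table = group_variability(frame)
    row = table[(table["metric"] == "bedtime_sd")].iloc[0]
    assert row["mean"] == pytest.approx(1.26)
    assert (row["min"], row["max"]) == (pytest.approx(0.2), pytest.approx(2.32))


def test_unwrap_times_window():
    out = unwrap_times([23.0, 1.0, 12.0], 12.0)
    np.testing.assert_allclose(out, [23.0, 25.0, 12.0])
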