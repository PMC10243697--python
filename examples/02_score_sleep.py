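"""Score one synthetic night: epoch classification, period delimitation,
and the derived night-level sleep parameters.
"""

import datetime as dt

import numpy as np
import pandas as pd

from actisleep import ActivitySeries, DiaryEntry, cole_kripke, detect_sleep_period, night_metrics

# one day of 1-min epochs starting at noon; asleep 23:10 -> 07:20
rng = np.random.default_rng(0)
counts = rng.poisson(rng.gamma(2.0, 150.0, size=1440))
asleep = slice(int((23 + 10 / 60 - 12) * 60), int((31 + 20 / 60 - 12) * 60))
counts[asleep] = rng.poisson(rng.gamma(2.0, 1.5, size=counts[asleep].size))
series = ActivitySeries("demo", pd.Timestamp("2021-03-01 12:00"), counts)

sw = cole_kripke(series)
print(f"epochs scored sleep: {sw.sleep.sum()} of {sw.n_epochs}")

# the diary reports 23:00 bed / 7:15 rise -- within 30 min of the activity
# candidates, so the diary edges are kept
diary = DiaryEntry("demo", dt.date(2021, 3, 2), reported_bedtime=23.0, reported_risetime=7.25)
period = detect_sleep_period(sw, diary)
print(f"source: {period.source}")
print(f"bed {period.bedtime:.3f} h, onset {period.onset:.3f} h, "
      f"offset {period.offset:.3f} h, rise {period.risetime:.3f} h")
print(f"diary discrepancies: bed {period.discrepancy_bed_min:+.1f} min, "
      f"rise {period.discrepancy_rise_min:+.1f} min")

rec = night_metrics(period, sw)
print(f"TIB {rec.tib_h:.2f} h, TST {rec.tst_h:.2f} h, efficiency {rec.efficiency:.3f}, "
      f"midpoint {rec.midpoint:.2f} h ({rec.day_type})")
# Efficiency is TST/TIB; the midpoint is the clock time halfway between
# sleep onset and offset.
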