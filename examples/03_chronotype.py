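"""Chronotype measures from weekly sleep timing: corrected midpoint of
sleep (MSFsc) and social jetlag (SJL).

The inputs below are the two study arms' group means: weekend/workday
midpoints of sleep and mean nightly sleep durations.
"""

from actisleep import msfsc, sjl
from actisleep.types import format_clock

groups = {
    "onsite": dict(mid_weekend=3 + 59 / 60, mid_workdays=2 + 57 / 60, sdu_weekend=7.15, sdu_workdays=6.83),
    "home_office": dict(mid_weekend=4 + 25 / 60, mid_workdays=3 + 33 / 60, sdu_weekend=7.23, sdu_workdays=6.82),
}

for name, g in groups.items():
    chronotype = msfsc(g["mid_weekend"], g["sdu_weekend"], g["sdu_workdays"])
    jetlag = sjl(g["mid_weekend"], g["mid_workdays"])
    print(f"{name:12s} MSFsc {format_clock(chronotype)} ({chronotype:.3f} h)   SJL {jetlag:.2f} h")

# MSFsc corrects the weekend midpoint for weekend oversleep relative to the
# weekly average sleep need; SJL is the weekend-minus-workday midpoint shift.
# A later MSFsc means a later chronotype; an SJL near 1 h says the workweek
# pulls sleep about an hour earlier than the body would choose.
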