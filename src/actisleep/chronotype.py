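"""Chronotype measures: corrected midpoint of sleep and social jetlag.

MSFsc corrects the weekend (free-day) midpoint of sleep for the sleep
pressure discharged by weekend oversleep relative to the individual's
weekly average sleep need:

    MSFsc = MPOS_weekend - 0.5 * (SDu_weekend
                                  - (5 * SDu_workdays + 2 * SDu_weekend) / 7)

which simplifies to MPOS_weekend - (5/14) * (SDu_weekend - SDu_workdays).
Social jetlag is the signed difference between the weekend and workday
midpoints of sleep.
"""

from __future__ import annotations

MIDPOINT_PIVOT = 12.0


def unwrap_scalar(t: float, pivot: float) -> float:
    """Shift a clock hour below the pivot forward by one day."""
    return t + 24.0 if t < pivot else t


def msfsc(mpos_weekend: float, sdu_weekend: float, sdu_workdays: float) -> float:
    """Corrected midpoint of sleep on free days, as a clock hour in [0, 24).

    ``mpos_weekend`` is the weekend midpoint of sleep (clock h);
    ``sdu_weekend``/``sdu_workdays`` are the average nightly sleep
    durations (h) on weekend and workdays.  With equal durations the
    correction vanishes and MSFsc equals the weekend midpoint.
    """
    if sdu_weekend <= 0 or sdu_workdays <= 0:
        raise ValueError("sleep durations must be positive")
    avg_need = (5.0 * sdu_workdays + 2.0 * sdu_weekend) / 7.0
    value = mpos_weekend - 0.5 * (sdu_weekend - avg_need)
    return value % 24.0


def sjl(mpos_weekend: float, mpos_workdays: float, pivot: float = MIDPOINT_PIVOT) -> float:
    """Social jetlag in hours: weekend minus workday midpoint of sleep.

    Signed and computed on the unwrapped axis, so a weekend midpoint just
    after midnight against a workday midpoint just before it gives a small
    positive delay, not a ~24-h artefact.
    """
    return unwrap_scalar(mpos_weekend, pivot) - unwrap_scalar(mpos_workdays, pivot)
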