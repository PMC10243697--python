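"""CSV interchange for epoch counts, sleep diaries and demographics.

The epoch dialect is the flat export one gets from ActiLife-style software:
``participant_id,timestamp,counts`` at a fixed 60-s cadence with no gaps.
Diary rows carry one participant-night each; demographics one participant.
"""

from __future__ import annotations

import datetime as _dt
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .types import ActivitySeries, DiaryEntry, format_clock, parse_clock

log = logging.getLogger(__name__)

DEMOGRAPHICS_COLUMNS = [
    "participant_id",
    "group",
    "age",
    "sex",
    "profession",
    "children",
    "MA",
    "EV",
    "DI",
]


class FormatError(ValueError):
    """A file violated the interchange contract (gap, bad value, bad time)."""


def write_epoch_csv(series: ActivitySeries, path) -> None:
    frame = pd.DataFrame(
        {
            "participant_id": series.participant_id,
            "timestamp": series.timestamps().strftime("%Y-%m-%dT%H:%M:%S"),
            "counts": series.counts.astype(int),
        }
    )
    frame.to_csv(path, index=False)


def read_epoch_csv(path) -> ActivitySeries:
    """Read one participant's epoch file, validating the 60-s cadence."""
    frame = pd.read_csv(path)
    required = {"participant_id", "timestamp", "counts"}
    if not required.issubset(frame.columns):
        raise FormatError(f"{path}: missing columns {sorted(required - set(frame.columns))}")
    if frame.empty:
        raise FormatError(f"{path}: empty epoch file")
    pids = frame["participant_id"].unique()
    if len(pids) != 1:
        raise FormatError(f"{path}: expected a single participant, found {list(pids)}")
    try:
        ts = pd.to_datetime(frame["timestamp"])
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: unparseable timestamp ({exc})") from exc
    deltas = ts.diff().dt.total_seconds().iloc[1:]
    bad = deltas[deltas != 60.0]
    if not bad.empty:
        row = int(bad.index[0])
        what = "duplicate timestamp" if bad.iloc[0] <= 0 else "gap"
        raise FormatError(
            f"{path}: {what} at row {row + 2} ({frame['timestamp'].iloc[row]} "
            f"follows {frame['timestamp'].iloc[row - 1]}; expected 60 s steps)"
        )
    counts = pd.to_numeric(frame["counts"], errors="coerce")
    if counts.isna().any():
        row = int(counts.index[counts.isna()][0])
        raise FormatError(f"{path}: non-numeric count at row {row + 2}")
    if (counts < 0).any():
        row = int(counts.index[counts < 0][0])
        raise FormatError(f"{path}: negative count at row {row + 2}")
    return ActivitySeries(
        participant_id=str(pids[0]),
        start=ts.iloc[0],
        counts=counts.to_numpy(dtype=np.int64),
    )


def _format_intervals(intervals) -> str:
    return ";".join(
        f"{pd.Timestamp(a).strftime('%Y-%m-%dT%H:%M')}/{pd.Timestamp(b).strftime('%Y-%m-%dT%H:%M')}"
        for a, b in intervals
    )


def _parse_intervals(text, path) -> list:
    if text is None or (isinstance(text, float) and np.isnan(text)) or str(text).strip() == "":
        return []
    out = []
    for chunk in str(text).split(";"):
        try:
            a, b = chunk.split("/")
            out.append((pd.Timestamp(a), pd.Timestamp(b)))
        except (ValueError, TypeError) as exc:
            raise FormatError(f"{path}: unparseable interval {chunk!r}") from exc
        if out[-1][1] <= out[-1][0]:
            raise FormatError(f"{path}: interval {chunk!r} is not forward in time")
    return out


def write_diary_csv(entries, path) -> None:
    rows = [
        {
            "participant_id": e.participant_id,
            "night_date": e.night_date.isoformat(),
            "bedtime": format_clock(e.reported_bedtime),
            "risetime": format_clock(e.reported_risetime),
            "naps": _format_intervals(e.naps),
            "awakenings": e.awakenings_count,
            "off_wrist": _format_intervals(e.off_wrist),
        }
        for e in entries
    ]
    pd.DataFrame(rows, columns=["participant_id", "night_date", "bedtime", "risetime", "naps", "awakenings", "off_wrist"]).to_csv(
        path, index=False
    )


def read_diary_csv(path) -> list:
    """Read a diary table into DiaryEntry records keyed by participant-night."""
    frame = pd.read_csv(path)
    if frame.empty:
        log.warning("diary file %s is empty", path)
        return []
    required = {"participant_id", "night_date", "bedtime", "risetime"}
    if not required.issubset(frame.columns):
        raise FormatError(f"{path}: missing columns {sorted(required - set(frame.columns))}")
    entries = []
    for i, row in frame.iterrows():
        try:
            bed = parse_clock(row["bedtime"])
            rise = parse_clock(row["risetime"])
        except ValueError as exc:
            raise FormatError(f"{path}: row {i + 2}: {exc}") from exc
        entries.append(
            DiaryEntry(
                participant_id=str(row["participant_id"]),
                night_date=_dt.date.fromisoformat(str(row["night_date"])),
                reported_bedtime=bed,
                reported_risetime=rise,
                naps=_parse_intervals(row.get("naps"), path),
                awakenings_count=int(row["awakenings"]) if "awakenings" in frame.columns and pd.notna(row["awakenings"]) else 0,
                off_wrist=_parse_intervals(row.get("off_wrist"), path),
            )
        )
    return entries


def write_demographics_csv(frame: pd.DataFrame, path) -> None:
    frame.loc[:, DEMOGRAPHICS_COLUMNS].to_csv(path, index=False)


def read_demographics_csv(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = set(DEMOGRAPHICS_COLUMNS) - set(frame.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    frame["participant_id"] = frame["participant_id"].astype(str)
    bad_group = set(frame["group"].unique()) - {"onsite", "home_office"}
    if bad_group:
        raise FormatError(f"{path}: unknown group labels {sorted(bad_group)}")
    return frame
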