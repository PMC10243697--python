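"""End-to-end orchestration: simulate/ingest -> validate -> score ->
summarize -> compare, with table-shaped reports.

The report bundle mirrors the structure of a two-group actigraphy study:
a demographics table, a sleep-pattern comparison with independent t-tests,
an age-adjusted ANCOVA table with estimated marginal means, and a
weekday-versus-weekend paired-comparison table, plus a machine-readable
JSON of every statistical result.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as aio
from .metrics import (
    PIVOT_BEDTIME,
    PIVOT_RISETIME,
    aggregate_participant,
    group_variability,
    night_metrics,
    summaries_to_frame,
    unwrap_times,
)
from .scoring import UnscorableNight, cole_kripke, detect_sleep_period
from .stats import ancova, chi2_independence, normality, ttest_ind, ttest_rel
from .synthetic import CohortConfig, CohortData, generate_cohort
from .types import format_clock
from .wear import (
    apply_diary_offwrist,
    count_valid_days,
    detect_nonwear,
    exclude_age_outliers,
    valid_participant,
    validity_report,
)

log = logging.getLogger(__name__)

GROUPS = ("onsite", "home_office")

# metric -> (label, unit, pivot for clock metrics or None)
TABLE2_METRICS = {
    "tib_all": ("Average total time in bed (all days)", "h", None),
    "tib_workdays": ("Average total time in bed (workdays)", "h", None),
    "tib_weekend": ("Average total time in bed (weekend)", "h", None),
    "tst_all": ("Average total sleep time (all days)", "h", None),
    "tst_workdays": ("Average total sleep time (workdays)", "h", None),
    "tst_weekend": ("Average total sleep time (weekend)", "h", None),
    "efficiency_all": ("Average sleep efficiency (all days)", "fraction", None),
    "efficiency_workdays": ("Average sleep efficiency (workdays)", "fraction", None),
    "efficiency_weekend": ("Average sleep efficiency (weekend)", "fraction", None),
    "bedtime_all": ("Average bedtime (all days)", "clock", PIVOT_BEDTIME),
    "bedtime_workdays": ("Average bedtime (workdays)", "clock", PIVOT_BEDTIME),
    "bedtime_weekend": ("Average bedtime (weekend)", "clock", PIVOT_BEDTIME),
    "midpoint_all": ("Average midpoint of sleep (all days)", "clock", PIVOT_BEDTIME),
    "midpoint_workdays": ("Average midpoint of sleep (workdays)", "clock", PIVOT_BEDTIME),
    "midpoint_weekend": ("Average midpoint of sleep (weekend)", "clock", PIVOT_BEDTIME),
    "msfsc": ("Average corrected midpoint of sleep", "clock", PIVOT_BEDTIME),
    "risetime_all": ("Average rise time (all days)", "clock", PIVOT_RISETIME),
    "risetime_workdays": ("Average rise time (workdays)", "clock", PIVOT_RISETIME),
    "risetime_weekend": ("Average rise time (weekend)", "clock", PIVOT_RISETIME),
    "sjl": ("Social jetlag", "h", None),
}

TABLE4_PAIRS = {
    "tib": ("Average total time in bed", "tib_workdays", "tib_weekend"),
    "tst": ("Average total sleep time", "tst_workdays", "tst_weekend"),
    "efficiency": ("Average sleep efficiency", "efficiency_workdays", "efficiency_weekend"),
    "bedtime": ("Average bedtime", "bedtime_workdays", "bedtime_weekend"),
    "midpoint": ("Average midpoint of sleep", "midpoint_workdays", "midpoint_weekend"),
    "risetime": ("Average rise time", "risetime_workdays", "risetime_weekend"),
}


@dataclass
class RunConfig:
    """One analysis run: either simulate a cohort or read CSV inputs."""

    simulation: Optional[CohortConfig] = None
    epoch_paths: Optional[list] = None
    diary_path: Optional[str] = None
    demographics_path: Optional[str] = None
    outdir: Optional[str] = None
    seed: Optional[int] = None
    min_sleep_run_min: int = 10
    discrepancy_limit_min: float = 30.0
    age_outlier_sd: float = 3.0
    age_outlier_per_group: bool = True

    def __post_init__(self) -> None:
        sim = self.simulation is not None
        files = self.epoch_paths is not None
        if sim == files:
            raise ValueError("exactly one of simulation config or input paths must be set")
        if files and (self.diary_path is None or self.demographics_path is None):
            raise ValueError("file mode needs epoch, diary and demographics paths")


@dataclass
class ReportBundle:
    table1: pd.DataFrame
    table2: pd.DataFrame
    table3: pd.DataFrame
    table4: pd.DataFrame
    summaries: pd.DataFrame
    validity: pd.DataFrame
    stat_results: dict

    def to_json(self) -> str:
        payload = {name: res.as_dict() for name, res in sorted(self.stat_results.items())}
        return json.dumps(payload, indent=2, sort_keys=True)

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.table1.to_csv(out / "table1_demographics.csv", index=False)
        self.table2.to_csv(out / "table2_sleep_patterns.csv", index=False)
        self.table3.to_csv(out / "table3_ancova.csv", index=False)
        self.table4.to_csv(out / "table4_weekday_weekend.csv", index=False)
        self.summaries.to_csv(out / "participant_summaries.csv", index=False)
        self.validity.to_csv(out / "validity_report.csv", index=False)
        (out / "stat_results.json").write_text(self.to_json())


def _load_inputs(config: RunConfig) -> CohortData:
    if config.simulation is not None:
        sim = config.simulation
        if config.seed is not None:
            sim = sim.replace(seed=config.seed)
        log.info("simulating cohort: n=%d/group, seed=%d", sim.n_per_group, sim.seed)
        return generate_cohort(sim)
    activity = [aio.read_epoch_csv(p) for p in config.epoch_paths]
    entries = aio.read_diary_csv(config.diary_path)
    diaries: dict = {}
    for e in entries:
        diaries.setdefault(e.participant_id, []).append(e)
    demographics = aio.read_demographics_csv(config.demographics_path)
    return CohortData(activity=activity, diaries=diaries, demographics=demographics,
                      ground_truth=None)


def score_participants(data: CohortData, config: RunConfig):
    """Wear-validate and score every participant; returns summaries + report."""
    validity_rows = []
    summaries = []
    demo_by_pid = data.demographics.set_index("participant_id").to_dict("index")
    for series in data.activity:
        pid = series.participant_id
        if pid not in demo_by_pid:
            log.warning("%s: no demographics row; skipped", pid)
            continue
        entries = data.diaries.get(pid, [])
        mask = detect_nonwear(series)
        off_wrist = [iv for e in entries for iv in e.off_wrist]
        mask = apply_diary_offwrist(mask, off_wrist)
        n_valid = count_valid_days(mask)
        if not valid_participant(n_valid):
            validity_rows.append((pid, n_valid, False, "fewer than 4 valid days"))
            continue
        sw = cole_kripke(series)
        # non-worn epochs cannot witness sleep: treat them as wake for
        # period delimitation so daytime gaps never masquerade as naps
        sw_masked = dataclasses.replace(sw, sleep=sw.sleep & mask.worn)
        nights = []
        for entry in sorted(entries, key=lambda e: e.night_date):
            try:
                period = detect_sleep_period(
                    sw_masked,
                    entry,
                    min_sleep_run_min=config.min_sleep_run_min,
                    discrepancy_limit_min=config.discrepancy_limit_min,
                )
                nights.append(night_metrics(period, sw_masked))
            except (UnscorableNight, ValueError) as exc:
                log.info("unscorable night: %s", exc)
        try:
            summary = aggregate_participant(nights, demographics=demo_by_pid[pid])
        except ValueError as exc:
            validity_rows.append((pid, n_valid, False, str(exc)))
            continue
        validity_rows.append((pid, n_valid, True, ""))
        summaries.append(summary)
    return summaries, validity_report(validity_rows)


def _mean_sd_se(values: np.ndarray):
    vals = values[np.isfinite(values)]
    n = len(vals)
    if n == 0:
        return np.nan, np.nan, np.nan, 0
    sd = float(np.std(vals, ddof=1)) if n > 1 else 0.0
    return float(np.mean(vals)), sd, sd / np.sqrt(n), n


def build_table1(frame: pd.DataFrame, results: dict) -> pd.DataFrame:
    rows = []
    g1 = frame[frame["group"] == "onsite"]
    g2 = frame[frame["group"] == "home_office"]

    age = ttest_ind(g1["age"], g2["age"])
    results["table1_age_ttest"] = age
    rows.append({"variable": "Age, years", "onsite": f"{g1['age'].mean():.1f} ({g1['age'].std():.1f})",
                 "home_office": f"{g2['age'].mean():.1f} ({g2['age'].std():.1f})",
                 "p": age.p, "sig": "*" if age.significant else ""})

    for var, label in (("sex", "Sex"), ("children", "Children in household"), ("profession", "Profession")):
        table = pd.crosstab(frame["group"], frame[var])
        table = table.loc[[g for g in GROUPS if g in table.index]]
        try:
            res = chi2_independence(table.to_numpy())
            results[f"table1_{var}_chi2"] = res
            p, sig = res.p, "*" if res.significant else ""
        except ValueError:
            p, sig = np.nan, ""
        rows.append({"variable": label,
                     "onsite": "; ".join(f"{c}: {table.loc['onsite', c]}" for c in table.columns),
                     "home_office": "; ".join(f"{c}: {table.loc['home_office', c]}" for c in table.columns),
                     "p": p, "sig": sig})

    for col, label in (("MA", "Morningness (MA)"), ("EV", "Eveningness (EV)"), ("DI", "Distinctness (DI)")):
        res = ttest_ind(g1[col], g2[col])
        results[f"table1_{col}_ttest"] = res
        rows.append({"variable": label, "onsite": f"{g1[col].mean():.2f} ({g1[col].std():.2f})",
                     "home_office": f"{g2[col].mean():.2f} ({g2[col].std():.2f})",
                     "p": res.p, "sig": "*" if res.significant else ""})

    for col, label in (("bedtime_sd", "Sleep time variability - bedtimes"),
                       ("risetime_sd", "Sleep time variability - rise times")):
        res = ttest_ind(g1[col].dropna(), g2[col].dropna())
        results[f"table1_{col}_ttest"] = res
        var_stats = group_variability(frame)
        sub = var_stats[var_stats["metric"] == col].set_index("group")
        rows.append({
            "variable": f"{label}, mean (SD), min/max [h]",
            "onsite": f"{sub.loc['onsite', 'mean']:.2f} ({sub.loc['onsite', 'sd']:.2f}), "
                      f"{sub.loc['onsite', 'min']:.2f}/{sub.loc['onsite', 'max']:.2f}",
            "home_office": f"{sub.loc['home_office', 'mean']:.2f} ({sub.loc['home_office', 'sd']:.2f}), "
                           f"{sub.loc['home_office', 'min']:.2f}/{sub.loc['home_office', 'max']:.2f}",
            "p": res.p, "sig": "*" if res.significant else ""})
    return pd.DataFrame(rows)


def _metric_values(frame: pd.DataFrame, metric: str, pivot) -> pd.Series:
    vals = frame[metric]
    if pivot is not None:
        vals = pd.Series(unwrap_times(vals.to_numpy(dtype=float), pivot), index=vals.index)
    return vals


def build_table2(frame: pd.DataFrame, results: dict) -> pd.DataFrame:
    rows = []
    for metric, (label, unit, pivot) in TABLE2_METRICS.items():
        vals = _metric_values(frame, metric, pivot)
        g1 = vals[frame["group"] == "onsite"].dropna()
        g2 = vals[frame["group"] == "home_office"].dropna()
        res = ttest_ind(g1, g2)
        results[f"table2_{metric}_ttest"] = res
        row = {"characteristic": label, "unit": unit}
        for name, g in (("onsite", g1), ("home_office", g2)):
            mean, sd, se, n = _mean_sd_se(g.to_numpy(dtype=float))
            shown = format_clock(mean) if unit == "clock" else round(mean, 3)
            row.update({f"{name}_mean": shown, f"{name}_mean_h": round(mean % 24 if unit == "clock" else mean, 4),
                        f"{name}_sd": round(sd, 3), f"{name}_se": round(se, 3), f"{name}_n": n})
        row.update({"p": res.p, "sig": "*" if res.significant else ""})
        rows.append(row)
    return pd.DataFrame(rows)


def build_table3(frame: pd.DataFrame, results: dict) -> pd.DataFrame:
    rows = []
    demo_ok = frame.dropna(subset=["age", "sex"])
    for metric, (label, unit, pivot) in TABLE2_METRICS.items():
        work = demo_ok.copy()
        work["_outcome"] = _metric_values(work, metric, pivot)
        work = work.dropna(subset=["_outcome"])
        res = ancova(work, "_outcome")
        results[f"table3_{metric}_ancova"] = res
        row = {"dependent_variable": label, "F": round(res.statistic, 4), "p": res.p,
               "sig": "*" if res.significant else ""}
        for g in GROUPS:
            emm = res.emms[g]
            shown = format_clock(emm["mean"]) if unit == "clock" else round(emm["mean"], 3)
            row.update({f"{g}_emm": shown, f"{g}_emm_h": round(emm["mean"] % 24 if unit == "clock" else emm["mean"], 4),
                        f"{g}_se": round(emm["se"], 3)})
        rows.append(row)
    return pd.DataFrame(rows)


def build_table4(frame: pd.DataFrame, results: dict) -> pd.DataFrame:
    rows = []
    for key, (label, work_col, wkend_col) in TABLE4_PAIRS.items():
        pivot = TABLE2_METRICS[work_col][2]
        for group in GROUPS:
            sub = frame[frame["group"] == group]
            x = _metric_values(sub, work_col, pivot)
            y = _metric_values(sub, wkend_col, pivot)
            res = ttest_rel(x.to_numpy(dtype=float), y.to_numpy(dtype=float))
            results[f"table4_{key}_{group}_paired"] = res
            rows.append({"characteristic": label, "group": group,
                         "mean_diff": round(res.estimate, 4),
                         "sd_diff": round(res.extra["sd_diff"], 4),
                         "p": res.p, "sig": "*" if res.significant else ""})
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute the full analysis and (optionally) write the report bundle."""
    data = _load_inputs(config)
    demographics = exclude_age_outliers(
        data.demographics, n_sd=config.age_outlier_sd, per_group=config.age_outlier_per_group
    )
    kept = set(demographics["participant_id"])
    data = CohortData(
        activity=[s for s in data.activity if s.participant_id in kept],
        diaries={k: v for k, v in data.diaries.items() if k in kept},
        demographics=demographics,
        ground_truth=data.ground_truth,
    )
    summaries, validity = score_participants(data, config)
    frame = summaries_to_frame(summaries)
    if frame.empty:
        raise RuntimeError("no participant passed validity screening")

    results: dict = {}
    table1 = build_table1(frame, results)
    table2 = build_table2(frame, results)
    table3 = build_table3(frame, results)
    table4 = build_table4(frame, results)
    for group in GROUPS:
        vals = frame.loc[frame["group"] == group, "msfsc"].dropna()
        if len(vals) >= 3:
            ks, sw = normality(unwrap_times(vals.to_numpy(dtype=float), PIVOT_BEDTIME))
            results[f"msfsc_normality_ks_{group}"] = ks
            results[f"msfsc_normality_sw_{group}"] = sw
    bundle = ReportBundle(table1, table2, table3, table4, frame, validity, results)
    if config.outdir:
        bundle.write(config.outdir)
    return bundle
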