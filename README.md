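# actisleep

A tested, reusable pipeline for comparing the sleep patterns of two groups
of wrist-actigraphy wearers — here, onsite versus home-office workers —
from one week of 1-min activity counts plus a sleep diary.

The package is aimed at sleep and chronobiology researchers who have
epoch-level ActiGraph-style exports and want the standard analysis chain
without stitching it together by hand:

1. **Ingest** epoch-count, diary and demographics CSVs
   (`actisleep.io`).
2. **Validate wear**: Troiano non-wear detection (≥ 60 min of zero counts
   with a 2-min spike tolerance below 100 counts), the "≥ 10 h worn during
   waking hours" day rule, the "≥ 4 valid days" participant rule, and a
   single-pass ±3 SD age-outlier screen (`actisleep.wear`).
3. **Score sleep**: Cole–Kripke 1-min epoch classification

   D(t) = 0.001 · (106 a₋₄ + 54 a₋₃ + 58 a₋₂ + 76 a₋₁ + 230 a₀ + 74 a₊₁ + 67 a₊₂),
   a = min(counts/100, 300), sleep ⇔ D < 1,

   then nightly sleep-period delimitation reconciling the diary against
   the activity trace with a 30-min discrepancy rule (`actisleep.scoring`).
4. **Summarize**: per-night TIB, TST, efficiency = TST/TIB and the sleep
   midpoint; per-participant means by workday/weekend/all days with
   pivot-based circular averaging of clock times, timing SDs, the
   corrected midpoint of sleep

   MSFsc = MPOS_weekend − 0.5 · (SDu_weekend − (5·SDu_workdays + 2·SDu_weekend)/7)

   and social jetlag SJL = MPOS_weekend − MPOS_workdays
   (`actisleep.metrics`, `actisleep.chronotype`).
5. **Compare groups**: Levene-gated independent t-tests, paired
   weekday-vs-weekend tests, summary-statistics t-tests, Pearson χ²,
   Lilliefors/Shapiro–Wilk normality checks, and per-outcome ANCOVA
   (sex and group sum-coded, age covariate) with estimated marginal means
   (`actisleep.stats`, `actisleep.pipeline`).

Because raw recordings of this kind are rarely shareable, the package
ships a ground-truthed synthetic cohort generator
(`actisleep.synthetic`) that emulates the two-arm study design — group
timing structure, within-person night-to-night variation, diary noise with
occasional gross (> 30 min) errors, and daytime non-wear gaps — so the
entire pipeline is testable end to end.

## Worked example

```python
from actisleep import CohortConfig, RunConfig, run_pipeline

bundle = run_pipeline(RunConfig(simulation=CohortConfig(n_per_group=20, seed=3)))
t2 = bundle.table2.set_index("characteristic")
print(t2.loc["Average bedtime (workdays)", ["onsite_mean", "home_office_mean", "p"]])
```

Running `python examples/05_full_pipeline.py` prints (abridged):

```
sleep-pattern comparison (selected rows):
  Average bedtime (workdays)               onsite  23:16  home-office  23:52  p = 0.086
  Average rise time (workdays)             onsite   7:00  home-office   7:20  p = 0.380
  Average midpoint of sleep (workdays)     onsite   3:11  home-office   3:38  p = 0.198
  Average corrected midpoint of sleep      onsite   4:16  home-office   4:20  p = 0.875
  Social jetlag                            onsite  1.115  home-office  0.901  p = 0.445
```

The home-office arm goes to bed and rises later on workdays (about half an
hour here), while chronotype (MSFsc) and social jetlag barely differ — at
n = 20/group the timing contrast is visible but not yet significant; at
realistic sample sizes it is (see `tests/test_acceptance.py`).

Each `examples/0*.py` script is a short narrative demo of one capability:
cohort simulation, night scoring, chronotype measures, the statistics
layer, and the full pipeline.

## Command line

```sh
actisleep simulate --seed 7 --outdir data/           # synthetic cohort CSVs
actisleep analyze --epochs-dir data/epochs --diary data/diary.csv \
    --demographics data/demographics.csv --outdir reports/
actisleep report --summaries reports/participant_summaries.csv --outdir reports2/
```

`analyze` writes four table-shaped CSV reports (demographics, sleep-pattern
comparison, age-adjusted ANCOVA with EMMs, weekday-vs-weekend paired
contrasts) plus a machine-readable `stat_results.json`.

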