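# Methods

This note documents the models, rules and numerical choices behind
`actisleep`, and what the synthetic-cohort tests do and do not establish
about real recordings.

## Time representation

Clock times are decimal hours in [0, 24). Night-level processing uses an
*unwrapped* axis — hours since midnight of the recording's first day — so
that ordering constraints (bedtime ≤ onset < offset ≤ rise time) and
differences across midnight are plain arithmetic. Averages of clock times
use the pivot method: values below a pivot are shifted forward by 24 h,
the arithmetic mean is taken, and 24 h is subtracted if the mean exceeds
24. Pivots are 12:00 for bedtimes and sleep midpoints and 0:00 (no shift)
for rise times; both are configurable. Timing standard deviations are
computed on the same pivot-unwrapped values, so a bedtime distribution
straddling midnight is not artificially inflated; whether clock-value or
unwrapped SDs are intended by the tabulated "sleep time variability"
convention is ambiguous, and the unwrapped choice is the documented one
here.

## Epoch scoring (Cole–Kripke, 1-min)

Counts are scaled a = min(counts/100, 300) and the 1-min "overall best"
kernel is applied:

D(t) = 0.001 (106 a(t−4) + 54 a(t−3) + 58 a(t−2) + 76 a(t−1) + 230 a(t) + 74 a(t+1) + 67 a(t+2)),

sleep ⇔ D < 1, with zero padding at the series boundaries. Webster
rescoring rules are not applied (off by default, no flag currently
exposed); nap intervals reported in the diary are carried through but not
scored as nighttime sleep.

## Non-wear and validity

An epoch is non-worn iff it lies inside *some* window of at least 60 min
that starts and ends on zero-count epochs, contains no count ≥ 100 and at
most 2 nonzero interior minutes (the published default parameters of the
sustained-zero-run rule). This union-of-windows reading is deliberately
declarative: it makes the rule monotone (raising any count can only shrink
the non-worn set) and is what the brute-force oracle in the tests checks.
Diary-declared off-wrist spells are OR-ed into the non-wear mask — the
diary wins where it says the device was off.

A day is valid when at least 600 worn minutes fall inside the waking
window, taken as 06:00–24:00 local (the 10-h rule names no window; this
choice excludes the nominal sleep period). Partial first/last days are
skipped. A participant is retained with ≥ 4 valid days. Age outliers are
removed in a single pass at ±3 SD using per-group moments by default
(pooled moments available via a flag); a zero-SD group keeps everyone.
Note that a single-pass 3-SD rule can only flag a point when the group is
large enough — in a group of n the largest attainable z-score is
(n−1)/√n — which the tests account for.

## Sleep-period delimitation

Within a window from diary bedtime − 3 h to diary rise time + 3 h, the
activity-based onset candidate is the start of the first run of ≥ 10
consecutive sleep-scored epochs, and the offset candidate is the end of
the last such run; the run length operationalizes "a sharp decrease or
increase in activity" and is configurable. Each diary edge is kept when it
agrees with its candidate to within 30 min, and replaced by the candidate
otherwise; a night is recorded `activity_anchored` when either edge was
replaced, and both signed discrepancies are retained. Bedtime is clamped
to be no later than onset, and rise time no earlier than offset. Non-worn
epochs are treated as wake for delimitation, so a daytime non-wear gap
(zero counts, hence scored "sleep") cannot masquerade as a nap or drag
the offset into the afternoon.

One consequence worth knowing: on nights with long sleep-onset latency
(beyond 30 min) the rule replaces the diary bedtime with the scored onset,
which biases scored bedtimes a few minutes late on average (≈ +5 min under
the default generator settings). Visual scorers show the same hybrid
behaviour; group *contrasts* are essentially unaffected because the bias
is similar in both arms.

## Night and participant summaries

TIB = rise time − bedtime; TST = sleep-scored minutes in [onset, offset);
efficiency = TST/TIB (capped at 1); midpoint = (onset + offset)/2. A night
belongs to the weekend when its rise time falls on Saturday or Sunday, so
the Fri→Sat and Sat→Sun nights are the free nights — the convention that
matches the social-clock logic of social jetlag. Aggregation requires at
least one workday night; weekend aggregates, MSFsc and SJL are defined
only when a weekend night exists.

## Chronotype

MSFsc = MPOS_weekend − 0.5 (SDu_weekend − (5 SDu_workdays + 2 SDu_weekend)/7),
where SDu is the mean nightly sleep duration (TST) per day type. The
formula is applied unconditionally, exactly as printed in the reference
presentation; the original free-day variant applies the correction only
when weekend sleep exceeds workday sleep, and that conditional form is not
enabled here. SJL = MPOS_weekend − MPOS_workdays is signed and computed on
the unwrapped axis, so midpoints on either side of midnight subtract
correctly.

## Statistics

Independent comparisons run Levene's test (center = mean) first and use
the pooled-variance t-test (df = n₁+n₂−2) when its p ≥ 0.05, Welch
otherwise. The summary-statistics t-test uses the pooled SED
= s_p √(1/n₁ + 1/n₂). Paired weekday-vs-weekend contrasts are one-sample
t-tests on within-person differences. The "general linear model
controlling for age" is implemented as per-outcome univariate ANCOVAs
sharing the factor structure — sum-coded work environment and sex plus
age — with a Type-III F for the group effect; a true MANOVA is out of
scope. Estimated marginal means average the model predictions over both
sex levels at the grand-mean age, with standard errors from the model
covariance. Normality uses Shapiro–Wilk plus the estimated-parameter
(Lilliefors) Kolmogorov–Smirnov variant, flagged as such; the Lilliefors
null needs n ≥ 4, below which the KS slot is reported as missing. χ² is
Pearson's without continuity correction. All tests are two-sided with
α = 0.05 flagging; no multiple-testing correction is applied, matching the
analysis design this pipeline reproduces.

Degenerate inputs are given explicit results rather than NaNs: two
constant samples yield t = 0, p = 1 when means agree and |t| = ∞, p = 0
when they differ (the noiseless-cohort limit).

## Synthetic cohort generator

The generator emulates a 7 × 24 h week of 1-min epochs starting Monday
12:00, so each participant contributes five workday nights (rise Tue–Fri,
Mon) and two weekend nights (rise Sat, Sun). Defaults encode the two-arm
study structure: onsite workday bed/rise 23:28/7:05, weekend 0:21/8:17;
home-office workday 0:07/7:44, weekend 0:45/8:47, with between-person SDs
of ≈ 1.0–1.3 h taken from the same tabulated group statistics, ages
30.3 ± 8.7 vs 25.8 ± 5.6 years, and the corresponding sex/profession/
children mixes and MESSi subscale means.

Per participant, a standard-normal phase factor scales the between-person
SDs of the workday times; the weekend phase is correlated 0.7 with it
(perfect correlation would make social jetlag nearly deterministic,
independence would decouple weekday and weekend chronotype; 0.7 yields
SJL spreads of ≈ 0.7–1.0 h, matching the tabulated SDs). Night-to-night
noise has SD 0.75 h per edge, chosen so that participant-level bed/rise
SDs land near the tabulated variability means of ≈ 0.9 h once the
weekday/weekend split is included. Sleep onset lags bedtime by an
exponential latency (mean 15 min); the true offset equals the rise time;
WASO is injected as short wake bursts (geometric lengths, mean 3 min) at
an expected 4 wake min per sleep hour. TIB is floored at 4 h.

Counts are gamma-mixed Poisson (negative binomial): mean 300 awake and 3
asleep, shape 2. The shape controls how often quiet-wakefulness epochs are
misscored as sleep: shape 2 gives ≈ 2% epoch-level misclassification on
wake and makes spurious ≥ 10-min sleep runs (which would trip the 30-min
reconciliation rule) vanishingly rare, while keeping the classifier's
input genuinely noisy. `activity_dispersion=None` produces deterministic
counts for exact zero-noise closed-loop tests. Diary reports add Gaussian
minute noise (SD 10 min) and, with probability 0.05 per edge
independently, a gross error of ±31–120 min — exercising the
reconciliation rule on both edges. Daytime non-wear blocks (60–180 min,
09:00–17:00) are inserted with probability 0.05 per day and mirrored into
the diary's off-wrist column.

What the generator does *not* emulate: circadian light entrainment,
napping, weekday alarm-clock truncation asymmetries, postural artefacts,
or any autocorrelation in wake activity beyond the mixing distribution.
Passing the closed-loop tests therefore shows that the pipeline's rules
are implemented correctly and recover a known structure under plausible
noise — not that the classifier's accuracy figures transfer to field
recordings.

## Problem sizes and determinism

Everything is driven by explicit integer seeds through
`numpy.random.SeedSequence` spawning, so identical config + seed gives
bit-identical cohorts and byte-identical report bundles. The test suite
uses cohorts of 3–16 participants for unit checks, eight replicates of
40/group for the distributional significance-pattern check, and a single
200/group cohort for mean-contrast recovery (tolerance three standard
errors). The acceptance script averages the recovered contrasts over three
200/group replicates to shrink Monte-Carlo error. At the published sample
size (40 vs 35) single-seed significance patterns are intrinsically
unstable — the weekend contrasts sit near the detection boundary — which
is why the pattern is asserted as rates over replicates rather than for
one cohort.

## Known limitations

- Visual/manual sleep scoring cannot be reproduced exactly; the
  deterministic ≥ 10-min-run surrogate is documented above, and results
  are mildly sensitive to that run length on noisy nights.
- The epoch CSV dialect is the package's interchange format; native
  AGD/GT3X binaries are not parsed.
- Whether vector-magnitude or single-axis counts feed the scorer is the
  caller's responsibility; the pipeline treats the count column as given.
- MESSi subscale scores are consumed as demographics covariates; the
  instrument itself is not scored.
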