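"""Group-comparison statistics: t-tests, ANCOVA with EMMs, chi-squared,
normality checks.

Independent-sample comparisons gate on Levene's test (center = mean) at
alpha = 0.05: pooled-variance t when equal variances are tenable, Welch
otherwise.  The "general linear model controlling for age" is a per-outcome
ANCOVA with sum-coded sex and work-environment factors plus age, a Type-III
F for the group effect, and estimated marginal means evaluated with factor
levels balanced and age at its grand mean.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from patsy import build_design_matrices
from statsmodels.stats.diagnostic import lilliefors

from .types import StatResult

log = logging.getLogger(__name__)

LEVENE_ALPHA = 0.05


def ttest_ind(x, y, levene_alpha: float = LEVENE_ALPHA) -> StatResult:
    """Independent-sample t-test with an explicit Levene equal-variance gate.

    Returns the mean difference (x - y) as the estimate and the standard
    error of the difference; pooled df = n1 + n2 - 2 when Levene's p is
    above the gate, Welch-Satterthwaite df otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs n >= 2")
    diff = float(np.mean(x) - np.mean(y))
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        # degenerate noiseless samples: t is 0 (equal means) or unbounded
        t = 0.0 if diff == 0 else float(np.sign(diff)) * np.inf
        return StatResult("ttest_ind", t, float(len(x) + len(y) - 2),
                          1.0 if diff == 0 else 0.0, diff, 0.0,
                          extra={"equal_var": True, "levene_p": np.nan})
    lev_stat, lev_p = sps.levene(x, y, center="mean")
    equal_var = bool(lev_p >= levene_alpha)
    res = sps.ttest_ind(x, y, equal_var=equal_var)
    t = float(res.statistic)
    se = diff / t if t != 0 else _se_ind(x, y, equal_var)
    return StatResult(
        test_name="ttest_ind",
        statistic=t,
        df=float(res.df),
        p=float(res.pvalue),
        estimate=diff,
        se=abs(se),
        extra={"equal_var": equal_var, "levene_stat": float(lev_stat), "levene_p": float(lev_p)},
    )


def _se_ind(x, y, equal_var: bool) -> float:
    n1, n2 = len(x), len(y)
    v1, v2 = np.var(x, ddof=1), np.var(y, ddof=1)
    if equal_var:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        return float(np.sqrt(sp2 * (1 / n1 + 1 / n2)))
    return float(np.sqrt(v1 / n1 + v2 / n2))


def ttest_from_summary(m1: float, sd1: float, n1: int, m2: float, sd2: float, n2: int) -> StatResult:
    """Pooled t-test from summary statistics (mean, SD, n) of two samples.

    t = (m2 - m1) / SED with the pooled standard error of the difference
    SED = s_p * sqrt(1/n1 + 1/n2) and df = n1 + n2 - 2.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each sample needs n >= 2")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    sed = float(np.sqrt(sp2) * np.sqrt(1.0 / n1 + 1.0 / n2))
    t = (m2 - m1) / sed
    p = float(2.0 * sps.t.sf(abs(t), df))
    return StatResult("ttest_from_summary", float(t), float(df), p, estimate=float(m2 - m1), se=sed)


def ttest_rel(x, y) -> StatResult:
    """Paired t-test on within-person differences x - y.

    Pairs with a missing member are dropped (and logged).  The estimate is
    the mean difference; its SD is carried in ``extra`` for tabulation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("paired samples must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < len(x):
        log.info("ttest_rel: dropped %d incomplete pair(s)", int(len(x) - ok.sum()))
    d = x[ok] - y[ok]
    n = len(d)
    if n < 2:
        raise ValueError("need at least 2 complete pairs")
    sd_d = float(np.std(d, ddof=1))
    mean_d = float(np.mean(d))
    if sd_d == 0:
        t, p = (0.0, 1.0) if mean_d == 0 else (np.inf * np.sign(mean_d), 0.0)
    else:
        res = sps.ttest_rel(x[ok], y[ok])
        t, p = float(res.statistic), float(res.pvalue)
    return StatResult(
        test_name="ttest_rel",
        statistic=t,
        df=float(n - 1),
        p=p,
        estimate=mean_d,
        se=sd_d / np.sqrt(n) if n else np.nan,
        extra={"sd_diff": sd_d, "n_pairs": n},
    )


def ancova(frame: pd.DataFrame, outcome: str, group_col: str = "group",
           sex_col: str = "sex", age_col: str = "age") -> StatResult:
    """Per-outcome ANCOVA: outcome ~ group + sex (sum-coded) + age.

    Reports the Type-III F and p for the group effect and estimated
    marginal means per group (factor levels balanced, age at its grand
    mean) with model-based standard errors.
    """
    data = frame[[outcome, group_col, sex_col, age_col]].dropna()
    for col in (group_col, sex_col):
        if data[col].nunique() < 2:
            raise ValueError(f"factor {col!r} needs >= 2 levels")
    formula = f"Q('{outcome}') ~ C(Q('{group_col}'), Sum) + C(Q('{sex_col}'), Sum) + Q('{age_col}')"
    model = smf.ols(formula, data=data)
    if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
        raise ValueError(f"rank-deficient design for {outcome!r}: aliased term among "
                         f"{list(model.exog_names)}")
    fit = model.fit()
    table = sm.stats.anova_lm(fit, typ=3)
    group_row = [ix for ix in table.index if group_col in ix][0]
    f_stat = float(table.loc[group_row, "F"])
    p = float(table.loc[group_row, "PR(>F)"])
    df_num = float(table.loc[group_row, "df"])
    df_den = float(table.loc["Residual", "df"])

    design_info = model.data.design_info
    age_bar = float(data[age_col].mean())
    sex_levels = sorted(data[sex_col].unique())
    emms = {}
    cov = fit.cov_params().to_numpy()
    for g in sorted(data[group_col].unique()):
        grid = pd.DataFrame(
            {group_col: g, sex_col: sex_levels, age_col: age_bar}
        )
        (mat,) = build_design_matrices([design_info], grid)
        l_vec = np.asarray(mat).mean(axis=0)
        emm = float(l_vec @ fit.params.to_numpy())
        se = float(np.sqrt(l_vec @ cov @ l_vec))
        emms[str(g)] = {"mean": emm, "se": se}
    return StatResult(
        test_name="ancova",
        statistic=f_stat,
        df=df_den,
        p=p,
        emms=emms,
        extra={"df_num": df_num, "outcome": outcome, "age_grand_mean": age_bar},
    )


def chi2_independence(table) -> StatResult:
    """Pearson chi-squared test of independence on an r x k count table."""
    table = np.asarray(table, dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero marginal")
    res = sps.chi2_contingency(table, correction=False)
    if (res.expected_freq <= 0).any():
        raise ValueError("expected counts must all be positive")
    return StatResult(
        test_name="chi2_independence",
        statistic=float(res.statistic),
        df=float(res.dof),
        p=float(res.pvalue),
    )


def normality(sample) -> tuple[StatResult, StatResult]:
    """Kolmogorov-Smirnov (Lilliefors variant) and Shapiro-Wilk tests.

    The KS test uses the estimated-parameter (Lilliefors) null, flagged in
    the result; a constant sample is reported as degenerate with p = NaN.
    """
    arr = np.asarray(sample, dtype=float)
    arr = arr[np.isfinite(arr)]
    if len(arr) < 3:
        raise ValueError("normality tests need n >= 3")
    if np.ptp(arr) == 0:
        degenerate = {"degenerate": True}
        ks = StatResult("ks_lilliefors", np.nan, float(len(arr)), np.nan, extra=degenerate)
        sw = StatResult("shapiro_wilk", np.nan, float(len(arr)), np.nan, extra=degenerate)
        return ks, sw
    if len(arr) < 4:  # the estimated-parameter KS null needs n >= 4
        sw_stat, sw_p = sps.shapiro(arr)
        ks = StatResult("ks_lilliefors", np.nan, float(len(arr)), np.nan,
                        extra={"estimated_params": True, "too_few_observations": True})
        sw = StatResult("shapiro_wilk", float(sw_stat), float(len(arr)), float(sw_p))
        return ks, sw
    ks_stat, ks_p = lilliefors(arr, dist="norm")
    sw_stat, sw_p = sps.shapiro(arr)
    ks = StatResult("ks_lilliefors", float(ks_stat), float(len(arr)), float(ks_p),
                    extra={"estimated_params": True})
    sw = StatResult("shapiro_wilk", float(sw_stat), float(len(arr)), float(sw_p))
    return ks, sw
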