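"""The statistical layer on its own: independent and summary t-tests,
chi-squared, and ANCOVA with estimated marginal means.
"""

import numpy as np
import pandas as pd

from actisleep import ancova, chi2_independence, ttest_from_summary, ttest_ind

rng = np.random.default_rng(7)

# --- summary-statistics t-test: group mean vs a published reference ------
res = ttest_from_summary(1.03, 1.02, 40, 1.33, 0.88, 599)
print(f"summary t-test: t = {res.statistic:.2f}, df = {res.df:.0f}, "
      f"SED = {res.se:.3f}, p = {res.p:.3f}")

# --- independent t-test with the Levene equal-variance gate --------------
x = rng.normal(30.3, 8.7, 40)
y = rng.normal(25.8, 5.6, 35)
res = ttest_ind(x, y)
print(f"age t-test: t = {res.statistic:.2f}, df = {res.df:.1f}, p = {res.p:.4f} "
      f"(pooled = {res.extra['equal_var']})")

# --- chi-squared on a 2x2 sex-by-group table -----------------------------
res = chi2_independence([[15, 25], [9, 26]])
print(f"sex chi2: statistic = {res.statistic:.2f}, df = {res.df:.0f}, p = {res.p:.3f}")

# --- ANCOVA: group effect adjusted for age, sex sum-coded ----------------
n = 60
group = np.repeat(["onsite", "home_office"], n // 2)
age = np.where(group == "onsite", 31.0, 26.0) + rng.normal(0, 5, n)
outcome = 7.0 + 0.05 * age + np.where(group == "home_office", 0.4, 0.0) + rng.normal(0, 0.4, n)
frame = pd.DataFrame({"outcome": outcome, "group": group, "age": age,
                      "sex": rng.choice(["male", "female"], n)})
res = ancova(frame, "outcome")
print(f"ANCOVA group effect: F = {res.statistic:.2f}, p = {res.p:.4f}")
for g, emm in res.emms.items():
    print(f"  EMM {g:12s} {emm['mean']:.2f} +/- {emm['se']:.2f}")
# The EMMs are evaluated at the grand-mean age with sex balanced, so the
# age confound between the groups is removed from the comparison.
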