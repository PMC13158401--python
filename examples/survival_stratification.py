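"""Exploratory survival analysis: iCCA patients stratified at the median
CD9+CD133/2+ small-EV level."""

import numpy as np

from lrmscore import generate_cohort, paper_like_config
from lrmscore.survival import (
    cox_hr_binary, km_estimate, median_ratio_bootstrap, stratify_by_median,
    weighted_logrank,
)

cohort = generate_cohort(paper_like_config(seed=42))
icca = cohort.subset(np.flatnonzero(cohort.label == 1))
group = stratify_by_median(icca, "cd9_cd133_2_per_ml")
t, e = icca.os_days, icca.event

for g, name in ((1, "above median"), (0, "at or below")):
    fit = km_estimate(t[group == g], e[group == g])
    med = "undefined" if fit.median_os is None else f"{fit.median_os:.0f} d"
    print(f"  {name} (n={int((group == g).sum())}): median OS {med}")

lr = weighted_logrank(t, e, group, "logrank")
gb = weighted_logrank(t, e, group, "gehan")
cox = cox_hr_binary(t, e, group)
mr = median_ratio_bootstrap(t, e, group, seed=4)
print(f"log-rank chi2 {lr.chi2:.3f} (p {lr.p:.4f}); "
      f"Gehan-Breslow chi2 {gb.chi2:.3f} (p {gb.p:.4f})")
print(f"Cox HR {cox.hr:.2f} (95% CI {cox.ci_low:.2f}-{cox.ci_high:.2f})")
if mr.ci_low is not None:
    print(f"median-OS ratio {mr.ratio:.2f} (bootstrap 95% CI {mr.ci_low:.2f}-{mr.ci_high:.2f})")
print("\nAn HR near the generator's planted 2.8 means patients above the"
      "\nCD9+CD133/2+ median die at close to 2.8 times the instantaneous rate.")
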