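"""Normality-gated group comparisons with a full decision audit.

Compares the recovery index of DCD vs glutamate-resistant cells from a
synthetic cohort. The ladder first tests each group for normality
(D'Agostino–Pearson), then picks Mann-Whitney / Kruskal-Wallis+Dunn /
ANOVA+Šidák accordingly, and reports every decision it made.
"""

import numpy as np

import excitoq as xq
from excitoq.dcd import results_frame

params = xq.preset("cortical", n_cells=150, seed=12)
cohort = xq.gen_calcium_cohort(params)
df = results_frame(xq.analyze_cohort(cohort.traces, cohort.events))
groups = {
    "dcd": df.loc[df["has_dcd"], "recovery_index_pct"].dropna().to_numpy(),
    "resistant": df.loc[~df["has_dcd"], "recovery_index_pct"].dropna().to_numpy(),
}

comp = xq.test_group_difference(groups, "independent_2")
print(f"test chosen:  {comp.chosen_test}")
print(f"statistic:    {comp.statistic:.3f}, p = {comp.p_value:.3g} "
      f"({'significant' if comp.significant else 'not significant'} at alpha={comp.alpha})")
print("audit trail:")
for line in comp.audit:
    print(f"  - {line}")

for label, values in groups.items():
    s = xq.summarize(values, "nonparametric")
    print(f"{label:10s} median {s['median']:.1f}% (IQR {s['q1']:.1f}-{s['q3']:.1f}), n={s['n']}")
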