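"""LPS effect: slowed post-washout recovery, sister-control normalization.

Simulates a control cohort and an LPS-treated cohort (recovery rate scaled
by 0.7), computes the per-cell recovery index in both, and expresses the
treated values in units of the control median — the sister-culture
normalization that makes cohorts from different platings comparable.
"""

import numpy as np

import excitoq as xq
from excitoq.dcd import results_frame

recovery = {}
for label, factor in (("control", 1.0), ("LPS", 0.7)):
    params = xq.preset("cortical", n_cells=120, seed=8, lps_recovery_factor=factor)
    cohort = xq.gen_calcium_cohort(params)
    df = results_frame(xq.analyze_cohort(cohort.traces, cohort.events))
    recovery[label] = df["recovery_index_pct"].dropna().to_numpy()
    print(f"{label:8s} median recovery: {np.median(recovery[label]):.1f}%")

normalized = xq.normalize_to_sister_control(recovery["LPS"], recovery["control"])
print(f"LPS recovery / control median: {np.median(normalized):.2f}")
# < 1 means the LPS cohort recovers less of its Ca2+ elevation than the
# paired sister control within the same washout horizon.
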