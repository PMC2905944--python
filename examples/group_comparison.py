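"""Group study: compare the five hybrid seed methods across subjects.

Simulates a subject group with amplitude variability and spatial jitter,
runs temporal-concatenation group ICA, picks the component of interest by
matching the group-mean task z map, then scores each method's per-subject
FC maps against the subjects' own task-GLM maps by Fisher-z correlation,
threshold-adjusted overlap, and adjusted ROC PAUC.
"""

import pandas as pd

from icaseed import experiment_group

pd.set_option("display.width", 140)

res = experiment_group(n_subjects=6, n_components=6, rng_seed=0)
print(
    f"group IC of interest: component {res.interest_index + 1} "
    f"(|r| with group task map = {res.interest_match_r:.3f})"
)
cols = ["method", "r_task_mean", "r_seed_mean", "overlap_pct_mean", "pauc_adjusted_mean"]
print(res.summary[cols].round(3).to_string(index=False))
print()
print("Higher r_task than r_seed means a method's maps reflect each")
print("subject's own data rather than echoing the group seed map; DRS and")
print("MV typically lead, while DRA's extra nuisance regressors absorb")
print("shared variance and depress its maps.")
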