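"""Choosing the static SUVR acquisition window against dynamic DVR.

Runs the full cohort analysis and reports how well each candidate late
window (50-70, 60-80, 70-90 min) reproduces the Logan DVR, within
subject and pooled.
"""

from synpet import AnalysisConfig, run_full_analysis
from synpet.simulate import CohortConfig

cfg = AnalysisConfig(cohort=CohortConfig(seed=42, n_young=3, n_old=4, n_patient=3))
res = run_full_analysis(cfg)
print(res.window_selection.table.to_string(index=False))
print(f"repeated-measures ANOVA on within-subject R^2: "
      f"F={res.window_selection.anova['F']:.2f}, p={res.window_selection.anova['p']:.4g}")
print(f"selected window: {res.window_selection.winner}")
print("-> the winner maximizes the mean within-subject shared variance with "
      "DVR; its pooled slope near 1 means SUVR is numerically close to DVR")
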