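"""Reference-region sensitivity analysis on a simulated cohort.

Ranks three candidate reference regions (cerebellar gray matter, whole
cerebellum, eroded white matter) by model fit and cohort stability.
"""

from synpet import AnalysisConfig, run_reference_optimization
from synpet.simulate import CohortConfig, simulate_cohort

cohort = simulate_cohort(CohortConfig(seed=42, n_young=3, n_old=4, n_patient=3))
res = run_reference_optimization(cohort)
cols = ["region", "mean_sse", "sse_cov", "k2p_cov", "suv_cov", "aggregate_rank"]
print(res.ranking[cols].to_string(index=False))
print(f"selected reference region: {res.winner}")
print("-> cereb_gm generated the cortical kinetics, so it fits best (lowest "
      "mean SSE) and takes the best aggregate rank across the four criteria")
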