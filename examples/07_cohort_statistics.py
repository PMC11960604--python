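"""Cohort association statistics on the simulated three-group study.

Group contrasts in summary ROIs, the within-subject tau-vs-SV2A spatial
correlation, the amyloid-burden association, and the volume-by-uptake
interaction model for cognition.
"""

from synpet import AnalysisConfig, run_full_analysis
from synpet.simulate import CohortConfig

cfg = AnalysisConfig(cohort=CohortConfig(seed=42))
res = run_full_analysis(cfg)

gc = res.group_contrasts
sel = gc[(gc["measure"] == "dvr") & (gc["roi"] == "temporal") & (~gc["pvc"])].iloc[0]
print(f"temporal-lobe DVR group means: Y={sel['mean_Y']:.2f} "
      f"O={sel['mean_O']:.2f} patient={sel['mean_patient']:.2f} "
      f"(F={sel['F']:.1f}, p={sel['p']:.2g})")

sp = res.spatial_correlation
print(f"tau vs SV2A spatial correlation: mean r={sp['per_subject_r'].mean():.3f}, "
      f"one-sample t={sp['t']:.2f}, p={sp['p']:.3g}")
print(f"  patients mean r={sp['group_contrast']['mean_r']['patient']:.3f} vs "
      f"controls {sp['group_contrast']['mean_r']['O']:.3f}")

print(f"centiloid vs global uptake: r={res.centiloid['r']:.3f}, "
      f"p={res.centiloid['p']:.3g}")

coef = res.mmse_model["coefficients"].set_index("term")
print(f"MMSE model adj R^2={res.mmse_model['adj_r2']:.2f}; "
      f"volume x uptake t={coef.loc['volume_x_uptake', 't']:.2f}")
print("-> synaptic binding is graded Y > O > patient, mirrors tau spatially in "
      "patients, tracks amyloid negatively, and buffers the cognitive cost of "
      "low temporal volume (negative interaction)")
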