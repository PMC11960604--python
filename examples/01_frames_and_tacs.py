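"""Frame schedules, time-activity curves and window averages.

Parses the standard 35-frame / 90-min dynamic acquisition, simulates a
reference-tissue curve, and averages the late 70-90-min frames (the SUV
window used for reference-region stability checks).
"""

from synpet import parse_frame_schedule, window_average
from synpet.simulate import InputFunctionParams, simulate_tissue_tac

schedule = parse_frame_schedule("4x15,8x30,9x60,2x180,10x300,2x600")
print(f"{len(schedule)} frames, {schedule.total_minutes:g} min total")
print(f"first mid-time {schedule.mid_times()[0]:g} min, "
      f"last {schedule.mid_times()[-1]:g} min")

plasma = InputFunctionParams(scale=0.072)
ref = simulate_tissue_tac(k1=0.3, k2=0.055, plasma=plasma, schedule=schedule)
suv = window_average(ref, (70, 90))
print(f"reference late-window (70-90 min) uptake: {suv:.2f}")
print("-> the per-subject SUV whose cohort coefficient of variation "
      "feeds reference-region ranking")
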