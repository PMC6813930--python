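"""Run the fully coupled untreated severe infection for 48 hours and report
when each clinical sepsis marker is crossed."""

import numpy as np

from sepsim import InfectionAction, SepsisEngine

engine = SepsisEngine()
engine.infect(InfectionAction(severity="Severe", mic_mg_L=16.0))
engine.run_until(48.0, record_every=0.05)
df = engine.frame()
t = df.time_h.values


def crossing(values, threshold, direction="down"):
    idx = np.flatnonzero(values < threshold if direction == "down"
                         else values > threshold)
    return t[idx[0]] if len(idx) else float("nan")


print(f"SBP < 100 mmHg (sepsis screen)  at {crossing(df.SBP_mmHg.values, 100):5.1f} h")
print(f"lactate > 2 mM (hyperlactatemia) at {crossing(df.lactate_mM.values, 2, 'up'):5.1f} h")
print(f"UO < 0.625 mL/min (hypovolemia)  at {crossing(df.UO_mL_min.values, 0.625):5.1f} h")
print(f"MAP < 65 mmHg (septic shock)     at {crossing(df.MAP_mmHg.values, 65):5.1f} h")
print(f"minimum SVR: {100 * df.SVR_frac_baseline.min():.0f}% of baseline")
print("\nThe cascade runs: NO-driven vasodilation and capillary leak -> "
      "systolic pressure falls;\nanaerobic metabolism raises lactate; "
      "sustained inflammation fatigues the baroreflex\nuntil mean pressure "
      "collapses into shock near hour 45.")
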