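"""Simulate the two resuscitation strategies for fluid-refractory septic
shock: a fluid-liberal control arm and a restricted-fluid arm with early
norepinephrine, both started 46 hours after a severe infection."""

import numpy as np

from sepsim import (InfectionAction, SepsisEngine, load_snapshot,
                    refresh_pretrial, run_refresh_arm, save_snapshot)

patient = SepsisEngine()
patient.infect(InfectionAction(severity="Severe", mic_mg_L=16.0))
refresh_pretrial(patient)         # 2 x 500 mL challenge at 44/44.5 h
print(f"after fluid challenge (46 h): SBP {patient.physio.hemo.SBP:.0f} mmHg, "
      f"MAP {patient.physio.hemo.MAP:.0f} mmHg, "
      f"UO {patient.physio.renal.UO_mL_min:.2f} mL/min "
      f"-> qualifies: {patient.qualifies}")
import os
import tempfile

snap = os.path.join(tempfile.mkdtemp(), "septic_patient.json")
save_snapshot(patient, snap)

for arm in ("control", "experimental"):
    eng = load_snapshot(snap)
    eng.pretrial_fluid_L = 1.0
    run_refresh_arm(eng, arm)
    df = eng.frame()
    d = df[df.time_h >= 46.0]
    reach = d[d.SBP_mmHg > 90.0].time_h.min() - 46.0
    boluses = sum(1 for e in eng.audit_log if e["event"] == "protocol_check"
                  for a in e["actions"] if a["type"] == "bolus")
    print(f"{arm:12s}: cumulative fluid {eng.protocol.cumulative_fluid_L:.2f} L, "
          f"{boluses} rescue boluses, SBP > 90 mmHg reached at +{reach:.2f} h, "
          f"blood pathogen fell {d.P_B.iloc[0]:.0f} -> {d.P_B.iloc[-1]:.0f}")

print("\nThe fluid-liberal arm gives more volume in large swings; the "
      "restricted arm leans on the\nvasopressor and smaller boluses, "
      "reaching the same pressure goal with about a litre less fluid.")
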