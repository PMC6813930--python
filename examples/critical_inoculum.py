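"""Locate the critical initial tissue load separating recovery from sepsis
at the nominal pathogen growth rate, by bisection on the initial condition."""

import warnings

warnings.filterwarnings("ignore", message="Trajectory spans only")

from sepsim import AIRParams, find_critical_load

params = AIRParams()
pt0_star = find_critical_load(0.6, params, bracket=(1e6, 1e7), rel_tol=0.01)
print(f"critical initial tissue load at S_P = 0.6: {pt0_star:.3g} counts")
print("Loads below this value are cleared from the blood; loads above it "
      "escape to the septic branch\n(the system is bistable in the initial "
      "condition).")
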