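# sepsim

A whole-body simulator of bacterial sepsis progression and treatment. It is
aimed at modelers and medical educators who want a desk-scale virtual
patient: one that develops sepsis from a tissue inoculum on a realistic
clinical timeline, and that responds — or fails to respond — to fluids,
vasopressors and antibiotics depending on strategy and timing.

The model has three coupled layers:

1. **Acute inflammatory response (AIR).** An 18-state ODE network: tissue
   pathogen `P_T`, local immune cells and an epithelial barrier gated by a
   hysteretic toll-like-receptor switch (on above `P⁺ = 2×10⁶`, off below
   `P⁻ = 10³`); blood pathogen `P_B` with resting/active macrophage and
   neutrophil pools; an iNOS/eNOS nitric-oxide cascade with
   `NO = iNOS·(1 + k_NOMA(M_A + N_A)) + eNOS`; the cytokines TNF, IL-6,
   IL-10, IL-12; and a tissue-integrity variable `TI ∈ [0, 1]`.
   Interactions use Hill functions `HU1 = x^h/(1+(x/n)^h)`,
   `HU2 = x^h/(x^h+n^h)`, `HD = 1/(1+(x/n)^h)`. The system is bistable: at
   growth rate `S_P = 0.6 h⁻¹` there is a critical inoculum
   `P_T0* ≈ 6.95×10⁶` separating recovery from persistent bacteremia.
2. **Reduced physiology.** Three vascular–interstitial compartment pairs
   exchanging fluid by the Starling relation `J = (ΔP_h − σΔCOP)/R1` (COP
   from the Landis–Pappenheimer cubic) and albumin by the Patlak
   convection–diffusion law, with check-valved lymphatic return tuned to
   4.0 L/day at baseline; a baroreflex-controlled circulation with
   NO-mediated vasodilation and inflammation-fatigued sympathetic gain;
   renal output, an energy-deficit/lactate loop, fever, tachypnea and
   leukocytosis.
3. **Treatment.** Two-compartment drug kinetics (exact matrix-exponential
   steps), the MIC-anchored antibiotic law
   `S_net = S_max − (S_max−S_min)(C_u/MIC)^γ / ((C_u/MIC)^γ − S_min/S_max)`
   (exactly zero at the MIC), a norepinephrine SVR block, crystalloid and
   colloid fluids, and scripted resuscitation protocols for
   fluid-refractory septic shock (a fluid-liberal control arm vs a
   restricted-fluid/early-vasopressor arm) with full decision audit logs
   and lossless patient-state snapshots.

The model equations, calibrated constants and limitations are documented in
[docs/methods.md](docs/methods.md).

## Worked example

Run the untreated severe infection and read off the clinical milestones:

```python
from sepsim import InfectionAction, SepsisEngine

engine = SepsisEngine()
engine.infect(InfectionAction(severity="Severe", mic_mg_L=16.0))
engine.run_until(48.0)
df = engine.frame()          # time series of vitals and AIR outputs
```

`examples/septic_shock_timeline.py` does exactly this and prints:

```
SBP < 100 mmHg (sepsis screen)  at  27.2 h
lactate > 2 mM (hyperlactatemia) at  21.2 h
UO < 0.625 mL/min (hypovolemia)  at  31.2 h
MAP < 65 mmHg (septic shock)     at  46.4 h
minimum SVR: 57% of baseline
```

The patient screens positive for sepsis when systolic pressure drops
through 100 mmHg around hour 27, is hyperlactatemic from hour 21, oliguric
from hour 31, and enters septic shock (MAP < 65 mmHg despite reflex
compensation, systemic resistance down to 57% of baseline) around hour 46.

`examples/refresh_trial.py` continues from this patient: a 1 L fluid
challenge at 44 h fails to restore pressure (fluid-refractory shock), after
which the two trial arms give

```
control     : cumulative fluid 3.84 L, 3 rescue boluses, SBP > 90 mmHg reached at +1.00 h
experimental: cumulative fluid 2.95 L, 6 rescue boluses, SBP > 90 mmHg reached at +0.25 h
```

— the restricted-fluid arm reaches the same pressure goal with roughly a
litre less fluid by leaning on early norepinephrine and smaller boluses.

The other examples locate the critical inoculum by bisection
(`critical_inoculum.py`, prints 6.96×10⁶), compare the three infection
severities (`infection_severities.py`), and trace piperacillin exposure
(`antibiotic_exposure.py`: AUC 278 mg·h/L, ~3 h of near-maximal effect
against a 16 mg/L pathogen).

A thin command-line interface wraps the engine for shell use:

```bash
sepsim run scenario.yaml --out results/      # YAML-scripted scenario
sepsim find-threshold --sp 0.6               # critical-inoculum bisection
sepsim resume snapshot.json --until 52       # continue a saved patient
```

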