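# Model and methods

`sepsim` simulates the whole-body course of bacterial sepsis in three
coupled layers: an 18-state acute inflammatory response (AIR) ODE network, a
reduced lumped-parameter physiology, and a drug/fluid treatment layer. This
note records the model equations as implemented, the calibrated constants
and why they take the values they do, the numerical choices, and the known
limitations.

## 1. The inflammation network

### States and structure

The AIR network couples a local infection compartment to the systemic
circulation. Locally it tracks the tissue pathogen count `P_T` (CFU/mL-like
units), recruited macrophages `M_T` and neutrophils `N_T`, and an epithelial
barrier integrity `B ∈ [0, 1]`. Systemically it tracks the blood pathogen
`P_B`, resting/active macrophage and neutrophil pools (`M_R/M_A`,
`N_R/N_A`), an inducible NO synthase cascade (`iNOSd → iNOS`), constitutive
`eNOS`, nitrate `NO3`, the cytokines TNF, IL-6, IL-10 and IL-12, and a
global tissue-integrity variable `TI ∈ [TI_min, 1]` (1 = healthy). Nitric
oxide is algebraic: `NO = iNOS·(1 + k_NOMA·(M_A + N_A)) + eNOS`.

All interactions use three Hill-type response functions: a saturating
up-regulation `HU1(x,n,h) = x^h/(1+(x/n)^h)`, a bounded sigmoid
`HU2(x,n,h) = x^h/(x^h+n^h)` and its complement `HD(x,n,h) = 1/(1+(x/n)^h)`
(so `HU2 + HD = 1` identically). Time is in hours; mediators are in
arbitrary concentration units.

A binary toll-like-receptor switch `R` gates the local response with
hysteresis: it turns on when `P_T` rises above `P⁺ = 2×10⁶`, off when `P_T`
falls below `P⁻ = 10³`, and otherwise holds its previous value. While on,
it drives neutrophil recruitment and degrades the barrier; a weakened
barrier in turn admits more immune traffic but also more pathogen into the
blood.

### Transcription choices

The published equation set mixes two unit systems (a CFU-scale invasion
submodel and a unit-scale systemic immune submodel) and several printed
terms are typographically ambiguous. The following structural choices were
made once and are fixed:

- **Logistic pathogen growth.** Tissue growth is
  `S_P·P_T·(1 − P_T/κ_PT)` with carrying capacity `κ_PT = 10¹⁰`
  (effectively unbounded on infection scales; it exists to keep the state
  finite). Blood growth is logistic with its own capacity
  `κ_PB = 2×10⁴`, which sets the septic-branch plateau (the "final
  non-zero blood count" of the bistable system, ~10⁴).
- **Barrier gating.** The tissue→blood flux is `θ_P·P_T/(1+k_PTB·B)`:
  an intact barrier suppresses translocation ~4-fold. Immune recruitment is
  enhanced by barrier damage, `(1 + k_NTB·(1−B))` for neutrophils, with the
  printed macrophage suppression of neutrophil influx `(1+k_NTMT·M_T)⁻¹`
  retained; macrophage recruitment keeps its printed form
  `S_MT·N_T·M_v/(1+k_MTB·B)`.
- **Count-unit conversion.** The tissue→blood flux is divided by
  `ν_PB = 18.8` (tissue counts per systemic count unit) and the
  neutrophil kill capacity in blood is scaled by `χ_PN = 7`
  (`k_PBNA·N_A·χ_PN·HU2(P_B, x_PN, 2)`). These two constants bridge the
  CFU-scale invasion model to the unit-scale immune model and are the
  calibration dials for the bistability anchors (§5).
- **Cytokine production brackets.** Production terms follow the parameter
  naming convention (`k_AB` = effect of B on A): IL-6 production is
  `(k_6N·N_A + k_6M·M_A)·(1 + k_6TNF·HU2(TNF) + k_6NO·HU2(NO))`, and
  IL-10 analogously with `k_10MA·M_A`. The IL-6 self-inhibition factor
  `HD(IL6, x_66, 1)` sits in the IL-6 equation.
- **Tissue damage.** `dTI/dt = k_D(1−TI)(TI−TI_min) −
  (TI−TI_min)·k_D6·HU2(IL6, x_D6, 6)/(x_DNO² + NO²)`: IL-6 above the
  `x_D6 = 0.85` knee erodes integrity, NO moderates the erosion, and repair
  is logistic with floor `TI_min = 0` (irreversible damage only in the
  limit).
- **Extinction floors.** A pathogen population below roughly one organism
  cannot regrow: `P_T < 1` is set to zero, and `P_B < 0.05` is set to zero
  once the tissue source is extinct. Without the floors, sub-unit residues
  reignite the infection on the multi-hundred-hour horizon, which is an
  artifact of continuous ODEs, not biology.

### Dynamics on the calibrated parameters

The system is bistable. A tissue inoculum seeds the blood through the
barrier flux; blood counts are opposed by a saturating non-specific
clearance (`k_PS·P_B/(x_PS+P_B)`, per-capita 0.53/h at low counts against
growth 0.60/h) and by active-neutrophil killing with bounded capacity. Small
inocula pin the blood count low until the tissue is cleared (by ~8–12 h)
and then the count collapses to extinction; the critical inoculum
(≈6.95×10⁶ at `S_P = 0.6`) is where the pinned count just exceeds the kill
capacity, after which net growth (~0.06–0.1/h) carries it to the septic
plateau over days. The lower edge of the bistable growth-rate window falls
out of the clearance ratio `k_PS/x_PS ≈ 0.53`: below `S_P ≈ 0.55` the blood
compartment cannot sustain growth at realistic loads.

A structural consequence of the printed immune constants is that the
resting-pool relaxation terms (`k_MR·(M_R − S_M)`, `k_NR·(N_R − S_N)`) cap
active macrophages at 0.25 and active neutrophils at 0.10 units, which caps
sustained IL-6 near 0.45 — well below the `x_D6 = 0.85` damage knee. Tissue
integrity therefore falls by under ~1% even in fulminant sepsis, on a slow
ramp (≈5×10⁻⁴ at 20 h, ≈7×10⁻³ at 48 h). The physiological couplings are
calibrated to this scale (§3); `TI` is best read as a normalized damage
signal rather than a literal fraction of destroyed tissue.

## 2. Hybrid integration

Between switch transitions the vector field is smooth, so the default
integrator runs LSODA (rtol 10⁻⁶, per-state atol 10⁻⁹, relaxed to 10⁻³ for
the pathogen counts) one switch regime at a time, with terminal events on
the active TLR threshold and on the extinction floors. Transitions land on
the threshold crossings to root-finder accuracy. If a trajectory grazes a
threshold and defeats the event localizer, the integrator advances one
short clamped step past the graze and resumes. A macro-step mode (switch
and drug exposure frozen over a fixed grid, default 0.05 h) exists for the
coupled engine and for time-varying antibiotic input; the two modes agree
to ~10⁻⁴ and halving the macro step moves the critical inoculum by well
under 1%. States are clamped to their domain after every accepted segment.

Outcome classification integrates to a 500 h horizon and calls a run
healthy when the final blood count is below 10⁻² (with the extinction
floors the healthy branch terminates at exactly zero, so any threshold
below the septic plateau gives the same answer; classification within a
factor 10 of the threshold is flagged inconclusive). The control time is
the first time after which the blood count never rises again. The critical
inoculum is found by bisection on the initial tissue load to a relative
bracket width of 1%, and the bistable growth-rate window by classifying
the extremes of a load range over a growth-rate grid.

## 3. Reduced physiology

### Fluid and albumin exchange

The circulation is lumped into three vascular–interstitial pairs
(muscle/skin 50%, gut 30%, other viscera 20% of exchange surface) with a
common lymphatic return. Baselines: blood volume 5.0 L, interstitium 10 L,
capillary pressure 25 mmHg (tracking MAP with gain 0.45), interstitial
pressure −3 mmHg on a 5 L/mmHg compliance, plasma albumin 4.5 g/dL,
interstitial 1.5 g/dL, reflection coefficient σ = 0.95. Colloid osmotic
pressure follows the Landis–Pappenheimer cubic on total plasma protein
(taken proportional to albumin, 7.0 g/dL at baseline).

Fluid crosses each endothelium as `J = (ΔP_h − σ·ΔCOP)/R1` and albumin by
the Patlak relation `J_alb = J(1−σ)(C_p − C_i e^{−Pe})/(1−e^{−Pe})` with
`Pe = J(1−σ)/PS` (pure diffusion `PS·(C_p−C_i)` in the small-Pe limit).
Lymph drains each interstitium through a check valve driven by interstitial
pressure plus an 8 mmHg pump head against the vena cava, with conductance
rising 3-fold per fractional interstitial overfill (lymphatic recruitment).
At construction the endothelial resistances, lymph resistances and
diffusion capacities are solved so that the healthy state is an exact
equilibrium with total filtration = lymph return = 4.0 L/day and a
self-consistent albumin cycle. Baseline runs therefore hold every variable
to machine precision, and fluid/albumin are conserved to better than
10⁻⁹ per step by construction (the same flux values update both sides).

Inflammation couples in through tissue integrity: `R1` and `σ` scale as
`max(floor, 1 − a·(1−TI))` with `a_R = 108`, `a_σ = 85` and 5% floors. The
large slopes reflect the compressed range of `TI` (§1); they place the
capillary-leak cascade on the published timeline. Crystalloid infusions
deliver half their volume to the vascular space and half directly to the
interstitium (acute redistribution); colloid stays vascular and carries
5 g/dL albumin.

### Hemodynamics

Stroke volume follows blood volume linearly (sensitivity 1.3, capped at
+5% — the septic heart gains little from volume above baseline). A
first-order baroreflex (time constant 0.5 h) drives the controlled part of
SVR and the heart rate toward restoring MAP to its 90 mmHg setpoint; fever
adds 8 bpm/°C. NO depresses SVR through a sigmoid Emax block (E_max 0.78,
midpoint 0.32 NO units above rest, Hill 2), but sympathetic tone masks 65%
of that effect until the baroreflex fatigues: once two or more systemic
inflammatory criteria (HR > 90, RR > 20, T > 38 °C, WBC > 12 000) have been
met continuously, an inhibition fraction ramps linearly to 0.7 over 14 h,
simultaneously reducing the reflex SVR gain and unmasking the NO
vasodilation. MAP = CVP + CO·SVR; pulse pressure scales with stroke volume
and narrows with vasodilation (gain 0.5); SBP = MAP + ⅔PP, DBP = MAP − ⅓PP.
Vasopressor effect multiplies SVR.

### Renal output, metabolism, symptoms

Urine output is a saturating function of MAP (floor 50 mmHg, exponent 1.5)
and blood volume (exponent 4), 0.9 mL/min at baseline and capped at 1.5×;
a constant volume-neutral intake replaces baseline losses. An energy
deficit accumulates at rate `g·(1−TI)/(1 + (1−TI)/d_sat)` (gain 3800/h,
saturation 1.2×10⁻³) and relaxes at 0.15/h when tissue is intact —
the saturation departs from strict proportionality to damage and prevents
lactate from diverging late while still crossing 2 mM at the published
time. Lactate is produced at 0.14 mM/h per deficit unit and cleared
first-order (0.18/h) toward a 1 mM baseline. Fever and tachypnea are
sigmoid functions of damage (E_max 2.5 °C and 14/min, midpoints 3.5×10⁻⁴,
Hill 1); white cells are baseline 7000/µL plus 60 000 per active-neutrophil
unit.

## 4. Drugs, fluids, protocols

Drug kinetics are linear two-compartment models advanced by an exact
augmented-matrix exponential (mass-conserving to machine precision).
Piperacillin: clearance is fixed by the published exposure
(CL = dose/AUC = 4500 mg / 278 mg·h/L = 16.2 L/h); central volume 10 L,
peripheral 30 L, inter-compartment clearance 50 L/h and fraction unbound
0.7 place the ~3 h near-maximal-effect window for a 16 mg/L pathogen.
The kill law `S_net = S_max − (S_max−S_min)·u^γ/(u^γ − S_min/S_max)`
(`u = C_u/MIC`, `S_max = 0.6`, `S_min = −0.1`, γ = 4) is zero at the MIC
for any parameters and replaces the pathogen growth rate in both the tissue
and blood equations (each substitution independently switchable).
Norepinephrine uses a fast-clearing one-notch PK block (8 L, 150 L/h) and a
sigmoid SVR effect (E_max 0.55, EC₅₀ 4 µg/L) sized so a 0.18 µg/kg/min
infusion holds the septic patient near the 65–70 mmHg MAP goal.

The scenario engine advances all layers on a shared 0.05 h grid:
drug kinetics first, then the inflammation step under the current net
growth rates, then the physiology consuming the AIR outputs. The
resuscitation protocols review the patient on their trial cadence (30 min
control, 60 min experimental) using trailing half-hour means of SBP, MAP
and urine output — instantaneous sampling at review boundaries made the
discrete bolus cascade knife-edged on transient bolus peaks, which is not
how reassessment works at a bedside. Control: 500 mL bolus whenever SBP
< 90 or MAP < 65, an hourly extra 500 mL when UO < 0.625 mL/min, and
de-escalation to 75 mL/h maintenance once both pressure goals are met.
Experimental: maintenance at 1 mL/kg/h plus fixed-rate norepinephrine, a
250 mL hourly bolus on low UO, and pressor stop at goals. Decision boluses
infuse over 27 min; every review and action is written to an audit log.
Patient state serializes to versioned, checksummed JSON and resuming a
snapshot reproduces the uninterrupted trajectory to 10⁻⁹.

## 5. Calibration and what the tests show

The package's quantitative anchors fall in three classes. Analytic ones
(the MIC identity, the AUC = dose/CL exposure, baseline fluid turnover,
conservation laws) hold by construction and are tested exactly. The
bistability anchors (critical inoculum 6.95×10⁶ at `S_P = 0.6`, bistable
window spanning 0.55–0.70, blood control within 24 h for the resolving
severities, ~2× blood growth per 12 h on the septic branch) were used to
fix `ν_PB`, `χ_PN` and `κ_PB` once; they are reproduced by bisection and
grid scan at run time. The clinical-timeline anchors (SBP < 100 near 26 h,
lactate > 2 mM near 20 h, MAP < 65 near 45 h, minimum SVR near 60%,
protocol fluid totals near 4.25/2.75 L) calibrate the physiological
coupling constants of §3; the model reproduces them to within a few
percent (27.3 h, 21.2 h, 46.4 h, 57%, 3.84 L, 2.95 L on the default
configuration).

Because the simulator is fully deterministic, these are regression-style
checks of a calibrated reduced model, not out-of-sample predictions. What
the passing suite shows is that the implemented equations possess the
qualitative structure of the disease — bistability with a sharp critical
inoculum, a severity-graded immune response, an ordered marker cascade, and
treatment responses that depend on strategy and timing — and that the
quantitative anchors are met under the stated study conditions. It does not
validate the model against patient data.

## 6. Known limitations

- Tissue integrity moves on a compressed scale (§1), so the endothelial
  slopes are large and `TI` is a signal, not a literal fraction.
- The septic branch ends in unopposed vascular collapse: treated patients
  whose protocols de-escalate early can deteriorate again within hours,
  because tissue repair (time constant ~7 h, gated on pathogen clearance)
  lags the 6 h protocol window. The published engine shows milder
  post-treatment decline.
- Core temperature is a pure fever offset; there is no thermoregulation,
  respiratory gas exchange, coagulation, or per-organ damage resolution.
- Blood pressure reconstruction (MAP = DBP + PP/3) and the one-size
  baroreflex are stand-ins for a full circuit model; DBP is the least
  constrained output.
- The 12 h treatment-delay comparison measures blood counts on the slow
  septic growth segment; delays long enough to reach the blood carrying
  capacity would erase the difference.
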