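"""Reduced whole-body physiology: capillary fluid exchange, hemodynamics,
renal output, metabolism, and inflammation symptoms.

The layer lumps the systemic circulation into three vascular–interstitial
compartment pairs (muscle/skin, gut, other viscera) joined by a common lymph
return path with a check valve.  Fluid crosses each endothelium down the
net Starling gradient (hydrostatic minus reflection-weighted colloid-osmotic
difference) through an endothelial resistance; albumin follows by the
Patlak convection–diffusion law.  Inflammation couples in through four
signals taken from the AIR network: tissue integrity (endothelial leak and
symptoms), nitric oxide (vasodilation), active neutrophils (leukocytosis),
and the systemic inflammatory state (baroreflex fatigue).

All baseline resistances, lymph conductances and diffusion capacities are
tuned at construction so the healthy state is an exact equilibrium with a
transcapillary filtration of 4.0 L/day returned in full by the lymph.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PhysioConfig",
    "CompartmentPair",
    "Hemodynamics",
    "RenalMetabolic",
    "SymptomParams",
    "PhysioModel",
    "colloid_osmotic_pressure",
    "starling_flux",
    "albumin_flux",
    "lymph_return",
    "endothelial_update",
    "symptom_effects",
]


def colloid_osmotic_pressure(C_pp: float) -> float:
    """Colloid osmotic pressure (mmHg) from total plasma protein (g/dL),
    by the Landis–Pappenheimer cubic."""
    if C_pp < 0:
        raise ValueError("Protein concentration must be nonnegative")
    return 2.1 * C_pp + 0.18 * C_pp ** 2 + 0.009 * C_pp ** 3


@dataclass
class SymptomParams:
    """Sigmoidal effect block E = E_max·x^γ / (E_50^γ + x^γ)."""

    E_max: float
    E_50: float
    gamma: float = 1.0

    def effect(self, x: float) -> float:
        if x <= 0:
            return 0.0
        xg = x ** self.gamma
        return self.E_max * xg / (self.E_50 ** self.gamma + xg)


@dataclass
class PhysioConfig:
    """Every constant of the reduced physiology, units in field names.

    The endothelial coupling slopes (``a_R``, ``a_sigma``) translate loss of
    tissue integrity into loss of endothelial resistance and reflection.
    The inflammation network keeps tissue integrity within a few percent of
    unity even in fulminant sepsis, so these slopes are large; they are
    calibrated jointly with the nitric-oxide vasodilation block and the
    baroreflex-fatigue ramp against the septic-shock timeline.
    """

    # compartment layout: fraction of exchange surface per pair
    pair_names: tuple = ("muscle_skin", "gut", "viscera")
    pair_fractions: tuple = (0.5, 0.3, 0.2)

    # baseline volumes and pressures
    blood_volume_L: float = 5.0
    interstitial_volume_L: float = 10.0
    capillary_pressure_mmHg: float = 25.0
    interstitial_pressure_mmHg: float = -3.0
    vena_cava_pressure_mmHg: float = 2.0
    lymph_pump_pressure_mmHg: float = 8.0
    lymph_overfill_gain: float = 3.0   # conductance rise per fractional overfill
    interstitial_compliance_L_per_mmHg: float = 5.0    # total, split by fraction
    capillary_map_gain: float = 0.45   # d(P_cap)/d(MAP)

    # albumin / protein
    plasma_albumin_g_dL: float = 4.5
    interstitial_albumin_g_dL: float = 1.5
    protein_per_albumin: float = 7.0 / 4.5  # total plasma protein per albumin
    reflection_coefficient: float = 0.95

    # anchor: healthy transcapillary filtration = lymph return, L/day
    baseline_filtration_L_day: float = 4.0

    # endothelial dysfunction coupling (slopes on 1 - TI, with floors)
    a_R: float = 108.0
    a_sigma: float = 85.0
    floor_R: float = 0.05
    floor_sigma: float = 0.05

    # hemodynamics
    MAP_mmHg: float = 90.0
    SBP_mmHg: float = 114.0
    DBP_mmHg: float = 78.0
    HR_per_min: float = 72.0
    stroke_volume_sensitivity: float = 1.3   # dSV/SV per dV/V
    baro_gain_SVR: float = 1.2
    baro_gain_HR: float = 1.2
    baro_tau_h: float = 0.5
    HR_per_degC: float = 8.0
    # NO vasodilation (Emax on SVR) and its sympathetic opposition
    no_hypotension: SymptomParams = field(
        default_factory=lambda: SymptomParams(E_max=0.78, E_50=0.32, gamma=2.0))
    sympathetic_opposition: float = 0.65   # fraction of NO effect masked at full tone
    pulse_pressure_vasodilation_gain: float = 0.5  # PP narrowing with vasodilation
    # baroreflex fatigue: SVR-gain inhibition ramps over sustained SIRS
    inhibition_max: float = 0.7
    inhibition_ramp_h: float = 14.0

    # SIRS detection thresholds (2 of 4 criteria)
    sirs_HR: float = 90.0
    sirs_RR: float = 20.0
    sirs_temp_C: float = 38.0
    sirs_WBC: float = 12000.0

    # renal
    urine_output_mL_min: float = 0.9
    uo_map_floor_mmHg: float = 50.0
    uo_map_exponent: float = 1.5
    uo_volume_exponent: float = 4.0
    uo_max_factor: float = 1.5

    # metabolic (energy deficit and lactate)
    lactate_baseline_mM: float = 1.0
    energy_deficit_gain: float = 3800.0     # per unit (1 - TI), 1/h
    energy_deficit_saturation: float = 1.2e-3  # damage scale where accumulation saturates
    energy_recovery_rate: float = 0.15      # 1/h at TI = 1
    lactate_production_mM_h: float = 0.14   # per unit energy deficit
    lactate_clearance_h: float = 0.22       # 1/h toward baseline

    # symptoms
    temperature_C: float = 37.0
    RR_per_min: float = 16.0
    WBC_ct_uL: float = 7000.0
    WBC_per_NA: float = 60000.0
    fever: SymptomParams = field(
        default_factory=lambda: SymptomParams(E_max=2.5, E_50=3.5e-4, gamma=1.0))
    tachypnea: SymptomParams = field(
        default_factory=lambda: SymptomParams(E_max=14.0, E_50=3.5e-4, gamma=1.0))


@dataclass
class CompartmentPair:
    """One lumped vascular–interstitial exchange unit."""

    name: str
    fraction: float
    interstitial_volume_L: float
    interstitial_albumin_g: float
    P_vascular_mmHg: float
    P_interstitial_mmHg: float
    R1: float                    # endothelial resistance, mmHg·min/mL
    sigma: float                 # reflection coefficient
    PS: float                    # albumin diffusion capacity, mL/min
    R_lymph: float               # lymph pathway resistance, mmHg·min/mL
    compliance_L_mmHg: float
    R1_baseline: float = 0.0
    sigma_baseline: float = 0.0
    V0_interstitial_L: float = 0.0

    def __post_init__(self):
        if self.R1_baseline == 0.0:
            self.R1_baseline = self.R1
        if self.sigma_baseline == 0.0:
            self.sigma_baseline = self.sigma
        if self.V0_interstitial_L == 0.0:
            self.V0_interstitial_L = self.interstitial_volume_L


def starling_flux(pair: CompartmentPair, COP_v: float, COP_i: float) -> float:
    """Volumetric transcapillary flux (mL/min, vascular→interstitial > 0).

    Ohmic Starling form (ΔP_h − σ·ΔCOP)/R1; with σ = 1 this is the plain
    pressure-difference-over-resistance law."""
    dP = pair.P_vascular_mmHg - pair.P_interstitial_mmHg
    dCOP = COP_v - COP_i
    return (dP - pair.sigma * dCOP) / pair.R1


def albumin_flux(pair: CompartmentPair, J_V: float, C_alb_p: float,
                 C_alb_i: float) -> float:
    """Patlak convection–diffusion albumin flux (g/min; concentrations g/mL).

    The Peclet number Pe = J_V (1−σ)/PS weighs convection against diffusion;
    the |Pe| → 0 limit is pure diffusion PS·(C_p − C_i)."""
    if pair.PS <= 0:
        raise ValueError("Diffusion capacity PS must be positive")
    pe = J_V * (1.0 - pair.sigma) / pair.PS
    if abs(pe) < 1e-6:
        return pair.PS * (C_alb_p - C_alb_i)
    emp = math.exp(-pe)
    return J_V * (1.0 - pair.sigma) * (C_alb_p - C_alb_i * emp) / (1.0 - emp)


def lymph_return(pairs, vena_cava_pressure: float,
                 pump_pressure: float = 8.0):
    """Per-pair lymph flow (mL/min), check-valved at zero."""
    flows = []
    for p in pairs:
        drive = p.P_interstitial_mmHg + pump_pressure - vena_cava_pressure
        flows.append(max(0.0, drive / p.R_lymph))
    return flows


def endothelial_update(pair: CompartmentPair, TI: float,
                       a_R: float = 0.9, a_sigma: float = 0.9,
                       floor_R: float = 0.05,
                       floor_sigma: float = 0.05) -> CompartmentPair:
    """Scale endothelial resistance and reflection with loss of tissue
    integrity: linear in (1 − TI), floored."""
    if not 0.0 <= TI <= 1.0:
        raise ValueError("TI must lie in [0, 1]")
    damage = 1.0 - TI
    pair.R1 = pair.R1_baseline * max(floor_R, 1.0 - a_R * damage)
    pair.sigma = pair.sigma_baseline * max(floor_sigma, 1.0 - a_sigma * damage)
    return pair


def symptom_effects(TI: float, N_A: float, fever: SymptomParams,
                    tachypnea: SymptomParams, WBC_baseline: float,
                    WBC_per_NA: float):
    """(ΔRR, Δtemperature, WBC) from tissue damage and active neutrophils."""
    if not 0.0 <= TI <= 1.0:
        raise ValueError("TI must lie in [0, 1]")
    damage = 1.0 - TI
    d_rr = tachypnea.effect(damage)
    d_temp = fever.effect(damage)
    wbc = WBC_baseline + WBC_per_NA * max(N_A, 0.0)
    return d_rr, d_temp, wbc


@dataclass
class Hemodynamics:
    MAP: float
    SBP: float
    DBP: float
    HR: float
    SVR: float                   # effective, mmHg·min/L
    SVR_control: float           # baroreflex-set component
    CO: float
    SV: float
    inhibition: float = 0.0      # SVR-gain inhibition fraction
    sirs_active_h: float = 0.0   # accumulated time with SIRS criteria met
    sirs_onset_h: float | None = None


@dataclass
class RenalMetabolic:
    UO_mL_min: float
    energy_deficit: float
    lactate_mM: float
    temperature_C: float
    RR_per_min: float
    WBC_ct_uL: float


class PhysioModel:
    """Stateful reduced physiology advanced on a fixed macro grid.

    One-way coupled to the inflammation network: ``step`` consumes the AIR
    outputs (TI, NO, N_A) plus treatment inputs and advances fluid, albumin,
    hemodynamic, renal and symptom state by ``dt`` hours.  Bookkeeping
    integrals (filtration, lymph, urine, intake, infusion) support exact
    conservation checking.
    """

    def __init__(self, config: PhysioConfig | None = None):
        self.cfg = config or PhysioConfig()
        cfg = self.cfg
        self.blood_volume_L = cfg.blood_volume_L
        self.vascular_albumin_g = cfg.plasma_albumin_g_dL / 100.0 * \
            cfg.blood_volume_L * 1000.0
        self.pairs: list[CompartmentPair] = []
        self._tune_baseline()

        pp0 = cfg.SBP_mmHg - cfg.DBP_mmHg
        co0 = cfg.HR_per_min * self._SV0 / 1000.0
        self.hemo = Hemodynamics(
            MAP=cfg.MAP_mmHg, SBP=cfg.SBP_mmHg, DBP=cfg.DBP_mmHg,
            HR=cfg.HR_per_min, SVR=self._SVR0, SVR_control=self._SVR0,
            CO=co0, SV=self._SV0)
        self.renal = RenalMetabolic(
            UO_mL_min=cfg.urine_output_mL_min, energy_deficit=0.0,
            lactate_mM=cfg.lactate_baseline_mM,
            temperature_C=cfg.temperature_C, RR_per_min=cfg.RR_per_min,
            WBC_ct_uL=cfg.WBC_ct_uL)
        self.time_h = 0.0
        # accounting integrals (L or g)
        self.cum_filtration_L = 0.0
        self.cum_lymph_L = 0.0
        self.cum_urine_L = 0.0
        self.cum_intake_L = 0.0
        self.cum_infused_L = 0.0
        self.cum_infused_albumin_g = 0.0
        self._infusions: list[dict] = []

    # ---- baseline tuning -------------------------------------------
    def _tune_baseline(self) -> None:
        cfg = self.cfg
        J_total = cfg.baseline_filtration_L_day * 1000.0 / (24.0 * 60.0)
        cop_v = colloid_osmotic_pressure(
            cfg.plasma_albumin_g_dL * cfg.protein_per_albumin)
        cop_i = colloid_osmotic_pressure(
            cfg.interstitial_albumin_g_dL * cfg.protein_per_albumin)
        drive = (cfg.capillary_pressure_mmHg - cfg.interstitial_pressure_mmHg
                 - cfg.reflection_coefficient * (cop_v - cop_i))
        if drive <= 0:
            raise ValueError("Baseline Starling drive must be positive")
        lymph_drive = (cfg.interstitial_pressure_mmHg
                       + cfg.lymph_pump_pressure_mmHg
                       - cfg.vena_cava_pressure_mmHg)
        if lymph_drive <= 0:
            raise ValueError("Baseline lymph drive must be positive")
        cp = cfg.plasma_albumin_g_dL / 100.0
        ci = cfg.interstitial_albumin_g_dL / 100.0
        sig = cfg.reflection_coefficient
        # PS from the albumin steady state: transcapillary influx equals
        # convective lymph return J·C_i  =>  closed form for exp(-Pe)
        x = (ci - (1.0 - sig) * cp) / (sig * ci)
        if not 0 < x < 1:
            raise ValueError("Baseline albumin state inconsistent with sigma")
        pe = -math.log(x)
        self.pairs = []
        for name, f in zip(cfg.pair_names, cfg.pair_fractions):
            Jk = f * J_total
            self.pairs.append(CompartmentPair(
                name=name, fraction=f,
                interstitial_volume_L=f * cfg.interstitial_volume_L,
                interstitial_albumin_g=ci * 1000.0 * f
                    * cfg.interstitial_volume_L * 100.0 / 100.0,
                P_vascular_mmHg=cfg.capillary_pressure_mmHg,
                P_interstitial_mmHg=cfg.interstitial_pressure_mmHg,
                R1=drive / Jk, sigma=sig,
                PS=Jk * (1.0 - sig) / pe,
                R_lymph=lymph_drive / Jk,
                compliance_L_mmHg=f * cfg.interstitial_compliance_L_per_mmHg))
        self._SVR0 = (cfg.MAP_mmHg - cfg.vena_cava_pressure_mmHg) / \
            (cfg.HR_per_min / 1000.0) / self._sv_baseline()
        self._SV0 = self._sv_baseline()
        self._PP0 = cfg.SBP_mmHg - cfg.DBP_mmHg
        self._NO_rest = 0.0125

    def _sv_baseline(self) -> float:
        # stroke volume from the configured pressures: CO = MAP_net / SVR is
        # closed by choosing SV0 so that HR0·SV0 = 5 L/min
        return 5000.0 / self.cfg.HR_per_min

    # ---- treatment inputs ------------------------------------------
    def add_fluid(self, volume_L: float, albumin_g: float = 0.0,
                  retention: float = 1.0) -> None:
        """Deliver fluid: ``retention`` stays vascular, the rest distributes
        straight to the interstitial compartments by exchange fraction."""
        self.blood_volume_L += volume_L * retention
        for p in self.pairs:
            p.interstitial_volume_L += volume_L * (1.0 - retention) * p.fraction
        self.vascular_albumin_g += albumin_g
        self.cum_infused_L += volume_L
        self.cum_infused_albumin_g += albumin_g

    def schedule_infusion(self, volume_mL: float, duration_h: float,
                          compound) -> None:
        self._infusions.append({
            "rate_L_h": volume_mL / 1000.0 / duration_h,
            "albumin_g_per_L": compound.albumin_g_per_mL() * 1000.0,
            "retention": getattr(compound, "intravascular_retention", 1.0),
            "remaining_h": duration_h,
        })

    def _infusion_rates(self, dt: float):
        vol_rate = 0.0
        ivc_rate = 0.0
        alb_rate = 0.0
        for inf in self._infusions:
            if inf["remaining_h"] <= 0:
                continue
            frac = min(1.0, inf["remaining_h"] / dt)
            vol_rate += inf["rate_L_h"] * frac
            ivc_rate += inf["rate_L_h"] * frac * inf["retention"]
            alb_rate += inf["rate_L_h"] * frac * inf["albumin_g_per_L"]
            inf["remaining_h"] -= dt
        self._infusions = [i for i in self._infusions if i["remaining_h"] > 0]
        return vol_rate, ivc_rate, alb_rate

    # ---- main stepper ----------------------------------------------
    def step(self, dt: float, TI: float, NO: float, N_A: float,
             pressor_effect: float = 0.0) -> None:
        """Advance the physiology by ``dt`` hours given the AIR outputs."""
        if dt <= 0:
            raise ValueError("dt must be positive")
        cfg = self.cfg
        h = self.hemo
        r = self.renal

        # 1. symptoms (algebraic) -- needed for SIRS detection
        d_rr, d_temp, wbc = symptom_effects(
            TI, N_A, cfg.fever, cfg.tachypnea, cfg.WBC_ct_uL, cfg.WBC_per_NA)
        r.RR_per_min = cfg.RR_per_min + d_rr
        r.temperature_C = cfg.temperature_C + d_temp
        r.WBC_ct_uL = wbc

        # 2. SIRS clock and baroreflex fatigue
        criteria = sum((h.HR > cfg.sirs_HR, r.RR_per_min > cfg.sirs_RR,
                        r.temperature_C > cfg.sirs_temp_C,
                        r.WBC_ct_uL > cfg.sirs_WBC))
        if criteria >= 2:
            if h.sirs_onset_h is None:
                h.sirs_onset_h = self.time_h
            h.sirs_active_h += dt
        else:
            h.sirs_active_h = max(0.0, h.sirs_active_h - dt)
        h.inhibition = cfg.inhibition_max * min(
            1.0, h.sirs_active_h / cfg.inhibition_ramp_h)

        # 3. endothelial state from tissue integrity
        for p in self.pairs:
            endothelial_update(p, TI, cfg.a_R, cfg.a_sigma,
                               cfg.floor_R, cfg.floor_sigma)

        # 4. fluid and albumin exchange
        cp_gdl = self.vascular_albumin_g / (self.blood_volume_L * 10.0)
        cop_v = colloid_osmotic_pressure(cp_gdl * cfg.protein_per_albumin)
        p_cap = cfg.capillary_pressure_mmHg + cfg.capillary_map_gain * \
            (h.MAP - cfg.MAP_mmHg)
        filtration = 0.0
        lymph_total = 0.0
        dV_int = []
        dA_int = []
        dA_vasc = 0.0
        for p in self.pairs:
            p.P_vascular_mmHg = p_cap
            p.P_interstitial_mmHg = cfg.interstitial_pressure_mmHg + \
                (p.interstitial_volume_L - p.V0_interstitial_L) / \
                p.compliance_L_mmHg
            ci_gdl = p.interstitial_albumin_g / \
                (p.interstitial_volume_L * 10.0)
            cop_i = colloid_osmotic_pressure(ci_gdl * cfg.protein_per_albumin)
            J = starling_flux(p, cop_v, cop_i)                   # mL/min
            Ja = albumin_flux(p, J, cp_gdl / 100.0, ci_gdl / 100.0)  # g/min
            overfill = max(0.0, (p.interstitial_volume_L
                                 - p.V0_interstitial_L) / p.V0_interstitial_L)
            lym = max(0.0, (p.P_interstitial_mmHg
                            + cfg.lymph_pump_pressure_mmHg
                            - cfg.vena_cava_pressure_mmHg)
                      * (1.0 + cfg.lymph_overfill_gain * overfill) / p.R_lymph)
            lym_alb = lym * ci_gdl / 100.0                        # g/min
            filtration += J
            lymph_total += lym
            dV_int.append((J - lym) * 0.06 * dt)                  # L
            dA_int.append((Ja - lym_alb) * 60.0 * dt)             # g
            dA_vasc += (lym_alb - Ja) * 60.0 * dt

        # 5. renal output and intake
        uo = self._urine_output(h.MAP, self.blood_volume_L)
        r.UO_mL_min = uo
        intake_rate = cfg.urine_output_mL_min                     # mL/min
        inf_rate_L_h, inf_ivc_rate_L_h, inf_alb_rate = self._infusion_rates(dt)

        dV_blood = (-(filtration - lymph_total) * 0.06
                    + (intake_rate - uo) * 0.06
                    + inf_ivc_rate_L_h) * dt
        inf_interstitial_L = (inf_rate_L_h - inf_ivc_rate_L_h) * dt

        # forward-Euler guard: scale back a transfer that would overdraw a
        # compartment within the step (conservation is preserved because the
        # same scaled amounts are applied on both sides)
        if self.vascular_albumin_g + dA_vasc + inf_alb_rate * dt < 0:
            scale = max(0.0, (self.vascular_albumin_g + inf_alb_rate * dt)
                        / max(-dA_vasc, 1e-300))
            dA_vasc *= scale
            dA_int = [da * scale for da in dA_int]
        self.blood_volume_L += dV_blood
        self.vascular_albumin_g += dA_vasc + inf_alb_rate * dt
        for p, dv, da in zip(self.pairs, dV_int, dA_int):
            p.interstitial_volume_L += dv + inf_interstitial_L * p.fraction
            p.interstitial_albumin_g += da
        if self.blood_volume_L < 0.3:
            raise RuntimeError(
                f"Blood volume collapsed below viability at t={self.time_h:.1f} h")
        self.cum_filtration_L += filtration * 0.06 * dt
        self.cum_lymph_L += lymph_total * 0.06 * dt
        self.cum_urine_L += uo * 0.06 * dt
        self.cum_intake_L += intake_rate * 0.06 * dt
        self.cum_infused_L += inf_rate_L_h * dt
        self.cum_infused_albumin_g += inf_alb_rate * dt

        # 6. hemodynamics
        self._hemodynamics_step(dt, NO, pressor_effect)

        # 7. metabolism
        self._metabolic_step(dt, TI)

        self.time_h += dt

    def _urine_output(self, MAP: float, Vb: float) -> float:
        cfg = self.cfg
        f = max(0.0, (MAP - cfg.uo_map_floor_mmHg)
                / (cfg.MAP_mmHg - cfg.uo_map_floor_mmHg)) ** cfg.uo_map_exponent
        g = max(0.0, Vb / cfg.blood_volume_L) ** cfg.uo_volume_exponent
        return min(cfg.uo_max_factor * cfg.urine_output_mL_min,
                   cfg.urine_output_mL_min * f * g)

    def _hemodynamics_step(self, dt: float, NO: float,
                           pressor_effect: float) -> None:
        cfg = self.cfg
        h = self.hemo
        dv = (self.blood_volume_L - cfg.blood_volume_L) / cfg.blood_volume_L
        h.SV = self._SV0 * float(np.clip(
            1.0 + cfg.stroke_volume_sensitivity * dv, 0.3, 1.05))
        err = (cfg.MAP_mmHg - h.MAP) / cfg.MAP_mmHg
        gain_scale = (1.0 - h.inhibition) if err > 0 else 1.0
        svr_target = self._SVR0 * float(np.clip(
            1.0 + cfg.baro_gain_SVR * gain_scale * err, 0.5, 2.2))
        hr_target = float(np.clip(
            cfg.HR_per_min * (1.0 + cfg.baro_gain_HR * max(err, 0.0))
            + cfg.HR_per_degC * (self.renal.temperature_C - cfg.temperature_C),
            45.0, 180.0))
        alpha = 1.0 - math.exp(-dt / cfg.baro_tau_h)
        h.SVR_control += (svr_target - h.SVR_control) * alpha
        h.HR += (hr_target - h.HR) * alpha
        # NO-mediated vasodilation, opposed by sympathetic tone until the
        # baroreflex fatigues
        e_no = cfg.no_hypotension.effect(max(NO - self._NO_rest, 0.0))
        vasodilation = e_no * (1.0 - cfg.sympathetic_opposition
                               * (1.0 - h.inhibition))
        h.SVR = h.SVR_control * (1.0 - vasodilation) * (1.0 + pressor_effect)
        h.CO = h.HR * h.SV / 1000.0
        h.MAP = cfg.vena_cava_pressure_mmHg + h.CO * h.SVR
        # pulse pressure scales with stroke volume and narrows as arterial
        # tone relaxes under vasodilation
        pp = self._PP0 * (h.SV / self._SV0) * \
            (1.0 - cfg.pulse_pressure_vasodilation_gain * vasodilation)
        h.SBP = h.MAP + 2.0 * pp / 3.0
        h.DBP = h.MAP - pp / 3.0

    def _metabolic_step(self, dt: float, TI: float) -> None:
        cfg = self.cfg
        r = self.renal
        damage = 1.0 - TI
        dED = (cfg.energy_deficit_gain * damage
               / (1.0 + damage / cfg.energy_deficit_saturation)
               - cfg.energy_recovery_rate * r.energy_deficit * TI)
        r.energy_deficit = max(0.0, r.energy_deficit + dED * dt)
        dLac = cfg.lactate_production_mM_h * r.energy_deficit - \
            cfg.lactate_clearance_h * (r.lactate_mM - cfg.lactate_baseline_mM)
        r.lactate_mM = max(0.0, r.lactate_mM + dLac * dt)

    # ---- public single-operation entry points -----------------------
    def hemodynamics_step(self, dt: float, NO: float,
                          pressor_effect: float = 0.0) -> "Hemodynamics":
        """Advance only the circulation by ``dt`` under the given NO level
        and vasopressor effect; returns the updated hemodynamic state."""
        self._hemodynamics_step(dt, NO, pressor_effect)
        return self.hemo

    def urine_output(self, MAP: float | None = None,
                     blood_volume_L: float | None = None) -> float:
        """Urine output (mL/min) at the given pressure and volume
        (current state by default)."""
        return self._urine_output(
            self.hemo.MAP if MAP is None else MAP,
            self.blood_volume_L if blood_volume_L is None else blood_volume_L)

    def metabolic_step(self, dt: float, TI: float) -> "RenalMetabolic":
        """Advance only the energy-deficit/lactate loop by ``dt``."""
        self._metabolic_step(dt, TI)
        return self.renal

    # ---- views ------------------------------------------------------
    @property
    def extravascular_volume_L(self) -> float:
        return sum(p.interstitial_volume_L for p in self.pairs)

    @property
    def total_fluid_L(self) -> float:
        return self.blood_volume_L + self.extravascular_volume_L

    @property
    def total_albumin_g(self) -> float:
        return self.vascular_albumin_g + sum(
            p.interstitial_albumin_g for p in self.pairs)

    def vitals(self) -> dict:
        h, r = self.hemo, self.renal
        return {
            "time_h": self.time_h,
            "blood_volume_L": self.blood_volume_L,
            "MAP_mmHg": h.MAP, "SBP_mmHg": h.SBP, "DBP_mmHg": h.DBP,
            "HR_per_min": h.HR,
            "SVR_frac_baseline": h.SVR / self._SVR0,
            "CO_L_min": h.CO, "SV_mL": h.SV,
            "UO_mL_min": r.UO_mL_min,
            "lactate_mM": r.lactate_mM,
            "temp_C": r.temperature_C,
            "RR_per_min": r.RR_per_min,
            "WBC_ct_uL": r.WBC_ct_uL,
            "extravascular_volume_L": self.extravascular_volume_L,
        }
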