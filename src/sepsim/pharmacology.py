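"""Drug and fluid models: reduced two-compartment PK, antibiotic and
vasopressor PD, and fluid-compound composition.

The antibiotic pharmacodynamic law maps unbound plasma concentration C_u to
a net bacterial growth rate

    S_net = S_max - (S_max - S_min) * (C_u/MIC)**gamma
                    / ((C_u/MIC)**gamma - S_min/S_max)

which is exactly zero at C_u = MIC for any parameter choice: growth stalls
at the minimum inhibitory concentration and turns negative above it.  The
kinetic side is a linear two-compartment model with zero-order infusion,
advanced by an exact matrix-exponential step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

__all__ = [
    "PKParams",
    "PKState",
    "AntibioticPD",
    "VasopressorPD",
    "FluidCompound",
    "pk_step",
    "antibiotic_snet",
    "vasopressor_effect",
    "apply_fluid",
    "DRUG_REGISTRY",
    "PIPERACILLIN",
    "NOREPINEPHRINE",
    "SALINE",
    "ALBUMIN_COLLOID",
]


@dataclass
class PKParams:
    """Two-compartment pharmacokinetic parameters."""

    central_volume_L: float
    peripheral_volume_L: float
    intercompartment_clearance_L_h: float
    elimination_clearance_L_h: float
    fraction_unbound: float = 1.0

    def __post_init__(self) -> None:
        if min(self.central_volume_L, self.peripheral_volume_L) <= 0:
            raise ValueError("Compartment volumes must be positive")
        if self.elimination_clearance_L_h < 0 or \
                self.intercompartment_clearance_L_h < 0:
            raise ValueError("Clearances must be nonnegative")
        if not 0 < self.fraction_unbound <= 1:
            raise ValueError("Fraction unbound must lie in (0, 1]")

    def rate_matrix(self) -> np.ndarray:
        k10 = self.elimination_clearance_L_h / self.central_volume_L
        k12 = self.intercompartment_clearance_L_h / self.central_volume_L
        k21 = self.intercompartment_clearance_L_h / self.peripheral_volume_L
        return np.array([[-(k10 + k12), k21], [k12, -k21]])


@dataclass
class PKState:
    """Mass in each compartment (mg) plus elimination bookkeeping."""

    central_mg: float = 0.0
    peripheral_mg: float = 0.0
    eliminated_mg: float = 0.0
    infused_mg: float = 0.0

    def unbound_concentration(self, params: PKParams) -> float:
        return params.fraction_unbound * self.central_mg / params.central_volume_L

    def plasma_concentration(self, params: PKParams) -> float:
        return self.central_mg / params.central_volume_L


def pk_step(params: PKParams, state: PKState, infusion_rate_mg_h: float,
            dt_h: float) -> PKState:
    """Advance the two-compartment model by ``dt_h`` under constant infusion.

    Uses the exact solution via an augmented matrix exponential, so the step
    is mass-conserving to machine precision regardless of step size.
    """
    if dt_h <= 0:
        raise ValueError("dt must be positive")
    if infusion_rate_mg_h < 0:
        raise ValueError("Infusion rate must be nonnegative")
    M = params.rate_matrix()
    # augmented system: d/dt [A1, A2, u] with u' = 0 feeding the infusion
    aug = np.zeros((3, 3))
    aug[:2, :2] = M
    aug[0, 2] = infusion_rate_mg_h
    E = expm(aug * dt_h)
    vec = E @ np.array([state.central_mg, state.peripheral_mg, 1.0])
    a1, a2 = float(vec[0]), float(vec[1])
    if a1 < -1e-9 or a2 < -1e-9:
        raise ArithmeticError("Negative drug mass: integration bug")
    infused = infusion_rate_mg_h * dt_h
    eliminated = (state.central_mg + state.peripheral_mg + infused) - (a1 + a2)
    return PKState(central_mg=max(a1, 0.0), peripheral_mg=max(a2, 0.0),
                   eliminated_mg=state.eliminated_mg + eliminated,
                   infused_mg=state.infused_mg + infused)


@dataclass
class AntibioticPD:
    """Sigmoidal kill law parameters for an antibiotic.

    ``S_max`` is the pathogen's drug-free growth rate, ``S_min`` the fully
    suppressed (negative) rate; their difference is the maximal effect on
    net growth (0.70/h for the default piperacillin block).
    """

    S_max: float = 0.60      # 1/h
    S_min: float = -0.10     # 1/h
    MIC: float = 16.0        # mg/L
    gamma: float = 4.0

    def __post_init__(self) -> None:
        if not self.S_min < 0 < self.S_max:
            raise ValueError("Require S_min < 0 < S_max")
        if self.MIC <= 0 or self.gamma <= 0:
            raise ValueError("MIC and gamma must be positive")


def antibiotic_snet(C_u: float, pd: AntibioticPD) -> float:
    """Net bacterial growth rate under unbound antibiotic concentration C_u."""
    if C_u < 0:
        raise ValueError("Concentration must be nonnegative")
    u = (C_u / pd.MIC) ** pd.gamma
    return pd.S_max - (pd.S_max - pd.S_min) * u / (u - pd.S_min / pd.S_max)


@dataclass
class VasopressorPD:
    """Sigmoidal concentration-effect block for an SVR-raising vasopressor."""

    E_max: float = 0.55      # maximal fractional SVR increase
    EC_50: float = 4.0       # µg/L plasma concentration at half effect
    gamma: float = 1.0


def vasopressor_effect(C_plasma_ug_L: float, pd: VasopressorPD) -> float:
    """Fractional SVR increase produced by plasma concentration (µg/L)."""
    if C_plasma_ug_L < 0:
        raise ValueError("Concentration must be nonnegative")
    cg = C_plasma_ug_L ** pd.gamma
    return pd.E_max * cg / (cg + pd.EC_50 ** pd.gamma)


@dataclass
class FluidCompound:
    """Composition of an infusible fluid.

    ``intravascular_retention`` is the fraction of the infused volume that
    stays in the vascular space on delivery; the remainder distributes
    directly to the interstitium (acute crystalloid redistribution).  The
    slower Starling exchange handles everything thereafter.
    """

    name: str
    albumin_g_per_dL: float = 0.0
    intravascular_retention: float = 1.0

    def albumin_g_per_mL(self) -> float:
        return self.albumin_g_per_dL / 100.0


SALINE = FluidCompound("saline", albumin_g_per_dL=0.0,
                       intravascular_retention=0.5)
ALBUMIN_COLLOID = FluidCompound("albumin_colloid", albumin_g_per_dL=5.0,
                                intravascular_retention=1.0)

# Piperacillin: clearance fixed by the published exposure for a 4.5 g dose
# (AUC = dose / CL = 278 mg·h/L); distribution volumes give the observed
# ~3 h window of near-maximal kill against a 16 mg/L pathogen.
PIPERACILLIN = {
    "pk": PKParams(central_volume_L=10.0, peripheral_volume_L=30.0,
                   intercompartment_clearance_L_h=50.0,
                   elimination_clearance_L_h=4500.0 / 278.0,
                   fraction_unbound=0.7),
    "pd": AntibioticPD(gamma=4.0),
}

# Norepinephrine: fast-clearing catecholamine; at 0.18 µg/kg/min in a 75 kg
# patient the steady-state plasma level is ~5 µg/L.
NOREPINEPHRINE = {
    "pk": PKParams(central_volume_L=8.0, peripheral_volume_L=8.0,
                   intercompartment_clearance_L_h=10.0,
                   elimination_clearance_L_h=150.0,
                   fraction_unbound=1.0),
    "pd": VasopressorPD(),
}

DRUG_REGISTRY = {
    "piperacillin": PIPERACILLIN,
    "norepinephrine": NOREPINEPHRINE,
}


def registry_to_dict(registry=None) -> dict:
    """Serializable view of the drug registry (plain floats and names)."""
    registry = registry or DRUG_REGISTRY
    out = {}
    for name, block in registry.items():
        pk = block["pk"]
        pd = block["pd"]
        entry = {
            "pk": {
                "central_volume_L": pk.central_volume_L,
                "peripheral_volume_L": pk.peripheral_volume_L,
                "intercompartment_clearance_L_h":
                    pk.intercompartment_clearance_L_h,
                "elimination_clearance_L_h": pk.elimination_clearance_L_h,
                "fraction_unbound": pk.fraction_unbound,
            },
        }
        if isinstance(pd, AntibioticPD):
            entry["pd"] = {"type": "antibiotic", "S_max": pd.S_max,
                           "S_min": pd.S_min, "MIC": pd.MIC,
                           "gamma": pd.gamma}
        else:
            entry["pd"] = {"type": "vasopressor", "E_max": pd.E_max,
                           "EC_50": pd.EC_50, "gamma": pd.gamma}
        out[name] = entry
    return out


def registry_from_dict(d: dict) -> dict:
    out = {}
    for name, entry in d.items():
        pk = PKParams(**entry["pk"])
        pd_d = dict(entry["pd"])
        kind = pd_d.pop("type")
        pd = AntibioticPD(**pd_d) if kind == "antibiotic" \
            else VasopressorPD(**pd_d)
        out[name] = {"pk": pk, "pd": pd}
    return out


def apply_fluid(compound: FluidCompound, volume_mL: float, duration_h: float,
                physio) -> None:
    """Apply a fluid dose to a physiology state.

    Instantaneous boluses (duration 0) increment blood volume and vascular
    albumin immediately; finite-duration infusions are registered on the
    physiology model's infusion schedule and delivered by its stepper.
    """
    if volume_mL <= 0:
        raise ValueError("Dose volume must be positive")
    if duration_h < 0:
        raise ValueError("Duration must be nonnegative")
    if duration_h == 0:
        physio.add_fluid(volume_mL / 1000.0,
                         compound.albumin_g_per_mL() * volume_mL,
                         retention=compound.intravascular_retention)
    else:
        physio.schedule_infusion(volume_mL, duration_h, compound)
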