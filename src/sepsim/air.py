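"""Acute inflammatory response (AIR) network: an 18-state ODE model of
pathogen invasion and systemic inflammation.

The model couples a local infection compartment (tissue pathogen, local
macrophages and neutrophils, an epithelial barrier gated by a hysteretic
toll-like-receptor switch) to a systemic compartment (blood pathogen,
resting/active macrophage and neutrophil pools, NO synthases, and the
cytokines TNF, IL-6, IL-10, IL-12) and a global tissue-integrity variable.
Time is measured in hours; immune mediators are in arbitrary concentration
units, pathogen counts on a CFU/mL-like scale.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields

import numpy as np

__all__ = [
    "AIRParams",
    "AIRState",
    "GrowthModifier",
    "TLRSwitch",
    "hill_up_sat",
    "hill_up",
    "hill_down",
    "nitric_oxide",
    "tlr_update",
    "air_derivatives",
    "air_rhs",
    "healthy_state",
    "quiescent_state",
    "STATE_NAMES",
]

STATE_NAMES = (
    "P_T", "M_T", "N_T", "B", "P_B",
    "M_R", "M_A", "N_R", "N_A",
    "iNOSd", "iNOS", "eNOS", "NO3",
    "TNF", "IL6", "IL10", "IL12", "TI",
)


def _check_hill_args(x: float, n: float, h: float) -> None:
    if x < 0:
        raise ValueError(f"Hill function argument must be nonnegative, got x={x}")
    if n <= 0 or h <= 0:
        raise ValueError(f"Hill scale and exponent must be positive, got n={n}, h={h}")


def hill_up_sat(x: float, n: float, h: float) -> float:
    """Saturating upregulation x**h / (1 + (x/n)**h); tends to n**h as x grows."""
    _check_hill_args(x, n, h)
    return x ** h / (1.0 + (x / n) ** h)


def hill_up(x: float, n: float, h: float) -> float:
    """Sigmoid upregulation x**h / (x**h + n**h), bounded by 1, half-max at x = n."""
    _check_hill_args(x, n, h)
    xh = (x / n) ** h
    return xh / (xh + 1.0)


def hill_down(x: float, n: float, h: float) -> float:
    """Sigmoid downregulation 1 / (1 + (x/n)**h); complements hill_up to 1."""
    _check_hill_args(x, n, h)
    return 1.0 / (1.0 + (x / n) ** h)


@dataclass
class AIRParams:
    """Named rate/threshold parameters of the AIR network.

    Defaults are the published nominal values (time scale 1/h).  Naming
    conventions: S_A source of A, k_A decay of A, k_AB effect of B on A,
    x_AB half-max scale of B's effect on A, A_v resting pool of A.
    ``kappa_PT`` is the pathogen carrying capacity used to normalize the
    logistic growth terms, and ``TI_min`` the floor of tissue integrity.
    """

    # -- tissue invasion compartment
    S_P: float = 0.60          # pathogen growth rate, 1/h
    k_PT: float = 3.7e4
    theta_P: float = 1.35e-4   # tissue -> blood diffusion rate
    k_PTB: float = 3.1         # barrier suppression of pathogen diffusion
    k_PTMT: float = 6.3e-3     # phagocytosis by local macrophages
    k_PTNT: float = 6.1e-4     # phagocytosis by local neutrophils
    S_MT: float = 2.6e-2
    M_v: float = 0.3           # resting pool of recruitable local macrophages
    k_MT: float = 6.43e-5
    k_MTB: float = 36.0
    S_NT: float = 7.0e-7
    N_v: float = 1e8           # resting pool of recruitable local neutrophils
    k_NTB: float = 36.0
    k_NTMT: float = 0.16
    k_NT: float = 6.1e-2
    S_B: float = 4.6e-2        # barrier repair rate
    k_BPT: float = 26.0
    k_BR: float = 0.14         # TLR-driven barrier degradation
    k_BNT: float = 4.0e-8
    PT_plus: float = 2.0e6     # TLR switch upper threshold
    PT_minus: float = 1e3      # TLR switch lower threshold
    # -- blood pathogen
    k_PBNA: float = 5.8        # phagocytosis by active blood neutrophils
    x_PN: float = 0.5
    k_PS: float = 6.9e3        # saturating non-specific blood clearance
    x_PS: float = 1.3e4
    # -- macrophages
    k_MP: float = 1.01
    x_MP: float = 37.5
    k_MD: float = 5.0e-2
    x_MD: float = 0.75
    x_MTNF: float = 0.4
    k_M6: float = 0.1
    x_M6: float = 1.0
    x_M10: float = 0.297
    k_MR: float = 0.05
    S_M: float = 1.0
    k_MA: float = 0.2
    # -- neutrophils
    k_NP: float = 33.75
    x_NP: float = 56.25
    k_ND: float = 0.05
    x_ND: float = 0.4
    k_NTNF: float = 0.2
    x_NTNF: float = 2.0
    k_N6: float = 1.5
    x_N6: float = 1.0
    x_N10: float = 0.2
    k_NR: float = 0.05
    S_N: float = 1.0
    k_NA: float = 0.5
    # -- NO synthases and nitrate
    k_INOSN: float = 1.5
    k_INOSM: float = 0.1
    k_INOSEC: float = 0.1
    x_INOSTNF: float = 0.05
    k_INOSd: float = 0.05
    k_INOS6: float = 2.0
    x_INOS6: float = 0.1
    x_INOS10: float = 0.1
    x_INOSNO: float = 0.3
    k_INOS: float = 0.101
    k_ENOSEC: float = 0.05
    x_ENOSTNF: float = 0.4
    x_ENOSP: float = 1.015
    k_ENOS: float = 4.0
    k_NO3: float = 0.46
    k_NOMA: float = 2.0        # NO amplification by active immune cells (Eq 19)
    # -- TNF
    k_TNFN: float = 2.97
    k_TNFM: float = 0.1
    x_TNF10: float = 7.9e-2
    x_TNF6: float = 5.9e-2
    k_TNF: float = 1.4
    # -- IL-6
    k_6N: float = 0.2
    k_6M: float = 3.03
    k_6TNF: float = 1.0
    x_6TNF: float = 0.1
    k_6NO: float = 2.97
    x_6NO: float = 0.4
    x_610: float = 0.1782
    x_66: float = 0.5          # IL-6 self-inhibition scale
    k_6: float = 0.7
    S_6: float = 1.0e-3
    # -- IL-10
    k_10N: float = 0.1
    k_10MA: float = 0.1
    k_10TNF: float = 1.485
    x_10TNF: float = 0.05
    k_106: float = 5.1e-2
    x_106: float = 8.0e-2
    k_10R: float = 0.1
    x_1012: float = 1.0e-2
    k_10: float = 0.35
    S_10: float = 1.0e-2
    # -- IL-12
    k_12M: float = 0.303
    x_1210: float = 0.2525
    k_12: float = 5.0e-2
    # -- tissue integrity
    k_D: float = 0.15
    k_D6: float = 0.125
    x_D6: float = 0.85
    x_DNO: float = 0.5
    # -- structural additions (see docs/methods.md)
    kappa_PT: float = 1.0e10   # tissue pathogen carrying capacity
    kappa_PB: float = 2.0e4    # blood pathogen carrying capacity
    nu_PB: float = 18.8        # tissue counts per systemic (blood) count unit
    chi_PN: float = 7.0        # count scale of neutrophil kill capacity in blood
    ext_PT: float = 1.0        # tissue pathogen extinction floor (counts)
    ext_PB: float = 0.05       # blood pathogen extinction floor (counts)
    TI_min: float = 0.0        # tissue-integrity floor

    def __post_init__(self) -> None:
        for f in dc_fields(self):
            v = getattr(self, f.name)
            if f.name == "TI_min":
                if not 0.0 <= v < 1.0:
                    raise ValueError("TI_min must lie in [0, 1)")
            elif v < 0:
                raise ValueError(f"AIR parameter {f.name} must be nonnegative, got {v}")
        if self.PT_minus >= self.PT_plus:
            raise ValueError("TLR thresholds require PT_minus < PT_plus")

    # -- registry / serialization -------------------------------------
    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "AIRParams":
        known = {f.name for f in dc_fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"Unknown AIR parameter name(s): {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        """Flat key→value parameter file; keys are the field names."""
        import yaml
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "AIRParams":
        import yaml
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def replace(self, **overrides) -> "AIRParams":
        d = self.to_dict()
        unknown = set(overrides) - set(d)
        if unknown:
            raise KeyError(f"Unknown AIR parameter name(s): {sorted(unknown)}")
        d.update(overrides)
        return AIRParams(**d)


@dataclass
class AIRState:
    """The 18 differential states of the AIR network (see STATE_NAMES)."""

    P_T: float = 0.0
    M_T: float = 0.0
    N_T: float = 0.0
    B: float = 1.0
    P_B: float = 0.0
    M_R: float = 1.0
    M_A: float = 0.0
    N_R: float = 1.0
    N_A: float = 0.0
    iNOSd: float = 0.0
    iNOS: float = 0.0
    eNOS: float = 0.0125
    NO3: float = 0.0125
    TNF: float = 0.0
    IL6: float = 1.0e-3
    IL10: float = 1.0e-2
    IL12: float = 0.0
    TI: float = 1.0

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in STATE_NAMES], dtype=float)

    @classmethod
    def from_array(cls, y) -> "AIRState":
        return cls(**{n: float(v) for n, v in zip(STATE_NAMES, y)})

    def to_dict(self) -> dict:
        return {n: getattr(self, n) for n in STATE_NAMES}


@dataclass
class GrowthModifier:
    """Effective net pathogen growth rates (1/h), set by antibiotic exposure.

    Defaults to the drug-free growth rate in both compartments.  Values may
    be negative (net kill) but never exceed the intrinsic growth rate.
    """

    S_net_tissue: float
    S_net_blood: float

    @classmethod
    def drug_free(cls, params: AIRParams) -> "GrowthModifier":
        return cls(S_net_tissue=params.S_P, S_net_blood=params.S_P)


@dataclass
class TLRSwitch:
    """Hysteretic toll-like-receptor switch thresholds."""

    P_plus: float = 2.0e6
    P_minus: float = 1e3

    def __post_init__(self) -> None:
        if not 0 <= self.P_minus < self.P_plus:
            raise ValueError("Require 0 <= P_minus < P_plus")

    @classmethod
    def from_params(cls, params: AIRParams) -> "TLRSwitch":
        return cls(P_plus=params.PT_plus, P_minus=params.PT_minus)


def tlr_update(P_T: float, previous_R: int, switch: TLRSwitch) -> int:
    """Hysteresis rule: on above P_plus, off below P_minus, else unchanged."""
    if P_T > switch.P_plus:
        return 1
    if P_T < switch.P_minus:
        return 0
    return int(previous_R)


def nitric_oxide(state: AIRState, params: AIRParams) -> float:
    """Algebraic NO level: iNOS output amplified by active immune cells,
    plus the constitutive eNOS background."""
    return state.iNOS * (1.0 + params.k_NOMA * (state.M_A + state.N_A)) + state.eNOS


def quiescent_state(params: AIRParams | None = None) -> AIRState:
    """Closed-form quiescent (pathogen-free) state.

    eNOS sits at its production/decay balance k_ENOSEC/k_ENOS; cytokines at
    their source levels.  This point is a fixed point of the dynamics up to
    residuals of order 1e-6 caused by baseline IL-6 leaking weakly into the
    neutrophil activation term.
    """
    p = params or AIRParams()
    enos = p.k_ENOSEC / p.k_ENOS
    return AIRState(
        P_T=0.0, M_T=0.0, N_T=0.0, B=1.0, P_B=0.0,
        M_R=p.S_M, M_A=0.0, N_R=p.S_N, N_A=0.0,
        iNOSd=0.0, iNOS=0.0, eNOS=enos, NO3=enos,
        TNF=0.0, IL6=p.S_6, IL10=p.S_10, IL12=0.0, TI=1.0,
    )


_EQUILIBRIUM_CACHE: dict = {}


def healthy_state(params: AIRParams | None = None) -> AIRState:
    """Healthy equilibrium: the quiescent closed form polished by a root
    solve so that every residual derivative vanishes (the baseline IL-6
    source sustains a ~1e-6 trickle of neutrophil activation, displacing
    N_A and its downstream mediators slightly from the closed form)."""
    p = params or AIRParams()
    key = tuple(sorted(p.to_dict().items()))
    cached = _EQUILIBRIUM_CACHE.get(key)
    if cached is not None:
        return AIRState.from_array(np.array(cached))

    from scipy.optimize import root

    y0 = quiescent_state(p).to_array()
    free = [5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15, 16]  # immune mediators

    def resid(sub):
        y = y0.copy()
        y[free] = sub
        return air_rhs(y, p, 0)[free]

    sol = root(resid, y0[free], method="hybr")
    y = y0.copy()
    if np.max(np.abs(resid(sol.x))) < 1e-10 and np.all(sol.x >= -1e-9):
        y[free] = np.maximum(sol.x, 0.0)
    _EQUILIBRIUM_CACHE[key] = tuple(y)
    return AIRState.from_array(y)


def air_rhs(y, p: AIRParams, R: int,
            s_tissue: float | None = None, s_blood: float | None = None):
    """Right-hand side of the AIR ODE system on a raw state vector.

    ``R`` is the frozen TLR switch value for this evaluation; ``s_tissue``
    and ``s_blood`` are the (antibiotic-modified) net pathogen growth rates,
    defaulting to p.S_P.  States are floored at their domain bounds before
    evaluation so that the Hill terms stay in-domain even if the integrator
    probes slightly outside.
    """
    if s_tissue is None:
        s_tissue = p.S_P
    if s_blood is None:
        s_blood = p.S_P

    PT = max(y[0], 0.0)
    MT = max(y[1], 0.0)
    NT = max(y[2], 0.0)
    B = min(max(y[3], 0.0), 1.0)
    PB = max(y[4], 0.0)
    MR = max(y[5], 0.0)
    MA = max(y[6], 0.0)
    NR = max(y[7], 0.0)
    NA = max(y[8], 0.0)
    iNOSd = max(y[9], 0.0)
    iNOS = max(y[10], 0.0)
    eNOS = max(y[11], 0.0)
    NO3 = max(y[12], 0.0)
    TNF = max(y[13], 0.0)
    IL6 = max(y[14], 0.0)
    IL10 = max(y[15], 0.0)
    IL12 = max(y[16], 0.0)
    TI = min(max(y[17], p.TI_min), 1.0)

    kappa = p.kappa_PT
    NO = iNOS * (1.0 + p.k_NOMA * (MA + NA)) + eNOS
    damage = 1.0 - TI

    # local Hill helpers on pre-floored values (cheap scalar forms)
    def hu1(x, n, h):
        return x ** h / (1.0 + (x / n) ** h)

    def hu2(x, n, h):
        xh = (x / n) ** h
        return xh / (xh + 1.0)

    def hd(x, n, h):
        return 1.0 / (1.0 + (x / n) ** h)

    barrier_flux = p.theta_P * PT / (1.0 + p.k_PTB * B)

    dPT = (s_tissue * PT * (1.0 - PT / kappa)
           - barrier_flux
           - p.k_PTMT * MT * PT
           - p.k_PTNT * NT * PT)

    dMT = p.S_MT * NT * p.M_v / (1.0 + p.k_MTB * B) - p.k_MT * MT

    dNT = (p.S_NT * R * p.N_v * (1.0 + p.k_NTB * (1.0 - B))
           / (1.0 + p.k_NTMT * MT)
           - p.k_NT * NT)

    dB = (p.S_B * B * (1.0 - B) / (1.0 + p.k_BPT * PT / kappa)
          - p.k_BR * R * B
          - p.k_BNT * NT * B)

    dPB = (s_blood * PB * (1.0 - PB / p.kappa_PB)
           + barrier_flux / p.nu_PB
           - p.k_PS * PB / (p.x_PS + PB)
           - p.k_PBNA * NA * p.chi_PN * hu2(PB, p.x_PN, 2))

    m_act = ((p.k_MP * hu2(PB, p.x_MP, 2) + p.k_MD * hu2(damage, p.x_MD, 4))
             * (hu2(TNF, p.x_MTNF, 2) + p.k_M6 * hu2(IL6, p.x_M6, 2))
             * hd(IL10, p.x_M10, 2))
    dMR = -m_act * MR - p.k_MR * (MR - p.S_M)
    dMA = m_act * MR - p.k_MA * MA

    n_act = ((p.k_NP * hu2(PB, p.x_NP, 1)
              + p.k_ND * hu1(damage, p.x_ND, 2)
              + p.k_NTNF * hu1(TNF, p.x_NTNF, 1)
              + p.k_N6 * hu1(IL6, p.x_N6, 2))
             * hd(IL10, p.x_N10, 2))
    dNR = -n_act * NR - p.k_NR * (NR - p.S_N)
    dNA = n_act * NR - p.k_NA * NA

    diNOSd = ((p.k_INOSN * NA + p.k_INOSM * MA
               + p.k_INOSEC * (hu1(TNF, p.x_INOSTNF, 2)
                               + p.k_INOS6 * hu1(IL6, p.x_INOS6, 2)))
              * hd(IL10, p.x_INOS10, 2) * hd(NO, p.x_INOSNO, 4)
              - p.k_INOSd * iNOSd)

    diNOS = p.k_INOS * (iNOSd - iNOS)

    deNOS = (p.k_ENOSEC * hd(TNF, p.x_ENOSTNF, 1) * hd(PB, p.x_ENOSP, 1)
             - p.k_ENOS * eNOS)

    dNO3 = p.k_NO3 * (NO - NO3)

    dTNF = ((p.k_TNFN * NA + p.k_TNFM * MA)
            * hd(IL10, p.x_TNF10, 2) * hd(IL6, p.x_TNF6, 3)
            - p.k_TNF * TNF)

    dIL6 = ((p.k_6N * NA + p.k_6M * MA)
            * (1.0 + p.k_6TNF * hu2(TNF, p.x_6TNF, 2)
               + p.k_6NO * hu2(NO, p.x_6NO, 2))
            * hd(IL10, p.x_610, 2) * hd(IL6, p.x_66, 1)
            - p.k_6 * (IL6 - p.S_6))

    dIL10 = ((p.k_10N * NA + p.k_10MA * MA)
             * (1.0 + p.k_10TNF * hu2(TNF, p.x_10TNF, 4)
                + p.k_106 * hu2(IL6, p.x_106, 4))
             * ((1.0 - p.k_10R) * hd(IL12, p.x_1012, 4) + p.k_10R)
             - p.k_10 * (IL10 - p.S_10))

    dIL12 = p.k_12M * MA * hd(IL10, p.x_1210, 2) - p.k_12 * IL12

    dTI = (p.k_D * (1.0 - TI) * (TI - p.TI_min)
           - (TI - p.TI_min) * p.k_D6 * hu2(IL6, p.x_D6, 6)
           / (p.x_DNO ** 2 + NO ** 2))

    return np.array([dPT, dMT, dNT, dB, dPB, dMR, dMA, dNR, dNA,
                     diNOSd, diNOS, deNOS, dNO3, dTNF, dIL6, dIL10,
                     dIL12, dTI])


def air_derivatives(state: AIRState, params: AIRParams, R: int,
                    modifier: GrowthModifier | None = None) -> AIRState:
    """Time derivatives of every AIR state at the given state and switch value.

    Raises FloatingPointError naming the offending variable if any derivative
    is non-finite (the usual symptom of a state blown far out of domain).
    """
    if modifier is None:
        modifier = GrowthModifier.drug_free(params)
    dy = air_rhs(state.to_array(), params, R,
                 modifier.S_net_tissue, modifier.S_net_blood)
    if not np.all(np.isfinite(dy)):
        bad = [STATE_NAMES[i] for i in np.flatnonzero(~np.isfinite(dy))]
        raise FloatingPointError(
            f"Non-finite derivative for state variable(s): {', '.join(bad)}")
    return AIRState.from_array(dy)
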