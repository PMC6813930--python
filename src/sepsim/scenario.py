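"""Scenario orchestration: infections, timed interventions, resuscitation
protocols, and patient-state serialization.

The engine advances the three layers on a shared macro grid (default
0.05 h): the TLR switch is refrozen at each step boundary, the inflammation
ODEs are integrated within the step by the adaptive stiff solver, drug
kinetics advance by their exact matrix-exponential step, and the physiology
layer consumes the inflammation outputs.  Antibiotic exposure feeds back
into the pathogen growth rate (both compartments by default) through the
MIC-anchored pharmacodynamic law.

Two resuscitation strategies for fluid-refractory septic shock are scripted
after a restricted-fluid/early-vasopressor trial design: a fluid-liberal
control arm (half-hourly 500 mL boluses against pressure goals, hourly
urine-output rescue boluses) and an experimental arm (maintenance fluid
plus fixed-rate norepinephrine with hourly 250 mL rescue boluses).  Every
protocol decision is recorded in an audit log.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.integrate import solve_ivp

from .air import (AIRParams, AIRState, TLRSwitch, air_rhs, healthy_state,
                  tlr_update)
from .dynamics import _clamp
from .pharmacology import (DRUG_REGISTRY, AntibioticPD, PKState, SALINE,
                           antibiotic_snet, pk_step, vasopressor_effect)
from .physio import PhysioConfig, PhysioModel

__all__ = [
    "SEVERITY_LOADS",
    "InfectionAction",
    "ProtocolState",
    "SepsisEngine",
    "Scenario",
    "run_scenario",
    "untreated_run",
    "run_refresh_arm",
    "refresh_pretrial",
    "refresh_control_step",
    "refresh_experimental_step",
    "delayed_treatment",
    "save_snapshot",
    "load_snapshot",
]

SNAPSHOT_VERSION = 1

SEVERITY_LOADS = {"Mild": 1e6, "Moderate": 5e6, "Severe": 1e7}


@dataclass
class InfectionAction:
    """Start of an infection: a severity (or explicit tissue load), the
    pathogen's MIC, and an informational location label."""

    severity: str | None = "Severe"
    initial_load: float | None = None
    mic_mg_L: float = 16.0
    location: str = "generic_tissue"

    def load(self) -> float:
        if self.initial_load is not None:
            return float(self.initial_load)
        if self.severity not in SEVERITY_LOADS:
            raise ValueError(
                f"Unknown severity {self.severity!r}; expected one of "
                f"{sorted(SEVERITY_LOADS)}")
        return SEVERITY_LOADS[self.severity]

    def __post_init__(self):
        if self.mic_mg_L <= 0:
            raise ValueError("MIC must be positive")


@dataclass
class ProtocolState:
    """Bookkeeping for a running resuscitation protocol."""

    arm: str                       # "control" or "experimental"
    start_h: float
    weight_kg: float = 75.0
    SBP_goal: float = 90.0
    MAP_goal: float = 65.0
    UO_goal_mL_min: float = 0.625
    review_interval_h: float = 0.5     # control cadence; experimental uses 1 h
    duration_h: float = 6.0
    cumulative_fluid_L: float = 0.0
    terminated: bool = False
    terminated_at_h: float | None = None
    maintenance_rate_mL_h: float = 0.0
    next_check_h: float = 0.0

    def __post_init__(self):
        if self.arm not in ("control", "experimental"):
            raise ValueError("arm must be 'control' or 'experimental'")
        if self.arm == "experimental":
            self.review_interval_h = 1.0
        self.next_check_h = self.start_h + self.review_interval_h


def refresh_control_step(state: ProtocolState, vitals: dict, t: float):
    """One control-arm review: half-hourly pressure checks with 500 mL
    boluses, an hourly urine-output rescue bolus, and goal-based
    de-escalation to maintenance fluid.  Returns a list of actions."""
    actions = []
    if state.terminated:
        return actions
    sbp, mapv, uo = vitals["SBP_mmHg"], vitals["MAP_mmHg"], vitals["UO_mL_min"]
    hourly = abs((t - state.start_h) % 1.0) < 1e-6 or \
        abs((t - state.start_h) % 1.0 - 1.0) < 1e-6
    if sbp > state.SBP_goal and mapv > state.MAP_goal:
        state.terminated = True
        state.terminated_at_h = t
        state.maintenance_rate_mL_h = 75.0
        actions.append({"type": "terminate_to_maintenance",
                        "rate_mL_h": 75.0})
        return actions
    if sbp < state.SBP_goal or mapv < state.MAP_goal:
        actions.append({"type": "bolus", "volume_mL": 500.0,
                        "reason": f"SBP {sbp:.0f} or MAP {mapv:.0f} below goal"})
    if hourly and uo < state.UO_goal_mL_min:
        actions.append({"type": "bolus", "volume_mL": 500.0,
                        "reason": f"UO {uo:.2f} mL/min below goal"})
    return actions


def refresh_experimental_step(state: ProtocolState, vitals: dict, t: float):
    """One experimental-arm review (hourly): 250 mL rescue bolus on low
    urine output; stop everything but maintenance once pressure goals met."""
    actions = []
    if state.terminated:
        return actions
    sbp, mapv, uo = vitals["SBP_mmHg"], vitals["MAP_mmHg"], vitals["UO_mL_min"]
    if sbp > state.SBP_goal and mapv > state.MAP_goal:
        state.terminated = True
        state.terminated_at_h = t
        actions.append({"type": "stop_pressor_keep_maintenance"})
        return actions
    if uo < state.UO_goal_mL_min:
        actions.append({"type": "bolus", "volume_mL": 250.0,
                        "reason": f"UO {uo:.2f} mL/min below goal"})
    return actions


class SepsisEngine:
    """Master loop binding inflammation, physiology, drugs and protocols."""

    MACRO_STEP_H = 0.05

    def __init__(self, air_params: AIRParams | None = None,
                 physio_config: PhysioConfig | None = None,
                 weight_kg: float = 75.0,
                 antibiotic_affects_tissue: bool = True,
                 antibiotic_affects_blood: bool = True):
        self.air_params = air_params or AIRParams()
        self.physio = PhysioModel(physio_config)
        self.weight_kg = weight_kg
        self.antibiotic_affects_tissue = antibiotic_affects_tissue
        self.antibiotic_affects_blood = antibiotic_affects_blood
        self.t = 0.0
        self.y = healthy_state(self.air_params).to_array()
        self.R = 0
        self.mic_mg_L = 16.0
        self.drugs: dict[str, dict] = {}
        self.protocol: ProtocolState | None = None
        self.audit_log: list[dict] = []
        self.rows: list[dict] = []
        self._switch = TLRSwitch.from_params(self.air_params)
        self._uo_history: list[tuple[float, float]] = []
        self._bp_history: list[tuple[float, float, float]] = []

    # ---- actions ----------------------------------------------------
    def infect(self, action: InfectionAction) -> None:
        self.y[0] += action.load()
        self.mic_mg_L = action.mic_mg_L
        self.R = tlr_update(self.y[0], self.R, self._switch)
        self._log("infect", severity=action.severity, load=action.load(),
                  mic=action.mic_mg_L, location=action.location)

    def give_bolus(self, volume_mL: float, duration_h: float = 0.25,
                   compound=SALINE, count_protocol: bool = True) -> None:
        if duration_h <= 0:
            self.physio.add_fluid(volume_mL / 1000.0,
                                  compound.albumin_g_per_mL() * volume_mL)
        else:
            self.physio.schedule_infusion(volume_mL, duration_h, compound)
        if self.protocol is not None and count_protocol:
            self.protocol.cumulative_fluid_L += volume_mL / 1000.0
        self._log("fluid_bolus", volume_mL=volume_mL, duration_h=duration_h,
                  compound=compound.name)

    def start_drug_infusion(self, name: str, dose_mg: float,
                            duration_h: float) -> None:
        block = DRUG_REGISTRY[name]
        if name not in self.drugs:
            self.drugs[name] = {"pk": block["pk"], "pd": block["pd"],
                                "state": PKState(), "infusions": []}
        self.drugs[name]["infusions"].append(
            {"start": self.t, "end": self.t + duration_h,
             "rate_mg_h": dose_mg / duration_h})
        self._log("drug_infusion", drug=name, dose_mg=dose_mg,
                  duration_h=duration_h)

    def start_drug_rate(self, name: str, rate_mg_h: float,
                        until_h: float = np.inf) -> None:
        block = DRUG_REGISTRY[name]
        if name not in self.drugs:
            self.drugs[name] = {"pk": block["pk"], "pd": block["pd"],
                                "state": PKState(), "infusions": []}
        self.drugs[name]["infusions"].append(
            {"start": self.t, "end": until_h, "rate_mg_h": rate_mg_h})
        self._log("drug_rate", drug=name, rate_mg_h=rate_mg_h)

    def stop_drug(self, name: str) -> None:
        if name in self.drugs:
            for inf in self.drugs[name]["infusions"]:
                inf["end"] = min(inf["end"], self.t)
            self._log("drug_stop", drug=name)

    def start_protocol(self, arm: str) -> None:
        self.protocol = ProtocolState(arm=arm, start_h=self.t,
                                      weight_kg=self.weight_kg)
        self._log("protocol_start", arm=arm)
        if arm == "control":
            self.start_drug_infusion("piperacillin", 4500.0, 0.5)
            self.give_bolus(1000.0, duration_h=1.0)
        else:
            self.start_drug_infusion("piperacillin", 4500.0, 0.5)
            # maintenance saline 1 mL/kg/h and fixed-rate norepinephrine
            self.protocol.maintenance_rate_mL_h = 1.0 * self.weight_kg
            ne_rate_mg_h = 0.18e-3 * self.weight_kg * 60.0
            self.start_drug_rate("norepinephrine", ne_rate_mg_h)

    # ---- stepping ---------------------------------------------------
    def _drug_rate(self, name: str) -> float:
        rate = 0.0
        for inf in self.drugs[name]["infusions"]:
            if inf["start"] - 1e-9 <= self.t < inf["end"] - 1e-9:
                rate += inf["rate_mg_h"]
        return rate

    def _growth_rates(self):
        s = self.air_params.S_P
        s_t = s_b = s
        if "piperacillin" in self.drugs:
            d = self.drugs["piperacillin"]
            cu = d["state"].unbound_concentration(d["pk"])
            pd = AntibioticPD(S_max=s, S_min=d["pd"].S_min,
                              MIC=self.mic_mg_L, gamma=d["pd"].gamma)
            snet = antibiotic_snet(cu, pd)
            if self.antibiotic_affects_tissue:
                s_t = snet
            if self.antibiotic_affects_blood:
                s_b = snet
        return s_t, s_b

    def _pressor_effect(self) -> float:
        if "norepinephrine" not in self.drugs:
            return 0.0
        d = self.drugs["norepinephrine"]
        conc_ug_L = d["state"].plasma_concentration(d["pk"]) * 1000.0
        return vasopressor_effect(conc_ug_L, d["pd"])

    def step(self, dt: float | None = None) -> None:
        dt = dt or self.MACRO_STEP_H
        # 1. refreeze the TLR switch at the step boundary
        self.R = tlr_update(self.y[0], self.R, self._switch)
        # 2. drugs advance first so growth modification uses current exposure
        for name, d in self.drugs.items():
            d["state"] = pk_step(d["pk"], d["state"], self._drug_rate(name), dt)
        s_t, s_b = self._growth_rates()
        # 3. inflammation network within the step
        sol = solve_ivp(lambda tt, yy: air_rhs(yy, self.air_params, self.R,
                                               s_t, s_b),
                        (self.t, self.t + dt), self.y, method="LSODA",
                        rtol=1e-6, atol=1e-9)
        if not sol.success:
            raise RuntimeError(
                f"AIR integration failed at t={self.t:.2f} h: {sol.message}")
        self.y = _clamp(sol.y[:, -1].copy(), self.air_params)
        # 4. physiology consumes the AIR outputs
        state = AIRState.from_array(self.y)
        NO = state.iNOS * (1.0 + self.air_params.k_NOMA *
                           (state.M_A + state.N_A)) + state.eNOS
        if self.protocol is not None and not self.protocol.terminated and \
                self.protocol.arm == "experimental" and \
                self.protocol.maintenance_rate_mL_h > 0:
            self.physio.schedule_infusion(
                self.protocol.maintenance_rate_mL_h * dt, dt, SALINE)
            self.protocol.cumulative_fluid_L += \
                self.protocol.maintenance_rate_mL_h * dt / 1000.0
        elif self.protocol is not None and self.protocol.terminated and \
                self.protocol.maintenance_rate_mL_h > 0:
            self.physio.schedule_infusion(
                self.protocol.maintenance_rate_mL_h * dt, dt, SALINE)
            self.protocol.cumulative_fluid_L += \
                self.protocol.maintenance_rate_mL_h * dt / 1000.0
        self.physio.step(dt, TI=state.TI, NO=NO, N_A=state.N_A,
                         pressor_effect=self._pressor_effect())
        self.t = round(self.t + dt, 9)
        self._uo_history.append((self.t, self.physio.renal.UO_mL_min))
        self._bp_history.append((self.t, self.physio.hemo.SBP,
                                 self.physio.hemo.MAP))
        # 5. protocol review
        if self.protocol is not None and \
                self.t >= self.protocol.next_check_h - 1e-9 and \
                self.t <= self.protocol.start_h + self.protocol.duration_h + 1e-9:
            self._protocol_review()

    def _trailing_uo(self, window_h: float = 0.5) -> float:
        vals = [u for (tt, u) in self._uo_history if tt > self.t - window_h]
        return float(np.mean(vals)) if vals else self.physio.renal.UO_mL_min

    def _trailing_bp(self, window_h: float = 0.5):
        vals = [(s, m) for (tt, s, m) in self._bp_history
                if tt > self.t - window_h]
        if not vals:
            return self.physio.hemo.SBP, self.physio.hemo.MAP
        arr = np.array(vals)
        return float(arr[:, 0].mean()), float(arr[:, 1].mean())

    def _protocol_review(self) -> None:
        p = self.protocol
        vit = self.physio.vitals()
        # decisions are made on the trailing half-hour means, so transient
        # bolus peaks between reviews do not flip the protocol state
        vit["UO_mL_min"] = self._trailing_uo()
        vit["SBP_mmHg"], vit["MAP_mmHg"] = self._trailing_bp()
        fn = refresh_control_step if p.arm == "control" \
            else refresh_experimental_step
        actions = fn(p, vit, self.t)
        for a in actions:
            if a["type"] == "bolus":
                self.give_bolus(a["volume_mL"], duration_h=0.45)
            elif a["type"] == "stop_pressor_keep_maintenance":
                self.stop_drug("norepinephrine")
        self._log("protocol_check", arm=p.arm, SBP=vit["SBP_mmHg"],
                  MAP=vit["MAP_mmHg"], UO=vit["UO_mL_min"],
                  actions=copy.deepcopy(actions),
                  terminated=p.terminated)
        p.next_check_h = round(p.next_check_h + p.review_interval_h, 9)

    def run_until(self, t_end: float, record_every: float = 0.25) -> None:
        next_rec = self.t
        while self.t < t_end - 1e-9:
            if self.t >= next_rec - 1e-9:
                self.record()
                next_rec = round(next_rec + record_every, 9)
            self.step()
        self.record()

    def record(self) -> None:
        v = self.physio.vitals()
        st = AIRState.from_array(self.y)
        v.update({
            "time_h": self.t,
            "P_T": st.P_T, "P_B": st.P_B, "TI": st.TI,
            "NO": st.iNOS * (1.0 + self.air_params.k_NOMA *
                             (st.M_A + st.N_A)) + st.eNOS,
            "IL6": st.IL6, "N_A": st.N_A, "R": self.R,
        })
        if "piperacillin" in self.drugs:
            d = self.drugs["piperacillin"]
            v["piperacillin_Cu_mg_L"] = d["state"].unbound_concentration(d["pk"])
        if "norepinephrine" in self.drugs:
            d = self.drugs["norepinephrine"]
            v["norepinephrine_ug_L"] = \
                d["state"].plasma_concentration(d["pk"]) * 1000.0
        if self.protocol is not None:
            v["cumulative_fluid_L"] = self.protocol.cumulative_fluid_L
        self.rows.append(v)

    def frame(self):
        import pandas as pd
        return pd.DataFrame(self.rows)

    def _log(self, event: str, **kw) -> None:
        entry = {"time_h": self.t, "event": event}
        entry.update(kw)
        self.audit_log.append(entry)

    # ---- serialization ---------------------------------------------
    def snapshot(self) -> dict:
        ph = self.physio
        payload = {
            "time_h": self.t,
            "air_state": list(map(float, self.y)),
            "R": int(self.R),
            "mic_mg_L": self.mic_mg_L,
            "air_params": self.air_params.to_dict(),
            "weight_kg": self.weight_kg,
            "physio": {
                "blood_volume_L": ph.blood_volume_L,
                "vascular_albumin_g": ph.vascular_albumin_g,
                "pairs": [{
                    "interstitial_volume_L": p.interstitial_volume_L,
                    "interstitial_albumin_g": p.interstitial_albumin_g,
                    "R1": p.R1, "sigma": p.sigma,
                } for p in ph.pairs],
                "hemo": asdict(ph.hemo),
                "renal": asdict(ph.renal),
                "time_h": ph.time_h,
                "cum": [ph.cum_filtration_L, ph.cum_lymph_L, ph.cum_urine_L,
                        ph.cum_intake_L, ph.cum_infused_L,
                        ph.cum_infused_albumin_g],
                "infusions": copy.deepcopy(ph._infusions),
            },
            "drugs": {
                name: {"state": asdict(d["state"]),
                       "infusions": copy.deepcopy(d["infusions"])}
                for name, d in self.drugs.items()
            },
            "protocol": asdict(self.protocol) if self.protocol else None,
            "uo_history": [[tt, u] for tt, u in self._uo_history[-20:]],
        }
        return payload


def _json_dumps(obj) -> str:
    def default(o):
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (np.integer,)):
            return int(o)
        if o in (np.inf, -np.inf):
            return None
        raise TypeError(type(o))
    return json.dumps(obj, sort_keys=True, default=default)


def save_snapshot(engine: SepsisEngine, path) -> None:
    """Serialize the full patient state to versioned, checksummed JSON."""
    payload = engine.snapshot()
    # JSON cannot carry inf: encode open-ended infusions explicitly
    for d in payload["drugs"].values():
        for inf in d["infusions"]:
            if inf["end"] == np.inf:
                inf["end"] = "inf"
    body = _json_dumps(payload)
    doc = {"version": SNAPSHOT_VERSION,
           "checksum": hashlib.sha256(body.encode()).hexdigest(),
           "state": payload}
    with open(path, "w") as fh:
        fh.write(_json_dumps(doc))


def load_snapshot(path, physio_config: PhysioConfig | None = None
                  ) -> SepsisEngine:
    """Rebuild an engine from a snapshot file; rejects version or checksum
    mismatches and truncated files."""
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as e:
            raise ValueError(f"Corrupt snapshot file: {e}") from e
    if doc.get("version") != SNAPSHOT_VERSION:
        raise ValueError(
            f"Snapshot version {doc.get('version')} unsupported "
            f"(expected {SNAPSHOT_VERSION})")
    payload = doc["state"]
    body = _json_dumps(payload)
    if hashlib.sha256(body.encode()).hexdigest() != doc.get("checksum"):
        raise ValueError("Snapshot checksum mismatch")

    eng = SepsisEngine(air_params=AIRParams.from_dict(payload["air_params"]),
                       physio_config=physio_config,
                       weight_kg=payload["weight_kg"])
    eng.t = payload["time_h"]
    eng.y = np.array(payload["air_state"], dtype=float)
    eng.R = payload["R"]
    eng.mic_mg_L = payload["mic_mg_L"]
    ph = eng.physio
    pp = payload["physio"]
    ph.blood_volume_L = pp["blood_volume_L"]
    ph.vascular_albumin_g = pp["vascular_albumin_g"]
    for p, pd_ in zip(ph.pairs, pp["pairs"]):
        p.interstitial_volume_L = pd_["interstitial_volume_L"]
        p.interstitial_albumin_g = pd_["interstitial_albumin_g"]
        p.R1 = pd_["R1"]
        p.sigma = pd_["sigma"]
    from .physio import Hemodynamics, RenalMetabolic
    ph.hemo = Hemodynamics(**pp["hemo"])
    ph.renal = RenalMetabolic(**pp["renal"])
    ph.time_h = pp["time_h"]
    (ph.cum_filtration_L, ph.cum_lymph_L, ph.cum_urine_L, ph.cum_intake_L,
     ph.cum_infused_L, ph.cum_infused_albumin_g) = pp["cum"]
    ph._infusions = copy.deepcopy(pp["infusions"])
    for name, d in payload["drugs"].items():
        block = DRUG_REGISTRY[name]
        infusions = copy.deepcopy(d["infusions"])
        for inf in infusions:
            if inf["end"] == "inf":
                inf["end"] = np.inf
        eng.drugs[name] = {"pk": block["pk"], "pd": block["pd"],
                           "state": PKState(**d["state"]),
                           "infusions": infusions}
    if payload["protocol"] is not None:
        eng.protocol = ProtocolState(**{
            k: v for k, v in payload["protocol"].items()})
    eng._uo_history = [(tt, u) for tt, u in payload["uo_history"]]
    return eng


# ---- canned scenarios ---------------------------------------------------

def untreated_run(severity: str = "Severe", until_h: float = 48.0,
                  air_params: AIRParams | None = None,
                  physio_config: PhysioConfig | None = None,
                  mic_mg_L: float = 16.0) -> SepsisEngine:
    """Infection at t = 0 with no interventions."""
    eng = SepsisEngine(air_params, physio_config)
    eng.infect(InfectionAction(severity=severity, mic_mg_L=mic_mg_L))
    eng.run_until(until_h)
    return eng


def refresh_pretrial(engine: SepsisEngine, challenge_start_h: float = 44.0,
                     observe_until_h: float = 46.0) -> SepsisEngine:
    """Fluid challenge qualifying a septic patient for the trial protocols.

    Two 500 mL boluses are given half an hour apart; the patient qualifies
    if systolic pressure has not been restored above the 100 mmHg sepsis
    screening threshold by the end of the observation hour."""
    if engine.t > challenge_start_h + 1e-9:
        raise ValueError("Engine already past the challenge start time")
    engine.run_until(challenge_start_h)
    engine.pretrial_fluid_L = 0.0
    engine.give_bolus(500.0, duration_h=0.25)
    engine.pretrial_fluid_L += 0.5
    engine.run_until(challenge_start_h + 0.5)
    engine.give_bolus(500.0, duration_h=0.25)
    engine.pretrial_fluid_L += 0.5
    engine.run_until(observe_until_h)
    sbp = engine.physio.hemo.SBP
    engine.qualifies = sbp < 100.0
    if not engine.qualifies:
        engine._log("pretrial_disqualified", SBP=sbp)
    return engine


def run_refresh_arm(engine: SepsisEngine, arm: str,
                    protocol_hours: float = 6.0) -> SepsisEngine:
    """Run one treatment arm from the current (qualified septic) state."""
    engine.start_protocol(arm)
    engine.protocol.duration_h = protocol_hours
    engine.protocol.cumulative_fluid_L += getattr(engine, "pretrial_fluid_L",
                                                  0.0)
    engine.run_until(engine.t + protocol_hours)
    return engine


def delayed_treatment(air_params: AIRParams | None = None,
                      physio_config: PhysioConfig | None = None,
                      delay_h: float = 12.0,
                      challenge_start_h: float = 44.0):
    """Control-protocol scenario deferred by ``delay_h`` hours.

    Returns the engine after the full delayed run; the untreated severe
    course simply continues during the deferral."""
    eng = SepsisEngine(air_params, physio_config)
    eng.infect(InfectionAction(severity="Severe"))
    refresh_pretrial(eng, challenge_start_h + delay_h,
                     challenge_start_h + delay_h + 2.0)
    run_refresh_arm(eng, "control")
    return eng


# ---- scenario files -----------------------------------------------------

@dataclass
class Scenario:
    """Declarative scenario: patient, infection, timed actions, protocol."""

    duration_h: float = 48.0
    weight_kg: float = 75.0
    infection: InfectionAction | None = None
    infection_time_h: float = 0.0
    actions: list = field(default_factory=list)
    protocol_arm: str | None = None
    protocol_start_h: float | None = None
    air_overrides: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        known = {"duration_h", "weight_kg", "patient", "infection",
                 "actions", "protocol", "air_overrides", "run"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"Unknown scenario key(s): {sorted(unknown)}")
        sc = cls()
        run = d.get("run", {})
        sc.duration_h = float(run.get("duration_h", d.get("duration_h", 48.0)))
        sc.weight_kg = float(d.get("patient", {}).get("weight_kg", 75.0)) \
            if "patient" in d else float(d.get("weight_kg", 75.0))
        inf = d.get("infection")
        if inf:
            sc.infection = InfectionAction(
                severity=inf.get("severity"),
                initial_load=inf.get("initial_load"),
                mic_mg_L=float(inf.get("mic_mg_L", 16.0)),
                location=inf.get("location", "generic_tissue"))
            sc.infection_time_h = float(inf.get("time_h", 0.0))
        sc.actions = list(d.get("actions", []))
        proto = d.get("protocol")
        if proto:
            sc.protocol_arm = proto["arm"]
            sc.protocol_start_h = float(proto["start_h"])
        sc.air_overrides = dict(d.get("air_overrides", {}))
        return sc

    @classmethod
    def from_yaml(cls, path) -> "Scenario":
        import yaml
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "patient" in d:
            d.setdefault("weight_kg", d["patient"].get("weight_kg", 75.0))
        return cls.from_dict(d)


def run_scenario(scenario: Scenario | dict,
                 physio_config: PhysioConfig | None = None,
                 snapshot_path=None) -> SepsisEngine:
    """Execute a declarative scenario and return the finished engine."""
    if isinstance(scenario, dict):
        scenario = Scenario.from_dict(scenario)
    params = AIRParams().replace(**scenario.air_overrides) \
        if scenario.air_overrides else AIRParams()
    eng = SepsisEngine(params, physio_config, weight_kg=scenario.weight_kg)

    events = []
    if scenario.infection is not None:
        events.append((scenario.infection_time_h, "infect",
                       {"action": scenario.infection}))
    for a in scenario.actions:
        events.append((float(a["time_h"]), a["type"],
                       {k: v for k, v in a.items()
                        if k not in ("time_h", "type")}))
    if scenario.protocol_arm is not None:
        events.append((scenario.protocol_start_h, "protocol_start",
                       {"arm": scenario.protocol_arm}))
    events.sort(key=lambda e: e[0])

    for t_ev, kind, kw in events:
        if t_ev > eng.t:
            eng.run_until(t_ev)
        if kind == "infect":
            eng.infect(kw["action"])
        elif kind == "bolus":
            eng.give_bolus(float(kw["volume_mL"]),
                           duration_h=float(kw.get("duration_h", 0.25)))
        elif kind == "drug_infusion":
            eng.start_drug_infusion(kw["drug"], float(kw["dose_mg"]),
                                    float(kw["duration_h"]))
        elif kind == "drug_rate":
            eng.start_drug_rate(kw["drug"], float(kw["rate_mg_h"]))
        elif kind == "drug_stop":
            eng.stop_drug(kw["drug"])
        elif kind == "protocol_start":
            eng.start_protocol(kw["arm"])
        else:
            raise ValueError(f"Unknown action type {kind!r}")
    if eng.t < scenario.duration_h:
        eng.run_until(scenario.duration_h)
    if snapshot_path is not None:
        save_snapshot(eng, snapshot_path)
    return eng
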