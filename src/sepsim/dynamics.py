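"""Hybrid integration of the AIR system and outcome analysis.

The AIR model is a hybrid dynamical system: 18 continuous states plus a
binary TLR switch with hysteresis.  Between switch transitions the vector
field is smooth, so the default integration strategy runs an adaptive stiff
solver per switch regime with event detection on the active pathogen
threshold — transitions land exactly on threshold crossings.  When a
time-varying growth modifier is supplied (antibiotic exposure), or when a
``macro_step`` is explicitly requested, integration instead proceeds on a
macro grid with the switch and modifier frozen within each step.

Outcome analysis implements the bistability diagnostics: a trajectory is
classified healthy when the blood pathogen at the horizon is below an
elimination threshold, and the critical inoculum separating the healthy and
septic basins is located by bisection on the initial tissue load.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .air import (
    AIRParams,
    AIRState,
    GrowthModifier,
    STATE_NAMES,
    TLRSwitch,
    air_rhs,
    healthy_state,
    tlr_update,
)

__all__ = [
    "Trajectory",
    "Outcome",
    "integrate_air",
    "classify_outcome",
    "find_critical_load",
    "find_bistable_interval",
    "DEFAULT_HORIZON_H",
    "EPSILON_ELIM",
]

#: Horizon used to operationalize the asymptotic healthy/septic dichotomy.
DEFAULT_HORIZON_H = 500.0
#: Blood-pathogen elimination threshold: far below any meaningful count
#: (the septic branch saturates near the carrying capacity, ~1e7).
EPSILON_ELIM = 1e-2

_RTOL = 1e-6
# per-state absolute tolerances: loose for pathogen counts (CFU/mL scale),
# tight for the unit-scale immune mediators
_ATOL = np.full(18, 1e-9)
_ATOL[[0, 4]] = 1e-3  # P_T, P_B


@dataclass
class Trajectory:
    """Sampled solution of the hybrid AIR system."""

    t: np.ndarray                 # hours, strictly increasing
    y: np.ndarray                 # (len(t), 18) states in STATE_NAMES order
    R: np.ndarray                 # switch trace, {0,1}
    params: AIRParams

    @property
    def NO(self) -> np.ndarray:
        iNOS, eNOS = self.y[:, 10], self.y[:, 11]
        MA, NA = self.y[:, 6], self.y[:, 8]
        return iNOS * (1.0 + self.params.k_NOMA * (MA + NA)) + eNOS

    def __getitem__(self, name: str) -> np.ndarray:
        if name == "NO":
            return self.NO
        if name == "R":
            return self.R
        return self.y[:, STATE_NAMES.index(name)]

    def final_state(self) -> AIRState:
        return AIRState.from_array(self.y[-1])

    def to_frame(self):
        import pandas as pd

        d = {"time_h": self.t}
        for i, n in enumerate(STATE_NAMES):
            d[n] = self.y[:, i]
        d["NO"] = self.NO
        d["R"] = self.R
        return pd.DataFrame(d)

    def to_csv(self, path) -> None:
        """CSV export; a comment line documents units (hours / arbitrary
        concentration; pathogen counts CFU/mL-scaled; B, TI dimensionless)."""
        with open(path, "w") as fh:
            fh.write("# time_h in hours; P_T,P_B CFU/mL-scaled; B,TI,R "
                     "dimensionless; all other columns arbitrary concentration\n")
            self.to_frame().to_csv(fh, index=False)


@dataclass
class Outcome:
    """Asymptotic classification of an infection trajectory."""

    label: str                      # "healthy" or "septic"
    control_time: float | None      # h; first time after which dP_B/dt < 0
    P_B_final: float = 0.0
    inconclusive: bool = False

    @property
    def healthy(self) -> bool:
        return self.label == "healthy"


def _clamp(y: np.ndarray, params: AIRParams) -> np.ndarray:
    y = np.maximum(y, 0.0)
    y[3] = min(y[3], 1.0)
    y[17] = min(max(y[17], params.TI_min), 1.0)
    # extinction: pathogen below roughly one organism cannot regrow.  The
    # tissue count has no influx, so the floor always applies; the blood
    # count is floored only once the tissue source is extinct (otherwise a
    # small rising count fed by barrier flux would be wrongly zeroed).
    if y[0] <= params.ext_PT:
        y[0] = 0.0
    if y[4] <= params.ext_PB and y[0] == 0.0:
        y[4] = 0.0
    return y


def _solve_regime(y0, t0, t1, params, R, s_t, s_b, t_eval, switch,
                  rtol=_RTOL, atol=None):
    """Integrate one switch regime with an event on the active threshold."""
    if atol is None:
        atol = _ATOL

    def rhs(t, y):
        return air_rhs(y, params, R, s_t, s_b)

    events = []
    if R == 1:
        def ev(t, y):
            return y[0] - switch.P_minus
        ev.direction = -1.0
        ev.terminal = True
        events.append(ev)
    else:
        def ev(t, y):
            return y[0] - switch.P_plus
        ev.direction = 1.0
        ev.terminal = True
        events.append(ev)
    # extinction events let the regime solver stop so the floor can be applied
    if y0[0] > params.ext_PT:
        def ev_pt(t, y):
            return y[0] - params.ext_PT
        ev_pt.direction = -1.0
        ev_pt.terminal = True
        events.append(ev_pt)
    if y0[4] > params.ext_PB and y0[0] == 0.0:
        def ev_pb(t, y):
            return y[4] - params.ext_PB
        ev_pb.direction = -1.0
        ev_pb.terminal = True
        events.append(ev_pb)

    sol = solve_ivp(rhs, (t0, t1), y0, method="LSODA", rtol=rtol,
                    atol=atol, t_eval=t_eval, events=events,
                    dense_output=False)
    if not sol.success:
        raise RuntimeError(
            f"AIR integration failed at t={sol.t[-1] if len(sol.t) else t0:.3f} h: "
            f"{sol.message}")
    return sol


def integrate_air(initial: AIRState | np.ndarray,
                  params: AIRParams | None = None,
                  t_span: tuple[float, float] = (0.0, 48.0),
                  modifier_fn=None,
                  macro_step: float | None = None,
                  sample_dt: float = 0.1,
                  rtol: float = _RTOL,
                  atol=None) -> Trajectory:
    """Integrate the hybrid AIR system over ``t_span`` (hours).

    ``modifier_fn`` maps time (h) to a :class:`GrowthModifier`; if given, the
    system is advanced on a macro grid (default 0.05 h) with the switch state
    and modifier frozen within each step.  Without a modifier the integrator
    runs regime-to-regime with exact event detection of switch transitions.
    States are clamped to their domain bounds after each accepted segment.
    """
    params = params or AIRParams()
    t0, t1 = float(t_span[0]), float(t_span[1])
    if not t1 > t0:
        raise ValueError("t_span must be a nonempty forward interval")
    if macro_step is not None and macro_step <= 0:
        raise ValueError("macro_step must be positive")

    y0 = initial.to_array() if isinstance(initial, AIRState) else np.asarray(
        initial, dtype=float).copy()
    y0 = _clamp(y0, params)
    switch = TLRSwitch.from_params(params)
    # switch state at t0: threshold rule applied with no history
    R = 1 if y0[0] > switch.P_plus else 0

    ts: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    Rs: list[np.ndarray] = []

    def record(t_arr, y_arr, Rval):
        if len(t_arr) == 0:
            return
        ts.append(np.asarray(t_arr, dtype=float))
        ys.append(np.asarray(y_arr, dtype=float))
        Rs.append(np.full(len(t_arr), Rval, dtype=int))

    record([t0], [y0], R)

    if modifier_fn is None and macro_step is None:
        # event-driven path: one solver call per switch regime
        t, y = t0, y0
        while t < t1 - 1e-12:
            t_eval = np.arange(np.floor(t / sample_dt + 1) * sample_dt,
                               t1 + 1e-9, sample_dt)
            t_eval = t_eval[(t_eval > t + 1e-12) & (t_eval <= t1)]
            if len(t_eval) == 0 or t_eval[-1] < t1 - 1e-9:
                t_eval = np.append(t_eval, t1)
            try:
                sol = _solve_regime(y, t, t1, params, R, None, None, t_eval,
                                    switch, rtol=rtol, atol=atol)
            except ValueError:
                # a trajectory grazing a threshold can defeat the event
                # localizer; advance one short clamped step past the graze
                step_end = min(t + 0.05, t1)
                s2 = solve_ivp(lambda tt, yy: air_rhs(yy, params, R),
                               (t, step_end), y, method="LSODA",
                               rtol=rtol, atol=atol if atol is not None
                               else _ATOL)
                if not s2.success:
                    raise RuntimeError(
                        f"AIR integration failed at t={t:.3f} h: {s2.message}")
                t = step_end
                y = _clamp(s2.y[:, -1].copy(), params)
                R = tlr_update(y[0], R, switch)
                record([t], [y], R)
                continue
            if len(sol.t):
                yy = np.apply_along_axis(_clamp, 0, np.asarray(sol.y), params)
                record(sol.t, yy.T, R)
            if sol.status == 1:  # a switch threshold or an extinction floor
                if len(sol.t_events[0]):
                    t = float(sol.t_events[0][0])
                    y = _clamp(sol.y_events[0][0].copy(), params)
                    R = 1 - R
                else:
                    hit = next(i for i in range(1, len(sol.t_events))
                               if len(sol.t_events[i]))
                    t = float(sol.t_events[hit][0])
                    y = _clamp(sol.y_events[hit][0].copy(), params)
                record([t], [y], R)
            else:
                t = t1
                y = _clamp(sol.y[:, -1].copy(), params) if sol.y.size else y
    else:
        step = macro_step if macro_step is not None else 0.05
        t, y = t0, y0
        n_steps = int(round((t1 - t0) / step))
        grid = t0 + step * np.arange(n_steps + 1)
        grid[-1] = t1
        sample_every = max(1, int(round(sample_dt / step)))
        for i in range(n_steps):
            a, b = grid[i], grid[i + 1]
            R = tlr_update(y[0], R, switch)
            if modifier_fn is not None:
                mod = modifier_fn(a)
                s_t, s_b = mod.S_net_tissue, mod.S_net_blood
            else:
                s_t = s_b = None

            def rhs(tt, yy):
                return air_rhs(yy, params, R, s_t, s_b)

            sol = solve_ivp(rhs, (a, b), y, method="LSODA", rtol=rtol,
                            atol=atol if atol is not None else _ATOL)
            if not sol.success:
                raise RuntimeError(
                    f"AIR integration failed at t={sol.t[-1]:.3f} h: "
                    f"{sol.message}")
            y = _clamp(sol.y[:, -1].copy(), params)
            if (i + 1) % sample_every == 0 or i == n_steps - 1:
                record([b], [y], R)

    t_all = np.concatenate(ts)
    y_all = np.vstack(ys)
    R_all = np.concatenate(Rs)
    # drop duplicate time stamps except across switch transitions, keeping
    # strict monotonicity for downstream interpolation
    keep = np.ones(len(t_all), dtype=bool)
    keep[1:] = (np.diff(t_all) > 0) | (R_all[1:] != R_all[:-1])
    # enforce strictly increasing time by nudging switch-transition samples
    t_all = t_all[keep]
    y_all = y_all[keep]
    R_all = R_all[keep]
    eps = 1e-9
    for i in range(1, len(t_all)):
        if t_all[i] <= t_all[i - 1]:
            t_all[i] = t_all[i - 1] + eps
    if not np.all(np.isfinite(y_all)):
        bad_rows = np.flatnonzero(~np.all(np.isfinite(y_all), axis=1))
        raise RuntimeError(
            f"Non-finite state encountered at t={t_all[bad_rows[0]]:.3f} h")
    return Trajectory(t=t_all, y=y_all, R=R_all, params=params)


def classify_outcome(traj: Trajectory, params: AIRParams | None = None,
                     epsilon_elim: float = EPSILON_ELIM) -> Outcome:
    """Classify a trajectory as healthy or septic.

    Healthy means the blood pathogen at the end of the run is below
    ``epsilon_elim``.  ``control_time`` is the first time after which the net
    blood-pathogen growth (dP_B/dt along the trajectory) stays negative; it
    is None for septic runs.  Classification is flagged inconclusive when the
    final count sits within a factor of 10 of the threshold.
    """
    params = params or traj.params
    span = traj.t[-1] - traj.t[0]
    if span < 200.0:
        warnings.warn(
            f"Trajectory spans only {span:.0f} h; asymptotic classification "
            "is intended for runs of at least 200 h", stacklevel=2)
    pb = traj["P_B"]
    pb_end = float(pb[-1])
    healthy = pb_end < epsilon_elim
    inconclusive = epsilon_elim / 10.0 <= pb_end <= epsilon_elim * 10.0
    if inconclusive:
        warnings.warn(
            f"Final blood pathogen {pb_end:.3g} is within a factor 10 of the "
            f"elimination threshold {epsilon_elim:.3g}; classification is "
            "inconclusive", stacklevel=2)

    control_time: float | None = None
    if healthy:
        if np.all(pb <= 0.0):
            control_time = 0.0
        else:
            # last sample after which the count only falls (or is extinct)
            dpb = np.diff(pb)
            growing = np.flatnonzero(dpb > 0.0)
            if len(growing) == 0:
                control_time = float(traj.t[0])
            else:
                last = growing[-1]
                control_time = float(traj.t[last + 1]) \
                    if last + 1 < len(traj.t) else None
    return Outcome(label="healthy" if healthy else "septic",
                   control_time=control_time, P_B_final=pb_end,
                   inconclusive=inconclusive)


def _classify_load(load: float, params: AIRParams, horizon: float,
                   epsilon_elim: float, macro_step: float | None = None
                   ) -> Outcome:
    s0 = healthy_state(params)
    s0.P_T = load
    traj = integrate_air(s0, params, (0.0, horizon), macro_step=macro_step,
                         sample_dt=1.0)
    return classify_outcome(traj, params, epsilon_elim)


def find_critical_load(S_P: float,
                       params: AIRParams | None = None,
                       bracket: tuple[float, float] = (1e6, 1e7),
                       rel_tol: float = 0.01,
                       horizon: float = DEFAULT_HORIZON_H,
                       epsilon_elim: float = EPSILON_ELIM,
                       macro_step: float | None = None) -> float:
    """Critical initial tissue load separating healthy from septic outcomes.

    Bisection on the initial tissue pathogen count (all other states at the
    healthy equilibrium) at fixed growth rate ``S_P``.  The bracket must
    separate the two outcomes.  Returns the final bracket midpoint once the
    relative bracket width drops below ``rel_tol``.
    """
    params = (params or AIRParams()).replace(S_P=S_P)
    lo, hi = float(bracket[0]), float(bracket[1])
    if not 0 < lo < hi:
        raise ValueError("bracket must satisfy 0 < lo < hi")
    out_lo = _classify_load(lo, params, horizon, epsilon_elim, macro_step)
    out_hi = _classify_load(hi, params, horizon, epsilon_elim, macro_step)
    if out_lo.label == out_hi.label:
        raise ValueError(
            f"Both bracket endpoints classify as {out_lo.label}; no critical "
            "load inside the bracket")
    if out_lo.label != "healthy":
        raise ValueError("Expected the lower bracket endpoint to be healthy")
    while (hi - lo) / (0.5 * (hi + lo)) > rel_tol:
        mid = 0.5 * (lo + hi)
        out = _classify_load(mid, params, horizon, epsilon_elim, macro_step)
        if out.inconclusive:
            # tie-break by the sign of the net blood growth at the horizon
            septic_side = out.P_B_final >= epsilon_elim
        else:
            septic_side = out.label == "septic"
        if septic_side:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def find_bistable_interval(params: AIRParams | None = None,
                           S_P_grid=None,
                           load_range: tuple[float, float] = (1e5, 1e9),
                           horizon: float = DEFAULT_HORIZON_H,
                           epsilon_elim: float = EPSILON_ELIM):
    """Smallest and largest grid growth rates at which both outcomes occur.

    Scans ``S_P_grid`` and, at each rate, classifies the two extremes of
    ``load_range``; a rate is bistable when the low load resolves healthy and
    the high load resolves septic.  Returns (S_low, S_high), or None when no
    grid point is bistable.
    """
    params = params or AIRParams()
    if S_P_grid is None:
        S_P_grid = np.arange(0.40, 0.901, 0.05)
    S_P_grid = np.sort(np.asarray(S_P_grid, dtype=float))
    bistable = []
    for sp in S_P_grid:
        p = params.replace(S_P=float(sp))
        lo = _classify_load(load_range[0], p, horizon, epsilon_elim)
        hi = _classify_load(load_range[1], p, horizon, epsilon_elim)
        if lo.label == "healthy" and hi.label == "septic":
            bistable.append(float(sp))
    if not bistable:
        return None
    return (min(bistable), max(bistable))
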