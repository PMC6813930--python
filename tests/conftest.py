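import warnings

import numpy as np
import pytest

from sepsim import (AIRParams, InfectionAction, SepsisEngine, healthy_state,
                    integrate_air, refresh_pretrial, save_snapshot)

warnings.filterwarnings("ignore", message="Trajectory spans only")


@pytest.fixture(scope="session")
def params():
    return AIRParams()


@pytest.fixture(scope="session")
def severe_traj(params):
    """Severe infection (1e7 tissue load), 60 h, event-driven integration."""
    s0 = healthy_state(params)
    s0.P_T = 1e7
    return integrate_air(s0, params, (0.0, 60.0), sample_dt=0.25)


@pytest.fixture(scope="session")
def severe_traj_long(params):
    s0 = healthy_state(params)
    s0.P_T = 1e7
    return integrate_air(s0, params, (0.0, 500.0), sample_dt=1.0)


@pytest.fixture(scope="session")
def septic_snapshot(tmp_path_factory):
    """Qualified fluid-refractory septic patient at 46 h, serialized."""
    eng = SepsisEngine()
    eng.infect(InfectionAction(severity="Severe"))
    refresh_pretrial(eng)
    assert eng.qualifies
    path = tmp_path_factory.mktemp("snaps") / "septic46.json"
    save_snapshot(eng, path)
    return path


def first_crossing(t, v, threshold, direction="down"):
    v = np.asarray(v)
    idx = np.flatnonzero(v < threshold if direction == "down"
                         else v > threshold)
    return None if len(idx) == 0 else float(np.asarray(t)[idx[0]])
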