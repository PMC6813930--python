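"""Scenario-engine tests: severity mapping, the master loop, protocol rules,
serialization round-trips, audit completeness, and fluid accounting."""

import json

import numpy as np
import pytest

from sepsim import (InfectionAction, ProtocolState, Scenario, SepsisEngine,
                    load_snapshot, run_refresh_arm, run_scenario,
                    save_snapshot)
from sepsim.scenario import (refresh_control_step, refresh_experimental_step)


class TestInfectionAction:
    def test_severity_mapping(self):
        assert InfectionAction(severity="Mild").load() == 1e6
        assert InfectionAction(severity="Moderate").load() == 5e6
        assert InfectionAction(severity="Severe").load() == 1e7
        assert InfectionAction(initial_load=3.3e6).load() == 3.3e6

    def test_validation(self):
        with pytest.raises(ValueError):
            InfectionAction(severity="Apocalyptic").load()
        with pytest.raises(ValueError):
            InfectionAction(mic_mg_L=0.0)


def test_uninfected_run_holds_baseline():
    """48 h with no infection: every recorded vital stays within 1% of its
    starting value (control condition for the coupled engine)."""
    eng = SepsisEngine()
    eng.run_until(48.0)
    df = eng.frame()
    for col in ["MAP_mmHg", "SBP_mmHg", "HR_per_min", "blood_volume_L",
                "UO_mL_min", "lactate_mM", "temp_C", "RR_per_min",
                "SVR_frac_baseline", "extravascular_volume_L"]:
        v = df[col].values
        assert np.max(np.abs(v - v[0])) <= 0.01 * abs(v[0]) + 1e-9, col


class TestProtocolRules:
    vitals_low = {"SBP_mmHg": 85.0, "MAP_mmHg": 70.0, "UO_mL_min": 0.7}

    def test_control_half_hour_check_gives_exactly_one_bolus(self):
        state = ProtocolState(arm="control", start_h=46.0)
        actions = refresh_control_step(state, self.vitals_low, 46.5)
        assert [a["type"] for a in actions] == ["bolus"]
        assert actions[0]["volume_mL"] == 500.0

    def test_control_hourly_check_adds_urine_rescue(self):
        state = ProtocolState(arm="control", start_h=46.0)
        vit = {"SBP_mmHg": 85.0, "MAP_mmHg": 60.0, "UO_mL_min": 0.3}
        actions = refresh_control_step(state, vit, 47.0)
        assert [a["type"] for a in actions] == ["bolus", "bolus"]

    def test_control_terminates_to_maintenance_on_goals(self):
        state = ProtocolState(arm="control", start_h=46.0)
        vit = {"SBP_mmHg": 95.0, "MAP_mmHg": 70.0, "UO_mL_min": 0.3}
        actions = refresh_control_step(state, vit, 47.0)
        assert actions == [{"type": "terminate_to_maintenance",
                            "rate_mL_h": 75.0}]
        assert state.terminated and state.maintenance_rate_mL_h == 75.0
        # no further actions once terminated
        assert refresh_control_step(state, self.vitals_low, 47.5) == []

    def test_experimental_urine_bolus_is_250(self):
        state = ProtocolState(arm="experimental", start_h=46.0)
        vit = {"SBP_mmHg": 85.0, "MAP_mmHg": 70.0, "UO_mL_min": 0.3}
        actions = refresh_experimental_step(state, vit, 47.0)
        assert actions == [{"type": "bolus", "volume_mL": 250.0,
                            "reason": actions[0]["reason"]}]

    def test_experimental_goal_stops_pressor_only(self):
        state = ProtocolState(arm="experimental", start_h=46.0)
        vit = {"SBP_mmHg": 95.0, "MAP_mmHg": 70.0, "UO_mL_min": 0.3}
        actions = refresh_experimental_step(state, vit, 47.0)
        assert actions == [{"type": "stop_pressor_keep_maintenance"}]

    def test_adequate_urine_no_extra_bolus(self):
        state = ProtocolState(arm="experimental", start_h=46.0)
        vit = {"SBP_mmHg": 85.0, "MAP_mmHg": 60.0, "UO_mL_min": 0.8}
        assert refresh_experimental_step(state, vit, 47.0) == []

    def test_invalid_arm_rejected(self):
        with pytest.raises(ValueError):
            ProtocolState(arm="placebo", start_h=0.0)


class TestSnapshots:
    def test_save_load_save_is_byte_identical(self, septic_snapshot,
                                              tmp_path):
        eng = load_snapshot(septic_snapshot)
        second = tmp_path / "again.json"
        save_snapshot(eng, second)
        assert second.read_bytes() == septic_snapshot.read_bytes()

    def test_truncated_file_rejected_cleanly(self, septic_snapshot,
                                             tmp_path):
        broken = tmp_path / "broken.json"
        broken.write_text(septic_snapshot.read_text()[:200])
        with pytest.raises(ValueError, match="Corrupt"):
            load_snapshot(broken)

    def test_version_and_checksum_guards(self, septic_snapshot, tmp_path):
        doc = json.loads(septic_snapshot.read_text())
        doc["version"] = 999
        bad = tmp_path / "badver.json"
        bad.write_text(json.dumps(doc))
        with pytest.raises(ValueError, match="version"):
            load_snapshot(bad)
        doc = json.loads(septic_snapshot.read_text())
        doc["state"]["time_h"] += 1.0  # tamper without updating checksum
        bad2 = tmp_path / "badsum.json"
        bad2.write_text(json.dumps(doc))
        with pytest.raises(ValueError, match="checksum"):
            load_snapshot(bad2)

    def test_resume_matches_uninterrupted_run(self, tmp_path):
        """Continuing from a snapshot reproduces the uninterrupted
        trajectory to 1e-9 in every state variable."""
        a = SepsisEngine()
        a.infect(InfectionAction(severity="Severe"))
        a.run_until(20.0)
        path = tmp_path / "mid.json"
        save_snapshot(a, path)
        a.run_until(22.0)

        b = load_snapshot(path)
        b.run_until(22.0)
        assert np.max(np.abs(a.y - b.y)) < 1e-9
        for attr in ("blood_volume_L", "vascular_albumin_g"):
            assert getattr(a.physio, attr) == pytest.approx(
                getattr(b.physio, attr), abs=1e-9)
        va, vb = a.physio.vitals(), b.physio.vitals()
        for k in va:
            assert va[k] == pytest.approx(vb[k], abs=1e-9), k


class TestTreatmentRuns:
    @pytest.fixture(scope="class")
    def control_run(self, septic_snapshot):
        eng = load_snapshot(septic_snapshot)
        eng.pretrial_fluid_L = 1.0
        run_refresh_arm(eng, "control")
        return eng

    def test_every_bolus_is_justified(self, control_run):
        """Audit completeness: each decision bolus carries a recorded
        threshold violation at its decision time."""
        checks = [e for e in control_run.audit_log
                  if e["event"] == "protocol_check"]
        assert checks, "no protocol reviews logged"
        n_boluses = 0
        for e in checks:
            for a in e["actions"]:
                if a["type"] == "bolus":
                    n_boluses += 1
                    assert "below goal" in a["reason"]
                    if "UO" in a["reason"]:
                        assert e["UO"] < 0.625
                    else:
                        assert e["SBP"] < 90.0 or e["MAP"] < 65.0
        assert n_boluses >= 1

    def test_fluid_accounting_closes(self, control_run):
        """Cumulative protocol fluid equals the integral of everything the
        physiology actually received, to 1 mL."""
        assert control_run.protocol.cumulative_fluid_L == pytest.approx(
            control_run.physio.cum_infused_L, abs=1e-3)

    def test_antibiotic_clears_blood_pathogen(self, control_run):
        df = control_run.frame()
        pb = df[df.time_h >= 46.0].P_B.values
        assert pb[-1] < 0.25 * pb[0]

    def test_protocol_is_deterministic(self, septic_snapshot, control_run):
        eng = load_snapshot(septic_snapshot)
        eng.pretrial_fluid_L = 1.0
        run_refresh_arm(eng, "control")
        assert eng.protocol.cumulative_fluid_L == \
            control_run.protocol.cumulative_fluid_L
        assert np.array_equal(eng.y, control_run.y)


class TestScenarioFiles:
    def test_yaml_round_trip_and_run(self, tmp_path):
        path = tmp_path / "scn.yaml"
        path.write_text(
            "run:\n  duration_h: 2.0\n"
            "patient:\n  weight_kg: 75\n"
            "infection:\n  severity: Mild\n  mic_mg_L: 16.0\n"
            "actions:\n- time_h: 1.0\n  type: bolus\n  volume_mL: 250\n")
        sc = Scenario.from_yaml(path)
        assert sc.infection.severity == "Mild"
        eng = run_scenario(sc)
        assert eng.t == pytest.approx(2.0)
        assert eng.physio.cum_infused_L == pytest.approx(0.25)

    def test_unknown_keys_reported(self):
        with pytest.raises(ValueError, match="typo_key"):
            Scenario.from_dict({"typo_key": 1})

    def test_unknown_action_type_reported(self):
        sc = Scenario.from_dict({"run": {"duration_h": 1.0},
                                 "actions": [{"time_h": 0.5,
                                              "type": "teleport"}]})
        with pytest.raises(ValueError, match="teleport"):
            run_scenario(sc)


def test_cli_run_and_errors(tmp_path):
    from click.testing import CliRunner
    from sepsim.cli import main

    runner = CliRunner()
    scn = tmp_path / "scn.yaml"
    scn.write_text("run:\n  duration_h: 1.0\n")
    out = tmp_path / "out"
    res = runner.invoke(main, ["run", str(scn), "--out", str(out)])
    assert res.exit_code == 0, res.output
    assert (out / "timeseries.csv").exists()

    bad = tmp_path / "bad.yaml"
    bad.write_text("nonsense_key: 1\n")
    res = runner.invoke(main, ["run", str(bad)])
    assert res.exit_code == 1
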