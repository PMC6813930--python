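"""Physiology-layer tests: Starling exchange, albumin transport, lymph
return, endothelial coupling, hemodynamics, renal output, metabolism,
symptoms, and the conservation laws."""

import numpy as np
import pytest

from sepsim import (PhysioConfig, PhysioModel, SymptomParams, albumin_flux,
                    colloid_osmotic_pressure, endothelial_update,
                    lymph_return, starling_flux, symptom_effects)
from sepsim.physio import CompartmentPair

NO_REST = 0.0125


def make_pair(**kw):
    base = dict(name="test", fraction=1.0, interstitial_volume_L=10.0,
                interstitial_albumin_g=150.0, P_vascular_mmHg=25.0,
                P_interstitial_mmHg=-3.0, R1=2.0, sigma=1.0, PS=1.0,
                R_lymph=1.0, compliance_L_mmHg=10.0)
    base.update(kw)
    return CompartmentPair(**base)


def test_colloid_osmotic_pressure_cubic():
    assert colloid_osmotic_pressure(0.0) == 0.0
    assert colloid_osmotic_pressure(7.0) == pytest.approx(26.607)
    assert colloid_osmotic_pressure(7.5) > colloid_osmotic_pressure(7.0)
    with pytest.raises(ValueError):
        colloid_osmotic_pressure(-1.0)


class TestStarling:
    def test_balanced_forces_give_zero_flux(self):
        pair = make_pair(P_vascular_mmHg=25.0, P_interstitial_mmHg=5.0)
        assert starling_flux(pair, 26.0, 6.0) == pytest.approx(0.0)

    def test_hand_value(self):
        pair = make_pair(P_vascular_mmHg=7.0, P_interstitial_mmHg=-3.0,
                         R1=2.0, sigma=1.0)
        assert starling_flux(pair, 10.0, 2.0) == pytest.approx(1.0)

    def test_halving_resistance_doubles_flux(self):
        a = make_pair(R1=2.0)
        b = make_pair(R1=1.0)
        assert starling_flux(b, 20.0, 6.0) == pytest.approx(
            2 * starling_flux(a, 20.0, 6.0))


class TestAlbuminFlux:
    def test_diffusion_limit(self):
        pair = make_pair(sigma=0.9, PS=1.0)
        expected = pair.PS * (0.045 - 0.015)
        assert albumin_flux(pair, 0.0, 0.045, 0.015) == pytest.approx(
            expected)
        # small-Pe continuity around the analytic limit
        assert albumin_flux(pair, 1e-5, 0.045, 0.015) == pytest.approx(
            expected, rel=1e-3)

    def test_convection_dominated_limit(self):
        pair = make_pair(sigma=0.5, PS=0.01)
        jv = 50.0
        assert albumin_flux(pair, jv, 0.045, 0.015) == pytest.approx(
            jv * 0.5 * 0.045, rel=1e-6)

    def test_no_gradient_no_convection_is_zero(self):
        pair = make_pair(sigma=0.9)
        assert albumin_flux(pair, 0.0, 0.03, 0.03) == 0.0


class TestLymph:
    def test_baseline_return_matches_filtration(self):
        m = PhysioModel()
        flows = lymph_return(m.pairs, m.cfg.vena_cava_pressure_mmHg,
                             m.cfg.lymph_pump_pressure_mmHg)
        total_L_day = sum(flows) * 60 * 24 / 1000.0
        assert total_L_day == pytest.approx(4.0, rel=1e-9)

    def test_check_valve_blocks_backflow(self):
        pair = make_pair(P_interstitial_mmHg=-20.0)
        assert lymph_return([pair], 2.0, 8.0) == [0.0]

    def test_return_monotone_in_interstitial_pressure(self):
        lo = make_pair(P_interstitial_mmHg=-3.0)
        hi = make_pair(P_interstitial_mmHg=-1.0)
        assert lymph_return([hi], 2.0, 8.0)[0] > lymph_return([lo], 2.0,
                                                              8.0)[0]


class TestEndothelialUpdate:
    def test_intact_tissue_leaves_baseline(self):
        pair = make_pair(R1=2.0, sigma=0.95)
        endothelial_update(pair, 1.0, a_R=0.9, a_sigma=0.9)
        assert pair.R1 == 2.0 and pair.sigma == 0.95

    def test_destroyed_tissue_hits_floors(self):
        pair = make_pair(R1=2.0, sigma=0.95)
        endothelial_update(pair, 0.0, a_R=2.0, a_sigma=2.0,
                           floor_R=0.05, floor_sigma=0.05)
        assert pair.R1 == pytest.approx(0.05 * 2.0)
        assert pair.sigma == pytest.approx(0.05 * 0.95)

    def test_linear_rule_hand_value(self):
        pair = make_pair(R1=2.0)
        endothelial_update(pair, 0.5, a_R=0.9, floor_R=0.05)
        assert pair.R1 == pytest.approx(0.55 * 2.0)

    def test_domain_check(self):
        with pytest.raises(ValueError):
            endothelial_update(make_pair(), 1.5)


def test_symptom_effects():
    fever = SymptomParams(E_max=2.5, E_50=0.1, gamma=1.0)
    tachypnea = SymptomParams(E_max=10.0, E_50=0.1, gamma=1.0)
    d_rr, d_t, wbc = symptom_effects(1.0, 0.0, fever, tachypnea, 7000.0,
                                     60000.0)
    assert d_rr == 0.0 and d_t == 0.0 and wbc == 7000.0
    # sigmoid midpoint: damage equal to E_50 gives half the maximum
    d_rr, d_t, _ = symptom_effects(0.9, 0.0, fever, tachypnea, 7000.0, 6e4)
    assert d_rr == pytest.approx(5.0) and d_t == pytest.approx(1.25)
    d_rr, _, wbc = symptom_effects(0.8, 0.1, fever, tachypnea, 7000.0, 6e4)
    assert d_rr == pytest.approx(10.0 * 0.2 / 0.3)
    assert wbc == pytest.approx(13000.0)


class TestBaselineAndConservation:
    def test_72h_homeostasis_within_one_percent(self):
        m = PhysioModel()
        base = m.vitals()
        for _ in range(int(72 / 0.05)):
            m.step(0.05, TI=1.0, NO=NO_REST, N_A=0.0)
        v = m.vitals()
        for key in v:
            if key == "time_h":
                continue
            assert abs(v[key] - base[key]) <= 0.01 * abs(base[key]) + 1e-9, key

    def test_baseline_filtration_anchor(self):
        m = PhysioModel()
        for _ in range(int(24 / 0.05)):
            m.step(0.05, TI=1.0, NO=NO_REST, N_A=0.0)
        assert m.cum_filtration_L == pytest.approx(4.0, rel=1e-6)
        assert m.cum_lymph_L == pytest.approx(m.cum_filtration_L, rel=1e-6)

    def test_fluid_and_albumin_conservation_per_step(self):
        """Total body fluid changes only through external inputs and urine;
        albumin only through infusion — step by step, to 1e-9."""
        m = PhysioModel()
        rng = np.random.default_rng(7)
        ti_path = np.clip(1.0 - np.cumsum(rng.uniform(0, 4e-5, 400)), 0, 1)
        m.add_fluid(0.5, 12.0, retention=0.6)
        for i in range(400):
            f0 = m.total_fluid_L
            a0 = m.total_albumin_g
            ext0 = m.cum_intake_L + m.cum_infused_L - m.cum_urine_L
            ainf0 = m.cum_infused_albumin_g
            if i == 100:
                m.schedule_infusion(250.0, 0.5, type(
                    "C", (), {"albumin_g_per_mL": lambda self: 0.05,
                              "intravascular_retention": 1.0})())
            m.step(0.05, TI=float(ti_path[i]), NO=0.3, N_A=0.05)
            ext = m.cum_intake_L + m.cum_infused_L - m.cum_urine_L
            assert m.total_fluid_L - f0 == pytest.approx(ext - ext0,
                                                         abs=1e-9)
            assert m.total_albumin_g - a0 == pytest.approx(
                m.cum_infused_albumin_g - ainf0, abs=1e-9)


def test_directional_cascade_under_forced_damage():
    """Forcing tissue integrity downward drains blood volume and raises
    heart rate: damage -> leak -> hypovolemia -> reflex tachycardia."""
    m = PhysioModel()
    vols, hrs = [], []
    for i in range(240):  # 12 h, TI ramping 1.0 -> 0.9976
        ti = 1.0 - 0.0002 * (i / 240.0 * 12.0)
        m.step(0.05, TI=ti, NO=NO_REST, N_A=0.0)
        vols.append(m.blood_volume_L)
        hrs.append(m.hemo.HR)
    assert vols[-1] < vols[60] < vols[0]
    assert hrs[-1] > hrs[60]


def test_cop_gradient_controls_flux_direction():
    """As albumin equalizes across the endothelium the osmotic term
    vanishes and the flux approaches the pure hydrostatic term."""
    pair = make_pair(sigma=0.95, R1=2.0)
    hydrostatic = (pair.P_vascular_mmHg - pair.P_interstitial_mmHg) / pair.R1
    cop = colloid_osmotic_pressure(4.5 * 7 / 4.5)
    assert starling_flux(pair, cop, cop) == pytest.approx(hydrostatic)


class TestRenalMetabolic:
    def test_urine_output_baseline_and_floors(self):
        m = PhysioModel()
        cfg = m.cfg
        assert m._urine_output(cfg.MAP_mmHg, cfg.blood_volume_L) == \
            pytest.approx(cfg.urine_output_mL_min)
        assert m._urine_output(cfg.uo_map_floor_mmHg - 5,
                               cfg.blood_volume_L) == 0.0
        # hypovolemic hypotension marker
        assert m._urine_output(65.0, 0.85 * cfg.blood_volume_L) < 0.625

    def test_lactate_stays_at_baseline_with_intact_tissue(self):
        m = PhysioModel()
        for _ in range(200):
            m.step(0.05, TI=1.0, NO=NO_REST, N_A=0.0)
        assert m.renal.lactate_mM == pytest.approx(
            m.cfg.lactate_baseline_mM)

    def test_sustained_damage_gives_monotone_lactate_to_plateau(self):
        # decouple from the circulation: no endothelial response, so the
        # two-stage deficit->lactate filter can be observed in isolation
        m = PhysioModel(PhysioConfig(a_R=0.0, a_sigma=0.0))
        lac = []
        for _ in range(int(300 / 0.05)):
            m.step(0.05, TI=0.5, NO=NO_REST, N_A=0.0)
            lac.append(m.renal.lactate_mM)
        lac = np.array(lac)
        assert np.all(np.diff(lac[:1000]) > 0)          # rising phase
        assert abs(lac[-1] - lac[-100]) < 1e-3 * lac[-1]  # near balance


class TestHemodynamics:
    def test_baseline_is_setpoint(self):
        m = PhysioModel()
        m.step(0.05, TI=1.0, NO=NO_REST, N_A=0.0)
        assert m.hemo.MAP == pytest.approx(m.cfg.MAP_mmHg, abs=1e-6)
        assert m.hemo.SBP == pytest.approx(m.cfg.SBP_mmHg, abs=1e-6)
        assert m.hemo.CO == pytest.approx(m.hemo.HR * m.hemo.SV / 1000.0)

    def test_hypovolemia_triggers_compensation(self):
        m = PhysioModel()
        m.blood_volume_L *= 0.9
        for _ in range(40):
            m.step(0.05, TI=1.0, NO=NO_REST, N_A=0.0)
        assert m.hemo.SVR_control > m._SVR0
        assert m.hemo.HR > m.cfg.HR_per_min
        assert m.hemo.MAP < m.cfg.MAP_mmHg  # partial restoration only

    def test_pressor_raises_map(self):
        a = PhysioModel()
        b = PhysioModel()
        for _ in range(40):
            a.step(0.05, TI=0.995, NO=0.5, N_A=0.1)
            b.step(0.05, TI=0.995, NO=0.5, N_A=0.1, pressor_effect=0.3)
        assert b.hemo.MAP > a.hemo.MAP

    def test_map_between_dbp_and_sbp(self, severe_traj, params):
        m = PhysioModel()
        t = severe_traj.t
        for i in range(int(48 / 0.05)):
            tt = i * 0.05
            m.step(0.05, TI=float(np.interp(tt, t, severe_traj["TI"])),
                   NO=float(np.interp(tt, t, severe_traj.NO)),
                   N_A=float(np.interp(tt, t, severe_traj["N_A"])))
            assert m.hemo.DBP < m.hemo.MAP < m.hemo.SBP
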