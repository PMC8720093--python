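"""Injection-cycle dynamics: needle flow law, tissue force, ODE invariants."""

import math
import warnings

import numpy as np
import pytest

import odrs
from odrs.dynamics import (DeviceState, Phase, derivatives, initial_state,
                           insertion_depth, needle_resistance, simulate_cycle,
                           tissue_force)
from odrs.geometry import ATM_PA, DomainError


class TestNeedleResistance:
    def test_published_needle(self, default_cfg):
        # 8 mu L / (pi r^4), mu = 0.658 cSt * 992.562 kg/m^3 = 6.531e-4 Pa s
        assert needle_resistance(default_cfg) == pytest.approx(1.6426e9, rel=1e-3)

    def test_fourth_power_radius_scaling(self, default_cfg):
        r1 = needle_resistance(default_cfg)
        r2 = needle_resistance(default_cfg.replace(
            needle_inner_diameter=2 * default_cfg.needle_inner_diameter))
        assert r1 / r2 == pytest.approx(16.0, rel=1e-12)

    def test_linear_in_length_and_viscosity(self, default_cfg):
        r1 = needle_resistance(default_cfg)
        assert needle_resistance(default_cfg.replace(
            needle_length=2 * default_cfg.needle_length)) == pytest.approx(
            2 * r1, rel=1e-12)
        assert needle_resistance(default_cfg.replace(
            fluid_viscosity=2 * default_cfg.fluid_viscosity)) == pytest.approx(
            2 * r1, rel=1e-12)


class TestTissueForce:
    def test_zero_before_membrane_contact(self, default_cfg):
        assert tissue_force(0.0, 0.0, default_cfg) == 0.0

    def test_negative_depth_rejected(self, default_cfg):
        with pytest.raises(DomainError):
            tissue_force(-1e-3, 0.0, default_cfg)

    def test_nondecreasing_in_velocity(self, default_cfg):
        for depth in (1e-3, 5e-3, 9e-3):
            forces = [tissue_force(depth, v, default_cfg) for v in (0.0, 0.1, 1.0)]
            assert forces == sorted(forces)

    def test_elastic_term_past_membrane(self, default_cfg):
        s = default_cfg.membrane_standoff_m
        k = default_cfg.tissue_force_params.stiffness
        assert tissue_force(s + 4e-3, 0.0, default_cfg) == pytest.approx(
            k * 4e-3, rel=1e-12)

    def test_peak_force_over_default_cycle_exceeds_1N(self, default_traj):
        assert default_traj.peak_force_n >= 1.0


class TestDerivatives:
    def test_ready_valve_closed_is_equilibrium(self, default_cfg):
        state = initial_state(default_cfg)
        d = derivatives(state, default_cfg, valve_open=False)
        assert all(v == 0.0 for v in d.values())

    def test_infusing_at_atmospheric_gives_no_flow(self, default_cfg):
        cfg = default_cfg
        x = 5e-3
        v_low = cfg.fluid_piston_area_m2 * x + cfg.dead_volume_m3
        state = DeviceState(
            x_main=x, x_needle=cfg.needle_piston_stroke_m,
            pv_lower=ATM_PA * v_low,
            pv_reservoir=ATM_PA * cfg.gas_reservoir_volume_m3,
            phase=Phase.INFUSING)
        d = derivatives(state, cfg, valve_open=False)
        assert d["v_injected"] == 0.0
        assert d["x_main"] == 0.0

    def test_nonfinite_state_reported(self, default_cfg):
        state = initial_state(default_cfg).replace(pv_lower=float("nan"))
        with pytest.raises(odrs.IntegrationError):
            derivatives(state, default_cfg, valve_open=True)

    def test_quasi_static_flow_matches_boyle_closed_form(self, default_cfg):
        """In the massless/springless/open-valve limit, the infusion flow must
        equal (P' - P_atm)/R with P' the Boyle-law pressure of the combined
        gas volume (closed-form oracle, 10 sampled piston positions)."""
        cfg = default_cfg.replace(chassis_mass=1e-6, spring_constant=0.0,
                                  valve_conductance=1e-6)
        resistance = needle_resistance(cfg)
        v_res = cfg.gas_reservoir_volume_m3
        pv_total = cfg.gas_initial_pressure_pa * v_res
        for x in np.linspace(3e-3, 10e-3, 10):
            v_low = cfg.fluid_piston_area_m2 * x + cfg.dead_volume_m3
            # equilibrated split of the shared inventory
            p_eq = pv_total / (v_low + v_res)
            state = DeviceState(
                x_main=float(x), x_needle=cfg.needle_piston_stroke_m,
                pv_lower=p_eq * v_low, pv_reservoir=p_eq * v_res,
                phase=Phase.INFUSING)
            oracle = (p_eq - ATM_PA) / resistance
            d = derivatives(state, cfg, valve_open=True)
            assert d["v_injected"] == pytest.approx(oracle, rel=0.01)


class TestSimulateCycle:
    def test_default_cycle_milestones(self, default_traj, default_cfg):
        assert default_traj.final_state.phase is Phase.DONE
        assert not default_traj.stalled
        assert default_traj.duration <= 1.2
        assert default_traj.injected_ml == pytest.approx(1.0, rel=0.01)
        assert insertion_depth(default_traj.final_state, default_cfg) == \
            pytest.approx(8.0, abs=1e-6)

    def test_no_needle_flow_before_full_insertion(self, default_traj):
        inserting = default_traj.phase == Phase.INSERTING.value
        assert inserting.any()
        assert np.all(default_traj.flow[inserting] == 0.0)

    def test_flow_starts_at_insertion_complete(self, default_traj):
        t_ins = default_traj.event_time("insertion_complete")
        infusing = default_traj.phase == Phase.INFUSING.value
        assert default_traj.t[infusing].min() >= t_ins
        assert default_traj.flow[infusing].max() > 0.0

    def test_gas_inventory_conserved(self, default_traj):
        total = default_traj.pv_lower + default_traj.pv_reservoir
        assert np.ptp(total) / total[0] < 1e-3

    def test_fluid_volume_conserved_during_infusion(self, default_traj, default_cfg):
        mask = default_traj.phase == Phase.INFUSING.value
        dx = default_traj.x_main[mask] - default_traj.x_main[mask][0]
        dv = default_traj.v_injected[mask] - default_traj.v_injected[mask][0]
        expected = default_cfg.fluid_piston_area_m2 * dx
        assert np.allclose(dv, expected, rtol=1e-3, atol=1e-12)

    def test_injected_volume_monotone_and_bounded(self, three_dose_trajs, default_cfg):
        cap_m3 = odrs.reservoir_capacity(default_cfg) * 1e-6
        for traj in three_dose_trajs:
            assert np.all(np.diff(traj.v_injected) >= -1e-15)
            assert traj.v_injected[-1] <= cap_m3

    def test_time_strictly_increasing(self, default_traj):
        assert np.all(np.diff(default_traj.t) > 0)

    def test_three_dose_chain_completes(self, three_dose_trajs, default_cfg):
        for i, traj in enumerate(three_dose_trajs, start=1):
            assert traj.final_state.phase is Phase.DONE, f"dose {i} incomplete"
            assert traj.injected_ml == pytest.approx(1.0, rel=0.01)
        assert three_dose_trajs[-1].final_state.v_injected == pytest.approx(
            3e-6, rel=0.01)

    def test_repeat_doses_skip_insertion(self, three_dose_trajs):
        assert not (three_dose_trajs[1].phase == Phase.INSERTING.value).any()

    def test_halving_conductance_never_shortens_cycle(self, default_cfg):
        durations = []
        cv = default_cfg.valve_conductance
        for factor in (4.0, 2.0, 1.0, 0.5, 0.25):
            traj = simulate_cycle(default_cfg.replace(valve_conductance=cv * factor))
            durations.append(traj.duration)
        assert durations == sorted(durations)

    def test_published_gas_budget_stalls(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", odrs.GasBudgetWarning)
            traj = simulate_cycle(odrs.table1_config())
        assert traj.stalled
        assert traj.final_state.phase is not Phase.DONE


class TestInsertionDepth:
    def test_stowed_needle(self, default_cfg):
        assert insertion_depth(initial_state(default_cfg), default_cfg) == 0.0

    def test_full_stroke_is_needle_length(self, default_cfg):
        state = initial_state(default_cfg).replace(
            x_needle=default_cfg.needle_piston_stroke_m)
        assert insertion_depth(state, default_cfg) == pytest.approx(8.0)

    def test_never_exceeds_needle_length(self, default_cfg, default_traj):
        depths = [insertion_depth(DeviceState(x_needle=float(x)), default_cfg)
                  for x in default_traj.x_needle]
        assert max(depths) <= default_cfg.needle_length + 1e-12
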