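"""Core vessel model: compliance map, drives, delay, integrator contracts."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from autoreg.model import (CMH2O_PA, ExperimentProtocol, SimulatedTrace,
                           StepEvent, VesselState, activation_rhs,
                           build_input_signals, effective_delay,
                           nominal_parameters, radius_rhs, relative_compliance,
                           sample_observation_grid, shear_signal, simulate,
                           steady_state_init, wall_tension)


class TestComplianceMap:
    def test_saturation_and_baseline(self, params):
        # upper asymptote 1 + delta_plus = 11, lower 1 - delta_minus = 0.2
        assert relative_compliance(1e6, params) == pytest.approx(11.0)
        assert relative_compliance(-1e6, params) == pytest.approx(0.2)
        assert relative_compliance(0.0, params) == pytest.approx(1.0)

    def test_central_slope_is_inverse_G_on_both_sides(self, params):
        h = 1e-8
        right = (relative_compliance(h, params) - 1.0) / h
        left = (1.0 - relative_compliance(-h, params)) / h
        assert right == pytest.approx(1.0 / params.G, rel=1e-6)
        assert left == pytest.approx(1.0 / params.G, rel=1e-6)

    @given(u=st.floats(-50, 50))
    @settings(max_examples=200, deadline=None)
    def test_bounds(self, u):
        p = nominal_parameters()
        c = relative_compliance(u, p)
        assert 0.2 - 1e-12 <= c <= 11.0 + 1e-12

    @given(u=st.floats(-0.6, 3.0))
    @settings(max_examples=200, deadline=None)
    def test_strictly_increasing_off_the_asymptotes(self, u):
        p = nominal_parameters()
        assert relative_compliance(u + 1e-4, p) > relative_compliance(u, p)

    def test_nonfinite_input_rejected(self, params):
        with pytest.raises(ValueError):
            relative_compliance(np.nan, params)


class TestDrives:
    def test_wall_tension(self):
        assert wall_tension(0.0, 9000.0) == 0.0
        assert wall_tension(30e-6, 5884.0) == pytest.approx(0.08826, rel=1e-3)
        assert wall_tension(2 * 30e-6, 5884.0) == 2 * wall_tension(30e-6, 5884.0)

    def test_shear_signal(self):
        assert shear_signal(30e-6, 0.0) == 0.0
        assert shear_signal(30e-6, 666.6) == pytest.approx(1.0e-2, rel=1e-3)
        assert shear_signal(30e-6, -100.0) < 0

    def test_activation_rhs_at_reference(self, params):
        st_ = VesselState(R=30e-6, xm=0.0, xe=0.0)
        dxm, _ = activation_rhs(st_, params.T0, params.tau0, params)
        assert dxm == 0.0

    def test_activation_rhs_double_tension(self, params):
        # drive (2T0 - T0)/T0 = 1 amplified by Sm=4 over tau_m=18
        st_ = VesselState(R=30e-6, xm=0.0, xe=0.0)
        dxm, _ = activation_rhs(st_, 2 * params.T0, params.tau0, params)
        assert dxm == pytest.approx(4.0 / 18.0)

    def test_activation_pure_decay_below_reference(self, params):
        st_ = VesselState(R=30e-6, xm=0.7, xe=0.3)
        dxm, dxe = activation_rhs(st_, 0.5 * params.T0, 0.5 * params.tau0, params)
        assert dxm == pytest.approx(-0.7 / params.tau_m)
        assert dxe == pytest.approx(-0.3 / params.tau_e)


class TestEffectiveDelay:
    def test_non_decreasing_shear_passthrough(self, params):
        t = np.arange(0.0, 200.0, 0.2)
        shear = 1e-2 + 1e-5 * t
        for tq in (10.0, 50.0, 150.0):
            assert effective_delay(t, shear, tq, params, pre_history=1e-2) == \
                pytest.approx(float(np.interp(tq, t, shear)))

    def test_step_down_held_for_zeta_seconds(self, params):
        t = np.arange(0.0, 200.0, 0.2)
        shear = np.where(t < 100.0, 1e-2, 4e-3)
        # zeta = 33: the pre-step value persists throughout (100, 133)
        for tq in (101.0, 120.0, 132.5):
            assert effective_delay(t, shear, tq, params) == pytest.approx(1e-2)
        assert effective_delay(t, shear, 140.0, params) == pytest.approx(4e-3)

    def test_zero_delay_is_identity(self, params):
        p0 = dataclasses.replace(params, zeta=0.0)
        t = np.arange(0.0, 50.0, 0.2)
        shear = np.where(t < 20.0, 1e-2, 2e-3)
        assert effective_delay(t, shear, 30.0, p0) == pytest.approx(2e-3)

    def test_missing_pre_history_raises(self, params):
        t = np.arange(0.0, 50.0, 0.2)
        shear = np.full_like(t, 2e-3)  # lookup before t=0 with declining shear
        with pytest.raises(ValueError):
            effective_delay(t, np.where(t < 5, 3e-3, 2e-3), 10.0, params)


class TestRadiusRHS:
    def test_equilibrium(self, params):
        st_ = VesselState(R=30e-6, xm=0.5, xe=0.5)
        assert radius_rhs(st_, 1.0, 0.0, 0.1, 0.1, params) == 0.0

    def test_passive_constriction_sign(self, params):
        st_ = VesselState(R=30e-6, xm=0.5, xe=0.5)
        assert radius_rhs(st_, 1.0, -100.0, 0.0, 0.0, params) < 0


class TestInputSignals:
    def test_no_events_constant(self):
        PI, dP, dPIdt = build_input_signals((), (5000.0, 600.0), 100.0, 2.0)
        assert np.all(PI == 5000.0) and np.all(dP == 600.0)
        assert np.all(dPIdt == 0.0)

    def test_single_step_ramp(self):
        ev = (StepEvent(50.0, "PI", 80 * CMH2O_PA),)
        PI, _, dPIdt = build_input_signals(ev, (60 * CMH2O_PA, 0.0), 100.0, 2.0)
        t = np.arange(0, 100.0 + 0.1, 0.2)
        assert np.interp(49.0, t, PI) == pytest.approx(60 * CMH2O_PA)
        assert np.interp(51.0, t, PI) == pytest.approx(80 * CMH2O_PA)
        assert np.interp(50.0, t, PI) == pytest.approx(70 * CMH2O_PA)
        # integral of the derivative recovers the net change
        assert np.sum(dPIdt) * 0.2 == pytest.approx(20 * CMH2O_PA, rel=1e-9)

    def test_overlapping_ramps_rejected(self):
        ev = (StepEvent(50.0, "PI", 1.0), StepEvent(50.5, "PI", 2.0))
        with pytest.raises(ValueError):
            build_input_signals(ev, (0.0, 0.0), 100.0, 2.0)


class TestSteadyState:
    def test_reference_baseline_gives_zero_activations(self, params):
        prot = ExperimentProtocol(PI_base=2 * params.T0 / 30e-6,
                                  dP_base=2 * params.tau0 / 30e-6, duration=10.0)
        ss = steady_state_init(30e-6, prot, params)
        assert ss.xm == 0.0 and ss.xe == 0.0

    def test_no_flow_baseline_gives_zero_xe(self, params):
        prot = ExperimentProtocol(PI_base=35 * CMH2O_PA, dP_base=0.0,
                                  duration=10.0)
        assert steady_state_init(30e-6, prot, params).xe == 0.0

    def test_invariance_under_constant_inputs(self, params, baseline_protocol):
        ss = steady_state_init(30e-6, baseline_protocol, params)
        tr = simulate(params, ss, baseline_protocol)
        assert np.max(np.abs(tr.R - 30e-6)) / 30e-6 < 1e-10


class TestIntegrator:
    def test_constant_protocol_flat_trace(self, params, baseline_protocol):
        ss = steady_state_init(30e-6, baseline_protocol, params)
        obs = sample_observation_grid(simulate(params, ss, baseline_protocol))
        assert np.allclose(obs.D, 60.0, atol=1e-8)

    def test_dp_step_dilates_with_compliance_rise(self, params, dp_step_protocol):
        ss = steady_state_init(30e-6, dp_step_protocol, params)
        tr = simulate(params, ss, dp_step_protocol)
        obs = sample_observation_grid(tr)
        assert obs.D[-1] > obs.D[0] + 1.0          # net dilation
        assert tr.C_rel[-1] > tr.C_rel[0] + 1.0    # concurrent compliance rise
        assert tr.C_rel.max() < 11.0

    def test_delay_inert_for_non_decreasing_shear(self, params, dp_step_protocol):
        ss = steady_state_init(30e-6, dp_step_protocol, params)
        tr_delay = simulate(params, ss, dp_step_protocol)
        tr_no = simulate(dataclasses.replace(params, zeta=0.0), ss, dp_step_protocol)
        assert np.array_equal(tr_delay.R, tr_no.R)

    def test_halving_dt_changes_trace_below_half_percent(self, params, dp_step_protocol):
        ss = steady_state_init(30e-6, dp_step_protocol, params)
        d1 = sample_observation_grid(simulate(params, ss, dp_step_protocol, dt=0.2)).D
        d2 = sample_observation_grid(simulate(params, ss, dp_step_protocol, dt=0.1)).D
        assert np.max(np.abs(d1 - d2) / d2) < 0.005

    def test_first_order_grid_convergence(self, params, dp_step_protocol):
        ss = steady_state_init(30e-6, dp_step_protocol, params)
        traces = {dt: sample_observation_grid(
            simulate(params, ss, dp_step_protocol, dt=dt)).D
            for dt in (0.2, 0.1, 0.05)}
        e1 = np.linalg.norm(traces[0.2] - traces[0.1])
        e2 = np.linalg.norm(traces[0.1] - traces[0.05])
        order = np.log2(e1 / e2)
        assert 0.8 <= order <= 1.2

    def test_low_pass_step_response_recovers_tau_m(self, params):
        # freeze R and PI: iterate only the xm update with a constant
        # doubled-tension drive, then regress the log residual
        dt, tau = 0.2, params.tau_m
        drive = params.Sm * 1.0                    # ReLU((2T0-T0)/T0) = 1
        n = int(5 * tau / dt)
        x = np.empty(n + 1)
        x[0] = 0.0
        for k in range(n):
            x[k + 1] = (x[k] + dt * (drive / tau)) / (1.0 + dt / tau)
        t = np.arange(n + 1) * dt
        resid = drive - x
        slope = np.polyfit(t, np.log(resid), 1)[0]
        assert abs((-1.0 / slope) - tau) / tau < 0.02


class TestObservationGrid:
    def test_linear_ramp_sampled_exactly(self):
        t = np.arange(0.0, 30.0 + 1e-9, 0.2)
        R = 30e-6 + 1e-8 * t
        tr = SimulatedTrace(times_fine=t, R=R, C_rel=np.ones_like(t),
                            xm=np.zeros_like(t), xe=np.zeros_like(t))
        obs = sample_observation_grid(tr)
        assert np.allclose(obs.D, 2e6 * (30e-6 + 1e-8 * obs.times), rtol=1e-12)
        assert np.allclose(np.diff(obs.times), 1.5)

    def test_empty_trace_rejected(self):
        tr = SimulatedTrace(times_fine=np.array([]), R=np.array([]),
                            C_rel=np.array([]), xm=np.array([]), xe=np.array([]))
        with pytest.raises(ValueError):
            sample_observation_grid(tr)


class TestProtocolValidation:
    def test_event_times_must_increase(self):
        with pytest.raises(ValueError):
            ExperimentProtocol(PI_base=1.0, dP_base=0.0, duration=100.0,
                               events=(StepEvent(50.0, "PI", 1.0),
                                       StepEvent(50.0, "PI", 2.0)))

    def test_event_must_lie_in_duration(self):
        with pytest.raises(ValueError):
            ExperimentProtocol(PI_base=1.0, dP_base=0.0, duration=100.0,
                               events=(StepEvent(150.0, "PI", 1.0),))
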