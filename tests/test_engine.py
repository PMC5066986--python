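"""0D stepping: exact gate integrator, Euler Vm update, stimuli, AP clamp,
latency-controlled stimulus search."""

import math

import numpy as np
import pytest
from numba import njit

from prmodel.engine import (
    NoCaptureError,
    SimulationConfig,
    StimulusSpec,
    Trace,
    find_stimulus_for_latency,
    resting_state,
    simulate_ap_clamp,
    simulate_cell,
    step_cell,
    step_gate_exact,
    upstroke_latency,
)
from prmodel.model_core import (
    CellState,
    potassium_current,
    sodium_current,
    steady_state_gate,
)
PACING_STIM = StimulusSpec(amplitude=-20.0, duration=2.0)


class TestStepGateExact:
    def test_zero_dt_is_identity(self):
        assert step_gate_exact(0.3, 0.9, 2.0, 0.0) == 0.3

    def test_long_step_equilibrates(self):
        assert step_gate_exact(0.3, 0.9, 2.0, 2e6) == pytest.approx(0.9, abs=1e-12)

    def test_hand_value(self):
        assert step_gate_exact(0.2, 0.8, 2.0, 2.0) == pytest.approx(
            0.8 - 0.6 * math.exp(-1.0)
        )

    def test_matches_fine_euler_over_full_ap(self, cell_beat):
        """Exact gate update vs an independent forward-Euler integration of
        the gate ODE at dt = 1e-5 ms along the same Vm trajectory."""

        @njit(cache=True)
        def euler_gates(vm, dt, substeps, e_m, k_m, tau_m, e_h, k_h, tau_h0, d_h):
            m = 1.0 / (1.0 + np.exp((vm[0] - e_m) / k_m))
            h = 1.0 / (1.0 + np.exp((vm[0] - e_h) / k_h))
            out_m = np.empty(vm.size)
            out_h = np.empty(vm.size)
            out_m[0], out_h[0] = m, h
            sub = dt / substeps
            for i in range(vm.size - 1):
                v = vm[i]  # Vm held at its pre-step value, as in the solver
                m_inf = 1.0 / (1.0 + np.exp((v - e_m) / k_m))
                u = (v - e_h) / k_h
                h_inf = 1.0 / (1.0 + np.exp(u))
                tau_h = 2.0 * tau_h0 * np.exp(d_h * u) / (1.0 + np.exp(u))
                for _ in range(substeps):
                    m += sub * (m_inf - m) / tau_m
                    h += sub * (h_inf - h) / tau_h
                out_m[i + 1], out_h[i + 1] = m, h
            return out_m, out_h

        na_em, na_km, na_tm = -41.0, -4.0, 0.12
        m_ref, h_ref = euler_gates(
            cell_beat.vm, cell_beat.dt, 100,
            na_em, na_km, na_tm, -74.9, 4.4, 6.80738, 0.799163,
        )
        assert np.max(np.abs(m_ref - cell_beat.m)) < 1e-4
        assert np.max(np.abs(h_ref - cell_beat.h)) < 1e-4


class TestStepCell:
    def test_resting_fixed_point_is_stationary(self, params, rest_state):
        na, k = params
        st = rest_state
        for _ in range(1000):
            st = step_cell(st, na, k, 0.0, 0.001)
        assert abs(st.vm - rest_state.vm) < 0.001

    def test_single_euler_step_formula(self, params, rest_state):
        na, k = params
        i_na = sodium_current(rest_state, na)
        i_k = potassium_current(rest_state.vm, k)
        st = step_cell(rest_state, na, k, -20.0, 0.001)
        assert st.vm - rest_state.vm == pytest.approx(
            0.001 * (20.0 - i_na - i_k), rel=1e-12
        )


class TestSimulateCell:
    def test_single_beat_characteristics(self, cell_metrics):
        assert cell_metrics.vm_max == pytest.approx(34.0, abs=2.0)
        assert cell_metrics.ina_min == pytest.approx(-233.0, rel=0.05)

    def test_unstimulated_cell_stays_at_rest(self, params, rest_state):
        na, k = params
        quiet = StimulusSpec(amplitude=0.0, duration=1.0, onset=2000.0)
        cfg = SimulationConfig(record_stride=100)
        tr = simulate_cell(rest_state, quiet, cfg, 1000.0, na=na, k=k)
        assert np.max(np.abs(tr.vm - rest_state.vm)) < 0.5

    def test_dt_halving_convergence(self, params, rest_state, cell_metrics):
        from prmodel.analysis import measure_ap

        na, k = params
        cfg = SimulationConfig(dt=0.0005, record_stride=2)
        tr = simulate_cell(rest_state, PACING_STIM, cfg, 400.0, na=na, k=k)
        m = measure_ap(tr, rest_vm=rest_state.vm)
        assert abs(m.apd - cell_metrics.apd) < 0.5
        assert abs(m.vm_max - cell_metrics.vm_max) < 0.2

    def test_gates_stay_in_unit_interval(self, cell_beat):
        for g in (cell_beat.m, cell_beat.h):
            assert g.min() >= 0.0 and g.max() <= 1.0

    def test_trace_grid_is_uniform(self, cell_beat):
        steps = np.diff(cell_beat.times)
        assert steps.max() - steps.min() < 1e-9 * steps.mean() + 1e-12


class TestStimulusSpec:
    def test_pulse_train_timing(self):
        stim = StimulusSpec(amplitude=-20.0, duration=2.0, period=100.0, count=3)
        assert stim.current_at(0.5) == -20.0
        assert stim.current_at(2.5) == 0.0
        assert stim.current_at(101.0) == -20.0
        assert stim.current_at(250.0) == 0.0  # beyond the train

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            StimulusSpec(duration=0.0)
        with pytest.raises(ValueError):
            StimulusSpec(period=1.0, duration=2.0, count=5)


class TestAPClamp:
    def test_constant_clamp_settles_ina(self, params):
        na, k = params
        t = np.arange(0.0, 200.0, 0.001)
        tr = simulate_ap_clamp(
            (t, np.full(t.size, -83.0)), na, SimulationConfig(record_stride=10), k=k
        )
        tail = tr.i_na[-100:]
        assert np.max(np.abs(np.diff(tail))) < 1e-10

    def test_step_clamp_matches_analytic_gates(self, params):
        """For a piecewise-constant waveform the exact integrator must equal
        the closed-form gate solution to round-off."""
        na, k = params
        dt = 0.001
        t = np.arange(0.0, 40.0 + dt / 2, dt)
        vm = np.where(t < 20.0, -83.0, -20.0)
        tr = simulate_ap_clamp((t, vm), na, SimulationConfig(), k=k)
        # analytic value of h at the end of the -20 mV step
        h0 = steady_state_gate(-83.0, na.e_h, na.k_h)
        h_inf = steady_state_gate(-20.0, na.e_h, na.k_h)
        from prmodel.model_core import gate_time_constant

        tau = gate_time_constant(-20.0, na.e_h, na.k_h, na.tau_h0, na.delta_h)
        # the clamp sees vm = -20 from the sample at t = 20.0 onward
        elapsed = tr.times[-1] - 20.0
        h_expect = h_inf + (h0 - h_inf) * math.exp(-elapsed / tau)
        assert tr.h[-1] == pytest.approx(h_expect, abs=1e-9)

    def test_depolarizing_step_produces_transient_ina(self, params):
        na, k = params
        dt = 0.001
        t = np.arange(0.0, 50.0 + dt / 2, dt)
        vm = np.where(t < 25.0, -83.0, -20.0)
        tr = simulate_ap_clamp((t, vm), na, SimulationConfig(record_stride=10), k=k)
        assert tr.i_na.min() < -50.0  # transient inward surge
        assert abs(tr.i_na[-1]) < abs(tr.i_na.min()) / 10  # decays by inactivation

    def test_short_waveform_rejected(self, params):
        na, _ = params
        t = np.arange(0.0, 10.0, 0.001)
        with pytest.raises(ValueError):
            simulate_ap_clamp(
                (t, np.full(t.size, -83.0)), na, SimulationConfig(), t_end=20.0
            )


class TestLatencySearch:
    def test_contract_from_rest(self, params, rest_state):
        na, k = params
        cfg = SimulationConfig()
        amp = find_stimulus_for_latency(
            1.0, 2.0, rest_state, cfg, na=na, k=k, tol=0.05
        )
        tr = simulate_cell(
            rest_state, StimulusSpec(amplitude=amp, duration=2.0), cfg, 30.0,
            na=na, k=k,
        )
        assert 0.95 <= upstroke_latency(tr, 0.0) <= 1.05

    def test_latency_decreases_with_amplitude(self, params, rest_state):
        na, k = params
        cfg = SimulationConfig()
        lats = []
        for amp in (-25.0, -50.0, -100.0, -200.0):
            tr = simulate_cell(
                rest_state, StimulusSpec(amplitude=amp, duration=2.0), cfg, 30.0,
                na=na, k=k,
            )
            lats.append(upstroke_latency(tr, 0.0))
        assert all(a > b for a, b in zip(lats, lats[1:]))

    def test_subthreshold_bracket_raises(self, params, rest_state):
        na, k = params
        with pytest.raises(NoCaptureError):
            find_stimulus_for_latency(
                1.0, 2.0, rest_state, SimulationConfig(), na=na, k=k,
                bracket=(-0.5, -5.0),
            )


def test_trace_csv_round_trip(tmp_path, cell_beat):
    sub = cell_beat.window(0.0, 5.0)
    path = tmp_path / "trace.csv"
    sub.to_csv(path)
    back = Trace.from_csv(path)
    np.testing.assert_allclose(back.vm, sub.vm, rtol=0, atol=1e-12)
    np.testing.assert_allclose(back.i_na, sub.i_na, rtol=0, atol=1e-12)
    header = path.read_text().splitlines()[0]
    assert header == "time_ms,vm_mV,m,h,ina_uA_per_uF,ik_uA_per_uF,istim_uA_per_uF"
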