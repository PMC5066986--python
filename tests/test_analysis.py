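"""Measurement operators: AP metrics, cycle lengths, tip tracking and
episode classification, exercised on constructed inputs with known answers."""

import numpy as np
import pytest

from prmodel.analysis import (
    InsufficientDataError,
    TipTrajectory,
    classify_episode,
    dominant_cycle_length,
    dominant_frequency,
    measure_ap,
    tip_counts,
    track_tips,
    trajectory_extent,
)
from prmodel.engine import NoCaptureError, Trace


def _triangle_ap(dt=0.05, t_rise=10.0, t_fall=110.0, t_end=200.0,
                 rest=-83.0, peak=30.0):
    """Linear upstroke at t_rise, linear repolarization crossing rest+5 at
    t_fall, exactly as constructed."""
    t = np.arange(0.0, t_end + dt / 2, dt)
    vm = np.full(t.size, rest)
    up = (t >= t_rise) & (t < t_rise + 1.0)
    vm[up] = rest + (peak - rest) * (t[up] - t_rise) / 1.0
    down = (t >= t_rise + 1.0) & (t <= t_fall)
    # descend so that vm hits rest+5 exactly at t_fall
    vm[down] = peak + (rest + 5.0 - peak) * (t[down] - t_rise - 1.0) / (
        t_fall - t_rise - 1.0
    )
    vm[t > t_fall] = rest + 4.9
    return Trace(times=t, vm=vm)


class TestMeasureAP:
    def test_constructed_triangle_apd(self):
        tr = _triangle_ap()
        m = measure_ap(tr, rest_vm=-83.0)
        # upstroke detected within the 1 ms linear rise; recovery at 110 ms
        assert m.apd == pytest.approx(100.0, abs=1.5)
        assert m.vm_max == pytest.approx(30.0, abs=0.1)

    def test_no_ap_raises(self):
        t = np.arange(0.0, 100.0, 0.05)
        with pytest.raises(NoCaptureError):
            measure_ap(Trace(times=t, vm=np.full(t.size, -83.0)), rest_vm=-83.0)

    def test_translation_invariance(self):
        tr = _triangle_ap()
        shifted = Trace(times=tr.times + 37.0, vm=tr.vm.copy())
        a = measure_ap(tr, rest_vm=-83.0).apd
        b = measure_ap(shifted, rest_vm=-83.0).apd
        assert a == pytest.approx(b, abs=0.5)

    def test_resampling_invariance(self, cell_beat, rest_state):
        m1 = measure_ap(cell_beat, rest_vm=rest_state.vm)
        coarse = Trace(
            times=cell_beat.times[::2], vm=cell_beat.vm[::2],
            m=cell_beat.m[::2], h=cell_beat.h[::2],
            i_na=cell_beat.i_na[::2], i_k=cell_beat.i_k[::2],
            i_stim=cell_beat.i_stim[::2],
        )
        m2 = measure_ap(coarse, rest_vm=rest_state.vm)
        assert abs(m1.apd - m2.apd) < 0.5

    def test_stimulus_artifact_excluded_from_dvdt(self, cell_beat, rest_state):
        m = measure_ap(cell_beat, rest_vm=rest_state.vm)
        # the upstroke (after the 2 ms pulse) is faster than the pulse ramp
        assert m.upstroke_time > 2.0
        assert m.dvdt_max > 100.0


class TestCycleLength:
    def _pulse_train(self, period=100.0, n=6, dt=0.1):
        t = np.arange(0.0, period * n, dt)
        phase = t % period
        vm = np.where(phase < 30.0, 20.0, -83.0)
        # smooth the edges slightly so gradients are finite
        return Trace(times=t, vm=vm)

    def test_periodic_train_recovers_period(self):
        tr = self._pulse_train(period=100.0)
        assert dominant_cycle_length(tr) == pytest.approx(100.0, abs=0.2)

    def test_too_few_upstrokes_raises(self):
        tr = self._pulse_train(period=100.0, n=2)
        with pytest.raises(InsufficientDataError):
            dominant_cycle_length(tr)

    def test_dominant_frequency_consistent_with_cycle_length(self):
        tr = self._pulse_train(period=125.0, n=16)
        f = dominant_frequency(tr)
        assert f == pytest.approx(1000.0 / 125.0, rel=0.1)


def _rotating_spiral_frames(
    nx=80, ny=80, dx=0.05, n_frames=40, dt_frame=1.0, period=20.0,
    center=None,
):
    """Synthetic rigidly rotating spiral: vm = rest + A*(1 + cos(theta -
    r/lam - omega*t)); its phase singularity sits at the center."""
    if center is None:
        center = ((nx - 1) * dx / 2, (ny - 1) * dx / 2)
    x = np.arange(nx) * dx
    y = np.arange(ny) * dx
    X, Y = np.meshgrid(x, y)
    R = np.hypot(X - center[0], Y - center[1])
    TH = np.arctan2(Y - center[1], X - center[0])
    omega = 2 * np.pi / period
    times = np.arange(n_frames) * dt_frame
    frames = np.empty((n_frames, ny, nx), dtype=np.float32)
    for i, t in enumerate(times):
        frames[i] = -83.0 + 56.5 * (1.0 + np.cos(TH - 2 * np.pi * R / 2.0 - omega * t))
    return frames, times


class TestTipTracking:
    def test_plane_wave_has_no_tips(self):
        t = np.arange(30.0)
        x = np.arange(60) * 0.05
        frames = np.empty((30, 40, 60), dtype=np.float32)
        for i, ti in enumerate(t):
            frames[i] = -83.0 + 110.0 / (
                1.0 + np.exp(-(ti * 0.1 - x[None, :]) * 8.0)
            )
        assert track_tips(frames, t, 0.05) == []

    def test_rotating_spiral_yields_one_persistent_tip(self):
        frames, times = _rotating_spiral_frames()
        tips = track_tips(frames, times, 0.05)
        main = max(tips, key=lambda tr: tr.duration)
        assert main.duration >= 0.9 * (times[-1] - times[0])
        # tip stays near the rotation center
        cx = (80 - 1) * 0.05 / 2
        assert np.hypot(
            np.mean(main.x) - cx, np.mean(main.y) - cx
        ) < 0.3
        assert main.rotations == pytest.approx(39.0 / 20.0, abs=0.5)

    def test_mirrored_snapshots_give_mirrored_tips(self):
        frames, times = _rotating_spiral_frames(center=(1.3, 2.4))
        tips = track_tips(frames, times, 0.05)
        tips_m = track_tips(frames[:, :, ::-1], times, 0.05)
        main = max(tips, key=lambda tr: tr.duration)
        main_m = max(tips_m, key=lambda tr: tr.duration)
        width = (80 - 1) * 0.05
        assert np.mean(main_m.x) == pytest.approx(width - np.mean(main.x), abs=0.1)
        assert np.mean(main_m.y) == pytest.approx(np.mean(main.y), abs=0.1)


class TestClassification:
    def _quiet_trace(self, t_end=500.0):
        t = np.arange(0.0, t_end, 1.0)
        return Trace(times=t, vm=np.full(t.size, -83.0))

    def test_quiescent_sheet_is_terminated(self):
        ft = np.arange(0.0, 500.0, 1.0)
        cls = classify_episode([], self._quiet_trace(), 500.0, ft, rest_vm=-83.0)
        assert cls == "terminated"

    def test_persistent_single_tip_is_sustained(self):
        ft = np.arange(0.0, 500.0, 1.0)
        tip = TipTrajectory(times=list(ft), x=[1.0] * ft.size, y=[1.0] * ft.size)
        t = np.arange(0.0, 500.0, 1.0)
        vm = -83.0 + 100.0 * (np.sin(2 * np.pi * t / 150.0) > 0)
        cls = classify_episode([tip], Trace(times=t, vm=vm), 500.0, ft, rest_vm=-83.0)
        assert cls == "sustained"

    def test_many_simultaneous_tips_is_breakup(self):
        ft = np.arange(0.0, 500.0, 1.0)
        tips = [
            TipTrajectory(times=list(ft), x=[i * 0.5] * ft.size, y=[1.0] * ft.size)
            for i in range(4)
        ]
        t = np.arange(0.0, 500.0, 1.0)
        vm = -83.0 + 100.0 * (np.sin(2 * np.pi * t / 30.0) > 0)
        cls = classify_episode(tips, Trace(times=t, vm=vm), 500.0, ft, rest_vm=-83.0)
        assert cls == "breakup"

    def test_tip_counts(self):
        ft = np.array([0.0, 1.0, 2.0, 3.0])
        tips = [
            TipTrajectory(times=[0.0, 1.0], x=[0, 0], y=[0, 0]),
            TipTrajectory(times=[1.0, 2.0, 3.0], x=[0, 0, 0], y=[0, 0, 0]),
        ]
        assert list(tip_counts(tips, ft)) == [1, 2, 1, 1]


class TestTrajectoryExtent:
    def test_circle_extent_is_diameter(self):
        t = np.linspace(0.0, 100.0, 400)
        ang = 2 * np.pi * t / 50.0  # two rotations
        tip = TipTrajectory(
            times=list(t), x=list(2.0 + np.cos(ang)), y=list(2.0 + np.sin(ang))
        )
        assert trajectory_extent(tip) == pytest.approx(2.0, rel=0.02)

    def test_insufficient_rotation_raises(self):
        t = np.linspace(0.0, 10.0, 50)
        ang = 2 * np.pi * t / 100.0  # a tenth of a rotation
        tip = TipTrajectory(
            times=list(t), x=list(np.cos(ang)), y=list(np.sin(ang))
        )
        with pytest.raises(InsufficientDataError):
            trajectory_extent(tip)
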