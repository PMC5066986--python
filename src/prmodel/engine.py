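"""0D time stepping: exact gate integration, forward-Euler Vm, stimuli, AP clamp.

The integration scheme is first-order Lie splitting: at each step the gates
are advanced exactly (Rush–Larsen) using y_inf and tau evaluated at the
pre-step Vm, and Vm is advanced by forward Euler with currents evaluated at
the pre-step state.  The default dt of 0.001 ms is conservative; the
constant activation time constant gives the model a well-defined fastest
time scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels
from .model_core import (
    CellState,
    PotassiumParams,
    SodiumParams,
    potassium_current,
    resting_potential,
    sodium_current,
    steady_state_gate,
    gate_time_constant,
)

__all__ = [
    "StimulusSpec",
    "SimulationConfig",
    "Trace",
    "NumericalBlowupError",
    "NoCaptureError",
    "step_gate_exact",
    "step_cell",
    "simulate_cell",
    "simulate_ap_clamp",
    "resting_state",
    "find_stimulus_for_latency",
    "ionic_rate",
    "upstroke_latency",
]

TRACE_COLUMNS = (
    "time_ms", "vm_mV", "m", "h",
    "ina_uA_per_uF", "ik_uA_per_uF", "istim_uA_per_uF",
)


class NumericalBlowupError(RuntimeError):
    """The solver produced a non-finite or runaway membrane potential."""


class NoCaptureError(RuntimeError):
    """No stimulus amplitude in the search bracket elicited an action potential."""


@dataclass(frozen=True)
class StimulusSpec:
    """Pulse-train stimulus.

    ``amplitude`` is in uA/uF with the electrophysiology sign convention:
    a *negative* amplitude depolarizes (it is subtracted from the membrane
    balance alongside the ionic currents).  ``period`` is the basic cycle
    length (BCL) for ``count`` > 1.
    """

    amplitude: float = -20.0
    duration: float = 2.0
    period: float = 1000.0
    count: int = 1
    onset: float = 0.0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("stimulus duration must be > 0")
        if self.count < 1:
            raise ValueError("stimulus count must be >= 1")
        if self.count > 1 and self.period <= self.duration:
            raise ValueError("period must exceed duration for pulse trains")

    def current_at(self, t: float) -> float:
        """Stimulus current at time t (uA/uF)."""
        return _kernels._stim_at(
            t, self.amplitude, self.duration, self.period, self.count, self.onset
        )


@dataclass(frozen=True)
class SimulationConfig:
    """Numerical settings: time step (ms), recording stride, capacitance (uF/cm^2)."""

    dt: float = 0.001
    record_stride: int = 1
    cm: float = 1.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.record_stride < 1:
            raise ValueError("record_stride must be >= 1")


@dataclass
class Trace:
    """Uniformly sampled time series of the cell state and currents."""

    times: np.ndarray
    vm: np.ndarray
    m: np.ndarray = field(default=None)  # type: ignore[assignment]
    h: np.ndarray = field(default=None)  # type: ignore[assignment]
    i_na: np.ndarray = field(default=None)  # type: ignore[assignment]
    i_k: np.ndarray = field(default=None)  # type: ignore[assignment]
    i_stim: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.vm = np.asarray(self.vm, dtype=float)
        n = self.times.size
        if self.vm.size != n:
            raise ValueError("times and vm must have equal length")
        for name in ("m", "h", "i_na", "i_k", "i_stim"):
            arr = getattr(self, name)
            if arr is None:
                setattr(self, name, np.zeros(n))
            else:
                arr = np.asarray(arr, dtype=float)
                if arr.size != n:
                    raise ValueError(f"{name} length mismatch")
                setattr(self, name, arr)
        if n >= 2:
            steps = np.diff(self.times)
            if steps.min() <= 0:
                raise ValueError("times must be strictly increasing")
            if (steps.max() - steps.min()) > 1e-9 * max(steps.mean(), 1e-300) + 1e-12:
                raise ValueError("times must be uniformly spaced")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0]) if self.times.size > 1 else 0.0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_ms": self.times,
                "vm_mV": self.vm,
                "m": self.m,
                "h": self.h,
                "ina_uA_per_uF": self.i_na,
                "ik_uA_per_uF": self.i_k,
                "istim_uA_per_uF": self.i_stim,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Trace":
        df = pd.read_csv(path)
        return cls(
            times=df["time_ms"].to_numpy(),
            vm=df["vm_mV"].to_numpy(),
            m=df["m"].to_numpy(),
            h=df["h"].to_numpy(),
            i_na=df["ina_uA_per_uF"].to_numpy(),
            i_k=df["ik_uA_per_uF"].to_numpy(),
            i_stim=df["istim_uA_per_uF"].to_numpy(),
        )

    def window(self, t0: float, t1: float) -> "Trace":
        """Sub-trace on [t0, t1]."""
        sel = (self.times >= t0) & (self.times <= t1)
        return Trace(
            times=self.times[sel], vm=self.vm[sel], m=self.m[sel], h=self.h[sel],
            i_na=self.i_na[sel], i_k=self.i_k[sel], i_stim=self.i_stim[sel],
        )


def _na_args(na: SodiumParams) -> tuple:
    return (
        na.g_na, na.e_na, na.e_m, na.k_m, na.tau_m,
        na.e_h, na.k_h, na.tau_h0, na.delta_h,
    )


def step_gate_exact(y: float, y_inf: float, tau: float, dt: float) -> float:
    """Exact one-step gate solution y_inf + (y - y_inf) * exp(-dt/tau)."""
    if tau <= 0:
        raise ValueError("tau must be > 0")
    if dt < 0:
        raise ValueError("dt must be >= 0")
    if dt == 0:
        return y
    return y_inf + (y - y_inf) * math.exp(-dt / tau)


def step_cell(
    state: CellState,
    na: SodiumParams,
    k: PotassiumParams,
    i_stim: float,
    dt: float,
    cm: float = 1.0,
) -> CellState:
    """Advance the cell one step; gates and Vm from the pre-step state."""
    i_na = sodium_current(state, na)
    i_k = potassium_current(state.vm, k)
    vm_new = state.vm - dt * (i_na + i_k + i_stim) / cm
    for name, val in (("vm", vm_new), ("i_na", i_na), ("i_k", i_k)):
        if not math.isfinite(val):
            raise NumericalBlowupError(f"non-finite {name} in step_cell")
    m_inf = steady_state_gate(state.vm, na.e_m, na.k_m)
    h_inf = steady_state_gate(state.vm, na.e_h, na.k_h)
    tau_h = gate_time_constant(state.vm, na.e_h, na.k_h, na.tau_h0, na.delta_h)
    m_new = min(1.0, max(0.0, step_gate_exact(state.m, m_inf, na.tau_m, dt)))
    h_new = min(1.0, max(0.0, step_gate_exact(state.h, h_inf, tau_h, dt)))
    return CellState(vm=vm_new, m=m_new, h=h_new)


def simulate_cell(
    initial: CellState,
    stim: StimulusSpec,
    cfg: SimulationConfig,
    t_end: float,
    na: SodiumParams | None = None,
    k: PotassiumParams | None = None,
    use_m_inf: bool = False,
) -> Trace:
    """Run a stimulated single cell for ``t_end`` ms and return the Trace."""
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    na = na if na is not None else SodiumParams()
    k = k if k is not None else PotassiumParams()
    n_steps = int(round(t_end / cfg.dt))
    out = _kernels.cell_run(
        initial.vm, initial.m, initial.h,
        *_na_args(na), k.g_k, k.b, k.e_k, cfg.cm,
        stim.amplitude, stim.duration, stim.period, stim.count, stim.onset,
        cfg.dt, n_steps, cfg.record_stride, use_m_inf,
    )
    status, t, vm, m, h, ina, ik, istim = out
    if status != _kernels.STATUS_OK:
        raise NumericalBlowupError(
            f"vm left the physical range near t = {t[-1]:.3f} ms"
        )
    return Trace(times=t, vm=vm, m=m, h=h, i_na=ina, i_k=ik, i_stim=istim)


def simulate_ap_clamp(
    waveform: Trace | tuple[np.ndarray, np.ndarray],
    na: SodiumParams,
    cfg: SimulationConfig,
    k: PotassiumParams | None = None,
    t_end: float | None = None,
    initial_gates: tuple[float, float] | None = None,
    use_m_inf: bool = False,
) -> Trace:
    """AP clamp: Vm prescribed by ``waveform``, gates evolve, INa recorded.

    The waveform (a Trace or a ``(times, vm)`` pair) is linearly
    interpolated onto the cfg.dt grid; there is no feedback from the
    currents to Vm.
    """
    if isinstance(waveform, Trace):
        wt, wv = waveform.times, waveform.vm
    else:
        wt, wv = np.asarray(waveform[0], float), np.asarray(waveform[1], float)
    if t_end is None:
        t_end = float(wt[-1] - wt[0])
    if t_end > wt[-1] - wt[0] + 1e-9:
        raise ValueError("waveform shorter than the requested simulation")
    k = k if k is not None else PotassiumParams()
    n_steps = int(round(t_end / cfg.dt))
    grid = wt[0] + np.arange(n_steps + 1) * cfg.dt
    vm_wave = np.interp(grid, wt, wv)
    if initial_gates is None:
        m0 = steady_state_gate(vm_wave[0], na.e_m, na.k_m)
        h0 = steady_state_gate(vm_wave[0], na.e_h, na.k_h)
    else:
        m0, h0 = initial_gates
    t, vm, m, h, ina, ik = _kernels.clamp_run(
        vm_wave, m0, h0, *_na_args(na), k.g_k, k.b, k.e_k,
        cfg.dt, cfg.record_stride, use_m_inf,
    )
    return Trace(times=t, vm=vm, m=m, h=h, i_na=ina, i_k=ik)


def resting_state(
    na: SodiumParams | None = None,
    k: PotassiumParams | None = None,
    settle_ms: float = 1000.0,
    cfg: SimulationConfig | None = None,
    use_m_inf: bool = False,
) -> CellState:
    """Settled resting state: start at the net-current root, relax unstimulated."""
    na = na if na is not None else SodiumParams()
    k = k if k is not None else PotassiumParams()
    cfg = cfg if cfg is not None else SimulationConfig(record_stride=1000)
    vr = resting_potential(na, k)
    st = CellState(
        vm=vr,
        m=steady_state_gate(vr, na.e_m, na.k_m),
        h=steady_state_gate(vr, na.e_h, na.k_h),
    )
    if settle_ms > 0:
        quiet = StimulusSpec(amplitude=0.0, duration=1.0, count=1, onset=2 * settle_ms)
        tr = simulate_cell(st, quiet, cfg, settle_ms, na=na, k=k, use_m_inf=use_m_inf)
        st = CellState(vm=float(tr.vm[-1]), m=float(tr.m[-1]), h=float(tr.h[-1]))
    return st


def ionic_rate(trace: Trace, cm: float = 1.0) -> np.ndarray:
    """Stimulus-free depolarization rate −(INa + IK)/Cm (mV/ms).

    Equals dVm/dt wherever the stimulus is off, and excludes the stimulus
    artifact during the pulse; used for latency detection.
    """
    return -(trace.i_na + trace.i_k) / cm


def upstroke_latency(trace: Trace, onset: float, cm: float = 1.0) -> float:
    """Latency from stimulus onset to the peak stimulus-free depolarization rate."""
    rate = ionic_rate(trace, cm)
    sel = trace.times >= onset
    idx = np.flatnonzero(sel)
    k_max = idx[np.argmax(rate[idx])]
    return float(trace.times[k_max] - onset)


def find_stimulus_for_latency(
    target_latency: float,
    duration: float,
    state_at_stim: CellState,
    cfg: SimulationConfig,
    na: SodiumParams | None = None,
    k: PotassiumParams | None = None,
    tol: float = 0.05,
    bracket: tuple[float, float] = (-2.0, -3000.0),
    capture_rise_mv: float = 40.0,
    t_probe: float = 30.0,
    use_m_inf: bool = False,
) -> float:
    """Amplitude (uA/uF, negative) whose upstroke latency matches the target.

    Latency decreases monotonically with stimulus strength over the
    captured range, so the amplitude is found by bisection between a weak
    (long-latency) and a strong (short-latency) bracket end.

    Raises
    ------
    NoCaptureError
        If no amplitude in the bracket elicits an action potential
        (membrane rise below ``capture_rise_mv``).
    """
    if target_latency <= 0:
        raise ValueError("target_latency must be > 0")
    na = na if na is not None else SodiumParams()
    k = k if k is not None else PotassiumParams()
    probe_cfg = SimulationConfig(dt=cfg.dt, record_stride=1, cm=cfg.cm)

    def latency_of(amp: float) -> float | None:
        stim = StimulusSpec(amplitude=amp, duration=duration, count=1, onset=0.0)
        try:
            tr = simulate_cell(
                state_at_stim, stim, probe_cfg, t_probe, na=na, k=k,
                use_m_inf=use_m_inf,
            )
        except NumericalBlowupError:
            # the pulse overdrives Vm out of the physical range: faster
            # than any latency target, so treat as zero latency
            return 0.0
        if tr.vm.max() - state_at_stim.vm < capture_rise_mv:
            return None
        return upstroke_latency(tr, onset=0.0, cm=cfg.cm)

    weak, strong = bracket
    lat_strong = latency_of(strong)
    if lat_strong is None:
        raise NoCaptureError("no capture even at the strong end of the bracket")
    if lat_strong > target_latency + tol:
        raise NoCaptureError(
            f"latency {lat_strong:.3f} ms at the strongest amplitude exceeds target"
        )
    # grow the weak end until it captures with latency above target
    amp_lo = weak  # weak (long latency) end
    lat_lo = latency_of(amp_lo)
    n_grow = 0
    while (lat_lo is None or lat_lo < target_latency) and n_grow < 40:
        if lat_lo is not None and lat_lo < target_latency - tol:
            # already faster than target at the weakest capture: relax toward 0
            amp_lo *= 0.5
        else:
            amp_lo *= 1.5 if lat_lo is None else 1.0
        if abs(amp_lo) >= abs(strong) or abs(amp_lo) < 1e-3:
            break
        lat_lo = latency_of(amp_lo)
        n_grow += 1
    if lat_lo is None:
        raise NoCaptureError("no captured amplitude with latency above target")
    lo, hi = amp_lo, strong  # |lo| < |hi|; latency(lo) >= latency(hi)
    for _ in range(60):
        mid = -math.sqrt(lo * hi)  # geometric bisection on magnitude
        lat = latency_of(mid)
        if lat is None or lat > target_latency:
            lo = mid
        else:
            hi = mid
            if target_latency - tol <= lat <= target_latency + tol:
                return mid
        if abs(hi - lo) < 1e-6:
            break
    lat_final = latency_of(hi)
    if lat_final is not None and abs(lat_final - target_latency) <= tol:
        return hi
    raise NoCaptureError("bisection failed to meet the latency tolerance")
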