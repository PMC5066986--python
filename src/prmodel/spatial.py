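"""1D cable and 2D sheet monodomain solvers.

Both use explicit finite differences: central (5-point in 2D) Laplacian,
no-flux boundaries by ghost-node mirroring, forward-Euler Vm and exact gate
updates (the same scheme as the 0D engine).  Cable waves are initiated by
holding a 1 mm end segment at 0 mV for 2 ms — initiating with a voltage
clamp rather than a large current avoids the unphysiologically long APD
the model produces when driven to unphysiologically high Vm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .engine import NumericalBlowupError, SimulationConfig, Trace
from .model_core import (
    PotassiumParams,
    SodiumParams,
    resting_potential,
    steady_state_gate,
)

__all__ = [
    "CableConfig",
    "TissueConfig",
    "FieldState",
    "FieldStimulus",
    "TissueResult",
    "NoPropagationError",
    "simulate_cable",
    "measure_cv",
    "simulate_tissue2d",
    "initiate_spiral_cross_field",
    "plane_wave_plan",
    "export_snapshots",
]


class NoPropagationError(RuntimeError):
    """No propagated upstroke was detected (a signal, not a solver failure)."""


@dataclass(frozen=True)
class CableConfig:
    """1D cable discretization.

    Defaults: 4 cm fiber, dx = 0.01 cm, D = 0.001 cm^2/ms, dt = 0.001 ms.
    ``record_positions`` default to 25%, 50%, 75% and 90% of the length.
    """

    length: float = 4.0
    dx: float = 0.01
    diffusion: float = 0.001
    dt: float = 0.001
    record_positions: tuple[float, ...] | None = None
    record_stride: int = 10
    clamp_length: float = 0.1  # cm held at clamp_vm to launch the wave
    clamp_vm: float = 0.0
    clamp_duration: float = 2.0  # ms

    def __post_init__(self) -> None:
        n_seg = self.length / self.dx
        if abs(n_seg - round(n_seg)) > 1e-9 or round(n_seg) < 2:
            raise ValueError("length/dx must be an integer node count >= 3")
        if self.dt * self.diffusion / self.dx**2 > 0.5 + 1e-12:
            raise ValueError(
                "explicit stability violated: dt*D/dx^2 must be <= 0.5"
            )

    @property
    def n_nodes(self) -> int:
        return int(round(self.length / self.dx)) + 1

    def positions(self) -> tuple[float, ...]:
        if self.record_positions is not None:
            return self.record_positions
        L = self.length
        return (0.25 * L, 0.5 * L, 0.75 * L, 0.9 * L)


@dataclass(frozen=True)
class TissueConfig:
    """2D sheet discretization.

    Defaults follow the tissue-scale settings: 4.8 x 4.8 cm, dx = 0.01 cm,
    dt = 0.02 ms, D = 0.001 cm^2/ms (i.e. 1 cm^2/s).  ``snapshot_interval``
    is in ms; set to 0 to disable snapshot recording.
    """

    width: float = 4.8
    height: float = 4.8
    dx: float = 0.01
    diffusion: float = 0.001
    dt: float = 0.02
    snapshot_interval: float = 1.0
    record_stride: int = 25

    def __post_init__(self) -> None:
        if self.dt * self.diffusion * 4.0 / self.dx**2 > 1.0 + 1e-12:
            raise ValueError(
                "2D explicit stability violated: 4*dt*D/dx^2 must be <= 1"
            )

    @property
    def shape(self) -> tuple[int, int]:
        ny = int(round(self.height / self.dx)) + 1
        nx = int(round(self.width / self.dx)) + 1
        return ny, nx


@dataclass
class FieldState:
    """Vm and gate fields over the 1D or 2D grid."""

    vm: np.ndarray
    m: np.ndarray
    h: np.ndarray


@dataclass(frozen=True)
class FieldStimulus:
    """Rectangular current stimulus: region (x0, x1, y0, y1) in cm."""

    region: tuple[float, float, float, float]
    amplitude: float  # uA/uF, negative depolarizes
    start: float  # ms
    duration: float  # ms


@dataclass
class TissueResult:
    """Site traces, snapshots and bookkeeping from a 2D run."""

    site_traces: list[Trace]
    site_positions: list[tuple[float, float]]
    snapshots: np.ndarray  # (n_snap, ny, nx) float32
    snapshot_times: np.ndarray
    cfg: TissueConfig
    rest_vm: float


def _resting_fields(na: SodiumParams, k: PotassiumParams, shape) -> FieldState:
    vr = resting_potential(na, k)
    vm = np.full(shape, vr, dtype=float)
    m = np.full(shape, steady_state_gate(vr, na.e_m, na.k_m), dtype=float)
    h = np.full(shape, steady_state_gate(vr, na.e_h, na.k_h), dtype=float)
    return FieldState(vm=vm, m=m, h=h)


def simulate_cable(
    na: SodiumParams,
    k: PotassiumParams,
    cfg: CableConfig,
    t_end: float,
    cm: float = 1.0,
    use_m_inf: bool = False,
    initiate: bool = True,
    initial: FieldState | None = None,
) -> dict[float, Trace]:
    """Run the cable and return {position_cm: Trace} at the recording sites.

    ``initiate=False`` suppresses the end clamp (e.g. for quiescence tests).
    Traces carry Vm and INa; gates and IK are not recorded along the fiber.
    """
    n = cfg.n_nodes
    state = initial if initial is not None else _resting_fields(na, k, (n,))
    positions = cfg.positions()
    rec_idx = np.asarray(
        [int(round(p / cfg.dx)) for p in positions], dtype=np.int64
    )
    if (rec_idx < 0).any() or (rec_idx >= n).any():
        raise ValueError("record position outside the cable")
    n_steps = int(round(t_end / cfg.dt))
    clamp_n = int(round(cfg.clamp_length / cfg.dx)) if initiate else 0
    status, t, vm_rec, ina_rec = _kernels.cable_run(
        state.vm, state.m, state.h,
        na.g_na, na.e_na, na.e_m, na.k_m, na.tau_m,
        na.e_h, na.k_h, na.tau_h0, na.delta_h,
        k.g_k, k.b, k.e_k, cm,
        cfg.diffusion, cfg.dx, cfg.dt, n_steps,
        clamp_n, cfg.clamp_vm, cfg.clamp_duration if initiate else -1.0,
        rec_idx, cfg.record_stride, use_m_inf,
    )
    if status != _kernels.STATUS_OK:
        raise NumericalBlowupError("cable simulation blew up")
    return {
        float(p): Trace(times=t, vm=vm_rec[:, s], i_na=ina_rec[:, s])
        for s, p in enumerate(positions)
    }


def _upstroke_time(trace: Trace, threshold: float = -20.0) -> float:
    """Time of (dVm/dt)max, requiring the site actually activated."""
    if trace.vm.max() < threshold:
        raise NoPropagationError("no upstroke at recording site")
    dvdt = np.gradient(trace.vm, trace.times)
    return float(trace.times[np.argmax(dvdt)])


def measure_cv(
    traces: list[Trace] | dict[float, Trace],
    positions: tuple[float, float] | None = None,
) -> float:
    """Conduction velocity (cm/s) from upstroke times at two sites.

    With a dict from :func:`simulate_cable`, the sites default to 25% and
    75% of the cable (the first and third recorded positions), avoiding
    initiation and boundary effects.
    """
    if isinstance(traces, dict):
        keys = sorted(traces)
        if positions is None:
            positions = (keys[0], keys[2]) if len(keys) >= 3 else (keys[0], keys[-1])
        pair = [traces[positions[0]], traces[positions[1]]]
    else:
        pair = list(traces)
        if positions is None or len(pair) != 2:
            raise ValueError("positions required for a bare trace pair")
    t0 = _upstroke_time(pair[0])
    t1 = _upstroke_time(pair[1])
    if t1 <= t0:
        raise NoPropagationError("degenerate or reversed upstroke times")
    return float((positions[1] - positions[0]) / (t1 - t0) * 1000.0)


def _rect_mask(cfg: TissueConfig, region) -> np.ndarray:
    ny, nx = cfg.shape
    x = np.arange(nx) * cfg.dx
    y = np.arange(ny) * cfg.dx
    x0, x1, y0, y1 = region
    return ((x >= x0) & (x <= x1))[None, :] & ((y >= y0) & (y <= y1))[:, None]


def plane_wave_plan(
    cfg: TissueConfig,
    edge: str = "left",
    amplitude: float = -30.0,
    duration: float = 2.0,
    strip: float = 0.1,
    start: float = 0.0,
) -> list[FieldStimulus]:
    """S1 current stimulus along a 1 mm strip of one edge."""
    W, H = cfg.width, cfg.height
    regions = {
        "left": (0.0, strip, 0.0, H),
        "right": (W - strip, W, 0.0, H),
        "bottom": (0.0, W, 0.0, strip),
        "top": (0.0, W, H - strip, H),
    }
    if edge not in regions:
        raise ValueError(f"unknown edge {edge!r}")
    return [FieldStimulus(regions[edge], amplitude, start, duration)]


def _quadrant_region(cfg: TissueConfig, quadrant: str):
    W, H = cfg.width, cfg.height
    regions = {
        "lower_left": (0.0, W / 2, 0.0, H / 2),
        "lower_right": (W / 2, W, 0.0, H / 2),
        "upper_left": (0.0, W / 2, H / 2, H),
        "upper_right": (W / 2, W, H / 2, H),
    }
    if quadrant not in regions:
        raise ValueError(f"unknown quadrant {quadrant!r}")
    return regions[quadrant]


def simulate_tissue2d(
    na: SodiumParams,
    k: PotassiumParams,
    cfg: TissueConfig,
    initiation: list[FieldStimulus],
    t_end: float,
    sites: list[tuple[float, float]] | None = None,
    cm: float = 1.0,
    use_m_inf: bool = False,
    initial: FieldState | None = None,
) -> TissueResult:
    """Run the 2D sheet under an initiation plan and record sites/snapshots.

    Default recording sites: the sheet center and (25%, 25%) of the domain.
    """
    ny, nx = cfg.shape
    state = initial if initial is not None else _resting_fields(na, k, (ny, nx))
    if sites is None:
        sites = [
            (cfg.width / 2, cfg.height / 2),
            (cfg.width / 4, cfg.height / 4),
        ]
    site_ix = np.asarray([int(round(sx / cfg.dx)) for sx, _ in sites], np.int64)
    site_iy = np.asarray([int(round(sy / cfg.dx)) for _, sy in sites], np.int64)

    n_stim = max(len(initiation), 1)
    stim_fields = np.zeros((n_stim, ny, nx), dtype=float)
    stim_start = np.full(n_stim, -1.0)
    stim_dur = np.zeros(n_stim)
    for i, ev in enumerate(initiation):
        stim_fields[i][_rect_mask(cfg, ev.region)] = ev.amplitude
        stim_start[i] = ev.start
        stim_dur[i] = ev.duration

    n_steps = int(round(t_end / cfg.dt))
    if cfg.snapshot_interval > 0:
        snap_every = max(1, int(round(cfg.snapshot_interval / cfg.dt)))
        n_snap = n_steps // snap_every + 1
    else:
        snap_every = n_steps + 1
        n_snap = 0
    snapshots = np.empty((n_snap, ny, nx), dtype=np.float32)

    tables = _kernels.build_gate_tables(
        na.e_m, na.k_m, na.e_h, na.k_h, na.tau_h0, na.delta_h,
        k.g_k, k.b, k.e_k, cfg.dt,
    )
    status, t, vm_sites, got_snap = _kernels.tissue_run(
        state.vm, state.m, state.h,
        na.g_na, na.e_na, na.tau_m,
        *tables, cm,
        cfg.diffusion, cfg.dx, cfg.dt, n_steps,
        stim_fields, stim_start, stim_dur,
        site_iy, site_ix, cfg.record_stride,
        snap_every, snapshots, use_m_inf,
    )
    if status != _kernels.STATUS_OK:
        raise NumericalBlowupError("tissue simulation blew up")
    snap_times = np.arange(got_snap) * snap_every * cfg.dt
    traces = [
        Trace(times=t, vm=vm_sites[:, s]) for s in range(len(sites))
    ]
    return TissueResult(
        site_traces=traces,
        site_positions=list(sites),
        snapshots=snapshots[:got_snap],
        snapshot_times=snap_times,
        cfg=cfg,
        rest_vm=float(resting_potential(na, k)),
    )


class SpiralInitiationError(RuntimeError):
    """No S2 timing in the scanned window produced reentry."""


def initiate_spiral_cross_field(
    cfg: TissueConfig,
    na: SodiumParams,
    k: PotassiumParams,
    s1_edge: str = "left",
    s2_quadrant: str = "lower_left",
    s2_time: float | None = None,
    s2_window: tuple[float, float] | None = None,
    s2_step: float = 10.0,
    s2_amplitude: float = -30.0,
    probe_t_end: float = 400.0,
    use_m_inf: bool = False,
) -> list[FieldStimulus]:
    """Cross-field S1–S2 plan producing a spiral wave.

    With an explicit ``s2_time``, returns the plan directly.  Otherwise the
    helper scans S2 timings over ``s2_window`` (ms after S1) until a run of
    ``probe_t_end`` shows at least one tip trajectory completing a full
    rotation, and returns the first plan that succeeds.
    """
    from .analysis import track_tips

    s1 = plane_wave_plan(cfg, s1_edge, amplitude=s2_amplitude)
    quad = _quadrant_region(cfg, s2_quadrant)

    def plan_at(t2: float) -> list[FieldStimulus]:
        return s1 + [FieldStimulus(quad, s2_amplitude, t2, 2.0)]

    if s2_time is not None:
        return plan_at(s2_time)
    if s2_window is None:
        raise ValueError("either s2_time or s2_window must be given")
    for t2 in np.arange(s2_window[0], s2_window[1] + 1e-9, s2_step):
        res = simulate_tissue2d(
            na, k, cfg, plan_at(float(t2)), t2 + probe_t_end,
            use_m_inf=use_m_inf,
        )
        after = res.snapshot_times >= t2
        tips = track_tips(
            res.snapshots[after], res.snapshot_times[after], cfg.dx
        )
        if any(tr.rotations >= 1.0 for tr in tips):
            return plan_at(float(t2))
    raise SpiralInitiationError(
        f"no reentry for S2 in {s2_window} (step {s2_step} ms)"
    )


def export_snapshots(result: TissueResult, out_dir) -> None:
    """Write snapshots as plain-text matrices plus a JSON sidecar."""
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(result.snapshots):
        np.savetxt(out / f"vm_{i:05d}.txt", frame, fmt="%.3f")
    sidecar = {
        "ny": int(result.cfg.shape[0]),
        "nx": int(result.cfg.shape[1]),
        "dx_cm": result.cfg.dx,
        "dt_ms": result.cfg.dt,
        "times_ms": [float(t) for t in result.snapshot_times],
    }
    (out / "snapshots.json").write_text(json.dumps(sidecar, indent=1))
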