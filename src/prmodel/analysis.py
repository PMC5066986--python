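"""Measurement operators shared by all protocols.

Conventions: the action potential duration (APD) runs from the time of
(dVm/dt)max to the first subsequent sample at which Vm has recovered to
within 5 mV of the resting potential — the same repolarization criterion
used for recovery time.  Spiral-wave tips are located as intersections of
the Vm = −30 mV isolines of consecutive snapshots (a zero normal-velocity
criterion) and linked frame-to-frame by nearest neighbour.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import NoCaptureError, Trace

__all__ = [
    "APMetrics",
    "TipTrajectory",
    "SpiralMetrics",
    "InsufficientDataError",
    "measure_ap",
    "measure_beats",
    "dominant_cycle_length",
    "dominant_frequency",
    "track_tips",
    "tip_counts",
    "classify_episode",
    "trajectory_extent",
]

REPOL_MARGIN_MV = 5.0  # "recovered" means within this margin of rest


class InsufficientDataError(RuntimeError):
    """Not enough events in the input to compute the requested statistic."""


@dataclass(frozen=True)
class APMetrics:
    """Per-beat action potential characteristics."""

    apd: float  # ms
    vm_max: float  # mV
    ina_min: float  # uA/uF
    dvdt_max: float  # mV/ms
    upstroke_time: float  # ms, time of (dVm/dt)max
    recovery_time_point: float  # ms, absolute time Vm reached rest + 5 mV


@dataclass
class TipTrajectory:
    """Path of one spiral-wave tip (phase singularity)."""

    times: list = field(default_factory=list)
    x: list = field(default_factory=list)
    y: list = field(default_factory=list)

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return np.asarray(self.times), np.asarray(self.x), np.asarray(self.y)

    @property
    def rotations(self) -> float:
        """Net angle swept about the trajectory centroid, in turns."""
        t, x, y = self.as_arrays()
        if t.size < 3:
            return 0.0
        ang = np.unwrap(np.arctan2(y - y.mean(), x - x.mean()))
        return float(abs(ang[-1] - ang[0]) / (2 * np.pi))

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0]) if len(self.times) > 1 else 0.0


@dataclass(frozen=True)
class SpiralMetrics:
    """Summary of one 2D reentry episode."""

    mean_cycle_length: float  # ms
    dominant_frequency: float  # Hz
    classification: str  # sustained | terminated | breakup
    trajectory_extent: float  # cm


def _dvdt(trace: Trace) -> np.ndarray:
    return np.gradient(trace.vm, trace.times)


def measure_ap(
    trace: Trace,
    rest_vm: float | None = None,
    capture_rise_mv: float = 40.0,
) -> APMetrics:
    """AP characteristics of a single-beat trace.

    Samples with active stimulus (plus one sample of margin) are excluded
    from the dVm/dt maximum so the stimulus artifact is never mistaken for
    the upstroke.  Raises :class:`NoCaptureError` when the membrane never
    rises ``capture_rise_mv`` above rest or never recovers.
    """
    if rest_vm is None:
        rest_vm = float(trace.vm[0])
    if trace.vm.max() < rest_vm + capture_rise_mv:
        raise NoCaptureError("no action potential in trace")
    dvdt = _dvdt(trace)
    stim_on = trace.i_stim != 0.0
    excluded = stim_on | np.roll(stim_on, 1) | np.roll(stim_on, -1)
    usable = np.flatnonzero(~excluded)
    if usable.size == 0:
        raise NoCaptureError("trace has no stimulus-free samples")
    k_up = usable[np.argmax(dvdt[usable])]
    t_up = float(trace.times[k_up])
    after = np.flatnonzero(
        (trace.times > t_up) & (trace.vm <= rest_vm + REPOL_MARGIN_MV)
    )
    if after.size == 0:
        raise NoCaptureError("membrane did not recover within the trace")
    t_rec = float(trace.times[after[0]])
    return APMetrics(
        apd=t_rec - t_up,
        vm_max=float(trace.vm.max()),
        ina_min=float(trace.i_na.min()),
        dvdt_max=float(dvdt[k_up]),
        upstroke_time=t_up,
        recovery_time_point=t_rec,
    )


def measure_beats(
    trace: Trace, onsets: np.ndarray, rest_vm: float
) -> list[APMetrics | None]:
    """Per-beat metrics for a paced trace, segmented at the stimulus onsets.

    Beats that fail to capture (or to repolarize within their cycle) yield
    ``None``.
    """
    onsets = np.asarray(onsets, dtype=float)
    out: list[APMetrics | None] = []
    for i, t0 in enumerate(onsets):
        t1 = onsets[i + 1] if i + 1 < onsets.size else trace.times[-1]
        seg = trace.window(t0, t1)
        try:
            out.append(measure_ap(seg, rest_vm=rest_vm))
        except NoCaptureError:
            out.append(None)
    return out


def _upstroke_times(trace: Trace, threshold: float = -40.0) -> np.ndarray:
    """Times of (dVm/dt)max around each upward crossing of ``threshold``."""
    vm = trace.vm
    cross = np.flatnonzero((vm[:-1] < threshold) & (vm[1:] >= threshold))
    if cross.size == 0:
        return np.empty(0)
    dvdt = _dvdt(trace)
    dt = trace.dt
    half = max(1, int(round(2.0 / dt)))  # search (dVm/dt)max within +/- 2 ms
    times = []
    for c in cross:
        lo = max(0, c - half)
        hi = min(vm.size, c + half + 1)
        times.append(trace.times[lo + np.argmax(dvdt[lo:hi])])
    return np.asarray(times)


def dominant_cycle_length(trace: Trace, threshold: float = -40.0) -> float:
    """Mean interval (ms) between successive upstrokes at one site."""
    ups = _upstroke_times(trace, threshold)
    if ups.size < 3:
        raise InsufficientDataError(
            f"need >= 3 upstrokes, found {ups.size}"
        )
    return float(np.mean(np.diff(ups)))


def dominant_frequency(
    trace: Trace, fmin: float = 0.5, fmax: float = 80.0
) -> float:
    """Peak of the Vm power spectrum at one site, Hz."""
    from scipy.signal import periodogram

    fs = 1000.0 / trace.dt  # Hz
    f, p = periodogram(trace.vm - trace.vm.mean(), fs=fs)
    band = (f >= fmin) & (f <= fmax)
    if not band.any():
        raise InsufficientDataError("no spectral estimate in band")
    return float(f[band][np.argmax(p[band])])


def _iso_lines(frame: np.ndarray, iso: float, dx: float):
    from shapely.geometry import LineString, MultiLineString
    from skimage.measure import find_contours

    lines = []
    for c in find_contours(frame, iso):
        if c.shape[0] >= 2:
            # find_contours yields (row, col); convert to (x, y) in cm
            lines.append(LineString(np.column_stack((c[:, 1], c[:, 0])) * dx))
    return MultiLineString(lines) if lines else None


def _tips_in_pair(
    frame_a: np.ndarray, frame_b: np.ndarray, iso: float, dx: float
) -> list[tuple[float, float]]:
    from shapely.geometry import GeometryCollection, MultiPoint, Point

    la = _iso_lines(frame_a, iso, dx)
    lb = _iso_lines(frame_b, iso, dx)
    if la is None or lb is None:
        return []
    inter = la.intersection(lb)
    pts: list[tuple[float, float]] = []

    def collect(geom):
        if geom.is_empty:
            return
        if isinstance(geom, Point):
            pts.append((geom.x, geom.y))
        elif isinstance(geom, (MultiPoint, GeometryCollection)):
            for g in geom.geoms:
                collect(g)
        else:  # lines from (near-)coincident contours: use the midpoint
            c = geom.centroid
            if not c.is_empty:
                pts.append((c.x, c.y))

    collect(inter)
    return pts


def track_tips(
    snapshots: np.ndarray,
    times: np.ndarray,
    dx: float,
    iso: float = -30.0,
    link_radius: float = 0.4,
    min_points: int = 3,
    max_gap: int = 3,
) -> list[TipTrajectory]:
    """Locate and link spiral tips across a snapshot sequence.

    A tip at frame k is an intersection of the ``iso`` isolines of frames
    k and k+1.  Tips are linked greedily to the nearest active trajectory
    within ``link_radius`` cm; a trajectory survives up to ``max_gap``
    frames without a match (isoline intersections flicker near tangency).
    Trajectories shorter than ``min_points`` frames are dropped as contour
    noise.
    """
    snapshots = np.asarray(snapshots)
    active: list[tuple[TipTrajectory, int]] = []  # (trajectory, missed frames)
    done: list[TipTrajectory] = []
    for k1 in range(snapshots.shape[0] - 1):
        t = float(times[k1])
        tips = _tips_in_pair(snapshots[k1], snapshots[k1 + 1], iso, dx)
        claimed = [False] * len(tips)
        still_active: list[tuple[TipTrajectory, int]] = []
        for traj, missed in active:
            best, best_d = -1, link_radius * (1 + missed)
            for i, (px, py) in enumerate(tips):
                if claimed[i]:
                    continue
                d = float(np.hypot(px - traj.x[-1], py - traj.y[-1]))
                if d <= best_d:
                    best, best_d = i, d
            if best >= 0:
                claimed[best] = True
                traj.times.append(t)
                traj.x.append(tips[best][0])
                traj.y.append(tips[best][1])
                still_active.append((traj, 0))
            elif missed < max_gap:
                still_active.append((traj, missed + 1))
            else:
                done.append(traj)
        for i, (px, py) in enumerate(tips):
            if not claimed[i]:
                still_active.append((TipTrajectory(times=[t], x=[px], y=[py]), 0))
        active = still_active
    done.extend(traj for traj, _ in active)
    return [tr for tr in done if len(tr.times) >= min_points]


def tip_counts(
    tips: list[TipTrajectory], frame_times: np.ndarray
) -> np.ndarray:
    """Simultaneous tip count at every frame time."""
    frame_times = np.asarray(frame_times)
    counts = np.zeros(frame_times.size, dtype=int)
    for tr in tips:
        t0, t1 = tr.times[0], tr.times[-1]
        counts[(frame_times >= t0) & (frame_times <= t1)] += 1
    return counts


def classify_episode(
    tips: list[TipTrajectory],
    site_trace: Trace,
    t_end: float,
    frame_times: np.ndarray,
    rest_vm: float = -83.0,
    breakup_tip_count: int = 3,
    breakup_hold_ms: float = 100.0,
) -> str:
    """Classify a 2D episode as ``breakup``, ``terminated`` or ``sustained``.

    Breakup requires at least ``breakup_tip_count`` simultaneous tips held
    for ``breakup_hold_ms``; termination requires the recorded site to sit
    within 5 mV of rest from some point on until ``t_end``.
    """
    counts = tip_counts(tips, frame_times)
    high = counts >= breakup_tip_count
    if high.any():
        ft = np.asarray(frame_times)
        run_start = None
        for i, flag in enumerate(high):
            if flag and run_start is None:
                run_start = ft[i]
            elif flag and ft[i] - run_start >= breakup_hold_ms:
                return "breakup"
            elif not flag:
                run_start = None
    quiet = np.abs(site_trace.vm - rest_vm) <= REPOL_MARGIN_MV
    if quiet[-1]:
        last_active = np.flatnonzero(~quiet)
        t_quiet = site_trace.times[0] if last_active.size == 0 else float(
            site_trace.times[last_active[-1]]
        )
        if t_quiet < t_end - 50.0:
            return "terminated"
    return "sustained"


def trajectory_extent(tip: TipTrajectory) -> float:
    """Maximum pairwise tip distance within one rotation (cm).

    A proxy for the length of the rotating line of functional block.
    """
    rot = tip.rotations
    if rot < 1.0:
        raise InsufficientDataError("trajectory covers less than one rotation")
    t, x, y = tip.as_arrays()
    period = tip.duration / rot
    best = 0.0
    for i in range(t.size):
        sel = (t >= t[i]) & (t <= t[i] + period)
        xs, ys = x[sel], y[sel]
        if xs.size < 2:
            continue
        dx_ = xs[:, None] - xs[None, :]
        dy_ = ys[:, None] - ys[None, :]
        best = max(best, float(np.sqrt(dx_**2 + dy_**2).max()))
    return best
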