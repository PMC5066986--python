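"""Virtual electrophysiology protocols.

Implemented here: dynamic current–voltage curves during the upstroke (cell
and propagation forms), the AP-clamp recovery-of-excitability protocol,
steady-state pacing bifurcation (alternans) scans, the reduced two-variable
model variant, propagation-failure threshold, the INa parameter-sensitivity
matrix, and the repolarization (g_k, b) sweep.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .analysis import (
    InsufficientDataError,
    _upstroke_times,
    classify_episode,
    dominant_cycle_length,
    dominant_frequency,
    measure_ap,
    measure_beats,
    track_tips,
    trajectory_extent,
)
from .engine import (
    NoCaptureError,
    SimulationConfig,
    StimulusSpec,
    Trace,
    find_stimulus_for_latency,
    resting_state,
    simulate_ap_clamp,
    simulate_cell,
)
from .model_core import CellState, PotassiumParams, SodiumParams
from .spatial import (
    CableConfig,
    NoPropagationError,
    TissueConfig,
    initiate_spiral_cross_field,
    measure_cv,
    simulate_cable,
)

__all__ = [
    "IVCurve",
    "RecoveryPoint",
    "BifurcationPoint",
    "ReducedModel",
    "dynamic_iv_cell",
    "dynamic_iv_propagation",
    "recovery_of_excitability",
    "summarize_recovery",
    "pacing_bifurcation",
    "alternans_window",
    "make_reduced_model",
    "match_reduced_conductance",
    "propagation_failure_threshold",
    "parameter_sensitivity_matrix",
    "repolarization_sweep",
    "DEFAULT_PACING_STIMULUS",
]

# pacing stimulus used throughout: 2 ms pulses of -20 uA/uF
DEFAULT_PACING_STIMULUS = StimulusSpec(amplitude=-20.0, duration=2.0)


@dataclass(frozen=True)
class IVCurve:
    """Dynamic current–voltage relationship over the AP upstroke."""

    vm: np.ndarray  # mV
    current: np.ndarray  # uA/uF
    phase: str = "upstroke"

    @property
    def peak_inward(self) -> float:
        return float(self.current.min()) if self.current.size else 0.0


def _upstroke_window(trace: Trace, dvdt: np.ndarray) -> np.ndarray:
    """Sample indices from the last sub-threshold point to the Vm peak,
    restricted to stimulus-free samples."""
    stim_on = trace.i_stim != 0.0
    excluded = stim_on | np.roll(stim_on, 1) | np.roll(stim_on, -1)
    usable = np.flatnonzero(~excluded)
    if usable.size == 0:
        raise ValueError("trace has no stimulus-free samples")
    k_peak = usable[np.argmax(trace.vm[usable])]
    rising = usable[(usable <= k_peak) & (dvdt[usable] > 0.5)]
    if rising.size == 0:
        raise ValueError("no upstroke in trace")
    k_start = rising[0]
    win = usable[(usable >= k_start) & (usable <= k_peak)]
    return win


def dynamic_iv_cell(trace: Trace, cm: float = 1.0) -> IVCurve:
    """Single-cell dynamic I–V: current estimated as −Cm dVm/dt.

    Valid after the stimulus is off, when the total membrane current is
    carried by the ionic currents (predominantly INa during the upstroke).
    """
    if trace.vm.max() - trace.vm.min() < 1.0:
        return IVCurve(vm=trace.vm.copy(), current=np.zeros(trace.vm.size))
    dvdt = np.gradient(trace.vm, trace.times)
    win = _upstroke_window(trace, dvdt)
    return IVCurve(vm=trace.vm[win], current=-cm * dvdt[win])


def dynamic_iv_propagation(
    trace: Trace,
    cv: float,
    diffusion: float,
    cm: float = 1.0,
    smooth_ms: float | None = None,
) -> IVCurve:
    """Propagation dynamic I–V: Cm (D/CV^2 d2Vm/dt2 − dVm/dt).

    ``cv`` is in cm/s (converted internally to cm/ms to match ``diffusion``
    in cm^2/ms); exact for a steadily travelling plane wave, where the
    wave-frame substitution turns the Laplacian into d2Vm/dt2 / CV^2.

    For traces recorded on a discrete cable the front advances node to
    node, which imprints a ripple of period dx/CV on the single-site time
    course; the second derivative amplifies it strongly.  Passing
    ``smooth_ms`` (a good choice is two lattice periods, 2*dx/CV)
    estimates the derivatives through a cubic Savitzky–Golay fit over that
    window instead of bare finite differences.
    """
    if cv <= 0:
        raise ValueError("cv must be positive")
    if trace.vm.max() - trace.vm.min() < 1.0:
        return IVCurve(vm=trace.vm.copy(), current=np.zeros(trace.vm.size))
    cv_ms = cv / 1000.0
    if smooth_ms is not None:
        from scipy.signal import savgol_filter

        w = max(5, int(round(smooth_ms / trace.dt)) // 2 * 2 + 1)
        dvdt = savgol_filter(trace.vm, w, 3, deriv=1, delta=trace.dt)
        d2 = savgol_filter(trace.vm, w, 3, deriv=2, delta=trace.dt)
    else:
        dvdt = np.gradient(trace.vm, trace.times)
        d2 = np.gradient(dvdt, trace.times)
    win = _upstroke_window(trace, dvdt)
    cur = cm * (diffusion / cv_ms**2 * d2[win] - dvdt[win])
    return IVCurve(vm=trace.vm[win], current=cur)


@dataclass(frozen=True)
class RecoveryPoint:
    """One point of the recovery-of-excitability curve."""

    recovery_time: float  # ms; stimulus time minus repolarization time
    normalized_peak_ina: float  # peak |INa| of test beat / 10th clamped beat
    waveform: int = 0
    captured: bool = True


def recovery_of_excitability(
    ap_waveforms: list[Trace],
    na: SodiumParams,
    k: PotassiumParams,
    coupling_times: list[float],
    cfg: SimulationConfig | None = None,
    latency: float = 1.0,
    stim_duration: float = 2.0,
    test_window: float = 30.0,
) -> list[RecoveryPoint]:
    """AP-clamp recovery protocol over an ensemble of AP waveforms.

    Each waveform (10 paced beats) drives an INa action-potential clamp.
    At each coupling time — measured from the 10th-beat upstroke — the
    simulation switches to current clamp from the clamped state and a 2 ms
    test stimulus is applied, its amplitude tuned so the upstroke latency
    is 1 ms.  The test beat's peak INa is normalized to the 10th clamped
    beat's, and reported against the recovery time (RT): the interval from
    the moment Vm recovered to within 5 mV of rest to the stimulus
    (negative when the stimulus lands before full repolarization).

    Refractory points (no capture at any amplitude) are recorded with a
    zero normalized response, not raised as errors.
    """
    if not ap_waveforms:
        raise ValueError("need at least one AP waveform")
    cfg = cfg if cfg is not None else SimulationConfig()
    points: list[RecoveryPoint] = []
    for w, wave in enumerate(ap_waveforms):
        clamp = simulate_ap_clamp(wave, na, cfg, k=k)
        ups = _upstroke_times(clamp)
        if ups.size < 10:
            raise ValueError(f"waveform {w} has {ups.size} beats; need 10")
        t10 = float(ups[9])
        rest = float(wave.vm[0])
        k10 = (clamp.times >= t10 - 5.0) & (clamp.times <= t10 + 20.0)
        i_ref = float(clamp.i_na[k10].min())
        rec = np.flatnonzero((clamp.times > t10) & (clamp.vm <= rest + 5.0))
        if rec.size == 0:
            raise ValueError(f"waveform {w} never repolarizes after beat 10")
        t_rep = float(clamp.times[rec[0]])
        for ct in coupling_times:
            t_sw = t10 + ct
            vm_sw = float(np.interp(t_sw, clamp.times, clamp.vm))
            m_sw = float(np.interp(t_sw, clamp.times, clamp.m))
            h_sw = float(np.interp(t_sw, clamp.times, clamp.h))
            state = CellState(vm=vm_sw, m=m_sw, h=h_sw)
            rt = t_sw - t_rep
            try:
                amp = find_stimulus_for_latency(
                    latency, stim_duration, state, cfg, na=na, k=k
                )
            except NoCaptureError:
                points.append(RecoveryPoint(rt, 0.0, w, captured=False))
                continue
            stim = StimulusSpec(amplitude=amp, duration=stim_duration, count=1)
            tr = simulate_cell(state, stim, cfg, test_window, na=na, k=k)
            norm = float(tr.i_na.min() / i_ref)
            points.append(RecoveryPoint(rt, norm, w))
    return points


def summarize_recovery(points: list[RecoveryPoint]) -> pd.DataFrame:
    """Mean ± SEM of RT and normalized peak INa across waveforms,
    grouped by protocol point (coupling-time order within each waveform)."""
    df = pd.DataFrame(
        {
            "waveform": [p.waveform for p in points],
            "recovery_time": [p.recovery_time for p in points],
            "normalized_peak_ina": [p.normalized_peak_ina for p in points],
        }
    )
    df["point"] = df.groupby("waveform").cumcount()
    g = df.groupby("point")
    n = g.size()
    out = pd.DataFrame(
        {
            "rt_mean": g["recovery_time"].mean(),
            "rt_sem": g["recovery_time"].std(ddof=1) / np.sqrt(n),
            "peak_mean": g["normalized_peak_ina"].mean(),
            "peak_sem": g["normalized_peak_ina"].std(ddof=1) / np.sqrt(n),
        }
    )
    return out.sort_values("rt_mean").reset_index(drop=True)


@dataclass(frozen=True)
class BifurcationPoint:
    """Steady-state even/odd beat statistics at one pacing cycle length."""

    bcl: float
    apd_even: float
    apd_odd: float
    vm_max_even: float
    vm_max_odd: float
    ina_min_even: float
    ina_min_odd: float
    alternans: bool
    captured: bool

    @property
    def delta_apd(self) -> float:
        return abs(self.apd_even - self.apd_odd)


ALTERNANS_DELTA_APD = 2.0  # ms; steady-state |even - odd| APD above this flags alternans


def pacing_bifurcation(
    na: SodiumParams,
    k: PotassiumParams,
    bcls: list[float],
    beats: int = 60,
    stim: StimulusSpec | None = None,
    cfg: SimulationConfig | None = None,
    use_m_inf: bool = False,
) -> list[BifurcationPoint]:
    """Steady-state pacing scan; the first half of the beats is discarded
    as transient and the remainder split into even/odd beats."""
    if beats < 40:
        raise ValueError("need >= 40 beats for a steady-state estimate")
    stim = stim if stim is not None else DEFAULT_PACING_STIMULUS
    cfg = cfg if cfg is not None else SimulationConfig(record_stride=20)
    rest = resting_state(na, k, use_m_inf=use_m_inf)
    out: list[BifurcationPoint] = []
    for bcl in bcls:
        train = replace(stim, period=float(bcl), count=beats, onset=0.0)
        tr = simulate_cell(
            rest, train, cfg, beats * float(bcl), na=na, k=k, use_m_inf=use_m_inf
        )
        onsets = np.arange(beats) * float(bcl)
        metrics = measure_beats(tr, onsets, rest_vm=rest.vm)
        tail = metrics[beats // 2 :]
        offset = beats // 2
        captured = all(mt is not None for mt in tail)
        even = [mt for j, mt in enumerate(tail) if mt and (offset + j) % 2 == 0]
        odd = [mt for j, mt in enumerate(tail) if mt and (offset + j) % 2 == 1]
        if not even or not odd:
            out.append(
                BifurcationPoint(bcl, np.nan, np.nan, np.nan, np.nan,
                                 np.nan, np.nan, False, False)
            )
            continue
        apd_e = float(np.mean([mt.apd for mt in even]))
        apd_o = float(np.mean([mt.apd for mt in odd]))
        pt = BifurcationPoint(
            bcl=float(bcl),
            apd_even=apd_e,
            apd_odd=apd_o,
            vm_max_even=float(np.mean([mt.vm_max for mt in even])),
            vm_max_odd=float(np.mean([mt.vm_max for mt in odd])),
            ina_min_even=float(np.mean([mt.ina_min for mt in even])),
            ina_min_odd=float(np.mean([mt.ina_min for mt in odd])),
            alternans=captured and abs(apd_e - apd_o) > ALTERNANS_DELTA_APD,
            captured=captured,
        )
        out.append(pt)
    return out


def alternans_window(points: list[BifurcationPoint]) -> tuple[float, float]:
    """Smallest and largest flagged BCL in a scan."""
    flagged = [p.bcl for p in points if p.alternans]
    if not flagged:
        raise InsufficientDataError("no alternans in the scanned range")
    return min(flagged), max(flagged)


@dataclass(frozen=True)
class ReducedModel:
    """Two-variable (Vm, h) variant: m^3 replaced by m_inf(Vm)^3."""

    na: SodiumParams
    use_m_inf: bool = True


def make_reduced_model(na: SodiumParams, g_na_reduced: float) -> ReducedModel:
    """Reduced model with instantaneous activation and rescaled conductance.

    Removing activation kinetics speeds the upstroke, so ``g_na`` must be
    lowered to preserve the conduction velocity of the full model.
    """
    if g_na_reduced <= 0:
        raise ValueError("g_na_reduced must be > 0")
    return ReducedModel(na=replace(na, g_na=g_na_reduced))


def match_reduced_conductance(
    na: SodiumParams,
    k: PotassiumParams,
    cable: CableConfig | None = None,
    target_cv: float | None = None,
    g_lo: float = 3.0,
    g_hi: float = 11.0,
    resolution: float = 0.1,
    t_end: float = 300.0,
) -> float:
    """g_na of the reduced model whose cable CV matches the full model's.

    CV grows monotonically with g_na, so the match is found by bisection
    down to ``resolution`` (mS/uF).
    """
    cable = cable if cable is not None else CableConfig()
    if target_cv is None:
        target_cv = measure_cv(simulate_cable(na, k, cable, t_end))

    def cv_of(g: float) -> float:
        red = make_reduced_model(na, g)
        tr = simulate_cable(red.na, k, cable, t_end, use_m_inf=True)
        try:
            return measure_cv(tr)
        except NoPropagationError:
            return 0.0

    lo, hi = g_lo, g_hi
    if not cv_of(lo) < target_cv < cv_of(hi):
        raise ValueError("target CV not bracketed by [g_lo, g_hi]")
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if cv_of(mid) < target_cv:
            lo = mid
        else:
            hi = mid
    return round(0.5 * (lo + hi) / resolution) * resolution


def propagation_failure_threshold(
    na: SodiumParams,
    k: PotassiumParams,
    cable: CableConfig | None = None,
    t_end: float = 300.0,
    resolution: float = 0.01,
    use_m_inf: bool = False,
) -> float:
    """Percent decrease of g_na at which cable propagation fails.

    Failure = no upstroke at the 90% position after end-clamp initiation.
    The conductance scale factor is bisected to ``resolution`` and the
    threshold reported as (1 - s) * 100 at the bisection midpoint.
    """
    cable = cable if cable is not None else CableConfig()
    check_pos = 0.9 * cable.length
    cfg = replace(cable, record_positions=(0.25 * cable.length, check_pos))

    def propagates(s: float) -> bool:
        tr = simulate_cable(
            na.with_scaled_g_na(s), k, cfg, t_end, use_m_inf=use_m_inf
        )
        return bool(tr[check_pos].vm.max() > -20.0)

    if not propagates(1.0):
        raise ValueError("nominal parameters fail to propagate")
    lo, hi = 0.02, 1.0  # lo fails, hi propagates
    if propagates(lo):
        raise ValueError("even strongly reduced g_na still propagates")
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if propagates(mid):
            hi = mid
        else:
            lo = mid
    return (1.0 - 0.5 * (lo + hi)) * 100.0


SENSITIVITY_PARAMS = (
    "g_na", "e_na", "e_m", "k_m", "tau_m", "e_h", "k_h", "tau_h0"
)
SENSITIVITY_QOIS = (
    "cell_ina_min", "cell_vm_max", "cell_dvdt_max", "cell_apd",
    "cable_ina_min", "cable_vm_max", "cable_cv", "cable_apd",
)


def parameter_sensitivity_matrix(
    na: SodiumParams,
    k: PotassiumParams,
    cable: CableConfig | None = None,
    cfg: SimulationConfig | None = None,
    rel_change: float = 0.01,
    cell_t_end: float = 400.0,
    cable_t_end: float = 300.0,
) -> pd.DataFrame:
    """Percent change of eight AP quantities per +1% change of each INa
    parameter (rows: parameters, columns: cell and cable quantities).

    Entries for perturbed runs that fail to capture or propagate are NaN.
    """
    cable = cable if cable is not None else CableConfig()
    cfg = cfg if cfg is not None else SimulationConfig(record_stride=10)

    def qois(na_p: SodiumParams) -> np.ndarray:
        row = np.full(len(SENSITIVITY_QOIS), np.nan)
        try:
            rest = resting_state(na_p, k)
            tr = simulate_cell(
                rest, DEFAULT_PACING_STIMULUS, cfg, cell_t_end, na=na_p, k=k
            )
            mc = measure_ap(tr, rest_vm=rest.vm)
            row[0:4] = (mc.ina_min, mc.vm_max, mc.dvdt_max, mc.apd)
        except (NoCaptureError, ValueError):
            pass
        try:
            traces = simulate_cable(na_p, k, cable, cable_t_end)
            cv = measure_cv(traces)
            mid = traces[sorted(traces)[1]]
            mm = measure_ap(mid, rest_vm=mid.vm[0])
            row[4:8] = (mm.ina_min, mm.vm_max, cv, mm.apd)
        except (NoPropagationError, NoCaptureError, ValueError):
            pass
        return row

    base = qois(na)
    rows = {}
    for pname in SENSITIVITY_PARAMS:
        val = getattr(na, pname)
        na_p = replace(na, **{pname: val * (1.0 + rel_change)})
        pert = qois(na_p)
        with np.errstate(divide="ignore", invalid="ignore"):
            rows[pname] = (pert - base) / base * 100.0
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=list(SENSITIVITY_QOIS)
    )


def repolarization_sweep(
    g_k_values: list[float],
    b_values: list[float],
    mode: str = "cell",
    na: SodiumParams | None = None,
    e_k: float = -83.0,
    cfg: SimulationConfig | None = None,
    tissue_cfg: TissueConfig | None = None,
    s2_window: tuple[float, float] = (120.0, 320.0),
    t_end_tissue: float = 2000.0,
    cell_t_end: float = 1500.0,
    cell_stim: StimulusSpec | None = None,
) -> pd.DataFrame:
    """Sweep the IK parameters (g_k, b).

    ``cell`` mode reports single-beat APD and peak Vm per pair; ``tissue2d``
    mode initiates a spiral per pair and reports cycle length, dominant
    frequency and the sustained/terminated/breakup classification.
    Per-pair failures are recorded in the ``error`` column and the sweep
    continues.
    """
    if not g_k_values or not b_values:
        raise ValueError("value grids must be non-empty")
    na = na if na is not None else SodiumParams()
    # a single suprathreshold pulse for the whole grid: the activation
    # threshold rises with g_k, and a uniform stimulus keeps the APD map
    # comparable across cells
    if cell_stim is None:
        cell_stim = StimulusSpec(amplitude=-30.0, duration=2.0)
    rows = []
    for gk in g_k_values:
        for b in b_values:
            kp = PotassiumParams(g_k=gk, b=b, e_k=e_k)
            row: dict = {"g_k": gk, "b": b, "error": ""}
            try:
                if mode == "cell":
                    ccfg = cfg if cfg is not None else SimulationConfig(record_stride=10)
                    rest = resting_state(na, kp)
                    tr = simulate_cell(
                        rest, cell_stim, ccfg, cell_t_end, na=na, k=kp
                    )
                    mt = measure_ap(tr, rest_vm=rest.vm)
                    row.update(apd=mt.apd, vm_max=mt.vm_max)
                elif mode == "tissue2d":
                    tcfg = tissue_cfg if tissue_cfg is not None else TissueConfig()
                    from .spatial import simulate_tissue2d

                    plan = initiate_spiral_cross_field(
                        tcfg, na, kp, s2_window=s2_window
                    )
                    res = simulate_tissue2d(na, kp, tcfg, plan, t_end_tissue)
                    center = res.site_traces[0]
                    s2t = plan[-1].start
                    late = center.window(s2t, t_end_tissue)
                    after = res.snapshot_times >= s2t
                    tips = track_tips(
                        res.snapshots[after], res.snapshot_times[after], tcfg.dx
                    )
                    label = classify_episode(
                        tips, late, t_end_tissue,
                        res.snapshot_times[after], rest_vm=res.rest_vm,
                    )
                    row["classification"] = label
                    try:
                        row["cycle_length"] = dominant_cycle_length(late)
                        row["dominant_frequency"] = dominant_frequency(late)
                    except InsufficientDataError:
                        row["cycle_length"] = np.nan
                        row["dominant_frequency"] = np.nan
                    ext = [
                        trajectory_extent(tr_) for tr_ in tips if tr_.rotations >= 1.0
                    ]
                    row["trajectory_extent"] = max(ext) if ext else np.nan
                else:
                    raise ValueError(f"unknown mode {mode!r}")
            except Exception as exc:  # per-pair failures do not stop the sweep
                row["error"] = f"{type(exc).__name__}: {exc}"
            rows.append(row)
    return pd.DataFrame(rows)
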