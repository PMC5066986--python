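"""Synthetic myocyte AP-waveform ensembles for the recovery protocol.

The recovery-of-excitability protocol clamps INa to paced action-potential
waveforms recorded from isolated rabbit myocytes (resting potential near
−83 mV, upstroke of a few ms, APD around 200 ms, modest cell-to-cell
variability).  This module emulates such an ensemble *self-consistently*:
each member is produced by pacing the PR cell model itself with per-cell
jittered repolarization parameters (g_k, b) and a shifted reversal/resting
potential, so the waveforms have physiologic upstroke–repolarization
coupling and exercise the same code paths as every other simulation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace

import numpy as np

from .analysis import measure_ap
from .engine import (
    SimulationConfig,
    StimulusSpec,
    Trace,
    find_stimulus_for_latency,
    resting_state,
    simulate_cell,
)
from .model_core import PotassiumParams, SodiumParams

__all__ = ["EnsembleSpec", "generate_ap_ensemble", "save_ensemble", "load_ensemble"]


@dataclass(frozen=True)
class EnsembleSpec:
    """Target statistics of the waveform ensemble (means and SDs)."""

    n_cells: int = 6
    rest_vm_mean: float = -83.0
    rest_vm_sd: float = 1.0
    apd_mean: float = 200.0
    apd_sd: float = 15.0
    peak_vm_mean: float = 34.0
    peak_vm_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if min(self.rest_vm_sd, self.apd_sd, self.peak_vm_sd) < 0:
            raise ValueError("standard deviations must be >= 0")


def _single_beat_apd(
    na: SodiumParams,
    k: PotassiumParams,
    stim: StimulusSpec,
    cfg: SimulationConfig,
) -> float:
    rest = resting_state(na, k, settle_ms=500.0)
    tr = simulate_cell(rest, stim, cfg, 900.0, na=na, k=k)
    return measure_ap(tr, rest_vm=rest.vm).apd


def _calibrate_b(
    target_apd: float,
    na: SodiumParams,
    k: PotassiumParams,
    stim: StimulusSpec,
    cfg: SimulationConfig,
    tol: float = 1.0,
    max_iter: int = 12,
) -> PotassiumParams:
    """Secant adjustment of the IK shape factor b to hit a target APD.

    APD is monotonically increasing in b (weaker rectified outward current
    at plateau potentials), which makes b the natural single knob.
    """
    b0, b1 = k.b, k.b * 1.05
    f0 = _single_beat_apd(na, replace(k, b=b0), stim, cfg) - target_apd
    if abs(f0) <= tol:
        return replace(k, b=b0)
    f1 = _single_beat_apd(na, replace(k, b=b1), stim, cfg) - target_apd
    for _ in range(max_iter):
        if abs(f1) <= tol:
            return replace(k, b=b1)
        if f1 == f0:
            break
        b2 = b1 - f1 * (b1 - b0) / (f1 - f0)
        b2 = min(max(b2, 0.02), 0.08)
        b0, f0, b1 = b1, f1, b2
        f1 = _single_beat_apd(na, replace(k, b=b1), stim, cfg) - target_apd
    return replace(k, b=b1)


def generate_ap_ensemble(
    spec: EnsembleSpec,
    n_beats: int = 10,
    bcl: float = 400.0,
    stim: StimulusSpec | None = None,
    cfg: SimulationConfig | None = None,
    gk_jitter_sd: float = 0.02,
    pacing_latency: float = 2.5,
    max_attempts: int = 100,
) -> list[Trace]:
    """Generate ``spec.n_cells`` paced AP waveforms (``n_beats`` beats each).

    Per cell: the resting/reversal potential is shifted to the drawn rest
    Vm, g_k receives a normal jitter, and b is calibrated (secant, single
    beat) so the drawn APD target is met; the cell is then paced for
    ``n_beats`` beats.  Deterministic given ``spec.seed``.
    """
    stim = stim if stim is not None else StimulusSpec(amplitude=-20.0, duration=2.0)
    cfg = cfg if cfg is not None else SimulationConfig(record_stride=10)
    rng = np.random.default_rng(spec.seed)
    na = SodiumParams()
    k_nom = PotassiumParams()
    traces: list[Trace] = []
    for _ in range(spec.n_cells):
        for attempt in range(max_attempts):
            rest_target = spec.rest_vm_mean + spec.rest_vm_sd * rng.standard_normal()
            apd_target = spec.apd_mean + spec.apd_sd * rng.standard_normal()
            g_k = k_nom.g_k + gk_jitter_sd * rng.standard_normal()
            if g_k > 0.05 and apd_target > 30.0:
                break
        else:
            raise RuntimeError("could not draw valid ensemble parameters")
        shift = rest_target - spec.rest_vm_mean
        k_cell = PotassiumParams(g_k=g_k, b=k_nom.b, e_k=k_nom.e_k + shift)
        # pace near threshold: amplitude tuned per cell for a 2.5 ms
        # upstroke latency, the latency at which the reference myocyte
        # recordings were taken; keeps peak Vm physiologic (~34 mV)
        rest0 = resting_state(na, k_cell, settle_ms=500.0)
        amp = find_stimulus_for_latency(
            pacing_latency, stim.duration, rest0, cfg, na=na, k=k_cell
        )
        cell_stim = replace(stim, amplitude=amp)
        k_cell = _calibrate_b(apd_target, na, k_cell, cell_stim, cfg)
        rest = resting_state(na, k_cell, settle_ms=1000.0)
        train = replace(cell_stim, period=bcl, count=n_beats)
        tr = simulate_cell(rest, train, cfg, n_beats * bcl, na=na, k=k_cell)
        traces.append(tr)
    return traces


def save_ensemble(traces: list[Trace], spec: EnsembleSpec, out_dir) -> None:
    """CSV per waveform plus a JSON sidecar of the generating spec."""
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, tr in enumerate(traces):
        tr.to_csv(out / f"waveform_{i:02d}.csv")
    (out / "ensemble.json").write_text(json.dumps(asdict(spec), indent=1))


def load_ensemble(in_dir) -> tuple[list[Trace], EnsembleSpec]:
    import pathlib

    p = pathlib.Path(in_dir)
    spec = EnsembleSpec(**json.loads((p / "ensemble.json").read_text()))
    traces = [
        Trace.from_csv(f) for f in sorted(p.glob("waveform_*.csv"))
    ]
    return traces, spec
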