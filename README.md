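# prmodel — parsimonious rabbit cardiac action potential model

`prmodel` implements a deliberately minimal ("parsimonious") model of the
rabbit ventricular action potential and the virtual electrophysiology
experiments built on it.  It is aimed at computational cardiac
electrophysiologists who want a mathematically identifiable model — few
parameters, each physiologically meaningful — that still reproduces
nontrivial emergent behavior: APD alternans under rapid pacing, functional
spiral-wave reentry, and spiral-wave breakup.

## The model

Three state variables (membrane potential `Vm`, sodium activation `m`,
sodium inactivation `h`) and two currents:

```
I_Na = g_Na · m³ · h · (Vm − E_Na)                 (Hodgkin–Huxley fast sodium)
I_K  = g_K · exp(−b (Vm − E_K)) · (Vm − E_K)      (time-independent rectifier)

dy/dt = (y∞(Vm) − y) / τ_y(Vm)          for y ∈ {m, h}

y∞(Vm) = 1 / (1 + exp((Vm − E_y)/k_y))
τ_h(Vm) = 2 τ_h0 · exp(δ_h (Vm − E_h)/k_h) / (1 + exp((Vm − E_h)/k_h))
τ_m     = const
```

Units throughout: mV, ms, mS/µF, µA/µF (Cm = 1 µF/cm², so µA/µF ≡ µA/cm²
and pA/pF ≡ µA/µF), cm, cm²/ms.  Nominal parameters
(`prmodel.default_parameters()`): g_Na = 11, E_Na = 65, E_m = −41,
k_m = −4.0, τ_m = 0.12, E_h = −74.9, k_h = 4.4, τ_h0 = 6.80738,
δ_h = 0.799163, g_K = 0.3, b = 0.047, E_K = −83.

Tissue is modelled as a monodomain reaction–diffusion system
(∂Vm/∂t = D∇²Vm − I_ion/Cm) on a 1D cable and a 2D sheet, solved with
exact (Rush–Larsen) gate updates, forward-Euler Vm, central-difference
Laplacians and no-flux boundaries.  See `docs/methods.md` for the full
numerical account.

## Worked example

```python
from prmodel import (default_parameters, resting_state, simulate_cell,
                     StimulusSpec, SimulationConfig, measure_ap)

na, k = default_parameters()
rest = resting_state(na, k)                      # settled rest near -83 mV
stim = StimulusSpec(amplitude=-20.0, duration=2.0)   # one 2 ms pacing pulse
cfg = SimulationConfig(dt=0.001, record_stride=1)
trace = simulate_cell(rest, stim, cfg, 400.0, na=na, k=k)
m = measure_ap(trace, rest_vm=rest.vm)
print(f"APD {m.apd:.1f} ms, peak Vm {m.vm_max:.1f} mV, "
      f"peak INa {m.ina_min:.0f} uA/uF")
```

prints

```
APD 196.5 ms, peak Vm 33.8 mV, peak INa -232 uA/uF
```

i.e. a ~197 ms action potential peaking near +34 mV whose upstroke is
carried by a ~230 µA/µF sodium surge.  The same model propagating in a
4 cm cable (`pr cable`) conducts at ~54 cm/s with a shorter APD (~139 ms)
and a larger sodium current (~−286 µA/µF) — single-cell and propagated
depolarization genuinely differ, which is one of the model's design
points.

## Command line

Every protocol is a subcommand of the `pr` console script, writing CSV
tables plus a JSON run manifest (parameters, seed, checksums):

```
pr cell         # one paced action potential + metrics
pr cable        # 4 cm cable run: CV, mid-cable AP metrics
pr tissue2d     # 2D sheet: cross-field S1-S2 spiral episode + tip tracking
pr iv           # dynamic I-V curves (cell and propagation forms)
pr recovery     # AP-clamp recovery-of-excitability protocol
pr bifurcation  # BCL scan -> steady-state alternans window
pr failure      # g_Na reduction threshold for propagation failure
pr sensitivity  # 8x8 matrix: 1% INa-parameter changes vs AP quantities
pr sweep        # (g_K, b) sweep, cell mode or tissue2d mode (overnight)
pr synth        # generate the synthetic myocyte AP-waveform ensemble
```

All defaults reproduce the reference setup, so `pr <cmd>` with no config
is meaningful; `-c config.yaml` overrides any flat key
(e.g. `g_na: 9.5`, `cable_length: 2.0`).

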