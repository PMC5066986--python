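# Methods

## Model

The model is a minimal Hodgkin–Huxley description of the rabbit
ventricular action potential with two currents and three state variables:

* **Fast sodium current** `I_Na = g_Na m³ h (Vm − E_Na)`: activation `m`
  and fast inactivation `h` follow first-order kinetics
  `dy/dt = (y∞ − y)/τ_y`.  Steady states are Boltzmann sigmoids
  `y∞ = 1/(1 + exp((Vm − E_y)/k_y))` with `k_m < 0` (activation) and
  `k_h > 0` (inactivation).  The inactivation time constant is the
  thermodynamically consistent bell
  `τ_h = 2 τ_h0 exp(δ_h u)/(1 + exp(u))`, `u = (Vm − E_h)/k_h`, which
  equals `τ_h0` exactly at `E_h`.  The activation time constant is a
  *constant* (τ_m = 0.12 ms): the pure bell form would drive τ_m toward
  zero away from its midpoint, implying unmeasurably fast and unphysical
  instantaneous gating; fixing it also gives the model a well-defined
  fastest time scale, which is what lets the explicit integrator run at a
  comparatively large step.  There is deliberately **no slow inactivation
  gate**: with only fast inactivation, excitability recovers as soon as
  the membrane repolarizes (no post-repolarization refractoriness), which
  the recovery-of-excitability protocol below probes directly.
* **Repolarizing potassium current**
  `I_K = g_K exp(−b (Vm − E_K)) (Vm − E_K)`: time independent, zero at
  `E_K`, rising to a single maximum `g_K/(b·e)` at `E_K + 1/b` and
  *rectifying* (decaying) beyond.  `g_K` sets the magnitude and the single
  shape parameter `b` (1/mV) controls how much outward current survives at
  plateau potentials, hence the APD.  Because `I_K` has no kinetics, the
  AP duration is a function of the peak voltage reached on the upstroke —
  APD therefore depends on the stimulus, and all quantitative statements
  here name the stimulus used.

Units everywhere: mV, ms, mS/µF, µA/µF (Cm = 1 µF/cm²), cm, cm²/ms.
No unit conversion happens inside the core; the one external convention
(2D diffusion quoted in cm²/s) is converted at the configuration surface
(1 cm²/s = 0.001 cm²/ms).

### Parameters (nominal)

| parameter | value | units | role |
|---|---|---|---|
| g_Na | 11 | mS/µF | sodium conductance; sets upstroke velocity and CV |
| E_Na | 65 | mV | sodium reversal |
| E_m, k_m | −41, −4.0 | mV | activation midpoint / slope |
| τ_m | 0.12 | ms | constant activation time constant |
| E_h, k_h | −74.9, 4.4 | mV | inactivation midpoint / slope |
| τ_h0, δ_h | 6.80738, 0.799163 | ms, – | inactivation τ bell scale / asymmetry |
| g_K | 0.3 | mS/µF | repolarization magnitude |
| b | 0.047 | 1/mV | rectification shape; the single phenomenological knob |
| E_K | −83 | mV | potassium reversal = resting potential |

`invert_inactivation_tau` recovers `(τ_h0, δ_h)` in closed form from two
`(Vm, τ_h)` calibration pairs (the ratio of two bell evaluations isolates
δ_h; τ_h0 follows by substitution) and is contract-tested by round trip to
1e−12 relative.  Note that the nominal `(τ_h0, δ_h)` above evaluate to
τ_h(−80 mV) ≈ 4.10 ms and τ_h(0 mV) ≈ 0.446 ms; the inversion of the
rounder pair (4.0 ms, 0.45 ms) would give (≈6.648, ≈0.8011).  The table
values are canonical for every simulation in this package; the inversion
is provided as a calibration utility, not as the source of the defaults.

## Numerics

* **0D/1D/2D time stepping.**  First-order Lie splitting: at each step the
  gates advance *exactly* (Rush–Larsen, `y ← y∞ + (y − y∞) e^{−dt/τ}`)
  with `y∞, τ` frozen at the pre-step Vm, and Vm advances by forward Euler
  with all currents evaluated at the pre-step state.  Gate fractions are
  clamped to [0, 1] after each update purely as a round-off guard (the
  exact update is analytically in range).  A step producing a non-finite
  Vm or |Vm| > 1000 mV aborts with a blow-up error naming the time.
* **Reference discretization.**  dt = 0.001 ms for cell and cable (a
  conservative choice: halving dt moves the single-cell APD by < 0.5 ms
  and peak Vm by < 0.2 mV); cable dx = 0.01 cm with D = 0.001 cm²/ms; 2D
  dt = 0.02 ms, dx as stated per experiment.  Explicit-stability guards
  (`dt·D/dx² ≤ 1/2` in 1D, `4·dt·D/dx² ≤ 1` in 2D) reject unstable
  configurations before running.
* **Boundaries.**  No flux, implemented by mirroring across the boundary
  *face* (ghost node = boundary node).  This is the conservative variant:
  the discrete Laplacian sums to zero over the domain for any field, so no
  charge leaks through the edges; the alternative (mirroring across the
  boundary node) does not conserve and is not used.
* **Wave initiation.**  Cable waves are launched by holding the first
  1 mm at 0 mV for 2 ms.  A current strong enough to launch a wave drives
  the end nodes far above physiologic peak voltages, and because APD is a
  function of peak Vm this produces an artificially long APD at the
  stimulus site; the voltage clamp avoids that.  2D plane waves use a 2 ms
  suprathreshold current (−30 µA/µF) along a 1 mm edge strip, where the
  same concern is diluted by the strip's small area.
* **Tissue inner loop.**  The 2D kernel evaluates `m∞`, `h∞`,
  `exp(−dt/τ_h)` and `I_K(Vm)` through voltage-indexed lookup tables
  (uniform 0.025 mV grid over ±250 mV, linear interpolation) built once
  per run for the run's dt.  The interpolation error is orders of
  magnitude below the PDE discretization error; the cell and cable
  kernels, which back the precision-sensitive 0D/1D results, evaluate the
  exponentials directly.
* **Conduction velocity** is measured from the (dVm/dt)max times at 25%
  and 75% of the cable, away from the initiation end and the far boundary.
  Halving dx from the reference 0.01 cm changes CV by ≈ 2.0%
  (54.16 → 55.25 cm/s).

## Virtual protocols

* **Dynamic I–V curves.**  In a cell the total current after stimulus
  offset is read as `−Cm dVm/dt`; during steady plane-wave propagation the
  wave-frame identity gives `Cm (D/CV² d²Vm/dt² − dVm/dt)`.  Both restrict
  to the upstroke (last sub-threshold sample to the Vm peak, stimulus
  samples excluded).  On a discrete cable the front advances node by node,
  imprinting a ripple of period dx/CV on single-site recordings that the
  second derivative amplifies; the propagation estimator therefore
  optionally takes its derivatives from a cubic Savitzky–Golay fit over
  ~two lattice periods, after which it agrees with the solver's recorded
  peak I_Na to ~2%.
* **Upstroke latency** (stimulus onset to (dVm/dt)max) is detected from
  the stimulus-free ionic rate `−(I_Na + I_K)/Cm`, which equals dVm/dt
  wherever the stimulus is off and excludes the stimulus artifact during
  the pulse.  This matters because the tuned test stimuli (2 ms pulses at
  1 ms latency) fire the upstroke *during* the pulse; a detector that only
  searched after stimulus offset could never report a latency below the
  pulse duration.  `find_stimulus_for_latency` exploits that latency
  decreases monotonically with pulse strength and bisects geometrically on
  the amplitude magnitude; a probe that overdrives Vm out of the physical
  range counts as "faster than target".
* **Recovery of excitability.**  Each synthetic myocyte waveform (below)
  drives a 10-beat action-potential clamp of the sodium current; at a
  chosen coupling time after the 10th-beat upstroke the simulation
  switches to current clamp from the clamped state and a 2 ms test pulse
  tuned to 1 ms latency is applied.  The test beat's peak I_Na, normalized
  to the 10th clamped beat's, is reported against the recovery time
  RT = (stimulus time) − (time Vm recovered to within 5 mV of rest);
  RT < 0 means the stimulus landed before full repolarization.  Points
  with no capture at any amplitude are recorded as zero response.  With
  the nominal model the curve rises monotonically, crosses ~0.5 just
  before full repolarization and exceeds 0.97 for RT ≥ 10 ms; the plateau
  sits ~1–2% above unity because the clamped reference beats are paced
  near threshold (≈2.5 ms latency, the regime the waveform ensemble
  emulates) and peak I_Na grows slightly as latency shortens.
* **APD and alternans.**  APD is measured from (dVm/dt)max to the first
  sample within 5 mV of rest — the same repolarization criterion as RT —
  so one convention covers both protocols.  Pacing scans run ≥ 40 beats
  per BCL (60 by default), discard the first half as transient, and flag
  alternans when steady-state even/odd APDs differ by more than 2 ms
  (well below the tens-of-ms alternans amplitude, well above residual
  transients).  Under 2 ms / −20 µA/µF pacing at dt = 0.001 ms the
  computed alternans window is BCL ∈ [200, 207] ms, delimited below by
  loss of 1:1 capture (BCL ≤ 199) and above by a period-doubling onset
  between 207 and 208 ms; the window edge positions move by ~1 ms with
  dt ∈ [0.0005, 0.002] and show no hysteresis under continuation.
* **Reduced two-variable model.**  Replacing `m³` by `m∞³(Vm)` removes
  activation kinetics, leaving (Vm, h).  The front then sharpens
  substantially: matching the full model's cable CV requires reducing
  g_Na to ≈ 3.6 mS/µF (bisection at 0.1 resolution) — a roughly
  threefold reduction.  Even at g_Na = 5.8 the reduced model's cable CV is
  ≈ 70 cm/s at the reference discretization (checked down to dt = 0.0005,
  dx = 0.005).  The reduced model exhibits steady-state APD alternans
  under pacing (e.g. ΔAPD ≈ 19 ms at BCL = 160 ms with g_Na = 5.8),
  demonstrating that inactivation kinetics alone, interacting with the
  nonlinear rectification of I_K, suffice for alternans.
* **Propagation failure** bisects a scale factor on g_Na to 1% resolution;
  failure means no upstroke at 90% of the cable after end-clamp
  initiation.  The computed threshold is an ≈ 81.5% conductance decrease,
  invariant (±1 point) to doubling the cable length.
* **Sensitivity matrix.**  Rows are the eight I_Na parameters
  (g_Na, E_Na, E_m, k_m, τ_m, E_h, k_h, τ_h0 — δ_h is excluded as the
  τ-bell's second, dependent shape parameter; this row set is a package
  convention).  Columns are eight AP quantities: cell and cable
  {peak inward I_Na, peak Vm, (dVm/dt)max or CV, APD}.  Entries are the
  percent change of each quantity per +1% parameter change; runs that
  lose capture yield NaN entries rather than aborting the matrix.
* **Repolarization sweep.**  Cell mode paces each (g_K, b) pair once with
  a uniform −30 µA/µF / 2 ms pulse (the capture threshold rises with g_K,
  and a uniform stimulus keeps the APD map comparable) and reports APD and
  peak Vm; APD rises with b and falls with g_K, spanning tens to hundreds
  of ms over g_K ∈ [0.1, 0.5], b ∈ [0.035, 0.05].  Tissue mode initiates a
  spiral per pair and reports cycle length, dominant frequency and the
  sustained/terminated/breakup classification.  The default 3×3 grid is
  g_K ∈ {0.1, 0.3, 0.5} × b ∈ {0.035, 0.0425, 0.05} (uniform over the
  physiological ranges); the full tissue sweep is an overnight CLI run.

## 2D spiral-wave experiments

Spirals are initiated by a cross-field S1–S2 protocol: an S1 plane wave
from one edge, then a 2 ms S2 current over one quadrant timed into the
vulnerable window of the S1 tail.  A helper scans the S2 timing until a
tracked tip completes a full rotation; the package default (S2 at 145 ms
on the 5×5 cm sheet) was found by that scan and is reproduced
deterministically.

Tip detection intersects the Vm = −30 mV isolines of consecutive
snapshots (points of zero normal velocity, i.e. phase singularities);
intersections are linked frame-to-frame by nearest neighbour within
0.4 cm, tolerating up to 3 missed frames (isoline intersections flicker
near tangency).  Episodes are classified *breakup* when ≥ 3 simultaneous
tips persist for ≥ 100 ms, *terminated* when the recorded site returns to
within 5 mV of rest before the episode end, else *sustained*.  The
trajectory extent (maximum pairwise tip distance within one rotation) is
a proxy for the length of the rotating line of functional block.

Problem sizes: the tests and default runs use dx = 0.02 cm sheets
(5.0 cm nominal, 4.8 cm short-APD regime) rather than dx = 0.01, a
package choice that preserves the phenomenology while keeping episodes at
desk scale; CV at dx = 0.02 is a few percent below the dx = 0.01 value.
With nominal parameters the episode sustains a single meandering spiral
(≥ 6 rotations over 1.5 s, cycle length ≈ 134 ms, trajectory extent
≈ 3.0 cm); at (g_K = 0.5, b = 0.035) — an APD ≈ 23 ms regime outside
normal rabbit physiology — the spiral fragments into many wavelets with a
dominant frequency of ≈ 30 Hz.  Only these two corners of the grid run in
the test suite; the 3×3 exclusivity statement (breakup in exactly one
cell of the grid) is an overnight claim checked via `pr sweep` in tissue
mode, not in the quick gate.

## Synthetic myocyte ensemble

The recovery protocol needs an ensemble of paced myocyte AP waveforms
(n = 6 by default): resting potential −83 ± 1 mV, APD 200 ± 15 ms, peak
~34 mV, 10 beats at BCL = 400 ms.  Rather than drawing spline shapes, the
generator runs the model itself with per-cell jitter: the drawn resting
potential shifts E_K, g_K receives a normal jitter (sd 0.02 mS/µF), and b
is calibrated by a secant iteration so the cell's single-beat APD hits its
drawn target; each cell is paced near threshold with its amplitude tuned
to a 2.5 ms upstroke latency, the latency regime of the microelectrode
recordings the ensemble stands in for.  This guarantees physiologic
upstroke–repolarization coupling and exercises the same solver paths as
every other experiment.  What it does *not* emulate: measurement noise,
electrode artifacts, beat-to-beat variability within a cell, and any
repolarization kinetics absent from the model itself — so passing tests
show protocol correctness and model-level behavior, not robustness to
real recording imperfections.  Generation is bit-deterministic given the
ensemble seed.

## Known limitations

* No calcium dynamics, no transient-outward or delayed-rectifier
  currents, no repolarization kinetics: APD is slaved to peak Vm, so
  stimulus strength visibly shifts APD, and rate-dependent APD
  accommodation beyond alternans is absent.
* The alternans window and the reduced-model conductance stated above are
  the values this implementation computes under the stated conditions;
  both protocols' full derivations and convergence checks are in the test
  suite.
* Tip tracking is isoline-intersection based; it is robust for the
  episodes here but coarser than phase-variable singularity detection,
  which is out of scope.
* The 2D solver is isotropic monodomain on a rectangle: no fiber
  anisotropy, no bidomain effects, no realistic geometry.
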