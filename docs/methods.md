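# Methods

This note documents the models, parameter choices and numerical
decisions behind `emgsim`, and what the synthetic-data tests do and do
not establish about real recordings.

## EMG processing chain

The chain is the standard linear-envelope recipe: zero-lag (forward–
backward) 4th-order Butterworth band-pass at 20–450 Hz, full-wave
rectification, zero-lag 4th-order Butterworth low-pass at 5 Hz,
per-muscle peak normalization, linear resampling to the simulation grid.
Zero-lag filtering squares the single-pass magnitude response and
cancels phase, so envelope peaks are not delayed relative to the
underlying bursts (asserted to sub-sample accuracy in the tests).

Decisions where the recipe is silent:

* **Edge handling** — even ("reflect") padding of length 3× the
  effective filter order for the forward–backward pass. The transient
  region this leaves at the extreme ends is why steady-state gains are
  measured over the central half of a test signal.
* **Envelope negativity** — the zero-phase low-pass can undershoot;
  outputs are clipped at 0 because activation is non-negative.
* **Normalization scope** — per muscle across the trials supplied in one
  call (a within-subject/session design). Cross-subject normalization is
  deliberately unsupported. Note the consequence: the peak activation of
  every recorded muscle is exactly 1.0 after normalization.
* **Resampling** — linear interpolation; grids outside the recorded span
  are an error rather than an extrapolation.
* Tremor-band content does not survive the 5 Hz envelope; oscillatory
  components are injected downstream by the scenario engine, never
  reconstructed from the raw signal.

## Synthetic EMG surrogate

Raw EMG is emulated as amplitude-modulated band-limited noise:
`x(t) = (p(t) + n₀·ξ(t)) · c(t)` with `p` a smooth raised-cosine
activation burst per cycle, `n₀` a noise floor (default 0.05), and `c`
zero-mean unit-RMS Gaussian noise band-passed to 20–450 Hz. Per-muscle
streams derive from one master seed by fixed offsets, so a seed pins the
entire recording bit-for-bit.

Default study conditions (chosen once as a plausible self-paced cycle):
4 s flexion–extension cycle at 2000 Hz; flexor burst peaking at 30 % of
the cycle with 50 % width and amplitude 0.8; extensor burst at 75 % with
40 % width and amplitude 0.25, riding on a 0.05 tonic co-contraction
floor (stabilizing antagonist activity, which also gives antagonist-
scaling scenarios mechanical leverage during flexion). Amplitudes are
stated pre-normalization; after per-muscle normalization both profiles
peak at 1.

The surrogate reproduces the two properties the processing chain sees —
amplitude modulation and spectral band — and nothing else. Passing the
recovery test (envelope–profile correlation ≥ 0.95) shows the chain is
faithful to the modulation; it says nothing about crosstalk, electrode
placement, motor-unit structure or fatigue in real data.

## Elbow model

Single DOF, flexion positive, θ = 0 with the forearm hanging vertically
(seated, upper arm supported). Rigid-tendon Hill-type actuators: fiber
length is algebraic in θ through a constant signed moment arm,
`ℓ_f cos α = ℓ_MTU(θ) − ℓ_slack`, `ℓ_MTU = ℓ₀ − r·θ`. Curve forms:
Gaussian active force–length `exp(−((ℓ̃−1)/0.45)²)`; Hill hyperbola
force–velocity with shortening intercept at ṽ = −1 and eccentric
plateau 1.4; exponential passive force engaging above optimal length
(k_pe = 4, ε₀ = 0.6). Activation dynamics are first-order with
τ_act = 10 ms / τ_deact = 40 ms, advanced by the exact exponential
update under zero-order hold (a bypass flag treats envelopes as
activations directly).

Muscle parameters follow published upper-limb model values:

| muscle  | F_max (N) | ℓ_opt (m) | ℓ_slack (m) | pennation (rad) | r (m) |
|---------|-----------|-----------|-------------|-----------------|--------|
| BIClong | 624.3     | 0.1157    | 0.2723      | 0               | +0.036 |
| TRIlong | 798.5     | 0.1340    | 0.1430      | 0.209           | −0.021 |
| BRA     | 987.3     | 0.0858    | 0.0535      | 0               | +0.022 |
| BRD     | 261.3     | 0.1726    | 0.1330      | 0               | +0.055 |

`v_max` = 10 ℓ_opt/s for all; each fiber sits at optimal length at
θ = 1 rad (`theta_opt`, configurable), which fixes ℓ_MTU(0). Constant
averaged moment arms replace polynomial geometry — a deliberate
simplification appropriate for a 1-DOF model; d(ℓ_MTU)/dθ = −r exactly.

Forearm + hand segment: m = 1.8 kg, elbow-to-COM c = 0.18 m,
I = 0.09 kg·m² about the elbow (standard adult anthropometry). Joint
limits 0–150° with exponential end-range stiffness
`k_lim (e^{−β(θ−θ_min)} − e^{β(θ−θ_max)})`, k_lim = 5 Nm, β = 30 rad⁻¹
(mid-range magnitude < 10⁻³ Nm), plus light passive damping
c_damp = 0.25 Nm·s/rad.

### The task-constraint term and the net internal moment

With every muscle normalized to peak activation 1.0, literature-strength
flexors acting on an unloaded forearm (gravity ≤ ~3 Nm, I = 0.09 kg·m²)
would slam the joint to its limit in a fraction of a second; a smooth
self-paced cycle is impossible on passive properties alone. The model
therefore includes a lumped viscous task-constraint moment
`M_task = −c_task·θ̇` with c_task = 25 Nm·s/rad, representing everything
that keeps a comfortable paced movement slow: soft-tissue damping,
unmodelled stabilizing co-contraction, and the subject's own pacing.

`M_task` enters the equation of motion like gravity but is **excluded**
from the reported net internal flexion–extension moment, which is
defined as muscle moments + passive joint mechanics. This split is what
makes the reported moment muscle-dominated (tens of Nm during the
flexor burst) rather than pinned to the small gravity mirror that any
quasi-static internal balance would otherwise impose — and it is the
only reading under which published desk-scale moment magnitudes
(~74 Nm peak alongside an ~85°, 1.3 s movement) are dynamically
consistent. The bookkeeping identity
`net_moment(t) = Σᵢ rᵢFᵢ(t) + M_passive(t)` holds to 1e-9 by
construction and is asserted in the tests.

### Integration

Fixed-step classical RK4 at dt = 1 ms (envelopes are interpolated
linearly onto the integration grid; activation states are precomputed).
The fastest system time constant is I/c_total ≈ 3.6 ms, comfortably
resolved; step-halving changes the final angle by < 0.1°. Initial state
defaults to the passive static equilibrium (≈ 31° with the default
parameters), located by bracketed root-finding on the static moment
balance. Non-finite state aborts with the failure time. The simulation
is deterministic: identical inputs give bit-identical results.

## Scenario engine

All modifications act on the normalized envelopes; the model never
changes. Outputs are clipped to [0, 1].

* **Weakness** — flexors × (1 − f). Exactly linear below clipping, so
  severity composes multiplicatively; timing of every local maximum is
  untouched.
* **Co-activation** — triceps × (1 + f), clipped at 1; flexors
  byte-identical.
* **Spasticity-like** — a′ = clip(b + g·a) with named severities mild
  (0.10, 1.1), moderate (0.20, 1.3), severe (0.30, 1.5). Default target
  is the task antagonist (TRIlong): movement-opposing tonic activity is
  the mechanism that progressively brakes flexion, shrinks ROM and
  attenuates the net moment with severity — the directional pattern the
  severity ladder is meant to produce. Any muscle subset can be
  targeted; tonic+gain on the flexors of a flexion task instead *adds*
  drive and enlarges the movement. This is a first-order activation-
  level approximation; velocity-dependent reflex dynamics are out of
  scope.
* **Tremor-like** — multiplicative modulation
  a′ = clip(a·(1 + A·w(t)·sin(2πf t + φ))), default f = 8 Hz (midpoint
  of the 4–12 Hz pathological band), applied to BIClong, BRD and
  TRIlong (TRIlong in antiphase, φ = π; BRA spared), inside cycle-
  fraction windows (0.20–0.60) and (0.60–0.85) with a 5 % cosine taper
  at each window edge. Multiplicative (relative-to-baseline) modulation
  keeps the cycle mean nearly unchanged (< 5 % of A). Whether tremor
  should run episodically (windows) or continuously is ambiguous in the
  source material; the windows are configuration, not hard-coded.

## Outcome metrics

ROM = max θ − min θ; peak flexion/moment with earliest-sample
tie-breaking, reported in seconds and % cycle; final angle at cycle end
(detects incomplete extension); time normalization to 101 points.

The **oscillation index** has no published definition; the
reconstruction used here is OI = RMS(M − LP₃(M)) / max|M| with a
zero-phase 4th-order Butterworth low-pass at 3 Hz — below the 4–12 Hz
tremor band, above voluntary-movement content. It is scale-invariant
and zero for constant traces. Tremor metrics use the same residual:
amplitude = residual RMS, dominant frequency = periodogram argmax over
[3 Hz, Nyquist), flagged undefined when the residual is < 10⁻⁶ of the
peak moment. At least 2 s of data are required for 0.5 Hz resolution.

## MQI

Components are normalized to [0, 1] and averaged with equal weights
(alternative weight vectors are accepted):

* moment score `clip(1 − |M_pk − M_pk,ref|/M_pk,ref)` — reconstructed
  by fitting all 16 rows of the published per-condition table,
  including the co-activation rows where moments *above* reference
  still lower the score.
* stability score `1 − OI/max(block OI)` — reconstructed likewise
  (block-maximum rows print exactly 0.000 in all four published
  blocks); the reference condition participates in the block maximum.
* kinematic score `clip(1 − |ROM − ROM_ref|/ROM_ref)` — the published
  kinematic column cannot be recovered exactly from the printed
  kinematic inputs by any simple ratio; the symmetric-deviation form is
  used because the published co-activation and tremor blocks penalize
  *enlarged* excursions, which a clipped ROM ratio cannot. The formula
  is configurable.

Known mismatch, documented rather than hidden: the published aggregate
MQI values are not the equal-weight mean of the published component
scores (e.g. a printed row with components 1.00/1.00/0.165 prints an
MQI of 79.14, not 72.2). This package follows the stated equal-weight
aggregation; consequently absolute MQI values are comparable only
within `emgsim`, while component scores reconstruct the published cells
exactly (moment scores to 2 dp; stability scores within print rounding,
±0.01). Severity *ordering* of the MQI within each scenario family is
reproduced and tested.

## Problem sizes and determinism

The default study battery is one 4 s cycle at 2000 Hz synthesis,
envelopes on a 200 Hz grid, dynamics at dt = 1 ms: 13 forward
simulations (healthy + four 3-level severity ladders), about half a
minute in total. All randomness flows from a single integer seed
through `numpy.random.default_rng`; the simulator itself is
deterministic, so repeated runs are byte-identical.

## Limitations

* One joint, one DOF; no shoulder/wrist coupling, no wrapping geometry.
* Constant moment arms and generic (non-individualized) muscle–tendon
  parameters; absolute angles and moments are model-specific and should
  be read comparatively, not clinically.
* The rigid-tendon assumption overestimates fiber-length excursion for
  long-tendon muscles at extreme angles.
* Scenario mechanisms are activation-level approximations (no reflex
  loops, no velocity-dependent spasticity, no tremor neurophysiology).
* The MQI is an engineering comparison metric, not a validated clinical
  outcome score.
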