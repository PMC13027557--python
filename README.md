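# emgsim

EMG-driven forward-dynamic simulation of the elbow, with parametric
virtual impairment scenarios and composite movement-quality scoring.

Surface electromyography (EMG) records muscle activation, but the
joint-level mechanical consequences of an activation pattern cannot be
read off the signal directly. `emgsim` closes that gap for a
single-degree-of-freedom elbow: normalized EMG linear envelopes are used
as the *sole* neural drive of a forward-dynamic Hill-type
musculoskeletal model (no tracking, optimization or feedback), so every
change in the simulated movement is attributable to the activation
pattern that produced it. Controlled modifications of the envelopes —
weakness, antagonist co-activation, spasticity-like tonic activity,
tremor-like oscillation — then turn the simulator into a virtual
scenario laboratory for activation-dependent movement alterations. The
package is aimed at biomechanics and rehabilitation-engineering
researchers who want a transparent, fully scriptable desk-scale
alternative to a full OpenSim pipeline.

## What it computes

**EMG processing.** Raw EMG (2000 Hz in the reference protocol) is
band-pass filtered with a zero-lag 4th-order Butterworth (20–450 Hz),
full-wave rectified, low-pass filtered at 5 Hz (zero-lag) into linear
envelopes, normalized per muscle to the maximum activation observed
across trials, and resampled to the simulation grid. Envelopes are
prescribed inputs: nothing is rescaled or optimized afterwards.

**Forward dynamics.** Four muscle–tendon actuators span the elbow —
biceps long head (BIClong), triceps long head (TRIlong), brachialis
(BRA), brachioradialis (BRD) — each a rigid-tendon Hill-type model

    F = F_max [ a · f_L(ℓ̃) · f_V(ṽ) + f_P(ℓ̃) ] cos α,

with Gaussian active force–length `f_L`, Hill-hyperbola force–velocity
`f_V` (eccentric plateau 1.4), exponential passive `f_P`, pennation α,
and first-order activation dynamics (τ_act = 10 ms, τ_deact = 40 ms).
Constant signed moment arms `r_i` map forces to joint moments, and the
joint obeys

    I θ̈ = Σᵢ rᵢ Fᵢ + M_passive(θ, θ̇) + M_task(θ̇) − m g c sin θ,

integrated with fixed-step RK4 (dt = 1 ms). The reported **net internal
moment** is Σᵢ rᵢ Fᵢ + M_passive — gravity and the viscous
task-constraint term are external to it.

**Scenarios.** Applied to the activation envelopes only:
weakness (flexors × (1−f), f ∈ {0.2, 0.4, 0.6}), co-activation
(triceps × (1+f), clipped at 1), spasticity-like (a′ = clip(b + g·a),
severity-graded tonic/gain), tremor-like (multiplicative sinusoid,
default 8 Hz within the 4–12 Hz band, in 20–60 % and 60–85 % cycle
windows, antagonist in antiphase).

**Outcomes and MQI.** Range of motion, peak flexion and timing, peak
net moment and timing, final angle, oscillation index
(OI = RMS of the >3 Hz moment residual / max |M|), tremor residual RMS
and dominant frequency. The Movement Quality Index aggregates three
unit-interval component scores with equal weights:

    kinematic  s_K = clip(1 − |ROM − ROM_ref| / ROM_ref, 0, 1)
    moment     s_M = clip(1 − |M_pk − M_pk,ref| / M_pk,ref, 0, 1)
    stability  s_S = 1 − OI / max(OI over the block)
    MQI = 100 · (s_K + s_M + s_S) / 3

## Worked example

```python
import emgsim as es

baseline = es.baseline_from_synthetic(es.SyntheticProfileSpec(seed=1))
model = es.ElbowModelParams()

healthy = es.compute_outcomes(es.forward_simulate(baseline, model), label="healthy")
weak = es.build_scenario_set(baseline, es.ScenarioSpec(kind="weakness", weakness_fraction=0.4))
weak40 = es.compute_outcomes(es.forward_simulate(weak, model), label="weakness -40%")

for m in (healthy, weak40):
    print(f"{m.label:14s} peak moment {m.peak_moment:5.1f} Nm, "
          f"peak flexion {m.peak_flexion:5.1f} deg, ROM {m.rom:5.1f} deg")
```

prints

```
healthy        peak moment  40.9 Nm, peak flexion 107.3 deg, ROM  77.7 deg
weakness -40%  peak moment  25.4 Nm, peak flexion  74.8 deg, ROM  46.2 deg
```

— a 40 % cut in flexor drive costs this model 38 % of its peak net
moment and 30° of peak flexion while leaving activation timing intact,
the qualitative signature of simulated muscle weakness. The
`examples/` directory has one narrative script per capability
(envelope recovery, forward dynamics, the four scenario ladders, the
full MQI pipeline, published-score reconstruction); each prints the
numbers it computes and what they mean. `emgsim run --seed 1 --out
results_dir` does the same from the shell.

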