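"""Apply the four virtual impairment mechanisms to one baseline.

Each scenario modifies the normalized activation envelopes only — the
musculoskeletal model never changes — and the table shows how each
mechanism reshapes the movement: weakness shrinks moment and excursion,
antagonist co-activation brakes the movement, spasticity-like tonic
antagonist activity constrains it progressively, and tremor injects
8 Hz oscillation into the net moment.
"""

import emgsim as es

baseline = es.baseline_from_synthetic(es.SyntheticProfileSpec(seed=1))
model = es.ElbowModelParams()

conditions = [es.ScenarioSpec(kind="healthy")]
for family, specs in es.FAMILY_SPECS.items():
    conditions.extend(specs)

print(f"{'condition':24s} {'peakM Nm':>9s} {'ROM deg':>8s} {'peak deg':>9s} "
      f"{'OI':>7s} {'f_dom Hz':>9s}")
for spec in conditions:
    acts = es.build_scenario_set(baseline, spec)
    m = es.compute_outcomes(es.forward_simulate(acts, model), label=spec.label())
    dom = f"{m.dominant_freq:.1f}" if m.dominant_freq is not None else "-"
    print(f"{m.label:24s} {m.peak_moment:9.2f} {m.rom:8.1f} {m.peak_flexion:9.1f} "
          f"{m.oscillation_index:7.4f} {dom:>9s}")
print("\nTremor rows: the dominant residual frequency equals the injected "
      "8 Hz modulation; the oscillation index grows with tremor amplitude.")
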