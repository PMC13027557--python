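"""Synthesize raw surface EMG and recover its activation envelope.

Generates a seeded amplitude-modulated noise surrogate for one biceps
channel, runs the full pre-processing chain (20-450 Hz zero-phase
band-pass, rectification, 5 Hz zero-phase envelope, peak normalization),
and reports how well the recovered envelope matches the profile that
generated the signal.  A correlation near 1 means the chain is faithful.
"""

import numpy as np

import emgsim as es

spec = es.SyntheticProfileSpec(seed=11)
profile = es.cycle_activation_profile(spec, "flexor")
raw = es.synthesize_raw_emg(profile, spec, muscle="BIClong")
print(f"raw EMG: {raw.n_samples} samples at {raw.sample_rate:.0f} Hz, "
      f"RMS {np.sqrt(np.mean(raw.samples**2)):.3f} mV")

(envelope,) = es.process_recording(raw, es.FilterSpec())
r = np.corrcoef(envelope.values, profile.values)[0, 1]
print(f"envelope peak after normalization: {envelope.values.max():.3f} "
      f"(norm reference {envelope.norm_reference:.3f} mV)")
print(f"correlation with the generating profile: r = {r:.4f}")
print("r >= 0.95 means the linear-envelope chain faithfully recovers the "
      "activation profile underneath the noise carrier.")
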