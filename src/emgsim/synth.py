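"""Seeded synthetic surface-EMG generation.

Real recordings of cyclic elbow flexion–extension are emulated by
amplitude-modulating band-limited (20–450 Hz) Gaussian noise with a
smooth per-muscle activation burst.  The generating profile is known
exactly, so the whole processing chain can be validated by parameter
recovery: processing the synthetic raw EMG must give back an envelope
highly correlated with the profile that produced it.

The surrogate is deliberately minimal: it reproduces the amplitude
modulation and spectral band of surface EMG, not motor-unit structure,
fatigue-related spectral compression, or electrode effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .emg import ActivationEnvelope, ConfigurationError, RawEMGRecording

#: canonical muscle set of the single-DOF elbow model
MUSCLES = ("BIClong", "TRIlong", "BRA", "BRD")
FLEXORS = ("BIClong", "BRA", "BRD")
EXTENSORS = ("TRIlong",)

# fixed per-muscle offsets from the master seed: independent noise streams
_SEED_OFFSETS = {name: 101 + 17 * i for i, name in enumerate(MUSCLES)}


@dataclass(frozen=True)
class SyntheticProfileSpec:
    """Study conditions for one synthetic flexion–extension recording.

    Defaults emulate a self-paced cycle of roughly four seconds with a
    submaximal flexor burst peaking in the first half of the cycle and a
    weaker extensor burst assisting the return in the second half.
    """

    duration: float = 4.0
    cycle_count: int = 1
    flexor_peak_frac: float = 0.30
    amplitude: float = 0.8
    extensor_amplitude: float = 0.25
    sample_rate: float = 2000.0
    noise_floor: float = 0.05
    seed: int = 0
    flexor_width_frac: float = 0.5  # raised-cosine burst width, fraction of a cycle
    extensor_peak_frac: float = 0.75
    extensor_width_frac: float = 0.4
    extensor_tonic: float = 0.05    # stabilizing co-contraction floor of the extensor

    def __post_init__(self) -> None:
        if not (0.0 < self.flexor_peak_frac < 1.0):
            raise ValueError("flexor_peak_frac must be in (0, 1)")
        if not (0.0 <= self.amplitude <= 1.0 and 0.0 <= self.extensor_amplitude <= 1.0):
            raise ValueError("amplitudes must be in [0, 1]")
        if self.duration <= 0 or self.cycle_count < 1:
            raise ValueError("duration must be > 0 and cycle_count >= 1")

    @property
    def cycle_duration(self) -> float:
        return self.duration / self.cycle_count

    def time_grid(self) -> np.ndarray:
        n = int(round(self.duration * self.sample_rate))
        return np.arange(n) / self.sample_rate


def _raised_cosine_burst(cycle_frac: np.ndarray, peak_frac: float, width_frac: float,
                         amplitude: float) -> np.ndarray:
    """Smooth non-negative burst: 0.5(1+cos) window centred at peak_frac."""
    x = (cycle_frac - peak_frac) / (width_frac / 2.0)
    burst = np.where(np.abs(x) <= 1.0, 0.5 * (1.0 + np.cos(np.pi * x)), 0.0)
    return amplitude * burst


def cycle_activation_profile(spec: SyntheticProfileSpec, role: str) -> ActivationEnvelope:
    """Per-cycle raised-cosine activation burst for a flexor or extensor.

    The flexor burst peaks at ``flexor_peak_frac`` of each cycle; the
    extensor burst peaks in the second half (return phase) and rides on
    a low tonic co-contraction floor.  Peak value equals the requested
    amplitude exactly (up to grid resolution).
    """
    if role not in ("flexor", "extensor"):
        raise ValueError(f"role must be 'flexor' or 'extensor', got {role!r}")
    t = spec.time_grid()
    cycle_frac = (t % spec.cycle_duration) / spec.cycle_duration
    if role == "flexor":
        vals = _raised_cosine_burst(cycle_frac, spec.flexor_peak_frac,
                                    spec.flexor_width_frac, spec.amplitude)
        muscle = "flexor_profile"
    else:
        tonic = min(spec.extensor_tonic, spec.extensor_amplitude)
        burst = _raised_cosine_burst(cycle_frac, spec.extensor_peak_frac,
                                     spec.extensor_width_frac, 1.0)
        vals = tonic + (spec.extensor_amplitude - tonic) * burst
        muscle = "extensor_profile"
    return ActivationEnvelope(muscle=muscle, time=t, values=vals,
                              normalized=True, norm_reference=1.0)


def _band_limited_carrier(n: int, sample_rate: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS Gaussian noise band-passed to the surface-EMG band."""
    white = rng.standard_normal(n)
    sos = signal.butter(4, [20.0, 450.0], btype="bandpass", fs=sample_rate, output="sos")
    carrier = signal.sosfiltfilt(sos, white)
    rms = np.sqrt(np.mean(carrier**2))
    return carrier / rms if rms > 0 else carrier


def synthesize_raw_emg(
    profile: ActivationEnvelope,
    spec: SyntheticProfileSpec,
    muscle: str = "BIClong",
) -> RawEMGRecording:
    """Amplitude-modulated band-limited noise surrogate for one channel.

    ``out(t) = (profile(t) + noise_floor * xi(t)) * carrier(t)`` where the
    carrier is zero-mean unit-RMS Gaussian noise confined to 20–450 Hz.
    A fixed seed gives bit-identical output.
    """
    if spec.sample_rate < 1000.0:
        raise ConfigurationError(
            f"sample_rate {spec.sample_rate} Hz too low for a 20-450 Hz carrier"
        )
    n = profile.values.size
    seed = (spec.seed + _SEED_OFFSETS.get(muscle, 499)) % (2**31)
    rng = np.random.default_rng(seed)
    floor_noise = spec.noise_floor * np.abs(rng.standard_normal(n)) if spec.noise_floor > 0 else 0.0
    modulation = profile.values + floor_noise
    if not np.any(modulation):
        samples = np.zeros(n)
    else:
        carrier = _band_limited_carrier(n, spec.sample_rate, rng)
        samples = modulation * carrier
    return RawEMGRecording(
        muscle_names=(muscle,),
        sample_rate=spec.sample_rate,
        samples=samples[:, None],
        t0=float(profile.time[0]),
    )


def synthesize_recording(spec: SyntheticProfileSpec) -> RawEMGRecording:
    """Four-channel synthetic recording for the canonical elbow muscle set.

    Flexors (BIClong, BRA, BRD) share the flexor profile, the extensor
    (TRIlong) gets the extensor profile; each channel has an independent
    noise stream derived from the master seed.
    """
    flex = cycle_activation_profile(spec, "flexor")
    ext = cycle_activation_profile(spec, "extensor")
    channels = []
    for name in MUSCLES:
        prof = ext if name in EXTENSORS else flex
        channels.append(synthesize_raw_emg(prof, spec, muscle=name).samples[:, 0])
    return RawEMGRecording(
        muscle_names=MUSCLES,
        sample_rate=spec.sample_rate,
        samples=np.column_stack(channels),
    )
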