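"""Surface-EMG pre-processing: band-pass, rectification, linear envelopes.

The processing chain turns raw multi-channel surface EMG into normalized
activation envelopes suitable as prescribed neural drive for forward
dynamics: zero-phase Butterworth band-pass (20–450 Hz), full-wave
rectification, zero-phase low-pass (5 Hz) envelope extraction,
per-muscle peak normalization across trials, and resampling onto the
simulation time grid.  Envelopes are treated as prescribed inputs
downstream — no amplitude optimization is ever applied after
normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal


class ConfigurationError(ValueError):
    """Raised when filter or model configuration is inconsistent."""


class DegenerateSignalError(ValueError):
    """Raised when a signal carries no usable content (e.g. all-zero)."""


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth filter settings for the EMG chain.

    ``band_lo``/``band_hi`` bound the band-pass in Hz, ``env_cutoff`` is
    the envelope low-pass cut-off.  ``zero_lag`` selects forward-backward
    filtering (squared single-pass magnitude, no phase lag).
    """

    band_lo: float = 20.0
    band_hi: float = 450.0
    bp_order: int = 4
    env_cutoff: float = 5.0
    env_order: int = 4
    zero_lag: bool = True

    def validate(self, sample_rate: float) -> None:
        if not (0.0 < self.band_lo < self.band_hi):
            raise ConfigurationError(
                f"band edges must satisfy 0 < lo < hi, got {self.band_lo}-{self.band_hi}"
            )
        if self.band_hi >= sample_rate / 2.0:
            raise ConfigurationError(
                f"band_hi {self.band_hi} Hz violates Nyquist for fs={sample_rate} Hz"
            )
        if not (self.env_cutoff < self.band_lo):
            raise ConfigurationError(
                f"env_cutoff {self.env_cutoff} must lie below band_lo {self.band_lo}"
            )
        if self.bp_order < 1 or self.env_order < 1:
            raise ConfigurationError("filter orders must be >= 1")


@dataclass(frozen=True)
class RawEMGRecording:
    """Multi-channel raw EMG block: ``samples`` is time x channels in mV."""

    muscle_names: tuple[str, ...]
    sample_rate: float
    samples: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim == 1:
            samples = samples[:, None]
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "muscle_names", tuple(self.muscle_names))
        if samples.shape[0] < 2:
            raise ValueError("recording needs at least 2 samples per channel")
        if samples.shape[1] != len(self.muscle_names):
            raise ValueError(
                f"{samples.shape[1]} channels but {len(self.muscle_names)} muscle names"
            )
        if not np.isfinite(samples).all():
            raise ValueError("recording contains non-finite samples")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def time(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.sample_rate


@dataclass(frozen=True)
class ActivationEnvelope:
    """Per-muscle activation envelope on its own time base.

    ``norm_reference`` records the per-muscle maximum that was divided
    out during normalization so the absolute scale can be recovered.
    """

    muscle: str
    time: np.ndarray
    values: np.ndarray
    normalized: bool = False
    norm_reference: float | None = None

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "values", values)
        if time.shape != values.shape:
            raise ValueError("time and values must have equal length")
        if time.size >= 2 and not np.all(np.diff(time) > 0):
            raise ValueError("time must be strictly increasing")
        if self.normalized and values.size and (values.min() < -1e-12 or values.max() > 1 + 1e-9):
            raise ValueError("normalized envelope values must lie in [0, 1]")


def _pad_len(order: int, n: int) -> int:
    # even ("reflect") padding, 3x the underlying filter order
    pad = 3 * max(order * 2, 1)  # band-pass doubles the order
    if pad >= n:
        raise ValueError(
            f"signal of {n} samples too short for zero-phase transient padding ({pad})"
        )
    return pad


def bandpass_filter(rec: RawEMGRecording, spec: FilterSpec = FilterSpec()) -> RawEMGRecording:
    """Zero-phase Butterworth band-pass applied channel-wise.

    Forward-backward filtering doubles the attenuation (effective gain is
    the squared single-pass magnitude) and cancels the phase response.
    """
    spec.validate(rec.sample_rate)
    sos = signal.butter(
        spec.bp_order,
        [spec.band_lo, spec.band_hi],
        btype="bandpass",
        fs=rec.sample_rate,
        output="sos",
    )
    pad = _pad_len(spec.bp_order, rec.n_samples)
    if spec.zero_lag:
        out = signal.sosfiltfilt(sos, rec.samples, axis=0, padtype="even", padlen=pad)
    else:
        out = signal.sosfilt(sos, rec.samples, axis=0)
    return replace(rec, samples=out)


def rectify(rec: RawEMGRecording) -> RawEMGRecording:
    """Full-wave rectification (elementwise absolute value)."""
    return replace(rec, samples=np.abs(rec.samples))


def extract_envelope(rec: RawEMGRecording, spec: FilterSpec = FilterSpec()) -> list[ActivationEnvelope]:
    """Zero-phase low-pass of the rectified signal; linear envelopes.

    The caller is responsible for having band-passed and rectified the
    input.  Small negative excursions from the zero-phase low-pass are
    clipped to zero (activation is non-negative by definition).
    """
    if spec.env_cutoff >= rec.sample_rate / 2.0:
        raise ConfigurationError(
            f"env_cutoff {spec.env_cutoff} Hz violates Nyquist for fs={rec.sample_rate}"
        )
    sos = signal.butter(spec.env_order, spec.env_cutoff, btype="lowpass",
                        fs=rec.sample_rate, output="sos")
    pad = _pad_len(spec.env_order, rec.n_samples)
    if spec.zero_lag:
        env = signal.sosfiltfilt(sos, rec.samples, axis=0, padtype="even", padlen=pad)
    else:
        env = signal.sosfilt(sos, rec.samples, axis=0)
    env = np.clip(env, 0.0, None)
    t = rec.time
    return [
        ActivationEnvelope(muscle=name, time=t, values=env[:, i])
        for i, name in enumerate(rec.muscle_names)
    ]


def normalize_envelopes(envelopes: list[ActivationEnvelope]) -> list[ActivationEnvelope]:
    """Divide each muscle's envelopes by that muscle's global maximum.

    The maximum is taken across all supplied trials of the same muscle
    (within-subject normalization); no MVC scaling is involved.
    """
    by_muscle: dict[str, float] = {}
    for env in envelopes:
        peak = float(env.values.max(initial=0.0))
        by_muscle[env.muscle] = max(by_muscle.get(env.muscle, 0.0), peak)
    out = []
    for env in envelopes:
        ref = by_muscle[env.muscle]
        if ref <= 0.0:
            raise DegenerateSignalError(
                f"muscle '{env.muscle}': global maximum is zero, cannot normalize"
            )
        out.append(
            ActivationEnvelope(
                muscle=env.muscle,
                time=env.time,
                values=env.values / ref,
                normalized=True,
                norm_reference=ref,
            )
        )
    return out


def resample_to_grid(env: ActivationEnvelope, grid: np.ndarray) -> ActivationEnvelope:
    """Linear interpolation of an envelope onto a simulation time grid."""
    grid = np.asarray(grid, dtype=float)
    if grid.size >= 2 and not np.all(np.diff(grid) > 0):
        raise ValueError("grid must be strictly increasing")
    if grid[0] < env.time[0] - 1e-12 or grid[-1] > env.time[-1] + 1e-12:
        raise ValueError(
            f"grid [{grid[0]}, {grid[-1]}] outside recorded span "
            f"[{env.time[0]}, {env.time[-1]}]"
        )
    vals = np.interp(grid, env.time, env.values)
    if env.normalized:
        vals = np.clip(vals, 0.0, 1.0)
    return ActivationEnvelope(
        muscle=env.muscle,
        time=grid,
        values=vals,
        normalized=env.normalized,
        norm_reference=env.norm_reference,
    )


def process_recording(
    rec: RawEMGRecording,
    spec: FilterSpec = FilterSpec(),
    grid: np.ndarray | None = None,
) -> list[ActivationEnvelope]:
    """Full chain: band-pass -> rectify -> envelope -> normalize -> resample.

    Returns one normalized :class:`ActivationEnvelope` per channel, on
    ``grid`` if given, else on the recording's own time base.  The output
    is deterministic and never amplitude-adjusted after normalization.
    """
    filtered = bandpass_filter(rec, spec)
    rectified = rectify(filtered)
    envelopes = extract_envelope(rectified, spec)
    normalized = normalize_envelopes(envelopes)
    if grid is not None:
        normalized = [resample_to_grid(e, grid) for e in normalized]
    return normalized


def zero_phase_bandpass_gain(freq: float, spec: FilterSpec, sample_rate: float) -> float:
    """Closed-form zero-phase gain of the digital Butterworth band-pass.

    Uses the bilinear-transform relation: the digital response at f equals
    the analog prototype response at nu = tan(pi f / fs), with band edges
    prewarped the same way.  The forward-backward pass squares the
    single-pass magnitude.
    """
    nu = np.tan(np.pi * freq / sample_rate)
    nu_lo = np.tan(np.pi * spec.band_lo / sample_rate)
    nu_hi = np.tan(np.pi * spec.band_hi / sample_rate)
    if nu == 0.0:
        return 0.0
    omega = (nu * nu - nu_lo * nu_hi) / (nu * (nu_hi - nu_lo))
    single_pass_sq = 1.0 / (1.0 + omega ** (2 * spec.bp_order))
    return float(single_pass_sq)  # |H|^2 of single pass = filtfilt gain
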