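"""Biomechanical outcome measures computed from a simulation result.

Covers range of motion, peak flexion angle and timing, peak net joint
moment and timing, final angle (incomplete-extension detection), an
oscillation index for moment smoothness, and tremor spectral metrics
(residual RMS amplitude and dominant frequency).

The oscillation index is defined here as the RMS of the high-frequency
residual of the net moment (above a 3 Hz zero-phase low-pass, i.e.
below the 4–12 Hz tremor band but above voluntary-movement content)
normalized by the peak absolute moment.  It is scale-invariant and zero
for a constant moment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .dynamics import SimulationResult


@dataclass
class OutcomeMetrics:
    """Scalar outcomes of one simulated condition."""

    label: str
    rom: float                 # deg
    peak_flexion: float        # deg
    t_peak_flexion: float      # s
    pct_peak_flexion: float    # % cycle
    peak_moment: float         # Nm
    t_peak_moment: float       # s
    pct_peak_moment: float     # % cycle
    final_angle: float         # deg at cycle end
    oscillation_index: float
    tremor_amplitude: float    # Nm, RMS of high-frequency residual
    dominant_freq: float | None  # Hz; None when no oscillatory content


def time_normalize(time: np.ndarray, values: np.ndarray,
                   cycle_span: tuple[float, float]) -> np.ndarray:
    """Resample a series onto 101 points spanning 0–100% of the cycle."""
    t0, t1 = cycle_span
    if not (t1 > t0):
        raise ValueError("degenerate cycle span")
    if t0 < time[0] - 1e-9 or t1 > time[-1] + 1e-9:
        raise ValueError("cycle span outside the series time range")
    grid = np.linspace(t0, t1, 101)
    return np.interp(grid, time, values)


def _pct_of_cycle(t: float, span: tuple[float, float]) -> float:
    t0, t1 = span
    return 100.0 * (t - t0) / (t1 - t0)


def compute_kinematic_metrics(result: SimulationResult) -> dict[str, float]:
    """ROM, peak flexion with timing, and final angle of the cycle.

    Ties at the peak are broken toward the earliest sample.
    """
    theta, time = result.theta, result.time
    i_peak = int(np.argmax(theta))  # argmax returns the first maximum
    span = result.cycle_span
    return {
        "rom": float(theta.max() - theta.min()),
        "peak_flexion": float(theta[i_peak]),
        "t_peak_flexion": float(time[i_peak]),
        "pct_peak_flexion": _pct_of_cycle(float(time[i_peak]), span),
        "final_angle": float(np.interp(span[1], time, theta)),
    }


def _highpass_residual(moment: np.ndarray, fs: float, fc: float) -> np.ndarray:
    """Residual above a zero-phase Butterworth low-pass at fc."""
    sos = signal.butter(4, fc, btype="lowpass", fs=fs, output="sos")
    trend = signal.sosfiltfilt(sos, moment, padtype="even")
    return moment - trend


def oscillation_index(moment: np.ndarray, fs: float, fc: float = 3.0) -> float:
    """Normalized high-frequency content of a joint-moment trace.

    ``OI = RMS(M - lowpass(M, fc)) / max|M|``; returns 0 for an
    identically-zero trace.
    """
    moment = np.asarray(moment, dtype=float)
    peak = float(np.max(np.abs(moment)))
    if peak == 0.0:
        return 0.0
    residual = _highpass_residual(moment, fs, fc)
    return float(np.sqrt(np.mean(residual**2)) / peak)


def tremor_spectrum(
    moment: np.ndarray,
    fs: float,
    fc: float = 3.0,
    min_freq: float = 3.0,
) -> tuple[float, float | None]:
    """RMS amplitude and dominant frequency of moment oscillations.

    The residual above the ``fc`` low-pass is taken as the oscillatory
    component; its dominant frequency is the periodogram argmax over
    [min_freq, fs/2).  Returns ``(rms, None)`` when the residual is
    negligible relative to the peak moment (no meaningful oscillation).
    """
    moment = np.asarray(moment, dtype=float)
    if moment.size / fs < 2.0:
        raise ValueError("need at least 2 s of data for 0.5 Hz resolution")
    residual = _highpass_residual(moment, fs, fc)
    rms = float(np.sqrt(np.mean(residual**2)))
    peak = float(np.max(np.abs(moment)))
    if peak == 0.0 or rms < 1e-6 * peak:
        return rms, None
    freqs, power = signal.periodogram(residual, fs=fs)
    band = freqs >= min_freq
    dominant = float(freqs[band][np.argmax(power[band])])
    return rms, dominant


def compute_outcomes(result: SimulationResult, label: str | None = None) -> OutcomeMetrics:
    """All outcome measures for one simulation."""
    fs = 1.0 / result.dt
    kin = compute_kinematic_metrics(result)
    net = result.net_moment
    i_pk = int(np.argmax(np.abs(net)))
    span = result.cycle_span
    rms, dom = tremor_spectrum(net, fs)
    return OutcomeMetrics(
        label=label if label is not None else result.provenance,
        rom=kin["rom"],
        peak_flexion=kin["peak_flexion"],
        t_peak_flexion=kin["t_peak_flexion"],
        pct_peak_flexion=kin["pct_peak_flexion"],
        peak_moment=float(np.abs(net[i_pk])),
        t_peak_moment=float(result.time[i_pk]),
        pct_peak_moment=_pct_of_cycle(float(result.time[i_pk]), span),
        final_angle=kin["final_angle"],
        oscillation_index=oscillation_index(net, fs),
        tremor_amplitude=rms,
        dominant_freq=dom,
    )
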