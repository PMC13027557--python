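"""Virtual impairment scenarios applied at the activation-signal level.

Four mechanisms, each a parametric modification of the normalized
activation envelopes and nothing else (the musculoskeletal model is
never touched):

* weakness — uniform scaling of the agonist (flexor) envelopes down;
* co-activation — scaling of the antagonist (triceps) envelope up;
* spasticity-like — tonic baseline plus gain on selected muscles,
  raising background activity and reducing relative modulation;
* tremor-like — multiplicative sinusoidal modulation (4–12 Hz band) in
  configurable windows of the movement cycle, antagonist in antiphase.

All outputs stay in [0, 1] by clipping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .emg import ConfigurationError
from .synth import FLEXORS, MUSCLES

#: named spasticity severity levels -> (tonic baseline b, gain g)
SPASTICITY_LEVELS = {
    "mild": (0.10, 1.1),
    "moderate": (0.20, 1.3),
    "severe": (0.30, 1.5),
}

#: muscles receiving tremor modulation (brachialis is spared)
TREMOR_TARGETS = ("BIClong", "BRD", "TRIlong")


@dataclass
class ActivationSet:
    """Per-muscle normalized activations on a shared simulation grid.

    ``cycle_span`` marks one flexion–extension cycle (start, end) in
    seconds and anchors cycle-fraction-based operations such as tremor
    windows and time normalization.  Muscles without recordings carry
    explicit zeros.
    """

    grid: np.ndarray
    activations: dict[str, np.ndarray]
    cycle_span: tuple[float, float] | None = None
    provenance: str = "baseline"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        for name, vals in self.activations.items():
            vals = np.asarray(vals, dtype=float)
            if vals.shape != self.grid.shape:
                raise ValueError(f"muscle {name}: values not on the shared grid")
            if vals.min() < -1e-12 or vals.max() > 1 + 1e-9:
                raise ValueError(f"muscle {name}: activations outside [0, 1]")
            self.activations[name] = vals
        if self.cycle_span is None:
            self.cycle_span = (float(self.grid[0]), float(self.grid[-1]))

    def copy(self, provenance: str | None = None) -> "ActivationSet":
        return ActivationSet(
            grid=self.grid.copy(),
            activations={k: v.copy() for k, v in self.activations.items()},
            cycle_span=self.cycle_span,
            provenance=provenance if provenance is not None else self.provenance,
        )

    def muscles(self) -> tuple[str, ...]:
        return tuple(self.activations)


@dataclass(frozen=True)
class ScenarioSpec:
    """Parametric description of one virtual impairment condition."""

    kind: str = "healthy"  # healthy | weakness | coactivation | spasticity | tremor
    weakness_fraction: float = 0.0
    coact_fraction: float = 0.0
    spasticity_level: str = "mild"
    tremor_amplitude: float = 0.0
    tremor_freq: float = 8.0
    tremor_windows: tuple[tuple[float, float], ...] = ((0.20, 0.60), (0.60, 0.85))
    agonist_phase: float = 0.0
    antagonist_phase: float = np.pi
    ramp_frac: float = 0.05

    def __post_init__(self) -> None:
        if self.kind not in ("healthy", "weakness", "coactivation", "spasticity", "tremor"):
            raise ConfigurationError(f"unknown scenario kind {self.kind!r}")
        if not (0.0 <= self.weakness_fraction < 1.0):
            raise ConfigurationError("weakness_fraction must be in [0, 1)")
        if self.coact_fraction < 0.0:
            raise ConfigurationError("coact_fraction must be >= 0")
        if not (0.0 <= self.tremor_amplitude <= 1.0):
            raise ConfigurationError("tremor_amplitude must be in [0, 1]")
        for lo, hi in self.tremor_windows:
            if not (0.0 <= lo < hi <= 1.0):
                raise ConfigurationError(f"bad tremor window ({lo}, {hi})")

    def label(self) -> str:
        if self.kind == "weakness":
            return f"weakness -{self.weakness_fraction:.0%}"
        if self.kind == "coactivation":
            return f"coactivation +{self.coact_fraction:.0%}"
        if self.kind == "spasticity":
            return f"spasticity {self.spasticity_level}"
        if self.kind == "tremor":
            return f"tremor {self.tremor_amplitude:.0%}"
        return "healthy"


def apply_weakness(
    acts: ActivationSet,
    fraction: float,
    targets: tuple[str, ...] = FLEXORS,
) -> ActivationSet:
    """Uniformly scale agonist activation down by ``fraction``.

    Amplitude shrinks proportionally; activation timing (every local
    maximum) is untouched.  Non-target muscles pass through unchanged.
    """
    if not (0.0 <= fraction < 1.0):
        raise ConfigurationError("weakness fraction must be in [0, 1)")
    for t in targets:
        if t not in acts.activations:
            raise ConfigurationError(f"unknown target muscle {t!r}")
    out = acts.copy(provenance=f"weakness fraction={fraction}")
    for t in targets:
        out.activations[t] = acts.activations[t] * (1.0 - fraction)
    return out


def apply_coactivation(
    acts: ActivationSet,
    fraction: float,
    antagonist: str = "TRIlong",
) -> ActivationSet:
    """Scale the antagonist envelope up by ``fraction`` (clipped at 1)."""
    if fraction < 0.0:
        raise ConfigurationError("coactivation fraction must be >= 0")
    if antagonist not in acts.activations:
        raise ConfigurationError(f"unknown antagonist muscle {antagonist!r}")
    out = acts.copy(provenance=f"coactivation fraction={fraction}")
    out.activations[antagonist] = np.clip(
        acts.activations[antagonist] * (1.0 + fraction), 0.0, 1.0
    )
    return out


def apply_spasticity(
    acts: ActivationSet,
    level: str | tuple[float, float],
    targets: tuple[str, ...] = ("TRIlong",),
) -> ActivationSet:
    """Tonic-plus-gain transform a'(t) = clip(b + g a(t), 0, 1).

    The tonic baseline ``b`` keeps activation elevated throughout the
    movement; once clipping engages, the relative modulation depth drops,
    mimicking the reduced activation modulation seen with upper motor
    neuron involvement.  The default target is the task antagonist
    (triceps): movement-opposing spastic activity is what progressively
    brakes flexion, shrinks the range of motion and attenuates the net
    moment as severity grows.  Any muscle subset can be targeted instead.
    """
    if isinstance(level, str):
        try:
            b, g = SPASTICITY_LEVELS[level]
        except KeyError:
            raise ConfigurationError(f"unknown spasticity level {level!r}") from None
    else:
        b, g = level
    if not (0.0 <= b < 1.0):
        raise ConfigurationError("tonic baseline must be in [0, 1)")
    if g < 1.0:
        raise ConfigurationError("spasticity gain must be >= 1")
    for t in targets:
        if t not in acts.activations:
            raise ConfigurationError(f"unknown target muscle {t!r}")
    out = acts.copy(provenance=f"spasticity b={b} g={g}")
    for t in targets:
        out.activations[t] = np.clip(b + g * acts.activations[t], 0.0, 1.0)
    return out


def _window_weight(cycle_frac: np.ndarray, windows, ramp_frac: float) -> np.ndarray:
    """Cosine-tapered indicator of the cycle-fraction windows."""
    w = np.zeros_like(cycle_frac)
    for lo, hi in windows:
        ramp = ramp_frac * (hi - lo)
        inside = (cycle_frac >= lo) & (cycle_frac <= hi)
        seg = np.zeros_like(cycle_frac)
        seg[inside] = 1.0
        if ramp > 0:
            rising = (cycle_frac >= lo) & (cycle_frac < lo + ramp)
            falling = (cycle_frac > hi - ramp) & (cycle_frac <= hi)
            seg[rising] = 0.5 * (1 - np.cos(np.pi * (cycle_frac[rising] - lo) / ramp))
            seg[falling] = 0.5 * (1 - np.cos(np.pi * (hi - cycle_frac[falling]) / ramp))
        w = np.maximum(w, seg)
    return w


def apply_tremor(acts: ActivationSet, spec: ScenarioSpec) -> ActivationSet:
    """Multiplicative oscillatory modulation in cycle-phase windows.

    ``a'(t) = clip(a(t) (1 + A w(t) sin(2 pi f (t - t0) + phi)), 0, 1)``
    with ``w`` the tapered window indicator; flexor targets carry the
    agonist phase, the triceps the antagonist phase (default antiphase,
    promoting alternating agonist–antagonist moment fluctuations).
    Brachialis is left untouched.
    """
    if not spec.tremor_windows:
        raise ConfigurationError("tremor requires at least one window")
    t0, t1 = acts.cycle_span
    if t1 <= t0:
        raise ConfigurationError("degenerate cycle span")
    cycle_frac = np.clip((acts.grid - t0) / (t1 - t0), 0.0, 1.0)
    w = _window_weight(cycle_frac, spec.tremor_windows, spec.ramp_frac)
    out = acts.copy(
        provenance=f"tremor A={spec.tremor_amplitude} f={spec.tremor_freq}Hz"
    )
    for muscle in TREMOR_TARGETS:
        if muscle not in acts.activations:
            continue
        phase = spec.antagonist_phase if muscle == "TRIlong" else spec.agonist_phase
        osc = np.sin(2 * np.pi * spec.tremor_freq * (acts.grid - t0) + phase)
        mod = 1.0 + spec.tremor_amplitude * w * osc
        out.activations[muscle] = np.clip(acts.activations[muscle] * mod, 0.0, 1.0)
    return out


def build_scenario_set(baseline: ActivationSet, spec: ScenarioSpec) -> ActivationSet:
    """Dispatch a :class:`ScenarioSpec` onto the matching operation."""
    if spec.kind == "healthy":
        return baseline.copy(provenance="healthy")
    if spec.kind == "weakness":
        return apply_weakness(baseline, spec.weakness_fraction)
    if spec.kind == "coactivation":
        return apply_coactivation(baseline, spec.coact_fraction)
    if spec.kind == "spasticity":
        return apply_spasticity(baseline, spec.spasticity_level)
    if spec.kind == "tremor":
        return apply_tremor(baseline, spec)
    raise ConfigurationError(f"unknown scenario kind {spec.kind!r}")
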