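"""Movement Quality Index: composite 0–100 scoring of simulated scenarios.

Each condition is scored relative to a healthy reference with three
unitless components in [0, 1]:

* kinematic score — ``clip(1 - |ROM - ROM_ref| / ROM_ref, 0, 1)``:
  deviation of the range of motion from the reference in either
  direction lowers the score;
* moment score — ``clip(1 - |peak - peak_ref| / peak_ref, 0, 1)``:
  deviation of peak net moment from the reference in either direction
  lowers the score;
* stability score — ``1 - OI / max(block OIs)``: the condition with the
  largest oscillation index in a block scores zero.

The aggregate is ``MQI = 100 * sum(w_i s_i)`` with equal weights by
default.  The moment- and stability-score forms are reconstructions
inferred from published score tables (docs/methods.md discusses the
evidence and the known mismatch in the absolute aggregate values);
alternative component formulas and weightings can be supplied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .metrics import OutcomeMetrics

EQUAL_WEIGHTS = (1.0 / 3.0, 1.0 / 3.0, 1.0 / 3.0)


@dataclass
class MQIResult:
    """Component scores and the aggregated index for one condition."""

    label: str
    kinematic_score: float
    moment_score: float
    stability_score: float
    mqi: float
    weights: tuple[float, float, float]


@dataclass
class ScenarioBlock:
    """A healthy reference plus scenarios of one impairment family."""

    reference: OutcomeMetrics
    scenarios: list[OutcomeMetrics]
    block_name: str = ""

    def __post_init__(self) -> None:
        if not self.scenarios:
            raise ValueError("a scenario block needs at least one scenario")

    def all_conditions(self) -> list[OutcomeMetrics]:
        return [self.reference, *self.scenarios]


def moment_score(peak: float, peak_ref: float) -> float:
    """Relative-deviation score of the peak net moment."""
    if peak_ref <= 0:
        raise ValueError("reference peak moment must be positive")
    return float(np.clip(1.0 - abs(peak - peak_ref) / peak_ref, 0.0, 1.0))


def stability_score(oi: float, block_ois: list[float]) -> float:
    """Block-max-normalized oscillation score (1 = smoothest possible)."""
    if not block_ois or any(x < 0 for x in block_ois):
        raise ValueError("block OIs must be non-empty and non-negative")
    top = max(block_ois)
    if top == 0.0:
        warnings.warn("all oscillation indices are zero; stability score = 1")
        return 1.0
    return float(1.0 - oi / top)


def kinematic_score(rom: float, rom_ref: float) -> float:
    """Relative-deviation score of the range of motion.

    Symmetric by design: both a constrained and an exaggerated excursion
    depart from the reference movement and are penalized alike (published
    score tables penalize enlarged co-activation/tremor excursions, which
    a plain ROM ratio cannot).  For rom <= rom_ref this coincides with
    the ROM ratio.
    """
    if rom_ref <= 0:
        raise ValueError("reference ROM must be positive")
    return float(np.clip(1.0 - abs(rom - rom_ref) / rom_ref, 0.0, 1.0))


def compute_mqi(
    kin: float,
    mom: float,
    stab: float,
    weights: tuple[float, float, float] = EQUAL_WEIGHTS,
) -> float:
    """Weighted 0–100 aggregate of the three component scores."""
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must be non-negative and sum to 1")
    return float(100.0 * (w[0] * kin + w[1] * mom + w[2] * stab))


def score_block(
    block: ScenarioBlock,
    weights: tuple[float, float, float] = EQUAL_WEIGHTS,
) -> list[MQIResult]:
    """Score every condition of a block, reference included.

    Kinematic and moment scores are computed against the reference;
    stability scores against the block-wide maximum oscillation index
    (reference included), so the least stable condition scores zero.
    """
    ref = block.reference
    block_ois = [c.oscillation_index for c in block.all_conditions()]
    out = []
    for cond in block.all_conditions():
        kin = kinematic_score(cond.rom, ref.rom)
        mom = moment_score(cond.peak_moment, ref.peak_moment)
        stab = stability_score(cond.oscillation_index, block_ois)
        out.append(
            MQIResult(
                label=cond.label,
                kinematic_score=kin,
                moment_score=mom,
                stability_score=stab,
                mqi=compute_mqi(kin, mom, stab, weights),
                weights=tuple(weights),
            )
        )
    return out
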