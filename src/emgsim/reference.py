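"""Published per-condition inputs to the MQI component scores.

These are the peak net elbow moments (Nm) and oscillation indices
reported for the original OpenSim-based study conditions, one block per
impairment family with its own healthy reference row.  They serve as
inputs for reconstructing the derived score columns (moment and
stability scores) and for cross-checking the scoring formulas; they are
not outputs of this package's simulator, whose bespoke elbow model
produces its own absolute values.
"""

from __future__ import annotations

#: block -> ordered list of (condition label, peak net moment Nm, oscillation index)
PUBLISHED_BLOCKS: dict[str, list[tuple[str, float, float]]] = {
    "weakness": [
        ("healthy", 74.41, 0.077),
        ("weakness -20%", 44.43, 0.081),
        ("weakness -40%", 30.07, 0.091),
        ("weakness -60%", 17.38, 0.092),
    ],
    "coactivation": [
        ("healthy", 74.41, 0.077),
        ("coactivation level 1", 68.72, 0.082),
        ("coactivation level 2", 105.02, 0.072),
        ("coactivation level 3", 117.27, 0.070),
    ],
    "spasticity": [
        ("healthy", 76.48, 0.075),
        ("spasticity mild", 67.47, 0.080),
        ("spasticity moderate", 48.40, 0.079),
        ("spasticity severe", 19.41, 0.075),
    ],
    "tremor": [
        ("healthy", 74.41, 0.077),
        ("tremor 20%", 74.44, 0.077),
        ("tremor 40%", 77.17, 0.078),
        ("tremor 60%", 81.50, 0.079),
    ],
}


def published_block(name: str) -> list[tuple[str, float, float]]:
    """Return the (label, peak moment, OI) rows of one published block."""
    try:
        return list(PUBLISHED_BLOCKS[name])
    except KeyError:
        raise KeyError(f"unknown block {name!r}; choose from {sorted(PUBLISHED_BLOCKS)}")
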