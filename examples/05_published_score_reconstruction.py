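"""Reconstruct the published derived score columns from the printed inputs.

The published condition table reports, per impairment block, the peak
net elbow moment and oscillation index of every condition together with
derived moment and stability scores.  Feeding the printed input columns
through this package's scoring formulas reproduces the printed score
columns — evidence that the reconstructed formulas are the ones behind
the published table.
"""

import emgsim as es
from emgsim.reference import PUBLISHED_BLOCKS

for block, rows in PUBLISHED_BLOCKS.items():
    ref_peak = rows[0][1]
    ois = [oi for _, _, oi in rows]
    print(f"\n{block} block (reference peak {ref_peak} Nm):")
    print(f"  {'condition':24s} {'peak Nm':>8s} {'moment score':>13s} "
          f"{'OI':>6s} {'stability score':>16s}")
    for label, peak, oi in rows:
        ms = es.moment_score(peak, ref_peak)
        ss = es.stability_score(oi, ois)
        print(f"  {label:24s} {peak:8.2f} {ms:13.2f} {oi:6.3f} {ss:16.3f}")
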