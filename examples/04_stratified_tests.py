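"""The stratified removal tests on synthetic data with a protective bias.

Simulates genes whose splicing avoids interface-overlapping exons
(β = 0.2), builds 1000 pulsed decoys per isoform, and compares real vs
randomized interface removal with the Cochran-Mantel-Haenszel test
across thresholds.
"""

import numpy as np

from spliceshield.decoys import single_isoform_control_set
from spliceshield.simulate import SimConfig, simulate_pairs
from spliceshield.splice_tests import single_isoform_test

cfg = SimConfig(n_genes=60, bias=0.2, seed=3)
sims = simulate_pairs(cfg, np.random.default_rng(3))
rng = np.random.default_rng(1003)

pairs = []
for sim in sims:
    for mask in sim.isoform_masks:
        if mask.n_missing:
            pairs.append(
                (sim.interface, mask, single_isoform_control_set(mask, 1000, rng))
            )
print(f"{len(pairs)} semi-interface/isoform pairs\n")
print("thr   real_freq  control_freq  statistic  p_value")
for threshold in (10, 30, 50, 70, 100):
    res = single_isoform_test(pairs, threshold)
    print(
        f"{threshold:3d}   {res.real_frequency:9.3f}  {res.control_frequency:12.3f}"
        f"  {res.statistic:9.3f}  {res.p_value:.2e}"
    )
# Real splicing removes interfaces less often than its randomized
# counterpart (the frequencies separate), and the stratified test is
# significant at the partial-removal thresholds.
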