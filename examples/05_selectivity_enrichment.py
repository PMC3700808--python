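"""Selectivity scores, protein partition, and annotation enrichment.

Scores how selectively each interface is removed relative to its decoys,
partitions proteins into selectively-removed / selectively-protected
classes, and tests term enrichment of the removed class against the full
background with a hypergeometric test under BH FDR control.
"""

import numpy as np

from spliceshield.decoys import (
    DecoyGenerationError,
    DecoySpec,
    all_isoforms_control_sets,
    single_isoform_control_set,
)
from spliceshield.selectivity import (
    hypergeometric_enrichment,
    partition_proteins,
    selectivity_scores,
)
from spliceshield.simulate import SimConfig, simulate_pairs

cfg = SimConfig(n_genes=30, bias=0.5, seed=9)
sims = simulate_pairs(cfg, np.random.default_rng(9))
rng = np.random.default_rng(1009)

pairs, all_controls = [], {}
for sim in sims:
    masks = [m for m in sim.isoform_masks if m.n_missing]
    if not masks:
        continue
    for mask in masks:
        pairs.append((sim.interface, mask, single_isoform_control_set(mask, 500, rng)))
    try:
        all_controls[masks[0].protein_id] = all_isoforms_control_sets(
            masks, DecoySpec(200), rng
        )
    except DecoyGenerationError:
        pass  # heavily spliced protein: group controls infeasible, skipped

scores = selectivity_scores(pairs, all_controls, threshold=30)
removed, protected = partition_proteins(scores, cutoff=0.5)
print(f"{len(scores)} scores; removed-class {len(removed)}, "
      f"protected-class {len(protected)}")

background = {mask.protein_id for _, mask, _ in pairs}
terms = [f"GO:{i:07d}" for i in range(20)]
ann_rng = np.random.default_rng(77)
annotations = {p: set(ann_rng.choice(terms, 3, replace=False)) for p in background}
rows = hypergeometric_enrichment(removed, background, annotations, q_max=0.05)
n_sig = sum(r.significant for r in rows)
print(f"{len(rows)} terms tested, {n_sig} significant at q < 0.05")
# With annotations assigned independently of the partition, FDR control
# keeps the significant-term count at (or very near) zero — the same
# no-enrichment outcome expected for a widespread, function-agnostic
# protection effect.
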