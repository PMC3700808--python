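"""Randomized-splicing null models: pulsed decoys and overlap groups.

Every missing and non-missing stretch of an isoform is given a new
Poisson-distributed size and the variable region is re-placed uniformly;
for a whole isoform group, overlap structure between isoforms is
preserved segment by segment.
"""

import numpy as np

from spliceshield.decoys import (
    DecoySpec,
    build_overlap_groups,
    make_all_isoforms_control,
    make_single_isoform_decoy,
    single_isoform_control_set,
)
from spliceshield.masks import IsoformMask, decompose_mask

rng = np.random.default_rng(42)

bits = np.zeros(120, dtype=np.uint8)
bits[29:39] = 1  # missing stretch at 30-39
bits[59:67] = 1  # missing stretch at 60-67
mask = IsoformMask("PROT1", "iso1", bits)

decoy = make_single_isoform_decoy(mask, rng)
print("real mask :", mask.to_runs())
print("one decoy :", decoy.to_runs())

controls = single_isoform_control_set(mask, 1000, rng)
print("mean decoy missing size:", controls.total_missing_sizes().mean(),
      "(real: 18)")
# Poisson pulsing preserves the expected amount of removed sequence.

partner = np.zeros(120, dtype=np.uint8)
partner[34:50] = 1  # overlaps iso1's first stretch
lone = np.zeros(120, dtype=np.uint8)
lone[99:110] = 1
masks = [
    mask,
    IsoformMask("PROT1", "iso2", partner),
    IsoformMask("PROT1", "iso3", lone),
]
groups = build_overlap_groups(masks)
for g in groups:
    print("overlap group:", g.member_ids, "region", g.region,
          "segments", list(zip(g.segment_starts, g.segment_lengths)))
# iso1 and iso2 share missing positions and form one group; iso3 is a
# singleton.  Group controls pulse segment sizes but keep who-shares-what.

control_group = make_all_isoforms_control(masks, DecoySpec(1), rng)
for decoy in control_group:
    print("group control decoy:", decoy.isoform_id, decoy.to_runs())
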