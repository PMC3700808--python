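"""Randomized-splicing null models.

Two null models are provided, mirroring the two statistical tests:

*single-isoform decoys* — every missing and non-missing stretch of the
real isoform is "pulsed": its size is redrawn from a Poisson law with mean
equal to the real size.  The pulsed stretches are concatenated in their
original order into a new variable region whose start is placed uniformly
at random along the protein.  This preserves the number, approximate
sizes, and relative order of the spliced-out regions while randomizing
where they fall.

*all-isoforms controls* — the isoforms of one protein are partitioned
into *overlap groups* (connected components under missing-stretch
overlap).  Each group's overlapping variable region is split into
segments at every junction between a missing and a non-missing stretch
(or the outside); segment sizes are pulsed and the group region is
re-placed as a block, so the overlap structure between isoforms of the
group is preserved exactly.  A draw is accepted only if (a) pulsed
missing-derived segments of different groups do not collide on the
protein and (b), when several groups exist, the total pulsed missing size
is at least 90% of the real total (condition (a) favours shrinkage, (b)
compensates).

Pulsed sizes may be zero (a stretch vanishes); a draw whose variable
region has zero length or no longer fits in the protein is redrawn, up to
``max_attempts``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from spliceshield.masks import IsoformMask, decompose_mask


@dataclass
class DecoySpec:
    """Parameters of control-set generation."""

    n_controls: int = 1000
    rng_seed: int | None = None
    max_attempts: int = 1000

    def __post_init__(self) -> None:
        if self.n_controls < 1:
            raise ValueError("n_controls must be >= 1")


class DecoyGenerationError(RuntimeError):
    """Raised when max_attempts draws never satisfy the acceptance rules."""


def pulse_sizes(sizes, rng: np.random.Generator) -> np.ndarray:
    """Redraw each stretch size from Poisson(λ = real size); zeros allowed."""
    sizes = np.asarray(sizes)
    if (sizes < 1).any():
        raise ValueError("stretch sizes must be positive")
    return rng.poisson(sizes)


# ---------------------------------------------------------------------------
# Single-isoform decoys
# ---------------------------------------------------------------------------


@dataclass
class ControlSet:
    """A batch of single-isoform decoys in compact stretch form.

    Stretches alternate missing, non-missing, missing, ... (odd count,
    missing first and last).  ``sizes[i, j]`` is decoy i's pulsed size of
    stretch j; ``starts[i]`` is the 1-based start of decoy i's variable
    region.  The compact form supports vectorized counting of how many
    interface positions each decoy removes, without materializing bit
    strings.
    """

    protein_id: str
    isoform_id: str
    length: int
    sizes: np.ndarray  # (n, k), k odd; columns 0,2,4,... are missing
    starts: np.ndarray  # (n,), 1-based

    @property
    def n_controls(self) -> int:
        return self.sizes.shape[0]

    def _segment_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """1-based [start, end) bounds of the *missing* segments, shapes (n, m)."""
        offsets = np.concatenate(
            [np.zeros((self.sizes.shape[0], 1), dtype=np.int64),
             np.cumsum(self.sizes[:, :-1], axis=1)],
            axis=1,
        )
        seg_start = self.starts[:, None] + offsets
        seg_end = seg_start + self.sizes
        return seg_start[:, ::2], seg_end[:, ::2]

    def missing_counts(self, positions) -> np.ndarray:
        """Per-decoy count of ``positions`` falling in a missing segment."""
        pos = np.sort(np.asarray(list(positions), dtype=np.int64))
        if pos.size == 0:
            raise ValueError("positions must be non-empty")
        seg_start, seg_end = self._segment_bounds()
        counts = np.zeros(self.n_controls, dtype=np.int64)
        for j in range(seg_start.shape[1]):
            lo = np.searchsorted(pos, seg_start[:, j], side="left")
            hi = np.searchsorted(pos, seg_end[:, j], side="left")
            counts += hi - lo
        return counts

    def missing_fractions(self, positions) -> np.ndarray:
        pos = list(positions)
        return self.missing_counts(pos) / len(pos)

    def total_missing_sizes(self) -> np.ndarray:
        return self.sizes[:, ::2].sum(axis=1)

    def to_masks(self) -> list[IsoformMask]:
        masks = []
        seg_start, seg_end = self._segment_bounds()
        for i in range(self.n_controls):
            bits = np.zeros(self.length, dtype=np.uint8)
            for s, e in zip(seg_start[i], seg_end[i]):
                bits[s - 1 : e - 1] = 1
            masks.append(
                IsoformMask(self.protein_id, f"{self.isoform_id}|decoy{i}", bits)
            )
        return masks


def single_isoform_control_set(
    mask: IsoformMask,
    n_controls: int,
    rng: np.random.Generator,
    max_attempts: int = 1000,
) -> ControlSet:
    """Generate ``n_controls`` pulsed decoys of one isoform mask (vectorized).

    Raises ``ValueError`` if the mask has no missing stretch (no decoy is
    defined for an isoform identical to the canonical protein) and
    ``DecoyGenerationError`` if valid variable regions cannot be drawn.
    """
    decomp = decompose_mask(mask)
    if not decomp.missing:
        raise ValueError(f"{mask.isoform_id}: mask has no missing stretch")
    L = len(mask)
    # interleave missing / non-missing in variable-region order
    base_sizes = []
    for idx, (_, m_len) in enumerate(decomp.missing):
        base_sizes.append(m_len)
        if idx < len(decomp.non_missing):
            base_sizes.append(decomp.non_missing[idx][1])
    lam = np.asarray(base_sizes, dtype=float)

    sizes = np.empty((n_controls, lam.size), dtype=np.int64)
    starts = np.empty(n_controls, dtype=np.int64)
    todo = np.arange(n_controls)
    for _ in range(max_attempts):
        draw = rng.poisson(lam, size=(todo.size, lam.size))
        v = draw.sum(axis=1)
        valid = (v >= 1) & (v <= L)
        idx_valid = todo[valid]
        sizes[idx_valid] = draw[valid]
        starts[idx_valid] = rng.integers(1, L - v[valid] + 2)
        todo = todo[~valid]
        if todo.size == 0:
            break
    else:
        raise DecoyGenerationError(
            f"{mask.isoform_id}: could not draw a valid variable region "
            f"in {max_attempts} attempts"
        )
    return ControlSet(mask.protein_id, mask.isoform_id, L, sizes, starts)


def make_single_isoform_decoy(
    mask: IsoformMask, rng: np.random.Generator, max_attempts: int = 1000
) -> IsoformMask:
    """One pulsed decoy of ``mask`` (see module docstring for the model)."""
    return single_isoform_control_set(mask, 1, rng, max_attempts).to_masks()[0]


# ---------------------------------------------------------------------------
# Overlap groups and all-isoforms controls
# ---------------------------------------------------------------------------


@dataclass
class OverlapGroup:
    """Isoforms connected by missing-stretch overlap, plus the segment split.

    ``segments`` partitions the overlapping variable region (1-based,
    inclusive bounds via start+length) into runs on which every member's
    missing status is constant; ``status[j][m]`` is 1 when member m is
    missing throughout segment j.
    """

    member_ids: list[str]
    region: tuple[int, int]  # 1-based inclusive
    segment_starts: list[int]
    segment_lengths: list[int]
    status: np.ndarray  # (n_segments, n_members), 0/1

    @property
    def missing_segment_idx(self) -> np.ndarray:
        return np.flatnonzero(self.status.any(axis=1))

    def real_missing_total(self) -> int:
        lengths = np.asarray(self.segment_lengths)
        return int(lengths[self.missing_segment_idx].sum())


def build_overlap_groups(masks: list[IsoformMask]) -> list[OverlapGroup]:
    """Partition a protein's isoform masks into overlap groups.

    Two isoforms are connected when any missing-stretch position is shared;
    groups are the connected components.  Within each group the overlapping
    variable region (min variable-region start to max end over members) is
    split into segments at every missing-stretch junction of any member.
    """
    if not masks:
        return []
    if len({m.protein_id for m in masks}) != 1:
        raise ValueError("all masks must belong to one protein")
    decomps = [decompose_mask(m) for m in masks]
    for m, d in zip(masks, decomps):
        if not d.missing:
            raise ValueError(f"{m.isoform_id}: mask has no missing stretch")

    n = len(masks)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj

    intervals = [
        [(s, s + l - 1) for s, l in d.missing] for d in decomps
    ]
    for i in range(n):
        for j in range(i + 1, n):
            if any(
                s1 <= e2 and s2 <= e1
                for s1, e1 in intervals[i]
                for s2, e2 in intervals[j]
            ):
                union(i, j)

    components: dict[int, list[int]] = {}
    for i in range(n):
        components.setdefault(find(i), []).append(i)

    groups = []
    for members in components.values():
        region_start = min(decomps[i].variable_region[0] for i in members)
        region_end = max(decomps[i].variable_region[1] for i in members)
        bounds = {region_start, region_end + 1}
        for i in members:
            for s, e in intervals[i]:
                bounds.add(s)
                bounds.add(e + 1)
        cuts = sorted(bounds)
        seg_starts = cuts[:-1]
        seg_lengths = [b - a for a, b in zip(cuts, cuts[1:])]
        status = np.zeros((len(seg_starts), len(members)), dtype=np.uint8)
        for col, i in enumerate(members):
            bits = masks[i].bits
            for row, s in enumerate(seg_starts):
                status[row, col] = bits[s - 1]
        groups.append(
            OverlapGroup(
                member_ids=[masks[i].isoform_id for i in members],
                region=(region_start, region_end),
                segment_starts=seg_starts,
                segment_lengths=seg_lengths,
                status=status,
            )
        )
    groups.sort(key=lambda g: g.region[0])
    return groups


@dataclass
class GroupControl:
    """One accepted all-isoforms control: per-group placement of pulsed segments."""

    starts: list[int]  # per group, 1-based start of the pulsed region
    sizes: list[np.ndarray]  # per group, pulsed segment sizes

    def isoform_missing_intervals(
        self, groups: list[OverlapGroup]
    ) -> dict[str, list[tuple[int, int]]]:
        """Per isoform, 1-based [start, end) intervals of missing residues."""
        out: dict[str, list[tuple[int, int]]] = {}
        for g, start, sizes in zip(groups, self.starts, self.sizes):
            offsets = np.concatenate(([0], np.cumsum(sizes[:-1])))
            for col, iso in enumerate(g.member_ids):
                rows = np.flatnonzero(g.status[:, col])
                out.setdefault(iso, []).extend(
                    (int(start + offsets[r]), int(start + offsets[r] + sizes[r]))
                    for r in rows
                    if sizes[r] > 0
                )
        return out


def _draw_group_control(
    groups: list[OverlapGroup],
    length: int,
    rng: np.random.Generator,
    max_attempts: int,
    protein_id: str,
) -> GroupControl:
    real_missing_total = sum(g.real_missing_total() for g in groups)
    for _ in range(max_attempts):
        starts: list[int] = []
        sizes_list: list[np.ndarray] = []
        ok = True
        for g in groups:
            lam = np.asarray(g.segment_lengths, dtype=float)
            sizes = rng.poisson(lam)
            v = int(sizes.sum())
            if v < 1 or v > length:
                ok = False
                break
            starts.append(int(rng.integers(1, length - v + 2)))
            sizes_list.append(sizes)
        if not ok:
            continue
        # constraint (a): pulsed missing-derived segments of different groups
        # must not share protein positions
        missing_intervals: list[list[tuple[int, int]]] = []
        for g, start, sizes in zip(groups, starts, sizes_list):
            offsets = np.concatenate(([0], np.cumsum(sizes[:-1])))
            ivs = [
                (int(start + offsets[r]), int(start + offsets[r] + sizes[r]))
                for r in g.missing_segment_idx
                if sizes[r] > 0
            ]
            missing_intervals.append(ivs)
        collision = False
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                if any(
                    s1 < e2 and s2 < e1
                    for s1, e1 in missing_intervals[gi]
                    for s2, e2 in missing_intervals[gj]
                ):
                    collision = True
                    break
            if collision:
                break
        if collision:
            continue
        # constraint (b): with multiple groups, keep at least 90% of the
        # real total missing size
        if len(groups) > 1:
            pulsed_total = sum(
                int(sizes[g.missing_segment_idx].sum())
                for g, sizes in zip(groups, sizes_list)
            )
            if pulsed_total < 0.9 * real_missing_total:
                continue
        return GroupControl(starts=starts, sizes=sizes_list)
    raise DecoyGenerationError(
        f"{protein_id}: no acceptable all-isoforms control in {max_attempts} attempts"
    )


@dataclass
class AllIsoformsControls:
    """A set of accepted all-isoforms controls for one protein."""

    protein_id: str
    length: int
    groups: list[OverlapGroup]
    controls: list[GroupControl]
    isoform_ids: list[str] = field(default_factory=list)

    def control_masks(self, index: int) -> list[IsoformMask]:
        intervals = self.controls[index].isoform_missing_intervals(self.groups)
        masks = []
        for iso in self.isoform_ids:
            bits = np.zeros(self.length, dtype=np.uint8)
            for s, e in intervals.get(iso, []):
                bits[s - 1 : e - 1] = 1
            masks.append(IsoformMask(self.protein_id, f"{iso}|ctrl{index}", bits))
        return masks

    def removal_flags(self, positions, threshold_pct: float) -> np.ndarray:
        """Per control: is the position set removed in at least one isoform?

        A control group removes the set when some member isoform misses at
        least ``threshold_pct``% of ``positions``.
        """
        pos = np.sort(np.asarray(list(positions), dtype=np.int64))
        need = threshold_pct / 100.0 * pos.size
        flags = np.zeros(len(self.controls), dtype=bool)
        for idx, ctrl in enumerate(self.controls):
            per_iso = ctrl.isoform_missing_intervals(self.groups)
            for ivs in per_iso.values():
                count = 0
                for s, e in ivs:
                    count += int(
                        np.searchsorted(pos, e, "left") - np.searchsorted(pos, s, "left")
                    )
                if count >= need:
                    flags[idx] = True
                    break
        return flags


def make_all_isoforms_control(
    masks: list[IsoformMask],
    spec: DecoySpec | None = None,
    rng: np.random.Generator | None = None,
) -> list[IsoformMask]:
    """One all-isoforms control: a decoy mask per input isoform."""
    spec = spec or DecoySpec(n_controls=1)
    rng = rng if rng is not None else np.random.default_rng(spec.rng_seed)
    sets = all_isoforms_control_sets(masks, DecoySpec(1, None, spec.max_attempts), rng)
    return sets.control_masks(0)


def all_isoforms_control_sets(
    masks: list[IsoformMask],
    spec: DecoySpec,
    rng: np.random.Generator | None = None,
) -> AllIsoformsControls:
    """Generate ``spec.n_controls`` all-isoforms controls for one protein."""
    if not masks:
        raise ValueError("at least one isoform mask required")
    rng = rng if rng is not None else np.random.default_rng(spec.rng_seed)
    groups = build_overlap_groups(masks)
    length = len(masks[0])
    protein_id = masks[0].protein_id
    controls = [
        _draw_group_control(groups, length, rng, spec.max_attempts, protein_id)
        for _ in range(spec.n_controls)
    ]
    return AllIsoformsControls(
        protein_id=protein_id,
        length=length,
        groups=groups,
        controls=controls,
        isoform_ids=[m.isoform_id for m in masks],
    )
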