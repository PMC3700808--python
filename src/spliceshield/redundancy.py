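"""Redundancy reduction among interfaces.

The same interface is typically observed many times (multiple crystals,
homomultimers, paralogous proteins binding a shared partner).  To keep one
representative per distinct binding site:

1. proteins are grouped by greedy single-linkage clustering on pairwise
   global-alignment identity (defaults: ≥30% identity over a region
   covering ≥90% of each sequence);
2. each protein cluster gets a multiple alignment (built-in center-star
   progressive merge, or a user-supplied alignment), so interface residues
   of different member proteins can be compared by alignment column;
3. (semi-)interfaces within a cluster are compared by the overlap value
   O = |shared columns| / |smaller (semi-)interface| and clustered by
   complete linkage on distance 1−O, cut at height 0.5 (every pair within
   a flat cluster has O ≥ 0.5);
4. one representative is elected per flat cluster by coverage, then
   resolution, then size, then a seeded random draw.

Heterodimeric units of clustering are individual semi-interfaces;
homodimeric units are whole interfaces (both sides on one protein).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from spliceshield.masks import global_align
from spliceshield.structures import InterfaceRecord


@dataclass
class ProteinCluster:
    """A group of similar proteins with a shared alignment-column map.

    ``msa`` maps protein id → {1-based position → alignment column}.
    """

    members: list[str]
    msa: dict[str, dict[int, int]] = field(default_factory=dict)


def _identity_and_coverage(seq_a: str, seq_b: str) -> tuple[float, float, float]:
    summary = global_align(seq_a, seq_b)
    cols = summary.n_aligned_columns
    identity = summary.n_matches / cols if cols else 0.0
    return identity, cols / len(seq_a), cols / len(seq_b)


def _center_star_msa(seqs: dict[str, str]) -> dict[str, dict[int, int]]:
    """Progressive center-star alignment; returns position→column maps.

    The center is the member with the highest summed pairwise identity
    (ties to the lexicographically smallest id).  Other members are
    aligned to the center pairwise; insertions relative to the center get
    private columns.  Adequate here because downstream consumers only use
    column identifiers shared through the center.
    """
    ids = sorted(seqs)
    if len(ids) == 1:
        only = ids[0]
        return {only: {i + 1: i for i in range(len(seqs[only]))}}
    total_identity = {i: 0.0 for i in ids}
    for i_idx, i in enumerate(ids):
        for j in ids[i_idx + 1 :]:
            ident, _, _ = _identity_and_coverage(seqs[i], seqs[j])
            total_identity[i] += ident
            total_identity[j] += ident
    center = min(ids, key=lambda i: (-total_identity[i], i))
    center_seq = seqs[center]

    # insertion columns keyed by the center position they follow (-1 = before start)
    inserts: list[tuple[int, str, int]] = []  # (slot, member, member_pos0)
    aligned_to_center: dict[str, dict[int, int]] = {}  # member -> center_pos0 -> pos0
    for member in ids:
        if member == center:
            continue
        summary = global_align(center_seq, seqs[member])
        ci = si = 0
        pairs: dict[int, int] = {}
        for ca, cb in zip(summary.aligned_a, summary.aligned_b):
            if ca != "-" and cb != "-":
                pairs[ci] = si
            if ca == "-" and cb != "-":
                inserts.append((ci - 1, member, si))
            if ca != "-":
                ci += 1
            if cb != "-":
                si += 1
        aligned_to_center[member] = pairs

    # final column order: insertions after slot -1, center pos 0, insertions
    # after 0, center pos 1, ...
    slot_inserts: dict[int, list[tuple[str, int]]] = {}
    for slot, member, pos in inserts:
        slot_inserts.setdefault(slot, []).append((member, pos))
    column_of_center: dict[int, int] = {}
    member_insert_cols: dict[str, dict[int, int]] = {m: {} for m in ids}
    col = 0
    for slot in range(-1, len(center_seq)):
        for member, pos in slot_inserts.get(slot, []):
            member_insert_cols[member][pos] = col
            col += 1
        if slot + 1 < len(center_seq):
            column_of_center[slot + 1] = col
            col += 1

    msa: dict[str, dict[int, int]] = {
        center: {cp + 1: c for cp, c in column_of_center.items()}
    }
    for member in ids:
        if member == center:
            continue
        mapping: dict[int, int] = {}
        for cp, sp in aligned_to_center[member].items():
            mapping[sp + 1] = column_of_center[cp]
        for sp, c in member_insert_cols[member].items():
            mapping[sp + 1] = c
        msa[member] = mapping
    return msa


def cluster_proteins(
    seqs: dict[str, str],
    min_identity: float = 0.30,
    min_coverage: float = 0.90,
    msa_override: dict[str, dict[str, dict[int, int]]] | None = None,
) -> list[ProteinCluster]:
    """Greedy single-linkage protein clustering plus per-cluster alignment.

    Two proteins join when their global alignment shows identity
    ≥ ``min_identity`` over aligned columns covering ≥ ``min_coverage`` of
    each sequence; clusters are the transitive closure.  Identity is
    matches / columns where both sequences have a residue.
    """
    ids = sorted(seqs)
    parent = {i: i for i in ids}

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a_idx, a in enumerate(ids):
        for b in ids[a_idx + 1 :]:
            ident, cov_a, cov_b = _identity_and_coverage(seqs[a], seqs[b])
            if ident >= min_identity and cov_a >= min_coverage and cov_b >= min_coverage:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[ra] = rb

    components: dict[str, list[str]] = {}
    for i in ids:
        components.setdefault(find(i), []).append(i)
    clusters = []
    for members in components.values():
        members = sorted(members)
        key = ",".join(members)
        if msa_override and key in msa_override:
            msa = msa_override[key]
        else:
            msa = _center_star_msa({m: seqs[m] for m in members})
        clusters.append(ProteinCluster(members=members, msa=msa))
    clusters.sort(key=lambda c: c.members[0])
    return clusters


def semi_interface_overlap(si_1: set[int], si_2: set[int]) -> float:
    """O = |shared residue identifiers| / |smaller semi-interface|."""
    if not si_1 or not si_2:
        raise ValueError("semi-interfaces must be non-empty")
    return len(set(si_1) & set(si_2)) / min(len(si_1), len(si_2))


def interface_overlap_homo(
    int_1: tuple[set[int], set[int]], int_2: tuple[set[int], set[int]]
) -> float:
    """Overlap of two homodimeric interfaces over both side pairings.

    The two semi-interfaces of one dimer can be matched to the other's in
    two ways; the pairing maximizing the shared-column count is used.  The
    denominator is the total residue count of the smaller interface.
    """
    a1, a2 = (set(s) for s in int_1)
    b1, b2 = (set(s) for s in int_2)
    if not (a1 and a2 and b1 and b2):
        raise ValueError("interface sides must be non-empty")
    numerator = max(
        len(a1 & b1) + len(a2 & b2),
        len(a1 & b2) + len(a2 & b1),
    )
    denominator = min(len(a1) + len(a2), len(b1) + len(b2))
    return numerator / denominator


def cluster_interfaces(o_matrix: np.ndarray) -> np.ndarray:
    """Complete-linkage clustering of interfaces on distance 1−O, cut at 0.5.

    Returns integer cluster labels.  Every pair within a flat cluster is
    guaranteed O ≥ 0.5 (complete-linkage diameter property).
    """
    o = np.asarray(o_matrix, dtype=float)
    if o.ndim != 2 or o.shape[0] != o.shape[1]:
        raise ValueError("overlap matrix must be square")
    if not np.allclose(o, o.T) or not np.allclose(np.diag(o), 1.0):
        raise ValueError("overlap matrix must be symmetric with unit diagonal")
    n = o.shape[0]
    if n == 1:
        return np.array([1])
    dist = 1.0 - o
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="complete")
    return fcluster(z, t=0.5, criterion="distance")


def elect_representative(
    cluster: list[InterfaceRecord],
    sides: list[str] | None = None,
    rng: np.random.Generator | None = None,
) -> InterfaceRecord:
    """Representative of one interface cluster.

    Lexicographic criteria: highest chain coverage (homodimers: product of
    both chains' coverages), then best (lowest) resolution — a missing
    resolution sorts worse than any number — then most residues, then a
    seeded random draw among the remaining ties.

    ``sides`` optionally names, per heterodimeric record, which side
    ('a'/'b') is the clustered semi-interface (default 'a').
    """
    if not cluster:
        raise ValueError("cluster must be non-empty")
    if sides is None:
        sides = ["a"] * len(cluster)

    def key(item: tuple[InterfaceRecord, str]):
        rec, side = item
        if rec.kind == "homo":
            coverage = rec.coverage_a * rec.coverage_b
            size = rec.n_residues
        else:
            coverage = rec.coverage_a if side == "a" else rec.coverage_b
            size = len((rec.side_a if side == "a" else rec.side_b).positions)
        resolution = rec.resolution if rec.resolution is not None else np.inf
        return (-coverage, resolution, -size)

    items = list(zip(cluster, sides))
    best = min(key(it) for it in items)
    ties = [it for it in items if key(it) == best]
    if len(ties) == 1:
        return ties[0][0]
    rng = rng if rng is not None else np.random.default_rng(0)
    return ties[int(rng.integers(len(ties)))][0]


def deduplicate_semi_interfaces(
    records: list[InterfaceRecord],
    seqs: dict[str, str],
    min_identity: float = 0.30,
    min_coverage: float = 0.90,
    seed: int = 0,
) -> list[tuple[InterfaceRecord, str]]:
    """Non-redundant heterodimeric semi-interfaces: (record, side) units."""
    units: list[tuple[InterfaceRecord, str]] = []
    for rec in records:
        if rec.kind != "hetero":
            continue
        units.append((rec, "a"))
        units.append((rec, "b"))
    return _dedupe_units(units, seqs, min_identity, min_coverage, seed, homo=False)


def deduplicate_homo_interfaces(
    records: list[InterfaceRecord],
    seqs: dict[str, str],
    min_identity: float = 0.30,
    min_coverage: float = 0.90,
    seed: int = 0,
) -> list[tuple[InterfaceRecord, str]]:
    """Non-redundant homodimeric interfaces as (record, 'a') units."""
    units = [(rec, "a") for rec in records if rec.kind == "homo"]
    return _dedupe_units(units, seqs, min_identity, min_coverage, seed, homo=True)


def _dedupe_units(units, seqs, min_identity, min_coverage, seed, homo):
    if not units:
        return []
    rng = np.random.default_rng(seed)
    proteins = {
        (rec.side_a if side == "a" else rec.side_b).protein_id for rec, side in units
    }
    clusters = cluster_proteins(
        {p: seqs[p] for p in proteins}, min_identity, min_coverage
    )
    representatives: list[tuple[InterfaceRecord, str]] = []
    for pc in clusters:
        members = [
            (rec, side)
            for rec, side in units
            if (rec.side_a if side == "a" else rec.side_b).protein_id in pc.members
        ]
        if not members:
            continue
        if len(members) == 1:
            representatives.append(members[0])
            continue
        n = len(members)
        o = np.eye(n)
        col_sets = []
        for rec, side in members:
            si = rec.side_a if side == "a" else rec.side_b
            cmap = pc.msa[si.protein_id]
            cols_a = {cmap[p] for p in si.positions if p in cmap}
            if homo:
                cmap_b = pc.msa[rec.side_b.protein_id]
                cols_b = {cmap_b[p] for p in rec.side_b.positions if p in cmap_b}
                cols_a = {cmap[p] for p in rec.side_a.positions if p in cmap}
                col_sets.append((cols_a, cols_b))
            else:
                col_sets.append(cols_a)
        for i in range(n):
            for j in range(i + 1, n):
                if homo:
                    o[i, j] = o[j, i] = interface_overlap_homo(col_sets[i], col_sets[j])
                else:
                    o[i, j] = o[j, i] = semi_interface_overlap(col_sets[i], col_sets[j])
        labels = cluster_interfaces(o)
        for label in np.unique(labels):
            group = [members[i] for i in np.flatnonzero(labels == label)]
            rep = elect_representative(
                [g[0] for g in group], [g[1] for g in group], rng
            )
            rep_side = next(s for r, s in group if r is rep)
            representatives.append((rep, rep_side))
    return representatives
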