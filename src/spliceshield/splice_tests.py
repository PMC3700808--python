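"""Interface-removal calls and the stratified splicing tests.

An interface is *removed* by an isoform, at threshold t percent, when the
isoform misses at least t% of the (semi-)interface residues.  For a
heterodimeric semi-interface the tested side is the one on the isoform's
protein; a homodimeric interface is removed when at least one of its two
semi-interfaces crosses the threshold.

The tests compare real against randomized splicing with a
Cochran-Mantel-Haenszel chi-square test (:mod:`spliceshield.cmh`), one
stratum per unit so that controls are only ever compared with the
real object they were derived from:

- *single-isoform test*: one stratum per (semi-)interface/isoform pair;
  rows real isoform (1 observation) vs its decoys.
- *all-isoforms test*: one stratum per interface; rows the real isoform
  group vs its control groups; "removed" means removed in ≥1 isoform.
- *hot-spot independence test*: one stratum per semi-interface/isoform
  pair; rows hot-spot vs non-hot-spot residues, columns removed/retained
  under the real mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from spliceshield.cmh import CMHResult, Stratified2x2, cmh_test
from spliceshield.decoys import AllIsoformsControls, ControlSet
from spliceshield.masks import IsoformMask
from spliceshield.structures import InterfaceRecord, SemiInterface


@dataclass
class RemovalCall:
    """Removal decision for one interface/isoform pair at one threshold."""

    missing_fraction: float
    threshold: float  # percent
    removed: bool


def missing_fraction(mask: IsoformMask, positions) -> float:
    """Fraction of ``positions`` (1-based) that the isoform is missing."""
    pos = np.asarray(sorted(positions), dtype=np.int64)
    if pos.size == 0:
        raise ValueError("positions must be non-empty")
    if pos[0] < 1 or pos[-1] > len(mask):
        raise ValueError("positions out of mask range")
    return float(mask.bits[pos - 1].mean())


def is_removed(
    rec: InterfaceRecord, mask: IsoformMask, threshold: float
) -> RemovalCall:
    """Removal call at ``threshold`` percent (inclusive: fraction ≥ t/100).

    Heterodimers: the side on the mask's protein is tested.  Homodimers:
    the interface is removed when the larger of the two sides' missing
    fractions reaches the threshold.
    """
    if rec.kind == "homo":
        if mask.protein_id != rec.side_a.protein_id:
            raise ValueError(
                f"mask protein {mask.protein_id} does not match interface protein"
            )
        frac = max(
            missing_fraction(mask, rec.side_a.positions),
            missing_fraction(mask, rec.side_b.positions),
        )
    else:
        if mask.protein_id == rec.side_a.protein_id:
            side = rec.side_a
        elif mask.protein_id == rec.side_b.protein_id:
            side = rec.side_b
        else:
            raise ValueError(
                f"mask protein {mask.protein_id} matches neither interface side"
            )
        frac = missing_fraction(mask, side.positions)
    return RemovalCall(
        missing_fraction=frac, threshold=threshold, removed=frac >= threshold / 100.0
    )


def _tested_sides(rec: InterfaceRecord, protein_id: str) -> list[SemiInterface]:
    if rec.kind == "homo":
        return [rec.side_a, rec.side_b]
    if rec.side_a.protein_id == protein_id:
        return [rec.side_a]
    if rec.side_b.protein_id == protein_id:
        return [rec.side_b]
    raise ValueError(f"{protein_id} matches neither interface side")


def _controls_removed(
    rec: InterfaceRecord, controls: ControlSet, threshold: float
) -> int:
    """How many decoys in the set remove the interface at the threshold."""
    sides = _tested_sides(rec, controls.protein_id)
    flags = np.zeros(controls.n_controls, dtype=bool)
    for side in sides:
        pos = sorted(side.positions)
        need = threshold / 100.0 * len(pos)
        flags |= controls.missing_counts(pos) >= need
    return int(flags.sum())


def single_isoform_test(
    pairs: list[tuple[InterfaceRecord, IsoformMask, ControlSet]],
    threshold: float,
    correction: bool = True,
) -> CMHResult:
    """CMH test of real vs decoy interface removal, one stratum per pair."""
    if not pairs:
        raise ValueError("at least one pair required")
    counts = []
    labels = []
    for rec, mask, controls in pairs:
        if controls.n_controls < 1:
            raise ValueError(f"{mask.isoform_id}: pair has no controls")
        real = is_removed(rec, mask, threshold).removed
        c = _controls_removed(rec, controls, threshold)
        counts.append(
            (1.0 if real else 0.0, 0.0 if real else 1.0, c, controls.n_controls - c)
        )
        labels.append(f"{rec.structure_id}|{mask.isoform_id}")
    return cmh_test(Stratified2x2.from_counts(counts, labels), correction=correction)


def all_isoforms_test(
    items: list[tuple[InterfaceRecord, list[IsoformMask], AllIsoformsControls]],
    threshold: float,
    correction: bool = True,
) -> CMHResult:
    """CMH test of removal-in-at-least-one-isoform, one stratum per interface."""
    if not items:
        raise ValueError("at least one interface required")
    counts = []
    labels = []
    for rec, masks, controls in items:
        if not masks:
            raise ValueError(f"{rec.structure_id}: empty isoform group")
        real = any(is_removed(rec, m, threshold).removed for m in masks)
        sides = _tested_sides(rec, controls.protein_id)
        flags = np.zeros(len(controls.controls), dtype=bool)
        for side in sides:
            flags |= controls.removal_flags(side.positions, threshold)
        c = int(flags.sum())
        n = len(controls.controls)
        counts.append((1.0 if real else 0.0, 0.0 if real else 1.0, c, n - c))
        labels.append(rec.structure_id)
    return cmh_test(Stratified2x2.from_counts(counts, labels), correction=correction)


def hotspot_independence_test(
    pairs: list[tuple[SemiInterface, IsoformMask]],
    correction: bool = True,
) -> CMHResult:
    """Is removal of an interface residue independent of hot-spot status?

    One stratum per semi-interface/isoform pair: rows hot-spot vs other
    interface residues, columns removed vs retained under the real mask.
    Pairs whose semi-interface has no hot spot or no non-hot-spot residue
    contribute a degenerate stratum, skipped by the CMH machinery.
    """
    if not pairs:
        raise ValueError("at least one pair required")
    counts = []
    labels = []
    for si, mask in pairs:
        if not si.hotspots:
            raise ValueError("pairs must carry semi-interfaces with ≥1 hot spot")
        hot = np.asarray(sorted(si.hotspots), dtype=np.int64)
        other = np.asarray(sorted(si.positions - si.hotspots), dtype=np.int64)
        hot_removed = int(mask.bits[hot - 1].sum())
        other_removed = int(mask.bits[other - 1].sum()) if other.size else 0
        counts.append(
            (
                hot_removed,
                hot.size - hot_removed,
                other_removed,
                other.size - other_removed,
            )
        )
        labels.append(f"{si.protein_id}|{mask.isoform_id}")
    return cmh_test(Stratified2x2.from_counts(counts, labels), correction=correction)


def filter_by_coverage(
    masks: list[IsoformMask], min_coverage: float
) -> list[IsoformMask]:
    """Keep isoforms retaining at least ``min_coverage``% of the canonical
    sequence (the similar-isoform restriction of the coverage-filtered tests)."""
    if not 0 <= min_coverage <= 100:
        raise ValueError("min_coverage must be in [0, 100]")
    return [m for m in masks if m.coverage >= min_coverage / 100.0]
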