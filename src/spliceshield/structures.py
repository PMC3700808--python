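"""Interface extraction from PDB-format structures.

Two residues on different chains are in contact when any atom of one lies
within the sum of the two atoms' van der Waals radii plus a margin
(default 0.5 Å) of any atom of the other.  Contacting residues are mapped
to canonical (UniProt-style) 1-based protein positions through a
SIFTS-style chain→protein table, then inclusion filters are applied:
both sides must contribute at least ``min_side`` residues (default 5) and
each chain must cover at least ``min_coverage`` of its protein
(default 30%).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

# Standard element van der Waals radii (Å).  Unknown elements fall back to
# FALLBACK_RADIUS with a warning.
VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "H": 1.20,
    "P": 1.80,
}
FALLBACK_RADIUS = 1.80
DEFAULT_MARGIN = 0.5

WATER_NAMES = {"HOH", "WAT", "DOD"}

ResidueKey = tuple[str, int, str]  # (chain_id, author residue number, icode)


class PDBParseError(ValueError):
    """Raised for malformed ATOM records; message names the line number."""


@dataclass(frozen=True)
class AtomRecord:
    """One ATOM record of a protein chain (author residue numbering)."""

    chain_id: str
    residue_number: int
    insertion_code: str
    residue_name: str
    atom_name: str
    altloc: str
    occupancy: float
    element: str
    x: float
    y: float
    z: float

    @property
    def residue_key(self) -> ResidueKey:
        return (self.chain_id, self.residue_number, self.insertion_code)

    @property
    def coords(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.z)


@dataclass
class ChainProteinMap:
    """Residue-level mapping from one chain to canonical protein positions.

    ``entries`` maps (author residue number, insertion code) to a 1-based
    position on the protein ``protein_id``.  The mapping must be injective.
    """

    chain_id: str
    protein_id: str
    entries: dict[tuple[int, str], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        positions = list(self.entries.values())
        if len(set(positions)) != len(positions):
            raise ValueError(
                f"chain {self.chain_id}: mapping to {self.protein_id} is not injective"
            )
        if any(p < 1 for p in positions):
            raise ValueError("protein positions must be 1-based")

    def get(self, key: ResidueKey) -> int | None:
        return self.entries.get((key[1], key[2]))


@dataclass
class SemiInterface:
    """Interface residues contributed by one chain, in protein numbering."""

    protein_id: str
    positions: frozenset[int]
    hotspots: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        self.positions = frozenset(self.positions)
        self.hotspots = frozenset(self.hotspots)
        if not self.positions:
            raise ValueError("semi-interface must contain at least one residue")
        if not self.hotspots <= self.positions:
            raise ValueError("hotspots must be a subset of interface positions")


@dataclass
class InterfaceRecord:
    """A heterodimeric or homodimeric interface with structure metadata."""

    kind: str  # "hetero" | "homo"
    side_a: SemiInterface
    side_b: SemiInterface
    structure_id: str = ""
    resolution: float | None = None
    coverage_a: float = 1.0
    coverage_b: float = 1.0
    unmapped_a: int = 0
    unmapped_b: int = 0

    def __post_init__(self) -> None:
        same = self.side_a.protein_id == self.side_b.protein_id
        if self.kind == "homo" and not same:
            raise ValueError("homo interface requires identical protein ids")
        if self.kind == "hetero" and same:
            raise ValueError("hetero interface requires distinct protein ids")
        if self.kind not in ("hetero", "homo"):
            raise ValueError(f"unknown interface kind {self.kind!r}")

    @property
    def n_residues(self) -> int:
        return len(self.side_a.positions) + len(self.side_b.positions)


def _parse_atom_line(line: str, lineno: int) -> AtomRecord:
    # PDB fixed-column format; columns are 1-based in the format description.
    if len(line.rstrip("\n")) < 54:
        raise PDBParseError(f"line {lineno}: ATOM record shorter than coordinate fields")
    try:
        atom_name = line[12:16].strip()
        altloc = line[16].strip()
        residue_name = line[17:20].strip()
        chain_id = line[21].strip() or " "
        residue_number = int(line[22:26])
        icode = line[26].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ_field = line[54:60].strip()
        occupancy = float(occ_field) if occ_field else 1.0
        element = line[76:78].strip().upper()
    except ValueError as exc:
        raise PDBParseError(f"line {lineno}: malformed ATOM record ({exc})") from exc
    if not element:
        # Fall back to the first letter of the atom name, PDB v2 style.
        element = atom_name.lstrip("0123456789")[:1].upper()
    if not all(math.isfinite(v) for v in (x, y, z)):
        raise PDBParseError(f"line {lineno}: non-finite coordinates")
    return AtomRecord(
        chain_id=chain_id,
        residue_number=residue_number,
        insertion_code=icode,
        residue_name=residue_name,
        atom_name=atom_name,
        altloc=altloc,
        occupancy=occupancy,
        element=element,
        x=x,
        y=y,
        z=z,
    )


def parse_structure(path: str | Path) -> list[AtomRecord]:
    """Read ATOM records of protein chains from a PDB-format file.

    HETATM records and waters are excluded.  For alternate locations the
    highest-occupancy conformer is kept (ties broken by the earliest
    altloc letter).  Hydrogens are retained if present.

    Raises
    ------
    PDBParseError
        On a malformed ATOM line (the message names the line number) or if
        no protein atoms are found.
    """
    atoms: list[AtomRecord] = []
    saw_records = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            record = line[:6]
            if record == "ENDMDL":  # first model only
                break
            if record == "HETATM":
                saw_records = True
            if record != "ATOM  ":
                continue
            saw_records = True
            atom = _parse_atom_line(line, lineno)
            if atom.residue_name in WATER_NAMES:
                continue
            atoms.append(atom)
    if not atoms:
        if saw_records:  # e.g. a ligand-only file: valid but empty
            return []
        raise PDBParseError(f"{path}: no coordinate records found")
    return _resolve_altlocs(atoms)


def _resolve_altlocs(atoms: list[AtomRecord]) -> list[AtomRecord]:
    best: dict[tuple, AtomRecord] = {}
    order: list[tuple] = []
    for atom in atoms:
        key = (*atom.residue_key, atom.atom_name)
        prev = best.get(key)
        if prev is None:
            best[key] = atom
            order.append(key)
        elif (atom.occupancy, prev.altloc) > (prev.occupancy, atom.altloc):
            # higher occupancy wins; on equal occupancy the earlier altloc
            # letter (already stored) is kept
            best[key] = atom
    return [best[k] for k in order]


def _radii_for(atoms: list[AtomRecord], radii: dict[str, float], fallback: float | None):
    out = np.empty(len(atoms))
    unknown: set[str] = set()
    for i, atom in enumerate(atoms):
        r = radii.get(atom.element)
        if r is None:
            unknown.add(atom.element)
            r = fallback if fallback is not None else np.nan
        out[i] = r
    if unknown:
        if fallback is None:
            raise ValueError(
                "unknown element(s) with no fallback radius: " + ", ".join(sorted(unknown))
            )
        warnings.warn(
            f"elements {sorted(unknown)} not in radii table; using fallback {fallback} Å",
            stacklevel=3,
        )
    return out


def find_contact_residues(
    atoms_a: list[AtomRecord],
    atoms_b: list[AtomRecord],
    radii: dict[str, float] | None = None,
    margin: float = DEFAULT_MARGIN,
    fallback_radius: float | None = FALLBACK_RADIUS,
) -> set[tuple[ResidueKey, ResidueKey]]:
    """All residue pairs (one per chain) with any atom pair within
    r_vdw(a) + r_vdw(b) + margin.

    Uses a KD-tree query at the largest possible threshold followed by an
    exact per-pair check, so results equal the brute-force all-pairs scan.
    """
    if margin < 0:
        raise ValueError("margin must be non-negative")
    if not atoms_a or not atoms_b:
        raise ValueError("both atom lists must be non-empty")
    radii = radii if radii is not None else VDW_RADII
    ra = _radii_for(atoms_a, radii, fallback_radius)
    rb = _radii_for(atoms_b, radii, fallback_radius)
    xa = np.array([a.coords for a in atoms_a])
    xb = np.array([b.coords for b in atoms_b])
    max_thr = ra.max() + rb.max() + margin
    tree_b = cKDTree(xb)
    pairs: set[tuple[ResidueKey, ResidueKey]] = set()
    neighbours = cKDTree(xa).query_ball_tree(tree_b, r=max_thr)
    for i, hits in enumerate(neighbours):
        if not hits:
            continue
        d = np.linalg.norm(xb[hits] - xa[i], axis=1)
        thr = ra[i] + rb[hits] + margin
        for j, ok in zip(hits, d <= thr):
            if ok:
                pairs.add((atoms_a[i].residue_key, atoms_b[j].residue_key))
    return pairs


def extract_interface(
    contacts: set[tuple[ResidueKey, ResidueKey]],
    map_a: ChainProteinMap,
    map_b: ChainProteinMap,
    structure_id: str = "",
    resolution: float | None = None,
    protein_lengths: dict[str, int] | None = None,
    chain_residue_counts: dict[str, int] | None = None,
) -> InterfaceRecord:
    """Map contacting residues to protein positions and assemble the record.

    Residues absent from the mapping are dropped; their counts are recorded
    on the result (``unmapped_a``/``unmapped_b``).  Chain coverages are
    computed when ``protein_lengths`` (protein_id → length) and
    ``chain_residue_counts`` (chain_id → number of observed residues) are
    supplied, else left at 1.0.
    """
    pos_a: set[int] = set()
    pos_b: set[int] = set()
    unmapped_a = unmapped_b = 0
    for key_a, key_b in contacts:
        pa = map_a.get(key_a)
        pb = map_b.get(key_b)
        if pa is None:
            unmapped_a += 1
        if pb is None:
            unmapped_b += 1
        if pa is not None and pb is not None:
            pos_a.add(pa)
            pos_b.add(pb)
    if not pos_a or not pos_b:
        raise ValueError(
            f"{structure_id}: no contacting residue pair could be mapped "
            f"({map_a.chain_id}/{map_b.chain_id})"
        )
    kind = "homo" if map_a.protein_id == map_b.protein_id else "hetero"

    def _coverage(cmap: ChainProteinMap) -> float:
        if protein_lengths is None or chain_residue_counts is None:
            return 1.0
        length = protein_lengths.get(cmap.protein_id)
        observed = chain_residue_counts.get(cmap.chain_id)
        if not length or observed is None:
            return 1.0
        return min(1.0, observed / length)

    return InterfaceRecord(
        kind=kind,
        side_a=SemiInterface(map_a.protein_id, frozenset(pos_a)),
        side_b=SemiInterface(map_b.protein_id, frozenset(pos_b)),
        structure_id=structure_id,
        resolution=resolution,
        coverage_a=_coverage(map_a),
        coverage_b=_coverage(map_b),
        unmapped_a=unmapped_a,
        unmapped_b=unmapped_b,
    )


def apply_inclusion_filters(
    rec: InterfaceRecord,
    min_side: int = 5,
    min_coverage: float = 0.30,
    biounit_ok: bool = True,
) -> tuple[bool, list[str]]:
    """Keep/drop decision with reason codes.

    Reasons: ``MIN_SIDE`` (a side has fewer than ``min_side`` residues),
    ``COVERAGE`` (a chain covers less than ``min_coverage`` of its
    protein), ``BIOUNIT`` (the chain pair's relative orientation is not
    confirmed by any author-assigned biological unit; supplied as a
    precomputed flag).
    """
    reasons: list[str] = []
    if len(rec.side_a.positions) < min_side or len(rec.side_b.positions) < min_side:
        reasons.append("MIN_SIDE")
    if rec.coverage_a < min_coverage or rec.coverage_b < min_coverage:
        reasons.append("COVERAGE")
    if not biounit_ok:
        reasons.append("BIOUNIT")
    return (not reasons, reasons)


def group_atoms_by_chain(atoms: list[AtomRecord]) -> dict[str, list[AtomRecord]]:
    chains: dict[str, list[AtomRecord]] = {}
    for atom in atoms:
        chains.setdefault(atom.chain_id, []).append(atom)
    return chains


def chain_residue_counts(atoms: list[AtomRecord]) -> dict[str, int]:
    seen: dict[str, set[ResidueKey]] = {}
    for atom in atoms:
        seen.setdefault(atom.chain_id, set()).add(atom.residue_key)
    return {c: len(keys) for c, keys in seen.items()}
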