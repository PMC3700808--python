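"""Extract interface residues from a two-chain structure.

Builds a toy complex realizing a prescribed pair of semi-interfaces,
then runs the distance-criterion contact detection and the mapping to
canonical protein numbering, and applies the inclusion filters.
"""

from pathlib import Path
import tempfile

from spliceshield.simulate import emit_toy_structure
from spliceshield.structures import (
    ChainProteinMap,
    SemiInterface,
    apply_inclusion_filters,
    chain_residue_counts,
    extract_interface,
    find_contact_residues,
    group_atoms_by_chain,
    parse_structure,
)

side_a = SemiInterface("PROT_A", frozenset({12, 13, 14, 15, 16, 40}))
side_b = SemiInterface("PROT_B", frozenset({5, 6, 7, 8, 9, 10, 11}))
lengths = {"PROT_A": 60, "PROT_B": 50}

with tempfile.TemporaryDirectory() as tmp:
    pdb_text, sifts_rows = emit_toy_structure(side_a, side_b, "DEMO", lengths)
    pdb = Path(tmp) / "demo.pdb"
    pdb.write_text(pdb_text)

    atoms = parse_structure(pdb)
    chains = group_atoms_by_chain(atoms)
    contacts = find_contact_residues(chains["A"], chains["B"])

    maps = {}
    for chain, protein in (("A", "PROT_A"), ("B", "PROT_B")):
        entries = {
            (r["pdb_resnum"], r["pdb_icode"]): r["protein_pos"]
            for r in sifts_rows
            if r["chain_id"] == chain
        }
        maps[chain] = ChainProteinMap(chain, protein, entries)

    record = extract_interface(
        contacts,
        maps["A"],
        maps["B"],
        structure_id="DEMO",
        resolution=2.0,
        protein_lengths=lengths,
        chain_residue_counts=chain_residue_counts(atoms),
    )

keep, reasons = apply_inclusion_filters(record)
print(f"kind:            {record.kind}")
print(f"side A residues: {sorted(record.side_a.positions)}")
print(f"side B residues: {sorted(record.side_b.positions)}")
print(f"coverages:       {record.coverage_a:.2f} / {record.coverage_b:.2f}")
print(f"kept by filters: {keep} {reasons}")
# Both sides recover exactly the prescribed residue sets: every intended
# contact pair sits at 3.0 Å (inside the C-C threshold of 3.90 Å) and all
# other inter-chain atoms are kept far apart.
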