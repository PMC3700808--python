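"""Encode alternative isoforms as bit masks over the canonical protein.

A three-exon gene loses its middle exon in one isoform; the mask marks
the corresponding residues missing and the decomposition reports the
missing stretch and variable region.
"""

from spliceshield.masks import (
    TranscriptCDS,
    build_isoform_mask,
    decompose_mask,
    enumerate_alternative_isoforms,
    select_reference_transcript,
)

# exon coordinates are genomic, half-open, whole codons
reference = TranscriptCDS("T.ref", "GENE1", "+", ((0, 30), (100, 145), (200, 230)))
skip_mid = TranscriptCDS("T.alt1", "GENE1", "+", ((0, 30), (200, 230)))
nmd = TranscriptCDS("T.nmd", "GENE1", "+", ((0, 30),), nmd_flag=True)

protein = "MKTAYIAKQRGDLWETSCHNPFVIEQRSTGDLASA"  # 35 residues = 105 nt of CDS
alternatives = enumerate_alternative_isoforms([reference, skip_mid, nmd], "T.ref")
print("alternative isoforms:", [t.transcript_id for t in alternatives])

mask = build_isoform_mask(reference, skip_mid, protein_id="PROT1")
decomp = decompose_mask(mask)
print("mask (RLE):       ", mask.to_runs())
print("missing stretches:", decomp.missing)
print("variable region:  ", decomp.variable_region)
print(f"coverage:          {mask.coverage:.3f}")
# The skipped 45-nt exon codes residues 11-25, so the mask shows one
# 15-residue missing stretch and the isoform retains ~57% of the protein.

chosen, reason = select_reference_transcript(protein, [(reference, protein)])
print("reference choice: ", chosen, "-", reason)
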