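"""Synthetic genes, isoforms, interfaces, and toy structures.

The generator emulates the features of the real corpus that the pipeline
consumes, with controlled statistical structure:

- multi-exon coding genes on a toy contig (whole-codon exons, so exon
  skipping never shifts the reading frame);
- one canonical (reference) transcript per gene plus alternative isoforms
  formed by skipping internal exons and, occasionally, truncating an
  exon's 3' end in-frame (an alternative-donor-like event);
- interfaces as one or two contiguous runs of residues (5-60 in total by
  default) on canonical proteins, optionally with clustered hot-spot
  subsets;
- toy two-chain structures whose contact residues equal a prescribed
  interface exactly: one pseudo-atom per residue, intended contact pairs
  at 3.0 Å (inside the C-C threshold of 3.90 Å), every other inter-chain
  pair at least 8 Å apart;
- a bias parameter β controlling how splicing treats interfaces: an
  internal exon is skipped with probability ``skip_prob × β`` when it
  overlaps the interface and ``skip_prob`` otherwise.  β = 1 is the
  neutral model, β < 1 makes splicing avoid interfaces (the effect under
  test), β > 1 makes it target them.

The bias acts at exon level because real splicing removes exon-delimited
stretches; residue-level biases would produce masks no splice pattern
could generate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np

from spliceshield.masks import IsoformMask, TranscriptCDS, build_isoform_mask
from spliceshield.structures import InterfaceRecord, SemiInterface

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
# one codon per amino acid keeps translation trivially invertible
_CODON_OF = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}


@dataclass
class SimConfig:
    """Generator parameters; defaults are the package's study conditions."""

    n_genes: int = 50
    exons_per_gene: tuple[int, int] = (4, 10)
    exon_len_codons: tuple[int, int] = (20, 60)
    intron_len: tuple[int, int] = (50, 500)
    isoforms_per_gene: tuple[int, int] = (1, 4)
    skip_prob: float = 0.25
    donor_prob: float = 0.10
    nmd_prob: float = 0.10
    interface_len: tuple[int, int] = (5, 60)
    interface_two_runs_prob: float = 0.3
    hotspot_frac: float = 0.25
    homodimer_prob: float = 0.0
    bias: float = 1.0  # β
    seed: int = 0

    def __post_init__(self) -> None:
        for rng_pair in (
            self.exons_per_gene,
            self.exon_len_codons,
            self.isoforms_per_gene,
            self.interface_len,
            self.intron_len,
        ):
            if rng_pair[0] > rng_pair[1] or rng_pair[0] < 1:
                raise ValueError(f"invalid range {rng_pair}")
        for frac in (self.skip_prob, self.donor_prob, self.nmd_prob, self.hotspot_frac):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if self.bias < 0:
            raise ValueError("bias must be non-negative")


@dataclass
class GeneModel:
    gene_id: str
    protein_id: str
    strand: str
    exon_intervals: list[tuple[int, int]]  # 5'→3', half-open genomic
    exon_codon_spans: list[tuple[int, int]]  # (first codon index 0-based, n codons)
    protein_seq: str
    reference: TranscriptCDS
    transcripts: list[TranscriptCDS] = field(default_factory=list)
    translations: dict[str, str] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return len(self.protein_seq)


def _rand_range(rng: np.random.Generator, lo_hi: tuple[int, int]) -> int:
    return int(rng.integers(lo_hi[0], lo_hi[1] + 1))


def simulate_gene(cfg: SimConfig, rng: np.random.Generator, index: int = 0) -> GeneModel:
    """One multi-exon coding gene with whole-codon exons on a toy contig."""
    gene_id = f"G{index:04d}"
    n_exons = _rand_range(rng, cfg.exons_per_gene)
    exon_codons = [_rand_range(rng, cfg.exon_len_codons) for _ in range(n_exons)]
    strand = "+" if rng.random() < 0.5 else "-"
    pos = int(rng.integers(1000, 10000))
    genomic: list[tuple[int, int]] = []
    for codons in exon_codons:
        genomic.append((pos, pos + 3 * codons))
        pos += 3 * codons + _rand_range(rng, cfg.intron_len)
    # 5'→3' order: ascending for +, descending for -
    exons = genomic if strand == "+" else genomic[::-1]
    total_codons = sum(exon_codons)
    protein_seq = "".join(rng.choice(list(AMINO_ACIDS), size=total_codons))
    spans = []
    start = 0
    ordered_codons = exon_codons if strand == "+" else exon_codons[::-1]
    for codons in ordered_codons:
        spans.append((start, codons))
        start += codons
    reference = TranscriptCDS(
        transcript_id=f"{gene_id}.ref",
        gene_id=gene_id,
        strand=strand,
        coding_exons=tuple(exons),
    )
    gene = GeneModel(
        gene_id=gene_id,
        protein_id=f"P{index:04d}",
        strand=strand,
        exon_intervals=exons,
        exon_codon_spans=spans,
        protein_seq=protein_seq,
        reference=reference,
    )
    gene.transcripts.append(reference)
    gene.translations[reference.transcript_id] = protein_seq
    return gene


def simulate_interface(
    protein_len: int, cfg: SimConfig, rng: np.random.Generator
) -> tuple[set[int], set[int]]:
    """Interface positions (1 or 2 contiguous runs) plus clustered hot spots."""
    total = min(_rand_range(rng, cfg.interface_len), protein_len)
    two_runs = total >= 4 and rng.random() < cfg.interface_two_runs_prob
    runs: list[tuple[int, int]] = []
    if two_runs and protein_len >= total + 2:
        len1 = int(rng.integers(2, total - 1))
        len2 = total - len1
        for _ in range(200):
            s1 = int(rng.integers(1, protein_len - total - 1 + 2))
            s2 = int(rng.integers(1, protein_len - len2 + 2))
            if s2 >= s1 + len1 + 1 or s2 + len2 <= s1 - 1:
                runs = [(s1, len1), (s2, len2)]
                break
        else:
            two_runs = False
    if not runs:
        s = int(rng.integers(1, protein_len - total + 2))
        runs = [(s, total)]
    positions: set[int] = set()
    for s, length in runs:
        positions.update(range(s, s + length))
    sorted_pos = sorted(positions)
    n_hot = int(round(cfg.hotspot_frac * len(sorted_pos)))
    hotspots: set[int] = set()
    if n_hot:
        # hot spots cluster in runs along the sequence ("hot regions")
        start_idx = int(rng.integers(0, len(sorted_pos) - n_hot + 1))
        hotspots = set(sorted_pos[start_idx : start_idx + n_hot])
    return positions, hotspots


def _interface_exons(gene: GeneModel, interface_positions: set[int]) -> list[bool]:
    flags = []
    for start, codons in gene.exon_codon_spans:
        residues = range(start + 1, start + codons + 1)
        flags.append(any(r in interface_positions for r in residues))
    return flags


def simulate_isoforms(
    gene: GeneModel,
    interface_positions: set[int],
    beta: float,
    rng: np.random.Generator,
    cfg: SimConfig,
) -> list[TranscriptCDS]:
    """Alternative isoforms by biased internal-exon skipping.

    Internal exon e is skipped with probability ``skip_prob × β`` when it
    overlaps the interface, ``skip_prob`` otherwise (capped at 1).  A kept
    internal exon may instead be truncated at its 3' end by a whole-codon
    amount (an alternative-donor-like event); the same bias applies when
    the truncated span overlaps the interface, so β = 0 guarantees that no
    isoform ever removes an interface residue.  Isoforms identical to the
    reference are resampled; a gene whose every removal event has zero
    probability yields no isoforms.
    """
    n_exons = len(gene.exon_intervals)
    if n_exons < 3:
        return []
    overlaps = _interface_exons(gene, interface_positions)
    p_skip = [
        min(1.0, cfg.skip_prob * (beta if overlaps[e] else 1.0))
        for e in range(n_exons)
    ]
    internal = list(range(1, n_exons - 1))
    if all(p_skip[e] == 0.0 for e in internal) and cfg.donor_prob == 0.0:
        return []
    n_isoforms = _rand_range(rng, cfg.isoforms_per_gene)
    isoforms: list[TranscriptCDS] = []
    for i in range(n_isoforms):
        for _ in range(200):
            kept: list[tuple[int, int]] = []
            changed = False
            for e in range(n_exons):
                s, t = gene.exon_intervals[e]
                if e in internal and rng.random() < p_skip[e]:
                    changed = True
                    continue
                codons = (t - s) // 3
                if e in internal and cfg.donor_prob > 0 and codons >= 2:
                    cut_codons = int(rng.integers(1, codons))
                    span_start, span_codons = gene.exon_codon_spans[e]
                    removed = range(
                        span_start + span_codons - cut_codons + 1,
                        span_start + span_codons + 1,
                    )
                    overlap = any(r in interface_positions for r in removed)
                    p_donor = min(
                        1.0, cfg.donor_prob * (beta if overlap else 1.0)
                    )
                    if rng.random() < p_donor:
                        cut = 3 * cut_codons
                        changed = True
                        # truncate the 3' end of the exon, in frame
                        if gene.strand == "+":
                            kept.append((s, t - cut))
                        else:
                            kept.append((s + cut, t))
                        continue
                kept.append((s, t))
            if changed:
                break
        else:
            continue
        nmd = rng.random() < cfg.nmd_prob
        iso = TranscriptCDS(
            transcript_id=f"{gene.gene_id}.t{i}",
            gene_id=gene.gene_id,
            strand=gene.strand,
            coding_exons=tuple(kept),
            nmd_flag=bool(nmd),
        )
        isoforms.append(iso)
    return isoforms


def _translate_isoform(gene: GeneModel, iso: TranscriptCDS) -> str:
    mask = build_isoform_mask(gene.reference, iso, protein_id=gene.protein_id)
    kept = [aa for aa, bit in zip(gene.protein_seq, mask.bits) if bit == 0]
    return "".join(kept)


# ---------------------------------------------------------------------------
# Toy structures
# ---------------------------------------------------------------------------

_CONTACT_DIST = 3.0
_SITE_SPACING = 20.0

RESNUM_OFFSET = 100  # author numbering = protein position + offset


def emit_toy_structure(
    si_a: SemiInterface,
    si_b: SemiInterface,
    structure_id: str,
    protein_lengths: dict[str, int],
) -> tuple[str, list[dict]]:
    """PDB text plus SIFTS-style mapping rows realizing the two sides.

    Chains A and B carry one carbon pseudo-atom per protein residue.
    Interface residues are paired at 3.0 Å; the construction keeps every
    unintended inter-chain atom pair at least 8 Å apart, so the contact
    stage recovers exactly the prescribed positions.
    """
    pos_a = sorted(si_a.positions)
    pos_b = sorted(si_b.positions)
    if not pos_a or not pos_b:
        raise ValueError("both sides must be non-empty")
    len_a = protein_lengths[si_a.protein_id]
    len_b = protein_lengths[si_b.protein_id]
    if max(pos_a) > len_a or max(pos_b) > len_b:
        raise ValueError("interface positions exceed protein length")
    n_a, n_b = len(pos_a), len(pos_b)
    n_sites = min(n_a, n_b)
    small_chain, small_pos = ("A", pos_a) if n_a <= n_b else ("B", pos_b)
    big_chain, big_pos = ("B", pos_b) if n_a <= n_b else ("A", pos_a)

    coords: dict[tuple[str, int], tuple[float, float, float]] = {}
    for s, p in enumerate(small_pos):
        coords[(small_chain, p)] = (0.0, 0.0, _SITE_SPACING * s)
    # extra atoms at one site fan out in the xy-plane: they stay 3.0 Å from
    # the site's partner atom and ≥ 17 Å from every other site
    per_site = -(-len(big_pos) // n_sites)
    for i, p in enumerate(big_pos):
        site = i % n_sites
        theta = 2.0 * np.pi * (i // n_sites) / per_site
        coords[(big_chain, p)] = (
            _CONTACT_DIST * float(np.cos(theta)),
            _CONTACT_DIST * float(np.sin(theta)),
            _SITE_SPACING * site,
        )
    # non-interface residues on two well-separated lines (all coordinates
    # kept positive and < 10000 to fit the fixed-width PDB fields)
    for p in range(1, len_a + 1):
        coords.setdefault(("A", p), (500.0 + 5.0 * p, 0.0, 0.0))
    for p in range(1, len_b + 1):
        coords.setdefault(("B", p), (500.0 + 5.0 * p, 500.0, 0.0))

    lines = [f"HEADER    TOY COMPLEX                             {structure_id}"]
    serial = 1
    sifts_rows: list[dict] = []
    for chain, length, protein in (("A", len_a, si_a.protein_id), ("B", len_b, si_b.protein_id)):
        for p in range(1, length + 1):
            x, y, z = coords[(chain, p)]
            resnum = p + RESNUM_OFFSET
            lines.append(
                f"ATOM  {serial:5d}  CA  ALA {chain}{resnum:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                f" C"
            )
            serial += 1
            sifts_rows.append(
                {
                    "structure_id": structure_id,
                    "chain_id": chain,
                    "pdb_resnum": resnum,
                    "pdb_icode": "",
                    "protein_id": protein,
                    "protein_pos": p,
                }
            )
    lines.append("END")
    return "\n".join(lines) + "\n", sifts_rows


# ---------------------------------------------------------------------------
# Whole-dataset simulation
# ---------------------------------------------------------------------------


@dataclass
class SimulatedGene:
    gene: GeneModel
    interface: InterfaceRecord | None
    hotspots: set[int]
    isoform_masks: list[IsoformMask]
    partner_protein: str | None
    partner_length: int | None


def simulate_pairs(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> list[SimulatedGene]:
    """In-memory simulation: genes, interfaces, masks, truth records.

    This is the fast path used by statistical experiments; toy structures
    and on-disk files are added by :func:`simulate_dataset`.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    out: list[SimulatedGene] = []
    for g in range(cfg.n_genes):
        gene = simulate_gene(cfg, rng, g)
        positions, hotspots = simulate_interface(gene.length, cfg, rng)
        homodimer = rng.random() < cfg.homodimer_prob
        if homodimer:
            positions_b, _ = simulate_interface(gene.length, cfg, rng)
            side_a = SemiInterface(gene.protein_id, frozenset(positions), frozenset(hotspots))
            side_b = SemiInterface(gene.protein_id, frozenset(positions_b))
            record = InterfaceRecord(
                kind="homo",
                side_a=side_a,
                side_b=side_b,
                structure_id=f"S{g:04d}",
                resolution=round(float(rng.uniform(1.5, 3.0)), 2),
            )
            partner, partner_len = None, None
            bias_positions = positions | positions_b
        else:
            partner = f"P{g:04d}X"
            partner_len = int(rng.integers(80, 300))
            n_partner = min(_rand_range(rng, cfg.interface_len), partner_len)
            start = int(rng.integers(1, partner_len - n_partner + 2))
            side_a = SemiInterface(gene.protein_id, frozenset(positions), frozenset(hotspots))
            side_b = SemiInterface(partner, frozenset(range(start, start + n_partner)))
            record = InterfaceRecord(
                kind="hetero",
                side_a=side_a,
                side_b=side_b,
                structure_id=f"S{g:04d}",
                resolution=round(float(rng.uniform(1.5, 3.0)), 2),
            )
            bias_positions = positions
        isoforms = simulate_isoforms(gene, bias_positions, cfg.bias, rng, cfg)
        masks = []
        for iso in isoforms:
            gene.transcripts.append(iso)
            gene.translations[iso.transcript_id] = _translate_isoform(gene, iso)
            if not iso.nmd_flag:
                masks.append(build_isoform_mask(gene.reference, iso, gene.protein_id))
        out.append(
            SimulatedGene(
                gene=gene,
                interface=record,
                hotspots=hotspots,
                isoform_masks=masks,
                partner_protein=partner,
                partner_length=partner_len,
            )
        )
    return out


def simulate_dataset(cfg: SimConfig, out_dir: str | Path) -> Path:
    """Write a full synthetic input bundle the pipeline consumes end-to-end.

    Emits proteins.fasta, transcripts.fasta, exons.tsv, structures/*.pdb,
    sifts.tsv, structures_meta.tsv, hotspots.tsv, and truth.json.
    """
    out = Path(out_dir)
    (out / "structures").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    sims = simulate_pairs(cfg, rng)

    fasta_lines = []
    transcript_lines = []
    exon_rows = ["gene_id\ttranscript_id\tstrand\texon_start\texon_end\tis_nmd"]
    sifts_rows = ["structure_id\tchain_id\tpdb_resnum\tpdb_icode\tprotein_id\tprotein_pos"]
    meta_rows = ["structure_id\tresolution\tbiounit_ok"]
    hotspot_rows = ["protein_id\tposition"]
    truth: dict = {"config": asdict(cfg), "genes": {}}

    for sim in sims:
        gene = sim.gene
        fasta_lines.append(f">{gene.protein_id} gene={gene.gene_id}")
        fasta_lines.append(gene.protein_seq)
        for t in gene.transcripts:
            transcript_lines.append(f">{t.transcript_id} gene={gene.gene_id}")
            transcript_lines.append(gene.translations[t.transcript_id])
            for s, e in t.coding_exons:
                exon_rows.append(
                    f"{gene.gene_id}\t{t.transcript_id}\t{t.strand}\t{s}\t{e}\t"
                    f"{int(t.nmd_flag)}"
                )
        rec = sim.interface
        if rec is None:
            continue
        lengths = {gene.protein_id: gene.length}
        if sim.partner_protein is not None:
            lengths[sim.partner_protein] = sim.partner_length
            fasta_lines.append(f">{sim.partner_protein} partner")
            fasta_lines.append("".join(rng.choice(list(AMINO_ACIDS), size=sim.partner_length)))
        pdb_text, rows = emit_toy_structure(rec.side_a, rec.side_b, rec.structure_id, lengths)
        (out / "structures" / f"{rec.structure_id}.pdb").write_text(pdb_text)
        for r in rows:
            sifts_rows.append(
                f"{r['structure_id']}\t{r['chain_id']}\t{r['pdb_resnum']}\t"
                f"{r['pdb_icode']}\t{r['protein_id']}\t{r['protein_pos']}"
            )
        meta_rows.append(f"{rec.structure_id}\t{rec.resolution}\t1")
        for h in sorted(sim.hotspots):
            hotspot_rows.append(f"{gene.protein_id}\t{h}")
        truth["genes"][gene.gene_id] = {
            "protein_id": gene.protein_id,
            "length": gene.length,
            "kind": rec.kind,
            "interface_a": sorted(rec.side_a.positions),
            "interface_b": sorted(rec.side_b.positions),
            "hotspots": sorted(sim.hotspots),
            "masks": {m.isoform_id: m.to_runs() for m in sim.isoform_masks},
            "bias": cfg.bias,
        }

    (out / "proteins.fasta").write_text("\n".join(fasta_lines) + "\n")
    (out / "transcripts.fasta").write_text("\n".join(transcript_lines) + "\n")
    (out / "exons.tsv").write_text("\n".join(exon_rows) + "\n")
    (out / "sifts.tsv").write_text("\n".join(sifts_rows) + "\n")
    (out / "structures_meta.tsv").write_text("\n".join(meta_rows) + "\n")
    (out / "hotspots.tsv").write_text("\n".join(hotspot_rows) + "\n")
    (out / "truth.json").write_text(json.dumps(truth, indent=1))
    return out
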