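"""Readers and writers for the pipeline's tabular and sequence formats.

Conventions: genomic intervals are 0-based half-open internally; GFF3/GTF
input (1-based inclusive) is converted on read.  The simplified exon TSV
dialect (columns gene_id, transcript_id, strand, exon_start, exon_end,
is_nmd) is already half-open 0-based.  Protein positions are 1-based
everywhere in I/O.
"""

from __future__ import annotations

import re
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from spliceshield.masks import IsoformMask, TranscriptCDS
from spliceshield.structures import ChainProteinMap, InterfaceRecord


def read_fasta(path: str | Path) -> dict[str, str]:
    """id → sequence; the description is discarded."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_fasta_with_genes(path: str | Path) -> tuple[dict[str, str], dict[str, str]]:
    """id → sequence plus id → gene_id parsed from ``gene=...`` in headers."""
    seqs: dict[str, str] = {}
    genes: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seqs[rec.id] = str(rec.seq)
        match = re.search(r"gene=(\S+)", rec.description)
        if match:
            genes[rec.id] = match.group(1)
    return seqs, genes


def read_exon_tsv(path: str | Path) -> dict[str, list[TranscriptCDS]]:
    """Simplified exon table → gene_id → transcripts (exons ordered 5'→3')."""
    df = pd.read_csv(path, sep="\t", dtype={"is_nmd": int})
    genes: dict[str, list[TranscriptCDS]] = {}
    for (gene_id, transcript_id), group in df.groupby(
        ["gene_id", "transcript_id"], sort=False
    ):
        strand = group["strand"].iloc[0]
        exons = sorted(
            zip(group["exon_start"].astype(int), group["exon_end"].astype(int)),
            reverse=(strand == "-"),
        )
        genes.setdefault(gene_id, []).append(
            TranscriptCDS(
                transcript_id=transcript_id,
                gene_id=gene_id,
                strand=strand,
                coding_exons=tuple(exons),
                nmd_flag=bool(group["is_nmd"].iloc[0]),
            )
        )
    return genes


_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]+)"')
_GFF3_ATTR = re.compile(r"(\w+)=([^;]+)")


def read_gff_cds(path: str | Path) -> dict[str, list[TranscriptCDS]]:
    """CDS features from GFF3 or GTF → gene_id → transcripts.

    Attributes must provide ``transcript_id`` and ``gene_id`` (GTF style)
    or ``Parent``/``gene_id`` (GFF3 style); an ``nmd`` attribute or a
    ``transcript_biotype`` containing "nonsense_mediated_decay" sets the
    NMD flag.
    """
    rows: dict[tuple[str, str, str], list[tuple[int, int]]] = {}
    nmd: dict[str, bool] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != "CDS":
                continue
            start, end, strand, attrs = int(fields[3]), int(fields[4]), fields[6], fields[8]
            pairs = dict(_GTF_ATTR.findall(attrs)) or dict(_GFF3_ATTR.findall(attrs))
            transcript = pairs.get("transcript_id") or pairs.get("Parent")
            gene = pairs.get("gene_id") or pairs.get("gene")
            if transcript is None or gene is None:
                continue
            rows.setdefault((gene, transcript, strand), []).append((start - 1, end))
            biotype = pairs.get("transcript_biotype", "") + pairs.get("nmd", "")
            nmd[transcript] = nmd.get(transcript, False) or (
                "nonsense_mediated_decay" in biotype or pairs.get("nmd") == "1"
            )
    genes: dict[str, list[TranscriptCDS]] = {}
    for (gene, transcript, strand), exons in rows.items():
        exons = sorted(exons, reverse=(strand == "-"))
        genes.setdefault(gene, []).append(
            TranscriptCDS(
                transcript_id=transcript,
                gene_id=gene,
                strand=strand,
                coding_exons=tuple(exons),
                nmd_flag=nmd.get(transcript, False),
            )
        )
    return genes


def read_sifts_tsv(path: str | Path) -> dict[tuple[str, str], ChainProteinMap]:
    """SIFTS-style table → (structure_id, chain_id) → ChainProteinMap."""
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    maps: dict[tuple[str, str], ChainProteinMap] = {}
    for (structure_id, chain_id, protein_id), group in df.groupby(
        ["structure_id", "chain_id", "protein_id"], sort=False
    ):
        entries = {
            (int(row.pdb_resnum), str(row.pdb_icode)): int(row.protein_pos)
            for row in group.itertuples()
        }
        maps[(structure_id, chain_id)] = ChainProteinMap(
            chain_id=chain_id, protein_id=protein_id, entries=entries
        )
    return maps


def read_structures_meta(path: str | Path) -> dict[str, dict]:
    df = pd.read_csv(path, sep="\t")
    return {
        str(row.structure_id): {
            "resolution": None if pd.isna(row.resolution) else float(row.resolution),
            "biounit_ok": bool(row.biounit_ok),
        }
        for row in df.itertuples()
    }


def read_hotspots_tsv(path: str | Path) -> dict[str, set[int]]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, set[int]] = {}
    for row in df.itertuples():
        out.setdefault(str(row.protein_id), set()).add(int(row.position))
    return out


def read_annotations_tsv(path: str | Path) -> dict[str, set[str]]:
    """gene→term TSV (columns protein_id/gene_id and term_id) or GAF 2.x."""
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("!gaf-version"):
        out: dict[str, set[str]] = {}
        with open(path) as fh:
            for line in fh:
                if line.startswith("!"):
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) > 4:
                    out.setdefault(fields[1], set()).add(fields[4])
        return out
    df = pd.read_csv(path, sep="\t")
    id_col = "protein_id" if "protein_id" in df.columns else df.columns[0]
    term_col = "term_id" if "term_id" in df.columns else df.columns[1]
    out = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(getattr(row, id_col)), set()).add(str(getattr(row, term_col)))
    return out


def write_interfaces_tsv(records: list[InterfaceRecord], path: str | Path) -> None:
    rows = []
    for rec in records:
        rows.append(
            {
                "kind": rec.kind,
                "structure_id": rec.structure_id,
                "protein_a": rec.side_a.protein_id,
                "positions_a": ",".join(map(str, sorted(rec.side_a.positions))),
                "hotspots_a": ",".join(map(str, sorted(rec.side_a.hotspots))),
                "protein_b": rec.side_b.protein_id,
                "positions_b": ",".join(map(str, sorted(rec.side_b.positions))),
                "resolution": rec.resolution,
                "coverage_a": rec.coverage_a,
                "coverage_b": rec.coverage_b,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_masks_tsv(masks: list[IsoformMask], path: str | Path) -> None:
    rows = [
        {"protein_id": m.protein_id, "isoform_id": m.isoform_id, "bits_rle": m.to_runs()}
        for m in masks
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_masks_tsv(path: str | Path) -> list[IsoformMask]:
    df = pd.read_csv(path, sep="\t")
    return [
        IsoformMask.from_runs(str(r.protein_id), str(r.isoform_id), str(r.bits_rle))
        for r in df.itertuples()
    ]
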