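"""Isoform two-bit masks over the canonical protein.

Each alternative isoform of a gene is encoded as a bit string with one bit
per canonical-protein residue: 0 if the residue is retained in the isoform,
1 if it is missing.  Bits are derived purely from genomic CDS coordinates:
residue i is missing when any base of its codon is absent from the
alternative transcript's coding exons (a partial codon cannot encode the
canonical residue).

Terminology used throughout the package:

- *missing stretch*: maximal run of 1-bits;
- *non-missing stretch*: run of 0-bits strictly between two missing
  stretches;
- *variable region*: span from the first missing stretch's start to the
  last missing stretch's end;
- *coverage*: fraction of 0-bits, i.e. how much of the canonical sequence
  the isoform retains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYXBZJUO*")

# Needleman-Wunsch scoring used for reference-transcript selection only:
# identity matrix (match +1 / mismatch -1), affine gaps (first gap residue
# -5, each further residue -1).  Exact scores are non-critical; the
# selection rule counts difference runs, not scores.
NW_MATCH = 1.0
NW_MISMATCH = -1.0
NW_GAP_OPEN = -5.0
NW_GAP_EXTEND = -1.0


@dataclass(frozen=True)
class TranscriptCDS:
    """Coding structure of one transcript.

    ``coding_exons`` are half-open genomic intervals [start, end), 0-based,
    ordered 5'→3' (descending genomic coordinates on the minus strand).
    """

    transcript_id: str
    gene_id: str
    strand: str
    coding_exons: tuple[tuple[int, int], ...]
    nmd_flag: bool = False

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        exons = tuple(tuple(e) for e in self.coding_exons)
        object.__setattr__(self, "coding_exons", exons)
        if any(e[1] <= e[0] for e in exons):
            raise ValueError("exon intervals must be non-empty half-open [start, end)")
        genomic = sorted(exons)
        if self.strand == "-":
            expected = tuple(sorted(exons, reverse=True))
        else:
            expected = tuple(genomic)
        if exons != expected:
            raise ValueError("exons must be ordered 5'→3'")
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if s2 < e1:
                raise ValueError("exons overlap")

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.coding_exons)

    def base_positions(self) -> np.ndarray:
        """Genomic position of every CDS base, in translation order."""
        parts = []
        for s, e in self.coding_exons:
            block = np.arange(s, e)
            if self.strand == "-":
                block = block[::-1]
            parts.append(block)
        return np.concatenate(parts)


@dataclass
class IsoformMask:
    """Presence/absence bit string of one isoform over a canonical protein."""

    protein_id: str
    isoform_id: str
    bits: np.ndarray

    def __post_init__(self) -> None:
        bits = np.asarray(self.bits, dtype=np.uint8)
        if bits.ndim != 1 or bits.size == 0:
            raise ValueError("bits must be a non-empty 1-D array")
        if not np.isin(bits, (0, 1)).all():
            raise ValueError("bits must be 0/1")
        self.bits = bits

    def __len__(self) -> int:
        return self.bits.size

    @property
    def coverage(self) -> float:
        return float(1.0 - self.bits.mean())

    @property
    def n_missing(self) -> int:
        return int(self.bits.sum())

    def to_runs(self) -> str:
        """Run-length encoding, e.g. ``"0:10,1:5,0:85"``."""
        out = []
        for value, length in _runs(self.bits):
            out.append(f"{value}:{length}")
        return ",".join(out)

    @classmethod
    def from_runs(cls, protein_id: str, isoform_id: str, runs: str) -> "IsoformMask":
        parts = []
        for token in runs.split(","):
            value, length = token.split(":")
            parts.append(np.full(int(length), int(value), dtype=np.uint8))
        return cls(protein_id, isoform_id, np.concatenate(parts))


def _runs(bits: np.ndarray) -> list[tuple[int, int]]:
    edges = np.flatnonzero(np.diff(bits)) + 1
    bounds = np.concatenate(([0], edges, [bits.size]))
    return [(int(bits[s]), int(e - s)) for s, e in zip(bounds, bounds[1:])]


@dataclass
class StretchDecomposition:
    """Stretch view of a mask.

    ``missing`` and ``non_missing`` are ordered ``(start, length)`` pairs
    with 1-based starts; ``variable_region`` is the 1-based inclusive span
    ``(start, end)`` from the first to the last missing stretch, or ``None``
    for an all-zero mask.
    """

    length: int
    missing: list[tuple[int, int]] = field(default_factory=list)
    non_missing: list[tuple[int, int]] = field(default_factory=list)
    variable_region: tuple[int, int] | None = None

    @property
    def coverage(self) -> float:
        return 1.0 - sum(l for _, l in self.missing) / self.length

    def reconstruct(self) -> np.ndarray:
        bits = np.zeros(self.length, dtype=np.uint8)
        for start, length in self.missing:
            bits[start - 1 : start - 1 + length] = 1
        return bits


def decompose_mask(mask: IsoformMask) -> StretchDecomposition:
    """Split a mask into missing / non-missing stretches and the variable region."""
    missing: list[tuple[int, int]] = []
    pos = 1
    for value, length in _runs(mask.bits):
        if value == 1:
            missing.append((pos, length))
        pos += length
    if not missing:
        return StretchDecomposition(length=len(mask))
    region = (missing[0][0], missing[-1][0] + missing[-1][1] - 1)
    non_missing = [
        (s1 + l1, s2 - (s1 + l1))
        for (s1, l1), (s2, _) in zip(missing, missing[1:])
    ]
    return StretchDecomposition(
        length=len(mask), missing=missing, non_missing=non_missing, variable_region=region
    )


# ---------------------------------------------------------------------------
# Global alignment and reference-transcript selection
# ---------------------------------------------------------------------------


@dataclass
class AlignmentSummary:
    """A pairwise global alignment plus its difference structure."""

    aligned_a: str
    aligned_b: str
    score: float
    n_differences: int  # maximal runs of gap or mismatch columns
    n_matches: int
    n_aligned_columns: int  # columns where both sequences have a residue


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = NW_MATCH
    aligner.mismatch_score = NW_MISMATCH
    aligner.open_gap_score = NW_GAP_OPEN
    aligner.extend_gap_score = NW_GAP_EXTEND
    return aligner


_ALIGNER = _make_aligner()


def global_align(seq_a: str, seq_b: str) -> AlignmentSummary:
    """Needleman-Wunsch global alignment with affine gap penalties.

    The difference count is the number of maximal runs of non-identity
    columns (gap or substitution), i.e. the count of non-contiguous gaps
    or substitutions used for reference-transcript selection.
    """
    for seq in (seq_a, seq_b):
        if not seq:
            raise ValueError("sequences must be non-empty")
        bad = set(seq.upper()) - AA_ALPHABET
        if bad:
            raise ValueError(f"invalid sequence characters: {sorted(bad)}")
    alignment = _ALIGNER.align(seq_a.upper(), seq_b.upper())[0]
    ga, gb = str(alignment[0]), str(alignment[1])
    n_diff = 0
    in_diff = False
    n_match = 0
    n_cols_both = 0
    for ca, cb in zip(ga, gb):
        is_diff = ca == "-" or cb == "-" or ca != cb
        if ca != "-" and cb != "-":
            n_cols_both += 1
            if ca == cb:
                n_match += 1
        if is_diff and not in_diff:
            n_diff += 1
        in_diff = is_diff
    return AlignmentSummary(
        aligned_a=ga,
        aligned_b=gb,
        score=float(alignment.score),
        n_differences=n_diff,
        n_matches=n_match,
        n_aligned_columns=n_cols_both,
    )


def select_reference_transcript(
    protein_seq: str,
    candidates: list[tuple[TranscriptCDS, str]],
    max_diffs: int = 5,
) -> tuple[str | None, str]:
    """Pick the transcript whose translation matches the canonical protein.

    Preference order: a candidate translating to the identical sequence;
    otherwise the candidate with the fewest non-contiguous differences,
    provided that count is at most ``max_diffs``; otherwise ``None``.
    Ties break to the lexicographically smallest transcript id.

    Returns ``(transcript_id or None, reason)``.
    """
    if not candidates:
        return None, "no candidate transcripts"
    exact = sorted(
        t.transcript_id for t, seq in candidates if seq.upper() == protein_seq.upper()
    )
    if exact:
        return exact[0], "identical coding sequence"
    scored: list[tuple[int, float, str]] = []
    for transcript, seq in candidates:
        summary = global_align(protein_seq, seq)
        scored.append((summary.n_differences, -summary.score, transcript.transcript_id))
    scored.sort()
    n_diff, _, best_id = scored[0]
    if n_diff <= max_diffs:
        return best_id, f"{n_diff} non-contiguous difference(s)"
    return None, f"best candidate has {n_diff} non-contiguous differences (> {max_diffs})"


def enumerate_alternative_isoforms(
    gene_transcripts: list[TranscriptCDS],
    reference_id: str,
    translations: dict[str, str] | None = None,
) -> list[TranscriptCDS]:
    """Alternative isoforms of a gene: all full-length coding transcripts
    except the reference, NMD-flagged transcripts, and transcripts whose
    translated protein is identical to the reference protein.

    Transcripts sharing one coding sequence distinct from the reference are
    all retained (their splicing patterns count separately).
    """
    reference = next(
        (t for t in gene_transcripts if t.transcript_id == reference_id), None
    )
    if reference is None:
        raise ValueError(f"reference transcript {reference_id} not in gene")
    ref_translation = translations.get(reference_id) if translations else None
    out = []
    for t in gene_transcripts:
        if t.transcript_id == reference_id or t.nmd_flag:
            continue
        if translations is not None and ref_translation is not None:
            if translations.get(t.transcript_id) == ref_translation:
                continue
        elif t.coding_exons == reference.coding_exons and t.strand == reference.strand:
            continue
        out.append(t)
    return out


def build_isoform_mask(
    reference: TranscriptCDS,
    alternative: TranscriptCDS,
    protein_id: str | None = None,
) -> IsoformMask:
    """Mask of an alternative isoform against the reference transcript.

    Residue i of the canonical protein gets bit 1 iff any base of its
    codon's genomic interval is absent from the alternative's coding exons.
    The comparison is purely genomic; no sequence is needed.
    """
    if reference.gene_id != alternative.gene_id:
        raise ValueError("reference and alternative must belong to the same gene")
    if reference.strand != alternative.strand:
        raise ValueError("reference and alternative must share a strand")
    if reference.cds_length % 3 != 0:
        raise ValueError(
            f"reference CDS length {reference.cds_length} is not divisible by 3"
        )
    bases = reference.base_positions()
    alt_exons = sorted(alternative.coding_exons)
    bounds = np.array([b for exon in alt_exons for b in exon])
    # position p is inside the alternative's exons iff searchsorted parity is odd
    inside = (np.searchsorted(bounds, bases, side="right") % 2) == 1
    codon_present = inside.reshape(-1, 3).all(axis=1)
    bits = (~codon_present).astype(np.uint8)
    return IsoformMask(
        protein_id=protein_id or reference.gene_id,
        isoform_id=alternative.transcript_id,
        bits=bits,
    )
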