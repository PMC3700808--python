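"""Selectivity of interface removal/protection, and annotation enrichment.

Each spliced (semi-)interface/isoform pair gets a score equal to the
fraction of its single-isoform decoys that remove the interface: a low
score means the real splicing event removes a site that random splicing
would rarely hit, i.e. the removal is selective.  Interfaces never
removed in any isoform are scored with the fraction of all-isoforms
control groups that remove them: a high score means random splicing would
usually have hit the site, i.e. the protection is selective.

Proteins with at least one spliced pair scoring below the cutoff
(default 0.5, strict) form the selectively-removed class; proteins with a
never-spliced interface scoring above the cutoff form the
selectively-protected class.  Enrichment of annotation terms in either
class against the full tested background uses an upper-tail
hypergeometric test with Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from spliceshield.decoys import AllIsoformsControls, ControlSet
from spliceshield.masks import IsoformMask
from spliceshield.splice_tests import _controls_removed, _tested_sides, is_removed
from spliceshield.structures import InterfaceRecord


@dataclass
class SelectivityScore:
    """Fraction of controls removing one interface (basis: which null)."""

    interface_id: str
    protein_id: str
    score: float
    basis: str  # "single" | "all"
    isoform_id: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("score must be in [0, 1]")
        if self.basis not in ("single", "all"):
            raise ValueError("basis must be 'single' or 'all'")


@dataclass
class EnrichmentRow:
    term_id: str
    target_count: int
    background_count: int
    p_value: float
    q_value: float
    significant: bool


def selectivity_scores(
    pairs: list[tuple[InterfaceRecord, IsoformMask, ControlSet]],
    all_controls: dict[str, AllIsoformsControls],
    threshold: float,
) -> list[SelectivityScore]:
    """Score selectivity at one interface-removal threshold.

    Spliced pairs (real isoform removes the interface) are scored from
    their single-isoform decoys.  Interfaces that no isoform removes are
    scored from the protein's all-isoforms controls (keyed by protein id
    in ``all_controls``).
    """
    scores: list[SelectivityScore] = []
    interface_spliced: dict[int, bool] = {}
    for rec, mask, controls in pairs:
        if is_removed(rec, mask, threshold).removed:
            interface_spliced[id(rec)] = True
            frac = _controls_removed(rec, controls, threshold) / controls.n_controls
            scores.append(
                SelectivityScore(
                    interface_id=rec.structure_id,
                    protein_id=mask.protein_id,
                    score=frac,
                    basis="single",
                    isoform_id=mask.isoform_id,
                )
            )
        else:
            interface_spliced.setdefault(id(rec), False)
    seen: set[int] = set()
    for rec, mask, _ in pairs:
        if interface_spliced.get(id(rec)) or id(rec) in seen:
            continue
        seen.add(id(rec))
        controls = all_controls.get(mask.protein_id)
        if controls is None:
            continue
        sides = _tested_sides(rec, controls.protein_id)
        flags = np.zeros(len(controls.controls), dtype=bool)
        for side in sides:
            flags |= controls.removal_flags(side.positions, threshold)
        scores.append(
            SelectivityScore(
                interface_id=rec.structure_id,
                protein_id=mask.protein_id,
                score=float(flags.mean()),
                basis="all",
            )
        )
    return scores


def partition_proteins(
    scores: list[SelectivityScore], cutoff: float = 0.5
) -> tuple[set[str], set[str]]:
    """(selectively_removed, selectively_protected) protein-id sets.

    Strict inequalities: a score exactly at the cutoff joins neither
    class.  A protein is selectively-removed when ≥1 of its spliced pairs
    scores below the cutoff, selectively-protected when one of its
    never-spliced interfaces scores above it.
    """
    removed = {
        s.protein_id for s in scores if s.basis == "single" and s.score < cutoff
    }
    protected = {
        s.protein_id for s in scores if s.basis == "all" and s.score > cutoff
    }
    return removed, protected


def hypergeometric_enrichment(
    target: set[str],
    background: set[str],
    annotations: dict[str, set[str]],
    q_max: float = 0.05,
) -> list[EnrichmentRow]:
    """Upper-tail hypergeometric enrichment of terms in ``target`` vs
    ``background``, BH-corrected across terms.

    ``annotations`` maps protein id → set of term ids; terms with no
    annotated background protein are skipped.
    """
    if not target <= background:
        raise ValueError("target must be a subset of background")
    if not target:
        return []
    term_bg: dict[str, int] = {}
    term_tg: dict[str, int] = {}
    for protein in background:
        for term in annotations.get(protein, ()):  # unannotated proteins allowed
            term_bg[term] = term_bg.get(term, 0) + 1
            if protein in target:
                term_tg[term] = term_tg.get(term, 0) + 1
    terms = sorted(term_bg)
    if not terms:
        return []
    n_bg, n_tg = len(background), len(target)
    p_values = []
    for term in terms:
        k = term_tg.get(term, 0)
        big_k = term_bg[term]
        p_values.append(float(hypergeom.sf(k - 1, n_bg, big_k, n_tg)))
    reject, q_values, _, _ = multipletests(p_values, alpha=q_max, method="fdr_bh")
    return [
        EnrichmentRow(
            term_id=term,
            target_count=term_tg.get(term, 0),
            background_count=term_bg[term],
            p_value=p,
            q_value=float(q),
            significant=bool(r and q < q_max),
        )
        for term, p, q, r in zip(terms, p_values, q_values, reject)
    ]
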