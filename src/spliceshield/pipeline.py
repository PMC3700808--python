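"""End-to-end orchestration: files in, stratified-test report out.

``run_full_analysis`` consumes a bundle directory (as written by
:func:`spliceshield.simulate.simulate_dataset`, or assembled from real
data in the same layout), runs interface extraction, reference-transcript
selection, mask construction, optional redundancy reduction, decoy
generation, and the stratified tests over a threshold × coverage grid,
and writes a results table, frequency/p-value plots, and a provenance
block (seed, package version, config hash).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from spliceshield import io as ssio
from spliceshield.decoys import (
    DecoyGenerationError,
    DecoySpec,
    all_isoforms_control_sets,
    single_isoform_control_set,
)
from spliceshield.masks import (
    build_isoform_mask,
    enumerate_alternative_isoforms,
    select_reference_transcript,
)
from spliceshield.redundancy import (
    deduplicate_homo_interfaces,
    deduplicate_semi_interfaces,
)
from spliceshield.splice_tests import (
    all_isoforms_test,
    filter_by_coverage,
    hotspot_independence_test,
    single_isoform_test,
)
from spliceshield.structures import (
    InterfaceRecord,
    SemiInterface,
    apply_inclusion_filters,
    chain_residue_counts,
    extract_interface,
    find_contact_residues,
    group_atoms_by_chain,
    parse_structure,
)

logger = logging.getLogger("spliceshield")


@dataclass
class RunConfig:
    """Configuration of a full analysis run."""

    input_dir: str
    out_dir: str
    thresholds: list[int] = field(default_factory=lambda: list(range(10, 101, 10)))
    coverage_grid: list[int] = field(default_factory=lambda: [0])
    n_controls: int = 1000
    seed: int = 0
    correction: bool = True
    min_side: int = 5
    min_coverage: float = 0.30
    max_diffs: int = 5
    dedupe: bool = True
    run_hotspot_test: bool = True
    make_plots: bool = True

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                result = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - stage name is the contract
                raise StageError(f"stage '{name}' failed: {exc}") from exc
            logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return result

        return inner

    return wrap


@_stage("extract-interfaces")
def _extract_all_interfaces(cfg: RunConfig, protein_lengths: dict[str, int]):
    bundle = Path(cfg.input_dir)
    maps = ssio.read_sifts_tsv(bundle / "sifts.tsv")
    meta = ssio.read_structures_meta(bundle / "structures_meta.tsv")
    records: list[InterfaceRecord] = []
    for pdb_path in sorted((bundle / "structures").glob("*.pdb")):
        structure_id = pdb_path.stem
        atoms = parse_structure(pdb_path)
        chains = group_atoms_by_chain(atoms)
        counts = chain_residue_counts(atoms)
        chain_ids = sorted(chains)
        info = meta.get(structure_id, {"resolution": None, "biounit_ok": True})
        for i, ca in enumerate(chain_ids):
            for cb in chain_ids[i + 1 :]:
                map_a = maps.get((structure_id, ca))
                map_b = maps.get((structure_id, cb))
                if map_a is None or map_b is None:
                    continue
                contacts = find_contact_residues(chains[ca], chains[cb])
                if not contacts:
                    continue
                rec = extract_interface(
                    contacts,
                    map_a,
                    map_b,
                    structure_id=structure_id,
                    resolution=info["resolution"],
                    protein_lengths=protein_lengths,
                    chain_residue_counts=counts,
                )
                keep, reasons = apply_inclusion_filters(
                    rec, cfg.min_side, cfg.min_coverage, info["biounit_ok"]
                )
                if keep:
                    records.append(rec)
                else:
                    logger.info("drop %s %s/%s: %s", structure_id, ca, cb, reasons)
    return records


@_stage("map-isoforms")
def _build_masks(cfg: RunConfig, proteins: dict[str, str], protein_gene: dict[str, str]):
    bundle = Path(cfg.input_dir)
    genes = ssio.read_exon_tsv(bundle / "exons.tsv")
    translations = ssio.read_fasta(bundle / "transcripts.fasta")
    masks_by_protein: dict[str, list] = {}
    for protein_id, gene_id in protein_gene.items():
        transcripts = genes.get(gene_id, [])
        candidates = [
            (t, translations[t.transcript_id])
            for t in transcripts
            if t.transcript_id in translations and not t.nmd_flag
        ]
        ref_id, reason = select_reference_transcript(
            proteins[protein_id], candidates, cfg.max_diffs
        )
        if ref_id is None:
            logger.info("no reference for %s: %s", protein_id, reason)
            continue
        reference = next(t for t in transcripts if t.transcript_id == ref_id)
        alternatives = enumerate_alternative_isoforms(
            transcripts, ref_id, {t: s for t, s in translations.items()}
        )
        masks = []
        for alt in alternatives:
            mask = build_isoform_mask(reference, alt, protein_id)
            if mask.n_missing > 0:
                masks.append(mask)
        if masks:
            masks_by_protein[protein_id] = masks
    return masks_by_protein


def _hotspot_annotated(rec: InterfaceRecord, hotspots: dict[str, set[int]]):
    def annotate(si: SemiInterface) -> SemiInterface:
        hs = hotspots.get(si.protein_id, set()) & set(si.positions)
        return SemiInterface(si.protein_id, si.positions, frozenset(hs))

    rec.side_a = annotate(rec.side_a)
    rec.side_b = annotate(rec.side_b)
    return rec


def run_full_analysis(cfg: RunConfig) -> dict:
    """Run every stage and write results under ``cfg.out_dir``.

    Returns a summary dict with the results table (as a DataFrame under
    ``"results"``), kept interfaces, and provenance.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = Path(cfg.input_dir)
    rng = np.random.default_rng(cfg.seed)

    proteins, protein_gene = ssio.read_fasta_with_genes(bundle / "proteins.fasta")
    lengths = {p: len(s) for p, s in proteins.items()}
    records = _extract_all_interfaces(cfg, lengths)
    hotspot_path = bundle / "hotspots.tsv"
    hotspots = ssio.read_hotspots_tsv(hotspot_path) if hotspot_path.exists() else {}
    records = [_hotspot_annotated(r, hotspots) for r in records]
    masks_by_protein = _build_masks(cfg, proteins, protein_gene)

    # retain interfaces whose gene yields at least one alternative isoform
    def has_masks(rec: InterfaceRecord) -> bool:
        return (
            rec.side_a.protein_id in masks_by_protein
            or rec.side_b.protein_id in masks_by_protein
        )

    records = [r for r in records if has_masks(r)]
    if cfg.dedupe:
        hetero_units = deduplicate_semi_interfaces(records, proteins, seed=cfg.seed)
        homo_units = deduplicate_homo_interfaces(records, proteins, seed=cfg.seed)
    else:
        hetero_units = [
            (r, side)
            for r in records
            if r.kind == "hetero"
            for side in ("a", "b")
        ]
        homo_units = [(r, "a") for r in records if r.kind == "homo"]
    hetero_units = [
        (r, s)
        for r, s in hetero_units
        if (r.side_a if s == "a" else r.side_b).protein_id in masks_by_protein
    ]
    homo_units = [(r, s) for r, s in homo_units if r.side_a.protein_id in masks_by_protein]

    decoy_spec = DecoySpec(n_controls=cfg.n_controls)
    results_rows = []
    pair_cache: dict[str, object] = {}
    group_cache: dict[tuple, object] = {}

    for mode, units in (("hetero", hetero_units), ("homo", homo_units)):
        if not units:
            continue
        for min_cov in cfg.coverage_grid:
            cov_units = []
            for rec, side in units:
                protein = (rec.side_a if side == "a" else rec.side_b).protein_id
                kept = filter_by_coverage(masks_by_protein[protein], min_cov)
                if kept:
                    cov_units.append((rec, side, kept))
            for threshold in cfg.thresholds:
                pairs = []
                for rec, side, kept in cov_units:
                    for mask in kept:
                        key = mask.isoform_id
                        if key not in pair_cache:
                            pair_cache[key] = single_isoform_control_set(
                                mask, cfg.n_controls, rng
                            )
                        pairs.append((rec, mask, pair_cache[key]))
                if pairs:
                    res = single_isoform_test(pairs, threshold, cfg.correction)
                    results_rows.append(
                        _row(mode, "single", threshold, min_cov, res)
                    )
                items = []
                for rec, side, kept in cov_units:
                    protein = (rec.side_a if side == "a" else rec.side_b).protein_id
                    gkey = (protein, min_cov)
                    if gkey not in group_cache:
                        try:
                            group_cache[gkey] = all_isoforms_control_sets(
                                kept, decoy_spec, rng
                            )
                        except DecoyGenerationError as exc:
                            # heavily spliced protein: the cross-group
                            # disjointness constraint can be near-infeasible
                            logger.warning("all-isoforms controls skipped: %s", exc)
                            group_cache[gkey] = None
                    if group_cache[gkey] is not None:
                        items.append((rec, kept, group_cache[gkey]))
                if items:
                    res = all_isoforms_test(items, threshold, cfg.correction)
                    results_rows.append(_row(mode, "all", threshold, min_cov, res))

    if cfg.run_hotspot_test:
        hot_pairs = []
        for rec, side in hetero_units:
            si = rec.side_a if side == "a" else rec.side_b
            if not si.hotspots:
                continue
            for mask in masks_by_protein[si.protein_id]:
                hot_pairs.append((si, mask))
        if hot_pairs:
            res = hotspot_independence_test(hot_pairs, cfg.correction)
            results_rows.append(_row("hetero", "hotspot", None, 0, res))

    results = pd.DataFrame(results_rows)
    results.to_csv(out / "results.tsv", sep="\t", index=False)
    ssio.write_interfaces_tsv(records, out / "interfaces.tsv")

    provenance = {
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "config": asdict(cfg),
        "n_interfaces": len(records),
        "n_proteins_with_masks": len(masks_by_protein),
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=1))

    if cfg.make_plots and not results.empty:
        _plot_results(results, out)
    return {"results": results, "interfaces": records, "provenance": provenance}


def _row(mode, test, threshold, min_cov, res):
    return {
        "mode": mode,
        "test": test,
        "threshold": threshold,
        "coverage_min": min_cov,
        "n_strata": res.n_strata,
        "real_freq": res.real_frequency,
        "control_freq": res.control_frequency,
        "statistic": res.statistic,
        "p_value": res.p_value,
        "correction": res.correction,
    }


def _plot_results(results: pd.DataFrame, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    subset = results[results["test"].isin(["single", "all"])]
    combos = subset[["mode", "test", "coverage_min"]].drop_duplicates()
    n = len(combos)
    if n == 0:
        return
    fig, axes = plt.subplots(n, 1, figsize=(6, 3 * n), squeeze=False)
    for ax, (_, combo) in zip(axes[:, 0], combos.iterrows()):
        rows = subset[
            (subset["mode"] == combo["mode"])
            & (subset["test"] == combo["test"])
            & (subset["coverage_min"] == combo["coverage_min"])
        ].sort_values("threshold")
        ax.plot(rows["threshold"], rows["real_freq"], "r-o", label="real splicing")
        ax.plot(rows["threshold"], rows["control_freq"], "b-s", label="randomized")
        ax2 = ax.twinx()
        ax2.plot(rows["threshold"], rows["p_value"], "g--", label="p-value")
        ax2.axhline(0.05, color="grey", lw=0.5)
        ax2.set_yscale("log")
        ax.set_xlabel("interface-removal threshold (%)")
        ax.set_ylabel("removal frequency")
        ax2.set_ylabel("p-value")
        ax.set_title(
            f"{combo['mode']} / {combo['test']}-isoform test "
            f"(coverage ≥ {combo['coverage_min']}%)"
        )
        ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(out / "removal_frequencies.png", dpi=120)
    plt.close(fig)


def cul4a_case_study(
    pdb_path: str | Path,
    sifts_path: str | Path,
    removed_prefix_len: int = 100,
    target_chain: str = "A",
    partner_chain: str = "B",
) -> tuple[int, int]:
    """Counts for an N-terminal-removal case study.

    Given a two-chain complex in which alternative isoforms of the target
    chain's protein lack its first ``removed_prefix_len`` residues,
    returns ``(semi-interface size, interface residues inside the removed
    prefix)`` for the target chain.
    """
    atoms = parse_structure(pdb_path)
    chains = group_atoms_by_chain(atoms)
    for chain in (target_chain, partner_chain):
        if chain not in chains:
            raise ValueError(f"chain {chain!r} not found in structure")
    maps = ssio.read_sifts_tsv(sifts_path)
    structure_ids = {sid for sid, _ in maps}
    if len(structure_ids) != 1:
        raise ValueError("mapping file must describe exactly one structure")
    sid = structure_ids.pop()
    map_a = maps[(sid, target_chain)]
    map_b = maps[(sid, partner_chain)]
    contacts = find_contact_residues(chains[target_chain], chains[partner_chain])
    rec = extract_interface(contacts, map_a, map_b, structure_id=sid)
    positions = rec.side_a.positions
    in_prefix = {p for p in positions if p <= removed_prefix_len}
    return len(positions), len(in_prefix)
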