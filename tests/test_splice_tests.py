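import numpy as np
import pytest

from spliceshield.cmh import Stratified2x2, cmh_test
from spliceshield.decoys import ControlSet, single_isoform_control_set
from spliceshield.masks import IsoformMask
from spliceshield.splice_tests import (
    all_isoforms_test,
    filter_by_coverage,
    hotspot_independence_test,
    is_removed,
    missing_fraction,
    single_isoform_test,
)
from spliceshield.structures import InterfaceRecord, SemiInterface


def _mask(length, ones, protein="P1", iso="i1"):
    bits = np.zeros(length, dtype=np.uint8)
    for p in ones:
        bits[p - 1] = 1
    return IsoformMask(protein, iso, bits)


def _hetero(pos_a, protein_a="P1", protein_b="P2"):
    return InterfaceRecord(
        kind="hetero",
        side_a=SemiInterface(protein_a, frozenset(pos_a)),
        side_b=SemiInterface(protein_b, frozenset({1, 2, 3, 4, 5})),
        structure_id="S1",
    )


def _homo(pos_a, pos_b, protein="P1"):
    return InterfaceRecord(
        kind="homo",
        side_a=SemiInterface(protein, frozenset(pos_a)),
        side_b=SemiInterface(protein, frozenset(pos_b)),
        structure_id="S1",
    )


class TestMissingFraction:
    def test_half_missing(self):
        mask = _mask(50, [20, 30])
        assert missing_fraction(mask, {10, 20, 30, 40}) == 0.5

    def test_all_zero_mask(self):
        assert missing_fraction(_mask(50, []), {1, 2, 3}) == 0.0

    def test_all_inside_missing_stretch(self):
        mask = _mask(50, range(10, 20))
        assert missing_fraction(mask, {11, 12, 13}) == 1.0

    def test_empty_positions_error(self):
        with pytest.raises(ValueError):
            missing_fraction(_mask(10, []), set())


class TestIsRemoved:
    def test_threshold_is_inclusive(self):
        rec = _hetero(range(1, 11))
        call = is_removed(rec, _mask(50, [1, 2, 3]), threshold=30)
        assert call.missing_fraction == pytest.approx(0.3)
        assert call.removed

    def test_homo_uses_worse_side(self):
        rec = _homo(range(1, 11), range(20, 31))  # sides of 10 and 11
        mask = _mask(60, [20, 21, 22, 23, 24, 1], protein="P1")
        call = is_removed(rec, mask, threshold=40)
        assert call.removed  # side_b loses 5/11 ≈ 45%

    def test_total_threshold_needs_everything(self):
        rec = _hetero(range(1, 101))
        mask = _mask(200, range(1, 100))  # 99 of 100
        assert not is_removed(rec, mask, threshold=100).removed

    def test_protein_mismatch_errors(self):
        rec = _hetero(range(1, 6))
        with pytest.raises(ValueError):
            is_removed(rec, _mask(10, [1], protein="P9"), 30)

    def test_monotone_in_threshold(self, rng):
        rec = _hetero(range(1, 21))
        for _ in range(50):
            mask = _mask(60, rng.choice(60, rng.integers(1, 30), replace=False) + 1)
            prev = True
            for t in range(10, 101, 10):
                removed = is_removed(rec, mask, t).removed
                assert prev or not removed  # once not removed, stays not removed
                prev = removed


def _control_set_removing(k, n, interface, length=50):
    """ControlSet in which exactly k of n decoys remove ``interface`` fully."""
    pos = sorted(interface)
    span = pos[-1] - pos[0] + 1
    sizes = np.full((n, 1), span, dtype=np.int64)
    starts = np.empty(n, dtype=np.int64)
    starts[:k] = pos[0]
    # the rest sit entirely off the interface
    off = 1 if pos[0] > span else pos[-1] + 1
    starts[k:] = off
    return ControlSet("P1", "i1", length, sizes, starts)


class TestSingleIsoformTest:
    def test_reduces_to_worked_stratum(self):
        interface = set(range(20, 30))
        rec = _hetero(interface)
        mask = _mask(50, interface)  # real isoform removes everything
        controls = _control_set_removing(225, 1000, interface)
        res = single_isoform_test([(rec, mask, controls)], 30, correction=False)
        assert res.statistic == pytest.approx(3.429, abs=0.001)
        assert res.real_frequency == 1.0
        assert res.control_frequency == pytest.approx(0.225)

    def test_frequencies_non_increasing_in_threshold(self, rng):
        pairs = []
        for i in range(12):
            interface = set(rng.choice(80, 10, replace=False) + 1)
            rec = _hetero(interface)
            n_miss = int(rng.integers(1, 30))
            mask = _mask(100, rng.choice(100, n_miss, replace=False) + 1)
            controls = single_isoform_control_set(mask, 100, rng)
            pairs.append((rec, mask, controls))
        prev_real, prev_ctrl = 1.1, 1.1
        for t in range(10, 101, 10):
            res = single_isoform_test(pairs, t)
            if res.n_strata == 0:
                break
            real = res.tables_real_total if hasattr(res, "tables_real_total") else None
            # pooled frequencies are over informative strata only; compute the
            # raw (unfiltered) frequencies directly for the monotonicity check
            n_rem_real = sum(
                is_removed(r, m, t).removed for r, m, _ in pairs
            ) / len(pairs)
            n_rem_ctrl = np.mean(
                [
                    (c.missing_fractions(sorted(r.side_a.positions)) >= t / 100).mean()
                    for r, m, c in pairs
                ]
            )
            assert n_rem_real <= prev_real + 1e-12
            assert n_rem_ctrl <= prev_ctrl + 1e-12
            prev_real, prev_ctrl = n_rem_real, n_rem_ctrl

    def test_zero_controls_rejected(self):
        rec = _hetero({1, 2, 3, 4, 5})
        mask = _mask(50, [1])
        bad = ControlSet("P1", "i1", 50, np.empty((0, 1), dtype=int), np.empty(0, dtype=int))
        with pytest.raises(ValueError):
            single_isoform_test([(rec, mask, bad)], 30)


class TestAllIsoformsTest:
    def test_one_removing_isoform_counts_as_removed(self, rng):
        from spliceshield.decoys import DecoySpec, all_isoforms_control_sets

        interface = set(range(30, 40))
        rec = _hetero(interface)
        masks = [_mask(100, range(30, 41), iso="hit")] + [
            _mask(100, [60 + i], iso=f"m{i}") for i in range(4)
        ]
        controls = all_isoforms_control_sets(masks, DecoySpec(100), rng)
        res = all_isoforms_test([(rec, masks, controls)], 50)
        # the real group removed the interface: real_frequency must be 1
        assert res.real_frequency == 1.0

    def test_never_removing_controls_give_max_discordance(self):
        interface = set(range(20, 30))
        rec = _hetero(interface)
        masks = [_mask(50, interface, iso="hit")]
        # one control group (single isoform) placed off the interface
        from spliceshield.decoys import AllIsoformsControls, GroupControl, build_overlap_groups

        groups = build_overlap_groups(masks)
        controls = AllIsoformsControls(
            protein_id="P1",
            length=50,
            groups=groups,
            controls=[GroupControl(starts=[1], sizes=[np.array([10])]) for _ in range(1000)],
            isoform_ids=["hit"],
        )
        res = all_isoforms_test([(rec, masks, controls)], 30, correction=False)
        assert res.control_frequency == 0.0
        assert res.real_frequency == 1.0


class TestHotspotIndependence:
    def test_proportional_removal_gives_zero_statistic(self):
        pairs = []
        for i in range(5):
            si = SemiInterface(
                "P1", frozenset(range(1, 21)), hotspots=frozenset(range(1, 6))
            )
            # remove 40% of hot spots (2/5) and 40% of the rest (6/15)
            mask = _mask(40, [1, 2, 6, 7, 8, 9, 10, 11], iso=f"i{i}")
            pairs.append((si, mask))
        res = hotspot_independence_test(pairs, correction=False)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_sparing_hotspots_detected_with_direction(self):
        pairs = []
        for i in range(40):
            si = SemiInterface(
                "P1", frozenset(range(1, 21)), hotspots=frozenset(range(1, 6))
            )
            # hot spots never removed, half the others removed
            mask = _mask(40, range(6, 16), iso=f"i{i}")
            pairs.append((si, mask))
        res = hotspot_independence_test(pairs)
        assert res.p_value < 1e-6
        assert res.real_frequency < res.control_frequency  # hot spots spared

    def test_pair_without_removed_residues_is_skipped(self):
        si = SemiInterface("P1", frozenset(range(1, 21)), hotspots=frozenset({1}))
        res = hotspot_independence_test([(si, _mask(40, [], iso="i"))])
        assert res.n_strata == 0 and res.n_skipped == 1

    def test_requires_hotspots(self):
        si = SemiInterface("P1", frozenset(range(1, 21)))
        with pytest.raises(ValueError):
            hotspot_independence_test([(si, _mask(40, [1]))])


class TestCoverageFilter:
    def test_zero_threshold_keeps_all(self):
        masks = [_mask(10, [1]), _mask(10, range(1, 10))]
        assert filter_by_coverage(masks, 0) == masks

    def test_low_coverage_dropped(self):
        mask = _mask(100, range(1, 56))  # 45% coverage
        assert filter_by_coverage([mask], 50) == []

    def test_full_threshold_allows_empty_result(self):
        masks = [_mask(10, [1])]
        assert filter_by_coverage(masks, 100) == []
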