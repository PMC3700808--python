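import numpy as np
import pytest

from helpers import overlap_groups_bruteforce, single_stretch_decoy_marginal
from spliceshield.decoys import (
    DecoySpec,
    all_isoforms_control_sets,
    build_overlap_groups,
    make_all_isoforms_control,
    make_single_isoform_decoy,
    pulse_sizes,
    single_isoform_control_set,
)
from spliceshield.masks import IsoformMask, decompose_mask


def _mask(length, stretches, protein="P", iso="i"):
    bits = np.zeros(length, dtype=np.uint8)
    for start, slen in stretches:
        bits[start - 1 : start - 1 + slen] = 1
    return IsoformMask(protein, iso, bits)


class TestPulseSizes:
    def test_poisson_moments(self):
        rng = np.random.default_rng(5)
        draws = pulse_sizes(np.full(100_000, 10), rng)
        assert draws.mean() == pytest.approx(10.0, abs=0.03)
        assert draws.var() == pytest.approx(10.0, rel=0.05)

    def test_unit_size_vanishes_at_poisson_rate(self):
        rng = np.random.default_rng(6)
        draws = pulse_sizes(np.ones(100_000, dtype=int), rng)
        assert (draws == 0).mean() == pytest.approx(np.exp(-1), abs=0.005)

    def test_seeded_reproducibility(self):
        a = pulse_sizes([4, 7, 9], np.random.default_rng(42))
        b = pulse_sizes([4, 7, 9], np.random.default_rng(42))
        assert (a == b).all()

    def test_rejects_non_positive(self):
        with pytest.raises(ValueError):
            pulse_sizes([0, 3], np.random.default_rng(0))


class TestSingleIsoformDecoys:
    def test_requires_a_missing_stretch(self):
        with pytest.raises(ValueError):
            make_single_isoform_decoy(_mask(50, []), np.random.default_rng(0))

    def test_single_stretch_decoy_shape(self):
        mask = _mask(200, [(41, 20)])
        rng = np.random.default_rng(0)
        lengths = []
        for _ in range(300):
            decoy = make_single_isoform_decoy(mask, rng)
            d = decompose_mask(decoy)
            assert len(decoy) == 200
            assert len(d.missing) <= 1
            if d.missing:
                lengths.append(d.missing[0][1])
        assert np.mean(lengths) == pytest.approx(20.0, abs=1.0)

    def test_stretch_order_preserved(self):
        mask = _mask(120, [(20, 8), (50, 10)])
        rng = np.random.default_rng(3)
        for _ in range(200):
            decoy = make_single_isoform_decoy(mask, rng)
            d = decompose_mask(decoy)
            # at most the original two missing stretches, in order, with a
            # single non-missing gap (zero-length collapses allowed)
            assert len(d.missing) <= 2
            starts = [s for s, _ in d.missing]
            assert starts == sorted(starts)

    def test_bits_outside_variable_region_zero_and_length_fixed(self):
        mask = _mask(90, [(10, 5), (40, 6)])
        rng = np.random.default_rng(9)
        controls = single_isoform_control_set(mask, 500, rng)
        for decoy in controls.to_masks():
            d = decompose_mask(decoy)
            assert len(decoy) == 90
            if d.variable_region:
                lo, hi = d.variable_region
                assert decoy.bits[: lo - 1].sum() == 0
                assert decoy.bits[hi:].sum() == 0

    def test_mean_total_missing_preserved(self):
        mask = _mask(300, [(30, 12), (80, 7), (200, 20)])
        rng = np.random.default_rng(2)
        controls = single_isoform_control_set(mask, 20_000, rng)
        assert controls.total_missing_sizes().mean() == pytest.approx(39.0, rel=0.02)

    def test_per_position_marginal_matches_enumeration_oracle(self):
        mask = _mask(200, [(41, 20)])
        rng = np.random.default_rng(7)
        controls = single_isoform_control_set(mask, 10_000, rng)
        empirical = np.zeros(200)
        for decoy in controls.to_masks():
            empirical += decoy.bits
        empirical /= controls.n_controls
        exact = single_stretch_decoy_marginal(200, 20)
        assert np.abs(empirical - exact).max() < 0.01

    def test_missing_counts_agrees_with_materialized_masks(self, rng):
        mask = _mask(150, [(20, 9), (60, 4), (100, 15)])
        controls = single_isoform_control_set(mask, 200, rng)
        positions = sorted(rng.choice(150, size=12, replace=False) + 1)
        counts = controls.missing_counts(positions)
        pos_idx = np.array(positions) - 1
        direct = [int(d.bits[pos_idx].sum()) for d in controls.to_masks()]
        assert (counts == np.array(direct)).all()

    def test_same_seed_gives_identical_serialized_controls(self):
        mask = _mask(80, [(10, 6), (30, 4)])
        runs = []
        for _ in range(2):
            controls = single_isoform_control_set(
                mask, 50, np.random.default_rng(123)
            )
            runs.append("|".join(d.to_runs() for d in controls.to_masks()))
        assert runs[0] == runs[1]


class TestOverlapGroups:
    def test_two_groups_from_worked_example(self):
        a = _mask(60, [(10, 11)], iso="A")  # 10-20
        b = _mask(60, [(15, 11)], iso="B")  # 15-25
        c = _mask(60, [(40, 11)], iso="C")  # 40-50
        groups = build_overlap_groups([a, b, c])
        assert len(groups) == 2
        ab = next(g for g in groups if set(g.member_ids) == {"A", "B"})
        assert ab.region == (10, 25)
        # junction boundaries 10,15,21,26 delimit segments [10-14],[15-20],[21-25]
        assert ab.segment_starts == [10, 15, 21]
        assert ab.segment_lengths == [5, 6, 5]

        col_a = ab.member_ids.index("A")
        col_b = ab.member_ids.index("B")
        assert ab.status[:, col_a].tolist() == [1, 1, 0]
        assert ab.status[:, col_b].tolist() == [0, 1, 1]

    def test_singleton_group_segments_are_own_stretches(self):
        m = _mask(50, [(10, 5), (20, 5)])
        (group,) = build_overlap_groups([m])
        assert group.segment_lengths == [5, 5, 5]  # M, N, M
        assert group.status[:, 0].tolist() == [1, 0, 1]

    def test_matches_bruteforce_transitive_closure(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 8))
            masks, intervals = [], []
            for i in range(n):
                k = int(rng.integers(1, 4))
                stretches = []
                for _ in range(k):
                    start = int(rng.integers(1, 90))
                    slen = int(rng.integers(1, 12))
                    stretches.append((start, min(slen, 100 - start + 1)))
                masks.append(_mask(100, stretches, iso=f"i{i}"))
                intervals.append(
                    [(s, s + l - 1) for s, l in decompose_mask(masks[-1]).missing]
                )
            groups = build_overlap_groups(masks)
            got = {frozenset(g.member_ids) for g in groups}
            expected = {
                frozenset(f"i{j}" for j in comp)
                for comp in overlap_groups_bruteforce(intervals)
            }
            assert got == expected


class TestAllIsoformsControls:
    def test_single_isoform_marginally_matches_single_decoy_law(self):
        mask = _mask(120, [(30, 10), (60, 8)])
        n = 8000
        single = single_isoform_control_set(mask, n, np.random.default_rng(11))
        emp_single = np.zeros(120)
        for d in single.to_masks():
            emp_single += d.bits
        emp_single /= n

        sets = all_isoforms_control_sets(
            [mask], DecoySpec(n_controls=n), np.random.default_rng(12)
        )
        emp_all = np.zeros(120)
        for i in range(n):
            emp_all += sets.control_masks(i)[0].bits
        emp_all /= n
        assert np.abs(emp_single - emp_all).max() < 0.025

    def test_accepted_controls_satisfy_90pct_bound(self):
        masks = [
            _mask(200, [(20, 15)], iso="a"),
            _mask(200, [(25, 10)], iso="b"),
            _mask(200, [(120, 18)], iso="c"),
        ]
        sets = all_isoforms_control_sets(
            masks, DecoySpec(n_controls=300), np.random.default_rng(4)
        )
        groups = sets.groups
        assert len(groups) == 2
        real_total = sum(g.real_missing_total() for g in groups)
        for ctrl in sets.controls:
            pulsed = sum(
                int(sizes[g.missing_segment_idx].sum())
                for g, sizes in zip(groups, ctrl.sizes)
            )
            assert pulsed >= 0.9 * real_total

    def test_cross_group_missing_segments_never_collide(self):
        masks = [
            _mask(150, [(10, 12)], iso="a"),
            _mask(150, [(100, 14)], iso="b"),
        ]
        sets = all_isoforms_control_sets(
            masks, DecoySpec(n_controls=400), np.random.default_rng(8)
        )
        for i in range(400):
            decoys = sets.control_masks(i)
            overlap = decoys[0].bits & decoys[1].bits
            assert overlap.sum() == 0

    def test_disjoint_far_groups_rarely_collide(self):
        # with two tiny stretches far apart on a long protein the geometric
        # constraint (a) almost never binds; rejections come only from the
        # 90% total-size rule, so generation succeeds within a few attempts
        masks = [
            _mask(2000, [(100, 5)], iso="a"),
            _mask(2000, [(1500, 5)], iso="b"),
        ]
        rng = np.random.default_rng(1)
        sets = all_isoforms_control_sets(masks, DecoySpec(n_controls=200), rng)
        assert len(sets.controls) == 200
        collisions = 0
        for i in range(200):
            d = sets.control_masks(i)
            collisions += int((d[0].bits & d[1].bits).sum() > 0)
        assert collisions == 0  # enforced by construction, and geometrically rare

    def test_one_control_per_isoform(self):
        masks = [_mask(90, [(10, 5)], iso="a"), _mask(90, [(12, 6)], iso="b")]
        decoys = make_all_isoforms_control(masks, rng=np.random.default_rng(2))
        assert [d.isoform_id.split("|")[0] for d in decoys] == ["a", "b"]
        assert all(len(d) == 90 for d in decoys)
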