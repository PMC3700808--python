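import numpy as np
import pytest

from helpers import complete_linkage_oracle
from spliceshield.redundancy import (
    cluster_interfaces,
    cluster_proteins,
    deduplicate_semi_interfaces,
    elect_representative,
    interface_overlap_homo,
    semi_interface_overlap,
    _identity_and_coverage,
)
from spliceshield.structures import InterfaceRecord, SemiInterface

AA = list("ACDEFGHIKLMNPQRSTVWY")


def _random_seq(rng, n):
    return "".join(rng.choice(AA, size=n))


def _mutate(rng, seq, identity):
    out = list(seq)
    n_mut = int(round(len(seq) * (1 - identity)))
    idx = rng.choice(len(seq), size=n_mut, replace=False)
    for i in idx:
        choices = [a for a in AA if a != out[i]]
        out[i] = choices[int(rng.integers(len(choices)))]
    return "".join(out)


class TestClusterProteins:
    def test_identical_sequences_single_cluster(self, rng):
        s = _random_seq(rng, 60)
        clusters = cluster_proteins({"p1": s, "p2": s})
        assert len(clusters) == 1
        assert clusters[0].members == ["p1", "p2"]

    def test_unrelated_sequences_stay_apart(self, rng):
        clusters = cluster_proteins({"p1": _random_seq(rng, 60), "p2": _random_seq(rng, 60)})
        assert len(clusters) == 2

    def test_single_linkage_transitive_closure(self, rng):
        # B close to both A and C; A and C distant: one cluster of three
        b = _random_seq(rng, 100)
        a = _mutate(rng, b, 0.55)
        c = _mutate(rng, b, 0.55)
        ia, _, _ = _identity_and_coverage(a, c)
        clusters = cluster_proteins({"A": a, "B": b, "C": c}, min_identity=0.5)
        if ia < 0.5:  # A-C below the threshold: linkage must still join them
            assert len(clusters) == 1
            assert clusters[0].members == ["A", "B", "C"]

    def test_transitive_closure_matches_oracle(self, rng):
        base = _random_seq(rng, 50)
        seqs = {f"p{i}": _mutate(rng, base, float(rng.uniform(0.2, 1.0))) for i in range(6)}
        clusters = cluster_proteins(seqs, min_identity=0.6)
        # independent union-find over the same pairwise joins
        ids = sorted(seqs)
        parent = {i: i for i in ids}

        def find(i):
            while parent[i] != i:
                i = parent[i]
            return i

        for i in ids:
            for j in ids:
                if i < j:
                    ident, ca, cb = _identity_and_coverage(seqs[i], seqs[j])
                    if ident >= 0.6 and ca >= 0.9 and cb >= 0.9:
                        parent[find(i)] = find(j)
        expected = {}
        for i in ids:
            expected.setdefault(find(i), set()).add(i)
        assert {frozenset(c.members) for c in clusters} == {
            frozenset(v) for v in expected.values()
        }

    def test_msa_maps_every_position_once(self, rng):
        s = _random_seq(rng, 40)
        seqs = {"A": s, "B": _mutate(rng, s, 0.8), "C": _mutate(rng, s, 0.75)}
        (cluster,) = cluster_proteins(seqs, min_identity=0.5)
        for member, seq in seqs.items():
            cmap = cluster.msa[member]
            assert set(cmap) == set(range(1, len(seq) + 1))
            assert len(set(cmap.values())) == len(seq)  # injective into columns
        # identical positions of identical prefixes share columns through the center
        assert len({cluster.msa[m][1] for m in "ABC"}) <= 3


class TestOverlapValues:
    def test_worked_example(self):
        assert semi_interface_overlap({1, 2, 3, 4}, {3, 4, 5, 6, 7, 8}) == 0.5

    def test_identical_sets(self):
        assert semi_interface_overlap({1, 2}, {1, 2}) == 1.0

    def test_disjoint_sets(self):
        assert semi_interface_overlap({1}, {2}) == 0.0

    def test_empty_set_errors(self):
        with pytest.raises(ValueError):
            semi_interface_overlap(set(), {1})

    def test_symmetry_and_bounds(self, rng):
        for _ in range(100):
            x = set(rng.choice(30, rng.integers(1, 12), replace=False))
            y = set(rng.choice(30, rng.integers(1, 12), replace=False))
            o1, o2 = semi_interface_overlap(x, y), semi_interface_overlap(y, x)
            assert o1 == o2 and 0 <= o1 <= 1
        assert semi_interface_overlap(x, x) == 1.0

    def test_homo_crossed_pairing_wins(self):
        o = interface_overlap_homo(({1, 2}, {10, 11}), ({10, 11}, {1, 2}))
        assert o == 1.0

    def test_homo_identical(self):
        o = interface_overlap_homo(({1, 2}, {5, 6}), ({1, 2}, {5, 6}))
        assert o == 1.0

    def test_homo_matches_two_pairing_oracle(self, rng):
        for _ in range(100):
            sets = [
                set(rng.choice(20, rng.integers(1, 8), replace=False)) for _ in range(4)
            ]
            a1, a2, b1, b2 = sets
            got = interface_overlap_homo((a1, a2), (b1, b2))
            num = max(
                len(a1 & b1) + len(a2 & b2), len(a1 & b2) + len(a2 & b1)
            )
            den = min(len(a1) + len(a2), len(b1) + len(b2))
            assert got == pytest.approx(num / den)


class TestClusterInterfaces:
    def test_full_overlap_single_cluster(self):
        o = np.ones((4, 4))
        labels = cluster_interfaces(o)
        assert len(set(labels)) == 1

    def test_zero_overlap_all_singletons(self):
        o = np.eye(5)
        labels = cluster_interfaces(o)
        assert len(set(labels)) == 5

    def test_matches_exhaustive_complete_linkage(self, rng):
        for _ in range(100):
            n = 4
            o = np.eye(n)
            for i in range(n):
                for j in range(i + 1, n):
                    o[i, j] = o[j, i] = rng.random()
            labels = cluster_interfaces(o)
            got = {frozenset(np.flatnonzero(labels == l)) for l in set(labels)}
            expected = {
                frozenset(c) for c in complete_linkage_oracle(1 - o, cut=0.5)
            }
            assert got == expected

    def test_within_cluster_overlap_at_least_half(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 10))
            o = np.eye(n)
            for i in range(n):
                for j in range(i + 1, n):
                    o[i, j] = o[j, i] = rng.random()
            labels = cluster_interfaces(o)
            for label in set(labels):
                members = np.flatnonzero(labels == label)
                for i in members:
                    for j in members:
                        assert o[i, j] >= 0.5 - 1e-12 or i == j


def _rec(cov_a, resolution, n_pos, protein="P1"):
    return InterfaceRecord(
        kind="hetero",
        side_a=SemiInterface(protein, frozenset(range(1, n_pos + 1))),
        side_b=SemiInterface("PX", frozenset({1, 2, 3, 4, 5})),
        structure_id=f"S{cov_a}{resolution}{n_pos}",
        resolution=resolution,
        coverage_a=cov_a,
        coverage_b=0.5,
    )


class TestElectRepresentative:
    def test_coverage_wins(self):
        a, b = _rec(0.9, 2.0, 10), _rec(0.8, 1.0, 20)
        assert elect_representative([a, b]) is a

    def test_resolution_breaks_coverage_tie(self):
        a, b = _rec(0.9, 2.5, 10), _rec(0.9, 1.8, 10)
        assert elect_representative([a, b]) is b

    def test_size_breaks_remaining_tie(self):
        a, b = _rec(0.9, 2.0, 12), _rec(0.9, 2.0, 9)
        assert elect_representative([a, b]) is a

    def test_missing_resolution_sorts_worst(self):
        a, b = _rec(0.9, None, 10), _rec(0.9, 3.5, 10)
        assert elect_representative([a, b]) is b

    def test_random_tie_is_seeded(self):
        a, b = _rec(0.9, 2.0, 10), _rec(0.9, 2.0, 10)
        picks = {
            elect_representative([a, b], rng=np.random.default_rng(7)).structure_id
            for _ in range(5)
        }
        assert len(picks) == 1


class TestDeduplication:
    def test_duplicate_interfaces_collapse(self, rng):
        seq = _random_seq(rng, 60)
        seqs = {"P1": seq, "P2": seq, "PX": _random_seq(rng, 40)}
        recs = []
        for protein, cov in (("P1", 0.9), ("P2", 0.7)):
            recs.append(
                InterfaceRecord(
                    kind="hetero",
                    side_a=SemiInterface(protein, frozenset(range(10, 20))),
                    side_b=SemiInterface("PX", frozenset(range(1, 6))),
                    structure_id=protein,
                    coverage_a=cov,
                    coverage_b=0.6,
                )
            )
        reps = deduplicate_semi_interfaces(recs, seqs)
        # P1/P2 identical proteins with identical interfaces merge; the PX
        # partner side of each record remains its own unit
        a_side_reps = [r for r, s in reps if s == "a"]
        assert len(a_side_reps) == 1
        assert a_side_reps[0].structure_id == "P1"  # higher coverage wins
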