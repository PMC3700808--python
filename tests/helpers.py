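"""Independent oracles used across the test suite.

Everything here is deliberately written from first principles (loops,
exhaustive enumeration, closed forms) and stays independent of the code
paths it validates.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import poisson


def cmh_oracle(tables, correction: bool) -> float:
    """Textbook Mantel-Haenszel chi-square, coded independently.

    ``tables`` is an iterable of (a, b, c, d).  Strata with a zero margin
    are skipped.  Returns nan when no variance accumulates.
    """
    num = 0.0
    var = 0.0
    for a, b, c, d in tables:
        n = a + b + c + d
        if min(a + b, c + d, a + c, b + d) <= 0 or n <= 1:
            continue
        expected = (a + b) * (a + c) / n
        num += a - expected
        var += (a + b) * (c + d) * (a + c) * (b + d) / (n * n * (n - 1))
    if var <= 0:
        return float("nan")
    dev = abs(num)
    if correction:
        dev -= 0.5
    return dev * dev / var


def nw_score_oracle(
    seq_a: str,
    seq_b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -5.0,
    gap_extend: float = -1.0,
) -> float:
    """Affine-gap global alignment score by explicit three-state DP.

    ``gap_open`` is the cost of the first residue of a gap, ``gap_extend``
    of each further residue (the PairwiseAligner convention).
    """
    n, m = len(seq_a), len(seq_b)
    neg = -math.inf
    # M: a[i] aligned to b[j]; X: gap in b (a consumed); Y: gap in a
    M = [[neg] * (m + 1) for _ in range(n + 1)]
    X = [[neg] * (m + 1) for _ in range(n + 1)]
    Y = [[neg] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0][j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if seq_a[i - 1] == seq_b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_extend,
                          Y[i - 1][j] + gap_open)
            Y[i][j] = max(M[i][j - 1] + gap_open, Y[i][j - 1] + gap_extend,
                          X[i][j - 1] + gap_open)
    return max(M[n][m], X[n][m], Y[n][m])


def contact_pairs_bruteforce(atoms_a, atoms_b, radii, margin):
    """All-pairs O(n²) contact scan."""
    pairs = set()
    for a in atoms_a:
        for b in atoms_b:
            d = math.dist(a.coords, b.coords)
            if d <= radii[a.element] + radii[b.element] + margin:
                pairs.add((a.residue_key, b.residue_key))
    return pairs


def complete_linkage_oracle(dist: np.ndarray, cut: float) -> list[set[int]]:
    """Naive agglomerative complete linkage, merging while min diameter ≤ cut."""
    clusters = [{i} for i in range(dist.shape[0])]
    while len(clusters) > 1:
        best = None
        best_d = math.inf
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = max(dist[a, b] for a in clusters[i] for b in clusters[j])
                if d < best_d:
                    best_d, best = d, (i, j)
        if best_d > cut:
            break
        i, j = best
        clusters[i] |= clusters[j]
        del clusters[j]
    return clusters


def overlap_groups_bruteforce(intervals_per_isoform):
    """Transitive closure of missing-stretch overlap; returns index sets."""
    n = len(intervals_per_isoform)
    adj = [[False] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            for s1, e1 in intervals_per_isoform[i]:
                for s2, e2 in intervals_per_isoform[j]:
                    if s1 <= e2 and s2 <= e1:
                        adj[i][j] = True
    groups = []
    seen = set()
    for i in range(n):
        if i in seen:
            continue
        stack, comp = [i], set()
        while stack:
            k = stack.pop()
            if k in comp:
                continue
            comp.add(k)
            stack.extend(j for j in range(n) if adj[k][j] and j not in comp)
        seen |= comp
        groups.append(comp)
    return groups


def single_stretch_decoy_marginal(length: int, lam: int, max_size: int = 60) -> np.ndarray:
    """Exact per-position probability that a pulsed single-stretch decoy
    marks the position missing.

    The decoy redraws the stretch size m ~ Poisson(lam) conditioned on
    1 ≤ m ≤ length (zero or overflow is redrawn) and places the stretch
    start uniformly over the length − m + 1 admissible positions.
    """
    sizes = np.arange(1, min(max_size, length) + 1)
    pmf = poisson.pmf(sizes, lam)
    pmf = pmf / pmf.sum()  # conditional on acceptance (truncation above max_size
    # is negligible for the λ used in tests)
    prob = np.zeros(length)
    for m, p in zip(sizes, pmf):
        n_starts = length - m + 1
        for start in range(1, n_starts + 1):
            prob[start - 1 : start - 1 + m] += p / n_starts
    return prob
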