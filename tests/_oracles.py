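"""Independent brute-force oracles used by the test suite.

Deliberately written in a different style from the library (pure-python
set agglomeration, exact rational arithmetic) so agreement is meaningful.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb


def naive_complete_linkage(D):
    """O(n^3) set-based complete-linkage agglomeration.

    Returns merges as ``(left_node, right_node, height)`` with leaves
    numbered 0..n-1 and merge t creating node n+t; ties broken toward the
    pair whose smallest member indices sort first; the child with the
    smaller representative is written first.
    """
    n = len(D)
    clusters = {i: frozenset([i]) for i in range(n)}  # node id -> members
    merges = []
    next_id = n
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            d = max(D[i][j] for i in clusters[a] for j in clusters[b])
            rep = tuple(sorted((min(clusters[a]), min(clusters[b]))))
            key = (d, rep)
            if best is None or key < best[0]:
                best = (key, a, b)
        (d, _), a, b = best
        if min(clusters[b]) < min(clusters[a]):
            a, b = b, a
        merges.append((a, b, d))
        clusters[next_id] = clusters.pop(a) | clusters.pop(b)
        next_id += 1
    return merges


def naive_cut(merges, n, k):
    """Partition (frozenset of frozensets of leaf indices) after a k-cut."""
    members = {i: frozenset([i]) for i in range(n)}
    for t, (a, b, _) in enumerate(merges[: n - k]):
        members[n + t] = members.pop(a) | members.pop(b)
    return frozenset(members.values())


def naive_siblings(merges, n, i, j):
    """True iff leaves i and j merge as singletons."""
    return any(
        {a, b} == {i, j} for a, b, _ in merges if a < n and b < n
    )


def fisher_two_sided_exact(a, b, c, d):
    """Two-sided Fisher p by exact integer hypergeometric enumeration."""
    r1, r2 = a + b, c + d
    c1 = a + c
    obs = comb(r1, a) * comb(r2, c)
    total = comb(r1 + r2, c1)
    acc = Fraction(0)
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        w = comb(r1, k) * comb(r2, c1 - k)
        if w <= obs:
            acc += Fraction(w, total)
    return float(acc)


def trend_statistic(outcomes, group_sizes, scores):
    """Linear trend score sum(w_g * x_g) for a flat outcome vector."""
    t = 0.0
    pos = 0
    for w, size in zip(scores, group_sizes):
        t += w * sum(outcomes[pos: pos + size])
        pos += size
    return t
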