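"""Independent brute-force oracles kept deliberately naive.

Every function here recomputes a quantity by enumeration or by the
textbook definition, sharing no code with the implementation it checks.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np


def hypergeom_upper_tail_enumerate(k: int, K: int, n: int, N: int) -> float:
    """P[|draw ∩ marked| >= k] by enumerating every n-subset of N items."""
    marked = set(range(K))
    hits = total = 0
    for draw in combinations(range(N), n):
        total += 1
        if len(marked.intersection(draw)) >= k:
            hits += 1
    return hits / total


def hypergeom_upper_tail_comb(k: int, K: int, n: int, N: int) -> float:
    """P[X >= k] from the exact combinatorial mass function."""
    denom = comb(N, n)
    return sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(K, n) + 1)) / denom


def bh_stepup(pvalues) -> np.ndarray:
    """Textbook BH step-up: adj_(i) = min_{j>=i} m p_(j)/j, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj_sorted = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        running = min(running, m * p[order[rank - 1]] / rank)
        adj_sorted[rank - 1] = running
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def transitive_ancestors(parents: dict[str, set[str]], term: str) -> set[str]:
    """Ancestor closure by repeated expansion until a fixed point."""
    out: set[str] = set()
    frontier = set(parents.get(term, set()))
    while frontier:
        nxt = frontier.pop()
        if nxt not in out:
            out.add(nxt)
            frontier |= set(parents.get(nxt, set()))
    return out


def complete_linkage_bruteforce(d: np.ndarray, cut: float) -> list[tuple[int, ...]]:
    """Agglomerate by rescanning the ORIGINAL matrix at every step.

    The inter-cluster distance is recomputed from scratch as the maximum
    original pairwise dissimilarity (no Lance-Williams update); merging
    stops once the smallest inter-cluster distance exceeds the cut.
    Ties merge the pair with the lexicographically smallest combined
    index tuple, matching the implementation's documented rule.
    """
    clusters: list[tuple[int, ...]] = [(i,) for i in range(len(d))]
    while len(clusters) > 1:
        best = None
        for a, b in combinations(range(len(clusters)), 2):
            dist = max(d[i, j] for i in clusters[a] for j in clusters[b])
            key = (dist, tuple(sorted(clusters[a] + clusters[b])))
            if best is None or key < best[0]:
                best = (key, a, b)
        (dist, _), a, b = best
        if dist > cut:
            break
        merged = tuple(sorted(clusters[a] + clusters[b]))
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)]
        clusters.append(merged)
    return sorted(clusters)
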