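"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the code paths (and libraries) they check:
edit distance is a full dynamic-programming table, convergence frequency
is an exhaustive pair scan, clustering is a hand-rolled union-find, and
graph diameters come from dense all-pairs shortest paths.
"""

from __future__ import annotations

import numpy as np


def dp_levenshtein(a: str, b: str) -> int:
    """Full O(|a||b|) dynamic-programming edit distance."""
    n, m = len(a), len(b)
    prev = list(range(m + 1))
    for i in range(1, n + 1):
        cur = [i] + [0] * m
        for j in range(1, m + 1):
            cur[j] = min(
                prev[j] + 1,
                cur[j - 1] + 1,
                prev[j - 1] + (a[i - 1] != b[j - 1]),
            )
        prev = cur
    return prev[m]


def brute_force_tcf(clones: list[tuple[str, str, float]]) -> float:
    """Exhaustive-pair convergence frequency.

    ``clones`` is a list of (nt, aa, frequency). A clone is convergent if
    any *other* clone has an identical amino-acid sequence.
    """
    total = 0.0
    for i, (nt_i, aa_i, f_i) in enumerate(clones):
        shared = any(aa_i == aa_j for j, (_, aa_j, _) in enumerate(clones) if j != i)
        if shared:
            total += f_i
    return total


class UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def union_find_clusters(sequences: list[str], max_dist: int) -> set[frozenset[int]]:
    """Transitive closure of all pairs at DP edit distance <= max_dist."""
    uf = UnionFind(len(sequences))
    for i in range(len(sequences)):
        for j in range(i + 1, len(sequences)):
            if dp_levenshtein(sequences[i], sequences[j]) <= max_dist:
                uf.union(i, j)
    groups: dict[int, set[int]] = {}
    for i in range(len(sequences)):
        groups.setdefault(uf.find(i), set()).add(i)
    return {frozenset(g) for g in groups.values()}


def floyd_warshall_diameter(n_nodes: int, edges: list[tuple[int, int]]) -> int:
    """Max finite shortest-path length via dense Floyd-Warshall."""
    if n_nodes == 0:
        return 0
    inf = np.inf
    d = np.full((n_nodes, n_nodes), inf)
    np.fill_diagonal(d, 0.0)
    for i, j in edges:
        d[i, j] = d[j, i] = 1.0
    for k in range(n_nodes):
        d = np.minimum(d, d[:, k : k + 1] + d[k : k + 1, :])
    finite = d[np.isfinite(d)]
    return int(finite.max())
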