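"""Independent reference implementations used only as test oracles.

Deliberately written with different algorithmic structure from the package
code: the agglomerator is a greedy global-minimum merger with
Lance-Williams averaging, peak matching is exhaustive enumeration, and the
component census is a hand-rolled union-find.
"""

from __future__ import annotations

import numpy as np


def naive_average_linkage(matrix: np.ndarray, threshold: float) -> list[frozenset]:
    """Greedy average-linkage clustering, merging while the global minimum
    inter-cluster mean distance is strictly below the threshold."""
    n = len(matrix)
    members: dict[int, frozenset] = {i: frozenset([i]) for i in range(n)}
    dist: dict[tuple[int, int], float] = {
        (i, j): float(matrix[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    next_id = n
    while len(members) > 1:
        (i, j), d = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        if not d < threshold:
            break
        ni, nj = len(members[i]), len(members[j])
        merged = members.pop(i) | members.pop(j)
        new_dists = {}
        for k in members:
            dik = dist.pop((min(i, k), max(i, k)))
            djk = dist.pop((min(j, k), max(j, k)))
            new_dists[k] = (ni * dik + nj * djk) / (ni + nj)
        del dist[(i, j)]
        members[next_id] = merged
        for k, dk in new_dists.items():
            dist[(min(k, next_id), max(k, next_id))] = dk
        next_id += 1
    return sorted(members.values(), key=lambda c: min(c))


def average_linkage_from_scratch(matrix: np.ndarray, threshold: float) -> list[frozenset]:
    """Same greedy merger but recomputing every cross-pair mean from the
    original matrix at each step (validates the Lance-Williams update)."""
    clusters = [frozenset([i]) for i in range(len(matrix))]
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = float(
                    np.mean([matrix[x, y] for x in clusters[a] for y in clusters[b]])
                )
                if best is None or d < best[0]:
                    best = (d, a, b)
        if not best[0] < threshold:
            break
        _, a, b = best
        merged = clusters[a] | clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
    return sorted(clusters, key=lambda c: min(c))


def best_matching_score(pairs: list[tuple[int, int, float]]) -> float:
    """Exhaustive maximum-weight one-to-one matching over candidate pairs."""

    def rec(k: int, used_a: frozenset, used_b: frozenset) -> float:
        if k == len(pairs):
            return 0.0
        i, j, w = pairs[k]
        best = rec(k + 1, used_a, used_b)
        if i not in used_a and j not in used_b:
            best = max(best, w + rec(k + 1, used_a | {i}, used_b | {j}))
        return best

    return rec(0, frozenset(), frozenset())


def connected_components(nodes: list[str], edges: list[tuple[str, str]]) -> list[set[str]]:
    parent = {n: n for n in nodes}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        parent[find(a)] = find(b)
    comps: dict[str, set[str]] = {}
    for n in nodes:
        comps.setdefault(find(n), set()).add(n)
    return list(comps.values())


def partition_as_sets(assignment: dict[str, int], ids: list[str]) -> set[frozenset]:
    groups: dict[int, set[int]] = {}
    index = {b: i for i, b in enumerate(ids)}
    for bgc_id, gcf in assignment.items():
        groups.setdefault(gcf, set()).add(index[bgc_id])
    return {frozenset(g) for g in groups.values()}


def random_distance_matrix(rng: np.random.Generator, n: int) -> np.ndarray:
    upper = rng.uniform(0.0, 1.0, size=(n, n))
    mat = np.triu(upper, k=1)
    mat = mat + mat.T
    return mat
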