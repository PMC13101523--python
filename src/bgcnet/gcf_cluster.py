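"""Clustering BGCs into gene cluster families (GCFs).

BGCs are grouped by average-linkage (UPGMA) agglomerative clustering on the
precomputed cosine distance matrix, cut so that merging proceeds while the
smallest current linkage distance is strictly below the threshold (default
0.2): two clusters whose average distance is exactly at the threshold stay
separate.  Each GCF carries a medoid representative, a majority category and
the set of source collections its members came from; the GCF-GCF distance is
the minimum cosine distance over cross pairs of members.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .bgc_io import BGCRecord
from .features import DistanceMatrix

#: Tie-break order for GCF category assignment (highest priority first).
CATEGORY_TIE_ORDER = ("Hybrids", "RiPP", "NRP", "Polyketide", "Terpene", "Others")


@dataclass
class GCFPartition:
    """bgc_id -> dense integer gcf_id assignment at a given threshold."""

    assignment: dict[str, int]
    threshold: float

    def groups(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for bgc_id, gcf_id in self.assignment.items():
            out.setdefault(gcf_id, []).append(bgc_id)
        for members in out.values():
            members.sort()
        return dict(sorted(out.items()))

    @property
    def n_gcfs(self) -> int:
        return len(set(self.assignment.values()))


@dataclass
class GCF:
    gcf_id: int
    members: tuple[str, ...]
    representative_bgc_id: str
    category: str
    collections: frozenset[str]

    def __post_init__(self) -> None:
        if self.representative_bgc_id not in self.members:
            raise ValueError(f"GCF {self.gcf_id}: representative not a member")
        if not self.collections:
            raise ValueError(f"GCF {self.gcf_id}: empty collection set")


def _check_square_symmetric(values: np.ndarray) -> None:
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(values, values.T, atol=1e-8):
        raise ValueError("distance matrix is not symmetric")
    if not np.allclose(np.diag(values), 0.0, atol=1e-12):
        raise ValueError("distance matrix diagonal must be zero")


def average_linkage_cluster(dist: DistanceMatrix, threshold: float = 0.2) -> GCFPartition:
    """Cut the UPGMA merge tree with a strict ``< threshold`` rule.

    Deterministic for a given matrix: the merge order comes from the linkage
    tree, and cluster labels are densely renumbered by smallest original
    member index.  Singletons are allowed.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    n = len(dist.ids)
    _check_square_symmetric(dist.values)
    if n == 1:
        return GCFPartition({dist.ids[0]: 0}, threshold)
    condensed = squareform(dist.values, checks=False)
    merge_tree = linkage(condensed, method="average")
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    # linkage rows are sorted by merge height for average linkage
    # (monotone), so cutting is a prefix of the rows
    clusters: dict[int, int] = {i: i for i in range(n)}  # scipy node id -> root
    next_node = n
    for left, right, height, _size in merge_tree:
        if height < threshold:
            ra, rb = find(clusters[int(left)]), find(clusters[int(right)])
            parent[rb] = ra
            clusters[next_node] = ra
        else:
            clusters[next_node] = -1
        next_node += 1
    roots = [find(i) for i in range(n)]
    label_of_root: dict[int, int] = {}
    assignment: dict[str, int] = {}
    for i, root in enumerate(roots):
        if root not in label_of_root:
            label_of_root[root] = len(label_of_root)
        assignment[dist.ids[i]] = label_of_root[root]
    return GCFPartition(assignment, threshold)


def select_representative(members: Sequence[str], dist: DistanceMatrix) -> str:
    """Medoid: the member minimising summed distance to the other members.

    Row-sum ties break to the lexicographically smallest bgc_id.
    """
    if not members:
        raise ValueError("members must be nonempty")
    if len(members) == 1:
        dist.between(members[0], members[0])  # raises if absent
        return members[0]
    best = min(
        sorted(members),
        key=lambda m: (sum(dist.between(m, other) for other in members if other != m), m),
    )
    return best


def gcf_distance(a: GCF, b: GCF, dist: DistanceMatrix) -> float:
    """Minimum cosine distance over cross pairs of the two families."""
    if set(a.members) & set(b.members):
        raise ValueError(f"GCFs {a.gcf_id} and {b.gcf_id} share members")
    return dist.submatrix_min(a.members, b.members)


def assign_gcf_category(member_categories: Sequence[str]) -> str:
    """Majority category of the members; ties break by a fixed order."""
    counts = Counter(member_categories)
    top = max(counts.values())
    tied = [c for c, k in counts.items() if k == top]
    for c in CATEGORY_TIE_ORDER:
        if c in tied:
            return c
    raise ValueError(f"unknown categories {tied}")


def build_gcfs(
    partition: GCFPartition,
    records: Mapping[str, BGCRecord] | Sequence[BGCRecord],
    dist: DistanceMatrix,
) -> list[GCF]:
    """Materialise GCF objects (medoid, category, collections) from a partition."""
    if not isinstance(records, Mapping):
        records = {r.bgc_id: r for r in records}
    gcfs = []
    for gcf_id, members in partition.groups().items():
        cats = [records[m].category for m in members]
        gcfs.append(
            GCF(
                gcf_id=gcf_id,
                members=tuple(members),
                representative_bgc_id=select_representative(members, dist),
                category=assign_gcf_category(cats),
                collections=frozenset(records[m].collection for m in members),
            )
        )
    return gcfs


def write_partition_tsv(
    partition: GCFPartition, gcfs: Sequence[GCF], path: str | Path
) -> None:
    by_id = {g.gcf_id: g for g in gcfs}
    rows = []
    for bgc_id in sorted(partition.assignment):
        gcf_id = partition.assignment[bgc_id]
        g = by_id[gcf_id]
        rows.append(
            {
                "bgc_id": bgc_id,
                "gcf_id": gcf_id,
                "is_representative": str(bgc_id == g.representative_bgc_id),
                "category": g.category,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
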