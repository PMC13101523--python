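"""Novelty of gene cluster families against reference BGC collections.

The novelty statistic d- of a GCF against a reference collection (e.g. a
MIBiG-style database of characterised BGCs, or BGCs from global seawater
isolates) is the mean, over the GCF's member BGCs, of each member's minimum
cosine distance to any reference BGC.  A family with d- strictly greater
than the threshold (default 0.2) is called novel.  Source-collection
membership of GCFs built from pooled collections yields the Venn
specificity report (families common to all sources vs specific to one).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .features import FeatureVector
from .gcf_cluster import GCF

NoveltyMethod = Literal["member-mean", "gcf-min"]


@dataclass
class NoveltyScore:
    gcf_id: int
    reference_name: str
    d_stat: float
    is_novel: bool

    def __post_init__(self) -> None:
        if not (0.0 <= self.d_stat <= 1.0):
            raise ValueError(f"d_stat out of [0,1]: {self.d_stat}")


@dataclass
class VennReport:
    """GCF counts per exact nonempty subset of source labels."""

    counts: dict[frozenset, int]
    labels: tuple[str, ...]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def common(self) -> int:
        """Families present in every declared source collection."""
        return self.counts.get(frozenset(self.labels), 0)

    def specific(self, label: str) -> int:
        """Families found in exactly one source collection."""
        return self.counts.get(frozenset({label}), 0)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "labels": sorted(self.labels),
            "cells": {
                "+".join(sorted(cell)): count
                for cell, count in sorted(self.counts.items(), key=lambda kv: sorted(kv[0]))
            },
            "total": self.total,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _min_distances(members: Sequence[FeatureVector], reference: Sequence[FeatureVector]) -> np.ndarray:
    member_dense = np.vstack([v.to_dense() for v in members])
    ref_dense = np.vstack([v.to_dense() for v in reference])
    d = np.clip(cdist(member_dense, ref_dense, metric="cosine"), 0.0, 1.0)
    return d.min(axis=1)


def d_statistic(
    members: Sequence[FeatureVector],
    reference: Sequence[FeatureVector],
    method: NoveltyMethod = "member-mean",
) -> float:
    """d- of one GCF against a reference collection.

    member-mean (default): mean over members of the minimum distance to any
    reference vector.  gcf-min: the single minimum distance between any
    member and any reference vector, i.e. the GCF-to-nearest-reference
    family distance when the reference is treated as one pool.
    """
    if not members:
        raise ValueError("GCF has no member vectors")
    if not reference:
        raise ValueError("reference collection is empty")
    minima = _min_distances(members, reference)
    if method == "member-mean":
        return float(minima.mean())
    if method == "gcf-min":
        return float(minima.min())
    raise ValueError(f"unknown novelty method {method!r}")


def classify_novelty(d: float, threshold: float = 0.2) -> bool:
    """Strictly-greater call: d- exactly at the threshold is not novel."""
    if not (0.0 <= d <= 1.0):
        raise ValueError(f"d out of [0,1]: {d}")
    return d > threshold


def score_gcfs(
    gcfs: Sequence[GCF],
    vectors_by_bgc: dict[str, FeatureVector],
    reference: Sequence[FeatureVector],
    reference_name: str,
    threshold: float = 0.2,
    method: NoveltyMethod = "member-mean",
) -> list[NoveltyScore]:
    scores = []
    for g in gcfs:
        d = d_statistic([vectors_by_bgc[m] for m in g.members], reference, method)
        scores.append(NoveltyScore(g.gcf_id, reference_name, d, classify_novelty(d, threshold)))
    return scores


def novelty_report(scores: Sequence[NoveltyScore]) -> tuple[int, float]:
    """(count of novel families, percentage rounded half-up to 1 decimal)."""
    if not scores:
        raise ValueError("no novelty scores")
    refs = {s.reference_name for s in scores}
    if len(refs) != 1:
        raise ValueError(f"scores mix reference collections: {sorted(refs)}")
    n_novel = sum(s.is_novel for s in scores)
    pct = float(
        Decimal(100 * n_novel) / Decimal(len(scores))
    )
    pct = float(Decimal(str(pct)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
    return n_novel, pct


def venn_partition(gcfs: Sequence[GCF], labels: Sequence[str] | None = None) -> VennReport:
    """Count each GCF once under its exact source-collection subset."""
    counts: dict[frozenset, int] = {}
    seen: set[str] = set()
    for g in gcfs:
        if not g.collections:
            raise ValueError(f"GCF {g.gcf_id} has no collections")
        cell = frozenset(g.collections)
        counts[cell] = counts.get(cell, 0) + 1
        seen |= g.collections
    if labels is None:
        labels = tuple(sorted(seen))
    return VennReport(counts, tuple(labels))


def write_novelty_tsv(scores: Sequence[NoveltyScore], path: str | Path) -> None:
    rows = [
        {
            "gcf_id": s.gcf_id,
            "reference": s.reference_name,
            "d_stat": f"{s.d_stat:.10g}",
            "is_novel": str(s.is_novel),
        }
        for s in sorted(scores, key=lambda s: s.gcf_id)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
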