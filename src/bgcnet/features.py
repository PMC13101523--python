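"""Domain feature vectors and cosine distances between BGCs.

Each BGC is represented as a sparse nonnegative vector over a shared
vocabulary of domain accessions; the clustering metric throughout the
pipeline is the cosine distance 1 - u.v/(|u||v|), which for nonnegative
vectors lies in [0, 1].  Cosine distance is not a metric (the triangle
inequality can fail), which is why downstream clustering treats it purely
as a dissimilarity.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .bgc_io import BGCRecord

FeatureMode = Literal["binary", "count", "bitscore"]


@dataclass(frozen=True)
class Vocabulary:
    """Deterministic (lexicographic) ordering of domain accessions."""

    domain_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.domain_ids)) != len(self.domain_ids):
            raise ValueError("vocabulary contains duplicate domain ids")
        if list(self.domain_ids) != sorted(self.domain_ids):
            raise ValueError("vocabulary must be lexicographically sorted")

    @property
    def index(self) -> dict[str, int]:
        return {d: i for i, d in enumerate(self.domain_ids)}

    def __len__(self) -> int:
        return len(self.domain_ids)

    def __contains__(self, domain_id: str) -> bool:
        return domain_id in self.index


@dataclass
class FeatureVector:
    """Sparse nonnegative weights over a :class:`Vocabulary`."""

    weights: dict[int, float]
    vocab: Vocabulary

    def __post_init__(self) -> None:
        if not self.weights:
            raise ValueError("feature vector has no nonzero entries")
        for pos, w in self.weights.items():
            if w <= 0:
                raise ValueError(f"stored weight must be > 0 (position {pos}: {w})")

    @property
    def norm(self) -> float:
        return sqrt(sum(w * w for w in self.weights.values()))

    def to_dense(self) -> np.ndarray:
        out = np.zeros(len(self.vocab))
        for pos, w in self.weights.items():
            out[pos] = w
        return out


@dataclass
class DistanceMatrix:
    """Symmetric zero-diagonal cosine distance matrix with row labels."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        self._index = {b: i for i, b in enumerate(self.ids)}

    def between(self, a: str, b: str) -> float:
        try:
            return float(self.values[self._index[a], self._index[b]])
        except KeyError as exc:
            raise KeyError(f"id {exc.args[0]!r} not in distance matrix") from exc

    def submatrix_min(self, left: Sequence[str], right: Sequence[str]) -> float:
        li = [self._index[b] for b in left]
        ri = [self._index[b] for b in right]
        return float(self.values[np.ix_(li, ri)].min())

    def write_tsv(self, path: str | Path) -> None:
        frame = pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids))
        frame.to_csv(path, sep="\t", float_format="%.10g")


def build_vocabulary(records: Sequence[BGCRecord]) -> Vocabulary:
    """Sorted union of domain accessions over all (pooled) records."""
    ids = sorted({h.domain_id for r in records for h in r.domains})
    if not ids:
        raise ValueError("no domain annotations in any record")
    return Vocabulary(tuple(ids))


def featurize(record: BGCRecord, vocab: Vocabulary, mode: FeatureMode = "bitscore") -> FeatureVector:
    """Turn a record's domain hits into a sparse vector.

    binary: 1 per distinct in-vocabulary domain; count: occurrence counts;
    bitscore: per-domain summed bitscores (the default, so records whose
    hits all default to bitscore 1.0 reduce to the count mode).
    """
    index = vocab.index
    weights: dict[int, float] = {}
    for hit in record.domains:
        pos = index.get(hit.domain_id)
        if pos is None:
            continue
        if mode == "binary":
            weights[pos] = 1.0
        elif mode == "count":
            weights[pos] = weights.get(pos, 0.0) + 1.0
        elif mode == "bitscore":
            weights[pos] = weights.get(pos, 0.0) + hit.bitscore
        else:
            raise ValueError(f"unknown featurization mode {mode!r}")
    if not weights:
        raise ValueError(f"BGC {record.bgc_id} has no in-vocabulary domains")
    return FeatureVector(weights, vocab)


def cosine_distance(u: FeatureVector, v: FeatureVector) -> float:
    """1 - cos(u, v); in [0, 1] for nonnegative vectors, 0 iff proportional."""
    if u.vocab is not v.vocab and u.vocab != v.vocab:
        raise ValueError("vectors from different vocabularies")
    dot = sum(w * v.weights[p] for p, w in u.weights.items() if p in v.weights)
    d = 1.0 - dot / (u.norm * v.norm)
    if abs(d) < 1e-12:  # proportional vectors, up to float rounding
        d = 0.0
    return min(1.0, max(0.0, d))


def pairwise_distances(
    vectors: Sequence[FeatureVector], ids: Sequence[str] | None = None
) -> DistanceMatrix:
    """Full symmetric cosine distance matrix over a list of vectors."""
    if len(vectors) < 2:
        raise ValueError("need at least two vectors")
    if ids is None:
        ids = [str(i) for i in range(len(vectors))]
    if len(ids) != len(vectors):
        raise ValueError("ids and vectors length mismatch")
    dense = np.vstack([v.to_dense() for v in vectors])
    mat = cdist(dense, dense, metric="cosine")
    np.fill_diagonal(mat, 0.0)
    mat = np.clip((mat + mat.T) / 2.0, 0.0, 1.0)
    return DistanceMatrix(tuple(ids), mat)


def feature_matrix(
    records: Sequence[BGCRecord], vocab: Vocabulary, mode: FeatureMode = "bitscore"
) -> tuple[list[str], list[FeatureVector]]:
    """Featurize a whole collection, preserving record order."""
    ids, vecs = [], []
    for r in records:
        ids.append(r.bgc_id)
        vecs.append(featurize(r, vocab, mode))
    return ids, vecs


def export_feature_tsv(
    records: Sequence[BGCRecord],
    vocab: Vocabulary,
    path: str | Path,
    mode: FeatureMode = "bitscore",
) -> None:
    ids, vecs = feature_matrix(records, vocab, mode)
    dense = np.vstack([v.to_dense() for v in vecs])
    pd.DataFrame(dense, index=ids, columns=list(vocab.domain_ids)).to_csv(
        path, sep="\t", float_format="%.10g"
    )
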