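"""MS/MS molecular networking.

Implements the classical molecular-networking pipeline: spectra are
peak-filtered and square-root/L2 scaled, all pairs are scored with the
modified cosine (fragment pairs match either at equal m/z or offset by the
precursor mass difference, one-to-one), and edges are kept when the cosine
and matched-peak thresholds hold (defaults 0.70 and 6, fragment tolerance
0.02 Da).  Network topology is then constrained GNPS-style: an edge
survives only if both endpoints rank each other within their top-K
neighbours, and oversized connected components are trimmed by repeatedly
dropping their weakest edge until no component exceeds the cap (default
100 nodes).  Components touching blank (medium-only) spectra can be
removed wholesale, and the final census counts nodes, singletons and
molecular families (components of two or more nodes).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal, Sequence

import networkx as nx
import numpy as np
from pyteomics import mgf as pymgf
from scipy.optimize import linear_sum_assignment


@dataclass
class Spectrum:
    """One centroided MS/MS spectrum; peaks sorted by m/z ascending."""

    spectrum_id: str
    precursor_mz: float
    peaks: np.ndarray  # shape (n, 2): m/z, intensity
    charge: int = 1
    source: str = "sample"

    def __post_init__(self) -> None:
        self.peaks = np.asarray(self.peaks, dtype=float).reshape(-1, 2)
        if self.precursor_mz <= 0:
            raise ValueError(f"{self.spectrum_id}: precursor_mz must be > 0")
        if self.charge < 1:
            raise ValueError(f"{self.spectrum_id}: charge must be a positive integer")
        if len(self.peaks) and (self.peaks[:, 1] < 0).any():
            raise ValueError(f"{self.spectrum_id}: negative intensity")
        order = np.argsort(self.peaks[:, 0], kind="stable")
        self.peaks = self.peaks[order]

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)


@dataclass(frozen=True)
class SpectralEdge:
    node_a: str
    node_b: str
    cosine: float
    n_matched: int

    @property
    def pair(self) -> tuple[str, str]:
        return tuple(sorted((self.node_a, self.node_b)))


@dataclass
class NetworkParams:
    min_cosine: float = 0.70
    min_matched: int = 6
    frag_tol: float = 0.02
    prec_tol: float = 0.02
    top_k: int = 10
    max_component: int = 100

    def as_dict(self) -> dict:
        return {
            "min_cosine": self.min_cosine,
            "min_matched": self.min_matched,
            "frag_tol": self.frag_tol,
            "prec_tol": self.prec_tol,
            "top_k": self.top_k,
            "max_component": self.max_component,
        }


@dataclass
class SpectralNetwork:
    graph: nx.Graph
    params: NetworkParams

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def edges(self) -> list[SpectralEdge]:
        out = [
            SpectralEdge(a, b, d["cosine"], d["n_matched"])
            for a, b, d in self.graph.edges(data=True)
        ]
        return sorted(out, key=lambda e: e.pair)

    def components(self) -> list[set[str]]:
        return sorted(nx.connected_components(self.graph), key=lambda c: sorted(c)[0])


@dataclass
class FamilyCensus:
    n_nodes: int
    n_singletons: int
    n_connected_nodes: int
    n_families: int

    def as_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_singletons": self.n_singletons,
            "n_connected_nodes": self.n_connected_nodes,
            "n_families": self.n_families,
        }


# ---------------------------------------------------------------------------
# MGF I/O


def read_mgf(path: str | Path) -> list[Spectrum]:
    """Read spectra from MGF; missing CHARGE defaults to 1+.

    A SOURCE=blank parameter (written by :func:`write_mgf`) marks
    medium-only blank spectra.
    """
    spectra = []
    with pymgf.MGF(str(path), convert_arrays=1) as reader:
        for i, entry in enumerate(reader):
            params = entry["params"]
            if "pepmass" not in params:
                raise ValueError(f"{path}: block {i} has no PEPMASS")
            pepmass = params["pepmass"]
            precursor = float(pepmass[0] if isinstance(pepmass, (tuple, list)) else pepmass)
            charge = params.get("charge")
            charge = int(charge[0]) if charge else 1
            title = str(params.get("title", f"scan_{i}"))
            source = str(params.get("source", "sample")).lower()
            peaks = np.column_stack([entry["m/z array"], entry["intensity array"]])
            spectra.append(
                Spectrum(
                    spectrum_id=title,
                    precursor_mz=precursor,
                    peaks=peaks,
                    charge=charge,
                    source=source,
                )
            )
    return spectra


def write_mgf(spectra: Sequence[Spectrum], path: str | Path) -> None:
    entries = []
    for s in spectra:
        entries.append(
            {
                "m/z array": s.peaks[:, 0],
                "intensity array": s.peaks[:, 1],
                "params": {
                    "title": s.spectrum_id,
                    "pepmass": s.precursor_mz,
                    "charge": f"{s.charge}+",
                    "source": s.source,
                },
            }
        )
    pymgf.write(entries, str(path), file_mode="w")


# ---------------------------------------------------------------------------
# Preprocessing and modified cosine


def preprocess(
    s: Spectrum,
    window: float = 50.0,
    keep_top: int = 6,
    sqrt_intensity: bool = True,
) -> Spectrum:
    """Window peak filter, optional sqrt scaling, then L2 normalisation.

    A peak survives only if it ranks within the ``keep_top`` most intense
    peaks inside +/- ``window`` Da of its own m/z (the GNPS default of 6 in
    50 Da).  Raises if nothing survives (callers exclude such spectra).
    """
    mz, inten = s.peaks[:, 0], s.peaks[:, 1]
    keep = np.zeros(len(mz), dtype=bool)
    for i in range(len(mz)):
        in_window = np.abs(mz - mz[i]) <= window
        rank = int((inten[in_window] > inten[i]).sum())
        keep[i] = rank < keep_top
    mz, inten = mz[keep], inten[keep]
    inten = inten[mz > 0]
    mz = mz[mz > 0]
    if len(mz) == 0:
        raise ValueError(f"{s.spectrum_id}: no peaks left after filtering")
    if sqrt_intensity:
        inten = np.sqrt(inten)
    norm = np.linalg.norm(inten)
    if norm == 0:
        raise ValueError(f"{s.spectrum_id}: zero total intensity")
    return replace(s, peaks=np.column_stack([mz, inten / norm]))


def preprocess_all(spectra: Sequence[Spectrum], **kwargs) -> list[Spectrum]:
    """Preprocess a batch, silently excluding spectra that lose all peaks."""
    out = []
    for s in spectra:
        try:
            out.append(preprocess(s, **kwargs))
        except ValueError:
            continue
    return out


def _candidate_pairs(a: Spectrum, b: Spectrum, frag_tol: float) -> list[tuple[int, int, float]]:
    shift = a.precursor_mz - b.precursor_mz
    mza, mzb = a.peaks[:, 0], b.peaks[:, 0]
    ia, ib = a.peaks[:, 1], b.peaks[:, 1]
    pairs = []
    for i in range(len(mza)):
        direct = np.abs(mza[i] - mzb) <= frag_tol
        shifted = np.abs(mza[i] - (mzb + shift)) <= frag_tol
        for j in np.nonzero(direct | shifted)[0]:
            pairs.append((i, int(j), float(ia[i] * ib[j])))
    return pairs


def modified_cosine(
    a: Spectrum,
    b: Spectrum,
    frag_tol: float = 0.02,
    method: Literal["greedy", "optimal"] = "greedy",
) -> tuple[float, int]:
    """Shift-tolerant spectral similarity with one-to-one peak pairing.

    Fragment pairs are candidates when their m/z agree within ``frag_tol``
    directly or after shifting by the precursor mass difference.  The
    greedy matcher (default) takes candidate pairs in descending intensity
    product; ``optimal`` solves the exact maximum-weight one-to-one
    matching.  Inputs must be preprocessed to unit intensity norm, so the
    score is the plain sum of matched intensity products, clipped to [0, 1].
    """
    if a.n_peaks == 0 or b.n_peaks == 0:
        raise ValueError("cannot score a zero-peak spectrum")
    pairs = _candidate_pairs(a, b, frag_tol)
    if not pairs:
        return 0.0, 0
    if method == "greedy":
        pairs.sort(key=lambda p: (-p[2], p[0], p[1]))
        used_a: set[int] = set()
        used_b: set[int] = set()
        score, n_matched = 0.0, 0
        for i, j, prod in pairs:
            if i in used_a or j in used_b:
                continue
            used_a.add(i)
            used_b.add(j)
            score += prod
            n_matched += 1
    elif method == "optimal":
        weight = np.zeros((a.n_peaks, b.n_peaks))
        allowed = np.zeros_like(weight, dtype=bool)
        for i, j, prod in pairs:
            weight[i, j] = prod
            allowed[i, j] = True
        rows, cols = linear_sum_assignment(weight, maximize=True)
        score, n_matched = 0.0, 0
        for i, j in zip(rows, cols):
            if allowed[i, j]:
                score += weight[i, j]
                n_matched += 1
    else:
        raise ValueError(f"unknown matching method {method!r}")
    return min(1.0, score), n_matched


# ---------------------------------------------------------------------------
# Network construction


def _top_k_filter(edges: list[SpectralEdge], top_k: int) -> list[SpectralEdge]:
    if top_k <= 0:
        return edges
    ranked: dict[str, list[tuple[float, str]]] = {}
    for e in edges:
        ranked.setdefault(e.node_a, []).append((-e.cosine, e.node_b))
        ranked.setdefault(e.node_b, []).append((-e.cosine, e.node_a))
    top: dict[str, set[str]] = {}
    for node, neighbours in ranked.items():
        neighbours.sort()
        top[node] = {other for _, other in neighbours[:top_k]}
    return [
        e
        for e in edges
        if e.node_b in top.get(e.node_a, set()) and e.node_a in top.get(e.node_b, set())
    ]


def _cap_components(graph: nx.Graph, max_component: int) -> None:
    """Trim oversized components by removing their weakest edge, repeatedly.

    Ties on cosine break on the lexicographically smallest node pair, so
    the pruning is deterministic.
    """
    while True:
        oversized = [c for c in nx.connected_components(graph) if len(c) > max_component]
        if not oversized:
            return
        comp = min(oversized, key=lambda c: sorted(c)[0])
        worst = min(
            graph.subgraph(comp).edges(data=True),
            key=lambda e: (e[2]["cosine"], tuple(sorted((e[0], e[1])))),
        )
        graph.remove_edge(worst[0], worst[1])


def build_network(
    spectra: Sequence[Spectrum],
    params: NetworkParams | None = None,
    preprocessed: bool = False,
) -> SpectralNetwork:
    """Score all pairs and build the thresholded molecular network.

    All input spectra become nodes (singletons included).  Spectra that
    lose every peak in preprocessing are dropped entirely.
    """
    if not spectra:
        raise ValueError("no spectra")
    params = params or NetworkParams()
    if not preprocessed:
        spectra = preprocess_all(spectra)
    graph = nx.Graph()
    for s in spectra:
        graph.add_node(s.spectrum_id, precursor_mz=s.precursor_mz, source=s.source)
    edges = []
    for idx_a in range(len(spectra)):
        for idx_b in range(idx_a + 1, len(spectra)):
            a, b = spectra[idx_a], spectra[idx_b]
            cos, n_matched = modified_cosine(a, b, params.frag_tol)
            if cos >= params.min_cosine and n_matched >= params.min_matched:
                edges.append(SpectralEdge(a.spectrum_id, b.spectrum_id, cos, n_matched))
    edges = _top_k_filter(edges, params.top_k)
    for e in edges:
        graph.add_edge(e.node_a, e.node_b, cosine=e.cosine, n_matched=e.n_matched)
    _cap_components(graph, params.max_component)
    return SpectralNetwork(graph, params)


def remove_blank_components(
    net: SpectralNetwork, spectra: Sequence[Spectrum], preprocessed: bool = False
) -> SpectralNetwork:
    """Drop every component touching the blank (medium-only) sample.

    A component is removed when it contains a blank-derived node, or a
    sample node that matches some blank spectrum at the network thresholds
    with precursors within the parent-mass tolerance.
    """
    params = net.params
    if not preprocessed:
        spectra = preprocess_all(spectra)
    by_id = {s.spectrum_id: s for s in spectra}
    blanks = [s for s in spectra if s.source == "blank"]
    flagged: set[str] = set()
    for node in net.graph.nodes:
        s = by_id.get(node)
        if s is None:
            continue
        if s.source == "blank":
            flagged.add(node)
            continue
        for blank in blanks:
            if abs(s.precursor_mz - blank.precursor_mz) > params.prec_tol:
                continue
            cos, n_matched = modified_cosine(s, blank, params.frag_tol)
            if cos >= params.min_cosine and n_matched >= params.min_matched:
                flagged.add(node)
                break
    graph = net.graph.copy()
    for comp in list(nx.connected_components(graph)):
        if comp & flagged:
            graph.remove_nodes_from(comp)
    return SpectralNetwork(graph, params)


def family_census(net: SpectralNetwork) -> FamilyCensus:
    """Nodes, singletons, connected nodes and molecular families (>=2 nodes)."""
    comps = list(nx.connected_components(net.graph))
    n_nodes = net.graph.number_of_nodes()
    n_singletons = sum(1 for c in comps if len(c) == 1)
    n_families = sum(1 for c in comps if len(c) >= 2)
    return FamilyCensus(
        n_nodes=n_nodes,
        n_singletons=n_singletons,
        n_connected_nodes=n_nodes - n_singletons,
        n_families=n_families,
    )


def write_edge_tsv(net: SpectralNetwork, path: str | Path) -> None:
    lines = ["node_a\tnode_b\tcosine\tn_matched"]
    for e in net.edges():
        a, b = e.pair
        lines.append(f"{a}\t{b}\t{e.cosine:.6f}\t{e.n_matched}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_graphml(net: SpectralNetwork, path: str | Path) -> None:
    nx.write_graphml(net.graph, str(path))
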