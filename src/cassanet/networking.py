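"""Modified-cosine spectral similarity and molecular network construction.

The similarity follows the GNPS/MetGem convention: peak intensities are
square-root transformed and L2-normalized (no m/z weighting); peak pairs
may match either directly (|mzA - mzB| <= tol) or shifted by the precursor
mass difference, and a one-to-one assignment maximizing the weighted dot
product is chosen, so the score lies in [0, 1].

Network construction applies, in order: a score threshold, a minimum
matched-peak count, a top-K neighbour rule (an edge survives only if each
endpoint ranks it among its K best), and a connected-component size cap
enforced by iteratively deleting the weakest edge of any oversized
component.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.optimize import linear_sum_assignment

from .spectra import Spectrum

__all__ = [
    "Edge",
    "MolecularNetwork",
    "cosine_score",
    "build_network",
    "export_graphml",
    "export_edgelist",
]


@dataclass(frozen=True)
class Edge:
    node_a: str
    node_b: str
    cs: float
    n_matched: int

    def __post_init__(self):
        if self.node_a > self.node_b:
            a, b = self.node_b, self.node_a
            object.__setattr__(self, "node_a", a)
            object.__setattr__(self, "node_b", b)


@dataclass
class MolecularNetwork:
    """Nodes (spectrum ids, with optional attributes) plus scored edges."""

    nodes: dict[str, dict] = field(default_factory=dict)
    edges: list[Edge] = field(default_factory=list)

    @property
    def components(self) -> list[set[str]]:
        g = self.to_graph()
        return [set(c) for c in nx.connected_components(g)]

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        for node, attrs in self.nodes.items():
            g.add_node(node, **attrs)
        for e in self.edges:
            g.add_edge(e.node_a, e.node_b, cs=e.cs, n_matched=e.n_matched)
        return g


def _weights(s: Spectrum) -> np.ndarray:
    w = np.sqrt(np.asarray(s.intensities, dtype=float))
    norm = math.sqrt(float(np.dot(w, w)))
    return w / norm if norm > 0 else w


def cosine_score(
    a: Spectrum,
    b: Spectrum,
    frag_tol: float = 0.02,
    modified: bool = True,
) -> tuple[float, int]:
    """Modified cosine similarity of two cleaned spectra.

    Returns ``(score, n_matched)``.  Candidate peak pairs are those within
    ``frag_tol`` directly, plus (when ``modified``) those whose m/z
    difference equals the precursor difference within ``frag_tol``.  The
    returned score uses the one-to-one assignment of candidate pairs that
    maximizes the dot product of sqrt-transformed, L2-normalized
    intensities (computed exactly via linear sum assignment, not greedily).
    Spectra with no peaks score (0.0, 0).
    """
    if frag_tol <= 0:
        raise ValueError("frag_tol must be positive")
    if not a.peaks or not b.peaks:
        return 0.0, 0
    wa, wb = _weights(a), _weights(b)
    mza = np.asarray(a.mzs)
    mzb = np.asarray(b.mzs)
    shift = a.precursor_mz - b.precursor_mz

    signed = mza[:, None] - mzb[None, :]
    candidate = np.abs(signed) <= frag_tol
    if modified:
        candidate |= np.abs(signed - shift) <= frag_tol
    if not candidate.any():
        return 0.0, 0
    score_matrix = np.where(candidate, wa[:, None] * wb[None, :], 0.0)
    rows, cols = linear_sum_assignment(score_matrix, maximize=True)
    pair_scores = score_matrix[rows, cols]
    used = pair_scores > 0
    score = float(pair_scores[used].sum())
    n_matched = int(np.count_nonzero(candidate[rows, cols] & used))
    return min(score, 1.0), n_matched


def build_network(
    spectra: Sequence[Spectrum],
    cs_min: float = 0.55,
    min_matched: int = 4,
    top_k: int = 10,
    max_component: int = 1000,
    frag_tol: float = 0.02,
    modified: bool = True,
    node_attrs: Mapping[str, Mapping] | None = None,
) -> MolecularNetwork:
    """Build a molecular network from all pairwise similarities.

    Edges are kept iff ``cs > cs_min`` and ``n_matched >= min_matched``;
    the top-K rule then requires each endpoint to rank the edge within its
    K best by score; finally components larger than ``max_component`` are
    reduced by iteratively removing their lowest-scoring edge (ties broken
    by lower matched-peak count, then lexicographic node ids).

    The default ``min_matched`` of 4 follows the MetGem import settings
    used for this kind of data; a stricter convention of 10 common
    fragment ions is sometimes applied when reading networks manually --
    both are accepted here via the parameter.
    """
    net = MolecularNetwork()
    for s in spectra:
        attrs = {"precursor_mz": s.precursor_mz, "rt": s.rt}
        if node_attrs and s.id in node_attrs:
            attrs.update(node_attrs[s.id])
        net.nodes[s.id] = attrs

    raw: list[Edge] = []
    for i in range(len(spectra)):
        for j in range(i + 1, len(spectra)):
            cs, n = cosine_score(spectra[i], spectra[j], frag_tol, modified)
            if cs > cs_min and n >= min_matched:
                raw.append(Edge(spectra[i].id, spectra[j].id, cs, n))

    # top-K: an edge survives only if BOTH endpoints rank it in their K best
    by_node: dict[str, list[Edge]] = {}
    for e in raw:
        by_node.setdefault(e.node_a, []).append(e)
        by_node.setdefault(e.node_b, []).append(e)
    kept = []
    for e in raw:
        ok = True
        for node in (e.node_a, e.node_b):
            ranked = sorted(
                by_node[node], key=lambda x: (-x.cs, -x.n_matched, x.node_a, x.node_b)
            )
            if e not in ranked[:top_k]:
                ok = False
                break
        if ok:
            kept.append(e)

    # component size cap: delete weakest edges of oversized components
    g = nx.Graph()
    g.add_nodes_from(net.nodes)
    for e in kept:
        g.add_edge(e.node_a, e.node_b, edge=e)
    while True:
        oversized = [c for c in nx.connected_components(g) if len(c) > max_component]
        if not oversized:
            break
        comp = oversized[0]
        weakest = min(
            (g.edges[u, v]["edge"] for u, v in g.subgraph(comp).edges),
            key=lambda e: (e.cs, e.n_matched, e.node_a, e.node_b),
        )
        g.remove_edge(weakest.node_a, weakest.node_b)

    net.edges = sorted(
        (d["edge"] for _, _, d in g.edges(data=True)),
        key=lambda e: (e.node_a, e.node_b),
    )
    return net


def export_graphml(net: MolecularNetwork, path: str | Path) -> None:
    """Write the network as GraphML with node and edge attributes."""
    g = net.to_graph()
    for _, attrs in g.nodes(data=True):
        for k, v in list(attrs.items()):
            if isinstance(v, (list, tuple, dict)):
                attrs[k] = str(v)
    nx.write_graphml(g, str(path))


def export_edgelist(net: MolecularNetwork, path: str | Path) -> None:
    """Write edges as TSV: node_a, node_b, cs, n_matched."""
    with open(path, "w") as fh:
        fh.write("node_a\tnode_b\tcs\tn_matched\n")
        for e in net.edges:
            fh.write(f"{e.node_a}\t{e.node_b}\t{e.cs:.4f}\t{e.n_matched}\n")
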