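"""Areal-unit graphs and the intrinsic Markov-random-field precision.

The spatial effect of a geoadditive disease-mapping model lives on an
undirected graph whose nodes are the areal units (wards) and whose edges
join neighbouring units.  The intrinsic Gaussian MRF (ICAR) prior on the
per-ward effect vector f has density proportional to

    exp( - f' Q f / (2 tau^2) ),      Q = D - A,

where D is the diagonal matrix of neighbour counts and A the adjacency
matrix.  Q is the graph Laplacian: positive semidefinite with one null
vector (the constant) per connected component, so the prior is improper
and the effect is identified by a sum-to-zero constraint per component.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import scipy.sparse as sp

__all__ = ["WardGraph", "MRFStructure", "build_mrf_precision", "connected_components"]

# dense conversion is cheap up to a few hundred wards; beyond that stay sparse
_DENSE_LIMIT = 500


class GraphError(ValueError):
    """Invalid graph structure (self-loop, unknown node, ...)."""


@dataclass(frozen=True, eq=False)
class WardGraph:
    """Undirected simple graph over ward identifiers.

    ``node_ids`` fixes the canonical ordering used everywhere downstream
    (design matrices, spatial draws, classification files).  Equality is
    structural: same node set, same edge set, regardless of ordering.
    """

    node_ids: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self):
        if len(self.node_ids) < 1:
            raise GraphError("graph needs at least one node")
        if len(set(self.node_ids)) != len(self.node_ids):
            raise GraphError("duplicate node ids")
        index = {nid: i for i, nid in enumerate(self.node_ids)}
        seen = set()
        norm = []
        for a, b in self.edges:
            if a == b:
                raise GraphError(f"self-loop on node {a!r}")
            if a not in index:
                raise GraphError(f"edge references unknown node {a!r}")
            if b not in index:
                raise GraphError(f"edge references unknown node {b!r}")
            key = (a, b) if a < b else (b, a)
            if key not in seen:
                seen.add(key)
                norm.append(key)
        object.__setattr__(self, "edges", tuple(sorted(norm)))
        object.__setattr__(self, "_index", index)

    def __eq__(self, other):
        if not isinstance(other, WardGraph):
            return NotImplemented
        return set(self.node_ids) == set(other.node_ids) and set(self.edges) == set(other.edges)

    def __hash__(self):
        return hash((frozenset(self.node_ids), frozenset(self.edges)))

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def index_of(self, node_id: str) -> int:
        return self._index[node_id]

    def edge_index_pairs(self) -> np.ndarray:
        """Edges as an (E, 2) array of node indices in canonical order."""
        if not self.edges:
            return np.empty((0, 2), dtype=int)
        return np.array([[self._index[a], self._index[b]] for a, b in self.edges])

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=int)
        for i, j in self.edge_index_pairs():
            deg[i] += 1
            deg[j] += 1
        return deg

    def adjacency_matrix(self) -> sp.csr_matrix:
        n = self.n_nodes
        pairs = self.edge_index_pairs()
        if len(pairs) == 0:
            return sp.csr_matrix((n, n), dtype=int)
        rows = np.r_[pairs[:, 0], pairs[:, 1]]
        cols = np.r_[pairs[:, 1], pairs[:, 0]]
        return sp.csr_matrix((np.ones(len(rows), dtype=int), (rows, cols)), shape=(n, n))

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.node_ids)
        g.add_edges_from(self.edges)
        return g

    def reindex(self, new_order: list[str] | tuple[str, ...]) -> "WardGraph":
        """Return the same graph with nodes in ``new_order``.

        Raises if ``new_order`` is not a permutation of the node set.
        """
        if set(new_order) != set(self.node_ids) or len(new_order) != self.n_nodes:
            raise GraphError("new order is not a permutation of the node set")
        return WardGraph(tuple(new_order), self.edges)


@dataclass(frozen=True)
class MRFStructure:
    """Precision structure Q = D - A of the intrinsic GMRF prior.

    ``rank(Q) = n_nodes - n_components``; the nullspace is spanned by the
    per-component indicator vectors.
    """

    Q: sp.csr_matrix
    degrees: np.ndarray
    n_components: int
    components: tuple[tuple[int, ...], ...]  # node indices per component

    @property
    def n_nodes(self) -> int:
        return self.Q.shape[0]

    @property
    def rank(self) -> int:
        return self.n_nodes - self.n_components

    def dense(self) -> np.ndarray:
        if self.n_nodes > _DENSE_LIMIT:
            raise ValueError(
                f"dense conversion disabled above {_DENSE_LIMIT} nodes "
                f"(graph has {self.n_nodes})"
            )
        return self.Q.toarray().astype(float)


def connected_components(graph: WardGraph) -> list[set[str]]:
    """Partition of the node ids into connected components."""
    return [set(c) for c in nx.connected_components(graph.to_networkx())]


def build_mrf_precision(graph: WardGraph) -> MRFStructure:
    """Graph Laplacian Q = diag(degrees) - adjacency, stored sparse.

    Isolated nodes are allowed and contribute all-zero rows (they carry no
    prior information and are handled by the per-component constraint).
    """
    A = graph.adjacency_matrix()
    deg = graph.degrees()
    Q = sp.diags(deg, format="csr", dtype=int) - A
    comps = connected_components(graph)
    comp_idx = tuple(
        tuple(sorted(graph.index_of(nid) for nid in comp)) for comp in comps
    )
    # stable order by smallest member
    comp_idx = tuple(sorted(comp_idx, key=lambda c: c[0]))
    return MRFStructure(Q=Q.tocsr(), degrees=deg, n_components=len(comps), components=comp_idx)
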