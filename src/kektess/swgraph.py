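"""Strength-weighted graphs and their distance primitives.

A strength-weighted graph G_sw = (G, (w_v, s_v), s_e) is a simple connected
graph G together with three non-negative weight maps: a vertex weight w_v,
a vertex strength s_v, and an edge strength s_e.  The *plain profile*
(w_v = 1, s_v = 0, s_e = 1) recovers the ordinary molecular graph, and every
distance-based index computed from a plain-profile graph equals its classical
value.  The point of the generalisation is quotient reduction: when a graph is
contracted along an edge-cut, the lost interior structure is folded into the
vertex strengths and edge strengths of the quotient, so that index
computations on the (much smaller) quotient remain exact.

Distances are always *unweighted* shortest-path edge counts; strengths and
weights never affect distances.  All weight arithmetic is exact: weights are
Python ints or :class:`fractions.Fraction`; floating point is never used in
the computation path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as _sp
from scipy.sparse.csgraph import connected_components as _cc
from scipy.sparse.csgraph import shortest_path as _shortest_path

Number = int | Fraction

__all__ = [
    "StrengthWeightedGraph",
    "ClosenessRecord",
    "DisconnectedGraphError",
    "all_pairs_distances",
    "vertex_edge_distance",
    "edge_edge_distance",
    "closeness_cardinalities",
    "swg_degree",
]


class DisconnectedGraphError(ValueError):
    """Raised when a connected graph is required; names the components."""

    def __init__(self, components: Sequence[Sequence[int]]):
        self.components = [sorted(c) for c in components]
        preview = "; ".join(
            "{" + ", ".join(map(str, c[:8])) + (", ..." if len(c) > 8 else "") + "}"
            for c in self.components[:4]
        )
        more = "" if len(self.components) <= 4 else f" (+{len(self.components) - 4} more)"
        super().__init__(
            f"graph is disconnected: {len(self.components)} components: {preview}{more}"
        )


def _as_exact(x) -> Number:
    """Coerce a weight to an exact number; reject floats."""
    if isinstance(x, (int, np.integer)):
        return int(x)
    if isinstance(x, Fraction):
        return x
    raise TypeError(f"weights must be int or Fraction, got {type(x).__name__}: {x!r}")


def _norm_edge(e) -> tuple[int, int]:
    u, v = e
    u, v = int(u), int(v)
    if u == v:
        raise ValueError(f"loop edge ({u},{v}) not allowed")
    return (u, v) if u < v else (v, u)


class StrengthWeightedGraph:
    """A simple, connected, strength-weighted graph with dense 0-based vertices.

    Parameters
    ----------
    n_vertices
        Number of vertices; ids are ``0 .. n_vertices-1``.
    edges
        Iterable of vertex pairs.  Stored sorted (both within each pair and
        lexicographically across pairs) for deterministic iteration.
    wv, sv, se
        Optional weight maps (vertex -> weight, vertex -> strength,
        edge-pair -> strength).  Missing entries default to the plain
        profile: ``w_v = 1``, ``s_v = 0``, ``s_e = 1``.

    Notes
    -----
    The all-pairs distance table is computed lazily by breadth-first search
    (graphs here are unweighted and sparse) and cached on the instance.
    """

    def __init__(
        self,
        n_vertices: int,
        edges: Iterable[tuple[int, int]],
        wv: Mapping[int, Number] | None = None,
        sv: Mapping[int, Number] | None = None,
        se: Mapping[tuple[int, int], Number] | None = None,
    ):
        n = int(n_vertices)
        if n <= 0:
            raise ValueError("graph must have at least one vertex")
        es = sorted({_norm_edge(e) for e in edges})
        for u, v in es:
            if not (0 <= u < n and 0 <= v < n):
                raise ValueError(f"edge ({u},{v}) out of range for {n} vertices")
        self.n = n
        self.edges: tuple[tuple[int, int], ...] = tuple(es)
        self.wv = {u: _as_exact((wv or {}).get(u, 1)) for u in range(n)}
        self.sv = {u: _as_exact((sv or {}).get(u, 0)) for u in range(n)}
        self.se = {e: _as_exact((se or {}).get(e, 1)) for e in self.edges}
        for d in (self.wv, self.sv):
            for u, x in d.items():
                if x < 0:
                    raise ValueError(f"negative weight/strength at vertex {u}")
        for e, x in self.se.items():
            if x < 0:
                raise ValueError(f"negative edge strength at {e}")
        self._edge_index = {e: i for i, e in enumerate(self.edges)}
        self._adj = self._build_adjacency()
        self._require_connected()
        self._dist: np.ndarray | None = None

    # -- construction helpers -------------------------------------------------

    @classmethod
    def plain(cls, n_vertices: int, edges: Iterable[tuple[int, int]]) -> "StrengthWeightedGraph":
        """Plain-profile graph (w_v = 1, s_v = 0, s_e = 1)."""
        return cls(n_vertices, edges)

    # -- basic structure ------------------------------------------------------

    @property
    def vertices(self) -> range:
        return range(self.n)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def has_edge(self, e) -> bool:
        return _norm_edge(e) in self._edge_index

    def edge_id(self, e) -> int:
        key = _norm_edge(e)
        try:
            return self._edge_index[key]
        except KeyError:
            raise KeyError(f"edge {key} not in graph") from None

    def neighbors(self, u: int) -> tuple[int, ...]:
        self._check_vertex(u)
        return self._neigh[u]

    def is_plain(self) -> bool:
        return (
            all(x == 1 for x in self.wv.values())
            and all(x == 0 for x in self.sv.values())
            and all(x == 1 for x in self.se.values())
        )

    def integer_weighted(self) -> bool:
        return (
            all(isinstance(x, int) for x in self.wv.values())
            and all(isinstance(x, int) for x in self.sv.values())
            and all(isinstance(x, int) for x in self.se.values())
        )

    def total_vertex_weight(self) -> Number:
        return sum(self.wv.values())

    def _check_vertex(self, u):
        if not (isinstance(u, (int, np.integer)) and 0 <= u < self.n):
            raise KeyError(f"vertex {u!r} not in graph (ids are 0..{self.n - 1})")

    def _build_adjacency(self) -> _sp.csr_matrix:
        neigh: list[list[int]] = [[] for _ in range(self.n)]
        for u, v in self.edges:
            neigh[u].append(v)
            neigh[v].append(u)
        self._neigh = tuple(tuple(sorted(ns)) for ns in neigh)
        if self.edges:
            rows = np.fromiter(
                (u for e in self.edges for u in e), dtype=np.int64, count=2 * len(self.edges)
            )
            cols = np.fromiter(
                (u for (a, b) in self.edges for u in (b, a)),
                dtype=np.int64,
                count=2 * len(self.edges),
            )
        else:
            rows = cols = np.empty(0, dtype=np.int64)
        data = np.ones(len(rows), dtype=np.int8)
        return _sp.csr_matrix((data, (rows, cols)), shape=(self.n, self.n))

    def _require_connected(self):
        ncomp, labels = _cc(self._adj, directed=False)
        if ncomp > 1:
            comps = [np.nonzero(labels == k)[0].tolist() for k in range(ncomp)]
            raise DisconnectedGraphError(comps)

    # -- distances ------------------------------------------------------------

    def distance_matrix(self) -> np.ndarray:
        """All-pairs shortest-path edge counts as an int32 array (cached)."""
        if self._dist is None:
            D = _shortest_path(self._adj, method="D", unweighted=True)
            self._dist = D.astype(np.int32)
        return self._dist

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        tag = "plain" if self.is_plain() else "weighted"
        return f"StrengthWeightedGraph(n={self.n}, m={self.n_edges}, {tag})"


@dataclass(frozen=True)
class ClosenessRecord:
    """Closeness cardinalities of one edge e = uv.

    ``n_u`` sums w_v over vertices strictly nearer u than v, ``m_u`` sums s_v
    over those vertices plus s_e over edges strictly nearer u, and
    ``t_u = n_u + m_u``; symmetrically for v.  Equidistant vertices and edges
    belong to neither side.
    """

    edge: tuple[int, int]
    n_u: Number
    n_v: Number
    m_u: Number
    m_v: Number
    t_u: Number = field(init=False)
    t_v: Number = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "t_u", self.n_u + self.m_u)
        object.__setattr__(self, "t_v", self.n_v + self.m_v)


def all_pairs_distances(swg: StrengthWeightedGraph) -> np.ndarray:
    """Return the (cached) all-pairs distance table of *swg*.

    Entry (u, v) is the number of edges on a shortest u-v path; the table is
    symmetric with zero diagonal.  Strengths and weights play no role.
    """
    return swg.distance_matrix()


def vertex_edge_distance(swg: StrengthWeightedGraph, u: int, f) -> int:
    """d(u, f) = min(d(u, x), d(u, y)) for the edge f = xy; 0 iff u in f."""
    swg._check_vertex(u)
    x, y = _norm_edge(f)
    if not swg.has_edge((x, y)):
        raise KeyError(f"edge ({x},{y}) not in graph")
    D = swg.distance_matrix()
    return int(min(D[u, x], D[u, y]))


def edge_edge_distance(swg: StrengthWeightedGraph, e, f) -> int:
    """D(e, f) = min over endpoints of e of the vertex-edge distance to f.

    This is the min-endpoint convention: D(e, e) = 0 and edges sharing a
    vertex are at distance 0 (not the line-graph convention).
    """
    u, v = _norm_edge(e)
    if not swg.has_edge((u, v)):
        raise KeyError(f"edge ({u},{v}) not in graph")
    return min(vertex_edge_distance(swg, u, f), vertex_edge_distance(swg, v, f))


def closeness_cardinalities(swg: StrengthWeightedGraph, e) -> ClosenessRecord:
    """Weighted closeness cardinalities n/m/t of both sides of edge e = uv."""
    u, v = _norm_edge(e)
    if not swg.has_edge((u, v)):
        raise KeyError(f"edge ({u},{v}) not in graph")
    D = swg.distance_matrix()
    du, dv = D[u], D[v]
    n_u = sum(swg.wv[int(x)] for x in np.nonzero(du < dv)[0])
    n_v = sum(swg.wv[int(x)] for x in np.nonzero(dv < du)[0])
    m_u = sum(swg.sv[int(x)] for x in np.nonzero(du < dv)[0])
    m_v = sum(swg.sv[int(x)] for x in np.nonzero(dv < du)[0])
    for f in swg.edges:
        dfu = min(du[f[0]], du[f[1]])
        dfv = min(dv[f[0]], dv[f[1]])
        if dfu < dfv:
            m_u += swg.se[f]
        elif dfv < dfu:
            m_v += swg.se[f]
    return ClosenessRecord(edge=(u, v), n_u=n_u, n_v=n_v, m_u=m_u, m_v=m_v)


def swg_degree(swg: StrengthWeightedGraph, u: int) -> Number:
    """Strength-weighted degree: sum of incident edge strengths."""
    swg._check_vertex(u)
    total: Number = 0
    for x in swg.neighbors(u):
        total += swg.se[_norm_edge((u, x))]
    return total
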