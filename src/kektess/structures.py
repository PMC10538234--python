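"""Generators for kekulene and the rectangular kekulene tessellations RK(m,n).

Kekulene is the doughnut-shaped cycloarene C48H24: twelve benzene rings fused
into a closed macrocycle.  On the hexagonal lattice its carbon skeleton is
the union of the 12 cells at cell-distance exactly 2 from a central cell
("crown"), giving 48 atoms and 60 bonds around a coronene-shaped cavity.

The rectangular tessellations arrange m x n kekulene units in a mesh:

* a **row** fuses m units through shared catacondensed chains of 3 hexagons
  (unit centers 4 cells apart), so a row has 34m+14 atoms;
* consecutive rows sit one cell-layer apart and are joined by one bridging
  hexagon above each unit center;
* **Type-I** additionally caps one end of every row junction with a hook of
  5 hexagons (18 atoms / 24 bonds), giving |V| = 36mn-2m+32n-18 and
  |E| = 48mn+40n-4m-24;
* **Type-II** caps both ends of every junction (the second hook is the
  point-inversion image of the first), giving |V| = 36mn+50n-2m-36 and
  |E| = 48mn+64n-4m-48.

This geometry is the unique one (up to isomorphism) that satisfies the
vertex/edge count formulas together with the published integer values of all
ten distance-based indices; it was pinned down against those oracles, not
read off a figure.

Cells use axial coordinates (q, r); atoms live on the honeycomb vertex
lattice in an integer *doubled* coordinate scheme, so atoms shared between
fused hexagons deduplicate by exact equality (no floating point).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .swgraph import StrengthWeightedGraph

__all__ = [
    "MolecularGraph",
    "build_kekulene",
    "build_rk",
    "fixture_graph",
    "vertex_count",
    "edge_count",
]

# axial neighbour directions on the hexagonal cell lattice
_AX_DIRS = ((1, 0), (0, 1), (-1, 1), (-1, 0), (0, -1), (1, -1))

# the 12 cells at cell-distance exactly 2 from the origin
_CROWN = (
    (2, 0), (1, 1), (0, 2), (-1, 2), (-2, 2), (-2, 1),
    (-2, 0), (-1, -1), (0, -2), (1, -2), (2, -2), (2, -1),
)

# row axis: consecutive unit centers; rows share a 3-hexagon chain
_ROW_STEP = (4, -2)
# stacking offset between consecutive rows
_ROW_OFFSET = (0, 6)
# junction hook: 5 extra hexagons capping one end of a row junction
_HOOK = ((-4, 4), (-4, 5), (-4, 6), (-3, 3), (-3, 6))


@dataclass(frozen=True)
class MolecularGraph:
    """Carbon skeleton on exact lattice coordinates.

    ``coords[i]`` is the doubled-coordinate position (X, Y) of atom i; the
    Euclidean embedding with unit bond length is (X*sqrt(3)/2, Y/2).
    Vertex ids are dense and ordered lexicographically by (X, Y).
    """

    n: int
    edges: tuple[tuple[int, int], ...]
    coords: tuple[tuple[int, int], ...]
    meta: dict = field(default_factory=dict, compare=False)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degree_histogram(self) -> dict[int, int]:
        deg = [0] * self.n
        for u, v in self.edges:
            deg[u] += 1
            deg[v] += 1
        hist: dict[int, int] = {}
        for d in deg:
            hist[d] = hist.get(d, 0) + 1
        return dict(sorted(hist.items()))

    def is_bipartite(self) -> bool:
        color = [-1] * self.n
        adj: list[list[int]] = [[] for _ in range(self.n)]
        for u, v in self.edges:
            adj[u].append(v)
            adj[v].append(u)
        for s in range(self.n):
            if color[s] >= 0:
                continue
            color[s] = 0
            stack = [s]
            while stack:
                u = stack.pop()
                for v in adj[u]:
                    if color[v] < 0:
                        color[v] = 1 - color[u]
                        stack.append(v)
                    elif color[v] == color[u]:
                        return False
        return True

    def to_swg(self) -> StrengthWeightedGraph:
        """Plain-profile strength-weighted view (w_v=1, s_v=0, s_e=1)."""
        return StrengthWeightedGraph.plain(self.n, self.edges)


# ----------------------------------------------------------------------------
# cell-level construction


def _cell_corners(cell: tuple[int, int]) -> list[tuple[int, int]]:
    """Six atom positions of one hexagonal cell, in doubled coordinates."""
    q, r = cell
    X, Y = 2 * q + r, 3 * r
    return [
        (X, Y + 2), (X + 1, Y + 1), (X + 1, Y - 1),
        (X, Y - 2), (X - 1, Y - 1), (X - 1, Y + 1),
    ]


def _cells_to_graph(cells: Iterable[tuple[int, int]], meta: dict) -> MolecularGraph:
    """Union of hexagonal cells -> deduplicated atom graph, deterministic ids."""
    edge_set: set[tuple[tuple[int, int], tuple[int, int]]] = set()
    atoms: set[tuple[int, int]] = set()
    for cell in cells:
        cor = _cell_corners(cell)
        atoms.update(cor)
        for i in range(6):
            a, b = cor[i], cor[(i + 1) % 6]
            edge_set.add((a, b) if a < b else (b, a))
    order = sorted(atoms)
    index = {p: i for i, p in enumerate(order)}
    edges = sorted(
        (index[a], index[b]) if index[a] < index[b] else (index[b], index[a])
        for a, b in edge_set
    )
    return MolecularGraph(n=len(order), edges=tuple(edges), coords=tuple(order), meta=meta)


def _crown(center: tuple[int, int]) -> list[tuple[int, int]]:
    cq, cr = center
    return [(cq + q, cr + r) for q, r in _CROWN]


def _rk_cells(type_: str, m: int, n: int) -> set[tuple[int, int]]:
    cells: set[tuple[int, int]] = set()
    for j in range(n):
        oq, orr = j * _ROW_OFFSET[0], j * _ROW_OFFSET[1]
        for k in range(m):
            cells.update(_crown((oq + _ROW_STEP[0] * k, orr + _ROW_STEP[1] * k)))
        if j + 1 < n:
            # bridging hexagon above each unit center of row j
            for k in range(m):
                cells.add((oq + 4 * k, orr - 2 * k + 3))
            # junction hooks
            for q, r in _HOOK:
                cells.add((q, r + orr))
                if type_ == "II":
                    # point-inversion image at the opposite junction end
                    cells.add((4 * (m - 1) - q, -2 * (m - 1) + 6 - r + orr))
    return cells


def vertex_count(type_: str, m: int, n: int) -> int:
    """Closed-form atom count of RK(m, n)."""
    if type_ == "I":
        return 36 * m * n - 2 * m + 32 * n - 18
    if type_ == "II":
        return 36 * m * n + 50 * n - 2 * m - 36
    raise ValueError(f"unknown tessellation type {type_!r} (expected 'I' or 'II')")


def edge_count(type_: str, m: int, n: int) -> int:
    """Closed-form bond count of RK(m, n)."""
    if type_ == "I":
        return 48 * m * n + 40 * n - 4 * m - 24
    if type_ == "II":
        return 48 * m * n + 64 * n - 4 * m - 48
    raise ValueError(f"unknown tessellation type {type_!r} (expected 'I' or 'II')")


def build_rk(type_: str, m: int, n: int) -> MolecularGraph:
    """Rectangular kekulene tessellation RK(m, n) of the given type.

    Parameters
    ----------
    type_
        ``"I"`` or ``"II"``.  At n = 1 the two types coincide (a single row
        has no junctions) and RK(1, 1) is the kekulene unit itself.
    m, n
        Number of unit columns and rows; both must be >= 1.

    The returned graph is simple, connected and bipartite, every atom has
    degree 2 or 3, and the atom/bond counts satisfy the closed-form count
    formulas (asserted here for every build).
    """
    type_ = str(type_).upper()
    if type_ not in ("I", "II"):
        raise ValueError(f"unknown tessellation type {type_!r} (expected 'I' or 'II')")
    if not (isinstance(m, int) and isinstance(n, int)) or m < 1 or n < 1:
        raise ValueError(f"m and n must be positive integers, got m={m!r}, n={n!r}")
    g = _cells_to_graph(
        _rk_cells(type_, m, n), meta={"family": f"RK-{type_}", "m": m, "n": n}
    )
    assert g.n == vertex_count(type_, m, n), "internal: vertex count formula violated"
    assert g.n_edges == edge_count(type_, m, n), "internal: edge count formula violated"
    return g


def build_kekulene() -> MolecularGraph:
    """The kekulene unit: carbon skeleton of C48H24 (48 atoms, 60 bonds)."""
    g = _cells_to_graph(_crown((0, 0)), meta={"family": "kekulene", "m": 1, "n": 1})
    return g


# ----------------------------------------------------------------------------
# small oracle fixtures


def _linear_chain_cells(h: int) -> list[tuple[int, int]]:
    # catacondensed chain of h hexagons fused along a straight line
    return [(q, 0) for q in range(h)]


def fixture_graph(name: str) -> MolecularGraph:
    """Named small graphs used as test oracles.

    Recognised names: ``edge``, ``path_k``, ``cycle_k`` (k >= 3),
    ``hexagon``, ``linear_chain_h`` (catacondensed chain of h hexagons),
    ``kekulene``.
    """
    if name == "edge":
        return MolecularGraph(2, ((0, 1),), ((0, 0), (1, 0)), {"family": "fixture"})
    if name == "hexagon":
        return _cells_to_graph([(0, 0)], {"family": "fixture"})
    if name == "kekulene":
        return build_kekulene()
    if name.startswith("path_"):
        k = int(name.split("_", 1)[1])
        if k < 2:
            raise ValueError("path needs at least 2 vertices")
        return MolecularGraph(
            k,
            tuple((i, i + 1) for i in range(k - 1)),
            tuple((i, 0) for i in range(k)),
            {"family": "fixture"},
        )
    if name.startswith("cycle_"):
        k = int(name.split("_", 1)[1])
        if k < 3:
            raise ValueError("cycle needs at least 3 vertices")
        edges = tuple(sorted(tuple(sorted((i, (i + 1) % k))) for i in range(k)))
        return MolecularGraph(k, edges, tuple((i, 0) for i in range(k)), {"family": "fixture"})
    if name.startswith("linear_chain_"):
        h = int(name.split("linear_chain_", 1)[1])
        if h < 1:
            raise ValueError("chain needs at least 1 hexagon")
        return _cells_to_graph(_linear_chain_cells(h), {"family": "fixture", "h": h})
    raise ValueError(
        f"unknown fixture {name!r}; choose from: edge, path_k, cycle_k, hexagon, "
        "linear_chain_h, kekulene"
    )
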