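"""Djokovic-Winkler relation, Theta* partition, quotient graphs, cut method.

Two edges e = uv and f = cd stand in the Djokovic-Winkler relation Theta when
d(u,c) + d(v,d) != d(u,d) + d(v,c).  Theta is reflexive and symmetric but not
transitive; its transitive closure Theta* is an equivalence on the edge set.
For benzenoid and coronoid graphs every Theta*-class is an edge cut, and each
distance-based index of the whole graph equals the sum, over classes, of the
same index evaluated on the class's strength-weighted quotient graph.  That
decomposition is the *cut method*; this module treats it as an empirically
asserted contract (checked against direct computation), never as a theorem
the code relies on.

The quotient G/F of a class F has the connected components of G - F as
vertices; component weights/strengths absorb the interior structure
(w = sum of vertex weights, s = sum of vertex strengths plus strengths of
interior edges) and a quotient edge bundles all class edges between two
components, with strength equal to their total strength.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import indices as _indices
from .indices import INDEX_NAMES, Number
from .swgraph import StrengthWeightedGraph

__all__ = [
    "EdgeClassPartition",
    "QuotientSWG",
    "ClassSignature",
    "theta_star_partition",
    "quotient_swg",
    "index_via_cuts",
    "cuts_compute_all",
    "class_signature_report",
]


@dataclass(frozen=True)
class EdgeClassPartition:
    """The Theta*-partition F = {F_1, ..., F_r} of the edge set.

    Classes are ordered by their lexicographically smallest edge, and edges
    within a class are sorted, so the partition is deterministic.
    """

    classes: tuple[tuple[tuple[int, int], ...], ...]

    def __len__(self) -> int:
        return len(self.classes)

    def __iter__(self):
        return iter(self.classes)

    def __getitem__(self, i):
        return self.classes[i]


@dataclass(frozen=True)
class QuotientSWG:
    """Strength-weighted quotient graph G/F with its component map."""

    swg: StrengthWeightedGraph
    component_map: tuple[tuple[int, ...], ...]  # quotient vertex -> original vertices


@dataclass(frozen=True)
class ClassSignature:
    """Geometry-free summary of one Theta*-class: the sorted multiset of
    (weight, strength) pairs over quotient vertices plus the total cut
    strength.  Comparable against published quotient tables without relying
    on figure orientation."""

    class_id: int
    components: tuple[tuple[Number, Number], ...]
    cut_strength: Number


class _UnionFind:
    __slots__ = ("parent",)

    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        p = self.parent
        while p[x] != x:
            p[x] = p[p[x]]
            x = p[x]
        return x

    def union(self, a: int, b: int):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def theta_star_partition(swg: StrengthWeightedGraph) -> EdgeClassPartition:
    """Compute the Theta*-partition by the pairwise Theta test + union-find.

    The test runs over all O(|E|^2) edge pairs on the cached distance table;
    no lattice-specific shortcut is assumed.
    """
    D = swg.distance_matrix()
    edges = swg.edges
    E = len(edges)
    eu = np.fromiter((e[0] for e in edges), dtype=np.int64, count=E)
    ev = np.fromiter((e[1] for e in edges), dtype=np.int64, count=E)
    uf = _UnionFind(E)
    Du = D[eu, :]  # E x N
    Dv = D[ev, :]
    for i in range(E - 1):
        # Theta: d(u,c)+d(v,d) != d(u,d)+d(v,c) for edges f=cd with index > i
        lhs = Du[i, eu[i + 1:]] + Dv[i, ev[i + 1:]]
        rhs = Du[i, ev[i + 1:]] + Dv[i, eu[i + 1:]]
        for j in np.nonzero(lhs != rhs)[0]:
            uf.union(i, i + 1 + int(j))
    groups: dict[int, list[int]] = {}
    for i in range(E):
        groups.setdefault(uf.find(i), []).append(i)
    classes = sorted(
        (tuple(edges[i] for i in sorted(g)) for g in groups.values()),
        key=lambda cl: cl[0],
    )
    return EdgeClassPartition(tuple(classes))


def quotient_swg(
    swg: StrengthWeightedGraph, cls: Sequence[tuple[int, int]]
) -> QuotientSWG:
    """Strength-weighted quotient of *swg* by the edge class *cls*.

    Raises ``ValueError`` if removing the class does not disconnect every
    class edge's endpoints (i.e. the class is not a cut).
    """
    cut = {tuple(sorted(e)) for e in cls}
    unknown = cut - set(swg.edges)
    if unknown:
        raise ValueError(f"class contains edges not in the graph: {sorted(unknown)[:5]}")
    uf = _UnionFind(swg.n)
    for e in swg.edges:
        if e not in cut:
            uf.union(*e)
    roots: dict[int, int] = {}
    comp_vertices: list[list[int]] = []
    for u in range(swg.n):
        r = uf.find(u)
        if r not in roots:
            roots[r] = len(comp_vertices)
            comp_vertices.append([])
        comp_vertices[roots[r]].append(u)
    k = len(comp_vertices)
    if k < 2:
        raise ValueError("edge class is not a cut: removal leaves the graph connected")
    comp_of = [uf.find(u) for u in range(swg.n)]
    comp_of = [roots[r] for r in comp_of]

    wv = {c: sum(swg.wv[u] for u in comp_vertices[c]) for c in range(k)}
    sv = {c: sum(swg.sv[u] for u in comp_vertices[c]) for c in range(k)}
    for e in swg.edges:
        if e not in cut:
            sv[comp_of[e[0]]] += swg.se[e]
    se: dict[tuple[int, int], Number] = {}
    for e in sorted(cut):
        a, b = comp_of[e[0]], comp_of[e[1]]
        if a == b:
            raise ValueError(
                f"edge class is not a cut: class edge {e} joins one component"
            )
        key = (a, b) if a < b else (b, a)
        se[key] = se.get(key, 0) + swg.se[e]
    q = StrengthWeightedGraph(k, se.keys(), wv=wv, sv=sv, se=se)
    return QuotientSWG(swg=q, component_map=tuple(tuple(c) for c in comp_vertices))


def cuts_compute_all(
    swg: StrengthWeightedGraph, partition: EdgeClassPartition | None = None
) -> dict[str, Number]:
    """All ten indices as sums of quotient contributions over Theta*-classes."""
    if partition is None:
        partition = theta_star_partition(swg)
    totals: dict[str, Number] = {name: 0 for name in INDEX_NAMES}
    for cls in partition:
        q = quotient_swg(swg, cls).swg
        # degree_mass: a contracted component's Schultz/Gutman degree is
        # d + 2 s_v (interior edges count twice in its total degree)
        for name, val in _indices.compute_all(q, degree_mass=True).items():
            totals[name] = totals[name] + val
    return totals


def index_via_cuts(
    swg: StrengthWeightedGraph,
    index_name: str,
    partition: EdgeClassPartition | None = None,
) -> Number:
    """One index via the cut decomposition (see :func:`cuts_compute_all`)."""
    if index_name not in INDEX_NAMES:
        raise ValueError(f"unknown index {index_name!r}; choose from {INDEX_NAMES}")
    return cuts_compute_all(swg, partition)[index_name]


def class_signature_report(
    swg: StrengthWeightedGraph, partition: EdgeClassPartition | None = None
) -> list[ClassSignature]:
    """Per-class (weight, strength) component signatures plus cut strengths."""
    if partition is None:
        partition = theta_star_partition(swg)
    out = []
    for i, cls in enumerate(partition):
        q = quotient_swg(swg, cls)
        comps = tuple(
            sorted((q.swg.wv[c], q.swg.sv[c]) for c in range(q.swg.n))
        )
        cut = sum(swg.se[tuple(sorted(e))] for e in cls)
        out.append(ClassSignature(class_id=i, components=comps, cut_strength=cut))
    return out


def signatures_to_frame(report: list[ClassSignature]):
    """Signature report as a pandas DataFrame (CSV-ready)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "class_id": [r.class_id for r in report],
            "component_weights": [
                " ".join(str(w) for w, _ in r.components) for r in report
            ],
            "component_strengths": [
                " ".join(str(s) for _, s in r.components) for r in report
            ],
            "cut_strength": [str(r.cut_strength) for r in report],
        }
    )
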