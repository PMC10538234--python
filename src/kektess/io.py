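"""Readers and writers for graph formats and run configuration.

Formats
-------
* SWG JSON: ``{"vertices": [...], "edges": [[u,v],...], "wv": {...},
  "sv": {...}, "se": {...}}``; absent weight maps default to the plain
  profile.  Edge strengths are keyed ``"u-v"`` with u < v.
* Edge-list TSV: two integer columns (header optional), plain graphs only.
* GraphML via networkx; SDF/MOL V2000 export with 2D unit-bond coordinates
  (visualisation only, never re-imported for computation).

All outputs are byte-stable across runs: vertices and edges are written in
sorted order and numbers in plain decimal (no separators, no exponents).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import networkx as nx
import yaml

from .structures import MolecularGraph
from .swgraph import StrengthWeightedGraph

__all__ = [
    "RunConfig",
    "load_config",
    "read_graph",
    "read_swg_json",
    "read_edgelist_tsv",
    "write_swg_json",
    "write_edgelist_tsv",
    "write_graphml",
    "write_molfile",
]


def _num_to_json(x):
    if isinstance(x, Fraction):
        return str(x)
    return x


def _num_from_json(x):
    if isinstance(x, str):
        return Fraction(x) if "/" in x else int(x)
    if isinstance(x, bool) or not isinstance(x, int):
        raise TypeError(f"weights must be exact integers or 'p/q' strings, got {x!r}")
    return x


def write_swg_json(swg: StrengthWeightedGraph, path: str | Path) -> None:
    doc = {
        "vertices": list(range(swg.n)),
        "edges": [list(e) for e in swg.edges],
    }
    if not swg.is_plain():
        doc["wv"] = {str(u): _num_to_json(swg.wv[u]) for u in range(swg.n)}
        doc["sv"] = {str(u): _num_to_json(swg.sv[u]) for u in range(swg.n)}
        doc["se"] = {f"{u}-{v}": _num_to_json(swg.se[(u, v)]) for u, v in swg.edges}
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def read_swg_json(path: str | Path) -> StrengthWeightedGraph:
    doc = json.loads(Path(path).read_text())
    verts = sorted(int(v) for v in doc["vertices"])
    remap = {v: i for i, v in enumerate(verts)}
    edges = [(remap[int(u)], remap[int(v)]) for u, v in doc["edges"]]
    wv = {remap[int(k)]: _num_from_json(x) for k, x in doc.get("wv", {}).items()}
    sv = {remap[int(k)]: _num_from_json(x) for k, x in doc.get("sv", {}).items()}
    se = {}
    for k, x in doc.get("se", {}).items():
        u, v = (int(t) for t in k.split("-"))
        u, v = remap[u], remap[v]
        se[(u, v) if u < v else (v, u)] = _num_from_json(x)
    return StrengthWeightedGraph(len(verts), edges, wv=wv, sv=sv, se=se)


def write_edgelist_tsv(graph: MolecularGraph | StrengthWeightedGraph, path: str | Path) -> None:
    lines = [f"{u}\t{v}" for u, v in graph.edges]
    Path(path).write_text("\n".join(lines) + "\n")


def read_edgelist_tsv(path: str | Path) -> StrengthWeightedGraph:
    """Plain graph from a two-column TSV; arbitrary integer ids are
    relabelled to dense 0-based ids in sorted order."""
    pairs = []
    for ln in Path(path).read_text().splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        parts = ln.split()
        if not all(p.lstrip("-").isdigit() for p in parts[:2]):
            continue  # header line
        pairs.append((int(parts[0]), int(parts[1])))
    if not pairs:
        raise ValueError(f"no edges found in {path}")
    ids = sorted({u for e in pairs for u in e})
    remap = {v: i for i, v in enumerate(ids)}
    return StrengthWeightedGraph.plain(len(ids), [(remap[u], remap[v]) for u, v in pairs])


def read_graph(path: str | Path, fmt: str | None = None) -> StrengthWeightedGraph:
    """Read a graph, inferring the format from the suffix when not given."""
    p = Path(path)
    fmt = fmt or {".json": "json", ".tsv": "tsv", ".txt": "tsv"}.get(p.suffix.lower())
    if fmt == "json":
        return read_swg_json(p)
    if fmt == "tsv":
        return read_edgelist_tsv(p)
    raise ValueError(f"cannot infer format of {path}; pass fmt='json' or 'tsv'")


def write_graphml(graph: MolecularGraph, path: str | Path) -> None:
    G = nx.Graph()
    for i in range(graph.n):
        X, Y = graph.coords[i]
        G.add_node(i, X=int(X), Y=int(Y))
    G.add_edges_from(graph.edges)
    nx.write_graphml(G, str(path))


def write_molfile(graph: MolecularGraph, path: str | Path, title: str = "") -> None:
    """MOL V2000 export with 2D coordinates scaled to unit bond length.

    All atoms are carbon and all bonds are written as single bonds; the file
    is for visualisation only.
    """
    s3 = math.sqrt(3.0) / 2.0
    lines = [title or graph.meta.get("family", "kektess"), "  kektess", ""]
    lines.append(
        f"{graph.n:>3}{graph.n_edges:>3}  0  0  0  0  0  0  0  0999 V2000"
    )
    for X, Y in graph.coords:
        lines.append(f"{X * s3:>10.4f}{Y * 0.5:>10.4f}{0.0:>10.4f} C   0  0  0  0  0  0  0  0  0  0  0  0")
    for u, v in graph.edges:
        lines.append(f"{u + 1:>3}{v + 1:>3}  1  0  0  0  0")
    lines.append("M  END")
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class RunConfig:
    """Configuration for one CLI run (flags or a YAML file).

    Exactly one of (``structure_type``, ``m``, ``n``) or ``input_path`` must
    be given; at least one method must be selected.
    """

    structure_type: str | None = None
    m: int | None = None
    n: int | None = None
    input_path: str | None = None
    input_format: str | None = None
    methods: tuple[str, ...] = ("direct",)
    output: str | None = None
    verbosity: int = 0
    seed: int = 0  # fixed iteration seed for property-style spot checks

    def __post_init__(self):
        has_struct = self.structure_type is not None
        if has_struct == (self.input_path is not None):
            raise ValueError("give either a structure spec (type, m, n) or an input file, not both")
        if has_struct and (self.m is None or self.n is None):
            raise ValueError("structure spec needs type, m and n")
        if not self.methods:
            raise ValueError("select at least one method")
        bad = set(self.methods) - {"direct", "cuts", "closed_form"}
        if bad:
            raise ValueError(f"unknown methods: {sorted(bad)}")


def load_config(path: str | Path) -> RunConfig:
    doc = yaml.safe_load(Path(path).read_text()) or {}
    if "methods" in doc and isinstance(doc["methods"], (list, tuple)):
        doc["methods"] = tuple(doc["methods"])
    return RunConfig(**doc)
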