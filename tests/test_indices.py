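"""The ten indices against independent brute-force oracles and invariants."""

import itertools
from fractions import Fraction

import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kektess import (
    INDEX_NAMES,
    StrengthWeightedGraph,
    compute_all,
    edge_wiener,
    fixture_graph,
    padmakar_ivan,
    schultz_gutman,
    szeged_indices,
    vertex_edge_wiener,
    wiener,
)


def _oracle_plain(n, edges):
    """Definition-level re-computation with plain python loops (test oracle,
    independent of the vectorised implementation path)."""
    G = nx.Graph(edges)
    G.add_nodes_from(range(n))
    d = dict(nx.all_pairs_shortest_path_length(G))
    dve = lambda u, f: min(d[u][f[0]], d[u][f[1]])
    dee = lambda e, f: min(dve(e[0], f), dve(e[1], f))
    W = sum(d[u][v] for u, v in itertools.combinations(range(n), 2))
    We = sum(dee(e, f) for e, f in itertools.combinations(edges, 2))
    Wve = Fraction(sum(dve(u, f) for u in range(n) for f in edges), 2)
    Szv = Sze = PI = 0
    Szev = Fraction(0)
    for e in edges:
        u, v = e
        nu = sum(1 for x in range(n) if d[x][u] < d[x][v])
        nv = sum(1 for x in range(n) if d[x][v] < d[x][u])
        mu = sum(1 for f in edges if dve(u, f) < dve(v, f))
        mv = sum(1 for f in edges if dve(v, f) < dve(u, f))
        Szv += nu * nv
        Sze += mu * mv
        Szev += Fraction(nu * mv + nv * mu, 2)
        PI += mu + mv
    S = sum(
        (G.degree(u) + G.degree(v)) * d[u][v]
        for u, v in itertools.combinations(range(n), 2)
    )
    Gut = sum(
        G.degree(u) * G.degree(v) * d[u][v]
        for u, v in itertools.combinations(range(n), 2)
    )
    return dict(W=W, We=We, Wve=Wve, Szv=Szv, Sze=Sze, Szev=Szev,
                Szt=Szv + Sze + 2 * Szev, PI=PI, S=S, Gut=Gut)


FIXTURES = ["edge", "path_3", "path_4", "cycle_5", "cycle_6", "hexagon",
            "linear_chain_2", "linear_chain_3"]


@pytest.mark.parametrize("name", FIXTURES)
def test_all_indices_match_bruteforce_oracle(name):
    g = fixture_graph(name)
    got = compute_all(g.to_swg())
    want = _oracle_plain(g.n, list(g.edges))
    for k in INDEX_NAMES:
        assert got[k] == want[k], (name, k)


@pytest.mark.parametrize(
    "name,expected",
    [
        ("edge", dict(W=1, We=0, Wve=0, Szv=1, Sze=0, Szev=0, Szt=1, PI=0, S=2, Gut=1)),
        ("hexagon", dict(W=27, We=12, Wve=18, Szv=54, Sze=24, Szev=36, Szt=150,
                         PI=24, S=108, Gut=108)),
    ],
)
def test_frozen_examples(name, expected):
    got = compute_all(fixture_graph(name).to_swg())
    assert {k: got[k] for k in expected} == expected


def test_wiener_agrees_with_networkx():
    for name in FIXTURES:
        g = fixture_graph(name)
        G = nx.Graph(list(g.edges))
        assert wiener(g.to_swg()) == round(nx.wiener_index(G))


def test_szt_identity_plain_and_weighted():
    for name in FIXTURES:
        sz = szeged_indices(fixture_graph(name).to_swg())
        assert sz.Szt == sz.Szv + sz.Sze + 2 * sz.Szev
    weighted = StrengthWeightedGraph(
        3, [(0, 1), (1, 2)], wv={0: 3}, sv={1: 2}, se={(0, 1): Fraction(5, 2)}
    )
    sz = szeged_indices(weighted)
    assert sz.Szt == sz.Szv + sz.Sze + 2 * sz.Szev


def test_vertex_transitive_cycles_schultz_gutman():
    # constant degree k=2: S = 2k W and Gut = k^2 W
    for name in ("cycle_5", "cycle_6", "cycle_8"):
        swg = fixture_graph(name).to_swg()
        W = wiener(swg)
        S, Gut = schultz_gutman(swg)
        assert S == 4 * W and Gut == 4 * W


def test_weighted_quotient_style_graph():
    # two-vertex quotient of the 6-cycle: w=3, s_v=2 each, one edge s_e=2
    q = StrengthWeightedGraph(2, [(0, 1)], wv={0: 3, 1: 3}, sv={0: 2, 1: 2},
                              se={(0, 1): 2})
    assert wiener(q) == 9
    # We: sv-pair 2*2*1; no edge pair; both vertex-edge distances are 0
    assert edge_wiener(q) == 4
    # Wve: [(3*2 + 3*2)*1 + 0] / 2
    assert vertex_edge_wiener(q) == 6
    assert padmakar_ivan(q) == 2 * (2 + 2)


def test_fraction_weights_exact():
    swg = StrengthWeightedGraph(2, [(0, 1)], wv={0: Fraction(1, 2), 1: 3})
    assert wiener(swg) == Fraction(3, 2)


def test_plain_profile_reduction():
    g = fixture_graph("cycle_6")
    explicit = StrengthWeightedGraph(
        g.n, g.edges,
        wv={u: 1 for u in range(g.n)},
        sv={u: 0 for u in range(g.n)},
        se={e: 1 for e in g.edges},
    )
    assert compute_all(explicit) == compute_all(g.to_swg())


@settings(derandomize=True, max_examples=20)
@given(perm_seed=st.integers(0, 10**6), name=st.sampled_from(FIXTURES))
def test_relabeling_invariance(perm_seed, name):
    import random

    g = fixture_graph(name)
    rng = random.Random(perm_seed)
    perm = list(range(g.n))
    rng.shuffle(perm)
    edges = [(perm[u], perm[v]) for u, v in g.edges]
    assert compute_all(StrengthWeightedGraph.plain(g.n, edges)) == compute_all(g.to_swg())
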