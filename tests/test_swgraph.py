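"""Distance primitives and closeness cardinalities of strength-weighted graphs."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kektess import (
    DisconnectedGraphError,
    StrengthWeightedGraph,
    all_pairs_distances,
    build_rk,
    closeness_cardinalities,
    edge_edge_distance,
    fixture_graph,
    quotient_swg,
    swg_degree,
    theta_star_partition,
    vertex_edge_distance,
)


def _swg(name):
    return fixture_graph(name).to_swg()


class TestDistances:
    def test_single_edge(self):
        D = all_pairs_distances(_swg("edge"))
        assert D[0, 1] == 1 and D[0, 0] == 0

    def test_hexagon_opposite_vertices(self):
        D = all_pairs_distances(_swg("hexagon"))
        # a 6-cycle in lattice order is not label-ordered; check via eccentricity
        assert D.max() == 3
        assert (D == 3).sum() == 6  # each vertex has exactly one antipode

    def test_cycle_labelled(self):
        D = all_pairs_distances(_swg("cycle_6"))
        assert D[0, 3] == 3 and D[0, 2] == 2 and D[1, 5] == 2

    def test_table_symmetric_zero_diagonal(self):
        D = all_pairs_distances(_swg("cycle_7"))
        assert np.array_equal(D, D.T)
        assert np.trace(D) == 0

    def test_weights_do_not_affect_distances(self):
        g = fixture_graph("path_4")
        plain = g.to_swg()
        weighted = StrengthWeightedGraph(
            g.n, g.edges, wv={0: 7}, sv={1: 3}, se={(0, 1): 5}
        )
        assert np.array_equal(
            all_pairs_distances(plain), all_pairs_distances(weighted)
        )

    def test_disconnected_error_names_components(self):
        with pytest.raises(DisconnectedGraphError) as exc:
            StrengthWeightedGraph.plain(4, [(0, 1), (2, 3)])
        assert len(exc.value.components) == 2
        assert [0, 1] in exc.value.components

    @settings(derandomize=True, max_examples=25)
    @given(st.data())
    def test_triangle_inequality_random_graphs(self, data):
        k = data.draw(st.integers(4, 9))
        # random connected graph: spanning path + extra edges
        extra = data.draw(
            st.sets(
                st.tuples(st.integers(0, k - 1), st.integers(0, k - 1)).filter(
                    lambda e: e[0] != e[1]
                ),
                max_size=6,
            )
        )
        edges = [(i, i + 1) for i in range(k - 1)] + sorted(
            tuple(sorted(e)) for e in extra
        )
        D = all_pairs_distances(StrengthWeightedGraph.plain(k, edges))
        for u in range(k):
            for v in range(k):
                for x in range(k):
                    assert D[u, v] <= D[u, x] + D[x, v]


class TestVertexEdgeDistance:
    def test_endpoint_is_zero(self):
        swg = _swg("edge")
        assert vertex_edge_distance(swg, 0, (0, 1)) == 0

    def test_cycle6(self):
        swg = _swg("cycle_6")
        assert vertex_edge_distance(swg, 0, (2, 3)) == 2

    def test_path(self):
        swg = _swg("path_4")
        assert vertex_edge_distance(swg, 0, (2, 3)) == 2

    def test_unknown_vertex_or_edge(self):
        swg = _swg("path_4")
        with pytest.raises(KeyError):
            vertex_edge_distance(swg, 9, (0, 1))
        with pytest.raises(KeyError):
            vertex_edge_distance(swg, 0, (0, 2))


class TestEdgeEdgeDistance:
    def test_self_and_adjacent(self):
        swg = _swg("cycle_6")
        assert edge_edge_distance(swg, (0, 1), (0, 1)) == 0
        assert edge_edge_distance(swg, (0, 1), (1, 2)) == 0  # shared endpoint

    def test_opposite_edges(self):
        swg = _swg("cycle_6")
        assert edge_edge_distance(swg, (0, 1), (3, 4)) == 2


class TestCloseness:
    def test_single_edge(self):
        r = closeness_cardinalities(_swg("edge"), (0, 1))
        assert (r.n_u, r.n_v, r.m_u, r.m_v) == (1, 1, 0, 0)
        assert r.t_u == 1 and r.t_v == 1

    def test_cycle6_any_edge(self):
        swg = _swg("cycle_6")
        for e in swg.edges:
            r = closeness_cardinalities(swg, e)
            # opposite edge is equidistant, so only 2 edges per side
            assert (r.n_u, r.n_v, r.m_u, r.m_v) == (3, 3, 2, 2)

    def test_path3(self):
        r = closeness_cardinalities(_swg("path_3"), (0, 1))
        assert (r.n_u, r.n_v, r.m_u, r.m_v) == (1, 2, 0, 1)

    def test_fraction_weights_exact(self):
        g = fixture_graph("path_3")
        swg = StrengthWeightedGraph(
            g.n, g.edges, wv={0: Fraction(1, 2), 1: 1, 2: 1}, sv={2: Fraction(1, 3)}
        )
        r = closeness_cardinalities(swg, (0, 1))
        assert r.n_u == Fraction(1, 2)
        assert r.m_v == Fraction(1, 3) + 1  # far vertex strength + far edge

    def test_bipartite_vertex_split_is_total(self):
        swg = build_rk("I", 2, 2).to_swg()
        total = swg.total_vertex_weight()
        for e in swg.edges:
            r = closeness_cardinalities(swg, e)
            assert r.n_u + r.n_v == total


class TestDegree:
    def test_plain(self):
        assert swg_degree(_swg("edge"), 0) == 1
        swg = _swg("cycle_6")
        assert all(swg_degree(swg, u) == 2 for u in range(6))

    def test_quotient_of_cycle_class(self):
        swg = _swg("cycle_6")
        cls = theta_star_partition(swg)[0]
        q = quotient_swg(swg, cls).swg
        assert swg_degree(q, 0) == 2  # one quotient edge of strength 2

    def test_unknown_vertex(self):
        with pytest.raises(KeyError):
            swg_degree(_swg("edge"), 5)


class TestValidation:
    def test_rejects_loops(self):
        with pytest.raises(ValueError):
            StrengthWeightedGraph.plain(2, [(0, 0)])

    def test_rejects_negative_weights(self):
        with pytest.raises(ValueError):
            StrengthWeightedGraph(2, [(0, 1)], wv={0: -1})

    def test_rejects_float_weights(self):
        with pytest.raises(TypeError):
            StrengthWeightedGraph(2, [(0, 1)], wv={0: 0.5})
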