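"""Phenotype metrics: hand-computed nesting statistics, topological lengths,
closed-form geometric values, and the scaling/invariance laws."""

import numpy as np
import pytest

from veintop.decomposition import build_nesting_tree
from veintop.fixtures import (
    make_caterpillar,
    make_grid,
    make_hierarchical,
    make_ladder,
    make_tapered_path,
    with_widths,
)
from veintop.metrics import (
    UndefinedMetricError,
    fingerprint,
    geometric_metrics,
    mean_topological_length,
    nesting_number,
    nesting_ratios,
    topological_lengths,
)
from veintop.network import EmptyNetworkError, VeinNetwork, build_network, extract_facets

from conftest import random_loopy_network


class TestNestingStatistics:
    def test_balanced_tree_all_ratios_one(self):
        tree = build_nesting_tree(make_hierarchical(2))
        assert nesting_ratios(tree) == [1.0, 1.0, 1.0]
        assert nesting_number(tree, "unweighted") == 1.0
        assert nesting_number(tree, "degree_weighted") == 1.0

    def test_caterpillar_hand_values(self):
        tree = build_nesting_tree(make_caterpillar(4))
        assert sorted(nesting_ratios(tree)) == pytest.approx([1 / 3, 1 / 2, 1.0])
        assert nesting_number(tree, "unweighted") == pytest.approx(11 / 18)
        # degree weights 3, 2, 1 for d = 4, 3, 2: (3/3 + 2/2 + 1)/6 = 1/2
        assert nesting_number(tree, "degree_weighted") == pytest.approx(0.5)

    def test_degree_filter(self):
        tree = build_nesting_tree(make_ladder(3, [1.0, 2.0], 3.0))
        assert sorted(nesting_ratios(tree)) == [0.5, 1.0]
        assert nesting_ratios(tree, max_degree=2) == [1.0]
        assert nesting_number(tree, max_degree=2) == 1.0
        with pytest.raises(UndefinedMetricError):
            nesting_number(tree, max_degree=1)

    def test_empty_filter_raises(self):
        tree = build_nesting_tree(make_hierarchical(0))  # single leaf, no internal nodes
        with pytest.raises(UndefinedMetricError):
            nesting_number(tree)


class TestTopologicalLength:
    def test_uniform_widths_all_zero(self):
        net = make_grid(2, 2)
        assert set(topological_lengths(net).values()) == {0}
        assert mean_topological_length(net) == 0.0

    def test_tapered_path_trace(self):
        net = make_tapered_path(3)  # widths 3, 2, 1
        assert [topological_lengths(net)[e] for e in range(3)] == [2, 1, 0]
        assert mean_topological_length(net) == pytest.approx(1.0)

    def test_star_trace(self):
        nodes = [(0, 0.0, 0.0), (1, 1.0, 0.0), (2, 0.0, 1.0), (3, -1.0, 0.0), (4, 0.0, -1.0)]
        edges = [(i, 0, i + 1, 4.0 - i, None) for i in range(4)]  # widths 4, 3, 2, 1 at one hub
        net = build_network(nodes, edges)
        assert [topological_lengths(net)[e] for e in range(4)] == [3, 2, 1, 0]

    @pytest.mark.parametrize("n", [2, 5, 9])
    def test_tapering_path_closed_form(self, n):
        assert mean_topological_length(make_tapered_path(n)) == pytest.approx((n - 1) / 2)

    def test_matches_memo_free_brute_force(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            net = random_loopy_network(rng)
            got = topological_lengths(net)
            incident = {}
            for eid, e in net.edges.items():
                incident.setdefault(e.node_a, []).append(eid)
                incident.setdefault(e.node_b, []).append(eid)
            for start in net.edges:
                steps, cur = 0, start
                while True:
                    e = net.edges[cur]
                    nbrs = [
                        o
                        for n in (e.node_a, e.node_b)
                        for o in incident[n]
                        if o != cur and net.edges[o].width < e.width
                    ]
                    if not nbrs:
                        break
                    cur = min(nbrs, key=lambda o: (-net.edges[o].width, o))
                    steps += 1
                assert got[start] == steps


class TestGeometricMetrics:
    def test_unit_square_closed_form(self, unit_square):
        g = geometric_metrics(unit_square)
        assert g.sigma == pytest.approx(0.4)
        assert g.A == pytest.approx(100.0)
        assert g.rho_A == pytest.approx(0.01)
        assert g.d == pytest.approx(0.1)
        # mean nearest-boundary distance inside a square is side/6
        assert g.a == pytest.approx(10.0 / 6.0, rel=1e-3)

    def test_grid_tiling_identity(self):
        g = geometric_metrics(make_grid(3, 3), grid_spacing_mm=0.5)
        assert g.A * g.rho_A == pytest.approx(1.0)

    def test_scaling_laws(self, unit_square):
        k = 3.0
        scaled = VeinNetwork(
            {n: (k * x, k * y) for n, (x, y) in unit_square.nodes.items()},
            {
                eid: type(e)(e.node_a, e.node_b, e.width, e.length * k)
                for eid, e in unit_square.edges.items()
            },
        )
        g0 = geometric_metrics(unit_square)
        g1 = geometric_metrics(scaled)
        assert g1.sigma == pytest.approx(g0.sigma / k)
        assert g1.a == pytest.approx(k * g0.a, rel=1e-3)
        assert g1.A == pytest.approx(k**2 * g0.A)
        assert g1.rho_A == pytest.approx(g0.rho_A / k**2)
        assert g1.d == pytest.approx(g0.d)

    def test_areole_cover_bound(self):
        rng = np.random.default_rng(77)
        for _ in range(10):
            net = random_loopy_network(rng)
            g = geometric_metrics(net, grid_spacing_mm=1.0)
            assert g.A * g.rho_A <= 1.0 + 1e-9


class TestFingerprint:
    def test_error_on_cycle_free_network(self):
        with pytest.raises(EmptyNetworkError):
            fingerprint(make_tapered_path(3))

    def test_rank_equivalent_widths_same_topology_metrics(self):
        net = make_caterpillar(4)
        fp1 = fingerprint(net, grid_spacing_mm=0.5)
        mapped = with_widths(net, {eid: e.width**2 + 1 for eid, e in net.edges.items()})
        fp2 = fingerprint(mapped, grid_spacing_mm=0.5)
        assert (fp1.i_u, fp1.i_w, fp1.L_top) == (fp2.i_u, fp2.i_w, fp2.L_top)
        assert fp1.d != fp2.d  # the geometric diameter does change

    def test_fingerprint_of_balanced_fixture(self):
        fp = fingerprint(make_hierarchical(3), grid_spacing_mm=0.2)
        assert fp.i_u == 1.0 and fp.i_w == 1.0
        assert fp.sigma > 0 and fp.a > 0 and fp.A * fp.rho_A <= 1.0
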