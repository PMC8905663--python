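"""Network construction and topology, checked against brute-force oracles."""

import math
import random
from collections import deque

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cfcg.io_core import EdgeTable
from cfcg.network import (
    all_eccentricities,
    build_ct_network,
    compare_degree_groups,
    converge_with_ppi,
    herb_subnetwork,
    median_degree_filter,
    node_eccentricity,
)
from conftest import make_record


def _bfs_ecc(adj: dict, src: str) -> int:
    """Independent eccentricity oracle: plain queue-based BFS."""
    dist = {src: 0}
    q = deque([src])
    while q:
        u = q.popleft()
        for w in adj.get(u, ()):  # noqa: B909
            if w not in dist:
                dist[w] = dist[u] + 1
                q.append(w)
    return max(dist.values())


def _random_net(rng: random.Random, n_comp: int, n_tgt: int, p: float):
    records = [make_record(f"c{i}") for i in range(n_comp)]
    edges = tuple(
        (f"c{i}", f"t{j}")
        for i in range(n_comp)
        for j in range(n_tgt)
        if rng.random() < p
    )
    return records, EdgeTable(edges=edges, kind="component-target")


class TestBuild:
    def test_toy_counts_and_degree(self):
        records = [make_record("c1"), make_record("c2")]
        et = EdgeTable(edges=(("c1", "t1"), ("c1", "t2"), ("c2", "t2")),
                       kind="component-target")
        net = build_ct_network(records, et)
        assert len(net.graph.nodes) == 4 and len(net.graph.edges) == 3
        assert net.degree("t2") == 2

    def test_no_edges_gives_isolated_components(self):
        net = build_ct_network([make_record("c1")], EdgeTable((), "component-target"))
        assert net.components == ["c1"] and net.degree("c1") == 0

    def test_unknown_component_edge_is_error(self):
        with pytest.raises(ValueError, match="cX"):
            build_ct_network([make_record("c1")],
                             EdgeTable((("cX", "t1"),), "component-target"))

    def test_handshake_on_random_graphs(self):
        rng = random.Random(0)
        for _ in range(20):
            records, et = _random_net(rng, 5, 8, 0.3)
            net = build_ct_network(records, et)
            assert sum(d for _, d in net.graph.degree) == 2 * len(net.graph.edges)


class TestHerbSubnetwork:
    def _two_herb_net(self):
        records = [
            make_record("a", herbs=("H",)),
            make_record("b", herbs=("C",)),
            make_record("s", herbs=("H", "C")),
        ]
        et = EdgeTable(edges=(("a", "t1"), ("b", "t2"), ("s", "t3")),
                       kind="component-target")
        return build_ct_network(records, et)

    def test_excludes_other_herb(self):
        sub = herb_subnetwork(self._two_herb_net(), "H")
        assert "b" not in sub.graph and "t2" not in sub.graph

    def test_shared_component_in_both(self):
        net = self._two_herb_net()
        for herb in ("H", "C"):
            assert "s" in herb_subnetwork(net, herb).graph

    def test_unknown_herb(self):
        with pytest.raises(ValueError, match="unknown herb"):
            herb_subnetwork(self._two_herb_net(), "Z")

    def test_edges_partition_across_herbs(self):
        net = self._two_herb_net()
        edges_h = set(herb_subnetwork(net, "H").graph.edges)
        edges_c = set(herb_subnetwork(net, "C").graph.edges)
        assert set(net.graph.edges) <= {frozenset(e) and e for e in edges_h | edges_c}
        # shared component's edges appear in every herb subnetwork
        assert ("s", "t3") in edges_h or ("t3", "s") in edges_h
        assert ("s", "t3") in edges_c or ("t3", "s") in edges_c


class TestConverge:
    def test_outside_ppi_edges_dropped(self):
        net = build_ct_network(
            [make_record("c1")],
            EdgeTable((("c1", "t1"), ("c1", "t2")), "component-target"),
        )
        conv = converge_with_ppi(net, EdgeTable((("t1", "t2"), ("t1", "tX")),
                                                "target-target"))
        assert conv.n_ppi_added == 1 and conv.n_ppi_dropped == 1
        assert conv.degree("t1") == 2  # 1 C-T + 1 PPI

    def test_empty_ppi_preserves_degrees(self):
        net = build_ct_network(
            [make_record("c1")], EdgeTable((("c1", "t1"),), "component-target")
        )
        conv = converge_with_ppi(net, EdgeTable((), "target-target"))
        assert all(conv.degree(n) == net.degree(n) for n in net.graph)

    def test_component_neighbourhood_stays_ct_only(self):
        net = build_ct_network(
            [make_record("c1"), make_record("c2")],
            EdgeTable((("c1", "t1"), ("c2", "t2")), "component-target"),
        )
        conv = converge_with_ppi(net, EdgeTable((("t1", "t2"),), "target-target"))
        assert conv.targets_of("c1") == ["t1"]


class TestEccentricity:
    def test_path_graph(self):
        net = build_ct_network(
            [make_record("a"), make_record("c")],
            EdgeTable((("a", "b"), ("c", "b")), "component-target"),
        )
        assert node_eccentricity(net, "a") == 2
        assert node_eccentricity(net, "b") == 1

    def test_isolated_node_is_zero(self):
        net = build_ct_network([make_record("c1")], EdgeTable((), "component-target"))
        assert node_eccentricity(net, "c1") == 0

    def test_unknown_node(self):
        net = build_ct_network([make_record("c1")], EdgeTable((), "component-target"))
        with pytest.raises(ValueError):
            node_eccentricity(net, "zz")

    def test_matches_bfs_oracle_on_random_graphs(self):
        rng = random.Random(42)
        for _ in range(30):
            records, et = _random_net(rng, rng.randint(2, 8), rng.randint(2, 10), 0.25)
            net = build_ct_network(records, et)
            adj = {n: set(net.graph.neighbors(n)) for n in net.graph}
            eccs = all_eccentricities(net)
            for n in net.graph:
                assert eccs[n] == _bfs_ecc(adj, n)
                assert eccs[n] <= len(net.graph.nodes) - 1


class TestMedianFilter:
    def test_pooled_median_strictly_greater(self):
        # degrees: c1=1, c2=2, c3=1, t1=3, t2=1 -> pooled median 1;
        # only t1 (degree 3) strictly exceeds it
        records = [make_record("c1"), make_record("c2"), make_record("c3")]
        net = build_ct_network(
            records,
            EdgeTable((("c1", "t1"), ("c2", "t1"), ("c2", "t2"), ("c3", "t1")),
                      "component-target"),
        )
        retained, m = median_degree_filter(net, net.components, net.targets)
        assert m == 1 and retained == {"t1"}

    def test_sorted_scan_oracle_on_random_instances(self):
        rng = random.Random(7)
        for _ in range(25):
            records, et = _random_net(rng, 6, 12, 0.3)
            net = build_ct_network(records, EdgeTable(et.edges, "component-target"))
            comps, tgts = net.components, net.targets
            if not comps and not tgts:
                continue
            retained, m = median_degree_filter(net, comps, tgts)
            pool = sorted(net.degree(n) for n in comps + tgts)
            k = len(pool)
            med = (pool[(k - 1) // 2] + pool[k // 2]) / 2  # midpoint oracle
            assert m == med
            assert retained == {t for t in tgts if net.degree(t) > med}

    def test_all_equal_degrees_retains_nothing(self):
        records = [make_record("c1"), make_record("c2")]
        net = build_ct_network(
            records, EdgeTable((("c1", "t1"), ("c2", "t2")), "component-target")
        )
        retained, _ = median_degree_filter(net, net.components, net.targets)
        assert retained == set()

    def test_empty_pool_is_error(self):
        net = build_ct_network([], EdgeTable((), "component-target"))
        with pytest.raises(ValueError):
            median_degree_filter(net, [], [])


class TestDegreeGroupTest:
    def test_identical_groups(self):
        t, df, p = compare_degree_groups([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == 1.0 and df == 4

    def test_clear_shift_is_significant(self):
        _, _, p = compare_degree_groups([1, 2, 3], [11, 12, 13])
        assert p < 0.01

    def test_constant_groups_equal_means(self):
        assert compare_degree_groups([2, 2], [2, 2]) == (0.0, 2, 1.0)

    def test_constant_groups_unequal_means_error(self):
        with pytest.raises(ValueError, match="zero pooled variance"):
            compare_degree_groups([2, 2], [3, 3])

    def test_matches_textbook_pooled_formula(self):
        """Dual route: the implementation vs the pooled-variance t formula
        written out explicitly, on random group pairs."""
        rng = random.Random(3)
        for _ in range(100):
            na, nb = rng.randint(2, 12), rng.randint(2, 12)
            a = [rng.gauss(0, 1) for _ in range(na)]
            b = [rng.gauss(0.5, 1.5) for _ in range(nb)]
            t, df, p = compare_degree_groups(a, b)
            ma, mb = sum(a) / na, sum(b) / nb
            ssa = sum((x - ma) ** 2 for x in a)
            ssb = sum((x - mb) ** 2 for x in b)
            sp2 = (ssa + ssb) / (na + nb - 2)
            t_ref = (ma - mb) / math.sqrt(sp2 * (1 / na + 1 / nb))
            assert abs(t - t_ref) < 1e-10
            assert df == na + nb - 2
            assert 0 <= p <= 1

    @given(st.lists(st.integers(0, 50), min_size=2, max_size=20))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_symmetry_flips_sign_only(self, degs):
        other = [d + 1 for d in degs]
        if len(set(degs)) == 1 and len(set(other)) == 1:
            return
        t1, _, p1 = compare_degree_groups(degs, other)
        t2, _, p2 = compare_degree_groups(other, degs)
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)
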