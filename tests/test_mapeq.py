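import math

import networkx as nx
import numpy as np
import pytest

from ctmotif import mapeq
from ctmotif.core import CTNetwork
from ctmotif.mapeq import (
    Partition,
    SDFM,
    codelength,
    module_significance,
    optimize_partition,
    rewire_bipartite,
    select_sdfms,
    visit_rates,
)
from ctmotif.synthetic import PlantedNetworkSpec, generate_planted_network

from oracles import entropy_bits, set_partitions


def two_triangles():
    """Two triangles joined by one bridge edge: 7 edges, known visit rates."""
    g = nx.Graph()
    g.add_edges_from([(1, 2), (2, 3), (1, 3), (4, 5), (5, 6), (4, 6), (3, 4)])
    return g


def random_connected_graph(n, p, seed):
    rng = np.random.default_rng(seed)
    while True:
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if g.number_of_edges() >= 1 and nx.is_connected(g):
            return g


class TestVisitRates:
    def test_single_edge_symmetry(self):
        net = CTNetwork.from_edges([("c1", "t1")])
        v = visit_rates(net, tau=0.0)
        assert v.p["C:c1"] == pytest.approx(0.5)
        assert v.p["T:t1"] == pytest.approx(0.5)

    def test_star_closed_form(self):
        net = CTNetwork.from_edges([("c1", "t1"), ("c1", "t2")])
        v = visit_rates(net, tau=0.0)
        assert v.p["C:c1"] == pytest.approx(0.5)
        assert v.p["T:t1"] == pytest.approx(0.25)
        assert v.p["T:t2"] == pytest.approx(0.25)

    def test_teleportation_limit_is_uniform(self):
        net = CTNetwork.from_edges([("c1", "t1"), ("c1", "t2"), ("c2", "t2")])
        v = visit_rates(net, tau=0.999)
        for rate in v.p.values():
            assert rate == pytest.approx(0.25, abs=2e-3)

    def test_tau_zero_disconnected_raises(self):
        net = CTNetwork.from_edges([("c1", "t1"), ("c2", "t2")])
        with pytest.raises(ValueError, match="tau"):
            visit_rates(net, tau=0.0)

    def test_invalid_tau_rejected(self):
        net = CTNetwork.from_edges([("c1", "t1")])
        with pytest.raises(ValueError):
            visit_rates(net, tau=1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_degree_closed_form_on_connected_graphs(self, seed):
        g = random_connected_graph(8, 0.4, seed)
        v = visit_rates(g, tau=0.0)
        two_m = 2 * g.number_of_edges()
        for node in g:
            assert abs(v.p[node] - g.degree(node) / two_m) < 1e-10

    def test_rates_sum_to_one_with_teleportation(self):
        net, _ = generate_planted_network(PlantedNetworkSpec(seed=3))
        v = visit_rates(net, tau=0.15)
        assert sum(v.p.values()) == pytest.approx(1.0, abs=1e-10)
        assert min(v.p.values()) > 0


class TestCodelength:
    def test_one_module_equals_visit_rate_entropy(self):
        for seed in range(10):
            net, _ = generate_planted_network(PlantedNetworkSpec(seed=seed))
            v = visit_rates(net, tau=0.15)
            part = Partition({n: 1 for n in v.p}, 1)
            report = codelength(net, part, v)
            assert report.L == pytest.approx(entropy_bits(list(v.p.values())), abs=1e-9)
            assert report.q_total == pytest.approx(0.0, abs=1e-12)

    def test_two_triangle_hand_value(self):
        g = two_triangles()
        v = visit_rates(g, tau=0.0)
        part = Partition({n: 1 for n in g}, 1)
        expected = 4 * (1 / 7) * math.log2(7) + 2 * (3 / 14) * math.log2(14 / 3)
        assert codelength(g, part, v).L == pytest.approx(expected, abs=1e-12)

    def test_triangle_split_beats_one_module(self):
        g = two_triangles()
        v = visit_rates(g, tau=0.0)
        one = codelength(g, Partition({n: 1 for n in g}, 1), v)
        split = codelength(g, Partition({1: 1, 2: 1, 3: 1, 4: 2, 5: 2, 6: 2}, 2), v)
        assert split.L < one.L

    def test_report_assembly_invariant(self):
        net, _ = generate_planted_network(PlantedNetworkSpec(seed=1))
        v = visit_rates(net, tau=0.15)
        part, report = optimize_partition(net, v, seed=0, n_restarts=4)
        assembled = report.q_total * report.HQ + sum(
            report.p_circ[i] * report.HP[i] for i in report.p_circ)
        assert report.L == pytest.approx(assembled, abs=1e-12)
        assert all(h >= 0 for h in report.HP.values())

    def test_missing_node_raises(self):
        net = CTNetwork.from_edges([("c1", "t1"), ("c1", "t2")])
        v = visit_rates(net, tau=0.15)
        with pytest.raises(ValueError, match="missing"):
            codelength(net, Partition({"C:c1": 1, "T:t1": 1}, 1), v)

    def test_invariant_under_node_relabeling(self):
        g = two_triangles()
        v = visit_rates(g, tau=0.1)
        part = Partition({n: 1 if n <= 3 else 2 for n in g}, 2)
        L1 = codelength(g, part, v).L
        mapping = {n: f"x{n}" for n in g}
        g2 = nx.relabel_nodes(g, mapping)
        v2 = mapeq.VisitDistribution({mapping[n]: v.p[n] for n in g}, v.tau)
        part2 = Partition({mapping[n]: part.assignment[n] for n in g}, 2)
        assert codelength(g2, part2, v2).L == pytest.approx(L1, abs=1e-12)

    def test_invariant_under_module_relabeling(self):
        g = two_triangles()
        v = visit_rates(g, tau=0.1)
        a = Partition({n: 1 if n <= 3 else 2 for n in g}, 2)
        b = Partition({n: 2 if n <= 3 else 1 for n in g}, 2)
        assert codelength(g, a, v).L == pytest.approx(codelength(g, b, v).L, abs=1e-12)


class TestPartitionType:
    def test_noncontiguous_ids_rejected(self):
        with pytest.raises(ValueError, match="contiguous"):
            Partition({"a": 1, "b": 3}, 3)

    def test_from_assignment_renumbers(self):
        p = Partition.from_assignment({"a": 7, "b": 7, "c": 42})
        assert p.m == 2
        assert p.assignment["a"] == p.assignment["b"] != p.assignment["c"]


class TestOptimizePartition:
    def test_planted_blocks_recovered(self):
        edges = [(f"c{i}", f"t{j}") for i in (1, 2) for j in (1, 2, 3)]
        edges += [(f"d{i}", f"u{j}") for i in (1, 2) for j in (1, 2, 3)]
        edges += [("c1", "u1")]  # bridge
        net = CTNetwork.from_edges(edges)
        v = visit_rates(net, tau=0.15)
        part, report = optimize_partition(net, v, seed=0, n_restarts=8)
        blocks = {frozenset(nodes) for nodes in part.modules().values()}
        left = frozenset({"C:c1", "C:c2", "T:t1", "T:t2", "T:t3"})
        right = frozenset({"C:d1", "C:d2", "T:u1", "T:u2", "T:u3"})
        assert blocks == {left, right}

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_exhaustive_minimum_small_graphs(self, seed):
        g = random_connected_graph(6, 0.5, seed=seed + 100)
        v = visit_rates(g, tau=0.15)
        best = math.inf
        n_parts = 0
        for blocks in set_partitions(sorted(g.nodes)):
            n_parts += 1
            assign = {n: i + 1 for i, blk in enumerate(blocks) for n in blk}
            best = min(best, codelength(g, Partition.from_assignment(assign), v).L)
        assert n_parts == 203  # Bell(6)
        _, report = optimize_partition(g, v, seed=seed, n_restarts=10)
        assert report.L == pytest.approx(best, abs=1e-9)

    def test_k22_stays_one_module(self):
        net = CTNetwork.from_edges(
            [("c1", "t1"), ("c1", "t2"), ("c2", "t1"), ("c2", "t2")])
        v = visit_rates(net, tau=0.15)
        part, _ = optimize_partition(net, v, seed=0, n_restarts=6)
        assert part.m == 1

    def test_deterministic_for_fixed_seed(self):
        net, _ = generate_planted_network(PlantedNetworkSpec(seed=5))
        v = visit_rates(net, tau=0.15)
        a = optimize_partition(net, v, seed=11, n_restarts=4)
        b = optimize_partition(net, v, seed=11, n_restarts=4)
        assert a[0].assignment == b[0].assignment
        assert a[1].L == b[1].L

    def test_never_worse_than_one_module(self):
        for seed in range(5):
            net, _ = generate_planted_network(PlantedNetworkSpec(seed=seed))
            v = visit_rates(net, tau=0.15)
            one_L = codelength(net, Partition({n: 1 for n in v.p}, 1), v).L
            _, report = optimize_partition(net, v, seed=seed, n_restarts=4)
            assert report.L <= one_L + 1e-12

    def test_single_node_rejected(self):
        g = nx.Graph()
        g.add_node("a")
        with pytest.raises(ValueError):
            optimize_partition(g, seed=0)


class TestSignificance:
    def test_zero_permutations_rejected(self):
        net, truth = generate_planted_network(PlantedNetworkSpec(seed=0))
        with pytest.raises(ValueError, match="n_perm"):
            module_significance(net, truth, n_perm=0)

    def test_singleton_module_gets_p_one(self):
        net = CTNetwork.from_edges(
            [("c1", "t1"), ("c1", "t2"), ("c2", "t1"), ("c2", "t2"), ("c3", "t3")])
        v = visit_rates(net, tau=0.15)
        part = Partition.from_assignment(
            {"C:c1": 1, "C:c2": 1, "T:t1": 1, "T:t2": 1, "C:c3": 2, "T:t3": 3})
        # module 3 is the singleton {T:t3}
        out = module_significance(net, part, v, n_perm=99, seed=0)
        by_id = {s.module_id: s for s in out}
        singleton = [s for s in out if len(s.members) == 1]
        assert singleton and all(s.p_value == 1.0 for s in singleton)
        assert len(by_id) == part.m

    def test_planted_module_is_significant(self):
        net, truth = generate_planted_network(
            PlantedNetworkSpec(3, 5, 10, 0.6, 0.05, seed=7))
        v = visit_rates(net, tau=0.15)
        out = module_significance(net, truth, v, n_perm=99, seed=7)
        assert all(s.p_value <= 0.05 for s in out)

    def test_reproducible_for_fixed_seed(self):
        net, truth = generate_planted_network(PlantedNetworkSpec(seed=2))
        v = visit_rates(net, tau=0.15)
        a = module_significance(net, truth, v, n_perm=99, seed=3)
        b = module_significance(net, truth, v, n_perm=99, seed=3)
        assert [(s.module_id, s.p_value, s.saving) for s in a] == \
               [(s.module_id, s.p_value, s.saving) for s in b]


class TestRewire:
    @pytest.mark.parametrize("seed", range(5))
    def test_degree_sequences_preserved(self, seed):
        net, _ = generate_planted_network(PlantedNetworkSpec(seed=seed))
        rng = np.random.default_rng(seed)
        null = rewire_bipartite(net, rng)
        def degs(n):
            out = {}
            for c, t, _ in n.edges:
                out[c] = out.get(c, 0) + 1
                out[t] = out.get(t, 0) + 1
            return out
        assert degs(null) == degs(net)
        assert null.n_edges == net.n_edges

    def test_rewiring_changes_edges(self):
        net, _ = generate_planted_network(PlantedNetworkSpec(seed=0))
        null = rewire_bipartite(net, np.random.default_rng(0))
        assert set(null.edges) != set(net.edges)


class TestSelectSDFMs:
    def _mk(self, mid, p, saving=1.0):
        return SDFM(module_id=mid, members=frozenset({f"C:c{mid}", f"T:t{mid}"}),
                    p_value=p, saving=saving)

    def test_keeps_below_alpha(self):
        mods = [self._mk(1, 0.01, 2.0), self._mk(2, 0.04, 3.0), self._mk(3, 0.2)]
        kept = select_sdfms(mods, alpha=0.05)
        assert [s.module_id for s in kept] == [2, 1]  # saving descending

    def test_empty_input(self):
        assert select_sdfms([]) == []

    def test_all_p_one_keeps_none(self):
        mods = [self._mk(i, 1.0) for i in range(1, 4)]
        assert select_sdfms(mods) == []
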