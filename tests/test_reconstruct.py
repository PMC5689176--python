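"""Approximate reconstruction, shared objective, path and local queries.

Independent oracles used here: exhaustive enumeration of edge subsets
(anchored optimum and undirected Steiner optimum) and exhaustive simple
path enumeration, all on instances small enough to enumerate.
"""

import itertools
import math
import warnings

import networkx as nx
import pytest

from anchornet.exact import brute_force_oracle
from anchornet.fixtures import generate_background, random_small_instance
from anchornet.netio import PDI, Edge, InteractionNetwork
from anchornet.reconstruct import (
    RootedInstance,
    anchored_approx,
    dijkstra,
    directed_adjacency,
    general_reconstruct,
    local_search,
    objective_value,
    path_likelihood,
    shortest_paths_query,
)


def _steiner_optimum(net: InteractionNetwork, terminals: set[str]) -> float:
    """Exhaustive minimum-cost subgraph connecting the terminals (undirected)."""
    edges = net.edges
    best = math.inf
    for r in range(len(edges) + 1):
        for combo in itertools.combinations(range(len(edges)), r):
            cost = sum(edges[j].cost for j in combo)
            if cost >= best:
                continue
            g = nx.Graph()
            g.add_nodes_from(terminals)
            for j in combo:
                g.add_edge(edges[j].u, edges[j].v)
            comp = nx.node_connected_component(g, next(iter(sorted(terminals))))
            if terminals <= comp:
                best = cost
    return best


class TestObjective:
    def test_single_edge_equals_cost_for_any_alpha(self):
        edge = Edge("a", "t", 0.5)
        net = InteractionNetwork([edge])
        for alpha in (0.0, 0.3, 1.0):
            inst = RootedInstance.build(net, {"a"}, {"t"}, alpha)
            size, path, comb = objective_value(inst, net)
            assert size == path == pytest.approx(edge.cost)
            assert comb == pytest.approx(edge.cost)

    def test_alpha_one_is_pure_size(self, diamond_net):
        inst = RootedInstance.build(diamond_net, {"a"}, {"t"}, 1.0)
        size, path, comb = objective_value(inst, diamond_net)
        assert comb == pytest.approx(size)

    def test_unreachable_terminal_raises(self):
        net = InteractionNetwork([Edge("a", "b", 0.5)], nodes={"a", "b", "t"})
        inst = RootedInstance.build(net, {"a"}, {"t"}, 0.5)
        with pytest.raises(ValueError, match="unreachable"):
            objective_value(inst, net)

    def test_matches_independent_dijkstra_recomputation(self):
        net = generate_background(8, 3.0, seed=5)
        nodes = sorted(net.nodes)
        inst = RootedInstance.build(net, {nodes[0]}, set(nodes[1:3]), 0.4)
        size, path, comb = objective_value(inst, net)
        g = net.to_digraph()
        expect_path = sum(
            nx.dijkstra_path_length(g, nodes[0], t, weight="cost")
            for t in sorted(inst.terminals)
        )
        assert path == pytest.approx(expect_path, abs=1e-9)
        assert size == pytest.approx(sum(e.cost for e in net.edges), abs=1e-9)
        assert comb == pytest.approx(0.4 * size + 0.6 * path, abs=1e-9)


class TestAnchoredApprox:
    def test_unique_route_returned_whole(self):
        net = InteractionNetwork(
            [Edge("a", "x", 0.5), Edge("t", "x", 0.5)]
        )
        for alpha in (0.0, 0.5, 1.0):
            inst = RootedInstance.build(net, {"a"}, {"t"}, alpha)
            sol = anchored_approx(inst)
            assert sol.biological_nodes == {"a", "x", "t"}
            assert sol.paths["t"] == ["a", "x", "t"]

    def test_diamond_takes_cheap_path(self, diamond_net):
        for alpha in (0.0, 0.25, 1.0):
            inst = RootedInstance.build(diamond_net, {"a"}, {"t"}, alpha)
            sol = anchored_approx(inst)
            assert sol.biological_nodes == {"a", "x", "t"}
            assert sol.combined == pytest.approx(2.0, abs=1e-9)

    def test_matches_brute_force_at_alpha_limits(self):
        # shared trunk vs disjoint cheap paths; brute force at both limits
        for seed in (1, 5, 9):
            inst = random_small_instance(seed, max_nodes=8, max_edges=12)
            if inst is None:
                continue
            for alpha in (0.0, 1.0):
                inst_a = RootedInstance(inst.net, inst.anchors, inst.terminals, alpha, inst.root)
                approx = anchored_approx(inst_a)
                exact = brute_force_oracle(inst_a)
                assert approx.combined >= exact.combined - 1e-9
                if alpha == 0.0:
                    # SP-union is optimal for the pure path objective
                    assert approx.combined == pytest.approx(exact.combined, abs=1e-9)
                else:
                    assert approx.size_term <= 2.0 * exact.size_term + 1e-9

    def test_pruning_keeps_endpoints_and_feasibility(self):
        inst = random_small_instance(3, max_nodes=9)
        assert inst is not None
        sol = anchored_approx(inst)
        for t in inst.terminals - sol.unreachable_terminals:
            assert t in sol.biological_nodes
            path = sol.paths[t]
            assert path[-1] == t
            for u, v in zip(path, path[1:]):
                assert sol.network.get_edge(u, v) is not None

    def test_every_connector_lies_on_a_path(self):
        for seed in (0, 4, 8):
            inst = random_small_instance(seed)
            if inst is None:
                continue
            sol = anchored_approx(inst)
            on_paths = {n for p in sol.paths.values() for n in p}
            for n, role in sol.node_roles.items():
                if role == "connector":
                    assert n in on_paths

    def test_required_node_joins_solution(self, diamond_net):
        inst = RootedInstance.build(diamond_net, {"a"}, {"t"}, 0.25)
        sol = anchored_approx(inst, required={"y"})
        assert "y" in sol.biological_nodes
        # required nodes do not enter the path term
        assert sol.path_term == pytest.approx(2.0, abs=1e-9)

    def test_excluded_node_is_avoided(self, diamond_net):
        inst = RootedInstance.build(diamond_net, {"a"}, {"t"}, 0.25)
        sol = anchored_approx(inst, excluded={"x"})
        assert sol.biological_nodes == {"a", "y", "t"}
        assert sol.combined == pytest.approx(6.0, abs=1e-9)

    def test_unreachable_terminal_dropped_with_warning(self):
        net = InteractionNetwork([Edge("a", "t1", 0.5)], nodes={"t2"})
        inst = RootedInstance.build(net, {"a"}, {"t1", "t2"}, 0.25)
        with pytest.warns(UserWarning, match="unreachable"):
            sol = anchored_approx(inst)
        assert sol.unreachable_terminals == {"t2"}

    def test_relabeling_equivariance(self):
        inst = random_small_instance(6)
        sol = anchored_approx(inst)
        mapping = {n: f"Z{n}" for n in inst.net.nodes}
        relabeled = InteractionNetwork(
            [Edge(mapping[e.u], mapping[e.v], e.p, e.kind) for e in inst.net.edges],
            nodes=[mapping[n] for n in inst.net.nodes],
        )
        inst2 = RootedInstance.build(
            relabeled,
            {mapping[a] for a in inst.anchors},
            {mapping[t] for t in inst.terminals},
            inst.alpha,
        )
        sol2 = anchored_approx(inst2)
        assert {mapping[n] for n in sol.biological_nodes} == sol2.biological_nodes
        assert sol2.combined == pytest.approx(sol.combined, abs=1e-9)


class TestGeneralReconstruct:
    def test_star_with_leaf_terminals_is_full_star(self):
        net = InteractionNetwork(
            [Edge("hub", f"t{i}", 0.5) for i in range(4)]
        )
        sol = general_reconstruct(net, {f"t{i}" for i in range(4)})
        assert sol.network == net
        assert sol.path_term == 0.0

    def test_triangle_two_terminals_takes_direct_edge(self):
        net = InteractionNetwork(
            [Edge("A", "B", 0.5), Edge("B", "C", 0.5), Edge("A", "C", 0.5)]
        )
        sol = general_reconstruct(net, {"A", "B"})
        assert sol.network.n_edges() == 1
        assert sol.network.get_edge("A", "B") is not None

    def test_single_terminal_rejected(self, mixed_net):
        with pytest.raises(ValueError):
            general_reconstruct(mixed_net, {"A"})

    def test_within_factor_two_of_exhaustive_steiner(self):
        checked = 0
        for seed in range(40):
            net = generate_background(8, 2.5, seed=seed)
            if net.n_edges() > 12 or net.n_edges() < 3:
                continue
            nodes = sorted(net.nodes)
            terminals = set(nodes[:3])
            opt = _steiner_optimum(net, terminals)
            if math.isinf(opt):
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sol = general_reconstruct(net, terminals)
            checked += 1
            assert sol.size_term <= 2.0 * opt + 1e-9
        assert checked >= 10


class TestShortestPaths:
    def test_single_edge(self):
        net = InteractionNetwork([Edge("a", "t", 0.8)])
        res = shortest_paths_query(net, {"a"}, {"t"})[("a", "t")]
        assert res.path == ["a", "t"]
        assert res.likelihood == pytest.approx(0.8)

    def test_wrong_direction_pdi_unreachable(self):
        net = InteractionNetwork([Edge("t", "x", 0.9, PDI), Edge("x", "a", 0.9, PDI)])
        res = shortest_paths_query(net, {"a"}, {"t"})[("a", "t")]
        assert not res.reachable

    def test_matches_exhaustive_simple_path_enumeration(self):
        for seed in (0, 3, 7):
            net = generate_background(7, 3.0, pdi_fraction=0.3, seed=seed)
            g = net.to_digraph()
            nodes = sorted(net.nodes)
            res = shortest_paths_query(net, {nodes[0]}, set(nodes[1:4]))
            for (a, t), r in res.items():
                best = math.inf
                for p in nx.all_simple_paths(g, a, t):
                    best = min(best, sum(g[u][v]["cost"] for u, v in zip(p, p[1:])))
                if math.isinf(best):
                    assert not r.reachable
                else:
                    assert r.cost == pytest.approx(best, abs=1e-9)
                    assert r.likelihood == pytest.approx(math.exp(-best), abs=1e-12)


class TestLocalSearch:
    def test_depth_zero_is_terminals_only(self, mixed_net):
        sub = local_search(mixed_net, {"A", "B"}, 0)
        assert sub.nodes == {"A", "B"}
        assert sub.get_edge("A", "B") is not None  # induced edge kept

    def test_star_depth_one(self):
        net = InteractionNetwork([Edge("hub", f"x{i}", 0.5) for i in range(5)])
        assert local_search(net, {"hub"}, 1).nodes == net.nodes

    @pytest.mark.parametrize("seed", [1, 2])
    def test_monotone_in_depth(self, seed):
        net = generate_background(25, 3.0, seed=seed)
        terms = set(sorted(net.nodes)[:2])
        prev: set = set()
        for depth in range(4):
            cur = local_search(net, terms, depth).nodes
            assert prev <= cur
            prev = cur


class TestPathLikelihood:
    def test_products(self, mixed_net):
        assert path_likelihood(mixed_net, ["A", "B"]) == pytest.approx(0.9)
        assert path_likelihood(mixed_net, ["A", "B", "C"]) == pytest.approx(0.72)

    def test_missing_edge_raises(self, mixed_net):
        with pytest.raises(ValueError):
            path_likelihood(mixed_net, ["A", "C"])

    def test_equals_exp_of_negative_cost(self, mixed_net):
        path = ["A", "B", "C", "D"]
        cost = sum(
            mixed_net.get_edge(u, v).cost for u, v in zip(path, path[1:])
        )
        assert path_likelihood(mixed_net, path) == pytest.approx(
            math.exp(-cost), rel=1e-12
        )


class TestDijkstraDeterminism:
    def test_parent_chain_terminates_on_zero_cost_ties(self):
        net = InteractionNetwork(
            [Edge("r", "a", 1.0), Edge("r", "b", 1.0), Edge("a", "b", 1.0)]
        )
        dist, parent = dijkstra(directed_adjacency(net), "r")
        for n in net.nodes:
            seen = set()
            cur = n
            while parent[cur] is not None:
                assert cur not in seen
                seen.add(cur)
                cur = parent[cur]
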