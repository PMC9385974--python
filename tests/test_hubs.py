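from itertools import combinations

import numpy as np
import pytest

import _oracles as oracles
from cernakit.cerna import CeRNANetwork, Node
from cernakit.errors import ConfigError, DataError
from cernakit.hubs import (
    ALGORITHMS,
    CentralityConfig,
    RegulatoryAxis,
    betweenness,
    closeness,
    compute_centralities,
    consensus_hubs,
    dedup_axes,
    degree,
    eccentricity_score,
    epc,
    extract_axes,
    maximal_cliques,
    mcc,
    radiality,
    top_k,
)
from cernakit.synthetic import paper_fixture_axes

PATH = [("a", "b"), ("b", "c")]
TRIANGLE = [("a", "b"), ("b", "c"), ("a", "c")]
STAR3 = [("c", "l1"), ("c", "l2"), ("c", "l3")]
K4 = [(a, b) for a, b in combinations("wxyz", 2)]


class TestDegree:
    def test_triangle_all_two(self):
        assert degree(TRIANGLE) == {"a": 2.0, "b": 2.0, "c": 2.0}

    def test_star(self):
        scores = degree(STAR3)
        assert scores["c"] == 3.0
        assert all(scores[l] == 1.0 for l in ("l1", "l2", "l3"))

    def test_isolated_node_zero(self):
        assert degree({"x": set()}) == {"x": 0.0}


class TestCloseness:
    def test_path(self):
        scores = closeness(PATH)
        assert scores["b"] == pytest.approx(2.0)
        assert scores["a"] == pytest.approx(1.5)

    def test_two_disconnected_edges(self):
        scores = closeness([("a", "b"), ("c", "d")])
        assert all(v == pytest.approx(1.0) for v in scores.values())


class TestEccentricity:
    def test_path(self):
        scores = eccentricity_score(PATH)
        assert scores["b"] == pytest.approx(1.0)
        assert scores["a"] == pytest.approx(0.5)

    def test_complete_graph(self):
        assert all(v == pytest.approx(1.0)
                   for v in eccentricity_score(K4).values())

    def test_isolated_node_zero(self):
        assert eccentricity_score({"x": set()})["x"] == 0.0


class TestRadiality:
    def test_triangle(self):
        assert all(v == pytest.approx(1.0) for v in radiality(TRIANGLE).values())

    def test_path_hand_values(self):
        scores = radiality(PATH)
        assert scores["b"] == pytest.approx(2.0)
        assert scores["a"] == pytest.approx(1.5)

    def test_complete_graph(self):
        assert all(v == pytest.approx(1.0) for v in radiality(K4).values())

    def test_singleton_zero(self):
        assert radiality({"x": set()})["x"] == 0.0


class TestBetweenness:
    def test_star_center(self):
        scores = betweenness(STAR3)
        assert scores["c"] == pytest.approx(3.0)
        assert scores["l1"] == pytest.approx(0.0)

    def test_triangle_zero(self):
        assert all(v == pytest.approx(0.0)
                   for v in betweenness(TRIANGLE).values())


class TestMcc:
    def test_k4_single_clique(self):
        assert all(v == pytest.approx(6.0) for v in mcc(K4).values())

    def test_path_degree_fallback(self):
        scores = mcc(PATH)
        assert scores["b"] == 2.0
        assert scores["a"] == 1.0

    def test_maximal_cliques_triangle_plus_tail(self):
        cliques = maximal_cliques(TRIANGLE + [("c", "d")])
        assert set(cliques) == {frozenset("abc"), frozenset("cd")}


class TestEpc:
    def test_retention_one_exact(self):
        cfg = CentralityConfig(epc_retention=1.0, epc_realizations=5)
        scores = epc(PATH + [("x", "y")], cfg)
        assert scores["a"] == pytest.approx(2.0)
        assert scores["x"] == pytest.approx(1.0)

    def test_retention_zero_all_zero(self):
        cfg = CentralityConfig(epc_retention=0.0, epc_realizations=5)
        assert all(v == 0.0 for v in epc(PATH, cfg).values())

    def test_single_edge_expectation(self):
        cfg = CentralityConfig(epc_retention=0.5, epc_realizations=1000, seed=3)
        scores = epc([("a", "b")], cfg)
        for v in scores.values():
            assert abs(v - 0.5) < 0.05

    def test_seed_determinism(self):
        cfg = CentralityConfig(seed=9, epc_realizations=50)
        assert epc(TRIANGLE, cfg) == epc(TRIANGLE, cfg)


IMPLEMENTATIONS = {
    "Degree": degree,
    "Closeness": closeness,
    "EcCentricity": eccentricity_score,
    "Radiality": radiality,
    "Betweenness": betweenness,
    "MCC": mcc,
}
ORACLES = {
    "Degree": lambda n, e: {v: float(len([x for x in e if v in x])) for v in n},
    "Closeness": oracles.closeness_oracle,
    "EcCentricity": oracles.eccentricity_oracle,
    "Radiality": oracles.radiality_oracle,
    "Betweenness": oracles.betweenness_oracle,
    "MCC": oracles.mcc_oracle,
}


@pytest.mark.parametrize("algorithm", sorted(IMPLEMENTATIONS))
def test_centrality_matches_oracle_on_random_graphs(algorithm, rng):
    for _ in range(25):
        nodes, edges = oracles.random_graph(rng)
        expected = ORACLES[algorithm](nodes, edges)
        adj = {v: set() for v in nodes}
        for a, b in edges:
            adj[a].add(b)
            adj[b].add(a)
        actual = IMPLEMENTATIONS[algorithm](adj)
        for v in nodes:
            assert actual[v] == pytest.approx(expected[v], abs=1e-9), (
                algorithm, nodes, edges, v)


def test_epc_matches_exact_enumeration(rng):
    checked = 0
    while checked < 5:
        nodes, edges = oracles.random_graph(rng, n_min=4, n_max=6,
                                            p_min=0.3, p_max=0.5)
        if len(edges) > 9 or not edges:
            continue
        checked += 1
        exact = oracles.epc_exact(nodes, edges, 0.5)
        cfg = CentralityConfig(epc_retention=0.5, epc_realizations=1000,
                               seed=checked)
        adj = {v: set() for v in nodes}
        for a, b in edges:
            adj[a].add(b)
            adj[b].add(a)
        approx = epc(adj, cfg)
        for v in nodes:
            se = np.sqrt(len(nodes) ** 2 / 4 / 1000)  # crude bound on MC error
            assert abs(approx[v] - exact[v]) <= max(3 * se, 0.15)


@pytest.mark.parametrize("algorithm", sorted(IMPLEMENTATIONS))
def test_relabeling_invariance(algorithm, rng):
    for _ in range(10):
        nodes, edges = oracles.random_graph(rng)
        perm = dict(zip(nodes, rng.permutation(nodes)))
        adj = {v: set() for v in nodes}
        for a, b in edges:
            adj[a].add(b)
            adj[b].add(a)
        scores = IMPLEMENTATIONS[algorithm](adj)
        relabeled_adj = {perm[v]: {perm[u] for u in nbrs}
                         for v, nbrs in adj.items()}
        relabeled = IMPLEMENTATIONS[algorithm](relabeled_adj)
        for v in nodes:
            assert scores[v] == pytest.approx(relabeled[perm[v]], abs=1e-9)


class TestTopK:
    def test_k_exceeds_n(self):
        scores = {c: float(i) for i, c in enumerate("abcde")}
        assert len(top_k(scores, CentralityConfig(k_top=10))) == 5

    def test_tie_extension(self):
        scores = {"a": 3.0, "b": 2.0, "c": 2.0, "d": 1.0}
        cfg = CentralityConfig(k_top=2, tie_policy="include_ties")
        assert top_k(scores, cfg) == ["a", "b", "c"]

    def test_truncate(self):
        scores = {"a": 3.0, "b": 2.0, "c": 2.0, "d": 1.0}
        cfg = CentralityConfig(k_top=2, tie_policy="truncate")
        assert top_k(scores, cfg) == ["a", "b"]

    def test_tie_break_by_identifier(self):
        scores = {"b": 1.0, "a": 1.0}
        assert top_k(scores, CentralityConfig(k_top=2)) == ["a", "b"]


class TestConsensusHubs:
    def test_node_in_all_seven_is_hub(self):
        lists = {alg: ["x", "y"] for alg in ALGORITHMS}
        assert consensus_hubs(lists).hubs == ("x", "y")

    def test_six_of_seven_not_hub(self):
        lists = {alg: ["x", "y"] for alg in ALGORITHMS}
        lists["Betweenness"] = ["y"]
        hubs = consensus_hubs(lists)
        assert "x" not in hubs
        assert "y" in hubs

    def test_missing_algorithm_rejected(self):
        lists = {alg: ["x"] for alg in ALGORITHMS[:-1]}
        with pytest.raises(ConfigError):
            consensus_hubs(lists)

    def test_membership_matrix_row_and(self):
        lists = {alg: ["x", "y"] for alg in ALGORITHMS}
        lists["MCC"] = ["x"]
        hubs = consensus_hubs(lists)
        for node, row in hubs.membership.items():
            assert (node in hubs) == all(row[a] for a in ALGORITHMS)


def _tripartite_net(lnc_mi_edges, mi_mrna_edges, label="t"):
    edges = set()
    for l, m in lnc_mi_edges:
        edges.add(frozenset((Node(l, "lncRNA"), Node(m, "miRNA"))))
    for m, g in mi_mrna_edges:
        edges.add(frozenset((Node(m, "miRNA"), Node(g, "mRNA"))))
    nodes = {n for e in edges for n in e}
    return CeRNANetwork(nodes=nodes, edges=edges, label=label)


class TestExtractAxes:
    def test_complete_hub_connectivity_four_axes(self):
        net = _tripartite_net(
            [("L1", "m1"), ("L1", "m2"), ("L2", "m1"), ("L2", "m2")],
            [("m1", "G"), ("m2", "G")])
        axes = extract_axes(net, net.nodes)
        assert len(axes) == 4

    def test_no_hub_mrna_empty(self):
        net = _tripartite_net([("L1", "m1")], [("m1", "G")])
        hubs = {n for n in net.nodes if n.kind != "mRNA"}
        assert extract_axes(net, hubs) == []

    def test_hub_outside_network_rejected(self, minimal_triple):
        with pytest.raises(DataError):
            extract_axes(minimal_triple, {Node("zz", "miRNA")})

    def test_matches_bruteforce_enumeration(self, rng):
        for _ in range(20):
            lncs = [f"L{i}" for i in range(rng.integers(1, 4))]
            mirs = [f"m{i}" for i in range(rng.integers(1, 4))]
            genes = [f"G{i}" for i in range(rng.integers(1, 4))]
            lm = [(l, m) for l in lncs for m in mirs if rng.random() < 0.6]
            mg = [(m, g) for m in mirs for g in genes if rng.random() < 0.6]
            used = {x for pair in lm + mg for x in pair}
            if not lm or not mg:
                continue
            # keep the network valid: drop nodes violating invariants
            mg = [(m, g) for m, g in mg]
            mirs_ok = {m for _, m in lm} & {m for m, _ in mg}
            lm = [(l, m) for l, m in lm if m in mirs_ok]
            mg = [(m, g) for m, g in mg if m in mirs_ok]
            if not lm or not mg:
                continue
            net = _tripartite_net(lm, mg)
            axes = extract_axes(net, net.nodes)
            brute = {
                (l, m, g)
                for l, m in lm
                for m2, g in mg
                if m == m2
            }
            assert {a.triple for a in axes} == brute

    def test_insertion_order_independent(self):
        lm = [("L1", "m1"), ("L2", "m1")]
        mg = [("m1", "G1"), ("m1", "G2")]
        net1 = _tripartite_net(lm, mg)
        net2 = _tripartite_net(list(reversed(lm)), list(reversed(mg)))
        assert (extract_axes(net1, net1.nodes)
                == extract_axes(net2, net2.nodes))


class TestDedupAxes:
    def test_listed_axes_dedupe_to_seven(self):
        assert len(dedup_axes(paper_fixture_axes())) == 7

    def test_shared_axis_carries_both_networks(self):
        unique = dedup_axes(paper_fixture_axes())
        shared = [a for a in unique if len(a.networks) == 2]
        assert len(shared) == 1
        assert shared[0].triple == ("Malat1", "miR-181a-5p", "Tnf")
        assert shared[0].networks == frozenset({"necroptosis", "pyroptosis"})

    def test_all_distinct_preserved(self):
        axes = [RegulatoryAxis(f"L{i}", f"m{i}", f"G{i}", network="n")
                for i in range(5)]
        assert len(dedup_axes(axes)) == 5

    def test_empty(self):
        assert dedup_axes([]) == []


class TestPlantedHubRecovery:
    def test_planted_hub_in_every_top_list(self, rng):
        # a miRNA connected to every lncRNA and every mRNA dominates all
        # seven rankings with high probability
        hits = 0
        trials = 10
        for t in range(trials):
            lncs = [f"L{i}" for i in range(5)]
            genes = [f"G{i}" for i in range(4)]
            hub = "mHub"
            others = [f"m{i}" for i in range(4)]
            lm = [(l, hub) for l in lncs]
            mg = [(hub, g) for g in genes]
            for m in others:
                lm.append((str(rng.choice(lncs)), m))
                mg.append((m, str(rng.choice(genes))))
            net = _tripartite_net(lm, mg)
            report = compute_centralities(
                net, CentralityConfig(k_top=3, seed=t))
            hub_node = Node(hub, "miRNA")
            if all(hub_node in report.top_lists[a] for a in ALGORITHMS):
                hits += 1
        assert hits / trials > 0.95
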