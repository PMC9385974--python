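"""Independent brute-force oracles used to verify the package's algorithms.

These deliberately avoid the code paths under test: distances come from
Floyd-Warshall on a dense matrix (not BFS), betweenness from explicit
shortest-path enumeration, cliques from subset enumeration, and EPC from
exhaustive edge-subset expectation.
"""

from itertools import combinations

import networkx as nx
import numpy as np

INF = float("inf")


def floyd_warshall(nodes, edges):
    """Dense all-pairs shortest-path lengths."""
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    dist = np.full((n, n), INF)
    np.fill_diagonal(dist, 0.0)
    for a, b in edges:
        dist[index[a], index[b]] = 1.0
        dist[index[b], index[a]] = 1.0
    for k in range(n):
        dist = np.minimum(dist, dist[:, k:k + 1] + dist[k:k + 1, :])
    return {v: {u: dist[index[v], index[u]] for u in nodes} for v in nodes}


def closeness_oracle(nodes, edges):
    dist = floyd_warshall(nodes, edges)
    return {
        v: sum(1.0 / d for u, d in dist[v].items() if u != v and d < INF)
        for v in nodes
    }


def eccentricity_oracle(nodes, edges):
    dist = floyd_warshall(nodes, edges)
    out = {}
    for v in nodes:
        reach = [d for d in dist[v].values() if d < INF]
        ecc = max(reach)
        out[v] = 1.0 / ecc if ecc > 0 else 0.0
    return out


def radiality_oracle(nodes, edges):
    dist = floyd_warshall(nodes, edges)
    out = {}
    comps = []
    remaining = set(nodes)
    while remaining:
        v = remaining.pop()
        comp = {u for u in nodes if dist[v][u] < INF}
        remaining -= comp
        comps.append(comp)
    for comp in comps:
        if len(comp) == 1:
            out[next(iter(comp))] = 0.0
            continue
        diameter = max(dist[v][u] for v in comp for u in comp)
        for v in comp:
            total = sum(diameter + 1 - dist[v][u] for u in comp if u != v)
            out[v] = total / (len(comp) - 1)
    return out


def betweenness_oracle(nodes, edges):
    """Sum over unordered pairs of the fraction of shortest paths through v,
    via explicit path enumeration."""
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    scores = {v: 0.0 for v in nodes}
    for s, t in combinations(nodes, 2):
        if not nx.has_path(g, s, t):
            continue
        paths = list(nx.all_shortest_paths(g, s, t))
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            if through:
                scores[v] += through / len(paths)
    return scores


def maximal_cliques_oracle(nodes, edges):
    """All maximal cliques by subset enumeration (n <= ~10)."""
    edge_set = {frozenset(e) for e in edges}
    nodes = list(nodes)
    cliques = []
    for r in range(1, len(nodes) + 1):
        for subset in combinations(nodes, r):
            if all(frozenset((a, b)) in edge_set
                   for a, b in combinations(subset, 2)):
                cliques.append(frozenset(subset))
    return [
        c for c in cliques
        if not any(c < d for d in cliques)
    ]


def mcc_oracle(nodes, edges):
    from math import factorial

    edge_set = {frozenset(e) for e in edges}
    adj = {v: set() for v in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    cliques = maximal_cliques_oracle(nodes, edges)
    out = {}
    for v in nodes:
        neighbourhood_has_edge = any(
            frozenset((a, b)) in edge_set for a, b in combinations(adj[v], 2)
        )
        if not neighbourhood_has_edge:
            out[v] = float(len(adj[v]))
        else:
            out[v] = float(sum(factorial(len(c) - 1) for c in cliques if v in c))
    return out


def epc_exact(nodes, edges, p):
    """Exact expected percolated-component size by enumerating all edge
    subsets (use only when len(edges) <= ~12)."""
    nodes = list(nodes)
    edges = list(edges)
    m = len(edges)
    expected = {v: 0.0 for v in nodes}
    for mask in range(2 ** m):
        kept = [edges[i] for i in range(m) if mask >> i & 1]
        k = len(kept)
        weight = (p ** k) * ((1 - p) ** (m - k))
        g = nx.Graph()
        g.add_nodes_from(nodes)
        g.add_edges_from(kept)
        for comp in nx.connected_components(g):
            for v in comp:
                expected[v] += weight * (len(comp) - 1)
    return expected


def hypergeom_tail_enumeration(k, K, n, N):
    """P(overlap >= k) by enumerating all C(N, n) draws from an urn whose
    first K items are marked."""
    total = 0
    hits = 0
    for draw in combinations(range(N), n):
        total += 1
        overlap = sum(1 for x in draw if x < K)
        if overlap >= k:
            hits += 1
    return hits / total if total else 1.0


def random_graph(rng, n_min=4, n_max=8, p_min=0.2, p_max=0.7):
    """A random simple graph as (nodes, edges) with string node labels."""
    n = int(rng.integers(n_min, n_max + 1))
    p = float(rng.uniform(p_min, p_max))
    nodes = [f"v{i}" for i in range(n)]
    edges = [
        (nodes[i], nodes[j])
        for i, j in combinations(range(n), 2)
        if rng.random() < p
    ]
    return nodes, edges
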