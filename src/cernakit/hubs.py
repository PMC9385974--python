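"""Seven centrality algorithms, consensus hub extraction, and axis listing.

All algorithms are implemented directly on unweighted, undirected simple
graphs (breadth-first search for distances; Bron-Kerbosch with pivoting for
maximal cliques; Brandes accumulation for betweenness; seeded Monte-Carlo
edge percolation for EPC). A node is a consensus hub when it appears in the
top-k list of every one of the seven algorithms.

Score definitions (d(v,t) = unweighted shortest-path distance):

- Degree:       |neighbours(v)|
- Closeness:    sum over t != v of 1/d(v,t)  (harmonic; unreachable -> 0)
- EcCentricity: 1 / max reachable d(v,t); isolated node -> 0
- Radiality:    within v's component (size n_c, diameter D):
                sum_t (D + 1 - d(v,t)) / (n_c - 1); singleton -> 0
- Betweenness:  sum over unordered pairs {s,t} of sigma_st(v)/sigma_st
- MCC:          sum over maximal cliques C containing v of (|C|-1)!;
                degree fallback when v's neighbourhood has no internal edge
- EPC:          mean, over random edge-retention realizations, of the number
                of other nodes still connected to v
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from typing import Dict, Hashable, Iterable, List, Mapping, Sequence, Tuple

import numpy as np

from .cerna import CeRNANetwork, Node
from .errors import ConfigError, DataError

ALGORITHMS = ("MCC", "Degree", "EPC", "EcCentricity", "Closeness",
              "Radiality", "Betweenness")

TIE_POLICIES = ("include_ties", "truncate")


@dataclass
class CentralityConfig:
    """Parameters for ranking and the EPC Monte-Carlo."""

    k_top: int = 10
    epc_realizations: int = 1000
    epc_retention: float = 0.5
    seed: int = 0
    tie_policy: str = "include_ties"

    def __post_init__(self):
        if self.k_top < 1:
            raise ConfigError("k_top must be >= 1")
        if self.epc_realizations < 1:
            raise ConfigError("epc_realizations must be >= 1")
        if not (0.0 <= self.epc_retention <= 1.0):
            raise ConfigError("epc_retention must be in [0, 1]")
        if self.tie_policy not in TIE_POLICIES:
            raise ConfigError(f"tie_policy must be one of {TIE_POLICIES}")


def _adjacency(net) -> Dict[Hashable, set]:
    """Adjacency dict from a CeRNANetwork, networkx graph, edge iterable, or
    an adjacency mapping (copied)."""
    if isinstance(net, CeRNANetwork):
        return net.adjacency()
    if isinstance(net, Mapping):
        adj = {v: set(nbrs) for v, nbrs in net.items()}
        for v, nbrs in adj.items():
            for u in nbrs:
                adj.setdefault(u, set()).add(v)
        return adj
    if hasattr(net, "adj"):  # networkx
        return {v: set(net.adj[v]) for v in net.nodes}
    adj: Dict[Hashable, set] = {}
    for a, b in net:
        if a == b:
            raise DataError("self-loops are not allowed")
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    return adj


def _bfs_distances(adj: Mapping, source) -> Dict[Hashable, int]:
    dist = {source: 0}
    queue = deque([source])
    while queue:
        v = queue.popleft()
        for u in adj[v]:
            if u not in dist:
                dist[u] = dist[v] + 1
                queue.append(u)
    return dist


def _components(adj: Mapping) -> List[set]:
    seen: set = set()
    comps = []
    for v in adj:
        if v not in seen:
            comp = set(_bfs_distances(adj, v))
            seen |= comp
            comps.append(comp)
    return comps


def degree(net) -> Dict[Hashable, float]:
    adj = _adjacency(net)
    return {v: float(len(nbrs)) for v, nbrs in adj.items()}


def closeness(net) -> Dict[Hashable, float]:
    adj = _adjacency(net)
    scores = {}
    for v in adj:
        dist = _bfs_distances(adj, v)
        scores[v] = float(sum(1.0 / d for t, d in dist.items() if t != v))
    return scores


def eccentricity_score(net) -> Dict[Hashable, float]:
    adj = _adjacency(net)
    scores = {}
    for v in adj:
        dist = _bfs_distances(adj, v)
        ecc = max(dist.values())
        scores[v] = 1.0 / ecc if ecc > 0 else 0.0
    return scores


def radiality(net) -> Dict[Hashable, float]:
    adj = _adjacency(net)
    scores: Dict[Hashable, float] = {}
    for comp in _components(adj):
        if len(comp) == 1:
            scores[next(iter(comp))] = 0.0
            continue
        dists = {v: _bfs_distances(adj, v) for v in comp}
        diameter = max(max(d.values()) for d in dists.values())
        n_c = len(comp)
        for v in comp:
            total = sum(diameter + 1 - d for t, d in dists[v].items() if t != v)
            scores[v] = total / (n_c - 1)
    return scores


def betweenness(net) -> Dict[Hashable, float]:
    """Brandes' algorithm; scores count each unordered pair once."""
    adj = _adjacency(net)
    scores = {v: 0.0 for v in adj}
    for s in adj:
        stack: List = []
        preds: Dict[Hashable, list] = {v: [] for v in adj}
        sigma = {v: 0.0 for v in adj}
        sigma[s] = 1.0
        dist = {s: 0}
        queue = deque([s])
        while queue:
            v = queue.popleft()
            stack.append(v)
            for u in adj[v]:
                if u not in dist:
                    dist[u] = dist[v] + 1
                    queue.append(u)
                if dist[u] == dist[v] + 1:
                    sigma[u] += sigma[v]
                    preds[u].append(v)
        delta = {v: 0.0 for v in adj}
        while stack:
            w = stack.pop()
            for v in preds[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                scores[w] += delta[w]
    # each unordered pair was accumulated from both endpoints
    return {v: s / 2.0 for v, s in scores.items()}


def _bron_kerbosch(adj: Mapping, r: set, p: set, x: set, out: List[frozenset]):
    if not p and not x:
        out.append(frozenset(r))
        return
    pivot = max(p | x, key=lambda u: len(adj[u] & p))
    for v in list(p - adj[pivot]):
        _bron_kerbosch(adj, r | {v}, p & adj[v], x & adj[v], out)
        p.remove(v)
        x.add(v)


def maximal_cliques(net) -> List[frozenset]:
    """All maximal cliques (Bron-Kerbosch with pivoting)."""
    adj = _adjacency(net)
    out: List[frozenset] = []
    if adj:
        _bron_kerbosch(adj, set(), set(adj), set(), out)
    return out


def mcc(net) -> Dict[Hashable, float]:
    adj = _adjacency(net)
    cliques = maximal_cliques(adj)
    scores = {}
    for v in adj:
        nbrs = adj[v]
        has_neighbour_edge = any(nbrs & adj[u] for u in nbrs)
        if not has_neighbour_edge:
            scores[v] = float(len(nbrs))
        else:
            scores[v] = float(sum(math.factorial(len(c) - 1)
                                  for c in cliques if v in c))
    return scores


def epc(net, config: CentralityConfig) -> Dict[Hashable, float]:
    """Monte-Carlo edge-percolated component size (excluding the node itself).

    Each realization keeps every edge independently with probability
    ``config.epc_retention``; the score is the mean count of other nodes in
    the node's surviving component.
    """
    adj = _adjacency(net)
    nodes = sorted(adj)
    index = {v: i for i, v in enumerate(nodes)}
    edges = sorted({tuple(sorted((index[a], index[b]), ))
                    for a in adj for b in adj[a] if index[a] < index[b]})
    n = len(nodes)
    totals = np.zeros(n)
    rng = np.random.default_rng(config.seed)
    m = len(edges)
    for _ in range(config.epc_realizations):
        if m:
            keep = rng.random(m) < config.epc_retention
        else:
            keep = np.empty(0, dtype=bool)
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for (a, b), k in zip(edges, keep):
            if k:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[ra] = rb
        roots = [find(i) for i in range(n)]
        sizes: Dict[int, int] = {}
        for r in roots:
            sizes[r] = sizes.get(r, 0) + 1
        totals += np.array([sizes[r] - 1 for r in roots], dtype=float)
    scores = totals / config.epc_realizations
    return {v: float(scores[index[v]]) for v in nodes}


def top_k(scores: Mapping[Hashable, float], config: CentralityConfig) -> List:
    """Nodes ranked by score descending, ties broken by identifier ascending.

    With ``include_ties`` (default) the list is extended past rank k to all
    nodes whose score equals the k-th score.
    """
    ranked = sorted(scores, key=lambda v: (-scores[v], v))
    k = config.k_top
    if len(ranked) <= k or config.tie_policy == "truncate":
        return ranked[:k]
    cutoff = scores[ranked[k - 1]]
    out = ranked[:k]
    for v in ranked[k:]:
        if scores[v] == cutoff:
            out.append(v)
        else:
            break
    return out


@dataclass
class CentralityReport:
    """Per-algorithm score maps and top-k lists."""

    scores: dict  # algorithm -> {node: score}
    top_lists: dict  # algorithm -> ordered node list
    config: CentralityConfig = field(default_factory=CentralityConfig)


def compute_centralities(net, config: CentralityConfig | None = None
                         ) -> CentralityReport:
    """Run all seven algorithms and rank each."""
    config = config or CentralityConfig()
    score_fns = {
        "MCC": mcc,
        "Degree": degree,
        "EPC": lambda g: epc(g, config),
        "EcCentricity": eccentricity_score,
        "Closeness": closeness,
        "Radiality": radiality,
        "Betweenness": betweenness,
    }
    scores = {alg: fn(net) for alg, fn in score_fns.items()}
    top_lists = {alg: top_k(scores[alg], config) for alg in ALGORITHMS}
    return CentralityReport(scores=scores, top_lists=top_lists, config=config)


@dataclass
class HubSet:
    """Nodes present in all seven top-k lists, plus the membership matrix."""

    hubs: tuple
    membership: dict  # node -> {algorithm: bool}

    def __contains__(self, node):
        return node in set(self.hubs)

    def membership_frame(self):
        import pandas as pd

        nodes = sorted(self.membership)
        return pd.DataFrame(
            [[self.membership[n][a] for a in ALGORITHMS] for n in nodes],
            index=[getattr(n, "id", n) for n in nodes], columns=list(ALGORITHMS),
        )


def consensus_hubs(report: CentralityReport | Mapping[str, Sequence]) -> HubSet:
    """Intersect the seven top-k lists; a hub must appear in all of them."""
    top_lists = report.top_lists if isinstance(report, CentralityReport) else report
    missing = set(ALGORITHMS) - set(top_lists)
    if missing:
        raise ConfigError(f"missing algorithms: {sorted(missing)}")
    union = {n for alg in ALGORITHMS for n in top_lists[alg]}
    membership = {
        n: {alg: n in set(top_lists[alg]) for alg in ALGORITHMS} for n in union
    }
    hubs = tuple(sorted(n for n in union
                        if all(membership[n][a] for a in ALGORITHMS)))
    return HubSet(hubs=hubs, membership=membership)


@dataclass(frozen=True, order=True)
class RegulatoryAxis:
    """A lncRNA -> miRNA -> mRNA path; the unit of interpretation."""

    lncrna: str
    mirna: str
    mrna: str
    network: str = ""

    @property
    def triple(self) -> Tuple[str, str, str]:
        return (self.lncrna, self.mirna, self.mrna)


def extract_axes(net: CeRNANetwork, hubs: HubSet | Iterable[Node]
                 ) -> List[RegulatoryAxis]:
    """All lncRNA-miRNA-mRNA paths whose three nodes are hubs and whose two
    edges exist in the network, sorted lexicographically."""
    hub_nodes = set(hubs.hubs) if isinstance(hubs, HubSet) else set(hubs)
    unknown = hub_nodes - net.nodes
    if unknown:
        raise DataError(f"hub nodes not in the network: {sorted(unknown)}")
    lncs = sorted(n for n in hub_nodes if n.kind == "lncRNA")
    mirs = sorted(n for n in hub_nodes if n.kind == "miRNA")
    genes = sorted(n for n in hub_nodes if n.kind == "mRNA")
    axes = []
    for m in mirs:
        for l in lncs:
            if not net.has_edge(l, m):
                continue
            for g in genes:
                if net.has_edge(m, g):
                    axes.append(RegulatoryAxis(lncrna=l.id, mirna=m.id,
                                               mrna=g.id, network=net.label))
    return sorted(axes)


@dataclass(frozen=True)
class DedupedAxis:
    lncrna: str
    mirna: str
    mrna: str
    networks: frozenset

    @property
    def triple(self):
        return (self.lncrna, self.mirna, self.mrna)


def dedup_axes(axes: Iterable[RegulatoryAxis]) -> List[DedupedAxis]:
    """Unique (lncRNA, miRNA, mRNA) triples across network labels, each
    annotated with the set of networks carrying it."""
    carriers: Dict[tuple, set] = {}
    for ax in axes:
        carriers.setdefault(ax.triple, set()).add(ax.network)
    return [
        DedupedAxis(lncrna=t[0], mirna=t[1], mrna=t[2],
                    networks=frozenset(carriers[t]))
        for t in sorted(carriers)
    ]
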