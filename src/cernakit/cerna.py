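"""Consensus voting over interaction sources and tripartite ceRNA assembly.

Interaction predictions disagree between sources, so pairs are retained only
when enough distinct sources report them (defaults: 3-of-4 for miRNA->mRNA,
2-of-2 for lncRNA->miRNA). Surviving pairs are assembled into an undirected
tripartite lncRNA-miRNA-mRNA network: the only edge types are lncRNA-miRNA
and miRNA-mRNA, and the network is anchored on a supplied mRNA set (the
differentially expressed genes of one cell-death category).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, NamedTuple, Sequence

import networkx as nx
import pandas as pd

from .errors import ConfigError, DataError, FormatError
from .gene_sets import normalize_symbol

NODE_KINDS = ("lncRNA", "miRNA", "mRNA")
#: Valid (regulator class, target class) pairs.
VALID_CLASS_PAIRS = {("miRNA", "mRNA"), ("lncRNA", "miRNA")}


class Node(NamedTuple):
    """A network node: identifier plus molecular class."""

    id: str
    kind: str


@dataclass(frozen=True)
class InteractionEvidence:
    """One predicted regulator->target pair from one source."""

    source: str
    regulator: str
    regulator_class: str
    target: str
    target_class: str

    def __post_init__(self):
        if (self.regulator_class, self.target_class) not in VALID_CLASS_PAIRS:
            raise FormatError(
                f"invalid class pair ({self.regulator_class}, {self.target_class}); "
                f"expected one of {sorted(VALID_CLASS_PAIRS)}"
            )


@dataclass(frozen=True)
class ConsensusInteraction:
    """A regulator->target pair supported by >= threshold distinct sources."""

    regulator: str
    regulator_class: str
    target: str
    target_class: str
    sources: frozenset

    @property
    def support(self) -> int:
        return len(self.sources)


def _normalize_identifier(identifier: str, kind: str) -> str:
    # gene symbols get canonical casing; ncRNA identifiers are case-preserved
    if kind == "mRNA":
        return normalize_symbol(identifier)
    return identifier.strip()


def load_evidence(paths: Sequence) -> List[InteractionEvidence]:
    """Read interaction TSVs (source, regulator, regulator_class, target,
    target_class), deduplicating (source, regulator, target) rows."""
    evidence: List[InteractionEvidence] = []
    seen = set()
    for path in paths:
        df = pd.read_csv(Path(path), sep="\t", dtype=str)
        required = {"source", "regulator", "regulator_class", "target",
                    "target_class"}
        missing = required - set(df.columns)
        if missing:
            raise FormatError(f"{path}: missing columns {sorted(missing)}")
        for rec in df.to_dict("records"):
            ev = InteractionEvidence(
                source=rec["source"].strip(),
                regulator=_normalize_identifier(rec["regulator"],
                                                rec["regulator_class"].strip()),
                regulator_class=rec["regulator_class"].strip(),
                target=_normalize_identifier(rec["target"],
                                             rec["target_class"].strip()),
                target_class=rec["target_class"].strip(),
            )
            key = (ev.source, ev.regulator, ev.target)
            if key not in seen:
                seen.add(key)
                evidence.append(ev)
    return evidence


def write_evidence_tsv(evidence: Iterable[InteractionEvidence], path) -> None:
    df = pd.DataFrame(
        [
            {
                "source": e.source,
                "regulator": e.regulator,
                "regulator_class": e.regulator_class,
                "target": e.target,
                "target_class": e.target_class,
            }
            for e in evidence
        ],
        columns=["source", "regulator", "regulator_class", "target",
                 "target_class"],
    )
    df.to_csv(Path(path), sep="\t", index=False)


def consensus_targets(evidence: Iterable[InteractionEvidence],
                      regulator_class: str, min_support: int
                      ) -> List[ConsensusInteraction]:
    """Vote-filter predicted pairs: keep those reported by >= ``min_support``
    distinct sources.

    Only evidence rows of the given ``regulator_class`` participate. Emits a
    config warning (and necessarily an empty result for that threshold) when
    ``min_support`` exceeds the number of distinct sources present.
    """
    if min_support < 1:
        raise ConfigError("min_support must be >= 1")
    rows = [e for e in evidence if e.regulator_class == regulator_class]
    all_sources = {e.source for e in rows}
    if rows and min_support > len(all_sources):
        warnings.warn(
            f"min_support={min_support} exceeds the {len(all_sources)} distinct "
            "sources present; consensus is necessarily empty", stacklevel=2)
    votes: Dict[tuple, set] = {}
    classes: Dict[tuple, tuple] = {}
    for e in rows:
        key = (e.regulator, e.target)
        votes.setdefault(key, set()).add(e.source)
        classes[key] = (e.regulator_class, e.target_class)
    out = [
        ConsensusInteraction(
            regulator=reg, regulator_class=classes[(reg, tgt)][0],
            target=tgt, target_class=classes[(reg, tgt)][1],
            sources=frozenset(sources),
        )
        for (reg, tgt), sources in votes.items()
        if len(sources) >= min_support
    ]
    out.sort(key=lambda c: (c.regulator, c.target))
    return out


@dataclass
class CeRNANetwork:
    """Undirected tripartite lncRNA-miRNA-mRNA network.

    ``nodes`` is a set of :class:`Node`; ``edges`` a set of frozenset node
    pairs. Edges may only join lncRNA-miRNA or miRNA-mRNA.
    """

    nodes: set = field(default_factory=set)
    edges: set = field(default_factory=set)
    label: str = ""

    def __post_init__(self):
        self.nodes = set(self.nodes)
        self.edges = {frozenset(e) for e in self.edges}
        self.validate()

    def validate(self, require_lncrna_partner: bool = False) -> None:
        """Check structural invariants; raises :class:`DataError` on failure.

        The requirement that every miRNA has a lncRNA neighbour is only
        enforced when ``require_lncrna_partner`` is set (assembly may retain
        partner-less miRNAs by default).
        """
        for n in self.nodes:
            if n.kind not in NODE_KINDS:
                raise DataError(f"unknown node class {n.kind!r}")
        for e in self.edges:
            if len(e) != 2:
                raise DataError("self-loops are not allowed")
        adjacency = self.adjacency()
        for e in self.edges:
            if len(e) != 2:
                raise DataError("self-loops are not allowed")
            kinds = {n.kind for n in e}
            if kinds not in ({"lncRNA", "miRNA"}, {"miRNA", "mRNA"}):
                raise DataError(
                    f"edge violates tripartite constraint: {sorted(kinds)}")
            for n in e:
                if n not in self.nodes:
                    raise DataError(f"edge endpoint {n} not in node set")
        for n in self.nodes:
            neigh = adjacency.get(n, set())
            kinds = {m.kind for m in neigh}
            if n.kind == "lncRNA" and "miRNA" not in kinds:
                raise DataError(f"lncRNA {n.id} has no miRNA neighbour")
            if n.kind == "mRNA" and "miRNA" not in kinds:
                raise DataError(f"mRNA {n.id} has no miRNA neighbour")
            if n.kind == "miRNA":
                if "mRNA" not in kinds:
                    raise DataError(f"miRNA {n.id} has no mRNA neighbour")
                if require_lncrna_partner and "lncRNA" not in kinds:
                    raise DataError(f"miRNA {n.id} has no lncRNA neighbour")

    def adjacency(self) -> Dict[Node, set]:
        adj: Dict[Node, set] = {n: set() for n in self.nodes}
        for e in self.edges:
            a, b = tuple(e)
            adj[a].add(b)
            adj[b].add(a)
        return adj

    def nodes_of_kind(self, kind: str) -> list:
        return sorted((n for n in self.nodes if n.kind == kind))

    def has_edge(self, a: Node, b: Node) -> bool:
        return frozenset((a, b)) in self.edges

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph(label=self.label)
        for n in sorted(self.nodes):
            g.add_node(f"{n.kind}:{n.id}", id=n.id, kind=n.kind)
        for e in sorted(self.edges, key=lambda e: tuple(sorted(e))):
            a, b = sorted(e)
            g.add_edge(f"{a.kind}:{a.id}", f"{b.kind}:{b.id}",
                       interaction="ceRNA")
        return g


def assemble(mrna_set: Iterable[str],
             mirna_consensus: Sequence[ConsensusInteraction],
             lncrna_consensus: Sequence[ConsensusInteraction],
             label: str = "",
             require_lncrna_partner: bool = False) -> CeRNANetwork:
    """Assemble a tripartite network anchored on an mRNA set.

    Keeps miRNA->mRNA consensus pairs whose target is in ``mrna_set``, then
    lncRNA->miRNA pairs whose miRNA survives. With ``require_lncrna_partner``
    miRNAs lacking a lncRNA sponge are dropped along with their edges;
    by default they are retained (targets of predictions are kept even
    without an upstream sponge).
    """
    mrna_norm = {normalize_symbol(g) for g in mrna_set}
    if not mrna_norm:
        raise ConfigError("mrna_set must be non-empty")
    mm = [c for c in mirna_consensus
          if c.regulator_class == "miRNA" and c.target in mrna_norm]
    kept_mirnas = {c.regulator for c in mm}
    lm = [c for c in lncrna_consensus
          if c.regulator_class == "lncRNA" and c.target in kept_mirnas]
    if require_lncrna_partner:
        partnered = {c.target for c in lm}
        mm = [c for c in mm if c.regulator in partnered]
        kept_mirnas &= partnered
        lm = [c for c in lm if c.target in kept_mirnas]
    edges = set()
    for c in mm:
        edges.add(frozenset((Node(c.regulator, "miRNA"), Node(c.target, "mRNA"))))
    for c in lm:
        edges.add(frozenset((Node(c.regulator, "lncRNA"), Node(c.target, "miRNA"))))
    nodes = {n for e in edges for n in e}
    net = CeRNANetwork(nodes=nodes, edges=edges, label=label)
    net.validate(require_lncrna_partner=require_lncrna_partner)
    return net


def network_summary(net: CeRNANetwork) -> Dict[str, int]:
    """Class/node/edge counts; class counts sum to the node count."""
    counts = {kind: len(net.nodes_of_kind(kind)) for kind in NODE_KINDS}
    return {
        "lncRNAs": counts["lncRNA"],
        "miRNAs": counts["miRNA"],
        "mRNAs": counts["mRNA"],
        "nodes": len(net.nodes),
        "edges": len(net.edges),
    }


# ---------------------------------------------------------------------------
# export / import

def write_sif(net: CeRNANetwork, path) -> None:
    """SIF export: one "<node>\tceRNA\t<node>" line per edge (lncRNA/miRNA
    listed first). Class information lives in the node-attribute TSV."""
    lines = []
    for e in sorted(net.edges, key=lambda e: tuple(sorted(e))):
        a, b = sorted(e, key=lambda n: (NODE_KINDS.index(n.kind), n.id))
        lines.append(f"{a.id}\tceRNA\t{b.id}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_node_attributes(net: CeRNANetwork, path) -> None:
    df = pd.DataFrame(
        [{"node": n.id, "class": n.kind} for n in sorted(net.nodes)],
        columns=["node", "class"],
    )
    df.to_csv(Path(path), sep="\t", index=False)


def write_edge_attributes(net: CeRNANetwork, path) -> None:
    records = []
    for e in sorted(net.edges, key=lambda e: tuple(sorted(e))):
        a, b = sorted(e, key=lambda n: (NODE_KINDS.index(n.kind), n.id))
        records.append({"node1": a.id, "class1": a.kind,
                        "node2": b.id, "class2": b.kind,
                        "interaction": "ceRNA"})
    pd.DataFrame(records, columns=["node1", "class1", "node2", "class2",
                                   "interaction"]).to_csv(
        Path(path), sep="\t", index=False)


def write_graphml(net: CeRNANetwork, path) -> None:
    nx.write_graphml(net.to_networkx(), Path(path))


def read_graphml(path, label: str = "") -> CeRNANetwork:
    g = nx.read_graphml(Path(path))
    nodes = {Node(data["id"], data["kind"]) for _, data in g.nodes(data=True)}
    by_key = {f"{n.kind}:{n.id}": n for n in nodes}
    edges = {frozenset((by_key[a], by_key[b])) for a, b in g.edges()}
    return CeRNANetwork(nodes=nodes, edges=edges,
                        label=label or g.graph.get("label", ""))


def read_sif(sif_path, node_attr_path, label: str = "") -> CeRNANetwork:
    """Reconstruct a network from SIF plus its node-attribute TSV.

    Requires identifiers to be unique across classes (guaranteed for
    networks exported by this module unless an id is reused by two classes,
    in which case GraphML is the lossless route).
    """
    attrs = pd.read_csv(Path(node_attr_path), sep="\t", dtype=str)
    kind_of = {}
    for rec in attrs.to_dict("records"):
        if rec["node"] in kind_of and kind_of[rec["node"]] != rec["class"]:
            raise FormatError(
                f"identifier {rec['node']!r} maps to two classes; "
                "use GraphML for round-tripping this network")
        kind_of[rec["node"]] = rec["class"]
    edges = set()
    text = Path(sif_path).read_text()
    for line in text.splitlines():
        if not line.strip():
            continue
        a, _, b = line.split("\t")
        edges.add(frozenset((Node(a, kind_of[a]), Node(b, kind_of[b]))))
    nodes = {Node(i, k) for i, k in kind_of.items()}
    return CeRNANetwork(nodes=nodes, edges=edges, label=label)


def export_network(net: CeRNANetwork, outdir, stem: str = "network") -> dict:
    """Write SIF, GraphML and attribute TSVs; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "sif": outdir / f"{stem}.sif",
        "graphml": outdir / f"{stem}.graphml",
        "nodes": outdir / f"{stem}.nodes.tsv",
        "edges": outdir / f"{stem}.edges.tsv",
    }
    write_sif(net, paths["sif"])
    write_graphml(net, paths["graphml"])
    write_node_attributes(net, paths["nodes"])
    write_edge_attributes(net, paths["edges"])
    return paths
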