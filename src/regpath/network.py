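"""Curated regulatory network container, sub-network extraction, topology.

The network is a simple directed graph over nodes of class TF, miRNA or
gene.  Building it from curated regulation records collapses redundant
edges (unioning their database provenance) and prunes self-directed loops.
A node that acts as a transcription factor anywhere keeps class TF even if
it is also somebody's target; "gene" is reserved for non-TF targets.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import networkx as nx

from .errors import ContractError, ValidationError
from .netio import RegulationRecord

logger = logging.getLogger(__name__)

NODE_CLASSES = ("TF", "miRNA", "gene")

#: class precedence when a node appears in conflicting roles
_CLASS_RANK = {"TF": 0, "miRNA": 1, "gene": 2}


@dataclass(frozen=True)
class Thresholds:
    """The tunable cut-offs of the pipeline.

    Defaults are the analysis' operating point: hubs at total degree >= 10,
    acyclic paths of 3..30 nodes, paths at least half differentially
    expressed, and per-path significance at p < 0.001.
    """

    hub_min_total_degree: int = 10
    min_path_len: int = 3
    max_path_len: int = 30
    de_fraction_min: float = 0.5
    alpha: float = 0.001

    def __post_init__(self):
        if self.min_path_len < 2:
            raise ValidationError("min_path_len must be >= 2")
        if self.max_path_len < self.min_path_len:
            raise ValidationError("max_path_len must be >= min_path_len")
        if not 0.0 <= self.de_fraction_min <= 1.0:
            raise ValidationError("de_fraction_min must be in [0, 1]")
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError("alpha must be in (0, 1)")
        if self.hub_min_total_degree < 0:
            raise ValidationError("hub_min_total_degree must be >= 0")


class DegreeSummary(NamedTuple):
    node: str
    in_degree: int
    out_degree: int
    total_degree: int


class RegulatoryNetwork:
    """Simple directed graph + node-class map + edge provenance.

    Invariants: no self-loops, at most one edge per ordered pair, every
    edge endpoint is a node, every node has a class.
    """

    def __init__(self):
        self._graph = nx.DiGraph()
        # populated by build_network
        self.self_loops_dropped: int = 0
        self.duplicates_collapsed: int = 0

    # -- construction -----------------------------------------------------

    def add_node(self, node: str, node_class: str) -> None:
        if node_class not in NODE_CLASSES:
            raise ValidationError(f"unknown node class {node_class!r}")
        current = self._graph.nodes[node]["node_class"] if node in self._graph else None
        if current is None or _CLASS_RANK[node_class] < _CLASS_RANK[current]:
            self._graph.add_node(node, node_class=node_class)
        else:
            self._graph.add_node(node)

    def add_edge(self, u: str, v: str, sources: Iterable[str] = ()) -> None:
        if u == v:
            raise ValidationError(f"self-loop {u}->{v} not allowed")
        if u not in self._graph or v not in self._graph:
            raise ValidationError(f"edge {u}->{v} references an unknown node")
        existing = self._graph.get_edge_data(u, v)
        pooled = set(sources)
        if existing is not None:
            pooled |= existing["sources"]
        self._graph.add_edge(u, v, sources=pooled)

    # -- views ------------------------------------------------------------

    @property
    def nodes(self) -> set[str]:
        return set(self._graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return set(self._graph.edges)

    @property
    def node_class(self) -> dict[str, str]:
        return nx.get_node_attributes(self._graph, "node_class")

    @property
    def edge_provenance(self) -> dict[tuple[str, str], set[str]]:
        return {(u, v): set(d["sources"]) for u, v, d in self._graph.edges(data=True)}

    @property
    def n_nodes(self) -> int:
        return self._graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._graph.number_of_edges()

    def in_degree(self, node: str) -> int:
        return self._graph.in_degree(node)

    def out_degree(self, node: str) -> int:
        return self._graph.out_degree(node)

    def successors(self, node: str) -> list[str]:
        return sorted(self._graph.successors(node))

    def predecessors(self, node: str) -> list[str]:
        return sorted(self._graph.predecessors(node))

    def neighbors(self, node: str) -> set[str]:
        """Neighbours in either direction (direction ignored)."""
        return set(self._graph.successors(node)) | set(self._graph.predecessors(node))

    def to_records(self) -> list[RegulationRecord]:
        """Dump the network back to regulation records (one per edge)."""
        classes = self.node_class
        records = []
        for u, v in sorted(self.edges):
            prov = sorted(self.edge_provenance.get((u, v), set()))
            records.append(
                RegulationRecord(u, classes[u], v, classes[v], ";".join(prov))
            )
        return records

    def to_networkx(self) -> nx.DiGraph:
        return self._graph.copy()

    def __contains__(self, node: str) -> bool:
        return node in self._graph

    def __repr__(self) -> str:  # pragma: no cover
        return f"RegulatoryNetwork(nodes={self.n_nodes}, edges={self.n_edges})"


@dataclass
class ActiveSubnetwork:
    """A seed-anchored sub-network and the seeds that induced it."""

    network: RegulatoryNetwork
    seeds: set[str] = field(default_factory=set)
    mapped_seed_count: int = 0


def build_network(records: Iterable[RegulationRecord]) -> RegulatoryNetwork:
    """Assemble a :class:`RegulatoryNetwork` from curated regulation records.

    Redundant (regulator, target) pairs collapse into one edge whose
    provenance is the union of source databases; self-directed loops are
    pruned.  Node classes resolve with precedence TF > miRNA > gene.  A
    node claimed both as TF and miRNA raises :class:`ValidationError`.
    """
    records = list(records)
    claimed: dict[str, set[str]] = {}
    for rec in records:
        claimed.setdefault(rec.regulator_id, set()).add(rec.regulator_class)
        claimed.setdefault(rec.target_id, set()).add(rec.target_class)
    offenders = sorted(n for n, cls in claimed.items() if {"TF", "miRNA"} <= cls)
    if offenders:
        raise ValidationError(
            "node(s) claimed both TF and miRNA: " + ", ".join(offenders)
        )

    net = RegulatoryNetwork()
    for rec in records:
        net.add_node(rec.regulator_id, rec.regulator_class)
        net.add_node(rec.target_id, rec.target_class)

    seen: set[tuple[str, str]] = set()
    self_loops = 0
    duplicates = 0
    for rec in records:
        pair = (rec.regulator_id, rec.target_id)
        if pair[0] == pair[1]:
            self_loops += 1
            continue
        if pair in seen:
            duplicates += 1
        seen.add(pair)
        sources = {rec.source_db} if rec.source_db else set()
        net.add_edge(*pair, sources)
    net.self_loops_dropped = self_loops
    net.duplicates_collapsed = duplicates
    logger.info(
        "built network: %d nodes, %d edges (%d self-loops pruned, %d duplicates collapsed)",
        net.n_nodes, net.n_edges, self_loops, duplicates,
    )
    return net


def extract_active_subnetwork(
    net: RegulatoryNetwork,
    seed_ids: Iterable[str],
    *,
    induced: bool = True,
) -> ActiveSubnetwork:
    """Extract the potentially active sub-network anchored at seed nodes.

    Retains every mapped seed plus each of its immediate neighbours,
    ignoring edge direction for neighbour discovery.  With ``induced=True``
    (default) the edge set is the full induced subgraph over the retained
    nodes; with ``induced=False`` only edges incident to a seed are kept.
    Seeds absent from the network are counted but not fatal; zero mapped
    seeds yields an empty sub-network with a warning.
    """
    seed_ids = set(seed_ids)
    mapped = seed_ids & net.nodes
    if not mapped:
        logger.warning("no seed mapped to the network; sub-network is empty")
        return ActiveSubnetwork(RegulatoryNetwork(), set(), 0)

    keep = set(mapped)
    for seed in mapped:
        keep |= net.neighbors(seed)

    sub = RegulatoryNetwork()
    classes = net.node_class
    for node in keep:
        sub.add_node(node, classes[node])
    provenance = net.edge_provenance
    for u, v in net.edges:
        if u in keep and v in keep:
            if induced or u in mapped or v in mapped:
                sub.add_edge(u, v, provenance.get((u, v), set()))
    logger.info(
        "active sub-network: %d/%d seeds mapped, %d nodes, %d edges",
        len(mapped), len(seed_ids), sub.n_nodes, sub.n_edges,
    )
    return ActiveSubnetwork(sub, mapped, len(mapped))


def degrees(net: RegulatoryNetwork) -> list[DegreeSummary]:
    """Per-node in/out/total degree, sorted by node identifier."""
    return [
        DegreeSummary(n, net.in_degree(n), net.out_degree(n),
                      net.in_degree(n) + net.out_degree(n))
        for n in sorted(net.nodes)
    ]


def degree_distribution(net: RegulatoryNetwork, node_class: str) -> dict[int, int]:
    """Histogram of total degree over nodes of one class."""
    if node_class not in NODE_CLASSES:
        raise ValidationError(f"unknown node class {node_class!r}")
    classes = net.node_class
    counts = Counter(
        net.in_degree(n) + net.out_degree(n)
        for n in net.nodes
        if classes[n] == node_class
    )
    return dict(counts)


def find_hubs(
    net: RegulatoryNetwork,
    thresholds: Thresholds | None = None,
    *,
    strict: bool = False,
) -> list[DegreeSummary]:
    """Nodes whose total degree reaches the hub threshold.

    Inclusive (``>=``) by default so that nodes sitting exactly at the
    threshold count as hubs; ``strict=True`` switches to ``>``.  Sorted by
    total degree descending, ties broken lexicographically.
    """
    thresholds = thresholds or Thresholds()
    cut = thresholds.hub_min_total_degree
    hubs = [
        d for d in degrees(net)
        if (d.total_degree > cut if strict else d.total_degree >= cut)
    ]
    return sorted(hubs, key=lambda d: (-d.total_degree, d.node))
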