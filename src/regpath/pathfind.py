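"""Acyclic regulatory path discovery and scoring.

A regulatory path is a repeat-free walk along directed edges from a source
(zero in-degree) to a sink (zero out-degree) of the searched network, 3-30
nodes long by default.  Candidate paths are filtered for differential-
expression content, scored by the coverage ratio of known disease nodes
(k / L) and an upper-tail hypergeometric test against the candidate-path
node population, and the significant paths are merged into one composite
path graph.

Source/sink status is evaluated on the searched (sub-)network, not any
parent network: the method runs on the seed-anchored active sub-network, so
path endpoints are relative to it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .errors import ContractError
from .network import RegulatoryNetwork, Thresholds
from .stats import hypergeom_upper_tail

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AcyclicPath:
    """An ordered source-to-sink node walk with no repeats."""

    nodes: tuple[str, ...]

    def __post_init__(self):
        if len(set(self.nodes)) != len(self.nodes):
            raise ContractError(f"path repeats a node: {'->'.join(self.nodes)}")

    @property
    def length(self) -> int:
        """Path length counted in nodes."""
        return len(self.nodes)

    def __iter__(self):
        return iter(self.nodes)


@dataclass(frozen=True)
class PathScore:
    """A path together with its DE fraction, coverage ratio and p-value."""

    path: AcyclicPath
    de_fraction: float
    n_known: int
    coverage_ratio: float
    p_value: float


@dataclass(frozen=True)
class PathPopulation:
    """Node population underlying per-path hypergeometric tests.

    ``n_total`` is the number of distinct nodes on any candidate path and
    ``n_known`` how many of those are known disease nodes.
    """

    n_total: int
    n_known: int

    def __post_init__(self):
        if self.n_known > self.n_total:
            raise ContractError("population cannot contain more known nodes than nodes")


def find_sources(net: RegulatoryNetwork) -> set[str]:
    """Nodes with zero in-degree (isolated nodes included)."""
    return {n for n in net.nodes if net.in_degree(n) == 0}


def find_sinks(net: RegulatoryNetwork) -> set[str]:
    """Nodes with zero out-degree (isolated nodes included)."""
    return {n for n in net.nodes if net.out_degree(n) == 0}


def enumerate_acyclic_paths(
    net: RegulatoryNetwork,
    thresholds: Thresholds | None = None,
) -> list[AcyclicPath]:
    """Enumerate every acyclic source-to-sink path within the length caps.

    Depth-first traversal from each zero-in-degree node, extending only to
    nodes not already on the current walk, emitting a path whenever a
    zero-out-degree node is reached at an admissible length.  Walks are
    abandoned once they exceed ``max_path_len`` nodes.  Cyclic input is
    fine: cycles are simply never traversed into a repeat.  Output is
    deduplicated and lexicographically ordered.
    """
    thresholds = thresholds or Thresholds()
    min_len, max_len = thresholds.min_path_len, thresholds.max_path_len
    successors = {n: net.successors(n) for n in net.nodes}
    sinks = {n for n, succ in successors.items() if not succ}

    found: set[tuple[str, ...]] = set()
    for source in sorted(find_sources(net)):
        # iterative DFS; each frame is (node, iterator over its successors)
        path = [source]
        on_path = {source}
        stack = [iter(successors[source])]
        if source in sinks and min_len <= 1 <= max_len:
            found.add((source,))
        while stack:
            child = next(stack[-1], None)
            if child is None:
                stack.pop()
                on_path.discard(path.pop())
                continue
            if child in on_path or len(path) >= max_len:
                continue
            path.append(child)
            on_path.add(child)
            if child in sinks:
                if min_len <= len(path):
                    found.add(tuple(path))
                on_path.discard(path.pop())
            else:
                stack.append(iter(successors[child]))
    paths = [AcyclicPath(nodes) for nodes in sorted(found)]
    logger.info("enumerated %d candidate acyclic paths", len(paths))
    return paths


def de_fraction(path: AcyclicPath, de_ids: Iterable[str]) -> float:
    de_ids = set(de_ids)
    return sum(1 for n in path.nodes if n in de_ids) / path.length


def filter_by_de_fraction(
    paths: Sequence[AcyclicPath],
    de_ids: Iterable[str],
    thresholds: Thresholds | None = None,
) -> list[AcyclicPath]:
    """Keep paths whose DE fraction meets the threshold (inclusive).

    All node classes count: TF genes are genes, so TFs enter both the
    numerator and the denominator.
    """
    thresholds = thresholds or Thresholds()
    de_ids = set(de_ids)
    kept = [p for p in paths if de_fraction(p, de_ids) >= thresholds.de_fraction_min]
    logger.info("%d/%d paths pass the DE-fraction filter", len(kept), len(paths))
    return kept


def build_path_population(
    paths: Sequence[AcyclicPath],
    known_ids: Iterable[str],
) -> PathPopulation:
    """Population (all candidate-path nodes, known among them) for scoring."""
    if not paths:
        raise ContractError("cannot build a path population from zero paths")
    union: set[str] = set()
    for p in paths:
        union.update(p.nodes)
    n_known = len(union & set(known_ids))
    return PathPopulation(n_total=len(union), n_known=n_known)


def score_paths(
    paths: Sequence[AcyclicPath],
    known_ids: Iterable[str],
    population: PathPopulation,
    de_ids: Iterable[str] = (),
) -> list[PathScore]:
    """Score each path by coverage ratio and hypergeometric upper tail.

    For a path of L nodes containing k known disease nodes the coverage
    ratio is k / L and the p-value is P(X >= k) with
    X ~ Hypergeometric(N_pop, K_pop, L).
    """
    known_ids = set(known_ids)
    de_ids = set(de_ids)
    scores = []
    for p in paths:
        if p.length > population.n_total:
            raise ContractError(
                f"path of {p.length} nodes exceeds population size {population.n_total}"
            )
        k = sum(1 for n in p.nodes if n in known_ids)
        scores.append(
            PathScore(
                path=p,
                de_fraction=de_fraction(p, de_ids),
                n_known=k,
                coverage_ratio=k / p.length,
                p_value=hypergeom_upper_tail(
                    population.n_total, population.n_known, p.length, k
                ),
            )
        )
    return scores


def select_significant(
    scored: Sequence[PathScore],
    thresholds: Thresholds | None = None,
) -> list[PathScore]:
    """Paths with p-value strictly below alpha, sorted ascending by p."""
    thresholds = thresholds or Thresholds()
    kept = [s for s in scored if s.p_value < thresholds.alpha]
    kept.sort(key=lambda s: (s.p_value, s.path.nodes))
    logger.info("%d/%d paths significant at alpha=%g", len(kept), len(scored), thresholds.alpha)
    return kept


def merge_paths(
    paths: Sequence[AcyclicPath],
    node_class: Mapping[str, str] | None = None,
) -> RegulatoryNetwork:
    """Union of paths as one composite path graph.

    Nodes are the union of path nodes, edges the union of consecutive
    pairs.  Classes are inherited from ``node_class`` (for example the
    searched network's class map); nodes without a known class default to
    "gene".  Merging is commutative and idempotent under set semantics.
    """
    if not paths:
        raise ContractError("cannot merge zero paths")
    node_class = dict(node_class or {})
    merged = RegulatoryNetwork()
    for p in paths:
        for n in p.nodes:
            merged.add_node(n, node_class.get(n, "gene"))
    for p in paths:
        for u, v in zip(p.nodes, p.nodes[1:]):
            merged.add_edge(u, v)
    return merged


@dataclass
class PathAnalysis:
    """Bundle of every stage of one path-discovery run."""

    candidates: list[AcyclicPath]
    population: PathPopulation | None
    filtered: list[AcyclicPath]
    scored: list[PathScore]
    significant: list[PathScore]


def find_significant_paths(
    net: RegulatoryNetwork,
    de_ids: Iterable[str],
    known_ids: Iterable[str],
    thresholds: Thresholds | None = None,
    *,
    apply_de_filter: bool = True,
    population: PathPopulation | None = None,
) -> PathAnalysis:
    """Run the full path stage: enumerate, filter, score, select.

    The hypergeometric population defaults to the union of ALL enumerated
    candidate paths (before DE filtering), mirroring a test of the
    significant paths' content against everything the path search could
    have returned; pass ``population`` to score against an externally
    determined population instead.
    """
    thresholds = thresholds or Thresholds()
    candidates = enumerate_acyclic_paths(net, thresholds)
    if not candidates:
        return PathAnalysis([], None, [], [], [])
    if population is None:
        population = build_path_population(candidates, known_ids)
    filtered = (
        filter_by_de_fraction(candidates, de_ids, thresholds)
        if apply_de_filter
        else list(candidates)
    )
    scored = score_paths(filtered, known_ids, population, de_ids)
    significant = select_significant(scored, thresholds)
    return PathAnalysis(candidates, population, filtered, scored, significant)
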