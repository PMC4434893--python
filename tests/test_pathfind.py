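"""Acyclic path enumeration, filtering, scoring, selection and merging.

Enumeration is checked against two independent oracles: networkx's
all_simple_paths over every source/sink pair, and (on DAGs) a dynamic-
programming count of source-to-sink paths over a topological order.
"""

import itertools

import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from regpath import (
    AcyclicPath,
    ContractError,
    PathPopulation,
    RegulationRecord,
    RegulatoryNetwork,
    Thresholds,
    build_network,
    build_path_population,
    enumerate_acyclic_paths,
    filter_by_de_fraction,
    find_sinks,
    find_sources,
    merge_paths,
    score_paths,
    select_significant,
)


def _net(edges, isolated=()):
    records = [RegulationRecord(u, "TF", v, "gene") for u, v in edges]
    net = build_network(records) if records else RegulatoryNetwork()
    for node in isolated:
        net.add_node(node, "gene")
    return net


def oracle_paths(net, min_len=3, max_len=30):
    """Independent enumeration via networkx over all source/sink pairs."""
    graph = net.to_networkx()
    sources = [n for n in graph if graph.in_degree(n) == 0]
    sinks = [n for n in graph if graph.out_degree(n) == 0]
    found = set()
    for s in sources:
        for t in sinks:
            if s == t:
                if min_len <= 1 <= max_len:
                    found.add((s,))
                continue
            for path in nx.all_simple_paths(graph, s, t, cutoff=max_len - 1):
                if min_len <= len(path) <= max_len:
                    found.add(tuple(path))
    return sorted(found)


def dp_source_sink_count(net):
    """Source-to-sink path count on a DAG by DP over a topological order."""
    graph = net.to_networkx()
    order = list(nx.topological_sort(graph))
    counts = {n: (1 if graph.in_degree(n) == 0 else 0) for n in order}
    for n in order:
        for succ in graph.successors(n):
            counts[succ] += counts[n]
    return sum(counts[n] for n in graph if graph.out_degree(n) == 0)


def _random_digraph(rng_edges):
    """Build a digraph from a hypothesis-drawn edge list (cycles allowed)."""
    return _net([e for e in rng_edges if e[0] != e[1]])


class TestSourcesAndSinks:
    def test_sts_sources_and_sink(self, sts):
        assert find_sources(sts.network) == {"AP2", "BMP-2"}
        assert find_sinks(sts.network) == {"TYMS"}

    def test_two_cycle_has_no_sources(self):
        net = _net([("A", "B"), ("B", "A")])
        assert find_sources(net) == set()
        assert find_sinks(net) == set()

    def test_isolated_node_is_source_and_sink(self):
        net = _net([("A", "B")], isolated=["X"])
        assert "X" in find_sources(net)
        assert "X" in find_sinks(net)


class TestEnumerate:
    def test_length_floor_drops_two_node_shortcut(self):
        net = _net([("A", "B"), ("B", "C"), ("A", "C")])
        paths = enumerate_acyclic_paths(net)
        assert [p.nodes for p in paths] == [("A", "B", "C")]

    def test_sts_merged_network_has_24_paths(self, sts):
        # two sources x two MYC branches x three PTEN branches x two
        # ESR1->TP53 routes
        assert len(enumerate_acyclic_paths(sts.network)) == 24

    def test_cycle_plus_chain(self):
        net = _net([("A", "B"), ("B", "A"), ("D", "E")], isolated=["C"])
        paths = enumerate_acyclic_paths(net, Thresholds(min_path_len=2))
        assert [p.nodes for p in paths] == [("D", "E")]

    def test_max_length_aborts_walk_instead_of_truncating(self):
        chain = [(f"n{i:02d}", f"n{i + 1:02d}") for i in range(6)]
        net = _net(chain)
        assert enumerate_acyclic_paths(net, Thresholds(max_path_len=5)) == []
        (full,) = enumerate_acyclic_paths(net, Thresholds(max_path_len=7))
        assert full.length == 7

    def test_deterministic_lexicographic_order(self, sts):
        paths = enumerate_acyclic_paths(sts.network)
        assert [p.nodes for p in paths] == sorted(p.nodes for p in paths)

    @settings(deadline=None, max_examples=100)
    @given(st.lists(st.tuples(st.integers(0, 9), st.integers(0, 9)),
                    min_size=0, max_size=20))
    def test_matches_oracle_on_random_digraphs(self, raw_edges):
        edges = [(f"v{a}", f"v{b}") for a, b in raw_edges if a != b]
        if not edges:
            return
        net = _net(edges)
        got = [p.nodes for p in enumerate_acyclic_paths(net, Thresholds(min_path_len=2))]
        assert got == oracle_paths(net, min_len=2)

    @settings(deadline=None, max_examples=100)
    @given(st.lists(st.tuples(st.integers(0, 11), st.integers(0, 11)),
                    min_size=1, max_size=25))
    def test_dp_count_on_dags(self, raw_edges):
        # orient every edge low->high so the graph is a DAG
        edges = {(f"v{min(a, b):02d}", f"v{max(a, b):02d}")
                 for a, b in raw_edges if a != b}
        if not edges:
            return
        net = _net(sorted(edges))
        paths = enumerate_acyclic_paths(
            net, Thresholds(min_path_len=2, max_path_len=30)
        )
        singletons = {n for n in net.nodes
                      if net.in_degree(n) == 0 and net.out_degree(n) == 0}
        assert len(paths) + len(singletons) == dp_source_sink_count(net)

    @settings(deadline=None, max_examples=60)
    @given(st.lists(st.tuples(st.integers(0, 9), st.integers(0, 9)),
                    min_size=0, max_size=20))
    def test_emitted_paths_satisfy_invariants(self, raw_edges):
        edges = [(f"v{a}", f"v{b}") for a, b in raw_edges if a != b]
        if not edges:
            return
        net = _net(edges)
        thresholds = Thresholds(min_path_len=2, max_path_len=6)
        for path in enumerate_acyclic_paths(net, thresholds):
            assert len(set(path.nodes)) == path.length
            assert thresholds.min_path_len <= path.length <= thresholds.max_path_len
            assert net.in_degree(path.nodes[0]) == 0
            assert net.out_degree(path.nodes[-1]) == 0
            for u, v in zip(path.nodes, path.nodes[1:]):
                assert (u, v) in net.edges

    def test_raising_max_len_never_removes_paths(self, sts):
        shorter = {p.nodes for p in enumerate_acyclic_paths(
            sts.network, Thresholds(max_path_len=9))}
        longer = {p.nodes for p in enumerate_acyclic_paths(
            sts.network, Thresholds(max_path_len=11))}
        assert shorter <= longer


class TestDeFilter:
    def test_boundary_is_inclusive(self):
        path = AcyclicPath(("A", "B", "C", "D"))
        assert filter_by_de_fraction([path], {"A", "B"}) == [path]

    def test_below_threshold_dropped(self):
        path = AcyclicPath(("A", "B", "C"))
        assert filter_by_de_fraction([path], {"A"}) == []

    def test_empty_de_set(self):
        path = AcyclicPath(("A", "B", "C"))
        assert filter_by_de_fraction([path], set()) == []
        assert filter_by_de_fraction(
            [path], set(), Thresholds(de_fraction_min=0.0)
        ) == [path]

    def test_raising_threshold_never_adds_paths(self, sts):
        low = set(
            p.nodes for p in filter_by_de_fraction(
                sts.chains, sts.de_ids, Thresholds(de_fraction_min=0.4))
        )
        high = set(
            p.nodes for p in filter_by_de_fraction(
                sts.chains, sts.de_ids, Thresholds(de_fraction_min=0.8))
        )
        assert high <= low


class TestPopulationAndScoring:
    def test_population_counts_union(self):
        paths = [AcyclicPath(("A", "B", "C")), AcyclicPath(("A", "C", "D"))]
        pop = build_path_population(paths, {"C", "D"})
        assert (pop.n_total, pop.n_known) == (4, 2)

    def test_population_with_disjoint_known(self):
        pop = build_path_population([AcyclicPath(("A", "B", "C"))], {"Z"})
        assert pop.n_known == 0

    def test_empty_paths_is_contract_error(self):
        with pytest.raises(ContractError):
            build_path_population([], set())

    def test_sts_chain_scores(self, sts):
        scores = score_paths(sts.chains, sts.known_ids, sts.population, sts.de_ids)
        for s in scores:
            assert s.n_known == 7
            assert s.path.length == 10
            assert s.coverage_ratio == pytest.approx(0.7)
            assert s.p_value == pytest.approx(7.4148e-4, rel=1e-4)
            assert round(s.p_value, 4) == 0.0007

    def test_unknown_free_path_scores_one(self):
        scores = score_paths(
            [AcyclicPath(("A", "B", "C"))], {"Z"}, PathPopulation(10, 3)
        )
        assert scores[0].n_known == 0
        assert scores[0].coverage_ratio == 0.0
        assert scores[0].p_value == 1.0

    def test_path_longer_than_population_rejected(self):
        with pytest.raises(ContractError):
            score_paths([AcyclicPath(("A", "B", "C"))], set(), PathPopulation(2, 1))


class TestSelectSignificant:
    def test_alpha_is_strict(self):
        pop = PathPopulation(127, 27)
        scores = score_paths(
            [AcyclicPath(tuple(f"n{i}" for i in range(10)))],
            {f"n{i}" for i in range(7)},
            pop,
        )
        assert scores[0].p_value < 0.001
        assert select_significant(scores) == scores
        at_boundary = scores[0].__class__(
            path=scores[0].path, de_fraction=0.5, n_known=7,
            coverage_ratio=0.7, p_value=0.001,
        )
        assert select_significant([at_boundary]) == []

    def test_sorted_ascending_by_p(self, sts):
        pop = sts.population
        short = AcyclicPath(("MYC", "PTEN", "TYMS"))
        scores = score_paths([short] + list(sts.chains[:1]), sts.known_ids, pop)
        selected = select_significant(scores, Thresholds(alpha=1.0 - 1e-12))
        assert [s.p_value for s in selected] == sorted(s.p_value for s in selected)

    def test_empty_input(self):
        assert select_significant([]) == []


class TestMergePaths:
    def test_sts_merge_is_15_nodes_18_edges(self, sts):
        merged = merge_paths(sts.chains, sts.network.node_class)
        assert merged.n_nodes == 15
        assert merged.n_edges == 18
        assert merged.edges == sts.network.edges

    def test_single_path_merges_to_its_chain(self):
        path = AcyclicPath(("A", "B", "C"))
        merged = merge_paths([path])
        assert merged.edges == {("A", "B"), ("B", "C")}

    def test_commutative_and_idempotent(self, sts):
        forward = merge_paths(sts.chains)
        backward = merge_paths(list(reversed(sts.chains)))
        doubled = merge_paths(list(sts.chains) * 2)
        assert forward.edges == backward.edges == doubled.edges
        assert forward.nodes == backward.nodes == doubled.nodes

    def test_classes_inherited(self, sts):
        merged = merge_paths(sts.chains, sts.network.node_class)
        assert merged.node_class["hsa-miR-215"] == "miRNA"
        assert merged.node_class["TYMS"] == "gene"

    def test_empty_input_is_contract_error(self):
        with pytest.raises(ContractError):
            merge_paths([])
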