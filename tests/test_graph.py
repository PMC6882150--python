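"""Counting, supports, distances, medians, sampling and subgraph algebra."""

import itertools
from fractions import Fraction

import pytest
from hypothesis import given, settings, strategies as st

import mprclust as m
from mprclust.graph import event_sort_key, traversal_json_obj, traversal_report

from conftest import brute_pair_distance_mean, graph_of, small_instances


def interesting_graphs(n, seed0=0, min_t=2, max_t=500):
    out = []
    seed = seed0
    while len(out) < n:
        inst = small_instances(1, seed0=seed, max_leaves=5)[0]
        seed += 1
        g = graph_of(inst)
        _, total = m.count_below(g)
        if min_t <= total <= max_t:
            out.append((inst, g))
    return out


class TestCounting:
    def test_single_leaf(self):
        g = graph_of(m.fixture("leaf1"))
        _, total = m.count_below(g)
        assert total == 1

    def test_toy3_count(self, toy3_graph):
        _, total = m.count_below(toy3_graph)
        assert total == 3

    def test_count_matches_enumeration(self):
        for inst, g in interesting_graphs(25):
            below, total = m.count_below(g)
            travs = m.enumerate_traversals(g)
            assert total == len(travs)

    def test_event_counts_match_enumeration(self):
        for inst, g in interesting_graphs(15, seed0=200):
            stats = m.subgraph_stats(g)
            travs = m.enumerate_traversals(g)
            for e in g.events:
                assert stats.event_count[e] == sum(1 for t in travs if e in t.events)
                assert 0 < stats.event_count[e] <= stats.mpr_count

    def test_above_source_is_one(self, toy3_graph):
        below, _ = m.count_below(toy3_graph)
        above = m.count_above(toy3_graph, below)
        for src in toy3_graph.sources:
            assert above[src] == 1

    def test_mapping_node_flow_conservation(self):
        """Event children of a fully included mapping node partition the
        traversals through it."""
        for inst, g in interesting_graphs(10, seed0=400):
            stats = m.subgraph_stats(g)
            travs = m.enumerate_traversals(g)
            for pair in g.mapping_nodes:
                through = sum(
                    1 for t in travs if any(e.pair == pair for e in t.events)
                )
                kids = g.events_at(pair)
                if kids:
                    assert sum(stats.event_count[e] for e in kids) == through


class TestSupportAndDistance:
    def test_toy3_supports(self, toy3_graph):
        stats = m.subgraph_stats(toy3_graph)
        for e in toy3_graph.events:
            expected = Fraction(1) if e.kind == "C" else Fraction(1, 3)
            assert stats.support[e] == expected
        assert stats.mean_support == Fraction(1, 3)
        assert stats.mean_pairwise_distance == Fraction(8, 3)

    def test_singleton_subgraph_supports_one(self):
        g = graph_of(m.fixture("dup1"))
        stats = m.subgraph_stats(g)
        assert stats.mpr_count == 1
        assert all(s == 1 for s in stats.support.values())
        assert stats.mean_support == 1
        assert stats.mean_pairwise_distance == 0

    def test_leaf_only_space_sigma_defined_as_one(self):
        stats = m.subgraph_stats(graph_of(m.fixture("leaf1")))
        assert stats.mean_support == 1

    def test_supports_in_unit_interval(self):
        for inst, g in interesting_graphs(10, seed0=300):
            stats = m.subgraph_stats(g)
            assert all(0 < s <= 1 for s in stats.support.values())
            assert 0 < stats.mean_support <= 1

    def test_mean_distance_matches_enumeration(self):
        """Per-event decomposition equals the brute-force pair average."""
        for inst, g in interesting_graphs(20, seed0=500):
            stats = m.subgraph_stats(g)
            travs = m.enumerate_traversals(g)
            assert stats.mean_pairwise_distance == brute_pair_distance_mean(travs)

    def test_traversal_costs_all_optimal(self):
        for inst, g in interesting_graphs(10, seed0=600):
            opt = m.compute_dp(inst).opt_cost
            for t in m.enumerate_traversals(g):
                assert t.cost(inst) == opt


class TestMedian:
    def test_unique_traversal_is_its_own_median(self):
        g = graph_of(m.fixture("dup1"))
        med = m.median_traversal(g)
        assert med.events == m.enumerate_traversals(g)[0].events

    def test_toy3_median_tie_break(self, toy3_graph):
        """The two transfer MPRs tie at total distance 5; the tie-break
        picks the one whose source sorts first (root placed at A)."""
        med = m.median_traversal(toy3_graph)
        assert med.root == toy3_graph.sources[1]
        assert sorted(e.kind for e in med.events) == ["C", "C", "T"]

    def test_median_minimizes_total_distance(self):
        for inst, g in interesting_graphs(20, seed0=700):
            med = m.median_traversal(g)
            sets = [t.events for t in m.enumerate_traversals(g)]
            total = lambda s: sum(len(s ^ q) for q in sets)
            assert med.events in set(sets)
            assert total(med.events) == min(total(s) for s in sets)


class TestSampling:
    def test_unique_traversal_always_sampled(self):
        g = graph_of(m.fixture("dup1"))
        for t in m.sample_traversals(g, 5, seed=1):
            assert sorted(e.kind for e in t.events) == ["C", "C", "D"]

    def test_reproducible_under_seed(self, toy3_graph):
        a = m.sample_traversals(toy3_graph, 50, seed=3)
        b = m.sample_traversals(toy3_graph, 50, seed=3)
        assert [t.events for t in a] == [t.events for t in b]

    def test_nonpositive_count_rejected(self, toy3_graph):
        with pytest.raises(ValueError):
            m.sample_traversals(toy3_graph, 0, seed=1)

    def test_empirical_frequencies_near_uniform(self, toy3_graph):
        import collections

        samples = m.sample_traversals(toy3_graph, 6000, seed=11)
        freq = collections.Counter(t.events for t in samples)
        assert len(freq) == 3
        for count in freq.values():
            assert abs(count / 6000 - 1 / 3) < 0.03  # ~5 sigma band

    def test_sampled_traversals_are_valid(self):
        for inst, g in interesting_graphs(5, seed0=800):
            opt = m.compute_dp(inst).opt_cost
            valid = {t.events for t in m.enumerate_traversals(g)}
            for t in m.sample_traversals(g, 20, seed=2):
                assert t.events in valid
                assert t.cost(inst) == opt


class TestEnumeration:
    def test_refusal_reports_count(self, toy3_graph):
        with pytest.raises(m.EnumerationLimitError) as exc:
            m.enumerate_traversals(toy3_graph, limit=2)
        assert exc.value.count == 3

    def test_traversal_structure(self, toy3_graph):
        for t in m.enumerate_traversals(toy3_graph):
            assert t.root in toy3_graph.sources
            # each included non-leaf mapping node has exactly one event child
            by_pair = {}
            for e in t.events:
                by_pair.setdefault(e.pair, []).append(e)
            assert all(len(v) == 1 for v in by_pair.values())


class TestSubgraphAlgebra:
    def test_closure_from_sources_is_full_graph(self, toy3_graph):
        sub = m.closure_from(toy3_graph, toy3_graph.sources)
        assert sub.events == toy3_graph.events
        assert sub.sources == toy3_graph.sources

    def test_closure_of_transfer_prefix(self, toy3_graph):
        """Keeping only the transfer-at-C prefix leaves a single MPR."""
        tC = next(
            e for e in toy3_graph.events
            if e.kind == "T" and toy3_graph.instance.species_tree.name(e.s) == "C"
        )
        sub = m.closure_from(
            toy3_graph, frontier=tC.children, prefix_events=[tC],
            sources=[tC.pair],
        )
        _, total = m.count_below(sub)
        assert total == 1

    def test_union_idempotent(self, toy3_graph):
        u = m.graph_union(toy3_graph, toy3_graph)
        assert u.events == toy3_graph.events

    def test_union_of_singletons_recovers_space(self, toy3_graph):
        travs = m.enumerate_traversals(toy3_graph)
        subs = [
            m.ReconGraph(toy3_graph.instance, t.events, [t.root]) for t in travs
        ]
        u = subs[0]
        for s in subs[1:]:
            u = m.graph_union(u, s)
        assert u.events == toy3_graph.events
        _, total = m.count_below(u)
        assert total == 3

    def test_union_preserves_member_traversals(self):
        """Every traversal of each part is a traversal of the union, so the
        union never counts fewer MPRs than either part."""
        for inst, g in interesting_graphs(8, seed0=900, min_t=3):
            travs = m.enumerate_traversals(g)
            a = m.ReconGraph(inst, travs[0].events, [travs[0].root])
            b = m.ReconGraph(inst, travs[-1].events, [travs[-1].root])
            u = m.graph_union(a, b)
            usets = {t.events for t in m.enumerate_traversals(u)}
            assert travs[0].events in usets and travs[-1].events in usets
            _, tu = m.count_below(u)
            assert tu >= 2

    def test_union_of_different_instances_rejected(self, toy3_graph):
        other = graph_of(m.fixture("dup1"))
        with pytest.raises(m.GraphError):
            m.graph_union(toy3_graph, other)


class TestReports:
    def test_report_lists_every_event(self, toy3_graph):
        med = m.median_traversal(toy3_graph)
        text = traversal_report(med, toy3_graph.instance)
        assert text.count("\n") == len(med.events)
        assert "transfer at A" in text  # tie-break picks the A placement

    def test_json_round_trippable(self, toy3_graph):
        import json

        med = m.median_traversal(toy3_graph)
        obj = traversal_json_obj(med, toy3_graph.instance)
        assert json.loads(json.dumps(obj)) == obj
        assert len(obj["events"]) == len(med.events)
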