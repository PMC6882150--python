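"""Algebra over reconciliation graphs and their subgraphs.

The reconciliation graph is a DAG that compactly encodes every maximum
parsimony reconciliation (MPR) of a gene tree into a species tree.  It
has two kinds of nodes:

* *mapping nodes* ``(g, s)``: gene vertex ``g`` is placed at, or passes
  through, species vertex ``s`` in some MPR;
* *event nodes*: tuples ``(kind, (g, s), associations)`` with
  ``kind`` one of ``S`` (speciation), ``D`` (duplication), ``T``
  (transfer), ``L`` (loss) or ``C`` (contemporaneous leaf association).
  The associations are the event's mapping-node children: two for
  S/D/T, one for L, none for C.

A *traversal* picks one event child for every included mapping node and
all mapping children of every included event node; traversals are in
bijection with MPRs.  A *reconciliation subgraph* is a union of one or
more traversals and is the representation used for clusters.

Because an event node's mapping children are determined by the event
tuple itself, a subgraph is fully described by its event-node set and
its source mapping nodes; all other structure is derived.

Counts use exact integer arithmetic throughout (MPR counts routinely
exceed 10**12); supports and distances are carried as exact rationals
and converted to floats only at the reporting boundary.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, NamedTuple, Optional

from .instance import DTLInstance

__all__ = [
    "Event",
    "Traversal",
    "ReconGraph",
    "SubgraphStats",
    "GraphError",
    "EnumerationLimitError",
    "event_sort_key",
    "event_cost_of",
    "count_below",
    "count_above",
    "event_support",
    "mean_pairwise_distance",
    "subgraph_stats",
    "median_traversal",
    "sample_traversals",
    "enumerate_traversals",
    "closure_from",
    "graph_union",
    "distance_histogram",
]


class GraphError(ValueError):
    """Structural error in a reconciliation (sub)graph."""


class EnumerationLimitError(GraphError):
    """Raised when exhaustive enumeration would exceed the caller's limit."""

    def __init__(self, count: int, limit: int):
        super().__init__(f"graph encodes {count} traversals, more than the limit {limit}")
        self.count = count
        self.limit = limit


_EVENT_RANK = {"S": 0, "D": 1, "T": 2, "L": 3, "C": 4}


class Event(NamedTuple):
    """An event node: ``kind`` in SDTLC, located at mapping pair ``(g, s)``.

    ``children`` are the mapping-node associations, canonically sorted.
    """

    kind: str
    g: int
    s: int
    children: tuple  # tuple of (g, s) pairs

    @property
    def pair(self) -> tuple:
        return (self.g, self.s)


def event_sort_key(e: Event) -> tuple:
    """Fixed total order on event nodes used for every tie-break."""
    return (e.g, e.s, _EVENT_RANK[e.kind], e.children)


def event_cost_of(e: Event, inst: DTLInstance) -> float:
    c = inst.costs
    return {"S": 0.0, "C": 0.0, "D": c.dup, "T": c.transfer, "L": c.loss}[e.kind]


@dataclass(frozen=True)
class Traversal:
    """One MPR, as the set of event nodes E(R) plus the source used."""

    events: frozenset
    root: tuple  # source mapping node (g, s)

    def cost(self, inst: DTLInstance) -> float:
        return sum(event_cost_of(e, inst) for e in self.events)

    def event_set(self) -> frozenset:
        return self.events


class ReconGraph:
    """A reconciliation graph or subgraph.

    ``events`` is the set of event nodes; ``sources`` the mapping nodes
    of the form ``(root(G), s)`` that the subgraph contains.  Mapping
    nodes and adjacency are derived.
    """

    __slots__ = ("instance", "events", "sources", "_events_at", "_mapping_nodes")

    def __init__(self, instance: DTLInstance, events: Iterable[Event], sources: Iterable[tuple]):
        self.instance = instance
        self.events = frozenset(events)
        self.sources = tuple(sorted(set(sources)))
        if not self.sources:
            raise GraphError("a reconciliation (sub)graph needs at least one source")
        events_at: dict = {}
        for e in self.events:
            events_at.setdefault(e.pair, []).append(e)
        for pair, evs in events_at.items():
            evs.sort(key=event_sort_key)
            events_at[pair] = tuple(evs)
        self._events_at = events_at
        nodes = set(self.sources)
        for e in self.events:
            nodes.add(e.pair)
            nodes.update(e.children)
        self._mapping_nodes = nodes

    # -- structure -------------------------------------------------------
    @property
    def mapping_nodes(self) -> frozenset:
        return frozenset(self._mapping_nodes)

    def events_at(self, pair: tuple) -> tuple:
        """Event children of a mapping node, in canonical order."""
        return self._events_at.get(pair, ())

    @property
    def n_nodes(self) -> int:
        return len(self.events) + len(self._mapping_nodes)

    @property
    def n_edges(self) -> int:
        return sum(1 + len(e.children) for e in self.events)

    def same_space(self, other: "ReconGraph") -> bool:
        return self.instance is other.instance

    def validate(self) -> "ReconGraph":
        """Check the subgraph contract: every non-terminal mapping node has
        an event child and every event node has the right child count."""
        arity = {"S": 2, "D": 2, "T": 2, "L": 1, "C": 0}
        for e in self.events:
            if len(e.children) != arity[e.kind]:
                raise GraphError(f"event {e} has {len(e.children)} mapping children")
        for pair in self._mapping_nodes:
            if not self.events_at(pair):
                raise GraphError(f"mapping node {pair} has no event child")
        return self

    # -- topological order (reverse = children before parents) -----------
    def topological_nodes(self) -> list:
        """All nodes reachable from the sources, parents before children.

        Mapping nodes are ``(g, s)`` tuples, event nodes are ``Event``s.
        Raises :class:`GraphError` on a cycle.
        """
        order: list = []
        state: dict = {}  # 0 visiting, 1 done
        stack: list = [(p, iter(self._node_children(p))) for p in reversed(self.sources)]
        for p in self.sources:
            state[p] = 0
        while stack:
            node, it = stack[-1]
            advanced = False
            for child in it:
                st = state.get(child)
                if st == 0:
                    raise GraphError("cycle detected in reconciliation graph")
                if st is None:
                    state[child] = 0
                    stack.append((child, iter(self._node_children(child))))
                    advanced = True
                    break
            if not advanced:
                stack.pop()
                state[node] = 1
                order.append(node)
        order.reverse()
        return order

    def _node_children(self, node):
        if isinstance(node, Event):
            return node.children
        return self.events_at(node)

    # -- serialization ----------------------------------------------------
    def to_json_obj(self) -> dict:
        st, gt = self.instance.species_tree, self.instance.gene_tree

        def pname(pair):
            return [gt.name(pair[0]), st.name(pair[1])]

        events = sorted(self.events, key=event_sort_key)
        return {
            "sources": [pname(p) for p in self.sources],
            "mapping_nodes": [pname(p) for p in sorted(self._mapping_nodes)],
            "events": [
                {
                    "kind": e.kind,
                    "at": pname(e.pair),
                    "children": [pname(c) for c in e.children],
                }
                for e in events
            ],
        }


# ---------------------------------------------------------------------------
# Counting and statistics
# ---------------------------------------------------------------------------

@dataclass
class SubgraphStats:
    """Exact statistics of a reconciliation subgraph.

    ``mpr_count`` is the number of traversals T; ``event_count[e]`` the
    number of traversals containing event node ``e``; ``support[e]`` the
    fraction c(e)/T; ``mean_support`` the unweighted mean of the supports
    of the non-C event nodes (1 when there are none); and
    ``mean_pairwise_distance`` the average symmetric distance
    |E(R1) xor E(R2)| over unordered distinct traversal pairs (0 when
    T <= 1).
    """

    mpr_count: int
    below_count: dict
    above_count: dict
    event_count: dict
    support: dict
    mean_support: Fraction
    mean_pairwise_distance: Fraction

    @property
    def sigma(self) -> Fraction:
        return self.mean_support

    @property
    def mu(self) -> Fraction:
        return self.mean_pairwise_distance


def count_below(graph: ReconGraph):
    """Completions beneath each node; returns (below_count, mpr_count).

    Reverse-topological DP: a C node completes in exactly one way, an
    event node in the product of its children's counts, a mapping node
    in the sum over its event children.
    """
    order = graph.topological_nodes()
    below: dict = {}
    for node in reversed(order):
        if isinstance(node, Event):
            b = 1
            for child in node.children:
                b *= below[child]
            below[node] = b
        else:
            below[node] = sum(below[e] for e in graph.events_at(node))
    total = sum(below[src] for src in graph.sources)
    return below, total


def count_above(graph: ReconGraph, below: dict):
    """Completions above each node (two-pass support counting).

    ``above(source) = 1``; an event node inherits its parent mapping
    node's count; a mapping node sums, over its event parents, the
    parent's count times the product of its siblings' below-counts.
    """
    order = graph.topological_nodes()
    above: dict = {node: 0 for node in order}
    for src in graph.sources:
        above[src] = 1
    for node in order:
        if isinstance(node, Event):
            a = above[node]
            if a == 0:
                continue
            for child in node.children:
                prod = a
                for sib in node.children:
                    if sib != child:
                        prod *= below[sib]
                above[child] += prod
        else:
            a = above[node]
            if a == 0:
                continue
            for e in graph.events_at(node):
                above[e] += a
    return above


def _event_counts(graph: ReconGraph, below: dict, above: dict) -> dict:
    counts = {}
    for e in graph.events:
        c = above[e]
        for child in e.children:
            c *= below[child]
        counts[e] = c
    return counts


def event_support(graph: ReconGraph, stats: Optional["SubgraphStats"] = None):
    """Per-event support c(e)/T and the mean support over non-C events."""
    st = stats if stats is not None else subgraph_stats(graph)
    return st.support, st.mean_support


def mean_pairwise_distance(graph: ReconGraph, stats: Optional["SubgraphStats"] = None) -> Fraction:
    """Average symmetric distance over unordered pairs of traversals.

    The symmetric distance decomposes per event: a non-C event node
    ``e`` is in exactly one traversal of a pair for exactly
    ``c(e) * (T - c(e))`` unordered pairs, so the mean is
    ``sum_e c(e)(T - c(e)) / (T (T-1) / 2)``.
    """
    st = stats if stats is not None else subgraph_stats(graph)
    return st.mean_pairwise_distance


def subgraph_stats(graph: ReconGraph) -> SubgraphStats:
    """Compute all counting-derived statistics of a subgraph in one pass."""
    below, total = count_below(graph)
    above = count_above(graph, below)
    counts = _event_counts(graph, below, above)
    support = {e: Fraction(c, total) for e, c in counts.items()}
    noncomp = [e for e in graph.events if e.kind != "C"]
    if noncomp:
        sigma = Fraction(sum(counts[e] for e in noncomp), len(noncomp) * total)
    else:
        # leaf-only space: every traversal is the same set of C events
        sigma = Fraction(1)
    if total >= 2:
        acc = sum(counts[e] * (total - counts[e]) for e in noncomp)
        mu = Fraction(2 * acc, total * (total - 1))
    else:
        mu = Fraction(0)
    return SubgraphStats(
        mpr_count=total,
        below_count=below,
        above_count=above,
        event_count=counts,
        support=support,
        mean_support=sigma,
        mean_pairwise_distance=mu,
    )


# ---------------------------------------------------------------------------
# Representative and sampling operations
# ---------------------------------------------------------------------------

def median_traversal(graph: ReconGraph, stats: Optional[SubgraphStats] = None) -> Traversal:
    """Traversal minimizing the summed symmetric distance to all traversals.

    Equivalent to maximizing ``sum_{e in E(R), e non-C} (c(e) - T/2)``;
    integer weights ``2 c(e) - T`` are used so the DP stays exact.
    Ties are broken by the fixed node order, so the result is
    deterministic.
    """
    st = stats if stats is not None else subgraph_stats(graph)
    total = st.mpr_count
    order = graph.topological_nodes()
    best: dict = {}
    choice: dict = {}
    for node in reversed(order):
        if isinstance(node, Event):
            w = 0 if node.kind == "C" else 2 * st.event_count[node] - total
            best[node] = w + sum(best[c] for c in node.children)
        else:
            evs = graph.events_at(node)
            bv, bc = None, None
            for e in evs:  # canonical order: first maximizer wins
                if bv is None or best[e] > bv:
                    bv, bc = best[e], e
            best[node] = bv
            choice[node] = bc
    src = None
    for s in graph.sources:  # sources sorted; first maximizer wins ties
        if src is None or best[s] > best[src]:
            src = s
    events = set()
    stack = [src]
    while stack:
        pair = stack.pop()
        e = choice.get(pair)
        if e is None:
            continue
        events.add(e)
        stack.extend(e.children)
    return Traversal(frozenset(events), src)


def sample_traversals(graph: ReconGraph, count: int, seed: int,
                      stats: Optional[SubgraphStats] = None) -> list:
    """Draw ``count`` i.i.d. uniform traversals of the subgraph.

    The source is chosen with probability below(source)/T and each
    mapping node's event child with probability proportional to the
    number of completions through it; this makes every traversal equally
    likely.  Reproducible under ``seed``.
    """
    if count <= 0:
        raise ValueError(f"sample count must be positive, got {count}")
    st = stats if stats is not None else subgraph_stats(graph)
    below = st.below_count
    total = st.mpr_count
    rng = random.Random(seed)
    out = []
    for _ in range(count):
        r = rng.randrange(total)
        src = None
        for s in graph.sources:
            if r < below[s]:
                src = s
                break
            r -= below[s]
        events = set()
        stack = [src]
        while stack:
            pair = stack.pop()
            evs = graph.events_at(pair)
            if not evs:
                continue
            r = rng.randrange(below[pair])
            chosen = None
            for e in evs:
                if r < below[e]:
                    chosen = e
                    break
                r -= below[e]
            events.add(chosen)
            stack.extend(chosen.children)
        out.append(Traversal(frozenset(events), src))
    return out


def enumerate_traversals(graph: ReconGraph, limit: int = 100_000) -> list:
    """All traversals of the subgraph (exhaustive oracle).

    Refuses with :class:`EnumerationLimitError` when the exact traversal
    count exceeds ``limit``.
    """
    below, total = count_below(graph)
    if total > limit:
        raise EnumerationLimitError(total, limit)
    memo: dict = {}
    order = graph.topological_nodes()
    for node in reversed(order):
        if isinstance(node, Event):
            parts = [memo[c] for c in node.children]
            sets = [frozenset((node,))]
            for p in parts:
                sets = [s | q for s in sets for q in p]
            memo[node] = sets
        else:
            acc = []
            for e in graph.events_at(node):
                acc.extend(memo[e])
            memo[node] = acc
    out = []
    for src in graph.sources:
        out.extend(Traversal(s, src) for s in memo[src])
    assert len(out) == total
    return out


def distance_histogram(graph: ReconGraph, seed: int = 0, enumerate_limit: int = 1000,
                       n_samples: int = 2000) -> list:
    """Pairwise symmetric distances between traversals of the subgraph.

    Exhaustive over all unordered pairs when T <= ``enumerate_limit``;
    otherwise over pairs of ``n_samples`` uniformly sampled traversals.
    Returns a list of integer distances.
    """
    below, total = count_below(graph)
    if total <= 1:
        return []
    if total <= enumerate_limit:
        travs = enumerate_traversals(graph, limit=enumerate_limit)
    else:
        travs = sample_traversals(graph, n_samples, seed)
    sets = [t.events for t in travs]
    return [len(a ^ b) for a, b in itertools.combinations(sets, 2)]


# ---------------------------------------------------------------------------
# Subgraph construction
# ---------------------------------------------------------------------------

def closure_from(graph: ReconGraph, frontier: Iterable[tuple], prefix_events: Iterable[Event] = (),
                 sources: Optional[Iterable[tuple]] = None) -> ReconGraph:
    """Reconciliation subgraph = prefix plus everything reachable from ``frontier``.

    ``frontier`` is a set of mapping nodes of ``graph``; all nodes
    reachable from them (with the full graph's edges) are added to the
    prefix events.  ``sources`` defaults to the prefix/frontier mapping
    nodes that are sources of ``graph``.
    """
    prefix_events = set(prefix_events)
    events = set(prefix_events)
    seen = set()
    stack = list(frontier)
    while stack:
        pair = stack.pop()
        if pair in seen:
            continue
        seen.add(pair)
        for e in graph.events_at(pair):
            if e not in events:
                events.add(e)
                stack.extend(e.children)
    if sources is None:
        root_g = graph.instance.gene_tree.root
        cand = {p for p in seen if p[0] == root_g}
        cand.update(p for e in prefix_events for p in (e.pair,) if p[0] == root_g)
        cand.update(p for p in frontier if p[0] == root_g)
        sources = cand & set(graph.sources)
    return ReconGraph(graph.instance, events, sources)


def graph_union(a: ReconGraph, b: ReconGraph) -> ReconGraph:
    """Node-set and edge-set union of two subgraphs of the same full graph."""
    if not a.same_space(b):
        raise GraphError("cannot union subgraphs of different instances")
    return ReconGraph(a.instance, a.events | b.events, set(a.sources) | set(b.sources))


# ---------------------------------------------------------------------------
# Traversal reports
# ---------------------------------------------------------------------------

_KIND_WORD = {
    "S": "speciation",
    "D": "duplication",
    "T": "transfer",
    "L": "loss",
    "C": "leaf",
}


def traversal_report(trav: Traversal, inst: DTLInstance) -> str:
    """Human-readable reconciliation: one line per gene vertex with its
    species placement and event type, plus one line per loss."""
    gt, st = inst.gene_tree, inst.species_tree
    lines = []
    for e in sorted(trav.events, key=event_sort_key):
        gname, sname = gt.name(e.g), st.name(e.s)
        if e.kind == "L":
            (_, s_next), = e.children
            lines.append(f"{gname}\tloss at {sname} (passes to {st.name(s_next)})")
        elif e.kind == "C":
            lines.append(f"{gname}\t{_KIND_WORD[e.kind]} at {sname}")
        else:
            kids = ", ".join(f"{gt.name(cg)}->{st.name(cs)}" for cg, cs in e.children)
            lines.append(f"{gname}\t{_KIND_WORD[e.kind]} at {sname} [{kids}]")
    return "\n".join(lines) + "\n"


def traversal_json_obj(trav: Traversal, inst: DTLInstance) -> dict:
    gt, st = inst.gene_tree, inst.species_tree
    return {
        "root": [gt.name(trav.root[0]), st.name(trav.root[1])],
        "events": [
            {
                "kind": e.kind,
                "at": [gt.name(e.g), st.name(e.s)],
                "children": [[gt.name(cg), st.name(cs)] for cg, cs in e.children],
            }
            for e in sorted(trav.events, key=event_sort_key)
        ],
    }
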