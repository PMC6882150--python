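"""Agglomerative clustering of MPR space.

Initial clusters are built from depth-L subtraversals of the
reconciliation graph: the smallest L giving at least the requested
number of clusters is used, each subtraversal is closed downward into a
reconciliation subgraph, and clusters are then merged greedily to k=1
under one of two linkage criteria:

* ``support``  — merge the pair giving the largest increase in the
  weighted average support WAS(C) = sum_i |C_i| sigma_i / sum_i |C_i|
  (gradient ascent);
* ``distance`` — merge the pair giving the largest decrease in the
  weighted average distance WAD(C) = sum_i |C_i| mu_i / sum_i |C_i|
  (gradient descent).

Here |C_i| is the cluster's MPR count, sigma_i its mean event support
and mu_i its mean pairwise symmetric distance.  All linkage comparisons
are carried out on exact rationals, with deterministic tie-breaks, so
repeated runs are byte-identical.

The full merge history is recorded so that a number of clusters k can
be chosen afterwards from the improvement and local-improvement scores.
"""

from __future__ import annotations

import itertools
import time
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional

from .graph import (
    ReconGraph,
    SubgraphStats,
    closure_from,
    graph_union,
    subgraph_stats,
)

__all__ = [
    "Subtraversal",
    "Cluster",
    "Clustering",
    "MergeRecord",
    "MergeHistory",
    "ClusteringError",
    "subtraversals_at_level",
    "initial_clusters",
    "was",
    "wad",
    "agglomerate",
    "improvement",
    "local_improvement",
]

INF = float("inf")


class ClusteringError(ValueError):
    pass


@dataclass(frozen=True)
class Subtraversal:
    """A partial traversal grown ``level`` expansion rounds from one source."""

    events: frozenset
    frontier: frozenset  # expandable mapping-node leaves
    source: tuple
    level: int

    @property
    def complete(self) -> bool:
        return not self.frontier


def _advance(graph: ReconGraph, subs: list, limit: Optional[int] = None):
    """One simultaneous expansion round of every subtraversal.

    Each expandable frontier mapping node picks one event child (the
    cartesian product over frontier nodes generates all extensions);
    frontier nodes whose children are all contemporaneous (C) events are
    closed.  Returns (new_subs, truncated): ``truncated`` is True when
    generation stopped after exceeding ``limit``.
    """
    out: list = []
    for sub in subs:
        closed: list = []
        choice_lists: list = []
        for pair in sorted(sub.frontier):
            kids = graph.events_at(pair)
            if all(e.kind == "C" for e in kids):
                closed.extend(kids)
            else:
                choice_lists.append(kids)
        if not choice_lists and not closed:
            out.append(sub)  # already complete; carried forward unchanged
        else:
            for combo in itertools.product(*choice_lists):
                events = sub.events | frozenset(closed) | frozenset(combo)
                frontier = frozenset(p for e in combo for p in e.children)
                out.append(Subtraversal(events, frontier, sub.source, sub.level + 1))
                if limit is not None and len(out) > limit:
                    return out, True
        if limit is not None and len(out) > limit:
            return out, True
    return out, False


def subtraversals_at_level(graph: ReconGraph, level: int, limit: Optional[int] = None) -> list:
    """All level-``level`` subtraversals of the graph.

    Level 0 is one subtraversal per source; at the largest possible
    level the subtraversals are complete traversals.
    """
    if level < 0:
        raise ClusteringError("level must be non-negative")
    subs = [Subtraversal(frozenset(), frozenset((src,)), src, 0) for src in graph.sources]
    for _ in range(level):
        subs, truncated = _advance(graph, subs, limit)
        if truncated:
            raise ClusteringError(f"more than {limit} subtraversals at an intermediate level")
        if all(s.complete for s in subs):
            break
    return subs


@dataclass
class Cluster:
    """A reconciliation subgraph plus its cached statistics."""

    subgraph: ReconGraph
    stats: SubgraphStats
    uid: int

    @classmethod
    def from_subgraph(cls, subgraph: ReconGraph, uid: int) -> "Cluster":
        return cls(subgraph, subgraph_stats(subgraph), uid)

    @property
    def size(self) -> int:
        return self.stats.mpr_count

    @property
    def sigma(self) -> Fraction:
        return self.stats.mean_support

    @property
    def mu(self) -> Fraction:
        return self.stats.mean_pairwise_distance


@dataclass
class Clustering:
    clusters: list

    @property
    def k(self) -> int:
        return len(self.clusters)


def _cluster_from_subtraversal(graph: ReconGraph, sub: Subtraversal, uid: int) -> Cluster:
    sg = closure_from(graph, sub.frontier, sub.events, sources=(sub.source,))
    return Cluster.from_subgraph(sg, uid)


def initial_clusters(graph: ReconGraph, min_clusters: int, cap: int = 200,
                     strict_cap: bool = False):
    """Initial clustering from the smallest level L with >= ``min_clusters``.

    Returns (clustering, n_initial, level).  If the first qualifying
    level exceeds ``cap`` subtraversals, either refuse (``strict_cap``)
    or fall back to the previous level.  If the graph never reaches
    ``min_clusters`` (fewer MPRs than requested), the deepest level is
    used and every cluster is a single MPR.
    """
    if min_clusters < 1:
        raise ClusteringError("min_clusters must be >= 1")
    if cap < min_clusters and strict_cap:
        raise ClusteringError("cap must be at least min_clusters")
    level = 0
    subs = [Subtraversal(frozenset(), frozenset((src,)), src, 0) for src in graph.sources]
    while len(subs) < min_clusters:
        nxt, truncated = _advance(graph, subs, cap)
        if truncated or len(nxt) > cap:
            if strict_cap:
                raise ClusteringError(
                    f"level {level + 1} has more than {cap} subtraversals "
                    f"(level {level} has {len(subs)})"
                )
            break  # fall back to the current level
        if nxt == subs:  # all complete: deepest level reached
            break
        subs = nxt
        level += 1
    clusters = [_cluster_from_subtraversal(graph, sub, uid) for uid, sub in enumerate(subs)]
    return Clustering(clusters), len(clusters), level


# ---------------------------------------------------------------------------
# Objectives
# ---------------------------------------------------------------------------

def was(clustering: Clustering) -> Fraction:
    """Weighted average support of a clustering (weights = MPR counts)."""
    num = sum(c.size * c.sigma for c in clustering.clusters)
    den = sum(c.size for c in clustering.clusters)
    return Fraction(num, den) if den else Fraction(0)


def wad(clustering: Clustering) -> Fraction:
    """Weighted average pairwise distance of a clustering."""
    num = sum(c.size * c.mu for c in clustering.clusters)
    den = sum(c.size for c in clustering.clusters)
    return Fraction(num, den) if den else Fraction(0)


# ---------------------------------------------------------------------------
# Agglomeration
# ---------------------------------------------------------------------------

@dataclass
class MergeRecord:
    k_before: int            # number of clusters before this merge
    merged_uids: tuple       # uids of the two clusters agglomerated
    new_uid: int
    was_before: Fraction
    was_after: Fraction
    wad_before: Fraction
    wad_after: Fraction
    pair_was: Fraction       # WAS({C_a, C_b})
    pair_wad: Fraction       # WAD({C_a, C_b})
    merged_sigma: Fraction   # sigma of C_ab
    merged_mu: Fraction      # mu of C_ab
    merged_size: int


@dataclass
class MergeHistory:
    """Record of a full agglomeration run, from N clusters down to one.

    ``snapshots[k]`` holds (WAS, WAD, per-cluster (size, sigma, mu)
    summaries) of the k-clustering; ``records`` holds one entry per
    merge.  ``partial`` is set when a timeout interrupted the run.
    """

    initial_n: int
    criterion: str
    records: list = field(default_factory=list)
    snapshots: dict = field(default_factory=dict)
    clusters_by_k: dict = field(default_factory=dict)
    partial: bool = False

    def clusters_at(self, k: int):
        if k not in self.snapshots:
            raise ClusteringError(
                f"no clustering of size {k}; valid range is "
                f"{min(self.snapshots)}..{max(self.snapshots)}"
            )
        return self.snapshots[k]

    def to_json_obj(self) -> dict:
        def fr(x):
            return float(x) if x != INF else "inf"

        return {
            "initial_n": self.initial_n,
            "criterion": self.criterion,
            "partial": self.partial,
            "merges": [
                {
                    "k_before": r.k_before,
                    "merged_uids": list(r.merged_uids),
                    "new_uid": r.new_uid,
                    "was_before": fr(r.was_before),
                    "was_after": fr(r.was_after),
                    "wad_before": fr(r.wad_before),
                    "wad_after": fr(r.wad_after),
                    "local_improvement_support": fr(local_improvement_of(r, "support")),
                    "local_improvement_distance": fr(local_improvement_of(r, "distance")),
                }
                for r in self.records
            ],
            "per_k": {
                str(k): {
                    "was": fr(snap["was"]),
                    "wad": fr(snap["wad"]),
                    "clusters": [
                        {"mpr_count": size, "sigma": fr(sg), "mu": fr(mu)}
                        for size, sg, mu in snap["clusters"]
                    ],
                }
                for k, snap in sorted(self.snapshots.items())
            },
        }


def _snapshot(clustering: Clustering) -> dict:
    return {
        "was": was(clustering),
        "wad": wad(clustering),
        "clusters": [(c.size, c.sigma, c.mu) for c in clustering.clusters],
        "uids": [c.uid for c in clustering.clusters],
    }


def agglomerate(clustering: Clustering, criterion: str,
                timeout: Optional[float] = None) -> MergeHistory:
    """Greedy agglomeration to a single cluster under the given linkage.

    Every unordered pair is evaluated by recomputing the statistics of
    the union subgraph (a merged subgraph can contain MPRs absent from
    both parts, so no algebraic shortcut is exact); candidate merges are
    cached per uid pair and only pairs touching the previous merge are
    re-evaluated.  Ties are broken toward the smallest uid pair.  An
    optional wall-clock ``timeout`` (seconds) aborts cleanly with a
    partial history.
    """
    if criterion not in ("support", "distance"):
        raise ClusteringError(f"unknown criterion {criterion!r}")
    start = time.monotonic()
    clusters = list(clustering.clusters)
    if not clusters:
        raise ClusteringError("cannot agglomerate an empty clustering")
    next_uid = max(c.uid for c in clusters) + 1
    history = MergeHistory(initial_n=len(clusters), criterion=criterion)
    history.snapshots[len(clusters)] = _snapshot(Clustering(clusters))
    history.clusters_by_k[len(clusters)] = list(clusters)
    cache: dict = {}

    while len(clusters) > 1:
        if timeout is not None and time.monotonic() - start > timeout:
            history.partial = True
            break
        total_sz = sum(c.size for c in clusters)
        was_num = sum(c.size * c.sigma for c in clusters)
        wad_num = sum(c.size * c.mu for c in clusters)
        best = None  # (objective, uid pair, i, j, merged Cluster)
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                a, b = clusters[i], clusters[j]
                key = (min(a.uid, b.uid), max(a.uid, b.uid))
                merged = cache.get(key)
                if merged is None:
                    merged = Cluster.from_subgraph(
                        graph_union(a.subgraph, b.subgraph), -1
                    )
                    cache[key] = merged
                sz = total_sz - a.size - b.size + merged.size
                if criterion == "support":
                    cand = Fraction(
                        was_num - a.size * a.sigma - b.size * b.sigma
                        + merged.size * merged.sigma,
                        sz,
                    )
                    better = best is None or cand > best[0] or (
                        cand == best[0] and key < best[1]
                    )
                else:
                    cand = Fraction(
                        wad_num - a.size * a.mu - b.size * b.mu
                        + merged.size * merged.mu,
                        sz,
                    )
                    better = best is None or cand < best[0] or (
                        cand == best[0] and key < best[1]
                    )
                if better:
                    best = (cand, key, i, j, merged)
        _, key, i, j, merged = best
        a, b = clusters[i], clusters[j]
        before = Clustering(clusters)
        was_before, wad_before = was(before), wad(before)
        merged = Cluster(merged.subgraph, merged.stats, next_uid)
        next_uid += 1
        clusters = [c for idx, c in enumerate(clusters) if idx not in (i, j)]
        clusters.append(merged)
        after = Clustering(clusters)
        pair_den = a.size + b.size
        history.records.append(
            MergeRecord(
                k_before=len(clusters) + 1,
                merged_uids=(a.uid, b.uid),
                new_uid=merged.uid,
                was_before=was_before,
                was_after=was(after),
                wad_before=wad_before,
                wad_after=wad(after),
                pair_was=Fraction(a.size * a.sigma + b.size * b.sigma, pair_den),
                pair_wad=Fraction(a.size * a.mu + b.size * b.mu, pair_den),
                merged_sigma=merged.sigma,
                merged_mu=merged.mu,
                merged_size=merged.size,
            )
        )
        history.snapshots[len(clusters)] = _snapshot(after)
        history.clusters_by_k[len(clusters)] = list(clusters)
        # drop cache entries touching the merged pair
        dead = set(key)
        cache = {k: v for k, v in cache.items() if not (dead & set(k))}
    return history


def improvement(history: MergeHistory, k: int, criterion: str):
    """Objective at k clusters relative to no clustering (k = 1).

    For support: WAS(C_k) / WAS(C_1); for distance: WAD(C_1) / WAD(C_k).
    Division by zero yields +inf.
    """
    if criterion not in ("support", "distance"):
        raise ClusteringError(f"unknown criterion {criterion!r}")
    if k == 1:
        return 1.0
    top = history.clusters_at(k)
    base = history.clusters_at(1)
    if criterion == "support":
        num, den = top["was"], base["was"]
    else:
        num, den = base["wad"], top["wad"]
    if den == 0:
        return INF
    return float(Fraction(num, den))


def local_improvement_of(record: MergeRecord, criterion: str):
    if criterion == "support":
        num, den = record.pair_was, record.merged_sigma
    elif criterion == "distance":
        num, den = record.merged_mu, record.pair_wad
    else:
        raise ClusteringError(f"unknown criterion {criterion!r}")
    if den == 0:
        return INF
    return float(Fraction(num, den))


def local_improvement(history: MergeHistory, k: int, criterion: str):
    """Improvement from splitting the k-1 clustering back into k clusters.

    For support: WAS({C_a, C_b}) / WAS({C_ab}); for distance:
    WAD({C_ab}) / WAD({C_a, C_b}), where C_a, C_b are the clusters whose
    merge reduced k clusters to k-1.
    """
    for record in history.records:
        if record.k_before == k:
            return local_improvement_of(record, criterion)
    raise ClusteringError(f"no merge from {k} to {k - 1} clusters in the history")
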