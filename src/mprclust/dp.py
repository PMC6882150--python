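"""The undated DTL maximum-parsimony dynamic program.

``compute_dp`` fills three tables over (gene vertex g, species vertex s):

* ``event_cost(g, s)`` — minimum cost of reconciling the subtree of
  ``g`` given that ``g`` is placed (an event occurs) at ``s``;
* ``descend(g, s)`` — minimum of ``event_cost(g, s')`` plus loss charges
  over ``s'`` equal to or below ``s`` (one loss per vertex passed
  through, charged from ``s`` down to the parent of ``s'``);
* ``outside(g, s)`` — minimum of ``event_cost(g, s_hat)`` over vertices
  ``s_hat`` not ancestrally related to ``s`` (transfer recipients).

``build_recon_graph`` backtracks *all* argmin choices into the
reconciliation graph of every MPR, and ``infer_events`` scores an
explicit reconciliation mapping by the events it induces (the scoring
function of the brute-force oracle).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .instance import DTLInstance, InstanceError
from .graph import Event, ReconGraph

__all__ = ["DPTables", "compute_dp", "build_recon_graph", "infer_events", "MappingError"]

INF = math.inf


class MappingError(InstanceError):
    """An explicit reconciliation mapping violates the ancestry constraints."""


@dataclass
class DPTables:
    event_cost: dict
    descend: dict
    outside: dict
    opt_cost: float


def compute_dp(inst: DTLInstance) -> DPTables:
    st = inst.species_tree
    gt = inst.gene_tree
    d, t, l = inst.costs.dup, inst.costs.transfer, inst.costs.loss
    s_post = st.postorder()
    event_cost: dict = {}
    descend: dict = {}
    outside: dict = {}

    for g in gt.postorder():
        if gt.is_leaf(g):
            target = inst.phi_vertex(g)
            for s in s_post:
                event_cost[(g, s)] = 0.0 if s == target else INF
        else:
            g1, g2 = gt.children[g]
            for s in s_post:
                best = INF
                if not st.is_leaf(s):
                    s1, s2 = st.children[s]
                    spec = min(
                        descend[(g1, s1)] + descend[(g2, s2)],
                        descend[(g1, s2)] + descend[(g2, s1)],
                    )
                    best = min(best, spec)
                best = min(best, d + descend[(g1, s)] + descend[(g2, s)])
                tr = min(
                    descend[(g1, s)] + outside[(g2, s)],
                    descend[(g2, s)] + outside[(g1, s)],
                )
                best = min(best, t + tr)
                event_cost[(g, s)] = best
        # descend: losses charged per vertex passed through
        for s in s_post:  # postorder: children before parents
            dc = event_cost[(g, s)]
            if not st.is_leaf(s):
                s1, s2 = st.children[s]
                dc = min(dc, l + min(descend[(g, s1)], descend[(g, s2)]))
            descend[(g, s)] = dc
        # outside: min event_cost over incomparable vertices (O(n^2) scan)
        for s in s_post:
            best = INF
            for s_hat in s_post:
                if not st.comparable(s, s_hat):
                    c = event_cost[(g, s_hat)]
                    if c < best:
                        best = c
            outside[(g, s)] = best

    rg = gt.root
    opt = min(event_cost[(rg, s)] for s in s_post)
    return DPTables(event_cost, descend, outside, opt)


def _events_achieving(inst: DTLInstance, tables: DPTables, g: int, s: int):
    """All event tuples at (g, s) whose cost realizes event_cost(g, s).

    Yields (event, child_contexts) where each child context is a pair
    ((g', s'), mode) with mode 'descend' or 'event' (transfer recipient).
    """
    st, gt = inst.species_tree, inst.gene_tree
    d, t = inst.costs.dup, inst.costs.transfer
    ec = tables.event_cost[(g, s)]
    if ec == INF:
        return
    if gt.is_leaf(g):
        if inst.phi_vertex(g) == s:
            yield Event("C", g, s, ()), ()
        return
    g1, g2 = gt.children[g]
    dsc = tables.descend
    if not st.is_leaf(s):
        s1, s2 = st.children[s]
        for a, b in ((s1, s2), (s2, s1)):
            if dsc[(g1, a)] + dsc[(g2, b)] == ec:
                kids = tuple(sorted(((g1, a), (g2, b))))
                yield Event("S", g, s, kids), (((g1, a), "descend"), ((g2, b), "descend"))
    if d + dsc[(g1, s)] + dsc[(g2, s)] == ec:
        kids = tuple(sorted(((g1, s), (g2, s))))
        yield Event("D", g, s, kids), (((g1, s), "descend"), ((g2, s), "descend"))
    evc = tables.event_cost
    for s_hat in range(st.n_vertices):
        if st.comparable(s, s_hat):
            continue
        if t + dsc[(g1, s)] + evc[(g2, s_hat)] == ec:
            kids = tuple(sorted(((g1, s), (g2, s_hat))))
            yield Event("T", g, s, kids), (((g1, s), "descend"), ((g2, s_hat), "event"))
        if t + dsc[(g2, s)] + evc[(g1, s_hat)] == ec:
            kids = tuple(sorted(((g2, s), (g1, s_hat))))
            yield Event("T", g, s, kids), (((g2, s), "descend"), ((g1, s_hat), "event"))


def build_recon_graph(inst: DTLInstance, tables: DPTables) -> ReconGraph:
    """Backtrack every argmin choice of the DP into the graph of all MPRs.

    Mapping nodes entered as sources or as transfer recipients must
    place an event exactly there (no losses above a gene root, none
    below a transfer recipient); nodes entered through a speciation,
    duplication, transfer-donor or loss edge may instead pass through
    with a loss for each species child realizing ``descend``.

    With a strictly positive loss cost the two entry modes never
    conflict at a shared node (an optimal transfer recipient or source
    provably has no loss child at its budget).  With loss cost 0 a
    conflict can arise, in which case loss placements below such nodes
    would be ambiguous; that degenerate scheme is rejected.
    """
    st, gt = inst.species_tree, inst.gene_tree
    l = inst.costs.loss
    opt = tables.opt_cost
    if opt == INF:
        raise InstanceError("instance admits no reconciliation")
    rg = gt.root
    sources = sorted(
        (rg, s) for s in range(st.n_vertices) if tables.event_cost[(rg, s)] == opt
    )
    events: set = set()
    seen: set = set()  # (pair, mode)
    event_entered: set = set()
    loss_children_of: dict = {}
    stack = [(p, "event") for p in sources]
    while stack:
        pair, mode = stack.pop()
        if (pair, mode) in seen:
            continue
        seen.add((pair, mode))
        g, s = pair
        if mode == "event":
            event_entered.add(pair)
            for e, contexts in _events_achieving(inst, tables, g, s):
                events.add(e)
                stack.extend(contexts)
        else:  # descend entry: optionally pass through with a loss
            dc = tables.descend[pair]
            if tables.event_cost[pair] == dc:
                for e, contexts in _events_achieving(inst, tables, g, s):
                    events.add(e)
                    stack.extend(contexts)
            if not st.is_leaf(s):
                for s_c in st.children[s]:
                    if l + tables.descend[(g, s_c)] == dc:
                        e = Event("L", g, s, ((g, s_c),))
                        events.add(e)
                        loss_children_of.setdefault(pair, []).append(e)
                        stack.append(((g, s_c), "descend"))
    conflicted = event_entered & set(loss_children_of)
    if conflicted:
        raise InstanceError(
            "ambiguous loss placement below a transfer recipient or gene root "
            f"(possible only with loss cost 0) at mapping nodes {sorted(conflicted)}; "
            "use a strictly positive loss cost"
        )
    return ReconGraph(inst, events, sources)


# ---------------------------------------------------------------------------
# Event inference for an explicit reconciliation mapping (oracle scoring)
# ---------------------------------------------------------------------------

def infer_events(inst: DTLInstance, phi: dict):
    """Events induced by a full reconciliation mapping, and their total cost.

    ``phi`` maps every gene-tree vertex to a species-tree vertex; leaves
    must agree with the instance's leaf mapping.  Events are returned in
    the reconciliation-graph tuple representation so they are directly
    comparable with graph event nodes.  Raises :class:`MappingError` if
    ``phi`` violates the reconciliation-mapping constraints.
    """
    st, gt = inst.species_tree, inst.gene_tree
    costs = inst.costs
    anc = st.is_ancestor_or_equal
    events: list = []
    total = 0.0

    for g in range(gt.n_vertices):
        if g not in phi:
            raise MappingError(f"phi does not place gene vertex {gt.name(g)}")
    for g in gt.leaves:
        if phi[g] != inst.phi_vertex(g):
            raise MappingError(f"phi disagrees with the leaf mapping at {gt.name(g)}")

    spec_assoc: dict = {}  # gene child -> species child it is associated with
    for g in range(gt.n_vertices):
        s = phi[g]
        if gt.is_leaf(g):
            events.append(Event("C", g, s, ()))
            continue
        g1, g2 = gt.children[g]
        v1, v2 = phi[g1], phi[g2]
        for v in (v1, v2):
            if anc(v, s) and v != s:
                raise MappingError(
                    f"phi({gt.name(g)}) is a proper descendant of a child's image"
                )
        in1, in2 = anc(s, v1), anc(s, v2)
        if not (in1 or in2):
            raise MappingError(
                f"no child of {gt.name(g)} maps into the subtree of phi({gt.name(g)})"
            )
        if in1 and in2:
            if st.is_leaf(s):
                is_spec = False
            else:
                s1, s2 = st.children[s]
                left1, left2 = anc(s1, v1), anc(s1, v2)
                is_spec = (v1 != s and v2 != s) and (left1 != left2)
            if is_spec:
                s1, s2 = st.children[s]
                a1 = s1 if anc(s1, v1) else s2
                a2 = s1 if anc(s1, v2) else s2
                events.append(Event("S", g, s, tuple(sorted(((g1, a1), (g2, a2))))))
                spec_assoc[g1], spec_assoc[g2] = a1, a2
            else:
                events.append(Event("D", g, s, tuple(sorted(((g1, s), (g2, s))))))
                total += costs.dup
                spec_assoc[g1] = spec_assoc[g2] = s
        else:
            stay, move = (g1, g2) if in1 else (g2, g1)
            events.append(
                Event("T", g, s, tuple(sorted(((stay, s), (move, phi[move])))))
            )
            total += costs.transfer
            spec_assoc[stay] = s  # recipient incurs no losses

    # losses: each vertex passed through on the way down to phi(g)
    for g in range(gt.n_vertices):
        if g == gt.root or g not in spec_assoc:
            continue
        top, bottom = spec_assoc[g], phi[g]
        path = st.path_down(top, bottom)
        for i in range(len(path) - 1):
            events.append(Event("L", g, path[i], ((g, path[i + 1]),)))
            total += costs.loss
    return events, total
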