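"""Brute-force reconciliation oracle for small instances.

Enumerates every function from gene-tree vertices to species-tree
vertices that extends the leaf mapping, keeps the ones satisfying the
reconciliation-mapping ancestry constraints, scores each with
:func:`mprclust.dp.infer_events`, and reports the optimum.  Exponential
in the number of internal gene vertices — intended purely as an
independent check of the dynamic program and of the reconciliation
graph, never as the implementation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from .dp import MappingError, infer_events
from .instance import DTLInstance

__all__ = ["BruteForceResult", "enumerate_valid_mappings", "brute_force_mprs"]


@dataclass
class BruteForceResult:
    opt_cost: float
    mappings: list  # all minimum-cost phi dicts
    event_sets: set  # frozensets of Event tuples, one per minimum-cost phi


def enumerate_valid_mappings(inst: DTLInstance):
    """Yield (phi, events, cost) for every valid reconciliation mapping."""
    gt, st = inst.gene_tree, inst.species_tree
    internal = [g for g in range(gt.n_vertices) if not gt.is_leaf(g)]
    base = {g: inst.phi_vertex(g) for g in gt.leaves}
    for assignment in itertools.product(range(st.n_vertices), repeat=len(internal)):
        phi = dict(base)
        phi.update(zip(internal, assignment))
        try:
            events, cost = infer_events(inst, phi)
        except MappingError:
            continue
        yield phi, events, cost


def brute_force_mprs(inst: DTLInstance) -> BruteForceResult:
    """All minimum-cost reconciliation mappings and their event sets."""
    best = float("inf")
    mappings: list = []
    event_sets: set = set()
    for phi, events, cost in enumerate_valid_mappings(inst):
        if cost < best:
            best = cost
            mappings = [phi]
            event_sets = {frozenset(events)}
        elif cost == best:
            mappings.append(phi)
            event_sets.add(frozenset(events))
    return BruteForceResult(best, mappings, event_sets)
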