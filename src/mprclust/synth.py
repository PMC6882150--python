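"""Seeded random DTL instances and hand-built fixtures.

The generator draws uniform random binary topologies by recursively
splitting the leaf set, assigns the leaf mapping either bijectively or
with replacement, and draws event costs from a small grid.  The default
grid contains the cost settings commonly used in DTL analyses of
prokaryotic gene families, (d,t,l) = (2,3,1) and (1,4,1), plus the unit
scheme (1,1,1).  Identical seeds give identical instances.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .instance import (
    CostScheme,
    DTLInstance,
    InstanceError,
    LeafMapping,
    PhyloTree,
    validate_instance,
)

__all__ = ["GeneratorConfig", "random_instance", "random_tree", "fixture", "FIXTURE_NAMES"]

DEFAULT_COST_GRID = ((1.0, 1.0, 1.0), (2.0, 3.0, 1.0), (1.0, 4.0, 1.0))


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int
    n_species_leaves: int = 4
    n_gene_leaves: int = 4
    mapping_mode: str = "random-with-replacement"  # or "bijective"
    cost_grid: tuple = DEFAULT_COST_GRID

    def __post_init__(self):
        if self.n_species_leaves < 1 or self.n_gene_leaves < 1:
            raise InstanceError("leaf counts must be >= 1")
        if self.mapping_mode not in ("bijective", "random-with-replacement"):
            raise InstanceError(f"unknown mapping mode {self.mapping_mode!r}")
        if self.mapping_mode == "bijective" and self.n_gene_leaves != self.n_species_leaves:
            raise InstanceError("bijective mapping needs equal leaf counts")


def _random_topology(labels: list, rng: random.Random) -> PhyloTree:
    """Uniform random rooted binary topology via recursive random splits."""
    children_of: dict = {}
    node_labels: dict = {}
    counter = [0]

    def build(items: list) -> int:
        vid = counter[0]
        counter[0] += 1
        if len(items) == 1:
            node_labels[vid] = items[0]
            return vid
        k = rng.randint(1, len(items) - 1)
        pool = list(items)
        rng.shuffle(pool)
        left, right = pool[:k], pool[k:]
        children_of[vid] = (build(left), build(right))
        return vid

    build(list(labels))
    return PhyloTree(children_of, node_labels)


def random_tree(n_leaves: int, prefix: str, rng: random.Random) -> PhyloTree:
    labels = [f"{prefix}{i}" for i in range(n_leaves)]
    return _random_topology(labels, rng)


def random_instance(cfg: GeneratorConfig) -> DTLInstance:
    rng = random.Random(cfg.seed)
    species = random_tree(cfg.n_species_leaves, "S", rng)
    gene = random_tree(cfg.n_gene_leaves, "g", rng)
    s_names = sorted(species.leaf_names)
    g_names = sorted(gene.leaf_names)
    if cfg.mapping_mode == "bijective":
        perm = list(s_names)
        rng.shuffle(perm)
        pairs = dict(zip(g_names, perm))
    else:
        pairs = {g: rng.choice(s_names) for g in g_names}
    d, t, l = cfg.cost_grid[rng.randrange(len(cfg.cost_grid))]
    inst = DTLInstance(species, gene, LeafMapping(pairs), CostScheme(d, t, l))
    return validate_instance(inst)


# ---------------------------------------------------------------------------
# Hand-built fixtures
# ---------------------------------------------------------------------------

def _tree(nested) -> PhyloTree:
    """Build a PhyloTree from a nested tuple of leaf labels."""
    children_of: dict = {}
    labels: dict = {}
    counter = [0]

    def build(x) -> int:
        vid = counter[0]
        counter[0] += 1
        if isinstance(x, str):
            labels[vid] = x
        else:
            l, r = x
            children_of[vid] = (build(l), build(r))
        return vid

    build(nested)
    return PhyloTree(children_of, labels)


def _make(species, gene, pairs, costs) -> DTLInstance:
    inst = DTLInstance(_tree(species), _tree(gene), LeafMapping(pairs), CostScheme(*costs))
    return validate_instance(inst)


FIXTURE_NAMES = ("leaf1", "dup1", "toy3", "tie_grid")


def fixture(name: str) -> DTLInstance:
    """Small instances with documented, oracle-checked statistics.

    * ``leaf1``: one leaf in each tree; a single zero-cost MPR.
    * ``dup1``: two gene leaves on one species leaf; the only feasible
      event is a duplication (costs 1,4,1).
    * ``toy3``: G=(a,c), S=((A,B),C), a->A, c->C, unit costs; several
      cost-1 co-optima (a speciation-with-loss and transfer placements).
    * ``tie_grid``: a discordant 4-leaf tangle under unit costs with a
      moderate number of tied co-optimal reconciliations.
    """
    if name == "leaf1":
        return _make("A", "a", {"a": "A"}, (1, 1, 1))
    if name == "dup1":
        return _make("A", ("a", "b"), {"a": "A", "b": "A"}, (1, 4, 1))
    if name == "toy3":
        return _make((("A", "B"), "C"), ("a", "c"), {"a": "A", "c": "C"}, (1, 1, 1))
    if name == "tie_grid":
        return _make(
            (("A", "B"), ("C", "D")),
            (("a", "b"), ("c", "d")),
            {"a": "A", "b": "C", "c": "B", "d": "D"},
            (1, 1, 1),
        )
    raise InstanceError(f"unknown fixture {name!r}; known: {FIXTURE_NAMES}")
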