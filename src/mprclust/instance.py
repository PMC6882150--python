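"""Data types and file I/O for DTL reconciliation instances.

A DTL instance consists of a rooted binary species tree ``S``, a rooted
binary gene tree ``G``, a mapping ``phi`` from gene-tree leaves to
species-tree leaves (not necessarily one-to-one nor onto), and
non-negative event costs for duplication, transfer and loss.  Speciation
is a null event of cost zero.  Trees are undated: branch lengths and
internal labels are accepted on input and discarded.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Optional

import dendropy

__all__ = [
    "PhyloTree",
    "LeafMapping",
    "CostScheme",
    "DTLInstance",
    "InstanceError",
    "NewickError",
    "read_newick",
    "write_newick",
    "read_mapping",
    "validate_instance",
]


class InstanceError(ValueError):
    """Raised when an instance component violates a structural invariant."""


class NewickError(InstanceError):
    """Raised when a Newick string cannot be parsed into a rooted binary tree."""


class PhyloTree:
    """A rooted binary tree with preorder-indexed vertices.

    Vertices are the integers ``0 .. n_vertices-1`` in preorder; the root
    is vertex 0.  Leaves carry the labels from the input; internal
    vertices receive deterministic synthetic names (``n<preorder>``) so
    that all outputs are reproducible.
    """

    __slots__ = (
        "parent",
        "children",
        "labels",
        "_tin",
        "_tout",
        "_postorder",
        "_leaf_vertex",
    )

    def __init__(self, children_of: dict, labels: dict):
        # children_of: vertex -> (left, right) over a provisional id space
        # rooted at id 0; re-indexed here to preorder.
        order: list = []
        stack = [0]
        prov_children = children_of
        while stack:
            v = stack.pop()
            order.append(v)
            kids = prov_children.get(v)
            if kids is not None:
                stack.append(kids[1])
                stack.append(kids[0])
        remap = {old: new for new, old in enumerate(order)}
        n = len(order)
        self.parent: list[Optional[int]] = [None] * n
        self.children: list[Optional[tuple[int, int]]] = [None] * n
        self.labels: list[Optional[str]] = [None] * n
        for old in order:
            new = remap[old]
            kids = prov_children.get(old)
            if kids is not None:
                l, r = remap[kids[0]], remap[kids[1]]
                self.children[new] = (l, r)
                self.parent[l] = new
                self.parent[r] = new
            lbl = labels.get(old)
            if lbl is not None:
                self.labels[new] = lbl
        # Euler intervals for O(1) ancestry tests.
        self._tin = [0] * n
        self._tout = [0] * n
        t = 0
        stack2: list[tuple[int, bool]] = [(0, False)]
        post: list[int] = []
        while stack2:
            v, done = stack2.pop()
            if done:
                self._tout[v] = t
                post.append(v)
                continue
            self._tin[v] = t
            t += 1
            stack2.append((v, True))
            kids = self.children[v]
            if kids is not None:
                stack2.append((kids[1], False))
                stack2.append((kids[0], False))
        self._postorder = post
        self._leaf_vertex = {}
        for v in range(n):
            if self.children[v] is None:
                lbl = self.labels[v]
                if lbl is None:
                    raise InstanceError(f"leaf vertex {v} has no label")
                if lbl in self._leaf_vertex:
                    raise InstanceError(f"duplicate leaf label {lbl!r}")
                self._leaf_vertex[lbl] = v

    # -- basic accessors -------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return 0

    def is_leaf(self, v: int) -> bool:
        return self.children[v] is None

    @property
    def leaves(self) -> list[int]:
        return [v for v in range(self.n_vertices) if self.children[v] is None]

    @property
    def leaf_names(self) -> list[str]:
        return sorted(self._leaf_vertex)

    def leaf_vertex(self, label: str) -> int:
        return self._leaf_vertex[label]

    def name(self, v: int) -> str:
        lbl = self.labels[v]
        return lbl if lbl is not None else f"n{v}"

    def postorder(self) -> list[int]:
        return list(self._postorder)

    def preorder(self) -> list[int]:
        return list(range(self.n_vertices))

    # -- ancestry --------------------------------------------------------
    def is_ancestor_or_equal(self, a: int, b: int) -> bool:
        """True iff ``a`` is ``b`` or a (not necessarily proper) ancestor of it."""
        return self._tin[a] <= self._tin[b] and self._tout[b] <= self._tout[a]

    def comparable(self, a: int, b: int) -> bool:
        return self.is_ancestor_or_equal(a, b) or self.is_ancestor_or_equal(b, a)

    def path_down(self, top: int, bottom: int) -> list[int]:
        """Vertices from ``top`` to ``bottom`` inclusive, along the tree path."""
        if not self.is_ancestor_or_equal(top, bottom):
            raise InstanceError(f"{self.name(top)} is not ancestral to {self.name(bottom)}")
        path = [bottom]
        v = bottom
        while v != top:
            v = self.parent[v]  # type: ignore[assignment]
            path.append(v)
        path.reverse()
        return path

    def swap_children(self, v: int) -> "PhyloTree":
        """Return a copy of the tree with the children of ``v`` exchanged."""
        if self.is_leaf(v):
            raise InstanceError(f"vertex {self.name(v)} is a leaf")
        children_of = {}
        labels = {}
        for u in range(self.n_vertices):
            kids = self.children[u]
            if kids is not None:
                children_of[u] = (kids[1], kids[0]) if u == v else kids
            if self.labels[u] is not None:
                labels[u] = self.labels[u]
        return PhyloTree(children_of, labels)


def read_newick(text) -> PhyloTree:
    """Parse a rooted binary tree from a Newick string or stream.

    Branch lengths and internal labels are parsed and discarded (the
    model is undated).  Non-binary internal vertices are rejected.
    """
    if hasattr(text, "read"):
        text = text.read()
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise NewickError(f"malformed Newick: {exc}") from exc
    children_of: dict = {}
    labels: dict = {}
    ids: dict = {}

    def vid(node) -> int:
        if node not in ids:
            ids[node] = len(ids)
        return ids[node]

    root = dtree.seed_node
    vid(root)
    for node in dtree.preorder_node_iter():
        kids = node.child_nodes()
        if len(kids) == 0:
            label = node.taxon.label if node.taxon is not None else node.label
            if label is None:
                raise NewickError("leaf without a label")
            labels[vid(node)] = str(label)
        elif len(kids) == 2:
            children_of[vid(node)] = (vid(kids[0]), vid(kids[1]))
        else:
            where = node.label or f"vertex with {len(kids)} children"
            raise NewickError(f"non-binary internal vertex: {where}")
    return PhyloTree(children_of, labels)


def write_newick(tree: PhyloTree) -> str:
    """Serialize a tree back to Newick (labels only, no branch lengths)."""

    out: list[str] = []
    stack: list[tuple[int, int]] = [(tree.root, 0)]
    while stack:
        v, state = stack.pop()
        if tree.is_leaf(v):
            out.append(tree.labels[v])  # type: ignore[arg-type]
            continue
        l, r = tree.children[v]  # type: ignore[misc]
        if state == 0:
            out.append("(")
            stack.append((v, 1))
            stack.append((l, 0))
        elif state == 1:
            out.append(",")
            stack.append((v, 2))
            stack.append((r, 0))
        else:
            out.append(")")
    return "".join(out) + ";"


@dataclass(frozen=True)
class LeafMapping:
    """The leaf association ``phi``: gene leaf label -> species leaf label."""

    pairs: dict

    def __getitem__(self, gene_label: str) -> str:
        return self.pairs[gene_label]

    def items(self):
        return self.pairs.items()


def read_mapping(text) -> LeafMapping:
    """Read a two-column TSV mapping (gene leaf, species leaf).

    Blank lines and lines starting with ``#`` are ignored.  Duplicate
    gene leaves are rejected; whether labels exist in the trees is
    checked at instance assembly.
    """
    if hasattr(text, "read"):
        text = text.read()
    pairs: dict = {}
    for lineno, raw in enumerate(io.StringIO(text), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 2 or not cols[0] or not cols[1]:
            raise InstanceError(f"line {lineno}: expected 'gene<TAB>species', got {line!r}")
        g, s = cols
        if g in pairs:
            raise InstanceError(f"line {lineno}: duplicate gene leaf {g!r}")
        pairs[g] = s
    return LeafMapping(pairs)


@dataclass(frozen=True)
class CostScheme:
    """Non-negative event costs; speciation is a null event of cost 0."""

    dup: float
    transfer: float
    loss: float
    speciation: float = field(default=0.0, init=False)

    def __post_init__(self):
        for name in ("dup", "transfer", "loss"):
            if getattr(self, name) < 0:
                raise InstanceError(f"{name} cost must be non-negative")


@dataclass(frozen=True)
class DTLInstance:
    """A reconciliation problem: (S, G, phi, d, t, loss)."""

    species_tree: PhyloTree
    gene_tree: PhyloTree
    mapping: LeafMapping
    costs: CostScheme

    def phi_vertex(self, gene_leaf_vertex: int) -> int:
        """Species leaf vertex associated with a gene leaf vertex."""
        glabel = self.gene_tree.labels[gene_leaf_vertex]
        return self.species_tree.leaf_vertex(self.mapping[glabel])


def validate_instance(inst: DTLInstance) -> DTLInstance:
    """Check that the mapping is total on gene leaves and lands on species leaves."""
    gene_leaves = set(inst.gene_tree.leaf_names)
    species_leaves = set(inst.species_tree.leaf_names)
    mapped = set(inst.mapping.pairs)
    missing = gene_leaves - mapped
    if missing:
        raise InstanceError(f"mapping missing gene leaves: {sorted(missing)}")
    extra = mapped - gene_leaves
    if extra:
        raise InstanceError(f"mapping names unknown gene leaves: {sorted(extra)}")
    bad_images = {s for s in inst.mapping.pairs.values() if s not in species_leaves}
    if bad_images:
        raise InstanceError(f"mapping images are not species leaves: {sorted(bad_images)}")
    return inst
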