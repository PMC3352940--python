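"""Phylogenetic tree container used throughout the package.

Trees are stored as an adjacency map over integer node ids with string
labels on leaves.  The same object serves rooted and unrooted roles: an
unrooted tree simply has ``root is None``.  Polytomies are allowed
everywhere; the search module only ever produces binary trees but the
strict consensus and the tail-scenario reference phylogeny are polytomous.

Canonical bipartitions are computed against the sorted taxon list: each
internal edge is represented by the leaf set on the side *not* containing
the alphabetically first taxon, so bipartition sets are directly comparable
between trees that share a leaf set.
"""

from __future__ import annotations

import io
from typing import Iterable, Iterator, Sequence

import dendropy

__all__ = ["Tree", "strict_consensus_tree", "robinson_foulds"]


class TreeError(ValueError):
    pass


class Tree:
    """Rooted or unrooted tree with labeled leaves and integer node ids."""

    __slots__ = ("adj", "labels", "root", "_next_id")

    def __init__(self) -> None:
        self.adj: dict[int, list[int]] = {}
        self.labels: dict[int, str] = {}
        self.root: int | None = None
        self._next_id: int = 0

    # ------------------------------------------------------------------ #
    # construction

    def new_node(self, label: str | None = None) -> int:
        nid = self._next_id
        self._next_id += 1
        self.adj[nid] = []
        if label is not None:
            self.labels[nid] = label
        return nid

    def add_edge(self, u: int, v: int) -> None:
        self.adj[u].append(v)
        self.adj[v].append(u)

    def remove_edge(self, u: int, v: int) -> None:
        self.adj[u].remove(v)
        self.adj[v].remove(u)

    @classmethod
    def star(cls, taxa: Sequence[str]) -> "Tree":
        """Unrooted star tree (single internal node) over ``taxa``."""
        if len(taxa) < 3:
            raise TreeError("star tree needs >= 3 taxa")
        t = cls()
        hub = t.new_node()
        for name in taxa:
            leaf = t.new_node(name)
            t.add_edge(hub, leaf)
        return t

    def copy(self) -> "Tree":
        t = Tree()
        t.adj = {u: list(vs) for u, vs in self.adj.items()}
        t.labels = dict(self.labels)
        t.root = self.root
        t._next_id = self._next_id
        return t

    # ------------------------------------------------------------------ #
    # basic queries

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(sorted(self.labels.values()))

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def leaf_nodes(self) -> dict[str, int]:
        return {lab: nid for nid, lab in self.labels.items()}

    def degree(self, node: int) -> int:
        return len(self.adj[node])

    def is_leaf(self, node: int) -> bool:
        return node in self.labels

    def edges(self) -> list[tuple[int, int]]:
        """Undirected edges as sorted (u, v) pairs, deterministic order."""
        out = []
        for u in sorted(self.adj):
            for v in self.adj[u]:
                if u < v:
                    out.append((u, v))
        return out

    def is_binary_unrooted(self) -> bool:
        return all(
            len(vs) == 3 for u, vs in self.adj.items() if u not in self.labels
        ) and all(len(self.adj[u]) == 1 for u in self.labels)

    def validate(self) -> None:
        labels = list(self.labels.values())
        if len(set(labels)) != len(labels):
            raise TreeError("duplicate leaf labels")
        if any(not lab for lab in labels):
            raise TreeError("empty leaf label")
        for u in self.adj:
            if u in self.labels:
                if len(self.adj[u]) != 1:
                    raise TreeError(f"leaf {self.labels[u]!r} has degree != 1")

    # ------------------------------------------------------------------ #
    # traversal

    def _anchor(self) -> int:
        """Deterministic traversal start: leaf with the smallest label."""
        lab2node = self.leaf_nodes()
        return lab2node[min(lab2node)]

    def postorder(self, handle: int | None = None) -> list[tuple[int, tuple[int, ...]]]:
        """Postorder (node, children) pairs rooted at ``handle``.

        Defaults to ``self.root`` if set, else the internal node next to the
        anchor leaf (scores are root-invariant, so any handle works for
        unrooted scoring).  Children are visited in sorted-id order, which is
        deterministic because node ids are assigned deterministically.
        """
        if handle is None:
            handle = self.root if self.root is not None else self.adj[self._anchor()][0]
        out: list[tuple[int, tuple[int, ...]]] = []
        stack: list[tuple[int, int | None, bool]] = [(handle, None, False)]
        while stack:
            node, parent, expanded = stack.pop()
            kids = tuple(v for v in sorted(self.adj[node]) if v != parent)
            if expanded or not kids:
                out.append((node, kids))
            else:
                stack.append((node, parent, True))
                for v in reversed(kids):
                    stack.append((v, node, False))
        return out

    def leafset_below(self, handle: int | None = None) -> dict[int, frozenset[str]]:
        """Leaf-label set under every node, for the rooting at ``handle``."""
        below: dict[int, frozenset[str]] = {}
        for node, kids in self.postorder(handle):
            if not kids:
                below[node] = frozenset([self.labels[node]])
            else:
                s: set[str] = set()
                for k in kids:
                    s |= below[k]
                below[node] = frozenset(s)
        return below

    # ------------------------------------------------------------------ #
    # bipartitions / clades

    def bipartitions(self) -> frozenset[frozenset[str]]:
        """Non-trivial bipartitions, canonical side excludes the first taxon."""
        taxa = set(self.taxa)
        n = len(taxa)
        anchor_lab = min(taxa)
        below = self.leafset_below(self.leaf_nodes()[anchor_lab])
        out = set()
        for node, side in below.items():
            if anchor_lab in side:
                side = frozenset(taxa - side)
            if 2 <= len(side) <= n - 2:
                out.add(side)
        return frozenset(out)

    def clades(self) -> dict[int, frozenset[str]]:
        """Rooted clades (node -> leaf set); requires a root."""
        if self.root is None:
            raise TreeError("tree is unrooted; root it first")
        return self.leafset_below(self.root)

    def has_bipartition(self, side: Iterable[str]) -> bool:
        taxa = set(self.taxa)
        side = frozenset(side)
        anchor_lab = min(taxa)
        if anchor_lab in side:
            side = frozenset(taxa - side)
        return side in self.bipartitions()

    # ------------------------------------------------------------------ #
    # rooting

    def unroot(self) -> "Tree":
        """Return an unrooted copy; a degree-2 root is suppressed."""
        t = self.copy()
        if t.root is not None and len(t.adj[t.root]) == 2:
            a, b = t.adj[t.root]
            t.remove_edge(t.root, a)
            t.remove_edge(t.root, b)
            del t.adj[t.root]
            t.add_edge(a, b)
        t.root = None
        return t

    def root_with_outgroup(self, outgroup: str) -> "Tree":
        """Rooted copy with a new degree-2 root on the outgroup's edge."""
        t = self.unroot()
        leaf = t.leaf_nodes()[outgroup]
        (nbr,) = t.adj[leaf]
        t.remove_edge(leaf, nbr)
        root = t.new_node()
        t.add_edge(root, leaf)
        t.add_edge(root, nbr)
        t.root = root
        return t

    # ------------------------------------------------------------------ #
    # newick I/O

    def newick(self) -> str:
        """Deterministic newick: subtrees sorted by their smallest leaf."""
        handle = self.root if self.root is not None else self.adj[self._anchor()][0]
        below = self.leafset_below(handle)

        def render(node: int, parent: int | None) -> str:
            kids = [v for v in self.adj[node] if v != parent]
            if not kids:
                return self.labels[node]
            kids.sort(key=lambda k: min(below[k]))
            return "(" + ",".join(render(k, node) for k in kids) + ")"

        return render(handle, None) + ";"

    @classmethod
    def from_newick(cls, text: str, rooted: bool = False) -> "Tree":
        dtree = dendropy.Tree.get(data=text, schema="newick")
        t = cls()

        def build(dnode) -> int:
            if dnode.is_leaf():
                return t.new_node(dnode.taxon.label if dnode.taxon else dnode.label)
            nid = t.new_node()
            for ch in dnode.child_nodes():
                cid = build(ch)
                t.add_edge(nid, cid)
            return nid

        root = build(dtree.seed_node)
        t.root = root
        t.validate()
        return t if rooted else t.unroot()

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tree({self.newick()})"

    # equality = same leaf set and same bipartition set
    def topology_key(self) -> tuple:
        return (self.taxa, self.bipartitions())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Tree):
            return NotImplemented
        return self.topology_key() == other.topology_key()

    def __hash__(self) -> int:
        return hash(self.topology_key())


def tree_from_bipartitions(
    taxa: Sequence[str], splits: Iterable[frozenset[str]]
) -> Tree:
    """Build the (unique) tree whose non-trivial splits are exactly ``splits``.

    ``splits`` must be pairwise compatible and canonically oriented (none may
    contain the alphabetically first taxon); unresolved parts become
    polytomies.
    """
    taxa = sorted(taxa)
    anchor = taxa[0]
    fam = sorted(set(splits), key=lambda s: (-len(s), sorted(s)))
    for s in fam:
        if anchor in s:
            raise TreeError("splits must be canonically oriented")

    t = Tree()
    root = t.new_node()
    # parent of each split in the laminar family
    node_of: dict[frozenset[str], int] = {}
    parent_of: dict[frozenset[str], frozenset[str] | None] = {}
    for s in fam:
        parent = None
        for other in fam:
            if other is not s and s < other:
                if parent is None or other < parent:
                    parent = other
        parent_of[s] = parent
    for s in fam:
        node_of[s] = t.new_node()
    for s in fam:
        p = parent_of[s]
        t.add_edge(node_of[s], root if p is None else node_of[p])
    for name in taxa:
        containing = [s for s in fam if name in s]
        leaf = t.new_node(name)
        if containing:
            smallest = min(containing, key=len)
            t.add_edge(leaf, node_of[smallest])
        else:
            t.add_edge(leaf, root)
    t.root = None
    return t


def strict_consensus_tree(trees: Sequence[Tree]) -> Tree:
    """Tree containing exactly the bipartitions shared by every input tree."""
    if not trees:
        raise TreeError("no trees given")
    taxa = trees[0].taxa
    for t in trees[1:]:
        if t.taxa != taxa:
            raise TreeError("consensus requires identical leaf sets")
    common = trees[0].bipartitions()
    for t in trees[1:]:
        common &= t.bipartitions()
    return tree_from_bipartitions(taxa, common)


def robinson_foulds(a: Tree, b: Tree) -> int:
    """Unweighted Robinson-Foulds distance (symmetric split difference)."""
    if a.taxa != b.taxa:
        raise TreeError("RF distance requires identical leaf sets")
    return len(a.bipartitions() ^ b.bipartitions())
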