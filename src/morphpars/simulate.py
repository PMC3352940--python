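"""Synthetic trees and discrete character matrices with known ground truth.

The generator emulates a published-style morphological matrix: a few
hundred mostly-binary unordered characters, heavy per-taxon missingness
concentrated on designated "fragmentary" taxa (fossil operational units
known from scraps), and occasional polymorphic cells.  Characters evolve
by a symmetric k-state change process along the branches of a known tree,
so tree-recovery and support behavior can be tested against truth without
downloading anything.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .matrix import MISSING, CharacterMatrix
from .trees import Tree

__all__ = [
    "SimulationConfig",
    "simulate_tree",
    "evolve_characters",
    "clean_matrix",
    "degrade_matrix",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition knobs for the generator.

    ``change_rate`` is the probability that a character changes state on a
    given branch (a single jump to a uniformly chosen different state).
    ``states_per_char`` of ``None`` draws the state count per character
    from a fossil-matrix-like mixture (mostly binary, occasionally up to
    five states).
    """

    n_taxa: int = 12
    n_char: int = 150
    states_per_char: int | None = None
    change_rate: float = 0.12
    fraction_ordered: float = 0.0
    missing_fraction: float = 0.25
    fragmentary_taxa: int = 2
    fragmentary_missing: float = 0.8
    polymorphism_fraction: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 4:
            raise ValueError("n_taxa must be >= 4")
        for name in (
            "change_rate",
            "fraction_ordered",
            "missing_fraction",
            "fragmentary_missing",
            "polymorphism_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.states_per_char is not None and not 2 <= self.states_per_char <= 5:
            raise ValueError("states_per_char must be in 2..5")


_STATE_COUNT_MIX = ([2, 3, 4, 5], [0.65, 0.20, 0.10, 0.05])


def simulate_tree(
    n_taxa: int, seed: int | np.random.Generator = 0, mode: str = "uniform"
) -> Tree:
    """Random unrooted binary tree with leaves ``t1..tn``.

    ``uniform`` draws uniformly over labeled topologies (random stepwise
    addition onto a uniformly chosen edge); ``yule`` grows by splitting a
    uniformly chosen *pendant* edge, biasing toward balanced shapes.
    """
    if n_taxa < 3:
        raise ValueError("need >= 3 taxa")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = [f"t{i + 1}" for i in range(n_taxa)]
    tree = Tree.star(labels[:3])
    for label in labels[3:]:
        edges = tree.edges()
        if mode == "yule":
            pendant = [e for e in edges if tree.is_leaf(e[0]) or tree.is_leaf(e[1])]
            edges = pendant
        u, v = edges[int(rng.integers(len(edges)))]
        tree.remove_edge(u, v)
        w = tree.new_node()
        leaf = tree.new_node(label)
        tree.add_edge(u, w)
        tree.add_edge(w, v)
        tree.add_edge(w, leaf)
    return tree


def evolve_characters(
    tree: Tree,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> CharacterMatrix:
    """Evolve ``config.n_char`` characters along ``tree``.

    Each character starts from a uniform root state and, on every branch,
    jumps to a different uniformly chosen state with probability
    ``change_rate``.  The generating tree (newick), per-character true
    change counts, and state counts are recorded in ``matrix.meta``.
    """
    rng = rng or np.random.default_rng(config.seed)
    nc = config.n_char
    if config.states_per_char is None:
        ks = rng.choice(_STATE_COUNT_MIX[0], size=nc, p=_STATE_COUNT_MIX[1])
    else:
        ks = np.full(nc, config.states_per_char)
    ordered = rng.random(nc) < config.fraction_ordered

    post = tree.postorder()
    root = post[-1][0]
    parent_of: dict[int, int] = {}
    preorder: list[int] = []
    for node, kids in reversed(post):
        preorder.append(node)
        for c in kids:
            parent_of[c] = node

    node_states: dict[int, np.ndarray] = {}
    true_changes = np.zeros(nc, dtype=int)
    node_states[root] = np.array([rng.integers(k) for k in ks])
    for node in preorder[1:]:
        parent_state = node_states[parent_of[node]]
        state = parent_state.copy()
        hit = rng.random(nc) < config.change_rate
        for j in np.flatnonzero(hit):
            k = int(ks[j])
            choices = [s for s in range(k) if s != state[j]]
            state[j] = choices[int(rng.integers(k - 1))]
        true_changes += hit.astype(int)
        node_states[node] = state

    taxa = sorted(tree.labels.values(), key=lambda s: int(s[1:]) if s[1:].isdigit() else 0)
    leaf_of = tree.leaf_nodes()
    cells = [
        [frozenset([int(node_states[leaf_of[t]][j])]) for j in range(nc)]
        for t in taxa
    ]
    m = CharacterMatrix(
        taxa,
        cells,
        states=[tuple(range(int(k))) for k in ks],
        ordered=list(map(bool, ordered)),
    )
    m.meta["true_tree"] = tree.newick()
    m.meta["true_changes"] = true_changes.tolist()
    return m


def clean_matrix(tree: Tree, chars_per_edge: int = 1) -> CharacterMatrix:
    """Homoplasy-free binary matrix: one split character per internal edge.

    Every internal edge of the generating tree gets ``chars_per_edge``
    characters whose derived state marks one side of the edge, so parsimony
    must recover exactly the generating tree, with CI = 1.
    """
    taxa = sorted(tree.labels.values())
    splits = sorted(tree.bipartitions(), key=lambda s: (len(s), sorted(s)))
    cells = [[] for _ in taxa]
    for side in splits:
        for _ in range(chars_per_edge):
            for i, t in enumerate(taxa):
                cells[i].append(frozenset([1 if t in side else 0]))
    if not splits:
        raise ValueError("tree has no internal edges")
    return CharacterMatrix(taxa, cells, states=[(0, 1)] * len(cells[0]))


def degrade_matrix(
    matrix: CharacterMatrix,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> CharacterMatrix:
    """Mask cells to missing and inject polymorphism, fossil-style.

    Uniform background missingness at ``missing_fraction`` plus
    concentrated missingness (``fragmentary_missing``) on
    ``fragmentary_taxa`` randomly chosen taxa.  The boolean mask and the
    fragmentary taxon list are recorded in ``meta``; a taxon that loses
    every cell is flagged rather than silently kept.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    nt, nc = matrix.n_taxa, matrix.n_char
    mask = rng.random((nt, nc)) < config.missing_fraction
    frag_idx = sorted(
        rng.choice(nt, size=min(config.fragmentary_taxa, nt), replace=False).tolist()
    )
    for i in frag_idx:
        mask[i] |= rng.random(nc) < config.fragmentary_missing
    poly = (rng.random((nt, nc)) < config.polymorphism_fraction) & ~mask

    cells = []
    starved = []
    for i in range(nt):
        row = []
        for j in range(nc):
            c = matrix.cells[i][j]
            if mask[i, j]:
                row.append(MISSING)
            elif poly[i, j] and isinstance(c, frozenset):
                k = len(matrix.states[j])
                if k >= 2:
                    cur = next(iter(c))
                    extra = (cur + 1 + int(rng.integers(k - 1))) % k
                    c = c | {extra}
                row.append(c)
            else:
                row.append(c)
        if all(x is MISSING for x in row):
            starved.append(matrix.taxa[i])
        cells.append(row)
    out = CharacterMatrix(
        matrix.taxa, cells, states=matrix.states, ordered=matrix.ordered
    )
    out.meta.update(matrix.meta)
    out.meta["mask"] = mask.tolist()
    out.meta["fragmentary_taxa"] = [matrix.taxa[i] for i in frag_idx]
    out.meta["fully_missing_taxa"] = starved
    return out
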