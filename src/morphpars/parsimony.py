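"""Parsimony scoring: character lengths, step bounds, homoplasy indices.

Unordered (non-additive) characters are scored with Hartigan's
minimum-mutation algorithm, which reduces to Fitch optimization on binary
trees and remains exact on polytomies.  Ordered (additive) characters use
the Sankoff dynamic program with Manhattan step costs; a general cost
matrix entry point is kept public because the Fitch == Sankoff(uniform
costs) equivalence is one of the package's cross-checks.

Step bounds per character:

* ``m`` — the minimum steps attainable on *any* tree.  For an unordered
  character this is (number of states needed to cover every cell) - 1,
  ambiguity resolved to minimize the count (a minimum hitting set over the
  observed states).  For an ordered character it is the width of the
  narrowest state window meeting every cell.
* ``g`` — the maximum steps over all trees, attained on the star tree
  (collapsing edges can only raise the parsimony length, so the fully
  unresolved tree is the worst case).  For an unordered character this is
  (scored cells) - (largest number of cells a single state can claim),
  ambiguity resolved to inflate the modal state.

Ensemble indices over a matrix: CI = M/S, HI = 1 - CI,
RI = (G - S)/(G - M), RC = CI * RI, with M, S, G the sums of per-character
m, s, g.  Uninformative characters are included in the sums by default
(the convention under which CI + HI = 1 holds exactly); a flag excludes
them for comparison with programs that drop uninformative characters.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np

from .matrix import MISSING, CharacterMatrix
from .trees import Tree

__all__ = [
    "character_length",
    "tree_length",
    "character_lengths",
    "char_bounds",
    "homoplasy_stats",
    "sankoff_length",
    "HomoplasyStats",
    "CoverageError",
]


class CoverageError(ValueError):
    pass


# ---------------------------------------------------------------------- #
# column encoding


def _column_bools(
    tree: Tree, columns: Sequence[Mapping[str, frozenset[int]]], k: int
) -> dict[int, np.ndarray]:
    """Leaf node -> boolean (n_col, k) state membership arrays."""
    out: dict[int, np.ndarray] = {}
    for lab, node in tree.leaf_nodes().items():
        arr = np.zeros((len(columns), k), dtype=bool)
        for i, col in enumerate(columns):
            try:
                cell = col[lab]
            except KeyError:
                raise CoverageError(f"leaf {lab!r} has no data in column {i + 1}")
            for s in cell:
                arr[i, s] = True
        out[node] = arr
    return out


def _check_leaves(tree: Tree, taxa: Sequence[str]) -> None:
    tree_taxa = set(tree.taxa)
    mat_taxa = set(taxa)
    if tree_taxa != mat_taxa:
        missing = sorted(mat_taxa - tree_taxa)
        extra = sorted(tree_taxa - mat_taxa)
        raise CoverageError(
            f"tree/matrix taxon mismatch: matrix-only={missing}, tree-only={extra}"
        )


# ---------------------------------------------------------------------- #
# unordered scoring (Hartigan, vectorized across columns)


def _hartigan_lengths(
    tree: Tree, columns: Sequence[Mapping[str, frozenset[int]]], k: int
) -> np.ndarray:
    sets = _column_bools(tree, columns, k)
    steps = np.zeros(len(columns), dtype=np.int64)
    for node, kids in tree.postorder():
        if not kids:
            continue
        counts = sets[kids[0]].astype(np.int32)
        for c in kids[1:]:
            counts = counts + sets[c]
        top = counts.max(axis=1)
        sets[node] = counts == top[:, None]
        steps += len(kids) - top
    return steps


# ---------------------------------------------------------------------- #
# Sankoff scoring (general cost matrix)


def _sankoff_vectors(
    tree: Tree,
    columns: Sequence[Mapping[str, frozenset[int]]],
    cost: np.ndarray,
) -> tuple[dict[int, np.ndarray], np.ndarray]:
    """Postorder cost vectors; returns (vectors, per-column minima)."""
    k = cost.shape[0]
    big = np.iinfo(np.int64).max // 4
    vecs: dict[int, np.ndarray] = {}
    leaf_sets = _column_bools(tree, columns, k)
    for node, kids in tree.postorder():
        if not kids:
            v = np.where(leaf_sets[node], 0, big)
            vecs[node] = v.astype(np.int64)
            continue
        total = np.zeros((len(columns), k), dtype=np.int64)
        for c in kids:
            child = vecs[c]  # (nc, k)
            # min over child state t of child[:, t] + cost[t, s]
            total = total + (child[:, :, None] + cost[None, :, :]).min(axis=1)
        vecs[node] = total
    root = tree.postorder()[-1][0]
    return vecs, vecs[root].min(axis=1)


def sankoff_length(
    tree: Tree, column: Mapping[str, frozenset[int]], cost: np.ndarray
) -> int:
    """Minimum total cost of ``column`` on ``tree`` under ``cost`` steps."""
    _, mins = _sankoff_vectors(tree, [column], np.asarray(cost, dtype=np.int64))
    return int(mins[0])


def _unit_cost(k: int) -> np.ndarray:
    return np.ones((k, k), dtype=np.int64) - np.eye(k, dtype=np.int64)


def _linear_cost(k: int) -> np.ndarray:
    idx = np.arange(k)
    return np.abs(idx[:, None] - idx[None, :]).astype(np.int64)


# ---------------------------------------------------------------------- #
# public scoring API


def character_length(
    tree: Tree, column: Mapping[str, frozenset[int]], ordered_flag: bool = False
) -> int:
    """Minimum number of state changes for one character on ``tree``.

    Missing cells should be passed as full state sets (see
    ``CharacterMatrix.column``); they constrain nothing.
    """
    if tree.n_leaves < 2:
        raise CoverageError("tree must have >= 2 leaves")
    k = max((max(c) for c in column.values() if c), default=0) + 1
    if ordered_flag:
        return sankoff_length(tree, column, _linear_cost(k))
    return int(_hartigan_lengths(tree, [column], k)[0])


def character_lengths(
    tree: Tree, matrix: CharacterMatrix, gap_as_state: bool = False
) -> np.ndarray:
    """Per-character observed steps ``s_i`` on ``tree`` (1-based order)."""
    _check_leaves(tree, matrix.taxa)
    out = np.zeros(matrix.n_char, dtype=np.int64)
    unordered = [j for j in range(matrix.n_char) if not matrix.ordered[j]]
    ordered = [j for j in range(matrix.n_char) if matrix.ordered[j]]
    if unordered:
        cols = [matrix.column(j, gap_as_state) for j in unordered]
        k = max(max((max(c) for c in col.values()), default=0) for col in cols) + 1
        out[unordered] = _hartigan_lengths(tree, cols, k)
    for j in ordered:
        out[j] = character_length(tree, matrix.column(j, gap_as_state), True)
    return out


def tree_length(tree: Tree, matrix: CharacterMatrix, gap_as_state: bool = False) -> int:
    """Total parsimony length S = sum of per-character minimum changes."""
    return int(character_lengths(tree, matrix, gap_as_state).sum())


# ---------------------------------------------------------------------- #
# per-character step bounds


def _proper_cells(raw: list[object]) -> list[frozenset[int]]:
    sets = [c for c in raw if isinstance(c, frozenset) and c]
    if not sets:
        return []
    universe = frozenset().union(*sets)
    if len(universe) <= 1:
        return sets
    return [c for c in sets if c != universe]


def char_bounds(
    column: Mapping[str, frozenset[int]] | Sequence[object],
    ordered_flag: bool = False,
) -> tuple[int, int]:
    """(m, g): min steps on any tree, max steps over all trees.

    Cells given as the MISSING/INAPPLICABLE markers or as full-ambiguity
    sets are excluded (they can always be assigned for free).
    """
    raw = list(column.values()) if isinstance(column, Mapping) else list(column)
    raw = [c for c in raw if c is not MISSING and isinstance(c, (frozenset, set))]
    cells = _proper_cells([frozenset(c) for c in raw])
    if not cells:
        return (0, 0)
    observed = sorted(frozenset().union(*cells))

    if ordered_flag:
        # m: narrowest window [a, b] containing a member of every cell
        best_m = None
        for a in observed:
            for b in observed:
                if b < a:
                    continue
                if all(any(a <= x <= b for x in c) for c in cells):
                    w = b - a
                    best_m = w if best_m is None else min(best_m, w)
        m = best_m or 0
        # g: star-tree length, ambiguity resolved against the center
        g = min(
            sum(max(abs(x - c) for x in cell) for cell in cells) for c in observed
        )
        return (m, g)

    # m: minimum hitting set over observed states, minus one
    m = len(observed) - 1
    for size in range(1, len(observed) + 1):
        hit = False
        for combo in combinations(observed, size):
            sc = set(combo)
            if all(c & sc for c in cells):
                hit = True
                break
        if hit:
            m = size - 1
            break
    # g: scored cells minus the best achievable modal-state frequency
    modal = max(sum(1 for c in cells if s in c) for s in observed)
    g = len(cells) - modal
    return (m, g)


# ---------------------------------------------------------------------- #
# homoplasy statistics


@dataclass(frozen=True)
class HomoplasyStats:
    """Per-character step bounds and the ensemble homoplasy indices."""

    m: np.ndarray  # minimum conceivable steps per character
    s: np.ndarray  # observed steps on the scored tree
    g: np.ndarray  # maximum conceivable steps per character
    S: int
    M: int
    G: int
    CI: float | None
    HI: float | None
    RI: float | None
    RC: float | None
    no_variation: bool = False

    def per_character_table(self) -> "list[dict]":
        rows = []
        for j in range(len(self.s)):
            mi, si, gi = int(self.m[j]), int(self.s[j]), int(self.g[j])
            rows.append(
                {
                    "character": j + 1,
                    "m": mi,
                    "s": si,
                    "g": gi,
                    "ci": (mi / si) if si > 0 else None,
                    "ri": ((gi - si) / (gi - mi)) if gi > mi else None,
                }
            )
        return rows


def homoplasy_stats(
    matrix: CharacterMatrix,
    tree: Tree,
    include_uninformative: bool = True,
    gap_as_state: bool = False,
) -> HomoplasyStats:
    """Ensemble CI/HI/RI/RC of ``matrix`` on ``tree``."""
    s = character_lengths(tree, matrix, gap_as_state)
    bounds = [
        char_bounds([row[j] for row in matrix.cells], matrix.ordered[j])
        for j in range(matrix.n_char)
    ]
    m = np.array([b[0] for b in bounds], dtype=np.int64)
    g = np.array([b[1] for b in bounds], dtype=np.int64)
    sel = np.ones(matrix.n_char, dtype=bool)
    if not include_uninformative:
        sel = np.array(
            [matrix.column_informative(j) for j in range(matrix.n_char)], dtype=bool
        )
    S, M, G = int(s[sel].sum()), int(m[sel].sum()), int(g[sel].sum())
    if S == 0:
        return HomoplasyStats(m, s, g, S, M, G, None, None, None, None, True)
    CI = M / S
    HI = 1.0 - CI
    RI = (G - S) / (G - M) if G > M else None
    RC = CI * RI if RI is not None else None
    return HomoplasyStats(m, s, g, S, M, G, CI, HI, RI, RC)
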