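"""Ancestral-state optimization and synapomorphy mapping on a rooted tree.

Both transformations are computed on the Sankoff cost-vector dynamic
program (unit costs for unordered characters, Manhattan costs for ordered
ones), so the total change count always equals the character's parsimony
length.  The two modes differ only in how ties among equally parsimonious
assignments are resolved during the preorder sweep:

* ACCTRAN (accelerated transformation) switches away from the parent's
  state as early as possible, pushing changes rootward and favoring
  reversals over parallelisms.
* DELTRAN (delayed transformation) keeps the parent's state whenever it
  remains optimal, pushing changes tipward and favoring parallelisms.

Remaining ties are broken toward the lowest state label, which makes both
reconstructions deterministic and invariant to child ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .matrix import CharacterMatrix
from .parsimony import _linear_cost, _unit_cost, _column_bools
from .trees import Tree, TreeError

__all__ = [
    "Reconstruction",
    "SynapomorphyRecord",
    "optimize_states",
    "synapomorphy_list",
]

ACCTRAN = "ACCTRAN"
DELTRAN = "DELTRAN"


@dataclass(frozen=True)
class Change:
    """One inferred state change on a branch (parent -> child node)."""

    parent: int
    child: int
    clade: frozenset[str]  # leaves under the child end of the branch
    from_state: int
    to_state: int


@dataclass
class Reconstruction:
    mode: str
    node_states: dict[int, int]
    changes: list[Change]

    def n_steps(self, ordered: bool = False) -> int:
        if ordered:
            return sum(abs(c.to_state - c.from_state) for c in self.changes)
        return len(self.changes)


@dataclass(frozen=True)
class SynapomorphyRecord:
    clade: frozenset[str]
    character: int  # 1-based index
    state: int
    support_mode: str  # both | ACCTRAN-only | DELTRAN-only
    description: str = ""


def optimize_states(
    tree: Tree,
    column: Mapping[str, frozenset[int]],
    mode: str = ACCTRAN,
    ordered_flag: bool = False,
) -> Reconstruction:
    """Minimum-change ancestral states for one character, per ``mode``."""
    if tree.root is None:
        raise TreeError("optimization requires a rooted tree (set an outgroup)")
    mode = mode.upper()
    if mode not in (ACCTRAN, DELTRAN):
        raise ValueError(f"unknown optimization mode {mode!r}")
    k = max(max(c) for c in column.values() if c) + 1
    cost = _linear_cost(k) if ordered_flag else _unit_cost(k)
    big = np.iinfo(np.int64).max // 4

    post = tree.postorder(tree.root)
    leaf_sets = _column_bools(tree, [column], k)
    vec: dict[int, np.ndarray] = {}
    for node, kids in post:
        if not kids:
            vec[node] = np.where(leaf_sets[node][0], 0, big).astype(np.int64)
            continue
        total = np.zeros(k, dtype=np.int64)
        for c in kids:
            total += (vec[c][:, None] + cost).min(axis=0)
        vec[node] = total

    below = tree.leafset_below(tree.root)
    states: dict[int, int] = {}
    changes: list[Change] = []
    root = post[-1][0]
    states[root] = int(np.argmin(vec[root]))  # ties -> lowest label
    for node, kids in reversed(post):
        if node not in states:
            continue
        ps = states[node]
        for c in kids:
            totals = vec[c] + cost[ps]
            best = totals.min()
            cand = np.flatnonzero(totals == best)
            if mode == DELTRAN and ps in cand:
                chosen = ps
            elif mode == ACCTRAN:
                non_parent = [s for s in cand if s != ps]
                chosen = non_parent[0] if non_parent else ps
            else:
                chosen = int(cand[0])
            states[c] = int(chosen)
            if chosen != ps:
                changes.append(Change(node, c, below[c], ps, int(chosen)))
    return Reconstruction(mode=mode, node_states=states, changes=changes)


def synapomorphy_list(
    tree: Tree,
    matrix: CharacterMatrix,
    clade: frozenset[str] | int,
    gap_as_state: bool = False,
) -> list[SynapomorphyRecord]:
    """Character states arising on the stem branch of ``clade``.

    ``clade`` may be an internal node id or its leaf set.  Each record is
    flagged by whether the change appears under both transformations or
    under only one.
    """
    if tree.root is None:
        raise TreeError("synapomorphy mapping requires a rooted tree")
    clades = tree.clades()
    if isinstance(clade, int):
        node = clade
    else:
        want = frozenset(clade)
        node = next((n for n, s in clades.items() if s == want), None)
        if node is None:
            raise TreeError(f"no internal node has leaf set {sorted(want)}")
    if tree.is_leaf(node):
        raise TreeError("synapomorphies are defined for internal clades, not leaves")
    leafset = clades[node]

    records: list[SynapomorphyRecord] = []
    for j in range(matrix.n_char):
        column = matrix.column(j, gap_as_state)
        per_mode: dict[str, set[int]] = {}
        for mode in (ACCTRAN, DELTRAN):
            rec = optimize_states(tree, column, mode, matrix.ordered[j])
            per_mode[mode] = {
                c.to_state for c in rec.changes if c.child == node
            }
        both = per_mode[ACCTRAN] & per_mode[DELTRAN]
        desc = (
            matrix.definitions[j].description
            if matrix.definitions is not None
            else ""
        )
        for state in sorted(both):
            records.append(
                SynapomorphyRecord(leafset, j + 1, state, "both", desc)
            )
        for state in sorted(per_mode[ACCTRAN] - both):
            records.append(
                SynapomorphyRecord(leafset, j + 1, state, "ACCTRAN-only", desc)
            )
        for state in sorted(per_mode[DELTRAN] - both):
            records.append(
                SynapomorphyRecord(leafset, j + 1, state, "DELTRAN-only", desc)
            )
    return records
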