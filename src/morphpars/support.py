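"""Bremer decay indices.

The decay index of a clade is the number of extra steps needed before
trees lacking the clade enter the optimal set: L(not-clade) - L(best).
The primary route is a converse-constraint heuristic search in which any
addition or swap product containing the constrained bipartition is
rejected; the exact route enumerates every topology and bins it by clade
presence, and serves as the small-instance oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrix import CharacterMatrix
from .search import (
    SearchConfig,
    SearchResult,
    Scorer,
    _NEIGHBORHOODS,
    _all_topologies,
    _attach_leaf,
    n_unrooted_topologies,
    branch_swap,
    random_addition,
    strict_consensus,
)
from .trees import Tree

__all__ = ["SupportRecord", "decay_index", "decay_index_exhaustive", "decay_table"]


@dataclass(frozen=True)
class SupportRecord:
    bipartition: frozenset[str]
    decay: int


def _canonical(matrix: CharacterMatrix, clade) -> frozenset[str]:
    taxa = set(matrix.taxa)
    side = frozenset(clade)
    unknown = side - taxa
    if unknown:
        raise ValueError(f"clade names not in matrix: {sorted(unknown)}")
    if len(side) < 2 or len(side) > len(taxa) - 2:
        raise ValueError("decay is defined for non-trivial bipartitions only")
    if min(taxa) in side:
        side = frozenset(taxa - side)
    return side


def _contains(tree: Tree, side: frozenset[str]) -> bool:
    return side in tree.bipartitions()


def _break_clade(tree: Tree, side: frozenset[str], scorer: Scorer) -> Tree:
    """Cheapest NNI across the clade's stem edge; guarantees the split is gone."""
    best = None
    best_len = None
    for nb in _NEIGHBORHOODS["nni"](tree):
        if _contains(nb, side):
            continue
        length = scorer.length(nb)
        if best_len is None or length < best_len:
            best, best_len = nb, length
    if best is None:  # pragma: no cover - NNI across the stem always works
        raise RuntimeError("could not break constrained clade")
    return best


def _constrained_swap(
    start: Tree,
    scorer: Scorer,
    side: frozenset[str],
    config: SearchConfig,
) -> int:
    """Best length reachable by swapping while never containing ``side``."""
    from collections import deque

    neighborhood = _NEIGHBORHOODS[config.swap]
    best = scorer.length(start)
    pool = {start.bipartitions()}
    queue = deque([start])
    while queue:
        current = queue.popleft()
        restart = None
        for nb in neighborhood(current):
            if _contains(nb, side):
                continue
            length = scorer.length(nb)
            if length < best:
                best = length
                restart = nb
                break
            if length == best:
                key = nb.bipartitions()
                if key not in pool:
                    if config.maxtrees is not None and len(pool) >= config.maxtrees:
                        continue
                    pool.add(key)
                    queue.append(nb)
        if restart is not None:
            pool = {restart.bipartitions()}
            queue = deque([restart])
    return best


def decay_index(
    matrix: CharacterMatrix,
    clade,
    best_length: int,
    config: SearchConfig = SearchConfig(),
    mpt_set: list[Tree] | None = None,
) -> int:
    """Extra steps required to lose ``clade`` from the optimal trees.

    Returns 0 immediately if some supplied most-parsimonious tree already
    lacks the clade.  Otherwise runs the converse-constraint heuristic
    (same replicate/seed policy as the main search).
    """
    side = _canonical(matrix, clade)
    if mpt_set is not None and any(not _contains(t, side) for t in mpt_set):
        return 0
    scorer = Scorer(matrix)
    master = np.random.SeedSequence(config.seed)
    best: int | None = None
    for child in master.spawn(config.replicates):
        rng = np.random.default_rng(child)
        start = random_addition(matrix, rng)
        if _contains(start, side):
            start = _break_clade(start, side, scorer)
        length = _constrained_swap(start, scorer, side, config)
        if best is None or length < best:
            best = length
    return max(0, best - best_length)


def decay_index_exhaustive(
    matrix: CharacterMatrix, clade, best_length: int, cap: int = 9
) -> int:
    """Exact decay by enumerating all topologies lacking the clade."""
    side = _canonical(matrix, clade)
    n = matrix.n_taxa
    if n > cap:
        raise ValueError(
            f"exhaustive decay over {n} taxa needs {n_unrooted_topologies(n)} trees"
        )
    scorer = Scorer(matrix)
    best = None
    for tree in _all_topologies(matrix.taxa):
        if _contains(tree, side):
            continue
        length = scorer.length(tree)
        if best is None or length < best:
            best = length
    return max(0, best - best_length)


def decay_table(
    matrix: CharacterMatrix,
    result: SearchResult,
    config: SearchConfig = SearchConfig(),
) -> list[SupportRecord]:
    """One record per internal bipartition of the strict consensus."""
    if not result.mpt_set:
        raise ValueError("empty most-parsimonious tree set")
    consensus = strict_consensus(result.mpt_set)
    records = []
    for side in sorted(consensus.bipartitions(), key=lambda s: (len(s), sorted(s))):
        d = decay_index(
            matrix, side, result.best_length, config, mpt_set=result.mpt_set
        )
        records.append(SupportRecord(side, d))
    return records
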