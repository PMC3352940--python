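"""Most-parsimonious tree search.

The reference procedure mirrors classic parsimony software: random
addition-sequence starting trees, branch swapping (TBR by default, with
SPR and NNI as cheaper tiers), retention of all equal-best trees, and a
strict consensus over the pooled result.  An exhaustive enumerator over
all unrooted binary topologies serves as the exact oracle on small
instances.

Tree counting is sensitive to the rule used to collapse unsupported
branches before deduplication.  The default collapses every internal
branch whose minimum optimized length is zero (contracting it does not
raise the tree length); ``collapse="never"`` keeps the binary trees.
Because published tree counts depend on this unstated convention, counts
are reported but lengths and consensus topology are the primary outputs.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

from .matrix import CharacterMatrix
from .parsimony import CoverageError, character_length, sankoff_length, _linear_cost
from .trees import Tree, strict_consensus_tree

__all__ = [
    "SearchConfig",
    "SearchResult",
    "Scorer",
    "random_addition",
    "branch_swap",
    "heuristic_search",
    "exhaustive_search",
    "strict_consensus",
    "collapse_unsupported",
]


@dataclass(frozen=True)
class SearchConfig:
    replicates: int = 10
    seed: int = 0
    swap: str = "tbr"  # tbr | spr | nni
    maxtrees: int | None = None
    collapse: str = "min"  # min | never
    steepest: bool = False
    exhaustive_cap: int = 9

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.swap not in ("tbr", "spr", "nni"):
            raise ValueError(f"unknown swap algorithm {self.swap!r}")
        if self.collapse not in ("min", "never"):
            raise ValueError(f"unknown collapse rule {self.collapse!r}")


@dataclass
class SearchResult:
    best_length: int
    mpt_set: list[Tree]
    replicate_log: list[dict] = field(default_factory=list)
    island_count: int | None = None
    truncated: bool = False
    n_topologies: int | None = None  # exhaustive searches only

    @property
    def mpt_count(self) -> int:
        return len(self.mpt_set)


# ---------------------------------------------------------------------- #
# fast rescoring


class Scorer:
    """Caches the matrix encoding so many trees can be scored cheaply."""

    def __init__(self, matrix: CharacterMatrix, gap_as_state: bool = False) -> None:
        self.matrix = matrix
        self.taxa = set(matrix.taxa)
        unordered = [j for j in range(matrix.n_char) if not matrix.ordered[j]]
        self.ordered_cols = [
            (matrix.column(j, gap_as_state), matrix.states[j])
            for j in range(matrix.n_char)
            if matrix.ordered[j]
        ]
        cols = [matrix.column(j, gap_as_state) for j in unordered]
        k = 1
        for col in cols:
            for cell in col.values():
                if cell:
                    k = max(k, max(cell) + 1)
        self.k = k
        self.leaf_arrays: dict[str, np.ndarray] = {}
        for taxon in matrix.taxa:
            arr = np.zeros((len(cols), k), dtype=bool)
            for i, col in enumerate(cols):
                for s in col[taxon]:
                    arr[i, s] = True
            self.leaf_arrays[taxon] = arr

    def length(self, tree: Tree) -> int:
        if set(tree.labels.values()) != self.taxa:
            raise CoverageError("tree leaves do not match matrix taxa")
        steps = 0
        arrs: dict[int, np.ndarray] = {}
        for node, kids in tree.postorder():
            if not kids:
                arrs[node] = self.leaf_arrays[tree.labels[node]]
                continue
            counts = arrs[kids[0]].astype(np.int32)
            for c in kids[1:]:
                counts = counts + arrs[c]
            top = counts.max(axis=1)
            arrs[node] = counts == top[:, None]
            steps += int((len(kids) - top).sum())
        for col, states in self.ordered_cols:
            k = max(states) + 1
            steps += sankoff_length(tree, col, _linear_cost(k))
        return steps


# ---------------------------------------------------------------------- #
# tree surgery helpers (operate on copies)


def _attach_leaf(tree: Tree, edge: tuple[int, int], label: str) -> Tree:
    t = tree.copy()
    u, v = edge
    t.remove_edge(u, v)
    w = t.new_node()
    leaf = t.new_node(label)
    t.add_edge(u, w)
    t.add_edge(w, v)
    t.add_edge(w, leaf)
    return t


def _suppress_if_degree2(t: Tree, node: int) -> None:
    if node not in t.labels and len(t.adj[node]) == 2:
        a, b = t.adj[node]
        t.remove_edge(node, a)
        t.remove_edge(node, b)
        del t.adj[node]
        t.add_edge(a, b)


def _component(t: Tree, start: int) -> set[int]:
    seen = {start}
    stack = [start]
    while stack:
        n = stack.pop()
        for v in t.adj[n]:
            if v not in seen:
                seen.add(v)
                stack.append(v)
    return seen


def _nni_neighbors(tree: Tree) -> Iterator[Tree]:
    for u, v in tree.edges():
        if tree.is_leaf(u) or tree.is_leaf(v):
            continue
        a_nbrs = [x for x in tree.adj[u] if x != v]
        b_nbrs = [x for x in tree.adj[v] if x != u]
        a = a_nbrs[1]
        for b in b_nbrs:
            t = tree.copy()
            t.remove_edge(u, a)
            t.remove_edge(v, b)
            t.add_edge(u, b)
            t.add_edge(v, a)
            yield t


def _spr_neighbors(tree: Tree) -> Iterator[Tree]:
    for u, v in [e for e in tree.edges()] + [(b, a) for a, b in tree.edges()]:
        # prune the subtree hanging from v (viewed from u)
        t = tree.copy()
        t.remove_edge(u, v)
        residual = _component(t, u)
        if len(residual) < 3:
            continue  # nowhere to regraft
        _suppress_if_degree2(t, u)
        sub_nodes = _component(t, v)
        for a, b in t.edges():
            if a in sub_nodes or b in sub_nodes:
                continue
            t2 = t.copy()
            t2.remove_edge(a, b)
            w = t2.new_node()
            t2.add_edge(a, w)
            t2.add_edge(w, b)
            t2.add_edge(w, v)
            yield t2


def _tbr_neighbors(tree: Tree) -> Iterator[Tree]:
    for u, v in tree.edges():
        t = tree.copy()
        t.remove_edge(u, v)
        comp_u = _component(t, u)
        comp_v = _component(t, v)
        _suppress_if_degree2(t, u)
        _suppress_if_degree2(t, v)
        comp_u &= set(t.adj)
        comp_v &= set(t.adj)
        edges_u = [e for e in t.edges() if e[0] in comp_u]
        edges_v = [e for e in t.edges() if e[0] in comp_v]
        # a component without internal edges is a single node (leaf)
        points_u: list = edges_u or [min(comp_u)]
        points_v: list = edges_v or [min(comp_v)]
        for pa in points_u:
            for pb in points_v:
                t2 = t.copy()
                ends = []
                for p in (pa, pb):
                    if isinstance(p, tuple):
                        a, b = p
                        t2.remove_edge(a, b)
                        w = t2.new_node()
                        t2.add_edge(a, w)
                        t2.add_edge(w, b)
                        ends.append(w)
                    else:
                        ends.append(p)
                t2.add_edge(ends[0], ends[1])
                yield t2


_NEIGHBORHOODS = {"nni": _nni_neighbors, "spr": _spr_neighbors, "tbr": _tbr_neighbors}


# ---------------------------------------------------------------------- #
# stepwise addition


def random_addition(
    matrix: CharacterMatrix,
    seed: int | np.random.Generator = 0,
    gap_as_state: bool = False,
) -> Tree:
    """Stepwise-addition starting tree under a seeded random taxon order.

    Each taxon is inserted on the edge giving the smallest incremental
    length; ties go to the first edge in canonical enumeration order.
    """
    if matrix.n_taxa < 3:
        raise ValueError("stepwise addition needs >= 3 taxa")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    order = [matrix.taxa[i] for i in rng.permutation(matrix.n_taxa)]
    scorer = _subset_scorer_factory(matrix, gap_as_state)
    tree = Tree.star(order[:3])
    for taxon in order[3:]:
        sc = scorer(set(tree.taxa) | {taxon})
        best = None
        best_len = None
        for edge in tree.edges():
            cand = _attach_leaf(tree, edge, taxon)
            length = sc.length(cand)
            if best_len is None or length < best_len:
                best, best_len = cand, length
        tree = best
    return tree


def _subset_scorer_factory(matrix: CharacterMatrix, gap_as_state: bool):
    """Scorer over taxon subsets (for growing trees during addition)."""

    def make(taxa: set[str]) -> Scorer:
        keep = [i for i, t in enumerate(matrix.taxa) if t in taxa]
        sub = CharacterMatrix(
            [matrix.taxa[i] for i in keep],
            [matrix.cells[i] for i in keep],
            states=matrix.states,
            ordered=matrix.ordered,
        )
        return Scorer(sub, gap_as_state)

    return make


# ---------------------------------------------------------------------- #
# collapse rule


def min_branch_length(tree: Tree, scorer: Scorer, edge: tuple[int, int]) -> int:
    """Minimum optimized changes on ``edge``: length(contracted) - length."""
    u, v = edge
    t = tree.copy()
    # contract: merge v into u
    for x in list(t.adj[v]):
        t.remove_edge(v, x)
        if x != u:
            t.add_edge(u, x)
    del t.adj[v]
    return scorer.length(t) - scorer.length(tree)


def collapse_unsupported(tree: Tree, scorer: Scorer) -> Tree:
    """Collapse internal branches whose minimum optimized length is zero.

    Branches are contracted one at a time in canonical edge order and the
    collapsible set recomputed, because two individually unsupported
    branches need not be jointly unsupported; each contraction therefore
    preserves the tree length exactly.
    """
    t = tree.copy()
    base = scorer.length(t)
    changed = True
    while changed:
        changed = False
        for u, v in t.edges():
            if t.is_leaf(u) or t.is_leaf(v):
                continue
            if min_branch_length(t, scorer, (u, v)) == 0:
                for x in list(t.adj[v]):
                    t.remove_edge(v, x)
                    if x != u:
                        t.add_edge(u, x)
                del t.adj[v]
                changed = True
                break
    assert scorer.length(t) == base
    return t


# ---------------------------------------------------------------------- #
# branch swapping


def branch_swap(
    start: Tree,
    matrix: CharacterMatrix,
    config: SearchConfig = SearchConfig(),
    scorer: Scorer | None = None,
) -> SearchResult:
    """Swap to local optimality, retaining all equal-best trees found.

    Breadth-first over the equal-length neighborhood with a visited set
    keyed on canonical bipartition sets; any strictly better tree restarts
    the sweep.
    """
    sc = scorer or Scorer(matrix)
    neighborhood = _NEIGHBORHOODS[config.swap]
    best = sc.length(start)
    pool: dict[frozenset, Tree] = {start.bipartitions(): start.copy()}
    queue: deque[Tree] = deque([start.copy()])
    truncated = False
    while queue:
        current = queue.popleft()
        restart = None
        for nb in neighborhood(current):
            length = sc.length(nb)
            if length < best:
                best = length
                restart = nb
                break
            if length == best:
                key = nb.bipartitions()
                if key not in pool:
                    if config.maxtrees is not None and len(pool) >= config.maxtrees:
                        truncated = True
                        continue
                    pool[key] = nb
                    queue.append(nb)
        if restart is not None:
            pool = {restart.bipartitions(): restart}
            queue = deque([restart])
    return _finalize(pool, best, matrix, config, sc, truncated=truncated)


def _finalize(
    pool: dict[frozenset, Tree],
    best: int,
    matrix: CharacterMatrix,
    config: SearchConfig,
    scorer: Scorer,
    truncated: bool = False,
    log: list[dict] | None = None,
    islands: int | None = None,
    n_topologies: int | None = None,
) -> SearchResult:
    trees = list(pool.values())
    if config.collapse == "min":
        seen: dict[frozenset, Tree] = {}
        for t in trees:
            c = collapse_unsupported(t, scorer)
            seen.setdefault(c.bipartitions(), c)
        trees = list(seen.values())
    trees.sort(key=lambda t: t.newick())
    return SearchResult(
        best_length=best,
        mpt_set=trees,
        replicate_log=log or [],
        island_count=islands,
        truncated=truncated,
        n_topologies=n_topologies,
    )


# ---------------------------------------------------------------------- #
# full heuristic and exhaustive searches


def heuristic_search(
    matrix: CharacterMatrix, config: SearchConfig = SearchConfig()
) -> SearchResult:
    """Random-addition + branch-swapping over ``config.replicates`` starts.

    Per-replicate seeds are spawned from the master seed with numpy's
    ``SeedSequence`` so replicates are independent and the whole run is
    reproducible from ``config.seed`` alone.
    """
    if matrix.n_taxa < 4:
        raise ValueError("heuristic search needs >= 4 taxa")
    scorer = Scorer(matrix)
    master = np.random.SeedSequence(config.seed)
    children = master.spawn(config.replicates)
    best: int | None = None
    pool: dict[frozenset, Tree] = {}
    rep_pools: list[set[frozenset]] = []
    log: list[dict] = []
    truncated = False
    for r, child in enumerate(children):
        rng = np.random.default_rng(child)
        start = random_addition(matrix, rng)
        start_len = scorer.length(start)
        res = branch_swap(start, matrix, _swap_only(config), scorer=scorer)
        log.append(
            {
                "replicate": r,
                "start_length": start_len,
                "final_length": res.best_length,
                "n_trees": len(res.mpt_set),
            }
        )
        truncated = truncated or res.truncated
        if best is None or res.best_length < best:
            best = res.best_length
            pool = {}
            rep_pools = []
        if res.best_length == best:
            keys = set()
            for t in res.mpt_set:
                key = t.bipartitions()
                keys.add(key)
                pool.setdefault(key, t)
            rep_pools.append(keys)
    islands = _count_islands(rep_pools)
    return _finalize(
        pool, best, matrix, config, scorer, truncated=truncated, log=log, islands=islands
    )


def _swap_only(config: SearchConfig) -> SearchConfig:
    """Replicate-internal config: collapse deferred to the global pool."""
    return SearchConfig(
        replicates=1,
        seed=config.seed,
        swap=config.swap,
        maxtrees=config.maxtrees,
        collapse="never",
        steepest=config.steepest,
        exhaustive_cap=config.exhaustive_cap,
    )


def _count_islands(rep_pools: list[set]) -> int:
    """Union-find over replicate tree pools sharing at least one tree."""
    groups: list[set] = []
    for keys in rep_pools:
        merged = set(keys)
        rest = []
        for g in groups:
            if g & merged:
                merged |= g
            else:
                rest.append(g)
        rest.append(merged)
        groups = rest
    return len(groups)


def n_unrooted_topologies(n: int) -> int:
    """(2n-5)!! distinct unrooted binary topologies on n labeled leaves."""
    out = 1
    for i in range(4, n + 1):
        out *= 2 * i - 5
    return out


def _all_topologies(taxa: Sequence[str]) -> Iterator[Tree]:
    taxa = sorted(taxa)
    base = Tree.star(taxa[:3])

    def grow(tree: Tree, idx: int) -> Iterator[Tree]:
        if idx == len(taxa):
            yield tree
            return
        for edge in tree.edges():
            yield from grow(_attach_leaf(tree, edge, taxa[idx]), idx + 1)

    yield from grow(base, 3)


def exhaustive_search(
    matrix: CharacterMatrix, config: SearchConfig = SearchConfig()
) -> SearchResult:
    """Exact optimum by enumerating every unrooted binary topology."""
    n = matrix.n_taxa
    if n < 3:
        raise ValueError("exhaustive search needs >= 3 taxa")
    if n > config.exhaustive_cap:
        raise ValueError(
            f"exhaustive search over {n} taxa would enumerate "
            f"{n_unrooted_topologies(n)} topologies (cap {config.exhaustive_cap})"
        )
    scorer = Scorer(matrix)
    best: int | None = None
    pool: dict[frozenset, Tree] = {}
    count = 0
    for tree in _all_topologies(matrix.taxa):
        count += 1
        length = scorer.length(tree)
        if best is None or length < best:
            best = length
            pool = {tree.bipartitions(): tree}
        elif length == best:
            pool.setdefault(tree.bipartitions(), tree)
    return _finalize(pool, best, matrix, config, scorer, n_topologies=count)


def strict_consensus(trees: Sequence[Tree]) -> Tree:
    """Strict consensus: exactly the bipartitions common to all inputs."""
    return strict_consensus_tree(list(trees))
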