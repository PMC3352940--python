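"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the package's scoring code paths: they
enumerate internal-node state assignments (and all tree topologies where
needed) directly, so they stay valid whatever the implementation does.
"""

from __future__ import annotations

from itertools import product

import numpy as np
import pytest

import morphpars as mp
from morphpars.search import _all_topologies


def assignment_min_steps(tree, column, ordered=False):
    """Minimum changes by enumerating every internal-node assignment.

    Leaves with ambiguous cells contribute the cheapest allowed state
    relative to their parent, which is exact because each leaf is
    constrained only through its single incident edge.
    """
    post = tree.postorder()
    internal = [n for n, kids in post if kids]
    k = max(max(c) for c in column.values() if c) + 1

    def dist(a, b):
        return abs(a - b) if ordered else int(a != b)

    edges = [(n, c) for n, kids in post for c in kids]
    best = None
    for combo in product(range(k), repeat=len(internal)):
        st = dict(zip(internal, combo))
        total = 0
        for a, b in edges:
            if b in st:
                total += dist(st[a], st[b])
            else:  # leaf: pick its cheapest allowed state
                cell = column[tree.labels[b]]
                total += min(dist(st[a], s) for s in cell)
        if best is None or total < best:
            best = total
    return best


def max_steps_over_trees(taxa, column, ordered=False):
    """Exhaustive maximization of the character length over all topologies."""
    worst = 0
    for tree in _all_topologies(sorted(taxa)):
        worst = max(worst, assignment_min_steps(tree, column, ordered))
    return worst


def min_steps_over_trees(taxa, column, ordered=False):
    best = None
    for tree in _all_topologies(sorted(taxa)):
        v = assignment_min_steps(tree, column, ordered)
        best = v if best is None else min(best, v)
    return best


def random_column(rng, taxa, k=3, p_ambiguous=0.15, p_missing=0.1):
    """Random state-set column over ``taxa`` (full sets play missing)."""
    col = {}
    full = frozenset(range(k))
    for t in taxa:
        r = rng.random()
        if r < p_missing:
            col[t] = full
        elif r < p_missing + p_ambiguous:
            size = int(rng.integers(2, k + 1))
            col[t] = frozenset(rng.choice(k, size=size, replace=False).tolist())
        else:
            col[t] = frozenset([int(rng.integers(k))])
    return col


def random_instance(seed, n_taxa=7, n_char=30, rate=0.2, missing=0.15):
    """Simulated degraded matrix plus its generating tree."""
    cfg = mp.SimulationConfig(
        n_taxa=n_taxa,
        n_char=n_char,
        change_rate=rate,
        missing_fraction=missing,
        fragmentary_taxa=1,
        seed=seed,
    )
    rng = np.random.default_rng(seed)
    tree = mp.simulate_tree(n_taxa, rng)
    matrix = mp.degrade_matrix(mp.evolve_characters(tree, cfg, rng), cfg, rng)
    return tree, matrix


@pytest.fixture(scope="session")
def tail_records():
    return mp.load_tail_table()


@pytest.fixture(scope="session")
def reference_tree():
    return mp.load_reference_tree()
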