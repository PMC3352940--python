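"""Heuristic and exhaustive tree search, consensus, collapse rule."""

import numpy as np
import pytest

import morphpars as mp
from morphpars.search import (
    Scorer,
    _NEIGHBORHOODS,
    collapse_unsupported,
    n_unrooted_topologies,
)
from morphpars.trees import Tree

from conftest import random_instance


class TestRandomAddition:
    def test_three_taxa_single_topology_any_seed(self):
        _, m = random_instance(0, n_taxa=6)
        m3 = mp.prune_taxa(m, m.taxa[3:])
        trees = {mp.random_addition(m3, s) for s in range(5)}
        assert len(trees) == 1

    def test_deterministic_given_seed(self):
        _, m = random_instance(1, n_taxa=8)
        assert mp.random_addition(m, 42) == mp.random_addition(m, 42)

    def test_clean_matrix_start_attains_lower_bound(self):
        tree = mp.simulate_tree(6, 7)
        m = mp.clean_matrix(tree)
        lower = sum(mp.char_bounds([r[j] for r in m.cells])[0] for j in range(m.n_char))
        start = mp.random_addition(m, 3)
        assert mp.tree_length(start, m) == lower

    def test_too_few_taxa(self):
        _, m = random_instance(0, n_taxa=6)
        with pytest.raises(ValueError):
            mp.random_addition(mp.prune_taxa(m, m.taxa[2:]), 0)


class TestExhaustive:
    def test_topology_counts(self):
        assert n_unrooted_topologies(4) == 3
        assert n_unrooted_topologies(6) == 105
        _, m4 = random_instance(2, n_taxa=4)
        assert mp.exhaustive_search(m4).n_topologies == 3
        _, m6 = random_instance(2, n_taxa=6)
        assert mp.exhaustive_search(m6).n_topologies == 105

    def test_cap_refusal_reports_required_count(self):
        _, m = random_instance(3, n_taxa=8)
        with pytest.raises(ValueError, match="10395"):
            mp.exhaustive_search(m, mp.SearchConfig(exhaustive_cap=7))


class TestBranchSwap:
    def test_finds_all_cooptimal_trees_from_optimal_start(self):
        _, m = random_instance(4, n_taxa=5, n_char=10, rate=0.3)
        ex = mp.exhaustive_search(m, mp.SearchConfig(collapse="never"))
        start = ex.mpt_set[0]
        res = mp.branch_swap(start, m, mp.SearchConfig(collapse="never"))
        assert res.best_length == ex.best_length
        assert {t.bipartitions() for t in res.mpt_set} == {
            t.bipartitions() for t in ex.mpt_set
        }

    def test_homoplasy_free_matrix_reaches_lower_bound(self):
        tree = mp.simulate_tree(7, 9)
        m = mp.clean_matrix(tree)
        start = mp.random_addition(m, 0)
        res = mp.branch_swap(start, m)
        assert res.best_length == sum(
            mp.char_bounds([r[j] for r in m.cells])[0] for j in range(m.n_char)
        )

    @pytest.mark.parametrize("seed", range(4))
    def test_neighborhood_inclusion_nni_spr_tbr(self, seed):
        tree, m = random_instance(40 + seed, n_taxa=7, n_char=15, rate=0.3)
        start = mp.random_addition(m, seed)
        sc = Scorer(m)
        keys = {}
        for swap in ("nni", "spr", "tbr"):
            keys[swap] = {t.bipartitions() for t in _NEIGHBORHOODS[swap](start)}
        assert keys["nni"] <= keys["spr"] <= keys["tbr"]
        lengths = {
            swap: mp.branch_swap(start, m, mp.SearchConfig(swap=swap)).best_length
            for swap in ("nni", "spr", "tbr")
        }
        assert lengths["tbr"] <= lengths["spr"] <= lengths["nni"]

    def test_maxtrees_truncation_flagged(self):
        # a constant matrix makes every topology co-optimal
        taxa = list("ABCDEF")
        m = mp.CharacterMatrix(
            taxa, [[frozenset([0])] * 4 for _ in taxa], states=[(0, 1)] * 4
        )
        start = mp.random_addition(m, 0)
        res = mp.branch_swap(start, m, mp.SearchConfig(maxtrees=2, collapse="never"))
        assert res.truncated and res.mpt_count <= 2


class TestHeuristicSearch:
    @pytest.mark.parametrize("seed", range(10))
    def test_equals_exhaustive_on_small_instances(self, seed):
        n = 5 + seed % 4
        _, m = random_instance(70 + seed, n_taxa=n, n_char=20, rate=0.25)
        ex = mp.exhaustive_search(m)
        he = mp.heuristic_search(m, mp.SearchConfig(replicates=5, seed=seed))
        assert he.best_length == ex.best_length
        assert {t.bipartitions() for t in he.mpt_set} == {
            t.bipartitions() for t in ex.mpt_set
        }

    def test_every_retained_tree_rescores_to_best(self):
        _, m = random_instance(8, n_taxa=8, n_char=20, rate=0.3)
        res = mp.heuristic_search(m, mp.SearchConfig(replicates=3, seed=1))
        for t in res.mpt_set:
            assert mp.tree_length(t, m) == res.best_length

    def test_reproducible_including_log(self):
        _, m = random_instance(9, n_taxa=7, n_char=15)
        cfg = mp.SearchConfig(replicates=4, seed=123)
        a = mp.heuristic_search(m, cfg)
        b = mp.heuristic_search(m, cfg)
        assert a.replicate_log == b.replicate_log
        assert [t.newick() for t in a.mpt_set] == [t.newick() for t in b.mpt_set]
        assert a.island_count == b.island_count

    def test_clean_matrix_recovers_generating_tree_uniquely(self):
        tree = mp.simulate_tree(8, 21)
        m = mp.clean_matrix(tree)
        res = mp.heuristic_search(m, mp.SearchConfig(replicates=3, seed=0))
        assert res.mpt_count == 1
        assert res.mpt_set[0] == tree
        assert mp.homoplasy_stats(m, res.mpt_set[0]).CI == 1.0


class TestCollapseRule:
    def test_collapse_preserves_length_and_reduces_counts(self):
        _, m = random_instance(12, n_taxa=7, n_char=10, rate=0.3, missing=0.4)
        never = mp.heuristic_search(
            m, mp.SearchConfig(replicates=3, seed=2, collapse="never")
        )
        collapsed = mp.heuristic_search(
            m, mp.SearchConfig(replicates=3, seed=2, collapse="min")
        )
        assert never.best_length == collapsed.best_length
        assert collapsed.mpt_count <= never.mpt_count
        for t in collapsed.mpt_set:
            assert mp.tree_length(t, m) == collapsed.best_length

    def test_unsupported_branch_is_collapsed(self):
        # character data resolve only one of the two internal edges
        taxa = list("ABCDE")
        cells = {
            "A": [0], "B": [0], "C": [1], "D": [1], "E": [1],
        }
        m = mp.CharacterMatrix(
            taxa, [[frozenset(v) for v in map(lambda x: [x], cells[t])] for t in taxa],
            states=[(0, 1)],
        )
        start = Tree.from_newick("((A,B),(C,D),E);")
        collapsed = collapse_unsupported(start, Scorer(m))
        assert collapsed.bipartitions() == {frozenset({"C", "D", "E"})}
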