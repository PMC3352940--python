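"""Parsimony scoring, step bounds, and homoplasy indices."""

import numpy as np
import pytest

import morphpars as mp
from morphpars.parsimony import _unit_cost, sankoff_length
from morphpars.search import _all_topologies
from morphpars.trees import Tree

from conftest import (
    assignment_min_steps,
    max_steps_over_trees,
    min_steps_over_trees,
    random_column,
    random_instance,
)


def _col(**kw):
    return {k: frozenset(v) for k, v in kw.items()}


class TestCharacterLength:
    def test_constant_character_is_free(self):
        t = Tree.from_newick("((A,B),(C,D));")
        assert mp.character_length(t, _col(A=[0], B=[0], C=[0], D=[0])) == 0

    def test_single_clean_split(self):
        t = Tree.from_newick("((A,B),(C,D));")
        assert mp.character_length(t, _col(A=[0], B=[0], C=[1], D=[1])) == 1

    def test_split_against_the_tree_costs_two(self):
        t = Tree.from_newick("((A,B),(C,D));")
        assert mp.character_length(t, _col(A=[0], B=[1], C=[0], D=[1])) == 2

    def test_missing_cells_constrain_nothing(self):
        t = Tree.from_newick("((A,B),(C,D));")
        col = _col(A=[0], B=[0, 1], C=[1], D=[0, 1])
        assert mp.character_length(t, col) == 1

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_assignment_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        tree = mp.simulate_tree(6, rng)
        col = random_column(rng, tree.taxa, k=4)
        assert mp.character_length(tree, col) == assignment_min_steps(tree, col)

    @pytest.mark.parametrize("seed", range(8))
    def test_ordered_matches_enumeration(self, seed):
        rng = np.random.default_rng(100 + seed)
        tree = mp.simulate_tree(5, rng)
        col = random_column(rng, tree.taxa, k=4)
        got = mp.character_length(tree, col, ordered_flag=True)
        assert got == assignment_min_steps(tree, col, ordered=True)

    def test_polytomies_scored_exactly(self):
        t = Tree.from_newick("((A,B,C),(D,E,F));")
        col = _col(A=[0], B=[1], C=[2], D=[0], E=[0], F=[0])
        assert mp.character_length(t, col) == assignment_min_steps(t, col)


@pytest.mark.parametrize("seed", range(40))
def test_fitch_equals_sankoff_with_uniform_costs(seed):
    rng = np.random.default_rng(1000 + seed)
    tree = mp.simulate_tree(int(rng.integers(4, 8)), rng)
    k = int(rng.integers(2, 5))
    col = random_column(rng, tree.taxa, k=k)
    assert mp.character_length(tree, col) == sankoff_length(tree, col, _unit_cost(k))


class TestTreeLength:
    def test_all_constant_matrix_scores_zero(self):
        tree = mp.simulate_tree(6, 0)
        taxa = sorted(tree.labels.values())
        m = mp.CharacterMatrix(
            taxa, [[frozenset([1])] * 5 for _ in taxa], states=[(0, 1)] * 5
        )
        assert mp.tree_length(tree, m) == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_is_sum_of_per_character_minima(self, seed):
        tree, m = random_instance(seed, n_taxa=7, n_char=12)
        per_char = [
            assignment_min_steps(tree, m.column(j)) for j in range(m.n_char)
        ]
        assert mp.tree_length(tree, m) == sum(per_char)
        assert mp.character_lengths(tree, m).tolist() == per_char

    def test_invariant_under_rerooting(self):
        tree, m = random_instance(11, n_taxa=7, n_char=20)
        base = mp.tree_length(tree, m)
        for og in list(tree.labels.values())[:4]:
            rooted = tree.root_with_outgroup(og)
            assert mp.tree_length(rooted, m) == base

    def test_label_mismatch_raises_coverage_error(self):
        tree = mp.simulate_tree(5, 0)
        _, m = random_instance(0, n_taxa=6)
        with pytest.raises(mp.CoverageError, match="mismatch"):
            mp.tree_length(tree, m)


class TestCharBounds:
    def test_k_minus_one_rule(self):
        col = [frozenset([s]) for s in (0, 1, 2, 0, 1)]
        m, _ = mp.char_bounds(col)
        assert m == 2

    def test_max_steps_formula_and_oracle(self):
        cells = [frozenset([s]) for s in (0, 0, 1, 1, 2)]
        _, g = mp.char_bounds(cells)
        assert g == 3
        col = {t: c for t, c in zip("ABCDE", cells)}
        assert g == max_steps_over_trees("ABCDE", col)

    def test_all_missing_column_is_uninformative(self):
        assert mp.char_bounds([mp.MISSING] * 5) == (0, 0)

    def test_ambiguity_resolved_to_minimize_m(self):
        # {0,2} can collapse onto either fixed state: only two states needed
        col = [frozenset([0]), frozenset([2]), frozenset([0, 2]), frozenset([1, 2])]
        m, _ = mp.char_bounds(col)
        assert m == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_bounds_bracket_observed_steps_everywhere(self, seed):
        rng = np.random.default_rng(3000 + seed)
        taxa = list("ABCDE")
        col = random_column(rng, taxa, k=3)
        cells = [col[t] for t in taxa]
        m, g = mp.char_bounds(cells)
        assert m == min_steps_over_trees(taxa, col)
        for tree in _all_topologies(taxa):
            s = mp.character_length(tree, col)
            assert m <= s <= g

    @pytest.mark.parametrize("seed", range(6))
    def test_unordered_g_matches_exhaustive_maximization(self, seed):
        rng = np.random.default_rng(4000 + seed)
        taxa = list("ABCDE")
        # singletons only: the printed maximization convention applies as-is
        col = {t: frozenset([int(rng.integers(3))]) for t in taxa}
        _, g = mp.char_bounds([col[t] for t in taxa])
        assert g == max_steps_over_trees(taxa, col)


class TestHomoplasyStats:
    def test_clean_matrix_has_no_homoplasy(self):
        tree = mp.simulate_tree(7, 2)
        m = mp.clean_matrix(tree)
        st = mp.homoplasy_stats(m, tree)
        assert (st.CI, st.HI, st.RI, st.RC) == (1.0, 0.0, 1.0, 1.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_algebraic_identities(self, seed):
        tree, m = random_instance(seed, n_taxa=8, n_char=30)
        st = mp.homoplasy_stats(m, tree)
        assert st.CI + st.HI == pytest.approx(1.0, abs=1e-12)
        assert st.RC == pytest.approx(st.CI * st.RI, abs=1e-12)
        assert 0 < st.CI <= 1
        assert np.all(st.m <= st.s) and np.all(st.s <= st.g)
        assert st.S == mp.tree_length(tree, m)

    def test_no_variation_result(self):
        taxa = ["a", "b", "c", "d"]
        m = mp.CharacterMatrix(
            taxa, [[frozenset([0])] * 3 for _ in taxa], states=[(0, 1)] * 3
        )
        tree = Tree.from_newick("((a,b),(c,d));")
        st = mp.homoplasy_stats(m, tree)
        assert st.no_variation and st.CI is None

    def test_uninformative_exclusion_flag(self):
        tree = Tree.from_newick("((a,b),(c,d));")
        cells = {
            "a": [0, 1, 0],
            "b": [0, 1, 1],
            "c": [1, 0, 0],
            "d": [1, 0, 1],
        }
        # char 3 has the pattern 0,1,0,1 (homoplastic); chars 1-2 are clean
        taxa = list(cells)
        m = mp.CharacterMatrix(
            taxa,
            [[frozenset([v]) for v in cells[t]] for t in taxa],
            states=[(0, 1)] * 3,
        )
        inc = mp.homoplasy_stats(m, tree, include_uninformative=True)
        exc = mp.homoplasy_stats(m, tree, include_uninformative=False)
        assert inc.S == exc.S == 4  # all three characters are informative here
        assert inc.CI == exc.CI


@pytest.mark.parametrize("seed", range(4))
def test_taxon_removal_never_raises_attainable_minimum(seed):
    rng = np.random.default_rng(500 + seed)
    tree = mp.simulate_tree(6, rng)
    taxa = sorted(tree.labels.values())
    col = random_column(rng, taxa, k=3)
    full = min_steps_over_trees(taxa, col)
    for drop in taxa[:3]:
        sub = {t: c for t, c in col.items() if t != drop}
        assert min_steps_over_trees(sorted(sub), sub) <= full
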