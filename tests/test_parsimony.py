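import math

import numpy as np
import pytest

from morphoclad import (
    INFEASIBLE,
    CharacterMatrix,
    CharacterTypeSpec,
    character_length,
    homoplasy_indices,
    max_steps,
    min_steps,
    tree_length,
)
from morphoclad.parsimony import round_half_up
from morphoclad.simulate import simulate_yule_tree

from conftest import brute_force_length, random_column, random_matrix


class TestCharacterLength:
    def test_constant_column_costs_nothing(self):
        t = simulate_yule_tree(6, seed=0)
        col = {leaf: 0 for leaf in t.leaves}
        for mode in ("unordered", "ordered", "irreversible"):
            assert character_length(t, col, mode) == 0

    def test_study_character_two_is_a_single_step(self, study, study_fit):
        matrix, _, outgroup = study
        for t in study_fit.mpts:
            assert character_length(t, matrix.column(2), "unordered") == 1
            assert character_length(t, matrix.column(2), "ordered") == 1

    @pytest.mark.parametrize("mode", ["unordered", "ordered"])
    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_assignment_minimum(self, mode, seed):
        t = simulate_yule_tree(6, seed=seed)
        col = random_column(seed, sorted(t.leaves), n_states=3, missing_p=0.15)
        expected = brute_force_length(t, col, mode)
        assert character_length(t, col, mode) == expected

    @pytest.mark.parametrize("mode", ["unordered", "ordered"])
    def test_rooting_invariance(self, mode):
        t = simulate_yule_tree(7, seed=5)
        col = random_column(11, sorted(t.leaves), n_states=3)
        lengths = {
            character_length(t, col, mode, root=leaf) for leaf in t.leaves
        }
        assert len(lengths) == 1

    def test_missing_tips_are_free(self):
        t = simulate_yule_tree(5, seed=1)
        leaves = sorted(t.leaves)
        col = {leaf: None for leaf in leaves}
        col[leaves[0]] = 0
        col[leaves[1]] = 1
        # the two observed tips differ: exactly one change, wherever they sit
        assert character_length(t, col, "unordered") == 1


class TestIrreversible:
    def test_counts_only_gains_from_the_root_state(self):
        t = simulate_yule_tree(4, seed=2)
        leaves = sorted(t.leaves)
        col = {leaf: 1 for leaf in leaves}
        col[leaves[0]] = 0  # root leaf is plesiomorphic
        s = character_length(t, col, "irreversible", root=leaves[0])
        assert s == brute_force_length(t, col, "irreversible")
        assert s >= 1

    def test_reversal_demand_is_infeasible(self):
        t = simulate_yule_tree(4, seed=3)
        leaves = sorted(t.leaves)
        col = {leaf: 0 for leaf in leaves}
        col[leaves[0]] = 1  # root starts above another tip's state
        assert character_length(t, col, "irreversible", root=leaves[0]) == INFEASIBLE
        assert math.isinf(INFEASIBLE)


class TestTreeLength:
    def test_study_length_is_59_on_both_mpts(self, study, study_fit):
        matrix, spec, outgroup = study
        for t in study_fit.mpts:
            total, per_char = tree_length(t, matrix, spec, root=outgroup)
            assert total == 59
            assert sum(per_char) == 59

    def test_additivity_base_case(self):
        t = simulate_yule_tree(5, seed=4)
        m = random_matrix(4, n_taxa=5, n_chars=1)
        m = CharacterMatrix(sorted(t.leaves), m.states)
        total, per_char = tree_length(t, m)
        assert total == per_char[0]

    def test_doubling_weights_doubles_length(self):
        t = simulate_yule_tree(6, seed=6)
        m = CharacterMatrix(sorted(t.leaves), random_matrix(7, 6, 8).states)
        base, _ = tree_length(t, m)
        doubled = CharacterTypeSpec(
            modes=("unordered",) * 8, weights=(2,) * 8
        )
        assert tree_length(t, m, doubled)[0] == 2 * base

    def test_inactive_characters_are_excluded(self):
        t = simulate_yule_tree(5, seed=8)
        m = CharacterMatrix(sorted(t.leaves), random_matrix(9, 5, 4).states)
        off = CharacterTypeSpec(
            modes=("unordered",) * 4, active=(True, False, True, False)
        )
        total, per_char = tree_length(t, m, off)
        assert per_char[1] == per_char[3] == 0
        assert total == per_char[0] + per_char[2]


class TestStepBounds:
    def test_binary_column_bounds(self):
        col = dict(zip("abcdefg", [0, 0, 0, 1, 1, 1, 1]))
        assert min_steps(col) == 1
        assert max_steps(col) == 3

    def test_study_totals(self, study):
        matrix, spec, _ = study
        mins = [min_steps(matrix.column(j), "ordered") for j in range(41)]
        maxs = [max_steps(matrix.column(j), "ordered") for j in range(41)]
        assert sum(mins) == 45
        assert sum(maxs) == 83

    def test_bounds_bracket_observed_length(self):
        # g from the star tree dominates every binary-tree length
        t = simulate_yule_tree(6, seed=9)
        for seed in range(8):
            col = random_column(seed + 100, sorted(t.leaves), n_states=3)
            s = character_length(t, col, "unordered")
            assert min_steps(col) <= s <= max_steps(col)

    def test_all_missing_column_rejected(self):
        with pytest.raises(ValueError):
            min_steps({"a": None, "b": None})


class TestHomoplasyIndices:
    def test_study_indices_round_to_printed_values(self, study, study_fit):
        matrix, spec, outgroup = study
        for t in study_fit.mpts:
            ci, ri, table = homoplasy_indices(t, matrix, spec, root=outgroup)
            assert round_half_up(ci) == 0.76
            assert round_half_up(ri) == 0.63
            assert ci == pytest.approx(45 / 59)
            assert ri == pytest.approx((83 - 59) / (83 - 45))
            assert len(table) == 41

    def test_homoplasy_free_matrix_scores_one(self):
        # each character changes exactly once on the generating topology
        t = simulate_yule_tree(6, seed=10)
        leaves = sorted(t.leaves)
        rv = t.rooted_at(leaves[0])
        internal = [v for v in rv.order if rv.children[v] and v != rv.root]
        cols = []
        for v in internal:
            clade = rv.clade_leaves(v)
            cols.append([1 if l in clade else 0 for l in leaves])
        m = CharacterMatrix(leaves, np.array(cols).T)
        ci, ri, _ = homoplasy_indices(t, m)
        assert ci == 1.0 and ri == 1.0

    def test_ensemble_identity_and_ranges(self):
        for seed in range(6):
            t = simulate_yule_tree(6, seed=seed)
            m = CharacterMatrix(
                sorted(t.leaves), random_matrix(seed + 50, 6, 12, 3).states
            )
            ci, ri, table = homoplasy_indices(t, m)
            assert 0 < ci <= 1
            assert 0 <= ri <= 1
            assert ci * table["steps"].sum() == pytest.approx(
                table["min_steps"].sum()
            )
            if (table["max_steps"] > table["min_steps"]).any():
                perfect = (table["steps"] == table["min_steps"]).all()
                assert (ri == 1.0) == bool(perfect)

    def test_rounding_is_half_up(self):
        assert round_half_up(0.765) == 0.77
        assert round_half_up(0.7627) == 0.76
        assert round_half_up(0.625) == 0.63
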