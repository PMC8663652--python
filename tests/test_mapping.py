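import itertools

import pytest

from morphoclad import (
    CharacterMatrix,
    mpr_state_sets,
    shared_changes_across_mpts,
    unambiguous_changes,
)
from morphoclad.simulate import simulate_yule_tree

from conftest import (
    BICORNIS,
    CLARAE,
    FOUR_SPECIES,
    HUYSI,
    INGROUP,
    KOREAN_TRIO,
    TYPICUS,
    brute_force_mpr,
    random_column,
)


def by_clade(records, clade, classification=None):
    out = [r for r in records if r.clade == frozenset(clade)]
    if classification is not None:
        out = [r for r in out if r.classification == classification]
    return out


class TestStudyChangeLists:
    def test_ingroup_stem_synapomorphies(self, study, study_fit):
        matrix, spec, outgroup = study
        for t in study_fit.mpts:
            recs = by_clade(
                unambiguous_changes(t, matrix, spec, outgroup),
                INGROUP,
                "synapomorphy",
            )
            assert sorted(r.character for r in recs) == [2, 3, 4, 17, 32]
            assert all((r.from_state, r.to_state) == (0, 1) for r in recs)

    def test_korean_trio_synapomorphies(self, study, study_fit):
        matrix, spec, outgroup = study
        for t in study_fit.mpts:
            recs = by_clade(
                unambiguous_changes(t, matrix, spec, outgroup),
                KOREAN_TRIO,
                "synapomorphy",
            )
            got = {r.character: r.to_state for r in recs}
            assert got == {25: 0, 30: 0, 33: 0, 38: 0, 40: 1}

    def test_four_species_clade_shares_four_synapomorphies(self, study, study_fit):
        matrix, spec, outgroup = study
        recs = by_clade(
            shared_changes_across_mpts(study_fit.mpts, matrix, spec, outgroup),
            FOUR_SPECIES,
            "synapomorphy",
        )
        got = {r.character: (r.from_state, r.to_state) for r in recs}
        assert got == {0: (1, 0), 6: (0, 1), 12: (0, 1), 14: (0, 1)}
        assert all(r.scope == "all_mpts" for r in recs)

    def test_terminal_autapomorphies(self, study, study_fit):
        matrix, spec, outgroup = study
        shared = shared_changes_across_mpts(study_fit.mpts, matrix, spec, outgroup)
        assert sorted(
            r.character for r in by_clade(shared, {HUYSI}, "autapomorphy")
        ) == [10, 16, 36]
        assert sorted(
            r.character for r in by_clade(shared, {CLARAE}, "autapomorphy")
        ) == [29, 31]
        assert sorted(
            r.character for r in by_clade(shared, {BICORNIS}, "autapomorphy")
        ) == [9, 34]

    def test_outgroup_unique_state_maps_to_the_outgroup_branch(self, study, study_fit):
        # character 37 is derived only in the outgroup; it must not surface
        # as an ingroup synapomorphy
        matrix, spec, outgroup = study
        for t in study_fit.mpts:
            recs = unambiguous_changes(t, matrix, spec, outgroup)
            on_outgroup = by_clade(recs, {TYPICUS})
            assert 37 in {r.character for r in on_outgroup}
            assert 37 not in {r.character for r in by_clade(recs, INGROUP)}


class TestMPRStateSets:
    def test_constant_column_fixes_every_node(self):
        t = simulate_yule_tree(5, seed=0)
        sets = mpr_state_sets(t, {leaf: 2 for leaf in t.leaves})
        assert all(s == {2} for s in sets.values())

    def test_study_character_two_polarity(self, study, study_fit):
        matrix, _, outgroup = study
        for t in study_fit.mpts:
            sets = mpr_state_sets(t, matrix.column(2), "unordered", root=outgroup)
            assert sets[frozenset(INGROUP)] == {1}
            assert sets[frozenset(t.leaves)] == {0}

    @pytest.mark.parametrize("mode", ["unordered", "ordered"])
    @pytest.mark.parametrize("seed", range(8))
    def test_sets_match_brute_force_union_of_optima(self, mode, seed):
        t = simulate_yule_tree(6, seed=seed)
        leaves = sorted(t.leaves)
        col = random_column(seed + 30, leaves, n_states=3, missing_p=0.1)
        _, node_sets, _ = brute_force_mpr(t, col, mode, outgroup=leaves[0])
        sets = mpr_state_sets(t, col, mode, root=leaves[0])
        for clade, expected in node_sets.items():
            if len(clade) == 1:
                continue  # oracle reports observed/free tip states directly
            assert sets[clade] == expected, (clade, mode, seed)


class TestUnambiguousChanges:
    @pytest.mark.parametrize("seed", range(8))
    def test_every_reported_change_is_in_all_optimal_reconstructions(self, seed):
        t = simulate_yule_tree(6, seed=seed)
        leaves = sorted(t.leaves)
        col = random_column(seed + 60, leaves, n_states=3)
        m = CharacterMatrix(leaves, [[col[l]] for l in leaves])
        recs = unambiguous_changes(t, m, outgroup=leaves[0])
        _, _, pair_sets = brute_force_mpr(t, col, "unordered", outgroup=leaves[0])
        for r in recs:
            assert pair_sets[r.clade] == {(r.from_state, r.to_state)}
        # and conversely: any branch whose optimal pairs are a single change
        # must be reported
        expected = {
            clade
            for clade, pairs in pair_sets.items()
            if len(pairs) == 1 and next(iter(pairs))[0] != next(iter(pairs))[1]
        }
        assert {r.clade for r in recs} == expected

    def test_constant_matrix_yields_no_changes(self):
        t = simulate_yule_tree(5, seed=2)
        leaves = sorted(t.leaves)
        m = CharacterMatrix(leaves, [[0, 1]] * 5)
        assert unambiguous_changes(t, m, outgroup=leaves[0]) == []

    def test_from_and_to_always_differ(self, study, study_fit):
        matrix, spec, outgroup = study
        for t in study_fit.mpts:
            for r in unambiguous_changes(t, matrix, spec, outgroup):
                assert r.from_state != r.to_state

    def test_perfect_characters_are_never_homoplastic(self, study, study_fit):
        matrix, spec, outgroup = study
        from morphoclad import character_length, min_steps

        for t in study_fit.mpts:
            for r in unambiguous_changes(t, matrix, spec, outgroup):
                col = matrix.column(r.character)
                perfect = min_steps(col, "ordered") == character_length(
                    t, col, "ordered"
                )
                assert (r.classification != "homoplasy") == perfect


class TestSharedChanges:
    def test_singleton_set_equals_per_tree_list(self, study, study_fit):
        matrix, spec, outgroup = study
        t = study_fit.mpts[0]
        solo = shared_changes_across_mpts([t], matrix, spec, outgroup)
        per_tree = unambiguous_changes(t, matrix, spec, outgroup)
        assert [
            (r.clade, r.character, r.from_state, r.to_state) for r in solo
        ] == [(r.clade, r.character, r.from_state, r.to_state) for r in per_tree]

    def test_order_invariance(self, study, study_fit):
        matrix, spec, outgroup = study
        for perm in itertools.permutations(study_fit.mpts):
            recs = shared_changes_across_mpts(list(perm), matrix, spec, outgroup)
            assert recs == shared_changes_across_mpts(
                study_fit.mpts, matrix, spec, outgroup
            )
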