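"""Sister-group extraction: maximal derived clades, richness, outcomes."""

import random
import warnings

import pytest
from hypothesis import given, strategies as st

import euryalida as eu
from euryalida.errors import AllDerivedWarning, MissingTaxonError, PolytomyWarning

from .oracles import brute_force_maximal_derived, random_states, random_tree


def S(**kw):
    return {k: frozenset({v}) for k, v in kw.items()}


class TestFindDerivedClades:
    def test_single_derived_tip(self):
        tree = eu.parse_newick("(A,B);")
        clades = eu.find_derived_clades(tree, S(A=1, B=0))
        assert [c.tip_labels() for c in clades] == [["A"]]

    def test_all_derived_warns_and_returns_empty(self):
        tree = eu.parse_newick("((A,B),C);")
        with pytest.warns(AllDerivedWarning):
            clades = eu.find_derived_clades(tree, S(A=1, B=1, C=1))
        assert clades == []

    def test_unknown_state_rejected(self):
        tree = eu.parse_newick("(A,B);")
        with pytest.raises(ValueError, match="unknown state"):
            eu.find_derived_clades(tree, {"A": frozenset({0, 1}),
                                          "B": frozenset({0})})

    def test_fixture_branched_six_clades(self, fixture_tree, branched_states):
        clades = eu.find_derived_clades(fixture_tree, branched_states)
        tip_sets = [frozenset(c.tip_labels()) for c in clades]
        assert frozenset({"Euryale", "Trichaster"}) in tip_sets
        assert frozenset({"Sthenocephalus"}) in tip_sets
        assert frozenset({"Astroclon"}) in tip_sets
        assert frozenset({"Astrodendrum", "Gorgonocephalus"}) in tip_sets
        assert frozenset({"Astrophyton"}) in tip_sets
        big = frozenset({"Astracme", "Astroboa", "Astrochalcis", "Astrocladus",
                         "Astroglymma", "Astrosierra", "Conocladus",
                         "Ophiocrene"})
        assert big in tip_sets
        assert len(clades) == 6

    @given(st.integers(0, 10 ** 6), st.integers(2, 12))
    def test_matches_brute_force_scan(self, seed, n):
        rng = random.Random(seed)
        tree = random_tree(rng, n, polytomy_prob=0.2)
        states = random_states(rng, tree)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            got = eu.find_derived_clades(tree, states)
        expected = brute_force_maximal_derived(tree, states)
        if all(states[t] == frozenset({1}) for t in tree.tip_labels()):
            assert got == []
        else:
            assert [id(c) for c in got] == [id(c) for c in expected]

    @given(st.integers(0, 10 ** 6), st.integers(3, 12))
    def test_every_derived_tip_in_exactly_one_clade(self, seed, n):
        rng = random.Random(seed)
        tree = random_tree(rng, n)
        states = random_states(rng, tree)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clades = eu.find_derived_clades(tree, states)
        derived_tips = {t for t in tree.tip_labels()
                        if states[t] == frozenset({1})}
        covered = [t for c in clades for t in c.tip_labels()]
        if derived_tips != set(tree.tip_labels()):
            assert sorted(covered) == sorted(derived_tips)


class TestSisterOf:
    def test_fixture_astrodendrum_clade_sister(self, fixture_tree,
                                               branched_states, fixture_chars):
        node = fixture_tree.mrca(["Astrodendrum", "Gorgonocephalus"])
        tips, poly = eu.sister_of(fixture_tree, node)
        assert tips == frozenset({"Astrochele", "Astrochlamys"})
        assert not poly

    def test_fixture_astracme_clade_sister_is_mixed_14(self, fixture_tree,
                                                       fixture_chars):
        node = fixture_tree.mrca(["Astracme", "Ophiocrene"])
        tips, _ = eu.sister_of(fixture_tree, node)
        assert tips == frozenset({"Asteroporpa", "Astrogomphus", "Astrophyton"})
        assert eu.clade_richness(tips, fixture_chars) == 14

    def test_root_has_no_sister(self, fixture_tree):
        with pytest.raises(ValueError):
            eu.sister_of(fixture_tree, fixture_tree.root)

    def test_polytomy_sister_is_cosibling_union(self):
        tree = eu.parse_newick("(A,B,C);")
        node = tree.tip("A")
        with pytest.warns(PolytomyWarning):
            tips, poly = eu.sister_of(tree, node)
        assert tips == frozenset({"B", "C"}) and poly


class TestCladeRichness:
    def test_fixture_examples(self, fixture_chars):
        assert eu.clade_richness(
            {"Astrodendrum", "Gorgonocephalus"}, fixture_chars) == 16
        big = {"Astracme", "Astroboa", "Astrochalcis", "Astrocladus",
               "Astroglymma", "Astrosierra", "Conocladus", "Ophiocrene"}
        assert eu.clade_richness(big, fixture_chars) == 30
        assert eu.clade_richness({"Astroniwa"}, fixture_chars) == 1

    def test_unknown_taxon_raises(self, fixture_chars):
        with pytest.raises(MissingTaxonError):
            eu.clade_richness({"Nosuchgenus"}, fixture_chars)


class TestBuildSisterPairs:
    def test_fixture_branched_table(self, fixture_tree, branched_states,
                                    fixture_chars):
        pairs = eu.build_sister_pairs(fixture_tree, branched_states,
                                      fixture_chars)
        rows = {(p.focal_richness, p.sister_richness, p.outcome) for p in pairs}
        assert rows == {(2, 5, "minus"), (5, 5, "zero"), (2, 4, "minus"),
                        (16, 6, "plus"), (1, 13, "minus"), (30, 14, "plus")}
        mixed = [p for p in pairs if p.sister_is_mixed]
        assert len(mixed) == 1 and mixed[0].focal_richness == 30

    def test_gorgonocephalid_scope_has_four_pairs(self, fixture_tree,
                                                  branched_states,
                                                  fixture_chars, family_scopes):
        pairs = eu.build_sister_pairs(fixture_tree, branched_states,
                                      fixture_chars,
                                      scope=family_scopes["Gorgonocephalidae"])
        assert len(pairs) == 4

    def test_pedicellariae_family_comparison(self, fixture_tree,
                                             pedicellariae_states,
                                             fixture_chars):
        pairs = eu.build_sister_pairs(fixture_tree, pedicellariae_states,
                                      fixture_chars,
                                      include_unplaced_families=True)
        assert len(pairs) == 1
        p = pairs[0]
        assert (p.focal_richness, p.sister_richness, p.outcome) == \
            (100, 84, "plus")
        # the strict clade sum excludes the 12 unplaced gorgonocephalids
        strict = eu.build_sister_pairs(fixture_tree, pedicellariae_states,
                                       fixture_chars)[0]
        assert strict.focal_richness == 88

    @given(st.integers(0, 10 ** 6), st.integers(3, 10))
    def test_pair_count_bounds_parsimony_cost(self, seed, n):
        """Assigning one gain at each maximal derived clade's stem is a
        feasible reconstruction, so the parsimony minimum (and with it the
        smallest MPR gain count) never exceeds the number of pairs."""
        rng = random.Random(seed)
        tree = random_tree(rng, n)
        states = random_states(rng, tree)
        matrix = eu.CharacterMatrix([
            eu.TaxonRecord(taxon_name=t, rank="genus", family="F",
                           species_count=rng.randint(1, 9),
                           branched=(states[t] == frozenset({1})),
                           pattern="basal" if states[t] == frozenset({1})
                           else "none",
                           pedicellariae=False)
            for t in tree.tip_labels()])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pairs = eu.build_sister_pairs(tree, states, matrix)
        s = eu.mpr_gain_range(tree, states, root_state=0)
        assert s.gains_min <= s.min_changes
        if pairs:
            assert s.min_changes <= len(pairs)
        else:
            # no derived tips at all, or the whole tree derived (stem gain)
            assert s.min_changes <= 1


class TestDistalSubcomparisons:
    def test_fixture_table(self, fixture_tree, fixture_chars):
        result = eu.distal_subcomparisons(
            fixture_tree, eu.pattern_map(fixture_chars), fixture_chars)
        rows = {(p.focal_label, p.focal_richness, p.sister_richness, p.outcome)
                for p in result.pairs}
        assert rows == {
            ("Sthenocephalus", 2, 5, "minus"),
            ("Trichaster", 3, 2, "plus"),
            ("Astroclon", 2, 4, "minus"),
            ("Astrosierra", 3, 1, "plus"),
        }
        assert {u.taxon_name for u in result.unplaced} == \
            {"Astrocnida_isidis", "Schizostella_bifurcata"}

    def test_no_distal_tips_gives_empty(self):
        tree = eu.parse_newick("(A,B);")
        matrix = eu.CharacterMatrix([
            eu.TaxonRecord(taxon_name=t, rank="genus", family="F",
                           species_count=1, branched=False, pattern="none",
                           pedicellariae=False)
            for t in "AB"])
        result = eu.distal_subcomparisons(tree, eu.pattern_map(matrix), matrix)
        assert result.pairs == () and result.unplaced == ()

    def test_tsv_mirror_contains_unknown_rows(self, fixture_tree,
                                              fixture_chars):
        result = eu.distal_subcomparisons(
            fixture_tree, eu.pattern_map(fixture_chars), fixture_chars)
        text = eu.pairs_to_tsv(result.pairs, result.unplaced)
        assert "Unknown" in text
        assert text.count("\n") == 1 + 4 + 2
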