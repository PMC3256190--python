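"""Diagnostic characteristic attributes: discovery, classification,
tree-derived groupings, planted-CA round trip."""

import pytest

from seabarcode.caos import (GroupingError, classify_by_cas, find_pure_cas,
                             groups_from_metadata, groups_from_tree)
from seabarcode.seqio import AlignmentShapeError, parse_newick
from seabarcode.simdata import (CAPlant, LocusSpec, SimulationConfig,
                                simulate_dataset)

from conftest import make_alignment


def hand_enumerated_alignment():
    """8 rows x 12 columns, three groups; the expected CA table below was
    enumerated column by column by hand."""
    rows = {
        #       123456789012
        "x1": "GAAATCGGAATT",
        "x2": "GAAATCGGAATT",
        "x3": "GAAATCGGACTT",
        "y1": "AAAGTCGGAATT",
        "y2": "AAAGTCGGAATT",
        "y3": "AAAGTCCGAATT",
        "z1": "AACGTAGGAATT",
        "z2": "AACGTAGGAATT",
    }
    groups = {"X": {"x1", "x2", "x3"}, "Y": {"y1", "y2", "y3"},
              "Z": {"z1", "z2"}}
    # column 1: X fixed G, outside all A -> CA (X,1,G)
    # column 3: Z fixed C, outside all A -> CA (Z,3,C)
    # column 4: X fixed A but z/y have G -> y has G, x has A, y1..y3 G, z G:
    #   X fixed 'A', outside = {G,G,G,G,G} -> CA (X,4,A)
    # column 6: Z fixed A, outside all C -> CA (Z,6,A)
    # others: shared or not fixed
    expected = {("X", 1, "G"), ("X", 4, "A"), ("Z", 3, "C"), ("Z", 6, "A")}
    return make_alignment(rows), groups, expected


class TestFindPureCAs:
    def test_fixed_state_single_column(self):
        aln = make_alignment({"x1": "AAAAG", "x2": "AAAAG",
                              "o1": "AAAAA", "o2": "AAAAA"})
        table = find_pure_cas(aln, {"X": {"x1", "x2"}, "O": {"o1", "o2"}})
        assert {(ca.clade_label, ca.position, ca.state)
                for ca in table.attributes} == {("X", 5, "G"), ("O", 5, "A")}

    def test_unfixed_state_yields_no_ca(self):
        aln = make_alignment({"x1": "AAAAG", "x2": "AAAAA",
                              "o1": "AAAAC", "o2": "AAAAC"})
        table = find_pure_cas(aln, {"X": {"x1", "x2"}})
        assert table.attributes == []

    def test_hand_enumerated_table(self):
        aln, groups, expected = hand_enumerated_alignment()
        table = find_pure_cas(aln, groups)
        got = {(ca.clade_label, ca.position, ca.state)
               for ca in table.attributes}
        assert got == expected
        assert table.alignment_length == 12

    def test_identical_groups_have_no_cas(self):
        aln = make_alignment({"a1": "ACGT", "a2": "ACGT",
                              "b1": "ACGT", "b2": "ACGT"})
        table = find_pure_cas(aln, {"A": {"a1", "a2"}, "B": {"b1", "b2"}})
        assert table.attributes == []

    def test_outside_missing_is_permissive(self):
        aln = make_alignment({"x1": "G", "x2": "G", "o1": "?", "o2": "A"})
        table = find_pure_cas(aln, {"X": {"x1", "x2"}})
        assert len(table.attributes) == 1
        strict = find_pure_cas(aln, {"X": {"x1", "x2"}}, strict_outside=True)
        assert strict.attributes == []

    def test_empty_group_rejected(self):
        aln = make_alignment({"a": "ACGT"})
        with pytest.raises(GroupingError):
            find_pure_cas(aln, {"X": set()})

    def test_row_order_invariant(self):
        aln, groups, _ = hand_enumerated_alignment()
        rows = {r.id: r.seq for r in aln.records}
        rev = make_alignment(dict(reversed(rows.items())))
        t1 = find_pure_cas(aln, groups)
        t2 = find_pure_cas(rev, groups)
        assert set(map(str, t1.attributes)) == set(map(str, t2.attributes))

    def test_gap_as_state_flag(self):
        aln = make_alignment({"x1": "A-G", "x2": "A-G",
                              "o1": "AAG", "o2": "AAG"})
        default = find_pure_cas(aln, {"X": {"x1", "x2"}})
        assert default.attributes == []
        with_gap = find_pure_cas(aln, {"X": {"x1", "x2"}}, gap_as_state=True)
        assert {(ca.position, ca.state) for ca in with_gap.attributes} \
            == {(2, "-")}


class TestClassify:
    def test_member_round_trip(self):
        aln, groups, _ = hand_enumerated_alignment()
        table = find_pure_cas(aln, groups)
        scores, assigned = classify_by_cas("GAAATCGGAATT", table)
        assert scores["X"] == 1.0
        assert assigned == "X"

    def test_half_mutated_unassigned(self):
        aln = make_alignment({"x1": "GGAA", "x2": "GGAA",
                              "o1": "AACC", "o2": "AACC"})
        table = find_pure_cas(aln, {"X": {"x1", "x2"}})
        assert len(table.by_clade()["X"]) == 4
        # mutate half of X's diagnostic columns
        scores, assigned = classify_by_cas("GGCC", table)
        assert scores["X"] == 0.5
        assert assigned is None

    def test_all_missing_query_unassigned(self):
        aln, groups, _ = hand_enumerated_alignment()
        table = find_pure_cas(aln, groups)
        scores, assigned = classify_by_cas("?" * 12, table)
        assert assigned is None

    def test_length_mismatch(self):
        aln, groups, _ = hand_enumerated_alignment()
        table = find_pure_cas(aln, groups)
        with pytest.raises(AlignmentShapeError):
            classify_by_cas("ACGT", table)


class TestGroupsFromTree:
    def test_balanced_four_leaf(self):
        tree = parse_newick("((a1,a2),(b1,b2));")
        aln = make_alignment({i: "ACGT" for i in ["a1", "a2", "b1", "b2"]})
        groups = groups_from_tree(tree, aln, min_size=2)
        assert sorted(map(sorted, groups.values())) \
            == [["a1", "a2"], ["b1", "b2"]]

    def test_min_size_one_adds_leaf_groups(self):
        tree = parse_newick("((a1,a2),(b1,b2));")
        aln = make_alignment({i: "ACGT" for i in ["a1", "a2", "b1", "b2"]})
        groups = groups_from_tree(tree, aln, min_size=1)
        member_sets = sorted(map(sorted, groups.values()))
        assert ["a1"] in member_sets and ["b2"] in member_sets

    def test_caterpillar_nested_chain(self):
        tree = parse_newick("(a,(b,(c,(d,e))));")
        aln = make_alignment({i: "A" for i in "abcde"})
        groups = groups_from_tree(tree, aln, min_size=2)
        expected = [{"d", "e"}, {"c", "d", "e"}, {"b", "c", "d", "e"}]
        assert sorted(map(sorted, groups.values())) \
            == sorted(map(sorted, expected))

    def test_leaf_mismatch(self):
        tree = parse_newick("((a1,a2),(b1,zz));")
        aln = make_alignment({i: "ACGT" for i in ["a1", "a2", "b1", "b2"]})
        with pytest.raises(GroupingError):
            groups_from_tree(tree, aln)


def test_planted_ca_round_trip():
    """Columns planted as diagnostic for one genus are all recovered as
    pure CAs and held-out members classify back at score 1.0."""
    cfg = SimulationConfig(
        n_families=2, genera_per_family=(2, 1),
        species_per_genus=(1, 1, 1), individuals_per_species=3,
        loci=(LocusSpec("L", length=300, rate_multiplier=2.0,
                        ca_plant=CAPlant(clade="GenusB", n_columns=5)),),
        seed=21)
    truth = simulate_dataset(cfg)
    aln = truth.alignments["L"]
    groups = groups_from_metadata(aln, truth.metadata, rank="genus")
    table = find_pure_cas(aln, groups)
    found_b = {(ca.position, ca.state) for ca in table.by_clade()["GenusB"]}
    planted = {(p["column"], p["state"]) for p in truth.planted_cas}
    assert planted <= found_b
    # hold out one member and classify it back
    member = sorted(groups["GenusB"])[0]
    held_out = aln.get(member).seq
    rest = make_alignment({r.id: r.seq for r in aln.records
                           if r.id != member})
    groups2 = {g: m - {member} for g, m in groups.items() if m - {member}}
    table2 = find_pure_cas(rest, groups2)
    scores, assigned = classify_by_cas(held_out, table2)
    assert assigned == "GenusB"
    assert scores["GenusB"] == 1.0
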