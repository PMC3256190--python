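"""Tree inference: NJ on additive matrices, Fitch vs exhaustive search,
pruning likelihood vs closed forms, bootstrap, consensus, RF."""

import itertools
import math

import numpy as np
import pytest

from seabarcode.distances import DistanceMatrix, distance_matrix
from seabarcode.seqio import parse_newick
from seabarcode.trees import (SubstitutionModel, TreeInputError, bipartitions,
                              bootstrap_support, compare_topologies,
                              fitch_score, log_likelihood, majority_consensus,
                              ml_search, mp_search, nj_tree)

from conftest import make_alignment


def random_additive_matrix(rng, n):
    """Distances realised on a random binary tree with random positive
    branch lengths (so the matrix is exactly additive)."""
    import dendropy
    labels = [f"t{i}" for i in range(n)]
    # random topology by sequential attachment
    newick = f"({labels[0]},{labels[1]},{labels[2]});"
    tree = parse_newick(newick)
    for lb in labels[3:]:
        edges = [e for e in tree.preorder_edge_iter() if e.tail_node is not None]
        edge = edges[rng.integers(0, len(edges))]
        parent, child = edge.tail_node, edge.head_node
        mid = dendropy.Node()
        parent.remove_child(child)
        parent.add_child(mid)
        mid.add_child(child)
        leaf = dendropy.Node()
        leaf.taxon = tree.taxon_namespace.new_taxon(lb)
        mid.add_child(leaf)
    for e in tree.preorder_edge_iter():
        if e.tail_node is not None:
            e.length = float(rng.uniform(0.1, 1.0))
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    d = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i != j:
                d[i, j] = pdm.distance(taxa[a], taxa[b])
    return DistanceMatrix(labels=labels, d=d), tree


class TestNJ:
    def test_four_taxon_additive_recovery(self):
        # tree ((A:1,B:2):1,(C:3,D:4)): path lengths written down by hand
        labels = ["A", "B", "C", "D"]
        d = np.array([
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 7, 0],
        ], dtype=float)
        tree = nj_tree(DistanceMatrix(labels, d))
        assert bipartitions(tree) == {frozenset({"C", "D"})} \
            or bipartitions(tree) == {frozenset({"A", "B"})}
        # branch lengths exact: leaf A at 1, B at 2 from their common node
        lengths = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
        assert lengths["A"] == pytest.approx(1.0)
        assert lengths["B"] == pytest.approx(2.0)
        assert lengths["C"] == pytest.approx(3.0)
        assert lengths["D"] == pytest.approx(4.0)

    def test_three_taxa_closed_form(self):
        d = np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], dtype=float)
        tree = nj_tree(DistanceMatrix(["a", "b", "c"], d))
        lengths = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
        # three-point formulas: a=(2+3-4)/2=0.5, b=(2+4-3)/2=1.5, c=(3+4-2)/2=2.5
        assert lengths == {"a": pytest.approx(0.5), "b": pytest.approx(1.5),
                           "c": pytest.approx(2.5)}

    def test_tie_rule_deterministic(self):
        d = np.full((4, 4), 0.5)
        np.fill_diagonal(d, 0.0)
        dm = DistanceMatrix(["a", "b", "c", "d"], d)
        t1, t2 = nj_tree(dm), nj_tree(dm)
        assert bipartitions(t1) == bipartitions(t2)

    def test_additive_recovery_property(self):
        rng = np.random.default_rng(42)
        for n in (4, 6, 8, 10):
            for _ in range(3):
                dm, true_tree = random_additive_matrix(rng, n)
                est = nj_tree(dm)
                assert compare_topologies(est, true_tree)["rf"] == 0, n

    def test_agrees_with_skbio_on_random_matrices(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(3)
        dm, _ = random_additive_matrix(rng, 7)
        ours = nj_tree(dm)
        sk_dm = skbio.DistanceMatrix(dm.d, ids=dm.labels)
        sk_tree = skbio.tree.nj(sk_dm)
        theirs = parse_newick(str(sk_tree))
        assert compare_topologies(ours, theirs)["rf"] == 0

    def test_undefined_entry_rejected(self):
        d = np.zeros((3, 3))
        d[0, 1] = d[1, 0] = np.nan
        with pytest.raises(TreeInputError):
            nj_tree(DistanceMatrix(["a", "b", "c"], d))


def all_topologies(labels):
    """All unrooted binary topologies via recursive edge insertion."""
    if len(labels) == 3:
        yield f"({labels[0]},{labels[1]},{labels[2]});"
        return
    for newick in all_topologies(labels[:-1]):
        tree = parse_newick(newick)
        edges = [e for e in tree.preorder_edge_iter() if e.tail_node is not None]
        for k in range(len(edges)):
            import dendropy
            t2 = parse_newick(newick)
            edges2 = [e for e in t2.preorder_edge_iter() if e.tail_node is not None]
            edge = edges2[k]
            parent, child = edge.tail_node, edge.head_node
            mid = dendropy.Node()
            parent.remove_child(child)
            parent.add_child(mid)
            mid.add_child(child)
            leaf = dendropy.Node()
            leaf.taxon = t2.taxon_namespace.new_taxon(labels[-1])
            mid.add_child(leaf)
            yield t2.as_string(schema="newick").strip()


class TestFitch:
    def test_single_column_examples(self):
        tree = parse_newick("((A,B),(C,D));")
        assert fitch_score(tree, make_alignment(
            {"A": "A", "B": "A", "C": "T", "D": "T"})) == 1
        assert fitch_score(tree, make_alignment(
            {"A": "A", "B": "A", "C": "A", "D": "A"})) == 0
        # missing data are union-neutral
        assert fitch_score(tree, make_alignment(
            {"A": "A", "B": "?", "C": "T", "D": "T"})) == 1

    def test_equals_exhaustive_minimum_on_five_taxa(self):
        rng = np.random.default_rng(5)
        labels = ["A", "B", "C", "D", "E"]
        rows = {lb: "".join(rng.choice(list("ACGT"), 20)) for lb in labels}
        aln = make_alignment(rows)
        scores = {}
        for nwk in all_topologies(labels):
            tree = parse_newick(nwk)
            scores[frozenset(bipartitions(tree))] = fitch_score(tree, aln)
        best = min(scores.values())
        found, _ = mp_search(aln, n_starts=3, seed=0)
        assert fitch_score(found[0], aln) == best


class TestMPSearch:
    def test_recovers_true_topology_with_strong_signal(self, small_truth):
        aln = small_truth.alignments["fast"]
        trees, score = mp_search(aln, n_starts=2, seed=1)
        true_tree = parse_newick(small_truth.tree_newick)
        # co-optimal trees must contain the generating topology's splits
        # above the species level (individual-level splits may be unresolved)
        rf = min(compare_topologies(t, true_tree)["rf"] for t in trees)
        assert rf == 0

    def test_deterministic_given_seed(self, small_truth):
        aln = small_truth.alignments["fast"]
        t1, s1 = mp_search(aln, n_starts=3, seed=9)
        t2, s2 = mp_search(aln, n_starts=3, seed=9)
        assert s1 == s2
        assert bipartitions(t1[0]) == bipartitions(t2[0])

    def test_invariant_alignment_scores_zero(self):
        aln = make_alignment({c: "AAAAA" for c in "ABCD"})
        trees, score = mp_search(aln, n_starts=1, seed=0)
        assert score == 0


class TestLikelihood:
    def test_two_taxon_jc69_closed_form(self):
        # P(identical) = 1/4 (1/4 + 3/4 e^{-4t/3}) summed over start states
        for t in (0.0, 0.1, 0.5):
            tree = parse_newick(f"(A:{t / 2},B:{t / 2});")
            aln = make_alignment({"A": "A", "B": "A"})
            expected = math.log(0.25 * (0.25 + 0.75 * math.exp(-4 * t / 3)))
            got = log_likelihood(tree, aln, SubstitutionModel("JC69"))
            assert got == pytest.approx(expected, abs=1e-10)

    def test_two_taxon_mismatch_closed_form(self):
        t = 0.3
        tree = parse_newick(f"(A:{t / 2},B:{t / 2});")
        aln = make_alignment({"A": "A", "B": "C"})
        expected = math.log(0.25 * (0.25 - 0.25 * math.exp(-4 * t / 3)))
        got = log_likelihood(tree, aln, SubstitutionModel("JC69"))
        assert got == pytest.approx(expected, abs=1e-10)

    def test_all_missing_leaf_is_marginalised_out(self):
        tree3 = parse_newick("(A:0.1,B:0.1,C:0.7);")
        tree2 = parse_newick("(A:0.1,B:0.1);")
        aln3 = make_alignment({"A": "ACGT", "B": "ACGA", "C": "????"})
        aln2 = make_alignment({"A": "ACGT", "B": "ACGA"})
        m = SubstitutionModel("HKY85", freqs=(0.3, 0.2, 0.2, 0.3), kappa=3.0)
        assert log_likelihood(tree3, aln3, m) == pytest.approx(
            log_likelihood(tree2, aln2, m), abs=1e-9)

    def test_rerooting_invariance(self):
        aln = make_alignment({"A": "ACGTTGCA", "B": "ACGATGCA",
                              "C": "TCGATGCA", "D": "TCGATGAA"})
        m = SubstitutionModel("GTR", freqs=(0.4, 0.1, 0.2, 0.3),
                              rates=(1, 2, 0.5, 1.2, 3, 1),
                              gamma_alpha=0.5, pinv=0.2)
        t1 = parse_newick("((A:0.1,B:0.2):0.05,(C:0.3,D:0.1):0.05);")
        t2 = parse_newick("(A:0.1,(B:0.2,((C:0.3,D:0.1):0.1)):0.0);")
        # same unrooted tree, different representation: A-B edge split 0.1+0.0
        ll1 = log_likelihood(t1, aln, m)
        t3 = parse_newick("((A:0.1,B:0.2):0.1,C:0.3,D:0.1);")
        ll3 = log_likelihood(t3, aln, m)
        assert ll1 == pytest.approx(ll3, abs=1e-9)
        del t2

    def test_gamma_category_rates_mean_one(self):
        m = SubstitutionModel("JC69", gamma_alpha=0.7)
        rates, weights = m.category_rates()
        assert sum(weights) == pytest.approx(1.0)
        assert float(np.dot(rates, weights)) == pytest.approx(1.0, abs=1e-6)


class TestMLSearch:
    def test_recovers_true_topology(self, small_truth):
        aln = small_truth.alignments["fast"]
        tree, ll = ml_search(aln)
        true_tree = parse_newick(small_truth.tree_newick)
        assert compare_topologies(tree, true_tree)["rf"] == 0
        # the optimised tree cannot be worse than the truth with the same
        # branch-length optimisation applied
        true_ll = log_likelihood(tree, aln, SubstitutionModel("JC69"))
        assert ll >= true_ll - 1e-6

    def test_branch_length_recovery(self):
        # data generated at pairwise distance 0.1 (t=0.05 per branch)
        from seabarcode.simdata import LocusSpec, SimulationConfig, simulate_dataset
        cfg = SimulationConfig(
            n_families=2, genera_per_family=(1, 1), species_per_genus=(1, 1),
            individuals_per_species=2, root_height=0.05,
            family_height=0.03, genus_height=0.02,
            intraspecific_divergence=0.02,
            loci=(LocusSpec("L", length=5000, rate_multiplier=1.0),), seed=4)
        truth = simulate_dataset(cfg)
        tree, _ = ml_search(truth.alignments["L"])
        # conspecific tips sit t=0.01 from their common node
        for lf in tree.leaf_node_iter():
            assert lf.edge.length == pytest.approx(0.01, abs=0.02)

    def test_deterministic(self, small_truth):
        aln = small_truth.alignments["fast"]
        t1, ll1 = ml_search(aln, seed=1)
        t2, ll2 = ml_search(aln, seed=1)
        assert ll1 == ll2
        assert bipartitions(t1) == bipartitions(t2)


class TestBootstrap:
    def diagnostic_alignment(self):
        """One split (AB|CD...) fixed by 50 identical diagnostic columns
        plus sparse noise columns."""
        rng = np.random.default_rng(8)
        labels = ["A", "B", "C", "D", "E", "F"]
        diag = {lb: ("A" if lb in "AB" else "T") * 50 for lb in labels}
        noise = {lb: "".join(rng.choice(list("ACGT"), 10)) for lb in labels}
        return make_alignment({lb: diag[lb] + noise[lb] for lb in labels})

    def test_diagnostic_split_high_support(self):
        aln = self.diagnostic_alignment()
        tree = bootstrap_support(aln, method="nj", reps=200, seed=1)
        supp = bipartitions(tree, with_support=True)
        ab = frozenset({"C", "D", "E", "F"})  # canonical side excludes 'A'
        assert supp[ab] >= 99.0

    def test_reps_one_supports_binary(self):
        aln = self.diagnostic_alignment()
        tree = bootstrap_support(aln, method="nj", reps=1, seed=2)
        vals = [v for v in bipartitions(tree, with_support=True).values()
                if v is not None]
        assert set(vals) <= {0.0, 100.0}

    def test_same_seed_identical(self):
        aln = self.diagnostic_alignment()
        s1 = bipartitions(bootstrap_support(aln, "nj", reps=50, seed=3),
                          with_support=True)
        s2 = bipartitions(bootstrap_support(aln, "nj", reps=50, seed=3),
                          with_support=True)
        assert s1 == s2

    def test_seed_convergence_on_strong_signal(self, small_truth):
        aln = small_truth.alignments["fast"]
        sa = bipartitions(bootstrap_support(aln, "nj", reps=300, seed=1),
                          with_support=True)
        sb = bipartitions(bootstrap_support(aln, "nj", reps=300, seed=2),
                          with_support=True)
        for split in sa:
            assert abs(sa[split] - sb[split]) < 5.0


class TestConsensus:
    def test_identical_trees(self):
        trees = [parse_newick("((A,B),(C,D));") for _ in range(3)]
        cons = majority_consensus(trees)
        supp = bipartitions(cons, with_support=True)
        assert set(supp.values()) == {100.0}

    def test_majority_frequency(self):
        trees = [parse_newick("((A,B),(C,D));"),
                 parse_newick("((A,B),(C,D));"),
                 parse_newick("((A,C),(B,D));")]
        cons = majority_consensus(trees)
        supp = bipartitions(cons, with_support=True)
        (split, pct), = supp.items()
        assert split == frozenset({"C", "D"})
        assert pct == pytest.approx(200 / 3, abs=0.1)

    def test_strict_consensus(self):
        trees = [parse_newick("((A,B),(C,D));"),
                 parse_newick("((A,C),(B,D));")]
        cons = majority_consensus(trees, threshold=1.0)
        assert bipartitions(cons) == set()

    def test_agrees_with_dendropy_rf(self):
        import dendropy
        rng = np.random.default_rng(12)
        dm1, t1 = random_additive_matrix(rng, 8)
        dm2, t2 = random_additive_matrix(rng, 8)
        # remap to a shared taxon namespace for dendropy's RF
        ns = dendropy.TaxonNamespace()
        d1 = dendropy.Tree.get(data=t1.as_string(schema="newick"),
                               schema="newick", taxon_namespace=ns)
        d2 = dendropy.Tree.get(data=t2.as_string(schema="newick"),
                               schema="newick", taxon_namespace=ns)
        d1.encode_bipartitions()
        d2.encode_bipartitions()
        expected = dendropy.calculate.treecompare.symmetric_difference(d1, d2)
        assert compare_topologies(t1, t2)["rf"] == expected


class TestCompare:
    def test_identical(self):
        t = parse_newick("((A,B),(C,D));")
        out = compare_topologies(t, parse_newick("((A,B),(C,D));"))
        assert out["rf"] == 0 and not out["only_t1"]

    def test_conflicting_four_taxon(self):
        out = compare_topologies(parse_newick("((A,B),(C,D));"),
                                 parse_newick("((A,C),(B,D));"))
        assert out["rf"] == 2

    def test_leaf_set_mismatch(self):
        with pytest.raises(TreeInputError):
            compare_topologies(parse_newick("((A,B),(C,D));"),
                               parse_newick("((A,B),(C,E));"))
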