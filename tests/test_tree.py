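import dendropy
import numpy as np
import pytest

from sprank.simulate import sample_tree, simulate_alignment
from sprank.likelihood import SubstitutionModel
from sprank.tree import (
    Alignment,
    AlignmentError,
    TreeError,
    build_starting_tree,
    read_newick,
    rf_distance,
    write_newick,
)


class TestNewickIO:
    def test_four_leaf_tree_has_five_branches(self):
        t = read_newick("((A:1,B:1):1,C:1,D:1);")
        assert t.n_taxa == 4
        assert len(t.branches) == 5
        assert t.leaves == {"A", "B", "C", "D"}

    def test_round_trip_preserves_topology_and_lengths(self):
        t = read_newick("((A:1,B:2):0.5,(C:1,D:1):0.5);")
        t2 = read_newick(write_newick(t))
        assert rf_distance(t, t2) == 0
        assert sorted(t.branch_lengths.values()) == pytest.approx(
            sorted(t2.branch_lengths.values()), rel=1e-10
        )

    def test_rooted_input_is_unrooted_by_merging_root_branches(self):
        t = read_newick("((A:1,B:1):0.3,(C:1,D:1):0.2);")
        assert t.n_taxa == 4 and len(t.branches) == 5
        assert 0.5 in t.branch_lengths.values()

    def test_three_leaf_star_shape(self):
        t = read_newick("(A:0.1,B:0.2,C:0.3);")
        assert len(t.branches) == 3
        assert write_newick(t).startswith("(A:")

    def test_zero_length_branch_emitted(self):
        t = read_newick("((A:0,B:1):1,C:1,D:1);")
        assert ":0," in write_newick(t) or ":0)" in write_newick(t)

    def test_random_trees_round_trip(self):
        for seed in range(20):
            t = sample_tree(int(np.random.default_rng(seed).integers(4, 20)), seed)
            t2 = read_newick(write_newick(t))
            assert rf_distance(t, t2) == 0
            assert sorted(t.branch_lengths.values()) == pytest.approx(
                sorted(t2.branch_lengths.values()), rel=1e-9
            )

    @pytest.mark.parametrize(
        "bad", ["", "((A:1,B:1;", "(A:1,A:1,C:1);", "(A:1);"]
    )
    def test_invalid_newick_rejected(self, bad):
        with pytest.raises(TreeError):
            read_newick(bad)


class TestRFDistance:
    def test_identical_trees(self):
        t = read_newick("((A:1,B:1):1,C:1,(D:1,E:1):1);")
        assert rf_distance(t, t.copy()) == 0

    def test_single_nni_on_five_taxa(self):
        # swapping C with B across the internal edge changes one split
        t1 = read_newick("(((A:1,B:1):1,C:1):1,D:1,E:1);")
        t2 = read_newick("(((A:1,C:1):1,B:1):1,D:1,E:1);")
        assert rf_distance(t1, t2) == 2

    def test_upper_bound_two_n_minus_three(self):
        for seed in range(10):
            n = 5 + seed
            t1 = sample_tree(n, seed)
            t2 = sample_tree(n, seed + 1000)
            assert rf_distance(t1, t2) <= 2 * (n - 3)

    def test_metric_properties_on_random_triples(self):
        for seed in range(8):
            a = sample_tree(8, 3 * seed)
            b = sample_tree(8, 3 * seed + 1)
            c = sample_tree(8, 3 * seed + 2)
            dab, dba = rf_distance(a, b), rf_distance(b, a)
            assert dab == dba
            assert rf_distance(a, c) <= dab + rf_distance(b, c)

    def test_leaf_set_mismatch_raises(self):
        t1 = read_newick("((A:1,B:1):1,C:1,D:1);")
        t2 = read_newick("((A:1,B:1):1,C:1,E:1);")
        with pytest.raises(TreeError):
            rf_distance(t1, t2)

    def test_agrees_with_dendropy(self):
        taxa = dendropy.TaxonNamespace()
        for seed in range(10):
            t1 = sample_tree(10, seed)
            t2 = sample_tree(10, seed + 99)
            d1 = dendropy.Tree.get(data=write_newick(t1), schema="newick", taxon_namespace=taxa)
            d2 = dendropy.Tree.get(data=write_newick(t2), schema="newick", taxon_namespace=taxa)
            d1.encode_bipartitions()
            d2.encode_bipartitions()
            expected = dendropy.calculate.treecompare.symmetric_difference(d1, d2)
            assert rf_distance(t1, t2) == expected


class TestAlignment:
    def test_validation(self):
        with pytest.raises(AlignmentError):
            Alignment({"A": "ACGT", "B": "ACG"})
        with pytest.raises(AlignmentError):
            Alignment({"A": "ACGT", "B": "----"})
        with pytest.raises(AlignmentError):
            Alignment({})

    def test_fasta_round_trip(self, tmp_path):
        aln = Alignment({"t1": "ACGT-", "t2": "ACGTN"})
        path = tmp_path / "a.fasta"
        aln.to_fasta(str(path))
        aln2 = Alignment.from_fasta(str(path))
        assert aln2.taxa == aln.taxa
        assert aln2.sequence("t1") == "ACGT-"

    def test_encoding_treats_ambiguity_as_missing(self):
        aln = Alignment({"a": "ACGTRN-U"})
        row = aln.encoded()[0]
        assert list(row[:4]) == [0, 1, 2, 3]
        assert list(row[4:7]) == [-1, -1, -1]
        assert row[7] == 3  # U read as T


class TestStartingTree:
    def test_three_taxa_unique_topology(self):
        aln = Alignment({"A": "ACGTAC", "B": "ACGTAA", "C": "ACGGAA"})
        t = build_starting_tree(aln)
        assert t.n_taxa == 3 and len(t.branches) == 3

    def test_identical_sequences_zero_lengths(self):
        aln = Alignment({k: "ACGTACGT" for k in "ABCD"})
        t = build_starting_tree(aln)
        assert t.n_taxa == 4
        assert max(t.branch_lengths.values()) == 0.0

    def test_recovers_generating_topology_with_long_alignment(self):
        true = sample_tree(10, 5, mean_branch_length=0.08)
        aln = simulate_alignment(true, SubstitutionModel.jc(), 10_000, 5)
        nj = build_starting_tree(aln)
        assert rf_distance(nj, true) == 0

    def test_saturated_pair_capped(self, caplog):
        # wildly divergent pair: p-distance >= 3/4 triggers the cap
        aln = Alignment({"A": "AAAAAAAA", "B": "CCCCCCCC", "C": "AAAACCCC"})
        t = build_starting_tree(aln, max_distance=5.0)
        assert all(np.isfinite(v) for v in t.branch_lengths.values())
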