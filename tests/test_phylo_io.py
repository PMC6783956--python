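import io

import numpy as np
import pandas as pd
import pytest

from elevagrad import (
    CommunityMatrix,
    exclude_taxa,
    parse_newick,
    patristic_distances,
    prune_to_taxa,
    read_community,
    reconcile,
    total_tree_length,
    write_newick,
)
from elevagrad.phylo_io import tip_labels

from oracles import naive_patristic


class TestNewick:
    def test_parse_simple(self, cherry_tree):
        assert sorted(tip_labels(cherry_tree)) == ["A", "B"]
        assert total_tree_length(cherry_tree) == pytest.approx(3.0)

    def test_patristic_through_internal_node(self, three_taxon_tree):
        d = patristic_distances(three_taxon_tree)
        assert d.loc["A", "C"] == pytest.approx(4.0)
        assert d.loc["A", "B"] == pytest.approx(2.0)

    def test_duplicate_tip_labels_rejected(self):
        with pytest.raises(ValueError):
            parse_newick("(A:1,A:2);")

    def test_missing_branch_length_rejected(self):
        with pytest.raises(ValueError, match="branch length"):
            parse_newick("(A:1,B);")

    def test_malformed_rejected(self):
        with pytest.raises(ValueError):
            parse_newick("((A:1,B:2;")

    def test_roundtrip_preserves_lengths_and_topology(self, three_taxon_tree):
        again = parse_newick(write_newick(three_taxon_tree))
        d1 = patristic_distances(three_taxon_tree)
        d2 = patristic_distances(again)
        pd.testing.assert_frame_equal(d1.sort_index(), d2.sort_index())


class TestPatristicProperties:
    @pytest.mark.parametrize("seed", range(25))
    def test_matches_naive_path_walk(self, seed):
        from conftest import random_instance

        tree, _ = random_instance(seed)
        d = patristic_distances(tree)
        labels = list(d.index)
        for i, a in enumerate(labels):
            assert d.loc[a, a] == 0.0
            for b in labels[i + 1 :]:
                expect = naive_patristic(tree, a, b)
                assert d.loc[a, b] == pytest.approx(expect, rel=1e-12)
                assert d.loc[b, a] == d.loc[a, b]

    def test_ultrametric_cross_root_distance(self):
        tree = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        d = patristic_distances(tree)
        for pair in [("A", "C"), ("A", "D"), ("B", "C"), ("B", "D")]:
            assert d.loc[pair] == pytest.approx(4.0)

    def test_requires_two_tips(self):
        single = prune_to_taxa(parse_newick("(A:1,B:2);"), {"A"})
        with pytest.raises(ValueError):
            patristic_distances(single)


class TestPrune:
    def test_collapses_unifurcations_summing_lengths(self, three_taxon_tree):
        pruned = prune_to_taxa(three_taxon_tree, {"A", "C"})
        assert total_tree_length(pruned) == pytest.approx(4.0)

    def test_prune_to_all_is_identity_on_length(self, three_taxon_tree):
        pruned = prune_to_taxa(three_taxon_tree, {"A", "B", "C"})
        assert total_tree_length(pruned) == pytest.approx(total_tree_length(three_taxon_tree))

    def test_single_tip_keeps_root_path(self, three_taxon_tree):
        pruned = prune_to_taxa(three_taxon_tree, {"A"})
        assert total_tree_length(pruned) == pytest.approx(2.0)

    def test_never_increases_total_length(self):
        from conftest import random_instance

        rng = np.random.default_rng(5)
        for seed in range(10):
            tree, _ = random_instance(seed)
            labels = tip_labels(tree)
            k = int(rng.integers(1, len(labels) + 1))
            keep = set(rng.choice(labels, size=k, replace=False))
            assert total_tree_length(prune_to_taxa(tree, keep)) <= total_tree_length(tree) + 1e-12

    def test_idempotent(self, three_taxon_tree):
        once = prune_to_taxa(three_taxon_tree, {"A", "B"})
        twice = prune_to_taxa(once, {"A", "B"})
        assert write_newick(once) == write_newick(twice)

    def test_unknown_label_and_empty_set(self, three_taxon_tree):
        with pytest.raises(ValueError):
            prune_to_taxa(three_taxon_tree, {"Z"})
        with pytest.raises(ValueError):
            prune_to_taxa(three_taxon_tree, set())


class TestReadCommunity:
    def test_roundtrip_conservation(self):
        text = "plot_id,elevation_m,A,B,C\np1,2500,2,1,1\np2,3000,0,3,5\n"
        m = read_community(io.StringIO(text))
        assert m.total_stems == 12
        assert m.species == ["A", "B", "C"]
        assert m.richness().tolist() == [3, 2]

    def test_tab_delimited_autodetect(self):
        text = "plot_id\televation_m\tA\tB\np1\t2500\t1\t2\n"
        m = read_community(io.StringIO(text))
        assert m.total_stems == 3

    def test_blank_cell_is_zero(self):
        text = "plot_id,elevation_m,A,B\np1,2500,,4\n"
        m = read_community(io.StringIO(text))
        assert m.counts.loc["p1", "A"] == 0

    def test_negative_count_rejected(self):
        text = "plot_id,elevation_m,A\np1,2500,-1\n"
        with pytest.raises(ValueError):
            read_community(io.StringIO(text))

    def test_non_integer_count_rejected(self):
        text = "plot_id,elevation_m,A\np1,2500,1.5\n"
        with pytest.raises(ValueError):
            read_community(io.StringIO(text))

    def test_duplicate_plot_id_rejected(self):
        text = "plot_id,elevation_m,A\np1,2500,1\np1,2600,2\n"
        with pytest.raises(ValueError):
            read_community(io.StringIO(text))

    def test_missing_elevation_rejected(self):
        text = "plot_id,elevation_m,A\np1,,1\n"
        with pytest.raises(ValueError):
            read_community(io.StringIO(text))


class TestExcludeAndReconcile:
    def test_exclude_nothing_is_identity(self, toy_matrix, three_taxon_tree):
        m, t = exclude_taxa(toy_matrix, three_taxon_tree, set())
        assert m is toy_matrix and t is three_taxon_tree

    def test_exclude_shrinks_pool_consistently(self, toy_matrix, three_taxon_tree):
        m, t = exclude_taxa(toy_matrix, three_taxon_tree, {"A"})
        assert m.species == ["B", "C"]
        assert sorted(tip_labels(t)) == ["B", "C"]

    def test_exclusion_can_empty_a_plot_but_keeps_it(self):
        counts = pd.DataFrame({"A": [2, 0], "B": [0, 3]}, index=["p1", "p2"])
        m = CommunityMatrix(counts, pd.Series([2500.0, 3000.0], index=["p1", "p2"]))
        tree = parse_newick("(A:1,B:1);")
        with pytest.raises(ValueError):
            exclude_taxa(m, tree, {"A", "B"})
        m2, _ = exclude_taxa(m, tree, {"A"})
        assert m2.plot_ids == ["p1", "p2"]
        assert m2.empty_plots == ["p1"]

    def test_reconcile_drops_unplaced_species_with_bookkeeping(self, toy_matrix):
        tree = parse_newick("(A:1,B:1);")  # no C
        m, t, report = reconcile(toy_matrix, tree)
        assert m.species == ["A", "B"]
        assert report.dropped_from_matrix == ["C"]
        # C has 6 of 12 stems
        assert report.fraction_individuals_dropped == pytest.approx(0.5)

    def test_reconcile_identity_when_pools_match(self, toy_matrix, three_taxon_tree):
        m, t, report = reconcile(toy_matrix, three_taxon_tree)
        assert report.dropped_from_matrix == [] and report.dropped_from_tree == []
        assert m.counts.equals(toy_matrix.counts)

    def test_reconcile_disjoint_pools_error(self, toy_matrix):
        tree = parse_newick("(X:1,Y:1);")
        with pytest.raises(ValueError):
            reconcile(toy_matrix, tree)

    def test_prune_commutes_with_exclude_on_disjoint_sets(self, toy_matrix, three_taxon_tree):
        # exclude A, then prune survivor set == prune first, then exclude
        m1, t1 = exclude_taxa(toy_matrix, three_taxon_tree, {"A"})
        t1 = prune_to_taxa(t1, {"B", "C"})
        t2 = prune_to_taxa(three_taxon_tree, {"A", "B", "C"})
        m2, t2 = exclude_taxa(toy_matrix, t2, {"A"})
        assert write_newick(t1) == write_newick(t2)
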