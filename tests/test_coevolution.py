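import dendropy
import pytest
from dendropy.calculate import treecompare

from gmrsd_context import (
    Association,
    SupportedTree,
    TreeSimSpec,
    coevolution_analysis,
    collapse_low_support,
    congruence,
    prune_unpaired,
    read_tanglegram,
    simulate_tree_pair,
    tanglegram_export,
)


def tree(newick):
    return SupportedTree.from_newick(newick)


class TestCollapseLowSupport:
    def test_boundary_079_collapsed_080_retained(self):
        t = tree("(((A,B)0.79,(C,D)0.80)0.95,E,F);")
        collapsed = collapse_low_support(t, 0.8)
        splits = collapsed.splits()
        cd = frozenset({frozenset({"C", "D"}), frozenset({"A", "B", "E", "F"})})
        ab = frozenset({frozenset({"A", "B"}), frozenset({"C", "D", "E", "F"})})
        assert cd in splits and ab not in splits

    def test_full_support_tree_unchanged(self):
        t = tree("(((A,B)1.0,C)1.0,D,E);")
        assert collapse_low_support(t, 0.8).splits() == t.splits()

    def test_idempotent_and_leafset_preserved(self):
        t = tree("(((A,B)0.5,(C,D)0.9)0.7,E,F);")
        once = collapse_low_support(t, 0.8)
        twice = collapse_low_support(once, 0.8)
        assert once.splits() == twice.splits()
        assert once.leaf_labels() == t.leaf_labels()

    def test_percentage_dialect_rescaled(self):
        t = tree("(((A,B)79,(C,D)95)100,E,F);")
        splits = collapse_low_support(t, 0.8).splits()
        assert len(splits) == 2  # CD kept, AB collapsed

    def test_missing_support_collapsed(self):
        t = tree("(((A,B),(C,D)0.9)0.9,E,F);")
        splits = collapse_low_support(t, 0.8).splits()
        ab = frozenset({frozenset({"A", "B"}), frozenset({"C", "D", "E", "F"})})
        assert ab not in splits


class TestPruneUnpaired:
    def test_all_paired_leaves_kept(self):
        ts = tree("((S1,S2)0.9,S3,S4);")
        td = tree("((D1,D2)0.9,D3,D4);")
        assoc = Association(tuple((f"S{i}", f"D{i}") for i in range(1, 5)))
        ps, pd_ = prune_unpaired(ts, td, assoc)
        assert ps.leaf_labels() == ts.leaf_labels()
        assert pd_.leaf_labels() == td.leaf_labels()

    def test_extra_unpaired_leaf_removed(self):
        ts = tree("((S1,S2)0.9,(S3,EXTRA)0.9,S4);")
        td = tree("((D1,D2)0.9,D3,D4);")
        assoc = Association(tuple((f"S{i}", f"D{i}") for i in range(1, 5)))
        ps, pd_ = prune_unpaired(ts, td, assoc)
        assert ps.leaf_labels() == {"S1", "S2", "S3", "S4"}
        assert pd_.leaf_labels() == {"D1", "D2", "D3", "D4"}

    def test_counts_after_partial_pairing(self):
        ts = tree("((S1,S2)0.9,(S3,S4)0.9,(S5,S6)0.9,(S7,S8)0.9,S9,S10);")
        td = tree("((D1,D2)0.9,(D3,D4)0.9,(D5,D6)0.9,(D7,D8)0.9,D9,D10);")
        assoc = Association(tuple((f"S{i}", f"D{i}") for i in range(1, 5)))
        ps, pd_ = prune_unpaired(ts, td, assoc)
        assert len(ps.leaf_labels()) == 4 and len(pd_.leaf_labels()) == 4

    def test_empty_association_warns(self):
        ts = tree("((S1,S2)0.9,S3,S4);")
        with pytest.warns(UserWarning):
            ps, pd_ = prune_unpaired(ts, ts.clone(), Association(()))
        assert ps.leaf_labels() == set()


class TestCongruence:
    def assoc(self, n):
        return Association(tuple((f"S{i}", f"D{i}") for i in range(1, n + 1)))

    def test_identical_topologies_rf_zero(self):
        ts = tree("(((S1,S2)0.9,S3)0.9,S4,S5);")
        td = tree("(((D1,D2)0.9,D3)0.9,D4,D5);")
        report = congruence(ts, td, self.assoc(5))
        assert report.rf == 0 and report.rf_normalized == 0.0

    def test_star_trees_rf_zero_with_zero_denominator(self):
        ts = tree("(S1,S2,S3,S4);")
        td = tree("(D1,D2,D3,D4);")
        report = congruence(ts, td, self.assoc(4))
        assert report.rf == 0 and report.rf_normalized == 0.0

    def test_leaf_set_mismatch_rejected(self):
        ts = tree("((S1,S2)0.9,S3,S4);")
        td = tree("((D1,D2)0.9,D3,D9);")
        with pytest.raises(ValueError, match="leaf sets"):
            congruence(ts, td, self.assoc(4))

    def test_symmetry_and_self_distance(self):
        for seed in range(5):
            pair = simulate_tree_pair(TreeSimSpec(n_leaves=10, n_spr=2, seed=seed))
            assoc = Association(pair.association)
            self_assoc = Association(tuple((s, s) for s, _ in pair.association))
            assert congruence(pair.tree_s, pair.tree_s, self_assoc).rf == 0
            fwd = congruence(pair.tree_s, pair.tree_d, assoc)
            rev = congruence(
                pair.tree_d, pair.tree_s, Association(tuple((d, s) for s, d in pair.association))
            )
            assert fwd.rf == rev.rf

    @pytest.mark.parametrize("seed", range(15))
    def test_rf_matches_dendropy_bipartition_oracle(self, seed):
        """Split-set RF on one-SPR derivatives agrees with an independent
        bipartition comparison (dendropy) on the same relabeled trees."""
        pair = simulate_tree_pair(TreeSimSpec(n_leaves=8, n_spr=1, seed=seed))
        report = congruence(pair.tree_s, pair.tree_d, Association(pair.association))
        tns = dendropy.TaxonNamespace()
        nd_s = dendropy.Tree.get(data=pair.newick_s, schema="newick",
                                 taxon_namespace=tns, suppress_internal_node_taxa=True)
        nd_d = dendropy.Tree.get(data=pair.newick_d.replace("D", "S"), schema="newick",
                                 taxon_namespace=tns, suppress_internal_node_taxa=True)
        nd_s.encode_bipartitions()
        nd_d.encode_bipartitions()
        assert report.rf == treecompare.symmetric_difference(nd_s, nd_d)


class TestTanglegramExport:
    def test_round_trip(self, tmp_path):
        pair = simulate_tree_pair(TreeSimSpec(n_leaves=8, n_spr=1, seed=1))
        assoc = Association(pair.association, tuple("double" for _ in pair.association))
        tanglegram_export(pair.tree_s, pair.tree_d, assoc, tmp_path)
        ts, td, assoc2 = read_tanglegram(tmp_path)
        assert ts.splits() == pair.tree_s.splits()
        assert td.splits() == pair.tree_d.splits()
        assert assoc2.pairs == assoc.pairs and assoc2.sources == assoc.sources
        assert len(assoc2) == pair.spec.n_leaves

    def test_empty_association_empty_links(self, tmp_path):
        pair = simulate_tree_pair(TreeSimSpec(n_leaves=6, seed=2))
        paths = tanglegram_export(pair.tree_s, pair.tree_d, Association(()), tmp_path)
        lines = paths["links"].read_text().splitlines()
        assert lines == ["s_leaf\td_leaf\tsource"]


class TestAssociation:
    def test_duplicate_leaf_rejected(self):
        with pytest.raises(ValueError, match="twice"):
            Association((("S1", "D1"), ("S1", "D2")))


class TestCoevolutionAnalysis:
    def test_pipeline_counts_pruned_leaves(self):
        ts = tree("(((S1,S2)0.9,(S3,EXTRA)0.9)0.9,S4,S5);")
        td = tree("(((D1,D2)0.9,D3)0.9,D4,D5);")
        assoc = Association(tuple((f"S{i}", f"D{i}") for i in range(1, 6)))
        ps, pd_, report = coevolution_analysis(ts, td, assoc)
        assert report.n_pruned_s == 1 and report.n_pruned_d == 0
        assert report.n_shared_pairs == 5
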