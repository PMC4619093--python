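import numpy as np
import pytest
from scipy.stats import chi2_contingency

from gmrsd_context import (
    ArchClass,
    FamilySimSpec,
    GenomeSimSpec,
    TreeSimSpec,
    compile_motif,
    count_domains,
    extract_neighborhood,
    scan_motif,
    simulate_family,
    simulate_genomes,
    simulate_tree_pair,
)
from gmrsd_context.simulate import MotifPlacement


class TestGenomeSimulation:
    def test_same_seed_identical_output(self):
        spec = GenomeSimSpec(n_genomes=3, orfs_per_contig=25, domain_vocab_size=8, seed=5)
        assert simulate_genomes(spec) == simulate_genomes(spec)

    def test_different_seed_differs(self):
        a = simulate_genomes(GenomeSimSpec(n_genomes=3, orfs_per_contig=25,
                                           domain_vocab_size=8, seed=5))
        b = simulate_genomes(GenomeSimSpec(n_genomes=3, orfs_per_contig=25,
                                           domain_vocab_size=8, seed=6))
        assert a != b

    def test_invalid_weights_rejected(self):
        spec = GenomeSimSpec(domain_vocab_size=3, background_weights=(0.5, 0.2, 0.2))
        with pytest.raises(ValueError, match="sum to 1"):
            simulate_genomes(spec)

    def test_multiplier_below_one_rejected(self):
        with pytest.raises(ValueError, match="multiplier"):
            simulate_genomes(GenomeSimSpec(enriched_domains={"D000": 0.5}))

    def test_all_multipliers_one_empty_truth(self):
        sim = simulate_genomes(
            GenomeSimSpec(n_genomes=2, orfs_per_contig=25, domain_vocab_size=5,
                          enriched_domains={"D001": 1.0}, seed=0)
        )
        assert sim.truth == frozenset()

    def test_planted_signal_detected_by_contingency_test(self):
        """With one domain at 5x odds, an independent chi-square contingency
        test on generated window-vs-background counts rejects at alpha 0.01."""
        spec = GenomeSimSpec(n_genomes=100, orfs_per_contig=60, domain_vocab_size=50,
                             enriched_domains={"D010": 5.0}, seed=3)
        sim = simulate_genomes(spec)
        windows = [
            extract_neighborhood(g, f, k=10)
            for g in sim.genomes
            for f in sim.focal_proteins[g.genome_id]
        ]
        neigh = count_domains(windows, sim.hits_by_protein)
        neighbor_ids = {p for w in windows for p in w.neighbor_protein_ids}
        outside = {
            pid: hs for pid, hs in sim.hits_by_protein.items() if pid not in neighbor_ids
        }
        out_counts: dict[str, int] = {}
        for hs in outside.values():
            for h in hs:
                out_counts[h.domain_id] = out_counts.get(h.domain_id, 0) + 1
        x_in = neigh.get("D010", 0)
        x_out = out_counts.get("D010", 0)
        n_in = sum(neigh.values())
        n_out = sum(out_counts.values())
        table = [[x_in, n_in - x_in], [x_out, n_out - x_out]]
        assert chi2_contingency(table).pvalue < 0.01
        # and the planted odds push the window proportion up, not down
        assert x_in / n_in > x_out / n_out

    def test_focal_windows_do_not_overlap(self):
        spec = GenomeSimSpec(n_genomes=10, orfs_per_contig=60, domain_vocab_size=10,
                             focal_per_genome=2, seed=2)
        sim = simulate_genomes(spec)
        for g in sim.genomes:
            focals = sim.focal_proteins[g.genome_id]
            assert len(focals) == 2
            positions = [g.locate(f) for f in focals]
            for (c1, p1), (c2, p2) in zip(positions, positions[1:]):
                if c1 == c2:
                    assert abs(p1 - p2) >= 2 * spec.window_k + 1


class TestFamilySimulation:
    def test_empty_family(self):
        sim = simulate_family(FamilySimSpec(n_double=0, n_pairs=0, n_orphans=0))
        assert sim.members == ()

    def test_motif_longer_than_region_rejected(self):
        placement = MotifPlacement(compile_motif("NxxFxxKK"), "S", 298)
        with pytest.raises(ValueError, match="does not fit"):
            simulate_family(FamilySimSpec(motif_placements=(placement,)))

    def test_full_conservation_every_motif_matches_truth(self, family_sim):
        patterns = {
            pl.pattern.name: pl.pattern for pl in family_sim.spec.motif_placements
        }
        for member in family_sim.members:
            for truth in member.motifs:
                starts = [
                    m.start for m in scan_motif(member.sequence, patterns[truth.pattern_name])
                ]
                assert truth.start in starts

    def test_architecture_labels_match_planted_regions(self, family_sim):
        for m in family_sim.members:
            if m.label is ArchClass.DOUBLE:
                assert len(m.hits) == 2
                assert len(m.sequence) >= family_sim.spec.seq_length_range[0]
            else:
                assert len(m.hits) == 1

    def test_same_seed_identical(self):
        spec = FamilySimSpec(n_double=3, n_pairs=1, n_orphans=2, seed=9)
        assert simulate_family(spec) == simulate_family(spec)

    def test_half_conservation_modal_frequency(self):
        """At conservation level c the planted (consensus) residue is kept
        with probability c and is redrawn uniformly otherwise, so the modal
        frequency at a motif column is ~ c + (1-c)/20 (~ c + (1-c)/19 within
        binomial sampling error)."""
        spec = FamilySimSpec(n_double=300, n_pairs=0, n_orphans=0,
                             conservation_level=0.5, seed=13)
        sim = simulate_family(spec)
        c = 0.5
        expected = c + (1 - c) / 20
        freqs = []
        for name, (start, end) in sim.motif_columns().items():
            for col in range(start - 1, end):
                residues = [m.sequence[col] for m in sim.members]
                counts = {}
                for r in residues:
                    counts[r] = counts.get(r, 0) + 1
                freqs.append(max(counts.values()) / len(residues))
        mean = np.mean(freqs)
        # 3 sigma of the per-column binomial, averaged over ~60 columns
        tol = 3 * np.sqrt(expected * (1 - expected) / (300 * len(freqs)))
        assert mean == pytest.approx(expected, abs=max(tol, 0.01))


class TestTreeSimulation:
    def test_too_few_leaves_rejected(self):
        with pytest.raises(ValueError, match="n_leaves"):
            simulate_tree_pair(TreeSimSpec(n_leaves=3))

    def test_no_spr_identical_topology(self):
        for seed in range(10):
            pair = simulate_tree_pair(TreeSimSpec(n_leaves=12, n_spr=0, seed=seed))
            renamed = {d: s for s, d in pair.association}
            assert pair.tree_s.splits() == pair.tree_d.splits(rename=renamed)

    def test_same_seed_identical_newick(self):
        spec = TreeSimSpec(n_leaves=9, n_spr=2, seed=21)
        a = simulate_tree_pair(spec)
        b = simulate_tree_pair(spec)
        assert a.newick_s == b.newick_s and a.newick_d == b.newick_d

    def test_association_is_index_aligned(self):
        pair = simulate_tree_pair(TreeSimSpec(n_leaves=6, seed=0))
        assert pair.association[0] == ("S0000", "D0000")
        assert pair.tree_s.leaf_labels() == {s for s, _ in pair.association}
        assert pair.tree_d.leaf_labels() == {d for _, d in pair.association}

    def test_supports_in_unit_interval(self):
        pair = simulate_tree_pair(TreeSimSpec(n_leaves=15, n_spr=1, seed=4))
        for t in (pair.tree_s, pair.tree_d):
            for node in t.tree.preorder_node_iter():
                if not node.is_leaf() and node.parent_node is not None:
                    sup = getattr(node, "support", None)
                    assert sup is not None and 0.0 <= sup <= 1.0
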