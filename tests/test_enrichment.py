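from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from gmrsd_context import (
    DomainCountTable,
    DomainHit,
    GenomeAnnotation,
    ORF,
    count_domains,
    enrichment_analysis,
    extract_neighborhood,
    neighborhood_enrichment,
    select_top_nonoverlapping,
    two_proportion_ci,
)

REFERENCE = Path(__file__).parent / "data" / "proptest_reference.csv"


def contig(genome_id, n, contig_id="c0"):
    orfs = tuple(
        ORF(contig_id, i, i * 100 + 1, i * 100 + 90, "+", f"{genome_id}_p{i}")
        for i in range(n)
    )
    return GenomeAnnotation(genome_id=genome_id, contigs={contig_id: orfs})


class TestExtractNeighborhood:
    def test_full_window(self):
        genome = contig("g", 30)
        window = extract_neighborhood(genome, "g_p15", k=10)
        assert len(window.neighbor_protein_ids) == 20
        assert not window.truncated
        expected = [f"g_p{i}" for i in list(range(5, 15)) + list(range(16, 26))]
        assert sorted(window.neighbor_protein_ids) == sorted(expected)

    def test_truncated_near_contig_start(self):
        window = extract_neighborhood(contig("g", 30), "g_p3", k=10)
        assert len(window.neighbor_protein_ids) == 13
        assert window.truncated

    def test_single_orf_contig(self):
        window = extract_neighborhood(contig("g", 1), "g_p0", k=10)
        assert window.neighbor_protein_ids == () and window.truncated

    def test_focal_not_found(self):
        with pytest.raises(KeyError):
            extract_neighborhood(contig("g", 5), "nope", k=10)

    def test_window_never_exceeds_2k(self, planted_genomes):
        for g in planted_genomes.genomes:
            for focal in planted_genomes.focal_proteins[g.genome_id]:
                w = extract_neighborhood(g, focal, k=10)
                assert len(w.neighbor_protein_ids) <= 20
                assert (len(w.neighbor_protein_ids) == 20) == (not w.truncated)


def mkhit(pid, dom, start, end, evalue):
    return DomainHit(pid, dom, start, end, evalue, 0.9)


class TestSelectTopNonoverlapping:
    def test_greedy_example(self):
        a = mkhit("p", "A", 1, 100, 1e-10)
        b = mkhit("p", "B", 50, 150, 1e-5)
        c = mkhit("p", "C", 160, 200, 1e-4)
        assert select_top_nonoverlapping([b, c, a]) == [a, c]

    def test_hit_above_threshold_dropped(self):
        assert select_top_nonoverlapping([mkhit("p", "A", 1, 10, 0.5)]) == []

    @pytest.mark.parametrize("seed", range(30))
    def test_greedy_matches_brute_force_verifier(self, seed):
        rng = np.random.default_rng(seed)
        hits = []
        for i in range(rng.integers(1, 15)):
            start = int(rng.integers(1, 300))
            hits.append(
                mkhit("p", f"d{i}", start, start + int(rng.integers(10, 120)),
                      float(10.0 ** rng.uniform(-12, 0)))
            )
        accepted = select_top_nonoverlapping(hits)
        # pairwise non-overlapping
        for i, a in enumerate(accepted):
            for b in accepted[i + 1:]:
                assert not a.overlaps(b)
        # every rejected passing hit lost to an accepted hit at least as good
        for h in hits:
            if h.evalue < 1e-3 and h not in accepted:
                assert any(h.overlaps(a) and a.evalue <= h.evalue for a in accepted)


class TestCountDomains:
    def test_no_windows(self):
        assert count_domains([], {}) == {}

    def test_shared_protein_counted_once_across_windows(self):
        from gmrsd_context import NeighborhoodWindow

        w1 = NeighborhoodWindow("f1", ("p1", "p2"), False, 10)
        w2 = NeighborhoodWindow("f2", ("p2", "p3"), False, 10)
        accepted = {p: [mkhit(p, "DUF262", 1, 50, 1e-9)] for p in ("p1", "p2", "p3")}
        counts = count_domains([w1, w2], accepted)
        assert counts == {"DUF262": 3}
        assert count_domains([w1, w2], accepted, dedupe=False) == {"DUF262": 4}


class TestTwoProportionCI:
    def test_matches_frozen_reference_to_1e9(self):
        """Numerical agreement with the frozen reference implementation of the
        continuity-corrected (and plain) equal-proportions CI."""
        ref = pd.read_csv(REFERENCE)
        assert len(ref) >= 200
        for r in ref.itertuples():
            _, lo, hi = two_proportion_ci(
                r.x1, r.n1, r.x2, r.n2, conf_level=r.conf_level, correct=bool(r.correct)
            )
            assert lo == pytest.approx(r.ci_lower, abs=1e-9)
            assert hi == pytest.approx(r.ci_upper, abs=1e-9)

    def test_equal_proportions_symmetric_about_zero(self):
        diff, lo, hi = two_proportion_ci(10, 100, 20, 200)
        assert diff == 0.0
        assert lo == pytest.approx(-hi)
        assert lo < 0 < hi

    def test_higher_level_contains_lower(self):
        _, lo95, hi95 = two_proportion_ci(30, 100, 10, 200, 0.95)
        _, lo99, hi99 = two_proportion_ci(30, 100, 10, 200, 0.99)
        assert lo99 < lo95 and hi99 > hi95

    @pytest.mark.parametrize("bad", [(1, 0, 1, 10), (1, 10, 1, 0)])
    def test_zero_denominator_rejected(self, bad):
        with pytest.raises(ValueError):
            two_proportion_ci(*bad)


class TestEnrichmentAnalysis:
    def test_single_domain_level_is_95(self):
        table = DomainCountTable({"A": 5}, {"A": 10})
        (res,) = enrichment_analysis(table, alpha=0.05)
        assert res.conf_level == pytest.approx(0.95)

    def test_identical_proportions_nothing_enriched(self):
        table = DomainCountTable({"A": 10, "B": 30}, {"A": 20, "B": 60})
        assert not any(r.enriched for r in enrichment_analysis(table))

    def test_empty_table(self):
        assert enrichment_analysis(DomainCountTable({}, {})) == []

    def test_enriched_iff_ci_lower_positive(self, planted_genomes):
        table, results, _ = neighborhood_enrichment(
            list(planted_genomes.genomes),
            planted_genomes.hits_by_protein,
            planted_genomes.focal_proteins,
        )
        for r in results:
            assert r.enriched == (r.ci_lower > 0)
            assert r.ci_lower <= r.diff <= r.ci_upper
        # conservation of counts
        assert sum(table.neighborhood.values()) == table.n1
        assert sum(table.background.values()) == table.n2

    def test_rank_direction_flag(self):
        table = DomainCountTable({"A": 30, "B": 5}, {"A": 10, "B": 40})
        desc = enrichment_analysis(table, rank_direction="descending")
        asc = enrichment_analysis(table, rank_direction="ascending")
        # same most-enriched-first ordering, opposite rank numbering
        assert [r.domain_id for r in desc] == [r.domain_id for r in asc]
        assert [r.rank for r in desc] == [1, 2]
        assert [r.rank for r in asc] == [2, 1]

    def test_planted_domain_detected(self, planted_genomes):
        _, results, _ = neighborhood_enrichment(
            list(planted_genomes.genomes),
            planted_genomes.hits_by_protein,
            planted_genomes.focal_proteins,
        )
        top = results[0]
        assert top.domain_id in planted_genomes.truth
        assert top.enriched
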