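"""Defense-island genomic-neighborhood enrichment statistics.

A focal gene's genomic neighborhood is the k ORFs upstream and k downstream
on the same contig (k = 10 by default).  Domain matches on neighborhood
proteins are filtered to top-scoring non-overlapping hits, tallied, and each
domain's proportion among neighborhood domain instances is compared with its
background proportion among all domain instances of the focal-gene-carrying
genomes.  The comparison uses the continuity-corrected confidence interval
for a difference of two proportions (the classical equal-proportions test),
with the Bonferroni-adjusted individual confidence level 1 - alpha/M for M
domains; a domain is called enriched when the whole interval lies above zero.
"""

from __future__ import annotations

from collections import Counter
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.stats import norm

from .architecture import DomainHit

__all__ = [
    "ORF",
    "GenomeAnnotation",
    "NeighborhoodWindow",
    "DomainCountTable",
    "EnrichmentResult",
    "extract_neighborhood",
    "select_top_nonoverlapping",
    "count_domains",
    "background_counts",
    "two_proportion_ci",
    "enrichment_analysis",
    "neighborhood_enrichment",
]


class ORF(NamedTuple):
    contig_id: str
    orf_index: int
    start: int
    end: int
    strand: str
    protein_id: str


@dataclass(frozen=True)
class GenomeAnnotation:
    """Ordered ORFs of one genome, grouped by contig."""

    genome_id: str
    contigs: dict[str, tuple[ORF, ...]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for contig_id, orfs in self.contigs.items():
            idx = [o.orf_index for o in orfs]
            if any(b <= a for a, b in zip(idx, idx[1:])):
                raise ValueError(f"orf_index not strictly increasing on {contig_id}")
            for o in orfs:
                if o.protein_id in seen:
                    raise ValueError(f"duplicate protein id {o.protein_id!r} in {self.genome_id}")
                seen.add(o.protein_id)

    def protein_ids(self) -> list[str]:
        return [o.protein_id for orfs in self.contigs.values() for o in orfs]

    def locate(self, protein_id: str) -> tuple[str, int]:
        """Contig id and list position of a protein's ORF."""
        for contig_id, orfs in self.contigs.items():
            for pos, o in enumerate(orfs):
                if o.protein_id == protein_id:
                    return contig_id, pos
        raise KeyError(f"protein {protein_id!r} not found in genome {self.genome_id}")


@dataclass(frozen=True)
class NeighborhoodWindow:
    focal_protein_id: str
    neighbor_protein_ids: tuple[str, ...]
    truncated: bool
    k: int

    def __post_init__(self) -> None:
        if len(self.neighbor_protein_ids) > 2 * self.k:
            raise ValueError("window larger than 2k neighbors")


def extract_neighborhood(
    genome: GenomeAnnotation, focal: str, k: int = 10
) -> NeighborhoodWindow:
    """The up-to-k ORFs on each side of the focal gene, focal excluded.

    ``truncated`` is set when a contig boundary cuts either side short.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    contig_id, pos = genome.locate(focal)
    orfs = genome.contigs[contig_id]
    lo = max(0, pos - k)
    hi = min(len(orfs), pos + k + 1)
    neighbors = tuple(
        o.protein_id for o in orfs[lo:hi] if o.protein_id != focal
    )
    truncated = (pos - lo) < k or (hi - 1 - pos) < k
    return NeighborhoodWindow(focal, neighbors, truncated, k)


def select_top_nonoverlapping(
    hits: Sequence[DomainHit], evalue_max: float = 1e-3
) -> list[DomainHit]:
    """Greedy top-scoring non-overlapping hit selection for one protein.

    Hits at or above the E-value threshold are discarded; the rest are taken
    in ascending E-value order (ties broken by envelope start, then domain id
    for determinism) and accepted iff they overlap no previously accepted hit.
    """
    passing = [h for h in hits if h.evalue < evalue_max]
    passing.sort(key=lambda h: (h.evalue, h.env_start, h.domain_id))
    accepted: list[DomainHit] = []
    for h in passing:
        if not any(h.overlaps(a) for a in accepted):
            accepted.append(h)
    return accepted


@dataclass(frozen=True)
class DomainCountTable:
    """Neighborhood (x1/n1) vs background (x2/n2) domain-instance counts."""

    neighborhood: dict[str, int]
    background: dict[str, int]

    @property
    def n1(self) -> int:
        return sum(self.neighborhood.values())

    @property
    def n2(self) -> int:
        return sum(self.background.values())

    def domains(self) -> list[str]:
        return sorted(set(self.neighborhood) | set(self.background))


def count_domains(
    windows: Sequence[NeighborhoodWindow],
    accepted_hits: Mapping[str, Sequence[DomainHit]],
    dedupe: bool = True,
) -> dict[str, int]:
    """Neighborhood-side domain-instance counts.

    A protein shared by overlapping windows is counted once when ``dedupe``
    is true (the default), avoiding double use of identical evidence.
    """
    counts: Counter[str] = Counter()
    if dedupe:
        proteins: Iterable[str] = sorted({p for w in windows for p in w.neighbor_protein_ids})
    else:
        proteins = [p for w in windows for p in w.neighbor_protein_ids]
    for pid in proteins:
        for h in accepted_hits.get(pid, ()):
            counts[h.domain_id] += 1
    return dict(counts)


def background_counts(
    genomes: Sequence[GenomeAnnotation],
    accepted_hits: Mapping[str, Sequence[DomainHit]],
    exclude_proteins: Iterable[str] = (),
) -> dict[str, int]:
    """Background domain-instance counts over whole proteomes.

    By default every protein of every genome contributes (neighborhood
    proteins included); ``exclude_proteins`` supports the alternative
    configuration that removes e.g. neighborhood members.
    """
    excluded = set(exclude_proteins)
    counts: Counter[str] = Counter()
    for g in genomes:
        for pid in g.protein_ids():
            if pid in excluded:
                continue
            for h in accepted_hits.get(pid, ()):
                counts[h.domain_id] += 1
    return dict(counts)


def _ci_arrays(x1, n1, x2, n2, conf_level: float, correct: bool):
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    p1 = x1 / n1
    p2 = x2 / n2
    diff = p1 - p2
    z = norm.ppf((1.0 + conf_level) / 2.0)
    se = np.sqrt(p1 * (1.0 - p1) / n1 + p2 * (1.0 - p2) / n2)
    if correct:
        cc = np.minimum(0.5 * (1.0 / n1 + 1.0 / n2), np.abs(diff))
    else:
        cc = 0.0
    width = z * se + cc
    return diff, np.maximum(diff - width, -1.0), np.minimum(diff + width, 1.0)


def two_proportion_ci(
    x1: int,
    n1: int,
    x2: int,
    n2: int,
    conf_level: float = 0.95,
    correct: bool = True,
) -> tuple[float, float, float]:
    """Confidence interval for p1 - p2 from the two-sample equal-proportions test.

    Matches the reference behaviour of the classical continuity-corrected
    interval: diff +/- (z * sqrt(p1(1-p1)/n1 + p2(1-p2)/n2) + CC) with
    CC = min(0.5 * (1/n1 + 1/n2), |diff|), clamped to [-1, 1].  Set
    ``correct=False`` for the plain Wald interval.

    Returns ``(diff, ci_lower, ci_upper)``.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("n1 and n2 must be positive (proportion undefined)")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("counts must satisfy 0 <= x <= n")
    if not 0.0 < conf_level < 1.0:
        raise ValueError("conf_level must be in (0, 1)")
    diff, lo, hi = _ci_arrays(x1, n1, x2, n2, conf_level, correct)
    return float(diff), float(lo), float(hi)


@dataclass(frozen=True)
class EnrichmentResult:
    domain_id: str
    x1: int
    n1: int
    x2: int
    n2: int
    p1: float
    p2: float
    diff: float
    ci_lower: float
    ci_upper: float
    conf_level: float
    enriched: bool
    rank: int


def enrichment_analysis(
    table: DomainCountTable,
    alpha: float = 0.05,
    rank_direction: str = "descending",
    correct: bool = True,
) -> list[EnrichmentResult]:
    """Per-domain Bonferroni-adjusted difference-of-proportions analysis.

    Each of the M distinct domains gets a CI at individual confidence level
    1 - alpha/M; a domain is enriched iff its interval lies entirely above
    zero.  Results are ranked by the CI lower bound — rank 1 is the largest
    (most enriched) bound under the default ``descending`` direction; pass
    ``ascending`` for the literal smallest-first ordering.  The returned list
    is always sorted most-enriched-first.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if rank_direction not in ("descending", "ascending"):
        raise ValueError(f"unknown rank_direction {rank_direction!r}")
    domains = table.domains()
    m = len(domains)
    if m == 0:
        return []
    n1, n2 = table.n1, table.n2
    if n1 == 0 or n2 == 0:
        raise ValueError("empty neighborhood or background count set")
    conf_level = 1.0 - alpha / m
    x1 = np.array([table.neighborhood.get(d, 0) for d in domains])
    x2 = np.array([table.background.get(d, 0) for d in domains])
    diff, lo, hi = _ci_arrays(x1, n1, x2, n2, conf_level, correct)

    order = sorted(range(m), key=lambda i: (-lo[i], domains[i]))
    results: list[EnrichmentResult] = []
    for out_pos, i in enumerate(order):
        rank = out_pos + 1 if rank_direction == "descending" else m - out_pos
        results.append(
            EnrichmentResult(
                domain_id=domains[i],
                x1=int(x1[i]),
                n1=n1,
                x2=int(x2[i]),
                n2=n2,
                p1=float(x1[i] / n1),
                p2=float(x2[i] / n2),
                diff=float(diff[i]),
                ci_lower=float(lo[i]),
                ci_upper=float(hi[i]),
                conf_level=conf_level,
                enriched=bool(lo[i] > 0.0),
                rank=rank,
            )
        )
    return results


def neighborhood_enrichment(
    genomes: Sequence[GenomeAnnotation],
    hits_by_protein: Mapping[str, Sequence[DomainHit]],
    focal_proteins: Mapping[str, Sequence[str]],
    k: int = 10,
    evalue_max: float = 1e-3,
    alpha: float = 0.05,
    rank_direction: str = "descending",
    correct: bool = True,
    dedupe_windows: bool = True,
    background_include_neighborhood: bool = True,
) -> tuple[DomainCountTable, list[EnrichmentResult], list[NeighborhoodWindow]]:
    """End-to-end neighborhood analysis on annotated genomes.

    ``focal_proteins`` maps genome id -> focal (GmrSD-like) protein ids.
    Only genomes carrying at least one focal gene contribute to the
    background.  Focal proteins themselves are excluded from neighborhood
    counts (they are the query, not its context).
    """
    genome_by_id = {g.genome_id: g for g in genomes}
    accepted: dict[str, list[DomainHit]] = {
        pid: select_top_nonoverlapping(hs, evalue_max=evalue_max)
        for pid, hs in hits_by_protein.items()
    }
    windows: list[NeighborhoodWindow] = []
    for genome_id in sorted(focal_proteins):
        genome = genome_by_id[genome_id]
        for focal in focal_proteins[genome_id]:
            windows.append(extract_neighborhood(genome, focal, k=k))

    neigh = count_domains(windows, accepted, dedupe=dedupe_windows)
    carrier_genomes = [genome_by_id[g] for g in sorted(focal_proteins) if focal_proteins[g]]
    if background_include_neighborhood:
        excluded: set[str] = set()
    else:
        excluded = {p for w in windows for p in w.neighbor_protein_ids}
    bg = background_counts(carrier_genomes, accepted, exclude_proteins=excluded)
    table = DomainCountTable(neighborhood=neigh, background=bg)
    results = enrichment_analysis(
        table, alpha=alpha, rank_direction=rank_direction, correct=correct
    )
    return table, results, windows
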