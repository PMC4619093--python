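"""Domain-architecture classification of GmrSD-family proteins.

GmrSD Type IV restriction systems are built from two domains: GmrS
(PFAM DUF262, a ParB/Srx-fold NTPase/putative nuclease) and GmrD
(PFAM DUF1524, an HNH-family endonuclease).  A family member is either a
double-domain fusion (DUF262 N-terminal of DUF1524), a single-domain GmrS
or GmrD protein, or an unrelated protein.  This module filters raw domain
hits, classifies proteins into those architectures, builds per-genome
inventories of the family, and applies the single-domain pairing rule that
merges a genome's lone GmrS-only and lone GmrD-only proteins into a
double-domain-like pseudo-fusion for joint analysis.
"""

from __future__ import annotations

import enum
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

__all__ = [
    "GMRS_DOMAIN",
    "GMRD_DOMAIN",
    "ArchClass",
    "DomainHit",
    "ProteinArchitecture",
    "GenomeInventory",
    "MergedPair",
    "accept_domain_hits",
    "classify_architecture",
    "build_inventory",
    "pair_single_domains",
]

#: PFAM family of the GmrS domain (PF03235).
GMRS_DOMAIN = "DUF262"
#: PFAM family of the GmrD domain (PF07510).
GMRD_DOMAIN = "DUF1524"


class ArchClass(enum.Enum):
    """Architecture classes of GmrSD-family proteins."""

    GMRS_ONLY = "GMRS_ONLY"
    GMRD_ONLY = "GMRD_ONLY"
    DOUBLE = "DOUBLE"
    OTHER = "OTHER"


@dataclass(frozen=True)
class DomainHit:
    """One domain match on a protein, hmmscan/HHsearch style.

    Envelope coordinates are 1-based and closed on input/output; internal
    arithmetic converts to 0-based half-open via :meth:`interval`.
    """

    protein_id: str
    domain_id: str
    env_start: int
    env_end: int
    evalue: float
    model_coverage: float

    def __post_init__(self) -> None:
        if self.env_start < 1 or self.env_end < self.env_start:
            raise ValueError(
                f"invalid envelope [{self.env_start}, {self.env_end}] "
                f"for {self.protein_id}/{self.domain_id}"
            )
        if not self.evalue > 0:
            raise ValueError(f"E-value must be positive, got {self.evalue}")
        if not 0.0 <= self.model_coverage <= 1.0:
            raise ValueError(f"model coverage must be in [0, 1], got {self.model_coverage}")

    def interval(self) -> tuple[int, int]:
        """Envelope as a 0-based half-open interval."""
        return self.env_start - 1, self.env_end

    def overlaps(self, other: "DomainHit") -> bool:
        a0, a1 = self.interval()
        b0, b1 = other.interval()
        return a0 < b1 and b0 < a1


@dataclass(frozen=True)
class ProteinArchitecture:
    protein_id: str
    klass: ArchClass
    extra_domains: tuple[str, ...] = ()
    s_region: tuple[int, int] | None = None  # 1-based closed
    d_region: tuple[int, int] | None = None
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class GenomeInventory:
    """Per-genome tally of GmrSD-family architectures (genome-inventory logic)."""

    genome_id: str
    n_double: int = 0
    n_s_only: int = 0
    n_d_only: int = 0
    n_other: int = 0

    @property
    def total(self) -> int:
        return self.n_double + self.n_s_only + self.n_d_only + self.n_other


@dataclass(frozen=True)
class MergedPair:
    """A genome's lone GmrS-only + lone GmrD-only proteins, concatenated S-then-D."""

    genome_id: str
    s_protein_id: str
    d_protein_id: str
    merged_sequence: str
    provenance: str = "merged"
    flags: tuple[str, ...] = ()

    @property
    def merged_id(self) -> str:
        return f"{self.genome_id}|{self.s_protein_id}+{self.d_protein_id}|merged"


def accept_domain_hits(
    hits: Iterable[DomainHit],
    evalue_max: float = 0.001,
    coverage_min: float = 0.8,
) -> list[DomainHit]:
    """Keep hits with E-value strictly below ``evalue_max`` and model coverage
    strictly above ``coverage_min``; order is preserved.

    Boundary values (E-value exactly 0.001, coverage exactly 0.8) are rejected.
    """
    return [h for h in hits if h.evalue < evalue_max and h.model_coverage > coverage_min]


def _union_span(hits: Sequence[DomainHit]) -> tuple[int, int]:
    # architecture treats repeated hits of one domain type as a single region
    return min(h.env_start for h in hits), max(h.env_end for h in hits)


def classify_architecture(accepted_hits: Sequence[DomainHit]) -> ProteinArchitecture:
    """Classify one protein's accepted hits into a GmrSD architecture.

    DUF262 present alone -> GMRS_ONLY; DUF1524 alone -> GMRD_ONLY; both, with
    the DUF262 region N-terminal of the DUF1524 region -> DOUBLE; neither ->
    OTHER.  Any other domain ids are reported as ``extra_domains``.  If the two
    core regions overlap (or appear in reversed order), the protein is flagged
    and classified by the higher-scoring (lower E-value) core hit.
    """
    if not accepted_hits:
        return ProteinArchitecture(protein_id="", klass=ArchClass.OTHER)
    pids = {h.protein_id for h in accepted_hits}
    if len(pids) != 1:
        raise ValueError(f"hits must belong to one protein, got {sorted(pids)}")
    (protein_id,) = pids

    s_hits = [h for h in accepted_hits if h.domain_id == GMRS_DOMAIN]
    d_hits = [h for h in accepted_hits if h.domain_id == GMRD_DOMAIN]
    extras = tuple(
        dict.fromkeys(
            h.domain_id
            for h in accepted_hits
            if h.domain_id not in (GMRS_DOMAIN, GMRD_DOMAIN)
        )
    )
    flags: list[str] = []

    s_region = _union_span(s_hits) if s_hits else None
    d_region = _union_span(d_hits) if d_hits else None

    if s_hits and d_hits:
        if s_region[1] < d_region[0]:
            klass = ArchClass.DOUBLE
        else:
            # overlapping (or reversed) core regions: keep the better-scoring one
            flags.append("core_overlap")
            best_s = min(h.evalue for h in s_hits)
            best_d = min(h.evalue for h in d_hits)
            if best_s <= best_d:
                klass, d_region = ArchClass.GMRS_ONLY, None
            else:
                klass, s_region = ArchClass.GMRD_ONLY, None
    elif s_hits:
        klass = ArchClass.GMRS_ONLY
    elif d_hits:
        klass = ArchClass.GMRD_ONLY
    else:
        klass = ArchClass.OTHER

    return ProteinArchitecture(
        protein_id=protein_id,
        klass=klass,
        extra_domains=extras,
        s_region=s_region,
        d_region=d_region,
        flags=tuple(flags),
    )


def build_inventory(
    by_genome: Mapping[str, Sequence[ProteinArchitecture]],
) -> list[GenomeInventory]:
    """Count architectures per genome.

    Raises if a protein id appears under two genomes (each protein must map to
    exactly one genome).
    """
    seen: dict[str, str] = {}
    out: list[GenomeInventory] = []
    for genome_id in by_genome:
        counts = {k: 0 for k in ArchClass}
        for arch in by_genome[genome_id]:
            prev = seen.setdefault(arch.protein_id, genome_id)
            if prev != genome_id:
                raise ValueError(
                    f"protein {arch.protein_id!r} assigned to both {prev!r} and {genome_id!r}"
                )
            counts[arch.klass] += 1
        out.append(
            GenomeInventory(
                genome_id=genome_id,
                n_double=counts[ArchClass.DOUBLE],
                n_s_only=counts[ArchClass.GMRS_ONLY],
                n_d_only=counts[ArchClass.GMRD_ONLY],
                n_other=counts[ArchClass.OTHER],
            )
        )
    return out


def pair_single_domains(
    inventories: Sequence[GenomeInventory],
    by_genome: Mapping[str, Sequence[ProteinArchitecture]],
    sequences: Mapping[str, str],
) -> list[MergedPair]:
    """Merge each genome's lone GmrS-only and lone GmrD-only proteins.

    A pair is emitted for a genome iff it contains exactly one GMRS_ONLY and
    exactly one GMRD_ONLY protein; the merged sequence is the S residues
    followed by the D residues.  Pairing proceeds even when the genome also
    encodes double-domain proteins, but such pairs are flagged
    ``double_present`` for auditability.
    """
    pairs: list[MergedPair] = []
    for inv in inventories:
        if inv.n_s_only != 1 or inv.n_d_only != 1:
            continue
        archs = by_genome.get(inv.genome_id, ())
        s_arch = next(a for a in archs if a.klass is ArchClass.GMRS_ONLY)
        d_arch = next(a for a in archs if a.klass is ArchClass.GMRD_ONLY)
        s_seq = sequences[s_arch.protein_id]
        d_seq = sequences[d_arch.protein_id]
        flags = ("double_present",) if inv.n_double > 0 else ()
        pairs.append(
            MergedPair(
                genome_id=inv.genome_id,
                s_protein_id=s_arch.protein_id,
                d_protein_id=d_arch.protein_id,
                merged_sequence=s_seq + d_seq,
                flags=flags,
            )
        )
    return pairs
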