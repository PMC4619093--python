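"""Synthetic annotated genomes, protein families and tree pairs with planted truth.

Every downstream stage of the pipeline is exercised against data generated
here, with the planted structure recorded exactly:

* :func:`simulate_genomes` — genomes of ordered ORFs whose proteins carry
  domain hits drawn from a background vocabulary, with a chosen subset of
  domains enriched (odds multiplied) inside the +/-k-ORF windows around
  focal GmrSD-like genes;
* :func:`simulate_family` — a protein family of double-domain fusions,
  pairable single-domain members and orphans, with degenerate signature
  motifs planted at known coordinates under a tunable conservation level;
* :func:`simulate_tree_pair` — a tree and its derivative after a chosen
  number of random subtree-prune-regraft (SPR) moves, with per-split
  support values, emulating two leaf-associated domain phylogenies of
  controlled discordance;
* :func:`simulate_merge_instance` — paired alignments sharing a backbone,
  for exercising the alignment-merge bookkeeping.

All generators are deterministic functions of their spec (fixed seed =>
bit-identical output).
"""

from __future__ import annotations

import copy
from collections.abc import Callable, Sequence
from dataclasses import dataclass, field

import numpy as np

from .architecture import GMRD_DOMAIN, GMRS_DOMAIN, ArchClass, DomainHit
from .coevolution import SupportedTree
from .enrichment import ORF, GenomeAnnotation
from .motifs import AMINO_ACIDS, SIGNATURE_MOTIFS, MotifPattern, compile_motif
from .msa import GAP, MSA

__all__ = [
    "GenomeSimSpec",
    "FamilySimSpec",
    "TreeSimSpec",
    "MotifPlacement",
    "SimulatedGenomes",
    "FamilyMember",
    "SimulatedFamily",
    "SimulatedTreePair",
    "simulate_genomes",
    "simulate_family",
    "simulate_tree_pair",
    "simulate_merge_instance",
    "default_motif_placements",
]

_AA = np.array(list(AMINO_ACIDS))


# ---------------------------------------------------------------------------
# annotated genomes with planted neighborhood enrichment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeSimSpec:
    """Study conditions for the genomic-neighborhood simulation.

    Defaults emulate the scale of the real survey (hundreds of focal genes
    over ~100 genomes, near-complete +/-10-ORF windows) at desk size: 100
    genomes of one 60-ORF contig each, a 50-domain vocabulary at uniform
    background frequencies, and one focal gene per genome.
    """

    n_genomes: int = 100
    contigs_per_genome: int = 1
    orfs_per_contig: int = 60
    domain_vocab_size: int = 50
    background_weights: tuple[float, ...] | None = None
    focal_per_genome: int = 1
    enriched_domains: dict[str, float] = field(default_factory=dict)
    window_k: int = 10
    hits_per_protein: tuple[int, int] = (1, 1)
    seed: int = 0

    def domain_ids(self) -> list[str]:
        return [f"D{i:03d}" for i in range(self.domain_vocab_size)]

    def weights(self) -> np.ndarray:
        if self.background_weights is None:
            return np.full(self.domain_vocab_size, 1.0 / self.domain_vocab_size)
        return np.asarray(self.background_weights, dtype=float)

    def validate(self) -> None:
        if min(self.n_genomes, self.contigs_per_genome, self.orfs_per_contig) < 1:
            raise ValueError("genome/contig/ORF counts must be positive")
        if self.domain_vocab_size < 1:
            raise ValueError("domain vocabulary must be non-empty")
        if self.window_k < 1:
            raise ValueError("window_k must be >= 1")
        w = self.weights()
        if len(w) != self.domain_vocab_size:
            raise ValueError("background_weights length must equal domain_vocab_size")
        if np.any(w < 0) or abs(float(w.sum()) - 1.0) > 1e-12:
            raise ValueError("background_weights must be non-negative and sum to 1 (+/- 1e-12)")
        known = set(self.domain_ids())
        for dom, mult in self.enriched_domains.items():
            if dom not in known:
                raise ValueError(f"enriched domain {dom!r} not in vocabulary")
            if mult < 1.0:
                raise ValueError(f"enrichment multiplier for {dom!r} must be >= 1")
        lo, hi = self.hits_per_protein
        if not (0 <= lo <= hi <= 3):
            raise ValueError("hits_per_protein must satisfy 0 <= min <= max <= 3")
        if self.focal_per_genome < 0:
            raise ValueError("focal_per_genome must be >= 0")


@dataclass(frozen=True)
class SimulatedGenomes:
    spec: GenomeSimSpec
    genomes: tuple[GenomeAnnotation, ...]
    hits_by_protein: dict[str, tuple[DomainHit, ...]]
    focal_proteins: dict[str, tuple[str, ...]]
    truth: frozenset[str]

    def all_hits(self) -> list[DomainHit]:
        return [h for hs in self.hits_by_protein.values() for h in hs]


def _place_focals(rng: np.random.Generator, spec: GenomeSimSpec) -> list[tuple[int, int]]:
    """(contig, position) per focal gene, windows kept non-overlapping.

    Focal positions within one contig are at least 2k+1 ORFs apart so that
    calibration tests see independent windows.
    """
    min_sep = 2 * spec.window_k + 1
    for _ in range(10_000):
        picks = sorted(
            (int(rng.integers(spec.contigs_per_genome)), int(rng.integers(spec.orfs_per_contig)))
            for _ in range(spec.focal_per_genome)
        )
        ok = all(
            c1 != c2 or abs(p1 - p2) >= min_sep
            for (c1, p1), (c2, p2) in zip(picks, picks[1:])
        )
        if ok:
            return picks
    raise ValueError("cannot place focal genes with non-overlapping windows; reduce focal_per_genome")


def simulate_genomes(spec: GenomeSimSpec) -> SimulatedGenomes:
    """Generate annotated genomes with planted neighborhood enrichment.

    Every non-focal protein draws 0-3 domain hits (one by default) from the
    background vocabulary; proteins within ``window_k`` ORFs of a focal gene
    draw instead from odds-multiplied weights for the enriched domains.
    Focal proteins themselves carry a DUF262 + DUF1524 (double-domain GmrSD)
    signature.  The returned truth set contains exactly the planted domains
    (multiplier > 1).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    domain_ids = spec.domain_ids()
    w = spec.weights()
    w_win = w.copy()
    for dom, mult in spec.enriched_domains.items():
        w_win[domain_ids.index(dom)] *= mult
    w_win = w_win / w_win.sum()

    lo_hits, hi_hits = spec.hits_per_protein
    genomes: list[GenomeAnnotation] = []
    hits_by_protein: dict[str, tuple[DomainHit, ...]] = {}
    focal_proteins: dict[str, tuple[str, ...]] = {}

    for gi in range(spec.n_genomes):
        genome_id = f"G{gi:04d}"
        focal_sites = _place_focals(rng, spec)
        contigs: dict[str, tuple[ORF, ...]] = {}
        focals: list[str] = []
        for ci in range(spec.contigs_per_genome):
            contig_id = f"{genome_id}c{ci}"
            n = spec.orfs_per_contig
            focal_pos = {p for c, p in focal_sites if c == ci}
            in_window = np.zeros(n, dtype=bool)
            for p in focal_pos:
                in_window[max(0, p - spec.window_k) : p + spec.window_k + 1] = True
            orfs = []
            for oi in range(n):
                pid = f"{genome_id}_c{ci}_p{oi:04d}"
                strand = "+" if (oi % 2 == 0) else "-"
                orfs.append(ORF(contig_id, oi, oi * 1000 + 1, oi * 1000 + 900, strand, pid))
                if oi in focal_pos:
                    focals.append(pid)
                    hits_by_protein[pid] = (
                        DomainHit(pid, GMRS_DOMAIN, 1, 280, 1e-30, 0.95),
                        DomainHit(pid, GMRD_DOMAIN, 301, 580, 1e-30, 0.95),
                    )
                    continue
                n_hits = int(rng.integers(lo_hits, hi_hits + 1))
                weights = w_win if (in_window[oi] and oi not in focal_pos) else w
                hs = []
                for j in range(n_hits):
                    dom = domain_ids[int(rng.choice(spec.domain_vocab_size, p=weights))]
                    length = int(rng.integers(80, 201))
                    start = j * 250 + 1
                    hs.append(
                        DomainHit(
                            pid,
                            dom,
                            start,
                            start + length - 1,
                            float(10.0 ** rng.uniform(-30.0, -5.0)),
                            float(rng.uniform(0.85, 1.0)),
                        )
                    )
                hits_by_protein[pid] = tuple(hs)
            contigs[contig_id] = tuple(orfs)
        genomes.append(GenomeAnnotation(genome_id=genome_id, contigs=contigs))
        focal_proteins[genome_id] = tuple(focals)

    truth = frozenset(d for d, m in spec.enriched_domains.items() if m > 1.0)
    return SimulatedGenomes(
        spec=spec,
        genomes=tuple(genomes),
        hits_by_protein=hits_by_protein,
        focal_proteins=focal_proteins,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# protein family with planted motifs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MotifPlacement:
    """A motif planted at a fixed 0-based offset within the S or D region."""

    pattern: MotifPattern
    region: str  # "S" or "D"
    offset: int

    def __post_init__(self) -> None:
        if self.region not in ("S", "D"):
            raise ValueError(f"region must be 'S' or 'D', got {self.region!r}")
        if self.offset < 0:
            raise ValueError("offset must be >= 0")


def default_motif_placements() -> tuple[MotifPlacement, ...]:
    """The five GmrS/GmrD signature motifs at their domain-relative offsets.

    Offsets echo where the motifs sit in the real domains: the DGQQR motif
    inside the N-terminal conserved region of GmrS, the three GmrD motifs
    inside the conserved 112-190 stretch, and the weak W motif near 211-231.
    """
    p = {name: compile_motif(text, name=name) for name, text in SIGNATURE_MOTIFS.items()}
    return (
        MotifPlacement(p["GmrS-DGQQR"], "S", 20),
        MotifPlacement(p["GmrD-EHxPQ"], "D", 111),
        MotifPlacement(p["GmrD-LGNL"], "D", 129),
        MotifPlacement(p["GmrD-NxxFxxKK"], "D", 149),
        MotifPlacement(p["GmrD-W"], "D", 210),
    )


@dataclass(frozen=True)
class FamilySimSpec:
    """Study conditions for the protein-family simulation.

    ``n_double`` fusion proteins, ``n_pairs`` genomes each contributing one
    GmrS-only plus one GmrD-only protein, and ``n_orphans`` unpaired
    single-domain members (alternating S / D), mirroring the family's
    dominant double-domain composition.  ``seq_length_range`` bounds the
    total double-domain length; the S and D regions each span half the
    minimum and the remainder is a variable C-terminal tail.
    """

    n_double: int = 40
    n_pairs: int = 5
    n_orphans: int = 10
    motif_placements: tuple[MotifPlacement, ...] = field(
        default_factory=default_motif_placements
    )
    conservation_level: float = 1.0
    seq_length_range: tuple[int, int] = (600, 700)
    seed: int = 0

    @property
    def s_len(self) -> int:
        return self.seq_length_range[0] // 2

    @property
    def d_len(self) -> int:
        return self.seq_length_range[0] - self.s_len

    def validate(self) -> None:
        if min(self.n_double, self.n_pairs, self.n_orphans) < 0:
            raise ValueError("family counts must be >= 0")
        if not 0.0 <= self.conservation_level <= 1.0:
            raise ValueError("conservation_level must be in [0, 1]")
        lo, hi = self.seq_length_range
        if not 2 <= lo <= hi:
            raise ValueError("invalid seq_length_range")
        for pl in self.motif_placements:
            region_len = self.s_len if pl.region == "S" else self.d_len
            if pl.offset + len(pl.pattern) > region_len:
                raise ValueError(
                    f"motif {pl.pattern.name!r} does not fit in region {pl.region} "
                    f"(offset {pl.offset} + length {len(pl.pattern)} > {region_len})"
                )


@dataclass(frozen=True)
class MotifTruth:
    pattern_name: str
    start: int  # 1-based on the ungapped sequence
    end: int


@dataclass(frozen=True)
class FamilyMember:
    seq_id: str
    genome_id: str
    label: ArchClass
    sequence: str
    hits: tuple[DomainHit, ...]
    motifs: tuple[MotifTruth, ...]


@dataclass(frozen=True)
class SimulatedFamily:
    spec: FamilySimSpec
    members: tuple[FamilyMember, ...]

    def sequences(self) -> dict[str, str]:
        return {m.seq_id: m.sequence for m in self.members}

    def hits_by_protein(self) -> dict[str, tuple[DomainHit, ...]]:
        return {m.seq_id: m.hits for m in self.members}

    def by_genome(self) -> dict[str, list[FamilyMember]]:
        out: dict[str, list[FamilyMember]] = {}
        for m in self.members:
            out.setdefault(m.genome_id, []).append(m)
        return out

    def alignment(self) -> MSA:
        """Gap-padded family alignment (S block, D block, variable tail).

        Single-domain members span only their region; length variation is
        confined to the C-terminal tail, so planted motif columns line up
        across all rows.
        """
        s_len, d_len = self.spec.s_len, self.spec.d_len
        width = max(
            (len(m.sequence) for m in self.members if m.label is ArchClass.DOUBLE),
            default=s_len + d_len,
        )
        pairs = []
        for m in self.members:
            if m.label is ArchClass.DOUBLE:
                row = m.sequence + GAP * (width - len(m.sequence))
            elif m.label is ArchClass.GMRS_ONLY:
                row = m.sequence + GAP * (width - len(m.sequence))
            else:  # GMRD_ONLY
                row = GAP * s_len + m.sequence + GAP * (width - s_len - len(m.sequence))
            pairs.append((m.seq_id, row))
        return MSA.from_pairs(pairs)

    def motif_columns(self) -> dict[str, tuple[int, int]]:
        """1-based alignment-column range of each planted motif."""
        out: dict[str, tuple[int, int]] = {}
        for pl in self.spec.motif_placements:
            base = 0 if pl.region == "S" else self.spec.s_len
            start = base + pl.offset + 1
            out[pl.pattern.name] = (start, start + len(pl.pattern) - 1)
        return out


def _realize_pattern(rng: np.random.Generator, pattern: MotifPattern) -> str:
    """Choose one concrete residue per element (the family's consensus)."""
    out = []
    for e in pattern.elements:
        choices = AMINO_ACIDS if e == "x" else e
        out.append(choices[int(rng.integers(len(choices)))])
    return "".join(out)


def _random_residues(rng: np.random.Generator, n: int) -> np.ndarray:
    return _AA[rng.integers(0, len(_AA), size=n)]


def _plant(
    rng: np.random.Generator,
    block: np.ndarray,
    offset: int,
    realized: str,
    conservation: float,
) -> None:
    """Write a motif into a residue block, per-column degraded at rate 1-c.

    Each motif column keeps the family consensus residue with probability
    ``conservation``; otherwise it is redrawn uniformly from the 20-letter
    alphabet (possibly coinciding with the consensus), so the modal-residue
    frequency at a motif column is c + (1-c)/20 in expectation.
    """
    for i, res in enumerate(realized):
        if rng.random() < conservation:
            block[offset + i] = res
        else:
            block[offset + i] = AMINO_ACIDS[int(rng.integers(20))]


def simulate_family(spec: FamilySimSpec) -> SimulatedFamily:
    """Generate a GmrSD-like protein family with planted signature motifs.

    Double-domain members carry the S-region motifs followed by the D-region
    motifs; GmrS-only members carry only S motifs, GmrD-only members only D
    motifs.  Domain hits are noise-free (DUF262 over the S region, DUF1524
    over the D region).  Truth lists the exact planted coordinates per
    sequence.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    s_len, d_len = spec.s_len, spec.d_len
    tail_max = spec.seq_length_range[1] - spec.seq_length_range[0]
    realized = {
        pl.pattern.name: _realize_pattern(rng, pl.pattern) for pl in spec.motif_placements
    }
    s_placements = [pl for pl in spec.motif_placements if pl.region == "S"]
    d_placements = [pl for pl in spec.motif_placements if pl.region == "D"]

    def make_block(length: int, placements: list[MotifPlacement]) -> tuple[np.ndarray, list[MotifTruth]]:
        block = _random_residues(rng, length)
        truths = []
        for pl in placements:
            _plant(rng, block, pl.offset, realized[pl.pattern.name], spec.conservation_level)
            truths.append(
                MotifTruth(pl.pattern.name, pl.offset + 1, pl.offset + len(pl.pattern))
            )
        return block, truths

    def shift(truths: list[MotifTruth], by: int) -> list[MotifTruth]:
        return [MotifTruth(t.pattern_name, t.start + by, t.end + by) for t in truths]

    members: list[FamilyMember] = []

    def s_hit(pid: str) -> DomainHit:
        return DomainHit(pid, GMRS_DOMAIN, 1, s_len, 1e-20, 0.95)

    def d_hit(pid: str, at: int = 0) -> DomainHit:
        return DomainHit(pid, GMRD_DOMAIN, at + 1, at + d_len, 1e-20, 0.95)

    for i in range(spec.n_double):
        pid, genome = f"double{i:04d}", f"FGdbl{i:04d}"
        s_block, s_truth = make_block(s_len, s_placements)
        d_block, d_truth = make_block(d_len, d_placements)
        tail = _random_residues(rng, int(rng.integers(0, tail_max + 1)))
        seq = "".join(s_block) + "".join(d_block) + "".join(tail)
        members.append(
            FamilyMember(
                pid, genome, ArchClass.DOUBLE, seq,
                (s_hit(pid), d_hit(pid, at=s_len)),
                tuple(s_truth + shift(d_truth, s_len)),
            )
        )

    for i in range(spec.n_pairs):
        genome = f"FGpair{i:04d}"
        s_block, s_truth = make_block(s_len, s_placements)
        pid_s = f"pairS{i:04d}"
        members.append(
            FamilyMember(pid_s, genome, ArchClass.GMRS_ONLY, "".join(s_block),
                         (s_hit(pid_s),), tuple(s_truth))
        )
        d_block, d_truth = make_block(d_len, d_placements)
        pid_d = f"pairD{i:04d}"
        members.append(
            FamilyMember(pid_d, genome, ArchClass.GMRD_ONLY, "".join(d_block),
                         (d_hit(pid_d),), tuple(d_truth))
        )

    for i in range(spec.n_orphans):
        genome = f"FGorph{i:04d}"
        if i % 2 == 0:
            block, truth = make_block(s_len, s_placements)
            pid = f"orphS{i:04d}"
            members.append(
                FamilyMember(pid, genome, ArchClass.GMRS_ONLY, "".join(block),
                             (s_hit(pid),), tuple(truth))
            )
        else:
            block, truth = make_block(d_len, d_placements)
            pid = f"orphD{i:04d}"
            members.append(
                FamilyMember(pid, genome, ArchClass.GMRD_ONLY, "".join(block),
                             (d_hit(pid),), tuple(truth))
            )

    return SimulatedFamily(spec=spec, members=tuple(members))


# ---------------------------------------------------------------------------
# tree pairs with controlled discordance
# ---------------------------------------------------------------------------


class _Node:
    __slots__ = ("children", "leaf", "support")

    def __init__(self, leaf: str | None = None):
        self.children: list["_Node"] = []
        self.leaf = leaf
        self.support: float | None = None


def _edges(root: _Node) -> list[tuple[_Node, _Node]]:
    """Parent/child edge list in deterministic preorder."""
    out: list[tuple[_Node, _Node]] = []

    def walk(n: _Node) -> None:
        for c in n.children:
            out.append((n, c))
            walk(c)

    walk(root)
    return out


def _random_topology(rng: np.random.Generator, leaf_names: Sequence[str]) -> _Node:
    """Random unrooted binary topology by sequential random edge attachment."""
    root = _Node()
    root.children = [_Node(leaf_names[0]), _Node(leaf_names[1]), _Node(leaf_names[2])]
    for name in leaf_names[3:]:
        edges = _edges(root)
        parent, child = edges[int(rng.integers(len(edges)))]
        mid = _Node()
        parent.children[parent.children.index(child)] = mid
        mid.children = [child, _Node(name)]
    return root


def _prune(root: _Node, parent: _Node, child: _Node) -> _Node:
    """Detach ``child``'s subtree; suppress the degree-2 node left behind.

    Returns the (possibly new) root of the remaining tree.
    """
    parent.children.remove(child)
    if parent is root:
        if len(root.children) == 1:
            return root.children[0]
        return root
    if len(parent.children) == 1:
        # find grandparent by search (trees are tiny)
        def find(n: _Node) -> _Node | None:
            for c in n.children:
                if c is parent:
                    return n
                got = find(c)
                if got is not None:
                    return got
            return None

        grand = find(root)
        assert grand is not None
        grand.children[grand.children.index(parent)] = parent.children[0]
    return root


def _spr(root: _Node, rng: np.random.Generator) -> _Node:
    """One SPR move chosen uniformly over valid (prune-edge, regraft-edge) pairs."""
    edges = _edges(root)
    candidates: list[tuple[int, int]] = []  # (prune edge index, n regraft edges)
    for i, (p, c) in enumerate(edges):
        trial_root = copy.deepcopy(root)
        trial_edges = _edges(trial_root)
        tp, tc = trial_edges[i]
        remaining = _prune(trial_root, tp, tc)
        n_regraft = len(_edges(remaining))
        if n_regraft >= 1:
            candidates.append((i, n_regraft))
    total = sum(n for _, n in candidates)
    if total == 0:
        raise ValueError("no valid SPR move on this tree")
    pick = int(rng.integers(total))
    for i, n in candidates:
        if pick < n:
            regraft_idx = pick
            prune_idx = i
            break
        pick -= n
    parent, child = _edges(root)[prune_idx]
    root = _prune(root, parent, child)
    u, h = _edges(root)[regraft_idx]
    mid = _Node()
    u.children[u.children.index(h)] = mid
    mid.children = [h, child]
    return root


def _assign_supports(
    root: _Node, rng: np.random.Generator, sampler: Callable[[np.random.Generator], float]
) -> None:
    def walk(n: _Node, is_root: bool) -> None:
        if not is_root and n.children:
            n.support = float(sampler(rng))
        for c in n.children:
            walk(c, False)

    walk(root, True)


def _newick(root: _Node, rename: Callable[[str], str] = lambda s: s) -> str:
    def fmt(n: _Node) -> str:
        if n.leaf is not None:
            return rename(n.leaf)
        inner = ",".join(fmt(c) for c in n.children)
        label = "" if n.support is None else f"{n.support:.4f}"
        return f"({inner}){label}"

    return fmt(root) + ";"


def _uniform_support(rng: np.random.Generator) -> float:
    return float(rng.uniform(0.0, 1.0))


@dataclass(frozen=True)
class TreeSimSpec:
    """Conditions for the coevolving-tree-pair simulation."""

    n_leaves: int = 20
    n_spr: int = 0
    support_distribution: Callable[[np.random.Generator], float] = _uniform_support
    seed: int = 0

    def validate(self) -> None:
        if self.n_leaves < 4:
            raise ValueError("n_leaves must be >= 4 (no internal splits otherwise)")
        if self.n_spr < 0:
            raise ValueError("n_spr must be >= 0")


@dataclass(frozen=True)
class SimulatedTreePair:
    spec: TreeSimSpec
    tree_s: SupportedTree
    tree_d: SupportedTree
    association: tuple[tuple[str, str], ...]
    newick_s: str
    newick_d: str


def simulate_tree_pair(spec: TreeSimSpec) -> SimulatedTreePair:
    """A GmrS-like tree and its GmrD-like counterpart after ``n_spr`` SPR moves.

    Leaf ``S####`` of the first tree is associated with leaf ``D####`` of the
    second; internal-split supports are drawn from ``support_distribution``
    independently for each tree.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    names = [f"P{i:04d}" for i in range(spec.n_leaves)]
    base = _random_topology(rng, names)
    derived = copy.deepcopy(base)
    for _ in range(spec.n_spr):
        derived = _spr(derived, rng)
    _assign_supports(base, rng, spec.support_distribution)
    _assign_supports(derived, rng, spec.support_distribution)
    newick_s = _newick(base, rename=lambda s: "S" + s[1:])
    newick_d = _newick(derived, rename=lambda s: "D" + s[1:])
    assoc = tuple((f"S{i:04d}", f"D{i:04d}") for i in range(spec.n_leaves))
    return SimulatedTreePair(
        spec=spec,
        tree_s=SupportedTree.from_newick(newick_s),
        tree_d=SupportedTree.from_newick(newick_d),
        association=assoc,
        newick_s=newick_s,
        newick_d=newick_d,
    )


# ---------------------------------------------------------------------------
# random alignment-merge instances
# ---------------------------------------------------------------------------


def simulate_merge_instance(
    seed: int,
    n_backbone: int = 3,
    n_add_a: int = 2,
    n_add_b: int = 2,
    n_cols: int = 14,
    max_insert: int = 3,
) -> tuple[MSA, MSA, list[str]]:
    """Two random alignments sharing a backbone, for merge round-trip tests.

    The backbone alignment has ``n_cols`` columns; alignment A adds
    ``n_add_a`` rows (and random insert columns where those rows overflow),
    alignment B likewise.  Returns ``(aln_a, aln_b, backbone_ids)``.
    """
    rng = np.random.default_rng(seed)
    backbone_ids = [f"bb{i}" for i in range(n_backbone)]

    # backbone alignment: random residues with some gaps, no all-gap column
    bb_rows = []
    for _ in range(n_backbone):
        row = ["".join(_random_residues(rng, 1)) if rng.random() < 0.8 else GAP
               for _ in range(n_cols)]
        bb_rows.append(row)
    for j in range(n_cols):
        if all(r[j] == GAP for r in bb_rows):
            bb_rows[int(rng.integers(n_backbone))][j] = str(_random_residues(rng, 1)[0])

    def extend(prefix: str, n_add: int) -> MSA:
        # per-junction insert lengths demanded by each added row
        ins = rng.integers(0, max_insert + 1, size=(n_add, n_cols + 1))
        ins[rng.random(size=ins.shape) < 0.6] = 0
        widths = ins.max(axis=0) if n_add else np.zeros(n_cols + 1, dtype=int)
        pairs: list[tuple[str, str]] = []
        for sid, row in zip(backbone_ids, bb_rows):
            cells = []
            for j in range(n_cols + 1):
                cells.append(GAP * int(widths[j]))
                if j < n_cols:
                    cells.append(row[j])
            pairs.append((sid, "".join(cells)))
        for r in range(n_add):
            cells = []
            for j in range(n_cols + 1):
                k = int(ins[r, j])
                cells.append("".join(_random_residues(rng, k)) + GAP * (int(widths[j]) - k))
                if j < n_cols:
                    cells.append(str(_random_residues(rng, 1)[0]) if rng.random() < 0.7 else GAP)
            pairs.append((f"{prefix}{r}", "".join(cells)))
        return MSA.from_pairs(pairs)

    return extend("a", n_add_a), extend("b", n_add_b), backbone_ids
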