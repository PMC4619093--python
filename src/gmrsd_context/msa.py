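"""Multiple-alignment containers, profile merging and column conservation.

The merge operation implements the bookkeeping used to combine two family
alignments that share a common backbone of double-domain sequences: one
alignment extends the backbone with GmrS-only sequences, the other with
GmrD-only sequences.  Columns contributed by the added sequences (columns in
which every backbone row is a gap) are re-inserted into a single merged
alignment as equal-length gap stretches applied identically to every backbone
sequence, so that single-domain representatives longer than their region fit
without disturbing backbone column homology.
"""

from __future__ import annotations

from collections import Counter
from collections.abc import Iterable, Sequence
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = ["GAP", "MSA", "ConservationProfile", "merge_alignments", "conservation_profile"]

GAP = "-"


@dataclass(frozen=True)
class MSA:
    """An immutable multiple sequence alignment (ordered id/row pairs)."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids in alignment")
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            raise ValueError(f"ragged alignment, widths {sorted(widths)}")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "MSA":
        ids, rows = zip(*pairs) if pairs else ((), ())
        return cls(tuple(ids), tuple(rows))

    @classmethod
    def from_fasta(cls, path: str | Path) -> "MSA":
        return cls.from_pairs(
            [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
        )

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(row), id=sid, description="")
            for sid, row in zip(self.ids, self.rows)
        ]
        SeqIO.write(records, str(path), "fasta")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def width(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, seq_id: str) -> str:
        return self.rows[self.ids.index(seq_id)]

    def ungapped(self, seq_id: str) -> str:
        return self.row(seq_id).replace(GAP, "")

    def restrict(self, keep_ids: Iterable[str]) -> "MSA":
        keep = set(keep_ids)
        return MSA.from_pairs(
            [(i, r) for i, r in zip(self.ids, self.rows) if i in keep]
        )

    def drop_allgap_columns(self) -> "MSA":
        if not self.rows:
            return self
        keep = [j for j in range(self.width) if any(r[j] != GAP for r in self.rows)]
        return MSA(self.ids, tuple("".join(r[j] for j in keep) for r in self.rows))

    def column(self, j: int) -> str:
        return "".join(r[j] for r in self.rows)


def _backbone_layout(aln: MSA, backbone_ids: set[str]) -> tuple[MSA, list[int]]:
    """Backbone-restricted alignment with its all-gap columns removed, plus the
    indices of the retained (backbone) columns in the original alignment."""
    sub = aln.restrict(backbone_ids)
    if not sub.rows:
        raise ValueError("no backbone rows in alignment")
    cols = [j for j in range(sub.width) if any(r[j] != GAP for r in sub.rows)]
    ref = MSA(sub.ids, tuple("".join(r[j] for j in cols) for r in sub.rows))
    return ref, cols


def _insert_blocks(aln: MSA, backbone_cols: list[int]) -> list[list[int]]:
    """Original-alignment column indices of the insert columns at each of the
    ``len(backbone_cols) + 1`` junctions (before, between, after)."""
    blocks: list[list[int]] = []
    prev = -1
    for c in backbone_cols + [aln.width]:
        blocks.append(list(range(prev + 1, c)))
        prev = c
    return blocks


def merge_alignments(aln_a: MSA, aln_b: MSA, backbone_ids: Iterable[str]) -> MSA:
    """Merge two alignments that share an identical backbone sub-alignment.

    Preconditions: every backbone id occurs in both alignments and its
    ungapped sequence is identical in the two; the backbone portions of the
    two alignments (backbone rows, all-gap columns removed) agree column for
    column.  The merged alignment contains every id of A and of B exactly
    once; at each backbone junction the inserted padding is a single gap
    stretch of the maximal overflow required by either side's added
    sequences, applied identically to every backbone row.
    """
    backbone = set(backbone_ids)
    missing = [i for i in backbone if i not in aln_a.ids or i not in aln_b.ids]
    if missing:
        raise ValueError(f"backbone ids missing from an alignment: {sorted(missing)}")
    for sid in sorted(backbone):
        if aln_a.ungapped(sid) != aln_b.ungapped(sid):
            raise ValueError(f"backbone sequence differs between alignments: {sid!r}")

    ref_a, cols_a = _backbone_layout(aln_a, backbone)
    ref_b, cols_b = _backbone_layout(aln_b, backbone)
    order = sorted(backbone)
    if {i: ref_a.row(i) for i in order} != {i: ref_b.row(i) for i in order}:
        raise ValueError("backbone portions of the two alignments are not column-identical")

    blocks_a = _insert_blocks(aln_a, cols_a)
    blocks_b = _insert_blocks(aln_b, cols_b)
    n_cols = len(cols_a)
    widths = [max(len(a), len(b)) for a, b in zip(blocks_a, blocks_b)]

    def rebuild(row: str, blocks: list[list[int]], cols: list[int]) -> str:
        out: list[str] = []
        for j in range(n_cols + 1):
            ins = "".join(row[c] for c in blocks[j])
            out.append(ins + GAP * (widths[j] - len(ins)))
            if j < n_cols:
                out.append(row[cols[j]])
        return "".join(out)

    pairs: list[tuple[str, str]] = []
    for sid, row in zip(aln_a.ids, aln_a.rows):
        pairs.append((sid, rebuild(row, blocks_a, cols_a)))
    for sid, row in zip(aln_b.ids, aln_b.rows):
        if sid not in backbone:
            pairs.append((sid, rebuild(row, blocks_b, cols_b)))
    return MSA.from_pairs(pairs)


@dataclass(frozen=True)
class ConservationProfile:
    """Per-column modal residue and its frequency over *all* sequences.

    The denominator counts every sequence, gapped rows included: a gap is a
    non-match.  ``plus_mark`` reproduces the strict "conserved in > 95 % of
    sequences" marking.
    """

    modal: tuple[str | None, ...]
    frequency: tuple[float, ...]
    plus_mark: tuple[bool, ...]
    threshold: float

    def __len__(self) -> int:
        return len(self.modal)


def conservation_profile(msa: MSA, threshold: float = 0.95) -> ConservationProfile:
    """Column-wise conservation of an alignment (strict ``> threshold`` mark).

    Residues are compared case-insensitively.  All-gap columns get frequency
    0 and no mark; ties on the modal residue break alphabetically for
    determinism.
    """
    if len(msa) == 0:
        raise ValueError("empty alignment")
    n = len(msa)
    modal: list[str | None] = []
    freq: list[float] = []
    mark: list[bool] = []
    for j in range(msa.width):
        counts = Counter(c.upper() for c in msa.column(j) if c != GAP)
        if not counts:
            modal.append(None)
            freq.append(0.0)
            mark.append(False)
            continue
        # deterministic: highest count, ties broken alphabetically
        top = max(counts.values())
        best = min(r for r in counts if counts[r] == top)
        f = counts[best] / n
        modal.append(best)
        freq.append(f)
        mark.append(f > threshold)
    return ConservationProfile(tuple(modal), tuple(freq), tuple(mark), threshold)
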