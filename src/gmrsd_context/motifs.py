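"""Degenerate sequence-motif compilation and scanning.

Motifs are written in the compact notation used throughout the restriction-
enzyme literature: fixed residues as capital letters, alternatives as
parenthesized slash-separated sets, and a lowercase ``x`` for any of the 20
standard amino acids.  The GmrS domain carries the signature motif
``(I/V)(I/V)DGQQRLTT(I/L/V)xLL`` (with the DGQQR core aligning to the
sulfiredoxin FG/SGCHR nucleotide-binding signature); the GmrD domain carries
``(I/L/V)(E/D)H(I/L/V)xPQ``, ``L(G/A)NLxLLxxxN`` and ``NxxFxxKK`` plus a
weakly conserved tryptophan motif.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass

from .msa import MSA, conservation_profile

__all__ = [
    "AMINO_ACIDS",
    "WILDCARD",
    "MotifPattern",
    "MotifMatch",
    "SIGNATURE_MOTIFS",
    "compile_motif",
    "scan_motif",
    "random_match_probability",
    "scan_alignment_consensus",
]

#: The 20 standard amino acids.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
WILDCARD = "x"

#: The signature motifs of the GmrS (DUF262) and GmrD (DUF1524) domains.
SIGNATURE_MOTIFS: dict[str, str] = {
    "GmrS-DGQQR": "(I/V)(I/V)DGQQRLTT(I/L/V)xLL",
    "GmrD-EHxPQ": "(I/L/V)(E/D)H(I/L/V)xPQ",
    "GmrD-LGNL": "L(G/A)NLxLLxxxN",
    "GmrD-NxxFxxKK": "NxxFxxKK",
    "GmrD-W": "Wxxxx(I/L/V)xxRxxxLxxxxxx(I/L/V)W",
}


@dataclass(frozen=True)
class MotifPattern:
    """A compiled degenerate motif.

    ``elements`` holds one string per motif position: a single residue, a
    multi-residue alternative set (residues in written order), or the
    wildcard sentinel ``"x"``.
    """

    name: str
    elements: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.elements:
            raise ValueError("motif must have at least one element")
        for e in self.elements:
            if e == WILDCARD:
                continue
            if not e or any(c not in AMINO_ACIDS for c in e):
                raise ValueError(f"invalid motif element {e!r}")

    def __len__(self) -> int:
        return len(self.elements)

    def element_matches(self, i: int, residue: str) -> bool:
        """Whether ``residue`` satisfies element ``i``.

        Comparison is case-insensitive; a non-standard residue (e.g. ``X``)
        matches nothing, not even the wildcard — an unknown residue is never
        evidence.
        """
        r = residue.upper()
        if r not in AMINO_ACIDS:
            return False
        e = self.elements[i]
        return True if e == WILDCARD else r in e

    def to_text(self) -> str:
        parts = []
        for e in self.elements:
            if e == WILDCARD:
                parts.append("x")
            elif len(e) == 1:
                parts.append(e)
            else:
                parts.append("(" + "/".join(e) + ")")
        return "".join(parts)


@dataclass(frozen=True)
class MotifMatch:
    seq_id: str
    pattern_name: str
    start: int  # 1-based, on the ungapped sequence
    end: int  # 1-based inclusive


class MotifParseError(ValueError):
    def __init__(self, message: str, position: int):
        super().__init__(f"{message} at position {position}")
        self.position = position


def compile_motif(pattern_text: str, name: str | None = None) -> MotifPattern:
    """Compile motif notation into a :class:`MotifPattern`.

    Round-trips: ``compile_motif(t).to_text() == t`` for canonical input.
    Malformed parentheses or non-amino-acid letters raise
    :class:`MotifParseError` carrying the offending position (0-based).
    """
    elements: list[str] = []
    i = 0
    n = len(pattern_text)
    while i < n:
        c = pattern_text[i]
        if c == "x":
            elements.append(WILDCARD)
            i += 1
        elif c == "(":
            j = pattern_text.find(")", i + 1)
            if j == -1:
                raise MotifParseError("unclosed '('", i)
            alts = pattern_text[i + 1 : j].split("/")
            if any(len(a) != 1 or a not in AMINO_ACIDS for a in alts):
                raise MotifParseError(f"malformed alternative set {pattern_text[i:j+1]!r}", i)
            # preserve written order, drop duplicates
            elements.append("".join(dict.fromkeys(alts)))
            i = j + 1
        elif c in AMINO_ACIDS:
            elements.append(c)
            i += 1
        else:
            raise MotifParseError(f"unexpected character {c!r}", i)
    if not elements:
        raise MotifParseError("empty pattern", 0)
    return MotifPattern(name=name if name is not None else pattern_text, elements=tuple(elements))


def scan_motif(sequence: str, pattern: MotifPattern, seq_id: str = "") -> list[MotifMatch]:
    """All (possibly overlapping) matches of ``pattern`` in an ungapped sequence.

    Starts are 1-based.  A sequence shorter than the pattern yields no match.
    """
    m = len(pattern)
    out: list[MotifMatch] = []
    for start in range(len(sequence) - m + 1):
        if all(pattern.element_matches(i, sequence[start + i]) for i in range(m)):
            out.append(MotifMatch(seq_id, pattern.name, start + 1, start + m))
    return out


def random_match_probability(pattern: MotifPattern) -> float:
    """Per-position match probability under i.i.d. uniform residues."""
    p = 1.0
    for e in pattern.elements:
        p *= 1.0 if e == WILDCARD else len(e) / len(AMINO_ACIDS)
    return p


def scan_alignment_consensus(
    msa: MSA,
    patterns: Sequence[MotifPattern] | Iterable[MotifPattern],
    min_column_freq: float,
) -> dict[str, list[tuple[int, int]]]:
    """Locate motifs in an alignment via its column consensus.

    A window of alignment columns matches a pattern when, for every pattern
    element, the corresponding column's modal residue satisfies the element
    and the modal frequency is at least ``min_column_freq``.  Returned column
    ranges are 1-based inclusive.
    """
    profile = conservation_profile(msa)
    width = len(profile)
    result: dict[str, list[tuple[int, int]]] = {}
    for pattern in patterns:
        m = len(pattern)
        windows: list[tuple[int, int]] = []
        for start in range(width - m + 1):
            ok = True
            for i in range(m):
                residue = profile.modal[start + i]
                if (
                    residue is None
                    or profile.frequency[start + i] < min_column_freq
                    or not pattern.element_matches(i, residue)
                ):
                    ok = False
                    break
            if ok:
                windows.append((start + 1, start + m))
        result[pattern.name] = windows
    return result
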