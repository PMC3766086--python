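"""Reverse translation of peptide patterns into degenerate sense-strand DNA.

Each amino acid is assigned one canonical degenerate codon built from its
codon family under the standard genetic code:

* a fully degenerate (4-fold) third position becomes inosine (``I``);
* a 2-fold third position becomes the matching two-base IUPAC code;
* Ile keeps its native 3-fold ambiguity as ``ATH``;
* the six-codon amino acids use one family each — Leu ``CTI`` (CTN only),
  Arg ``MGI`` (CGN plus AGR), Ser ``TCI`` (TCN only) — so Leu and Ser
  codons outside the chosen family are *not* covered and the codon carries
  an incomplete-coverage flag.

A peptide position may allow several amino acids (e.g. ``[FY]``); the
canonical codons of the alternatives are then merged base-by-base by IUPAC
union.  Merging can widen coverage beyond the requested residues (``MGI``
already pairs with two Ser codons); the true covered set is always
reported, never silently assumed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .alphabet import base_set, expand, symbol_for_set

__all__ = [
    "EncodingError",
    "AMINO_ACIDS",
    "CANONICAL_CODONS",
    "PeptidePattern",
    "DegenerateCodon",
    "codon_for",
    "encode_sense",
    "encode_codons",
    "translate",
    "translate_frames",
]


class EncodingError(ValueError):
    """A peptide position cannot be reverse translated."""


AMINO_ACIDS: frozenset[str] = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: canonical degenerate codon per amino acid (see module docstring)
CANONICAL_CODONS: dict[str, str] = {
    "A": "GCI", "C": "TGY", "D": "GAY", "E": "GAR", "F": "TTY",
    "G": "GGI", "H": "CAY", "I": "ATH", "K": "AAR", "L": "CTI",
    "M": "ATG", "N": "AAY", "P": "CCI", "Q": "CAR", "R": "MGI",
    "S": "TCI", "T": "ACI", "V": "GTI", "W": "TGG", "Y": "TAY",
}

_FORWARD_TABLE = standard_dna_table.forward_table  # codon -> amino acid


@lru_cache(maxsize=None)
def _codons_of(aa: str) -> frozenset[str]:
    """All standard codons translating to one amino acid."""
    return frozenset(c for c, a in _FORWARD_TABLE.items() if a == aa)


@dataclass(frozen=True)
class DegenerateCodon:
    """A degenerate triplet together with what it really covers.

    ``amino_acids_covered`` is the exact set of residues produced by
    translating every expansion of the triplet (``*`` if a stop slips in
    through merging).  ``incomplete_coverage`` flags a requested residue
    some of whose codons the triplet cannot pair with (Leu, Ser, and any
    merge inheriting them); ``widened_coverage`` flags extra residues
    covered beyond the request.
    """

    triplet: str
    requested: frozenset[str]
    amino_acids_covered: frozenset[str]
    incomplete_coverage: bool
    widened_coverage: bool


@dataclass(frozen=True)
class PeptidePattern:
    """An ordered list of per-position amino-acid alternative sets.

    Text form uses brackets for alternatives: ``WR[FY][DN]WF``.  The
    parenthesis-slash style ``WR(F/Y)(D/N)WF`` seen in the literature is
    accepted on input.
    """

    positions: tuple[frozenset[str], ...] = field()

    def __post_init__(self) -> None:
        if not self.positions:
            raise EncodingError("peptide pattern must have at least one position")
        for i, pos in enumerate(self.positions):
            if not pos:
                raise EncodingError(f"empty alternative set at position {i + 1}")
            bad = pos - AMINO_ACIDS
            if bad:
                raise EncodingError(
                    f"non-standard amino acid {sorted(bad)} at position {i + 1}"
                )

    @classmethod
    def parse(cls, text: str) -> "PeptidePattern":
        """Parse ``YWDCCK``, ``WR[FY][DN]WF`` or ``WR(F/Y)(D/N)WF``."""
        text = text.strip().upper().replace("/", "")
        positions: list[frozenset[str]] = []
        i = 0
        while i < len(text):
            ch = text[i]
            if ch in "([":
                close = ")" if ch == "(" else "]"
                j = text.find(close, i)
                if j < 0:
                    raise EncodingError(f"unclosed {ch!r} in pattern {text!r}")
                positions.append(frozenset(text[i + 1 : j]))
                i = j + 1
            else:
                positions.append(frozenset(ch))
                i += 1
        return cls(tuple(positions))

    @property
    def text(self) -> str:
        parts = []
        for pos in self.positions:
            if len(pos) == 1:
                parts.append(next(iter(pos)))
            else:
                parts.append("[" + "".join(sorted(pos)) + "]")
        return "".join(parts)

    def __len__(self) -> int:
        return len(self.positions)

    def __str__(self) -> str:
        return self.text

    def matches(self, peptide: str) -> bool:
        """Exact-length set-membership match against a concrete peptide."""
        if len(peptide) != len(self.positions):
            return False
        return all(r in pos for r, pos in zip(peptide.upper(), self.positions))

    def _regex(self) -> "re.Pattern[str]":
        # lookahead so overlapping occurrences are all reported
        body = "".join(
            next(iter(pos)) if len(pos) == 1 else "[" + "".join(sorted(pos)) + "]"
            for pos in self.positions
        )
        return re.compile(f"(?=({body}))")

    def occurrences(self, sequence: str) -> list[int]:
        """All (possibly overlapping) start offsets of the pattern."""
        return [m.start() for m in self._regex().finditer(sequence.upper())]


def codon_for(aa_set: frozenset[str] | set[str] | str) -> DegenerateCodon:
    """Canonical degenerate codon for one amino acid or alternative set.

    Multi-residue sets are merged by per-base IUPAC union of the members'
    canonical codons; a union covering all four bases is written as
    inosine (it would otherwise be synthesized as an N mixture, which the
    inosine convention replaces).
    """
    if isinstance(aa_set, str):
        aa_set = frozenset(aa_set.upper())
    else:
        aa_set = frozenset(a.upper() for a in aa_set)
    if not aa_set:
        raise EncodingError("empty amino-acid set")
    if "*" in aa_set:
        raise EncodingError("stop codons cannot be encoded into a primer")
    bad = aa_set - AMINO_ACIDS
    if bad:
        raise EncodingError(f"unknown amino acid(s): {sorted(bad)}")

    members = [CANONICAL_CODONS[a] for a in sorted(aa_set)]
    triplet_chars = []
    for pos in range(3):
        union: frozenset[str] = frozenset()
        for codon in members:
            union |= base_set(codon[pos])
        triplet_chars.append("I" if len(union) == 4 else symbol_for_set(union))
    triplet = "".join(triplet_chars)

    covered = frozenset(
        _FORWARD_TABLE.get(c, "*") for c in expand(triplet, limit=64)
    )
    incomplete = any(
        not _codons_of(a) <= frozenset(expand(triplet, limit=64)) for a in aa_set
    )
    return DegenerateCodon(
        triplet=triplet,
        requested=aa_set,
        amino_acids_covered=covered,
        incomplete_coverage=incomplete,
        widened_coverage=bool(covered - aa_set),
    )


def encode_codons(pattern: PeptidePattern) -> list[DegenerateCodon]:
    """Per-position degenerate codons for a peptide pattern."""
    out = []
    for i, pos in enumerate(pattern.positions):
        try:
            out.append(codon_for(pos))
        except EncodingError as exc:
            raise EncodingError(f"position {i + 1} of {pattern.text}: {exc}") from exc
    return out


def encode_sense(pattern: PeptidePattern | str) -> str:
    """Sense-strand degenerate DNA encoding a peptide pattern (3x length)."""
    if isinstance(pattern, str):
        pattern = PeptidePattern.parse(pattern)
    return "".join(c.triplet for c in encode_codons(pattern))


def translate(dna: str) -> str:
    """Standard-code translation of frame +1; stops as ``*``, trailing
    partial codon dropped."""
    dna = dna.upper()
    usable = len(dna) - len(dna) % 3
    return str(Seq(dna[:usable]).translate())


def translate_frames(dna: str) -> dict[str, str]:
    """Six-frame translation, keyed ``+1..+3`` and ``-1..-3``."""
    dna = dna.upper()
    rc = str(Seq(dna).reverse_complement())
    frames = {}
    for off in range(3):
        frames[f"+{off + 1}"] = translate(dna[off:])
        frames[f"-{off + 1}"] = translate(rc[off:])
    return frames
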