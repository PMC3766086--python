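"""Exact algebra over degenerate DNA sequences.

The working alphabet is the 15 IUPAC nucleotide codes plus inosine (``I``).
Inosine is a single physical nucleoside that base-pairs with all four DNA
bases, so it behaves like ``N`` for *matching* but contributes a factor of 1
(not 4) to the *degeneracy* of a primer mixture.  We therefore track two
numbers per sequence:

``degeneracy``
    number of distinct oligonucleotide species in the synthesized mixture
    (inosine counts 1);
``coverage_fold``
    number of concrete A/C/G/T sequences the primer can base-pair with
    (inosine counts 4).

Sequences are plain uppercase ``str`` objects; every public function
validates its input.  RNA (``U``) is rejected: this is a DNA-only toolkit.
"""

from __future__ import annotations

import itertools
from typing import Iterable

__all__ = [
    "AlphabetError",
    "ALPHABET",
    "base_set",
    "clean",
    "complement_base",
    "reverse_complement",
    "degeneracy",
    "coverage_fold",
    "matches",
    "expand",
    "symbol_for_set",
    "is_concrete",
]


class AlphabetError(ValueError):
    """An input character is outside the degenerate DNA alphabet."""


#: base sets used for matching; inosine pairs with everything
_BASE_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
    "I": frozenset("ACGT"),
}

ALPHABET: frozenset[str] = frozenset(_BASE_SETS)

_COMPLEMENT: dict[str, str] = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
    # inosine pairs indiscriminately on either strand
    "I": "I",
}

#: IUPAC symbol for each non-empty base set (the 4-base set maps to N;
#: callers that want inosine there must ask for it explicitly)
_SET_TO_SYMBOL: dict[frozenset[str], str] = {
    s: c for c, s in _BASE_SETS.items() if c != "I"
}


def clean(seq: str, *, name: str = "sequence") -> str:
    """Uppercase and validate a degenerate DNA string.

    Raises :class:`AlphabetError` naming the first offending character and
    its 1-based position.  ``U`` gets a dedicated hint since it usually
    signals RNA input.
    """
    up = seq.upper()
    for i, ch in enumerate(up):
        if ch not in _BASE_SETS:
            hint = " (RNA is not supported; did you mean T?)" if ch == "U" else ""
            raise AlphabetError(
                f"invalid character {ch!r} at position {i + 1} of {name}{hint}"
            )
    return up


def base_set(symbol: str) -> frozenset[str]:
    """Concrete bases matched by one alphabet symbol (``I`` -> all four)."""
    try:
        return _BASE_SETS[symbol.upper()]
    except KeyError:
        raise AlphabetError(f"invalid character {symbol!r}") from None


def symbol_for_set(bases: Iterable[str]) -> str:
    """IUPAC code for a non-empty set of concrete bases (ACGT -> ``N``)."""
    key = frozenset(b.upper() for b in bases)
    try:
        return _SET_TO_SYMBOL[key]
    except KeyError:
        raise AlphabetError(f"no IUPAC symbol for base set {sorted(key)}") from None


def is_concrete(seq: str) -> bool:
    """True if the sequence contains only A/C/G/T."""
    return all(ch in "ACGT" for ch in seq)


def complement_base(b: str) -> str:
    try:
        return _COMPLEMENT[b.upper()]
    except KeyError:
        raise AlphabetError(f"invalid character {b!r}") from None


def reverse_complement(seq: str) -> str:
    """Reverse complement under the full degenerate alphabet.

    An involution: ``reverse_complement(reverse_complement(s)) == s``.
    Inosine complements to itself (it sits opposite any base on the
    template strand just as it does on its own).
    """
    seq = clean(seq)
    return "".join(_COMPLEMENT[ch] for ch in reversed(seq))


def degeneracy(seq: str) -> int:
    """Number of oligo species in the mixture; inosine counts as one."""
    seq = clean(seq)
    d = 1
    for ch in seq:
        d *= 1 if ch == "I" else len(_BASE_SETS[ch])
    return d


def coverage_fold(seq: str) -> int:
    """Number of concrete sequences the primer can pair with (``I`` -> 4)."""
    seq = clean(seq)
    d = 1
    for ch in seq:
        d *= len(_BASE_SETS[ch])
    return d


def matches(pattern: str, text: str, max_mismatches: int = 0) -> tuple[bool, int]:
    """Match a degenerate pattern against an equal-length concrete string.

    Position ``i`` matches iff ``text[i]`` is in the base set of
    ``pattern[i]``; inosine matches any base.  ``N`` in the text matches
    nothing (conservative: an unknown template base cannot be certified to
    pair).  Returns ``(ok, n_mismatches)`` where ``ok`` is whether the
    mismatch count is within budget.
    """
    pattern = clean(pattern, name="pattern")
    text = text.upper()
    if len(pattern) != len(text):
        raise ValueError(
            f"pattern length {len(pattern)} != text length {len(text)}"
        )
    mism = 0
    for i, (p, t) in enumerate(zip(pattern, text)):
        if t not in "ACGTN":
            raise AlphabetError(
                f"invalid template character {t!r} at position {i + 1}"
            )
        if t == "N" or t not in _BASE_SETS[p]:
            mism += 1
    return mism <= max_mismatches, mism


def expand(seq: str, limit: int = 65536) -> set[str]:
    """All concrete sequences covered by ``seq`` (``I`` expands to ACGT).

    Refuses to expand above ``limit`` concrete sequences, reporting the
    required size.
    """
    seq = clean(seq)
    size = coverage_fold(seq)
    if size > limit:
        raise ValueError(
            f"expansion would produce {size} sequences, above the limit of {limit}"
        )
    pools = [sorted(_BASE_SETS[ch]) for ch in seq]
    return {"".join(p) for p in itertools.product(*pools)}
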