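"""Conserved k-peptide mining across a homologous protein family.

Conservation is alignment-free: a k-peptide's support is the number of
*distinct* sequences containing at least one match, since a primer is
useful exactly when it can amplify the gene from many species — repeated
occurrences within one sequence add nothing.  Near-identical k-mers can be
merged into an ambiguous pattern (e.g. ``WR[FY][DN]WF``) so that a single
degenerate primer covers closely related variants.

No multiple-sequence alignment is performed; all counting is exhaustive
containment over k-windows.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

from .alphabet import degeneracy
from .codons import AMINO_ACIDS, CANONICAL_CODONS, PeptidePattern, encode_sense

__all__ = ["ProteinSet", "ConservedPeptideHit", "mine_conserved", "score_pattern"]

#: per-residue mixture degeneracy of the canonical codon, so that the
#: degeneracy of a k-mer's encoding is a simple product
_RESIDUE_DEGENERACY = {aa: degeneracy(c) for aa, c in CANONICAL_CODONS.items()}


@dataclass(frozen=True)
class ProteinSet:
    """A family of homologous protein sequences.

    Identifiers must be unique; sequences are uppercase, non-empty, and
    drawn from the 20 standard residues plus ``X`` (tolerated but never
    matchable by any pattern position).
    """

    records: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("protein set is empty")
        seen: set[str] = set()
        allowed = AMINO_ACIDS | {"X"}
        for ident, seq in self.records:
            if ident in seen:
                raise ValueError(f"duplicate sequence identifier {ident!r}")
            seen.add(ident)
            if not seq:
                raise ValueError(f"empty sequence for {ident!r}")
            bad = set(seq) - allowed
            if bad:
                raise ValueError(
                    f"invalid residue(s) {sorted(bad)} in sequence {ident!r}"
                )

    @classmethod
    def from_pairs(cls, pairs) -> "ProteinSet":
        return cls(tuple((i, s.upper()) for i, s in pairs))

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def min_length(self) -> int:
        return min(len(s) for _, s in self.records)


@dataclass(frozen=True)
class ConservedPeptideHit:
    """A mined peptide pattern with its conservation evidence.

    ``degeneracy`` is that of the full (untrimmed) sense-strand encoding,
    reported because it drives how dilute the primer mixture is and hence
    how much annealing-temperature optimization the primer will need.
    """

    pattern: PeptidePattern
    support: int
    support_fraction: float
    degeneracy: int
    positions: tuple[tuple[str, int], ...]
    rank: int


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _kmer_degeneracy(kmer: str) -> int:
    d = 1
    for aa in kmer:
        d *= _RESIDUE_DEGENERACY[aa]
    return d


def score_pattern(
    proteins: ProteinSet, pattern: PeptidePattern, rank: int = 0
) -> ConservedPeptideHit:
    """Support and occurrence list of a (possibly ambiguous) pattern."""
    positions: list[tuple[str, int]] = []
    support = 0
    for ident, seq in proteins.records:
        occ = pattern.occurrences(seq)
        if occ:
            support += 1
            positions.extend((ident, off) for off in occ)
    return ConservedPeptideHit(
        pattern=pattern,
        support=support,
        support_fraction=support / proteins.n,
        degeneracy=degeneracy(encode_sense(pattern)),
        positions=tuple(positions),
        rank=rank,
    )


def _neighbor_index(kmers: list[str], d: int, k: int):
    """Pigeonhole index: k-mers within Hamming distance d share at least
    one of d+1 contiguous chunks verbatim."""
    bounds = [round(i * k / (d + 1)) for i in range(d + 2)]
    index: dict[tuple[int, str], list[str]] = defaultdict(list)
    for kmer in kmers:
        for part in range(d + 1):
            index[(part, kmer[bounds[part] : bounds[part + 1]])].append(kmer)

    def neighbors(kmer: str) -> set[str]:
        cands: set[str] = set()
        for part in range(d + 1):
            cands.update(index[(part, kmer[bounds[part] : bounds[part + 1]])])
        return {c for c in cands if c != kmer and _hamming(kmer, c) <= d}

    return neighbors


def mine_conserved(
    proteins: ProteinSet,
    k: int = 6,
    min_support_fraction: float = 0.5,
    max_variable_positions: int = 0,
    max_patterns: int = 10,
) -> list[ConservedPeptideHit]:
    """Find the most conserved k-peptides, optionally merged into patterns.

    Procedure:

    1. count every exact k-mer by the number of distinct sequences
       containing it (k-mers touching ``X`` are skipped);
    2. greedily merge k-mers within Hamming distance
       ``max_variable_positions`` of a seed, highest-support seed first,
       into a pattern whose variable positions carry the union of observed
       residues; a candidate is only absorbed while the merged pattern
       keeps at most ``max_variable_positions`` ambiguous positions;
    3. drop hits whose support fraction is below ``min_support_fraction``;
    4. rank by (support desc, encoded-core degeneracy asc, pattern text
       asc) and truncate to ``max_patterns``.

    The ordering keys are all total, so the result is deterministic,
    including tie cases.
    """
    if not 4 <= k <= 10:
        raise ValueError(f"k must be in [4, 10], got {k}")
    if not 0 < min_support_fraction <= 1:
        raise ValueError("min_support_fraction must be in (0, 1]")
    if not 0 <= max_variable_positions <= 2:
        raise ValueError("max_variable_positions must be in [0, 2]")
    if k > proteins.min_length:
        raise ValueError(
            f"k={k} exceeds the shortest sequence length {proteins.min_length}"
        )

    kmer_seqs: dict[str, set[str]] = defaultdict(set)
    for ident, seq in proteins.records:
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "X" not in kmer:
                kmer_seqs[kmer].add(ident)

    def seed_key(kmer: str):
        return (-len(kmer_seqs[kmer]), _kmer_degeneracy(kmer), kmer)

    ordered = sorted(kmer_seqs, key=seed_key)
    neighbors = (
        _neighbor_index(ordered, max_variable_positions, k)
        if max_variable_positions > 0
        else None
    )

    consumed: set[str] = set()
    # (sort key, pattern, known support or None-if-merged)
    candidates: list[tuple[PeptidePattern, int | None]] = []
    for seed in ordered:
        if seed in consumed:
            continue
        consumed.add(seed)
        merged = [frozenset(r) for r in seed]
        did_merge = False
        if neighbors is not None:
            for cand in sorted(neighbors(seed) - consumed, key=seed_key):
                trial = [a | frozenset(b) for a, b in zip(merged, cand)]
                if sum(len(s) > 1 for s in trial) <= max_variable_positions:
                    merged = trial
                    consumed.add(cand)
                    did_merge = True
        pattern = PeptidePattern(tuple(merged))
        candidates.append((pattern, None if did_merge else len(kmer_seqs[seed])))

    n = proteins.n
    min_support = min_support_fraction * n
    scored: list[tuple[PeptidePattern, int]] = []
    for pattern, known in candidates:
        if known is not None:
            support = known
        else:
            # merged patterns can match recombinants of their members, so
            # their support must be measured, not inferred from the seeds
            support = sum(
                1 for _, seq in proteins.records if pattern.occurrences(seq)
            )
        if support >= min_support:
            scored.append((pattern, support))

    scored.sort(
        key=lambda ps: (-ps[1], degeneracy(encode_sense(ps[0])), ps[0].text)
    )
    return [
        score_pattern(proteins, pattern, rank=i + 1)
        for i, (pattern, _) in enumerate(scored[:max_patterns])
    ]
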