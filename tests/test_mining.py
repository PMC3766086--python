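"""Conserved k-peptide mining against a brute-force oracle."""

import itertools

import numpy as np
import pytest

from hexaprime.alphabet import degeneracy
from hexaprime.codons import PeptidePattern, encode_sense
from hexaprime.mining import ProteinSet, mine_conserved, score_pattern
from hexaprime.simulate import FamilySpec, generate_family

AAS = "ACDEFGHIKLMNPQRSTVWY"


def brute_force_mine(proteins, k, min_support_fraction, max_variable_positions,
                     max_patterns):
    """Independent re-derivation: direct window enumeration, pairwise
    Hamming comparison, and the same documented greedy merge/ranking."""
    kmer_seqs = {}
    for ident, seq in proteins.records:
        for i in range(len(seq) - k + 1):
            w = seq[i:i + k]
            if "X" not in w:
                kmer_seqs.setdefault(w, set()).add(ident)

    def enc_deg(kmer):
        return degeneracy(encode_sense(kmer))

    def key(kmer):
        return (-len(kmer_seqs[kmer]), enc_deg(kmer), kmer)

    ordered = sorted(kmer_seqs, key=key)
    consumed, patterns = set(), []
    for seed in ordered:
        if seed in consumed:
            continue
        consumed.add(seed)
        merged = [set(c) for c in seed]
        for cand in sorted(ordered, key=key):
            if cand in consumed:
                continue
            if sum(a != b for a, b in zip(seed, cand)) > max_variable_positions:
                continue
            trial = [a | {b} for a, b in zip(merged, cand)]
            if sum(len(s) > 1 for s in trial) <= max_variable_positions:
                merged = trial
                consumed.add(cand)
        patterns.append(PeptidePattern(tuple(frozenset(s) for s in merged)))

    scored = []
    for p in patterns:
        support = sum(
            1 for _, seq in proteins.records
            if any(p.matches(seq[i:i + k]) for i in range(len(seq) - k + 1))
        )
        if support / proteins.n >= min_support_fraction:
            scored.append((p, support))
    scored.sort(key=lambda ps: (-ps[1], degeneracy(encode_sense(ps[0])),
                                ps[0].text))
    return [(p.text, s) for p, s in scored[:max_patterns]]


def test_unanimous_planted_hexapeptide():
    proteins = ProteinSet.from_pairs(
        [("a", "GGYWDCCKAA"), ("b", "TTYWDCCKCC"), ("c", "PPYWDCCKDD")]
    )
    hits = mine_conserved(proteins, k=6, min_support_fraction=1.0,
                          max_variable_positions=0)
    assert hits[0].pattern.text == "YWDCCK"
    assert hits[0].support == 3
    assert hits[0].rank == 1


def test_half_and_half_variants_merge_into_ambiguous_pattern():
    proteins = ProteinSet.from_pairs(
        [("a", "WRFDWF"), ("b", "WRFDWF"), ("c", "WRYNWF"), ("d", "WRYNWF")]
    )
    hits = mine_conserved(proteins, k=6, min_support_fraction=1.0,
                          max_variable_positions=2)
    assert hits[0].pattern.text == "WR[FY][DN]WF"
    assert hits[0].support == 4


def test_score_pattern_counts_distinct_sequences():
    proteins = ProteinSet.from_pairs([("a", "W"), ("b", "A")])
    assert score_pattern(proteins, PeptidePattern.parse("W")).support == 1

    proteins = ProteinSet.from_pairs([("a", "F"), ("b", "Y"), ("c", "A")])
    hit = score_pattern(proteins, PeptidePattern.parse("[FY]"))
    assert hit.support == 2
    assert hit.support_fraction == pytest.approx(2 / 3)


def test_score_pattern_on_seeded_fixture():
    rng = np.random.default_rng(11)
    records = []
    for i in range(10):
        seq = "".join(AAS[j] for j in rng.integers(20, size=40))
        if i < 7:
            seq = seq[:17] + "GTGYCD" + seq[23:]
        records.append((f"s{i}", seq))
    proteins = ProteinSet.from_pairs(records)
    hit = score_pattern(proteins, PeptidePattern.parse("GTGYCD"))
    assert hit.support == 7
    assert all(off == 17 for _, off in hit.positions)


@pytest.mark.parametrize("seed", range(6))
@pytest.mark.parametrize("max_var", [0, 1, 2])
def test_equivalence_with_brute_force_oracle(seed, max_var):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 10))
    records = []
    for i in range(n):
        length = int(rng.integers(10, 50))
        # a reduced residue alphabet makes near-identical k-mers common
        records.append(
            ("p%d" % i, "".join("ACDWY"[j] for j in rng.integers(5, size=length)))
        )
    proteins = ProteinSet.from_pairs(records)
    hits = mine_conserved(proteins, k=6, min_support_fraction=0.25,
                          max_variable_positions=max_var, max_patterns=15)
    expected = brute_force_mine(proteins, 6, 0.25, max_var, 15)
    assert [(h.pattern.text, h.support) for h in hits] == expected
    assert [h.rank for h in hits] == list(range(1, len(hits) + 1))


def test_merging_never_decreases_seed_support():
    proteins = ProteinSet.from_pairs(
        [("a", "WRFDWF"), ("b", "WRFDWF"), ("c", "WRYNWF")]
    )
    exact = mine_conserved(proteins, k=6, min_support_fraction=0.1,
                           max_variable_positions=0)
    merged = mine_conserved(proteins, k=6, min_support_fraction=0.1,
                            max_variable_positions=2)
    assert merged[0].support >= exact[0].support
    assert all(h.support <= proteins.n for h in merged)


def test_determinism_including_ties():
    proteins = ProteinSet.from_pairs(
        [("a", "AAAAAACCCCCC"), ("b", "CCCCCCAAAAAA")]
    )
    runs = [
        mine_conserved(proteins, k=6, min_support_fraction=0.5)
        for _ in range(3)
    ]
    assert runs[0] == runs[1] == runs[2]


def test_planted_motif_ranks_first_on_fixture_family():
    fam = FamilySpec(n_sequences=20, length=300,
                     planted_motifs=(("YWDCCK", 120, 1.0),),
                     substitution_rate=0.3, seed=42)
    hits = mine_conserved(generate_family(fam))
    assert hits[0].pattern.text == "YWDCCK"
    assert hits[0].support == 20


def test_input_errors():
    with pytest.raises(ValueError, match="empty"):
        ProteinSet(())
    with pytest.raises(ValueError, match="duplicate"):
        ProteinSet.from_pairs([("a", "WWWWWW"), ("a", "YYYYYY")])
    proteins = ProteinSet.from_pairs([("a", "WWW")])
    with pytest.raises(ValueError, match="shortest"):
        mine_conserved(proteins, k=6)
    with pytest.raises(ValueError, match="k must"):
        mine_conserved(proteins, k=3)


def test_x_windows_are_skipped_and_unmatchable():
    proteins = ProteinSet.from_pairs([("a", "WWXWWY"), ("b", "WWAWWY")])
    hits = mine_conserved(proteins, k=4, min_support_fraction=0.5)
    assert all("X" not in h.pattern.text for h in hits)
    # X in a sequence matches no pattern position
    assert score_pattern(proteins, PeptidePattern.parse("WWAW")).support == 1
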