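"""In-silico PCR scanning, amplicon prediction, product extraction."""

import numpy as np
import pytest

from conftest import random_concrete_dna

from hexaprime.alphabet import base_set, expand, reverse_complement
from hexaprime.pcr import (
    TemplateSeq,
    extract_products,
    find_binding_sites,
    predict_amplicons,
)
from hexaprime.primers import build_primer


def brute_force_sites(core, template, max_mismatches, anchor_len):
    """Per-offset enumeration over both strands, used as the scanning
    oracle."""
    out = []
    text = template.sequence
    L = len(core)
    for strand in "+-":
        pat = core if strand == "+" else reverse_complement(core)
        anchor = (range(L - anchor_len, L) if strand == "+"
                  else range(anchor_len))
        for s in range(len(text) - L + 1):
            window = text[s:s + L]
            mism = sum(
                t == "N" or t not in base_set(p)
                for p, t in zip(pat, window)
            )
            anchored = all(
                window[i] != "N" and window[i] in base_set(pat[i])
                for i in anchor
            )
            if mism <= max_mismatches and anchored:
                out.append((strand, s, s + L, mism))
    out.sort(key=lambda t: (t[1], t[0]))
    return out


def _pair(fwd_pep="YWDCCK", rev_pep="WDCCKP"):
    return build_primer(fwd_pep, "forward"), build_primer(rev_pep, "reverse")


def _planted_template(rng, fwd, rev, spacer=200, flank=50):
    fwd_site = sorted(expand(fwd.core))[int(rng.integers(len(expand(fwd.core))))]
    rev_site_sense = reverse_complement(rev.core)
    rev_site = sorted(expand(rev_site_sense))[
        int(rng.integers(len(expand(rev_site_sense))))
    ]
    seq = (random_concrete_dna(rng, flank) + fwd_site
           + random_concrete_dna(rng, spacer) + rev_site
           + random_concrete_dna(rng, flank))
    return TemplateSeq("planted", seq)


@pytest.mark.parametrize(
    "core,template,expected",
    [
        ("TGGGAY", "ATTGGGACAA", [("+", 2, 8, 0)]),
        ("TGGGAY", "AAGTCCCAAAA", [("-", 2, 8, 0)]),
        # anchored 3' mismatch suppresses the site entirely
        ("GAYTG", "GACTA", []),
    ],
)
def test_find_binding_sites_examples(core, template, expected):
    t = TemplateSeq("t", template)
    assert find_binding_sites(core, t, max_mismatches=0, anchor_len=3) == expected


def test_core_longer_than_template_gives_empty_result():
    assert find_binding_sites("TGGGAY", TemplateSeq("t", "ACG")) == []


def test_anchor_must_fit_in_core():
    with pytest.raises(ValueError, match="anchor"):
        find_binding_sites("TGG", TemplateSeq("t", "ACGT"), anchor_len=4)


def test_mismatch_budget_without_anchor_violation():
    t = TemplateSeq("t", "ATTGAGACAA")  # one internal mismatch vs TGGGAY
    assert find_binding_sites("TGGGAY", t, max_mismatches=0) == []
    assert find_binding_sites("TGGGAY", t, max_mismatches=1) == [("+", 2, 8, 1)]


def test_planted_template_yields_single_amplicon(rng):
    fwd, rev = _pair()
    t = _planted_template(rng, fwd, rev, spacer=200)
    hits = predict_amplicons(fwd, rev, [t])
    assert len(hits) == 1
    h = hits[0]
    assert h.strand == "+"
    assert h.product_length == len(fwd.core) + 200 + len(rev.core)
    assert h.mismatches_forward == h.mismatches_reverse == 0


def test_length_filter_excludes_construction(rng):
    fwd, rev = _pair()
    t = _planted_template(rng, fwd, rev, spacer=200)
    built = len(fwd.core) + 200 + len(rev.core)
    assert predict_amplicons(fwd, rev, [t], min_len=built + 1) == []
    assert predict_amplicons(fwd, rev, [t], max_len=built - 1) == []


def test_fifty_planted_templates_one_hit_each(rng):
    fwd, rev = _pair()
    templates = []
    for i in range(50):
        t = _planted_template(rng, fwd, rev, spacer=int(rng.integers(100, 400)))
        templates.append(TemplateSeq(f"t{i}", t.sequence))
    hits = predict_amplicons(fwd, rev, templates)
    assert len(hits) == 50
    assert [h.template_id for h in hits] == [t.identifier for t in templates]


def test_scanning_equals_brute_force_on_random_templates(rng):
    fwd, rev = _pair()
    for _ in range(15):
        t = TemplateSeq("r", random_concrete_dna(rng, int(rng.integers(50, 800))))
        for core in (fwd.core, rev.core):
            for mm in (0, 1):
                assert (find_binding_sites(core, t, mm, 3)
                        == brute_force_sites(core, t, mm, 3))


def test_strand_symmetry(rng):
    fwd, rev = _pair()
    t = _planted_template(rng, fwd, rev)
    mirrored = TemplateSeq(t.identifier, reverse_complement(t.sequence))
    hits = predict_amplicons(fwd, rev, [t])
    mhits = predict_amplicons(fwd, rev, [mirrored])
    assert len(hits) == len(mhits) == 1
    assert mhits[0].strand == "-"
    assert mhits[0].product_length == hits[0].product_length
    assert mhits[0].mismatches_forward == hits[0].mismatches_forward
    assert mhits[0].mismatches_reverse == hits[0].mismatches_reverse


def test_tails_never_affect_binding(rng):
    fwd, rev = _pair()
    t = _planted_template(rng, fwd, rev)
    bare_f = build_primer("YWDCCK", "forward", "")
    bare_r = build_primer("WDCCKP", "reverse", "")
    with_tails = predict_amplicons(fwd, rev, [t])
    without = predict_amplicons(bare_f, bare_r, [t])
    strip = lambda h: (h.template_id, h.fwd_start, h.fwd_end, h.rev_start,
                       h.rev_end, h.strand, h.product_length)
    assert [strip(h) for h in with_tails] == [strip(h) for h in without]


def test_extract_products_orientation(rng):
    fwd, rev = _pair()
    t = _planted_template(rng, fwd, rev)
    hits = predict_amplicons(fwd, rev, [t])
    (prod,) = extract_products(hits, [t])
    assert len(prod.sequence) == hits[0].product_length
    assert prod.sequence == t.sequence[hits[0].fwd_start:hits[0].rev_end]

    mirrored = TemplateSeq(t.identifier, reverse_complement(t.sequence))
    mhits = predict_amplicons(fwd, rev, [mirrored])
    (mprod,) = extract_products(mhits, [mirrored])
    # minus-strand product equals the reverse complement of the slice
    lo, hi = mhits[0].rev_start, mhits[0].fwd_end
    assert mprod.sequence == reverse_complement(mirrored.sequence[lo:hi])
    assert mprod.sequence == prod.sequence


def test_product_translation_contains_trimmed_motif(rng):
    # the reverse core loses its last-codon wobble bases, so the product
    # carries the reverse peptide minus its final residue
    fwd, rev = _pair()
    t = _planted_template(rng, fwd, rev)
    hits = predict_amplicons(fwd, rev, [t])
    (prod,) = extract_products(hits, [t])
    assert any("YWDCC" in f for f in prod.translations.values())


def test_extract_products_rejects_unknown_template(rng):
    fwd, rev = _pair()
    t = _planted_template(rng, fwd, rev)
    hits = predict_amplicons(fwd, rev, [t])
    with pytest.raises(ValueError, match="unknown template"):
        extract_products(hits, [TemplateSeq("other", "ACGT")])


def test_template_validation():
    with pytest.raises(Exception, match="non-DNA"):
        TemplateSeq("t", "ACGU")
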