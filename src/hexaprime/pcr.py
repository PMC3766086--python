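"""In-silico PCR: binding-site search and amplicon prediction.

Only the primer *core* is matched against the template — the 5' tail is
non-templated and never anneals — and a site is accepted only when its
3'-terminal ``anchor_len`` bases pair perfectly, since polymerases do not
extend from a mismatched 3' end.  Mismatch counting is plain set
membership per position (inosine pairs with everything); template ``N``
pairs with nothing.

Coordinates are 0-based half-open on the plus strand of the template.
Product length runs from the 5' end of the forward binding site through
the 5' end of the reverse binding site and excludes tails; a gel would see
each product longer by the two tail lengths (+12 nt for the standard
six-base tails).
"""

from __future__ import annotations

from dataclasses import dataclass

from .alphabet import AlphabetError, base_set, reverse_complement
from .codons import translate_frames
from .primers import PrimerRecord

__all__ = [
    "TemplateSeq",
    "AmpliconHit",
    "ProductRecord",
    "find_binding_sites",
    "predict_amplicons",
    "extract_products",
]


@dataclass(frozen=True)
class TemplateSeq:
    """A concrete DNA template (A/C/G/T; N tolerated, pairs with nothing)."""

    identifier: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        bad = set(self.sequence.upper()) - set("ACGTN")
        if bad:
            raise AlphabetError(
                f"template {self.identifier!r} contains non-DNA characters "
                f"{sorted(bad)}"
            )
        object.__setattr__(self, "sequence", self.sequence.upper())


@dataclass(frozen=True)
class AmpliconHit:
    """A predicted PCR product.

    ``strand`` is the strand of the template whose sequence the product's
    plus strand reproduces.  ``fwd_start/fwd_end`` and ``rev_start/rev_end``
    are the core binding intervals on the template plus strand.
    """

    template_id: str
    fwd_name: str
    fwd_start: int
    fwd_end: int
    rev_name: str
    rev_start: int
    rev_end: int
    strand: str
    product_length: int
    mismatches_forward: int
    mismatches_reverse: int


@dataclass(frozen=True)
class ProductRecord:
    """An extracted product in product orientation, with six-frame
    translations for downstream inspection."""

    identifier: str
    sequence: str
    translations: dict[str, str]


def _scan(pattern: str, text: str, max_mismatches: int, anchor: set[int]):
    """Yield (start, mismatches) for every window of ``text`` matching the
    degenerate ``pattern``; positions in ``anchor`` must match perfectly."""
    L = len(pattern)
    sets = [base_set(ch) for ch in pattern]
    for s in range(len(text) - L + 1):
        mism = 0
        ok = True
        for i in range(L):
            t = text[s + i]
            if t == "N" or t not in sets[i]:
                if i in anchor:
                    ok = False
                    break
                mism += 1
                if mism > max_mismatches:
                    ok = False
                    break
        if ok:
            yield s, mism


def find_binding_sites(
    primer: PrimerRecord | str,
    template: TemplateSeq,
    max_mismatches: int = 0,
    anchor_len: int = 3,
) -> list[tuple[str, int, int, int]]:
    """All core binding sites on both strands of a template.

    Returns ``(strand, start, end, mismatches)`` tuples, coordinates on
    the plus strand.  A plus-strand site means the core itself matches the
    plus strand (the primer anneals to the minus strand and extends
    rightward); a minus-strand site means the reverse complement of the
    core matches the plus strand.  The 3'-anchor positions are the last
    ``anchor_len`` core bases, which sit rightmost for a plus-strand site
    and leftmost for a minus-strand one.
    """
    core = primer.core if isinstance(primer, PrimerRecord) else primer.upper()
    if anchor_len > len(core):
        raise ValueError(
            f"anchor_len {anchor_len} exceeds core length {len(core)}"
        )
    text = template.sequence
    L = len(core)
    out: list[tuple[str, int, int, int]] = []
    plus_anchor = set(range(L - anchor_len, L))
    for s, m in _scan(core, text, max_mismatches, plus_anchor):
        out.append(("+", s, s + L, m))
    minus_anchor = set(range(anchor_len))
    for s, m in _scan(reverse_complement(core), text, max_mismatches, minus_anchor):
        out.append(("-", s, s + L, m))
    out.sort(key=lambda t: (t[1], t[0]))
    return out


def predict_amplicons(
    fwd: PrimerRecord,
    rev: PrimerRecord,
    templates: list[TemplateSeq],
    max_mismatches: int = 0,
    min_len: int = 30,
    max_len: int = 10_000,
    anchor_len: int = 3,
) -> list[AmpliconHit]:
    """Predict products of a primer pair over a set of templates.

    A plus-strand product pairs a plus-strand forward site with a
    downstream minus-strand reverse site; a minus-strand product is the
    mirror image (forward core on the minus strand, reverse core upstream
    on the plus strand).  Zero hits is a valid outcome.  Output order is
    deterministic: (template order, product start, strand).
    """
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    hits: list[AmpliconHit] = []
    for template in templates:
        f_sites = find_binding_sites(fwd, template, max_mismatches, anchor_len)
        r_sites = find_binding_sites(rev, template, max_mismatches, anchor_len)
        per_template: list[AmpliconHit] = []
        for fs in f_sites:
            for rs in r_sites:
                if fs[0] == "+" and rs[0] == "-" and rs[1] >= fs[2]:
                    length = rs[2] - fs[1]
                    start = fs[1]
                    strand = "+"
                elif fs[0] == "-" and rs[0] == "+" and fs[1] >= rs[2]:
                    length = fs[2] - rs[1]
                    start = rs[1]
                    strand = "-"
                else:
                    continue
                if not min_len <= length <= max_len:
                    continue
                per_template.append(
                    AmpliconHit(
                        template_id=template.identifier,
                        fwd_name=fwd.name,
                        fwd_start=fs[1],
                        fwd_end=fs[2],
                        rev_name=rev.name,
                        rev_start=rs[1],
                        rev_end=rs[2],
                        strand=strand,
                        product_length=length,
                        mismatches_forward=fs[3],
                        mismatches_reverse=rs[3],
                    )
                )
        per_template.sort(key=lambda h: (min(h.fwd_start, h.rev_start), h.strand))
        hits.extend(per_template)
    return hits


def extract_products(
    hits: list[AmpliconHit], templates: list[TemplateSeq]
) -> list[ProductRecord]:
    """Product sequences in product orientation (forward core at the 5'
    end), each with its six-frame translation."""
    by_id = {t.identifier: t for t in templates}
    out: list[ProductRecord] = []
    for i, hit in enumerate(hits, start=1):
        try:
            template = by_id[hit.template_id]
        except KeyError:
            raise ValueError(f"hit references unknown template {hit.template_id!r}")
        if hit.strand == "+":
            lo, hi = hit.fwd_start, hit.rev_end
        else:
            lo, hi = hit.rev_start, hit.fwd_end
        if lo < 0 or hi > len(template.sequence) or hi - lo != hit.product_length:
            raise ValueError(
                f"hit {i} coordinates [{lo}, {hi}) are inconsistent with "
                f"template {hit.template_id!r}"
            )
        seq = template.sequence[lo:hi]
        if hit.strand == "-":
            seq = reverse_complement(seq)
        out.append(
            ProductRecord(
                identifier=f"{hit.template_id}|{hit.fwd_name}|{hit.rev_name}|{i}",
                sequence=seq,
                translations=translate_frames(seq),
            )
        )
    return out
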