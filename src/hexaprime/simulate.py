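"""Seeded generators for synthetic protein families and DNA templates.

These fixtures emulate the situation the primer-design pipeline is meant
for: a family of homologous enzymes that share short, strongly conserved
peptide motifs while the rest of the sequence has diverged.  A family is
generated by drawing a random ancestor, planting motifs at fixed
positions, and deriving homologs by independent per-site substitution
outside the motif spans — no tree-structured evolution and no indels, so
divergence is i.i.d. rather than phylogenetically correlated.

Matched DNA templates are produced by back-translating each protein with
uniformly random codon choices, except inside the planted primer sites,
where codons are drawn from the degenerate core's own codon family so
that each template carries exactly one perfect binding site per primer
(uniqueness is checked and the template resampled if a second
zero-mismatch site arises by chance).  Everything is a pure function of
its spec, seeds included.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from .alphabet import reverse_complement
from .codons import PeptidePattern, encode_codons, translate
from .mining import ProteinSet
from .pcr import TemplateSeq, find_binding_sites
from .primers import trim_wobble

__all__ = [
    "FamilySpec",
    "TemplateSpec",
    "TemplateTruth",
    "generate_family",
    "generate_templates",
]

logger = logging.getLogger(__name__)

_RESIDUES = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class FamilySpec:
    """Parameters of a synthetic protein family.

    Defaults describe a family divergent enough to be a fair mining
    challenge: 20 homologs of 300 residues with 30% per-site substitution
    away from the ancestor outside the planted motifs.
    """

    n_sequences: int = 20
    length: int = 300
    planted_motifs: tuple[tuple[str, int, float], ...] = ()
    substitution_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sequences < 1 or self.length < 1:
            raise ValueError("n_sequences and length must be positive")
        if not 0 <= self.substitution_rate <= 1:
            raise ValueError("substitution_rate must be in [0, 1]")
        spans = []
        for text, pos, frac in self.planted_motifs:
            pattern = PeptidePattern.parse(text)
            if not 0 <= frac <= 1:
                raise ValueError(f"conservation fraction {frac} outside [0, 1]")
            if pos < 0 or pos + len(pattern) > self.length:
                raise ValueError(
                    f"motif {text!r} at {pos} does not fit in length {self.length}"
                )
            spans.append((pos, pos + len(pattern)))
        spans.sort()
        for (_, e1), (s2, _) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError("planted motif positions overlap")


@dataclass(frozen=True)
class TemplateSpec:
    """Parameters of the matched DNA templates for one family.

    ``spacer_length`` bounds the distance (nt, inclusive) between the 3'
    end of the forward binding site and the 5' start of the reverse one;
    ``flank_length`` bounds the random flanks outside the two coding
    segments.  ``introns`` are (offset, length) pairs, the offset measured
    from the 3' end of the forward binding site into the spacer, each
    inserted with GT...AG termini.
    """

    family: FamilySpec = field(default_factory=FamilySpec)
    codon_choice_seed: int = 0
    spacer_length: tuple[int, int] = (100, 400)
    flank_length: tuple[int, int] = (30, 60)
    introns: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        for name, (lo, hi) in (
            ("spacer_length", self.spacer_length),
            ("flank_length", self.flank_length),
        ):
            if lo < 0 or hi < lo:
                raise ValueError(f"invalid {name} bounds ({lo}, {hi})")
        if self.spacer_length[0] < 2:
            # trimmed wobble bases of the forward motif's last codon land
            # in the spacer, so it cannot be shorter than the trim (<= 2)
            raise ValueError("spacer_length minimum must be at least 2")
        for off, ln in self.introns:
            if ln < 4:
                raise ValueError(f"intron length {ln} below minimum of 4 (GT..AG)")
            if off < 0:
                raise ValueError("intron offset must be non-negative")


@dataclass(frozen=True)
class TemplateTruth:
    """Ground truth recorded for one generated template."""

    template_id: str
    fwd_start: int
    fwd_end: int
    rev_start: int
    rev_end: int
    inter_primer_distance: int
    expected_product_length: int


def _realize(pattern: PeptidePattern, rng: np.random.Generator) -> str:
    return "".join(
        sorted(pos)[rng.integers(len(pos))] for pos in pattern.positions
    )


def generate_family(spec: FamilySpec) -> ProteinSet:
    """Generate a seeded protein family with planted conserved motifs.

    Each motif is retained (re-realized from its pattern) in exactly
    ``round(fraction * n)`` sequences; in the remaining sequences its span
    is substituted like background and forced off-pattern.  Reproducible:
    the output is a pure function of the spec.
    """
    rng = np.random.default_rng(spec.seed)
    ancestor = rng.choice(_RESIDUES, size=spec.length)
    motifs = [
        (PeptidePattern.parse(text), pos, frac)
        for text, pos, frac in spec.planted_motifs
    ]
    in_motif = np.zeros(spec.length, dtype=bool)
    for pattern, pos, _ in motifs:
        in_motif[pos : pos + len(pattern)] = True

    keep_sets = []
    for _, _, frac in motifs:
        n_keep = round(frac * spec.n_sequences)
        keep = rng.permutation(spec.n_sequences)[:n_keep]
        keep_sets.append(set(int(i) for i in keep))

    records = []
    width = len(str(spec.n_sequences))
    for i in range(spec.n_sequences):
        seq = ancestor.copy()
        mutate = (rng.random(spec.length) < spec.substitution_rate) & ~in_motif
        # substitute to a uniformly drawn *different* residue
        for j in np.nonzero(mutate)[0]:
            choices = _RESIDUES[_RESIDUES != seq[j]]
            seq[j] = choices[rng.integers(len(choices))]
        for (pattern, pos, _), keep in zip(motifs, keep_sets):
            span = slice(pos, pos + len(pattern))
            if i in keep:
                seq[span] = list(_realize(pattern, rng))
            else:
                window = ancestor[span].copy()
                for j in range(len(pattern)):
                    if rng.random() < spec.substitution_rate:
                        choices = _RESIDUES[_RESIDUES != window[j]]
                        window[j] = choices[rng.integers(len(choices))]
                if pattern.matches("".join(window)):
                    # force the motif off in non-retaining sequences
                    j = int(rng.integers(len(pattern)))
                    bad = sorted(set(_RESIDUES) - pattern.positions[j])
                    window[j] = bad[rng.integers(len(bad))]
                seq[span] = window
        records.append((f"syn{i + 1:0{width}d}", "".join(seq)))
    return ProteinSet(tuple(records))


def _compatible_codons(pattern: PeptidePattern) -> list[dict[str, list[str]]]:
    """Per motif position: residue -> codons compatible with the
    degenerate core at that position."""
    from .alphabet import expand

    out: list[dict[str, list[str]]] = []
    for codon in encode_codons(pattern):
        table: dict[str, list[str]] = {}
        expansions = sorted(expand(codon.triplet, limit=64))
        for aa in sorted(codon.requested):
            table[aa] = [c for c in expansions if translate(c) == aa]
        out.append(table)
    return out


#: residue -> all standard codons, for unconstrained back-translation
_ALL_CODONS: dict[str, list[str]] = {
    str(aa): sorted(
        "".join(c)
        for c in itertools.product("ACGT", repeat=3)
        if translate("".join(c)) == aa
    )
    for aa in _RESIDUES
}


def _back_translate(
    protein: str,
    rng: np.random.Generator,
    constrained: dict[int, dict[str, list[str]]] | None = None,
) -> str:
    """Random back-translation; positions in ``constrained`` draw from the
    supplied codon subset instead of the residue's full codon set."""
    codons = []
    constrained = constrained or {}
    for i, aa in enumerate(protein):
        pool = constrained.get(i, _ALL_CODONS)[aa]
        codons.append(pool[rng.integers(len(pool))])
    return "".join(codons)


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(4, size=n)])


def generate_templates(
    spec: TemplateSpec,
    fwd_peptide: PeptidePattern | str,
    rev_peptide: PeptidePattern | str,
    max_resample: int = 50,
) -> tuple[list[TemplateSeq], list[TemplateTruth]]:
    """Generate one DNA template per family protein, with ground truth.

    Each template is ``flank — coding(A) — spacer — coding(B) — flank``
    where A is the protein prefix through the forward motif and B the
    suffix from the reverse motif on; both coding segments translate back
    to their protein segment exactly.  The recorded inter-primer distance
    (forward-core 3' end to reverse-core 5' start) equals the drawn spacer
    length, so the expected product length is
    ``len(fwd core) + spacer + len(rev core)`` plus any intron inserted
    between the sites.
    """
    if isinstance(fwd_peptide, str):
        fwd_peptide = PeptidePattern.parse(fwd_peptide)
    if isinstance(rev_peptide, str):
        rev_peptide = PeptidePattern.parse(rev_peptide)
    proteins = generate_family(spec.family)
    rng = np.random.default_rng(spec.codon_choice_seed)

    fwd_sense = "".join(c.triplet for c in encode_codons(fwd_peptide))
    rev_sense = "".join(c.triplet for c in encode_codons(rev_peptide))
    fwd_core = trim_wobble(fwd_sense)
    rev_site = trim_wobble(rev_sense)  # plus-strand footprint of the reverse core
    rev_core = reverse_complement(rev_site)
    k1, k2 = len(fwd_peptide), len(rev_peptide)
    fwd_tables = _compatible_codons(fwd_peptide)
    rev_tables = _compatible_codons(rev_peptide)

    templates: list[TemplateSeq] = []
    truths: list[TemplateTruth] = []
    for ident, protein in proteins.records:
        occ_f = fwd_peptide.occurrences(protein)
        if not occ_f:
            raise ValueError(f"forward peptide absent from protein {ident!r}")
        p1 = occ_f[0]
        occ_r = [o for o in rev_peptide.occurrences(protein) if o >= p1 + k1]
        if not occ_r:
            raise ValueError(
                f"reverse peptide absent downstream of the forward motif "
                f"in protein {ident!r}"
            )
        p2 = occ_r[0]
        seg_a = protein[: p1 + k1]
        seg_b = protein[p2:]
        trim_a = 3 * k1 - len(fwd_core)  # wobble bases shed into the spacer

        for attempt in range(max_resample):
            spacer = int(rng.integers(spec.spacer_length[0], spec.spacer_length[1] + 1))
            insert = spacer - trim_a
            if insert < 0:
                raise ValueError(
                    f"spacer of {spacer} nt is shorter than the {trim_a} "
                    f"trimmed wobble base(s) of the forward motif"
                )
            flank5 = _random_dna(
                rng, int(rng.integers(spec.flank_length[0], spec.flank_length[1] + 1))
            )
            flank3 = _random_dna(
                rng, int(rng.integers(spec.flank_length[0], spec.flank_length[1] + 1))
            )
            cds_a = _back_translate(
                seg_a, rng, {p1 + j: fwd_tables[j] for j in range(k1)}
            )
            cds_b = _back_translate(
                seg_b, rng, {j: rev_tables[j] for j in range(k2)}
            )
            seq = flank5 + cds_a + _random_dna(rng, insert) + cds_b + flank3
            fwd_start = len(flank5) + 3 * p1
            fwd_end = fwd_start + len(fwd_core)
            rev_start = len(flank5) + len(cds_a) + insert
            rev_end = rev_start + len(rev_core)
            product = len(fwd_core) + spacer + len(rev_core)

            for off, ln in spec.introns:
                if off > spacer:
                    raise ValueError(
                        f"intron offset {off} beyond the {spacer}-nt spacer"
                    )
                at = fwd_end + off
                intron = "GT" + _random_dna(rng, ln - 4) + "AG"
                seq = seq[:at] + intron + seq[at:]
                rev_start += ln
                rev_end += ln
                product += ln

            template = TemplateSeq(ident, seq, description="synthetic template")
            n_f = len(find_binding_sites(fwd_core, template, 0, anchor_len=0))
            n_r = len(find_binding_sites(rev_core, template, 0, anchor_len=0))
            if n_f == 1 and n_r == 1:
                break
            logger.info(
                "template %s attempt %d: spurious binding site "
                "(fwd %d, rev %d); resampling", ident, attempt + 1, n_f, n_r
            )
        else:
            raise RuntimeError(
                f"could not build a unique-site template for {ident!r} "
                f"in {max_resample} attempts"
            )

        templates.append(template)
        truths.append(
            TemplateTruth(
                template_id=ident,
                fwd_start=fwd_start,
                fwd_end=fwd_end,
                rev_start=rev_start,
                rev_end=rev_end,
                inter_primer_distance=spacer,
                expected_product_length=product,
            )
        )
    return templates, truths
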