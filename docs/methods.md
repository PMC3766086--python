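# Methods

## Sequence algebra

All primer and template arithmetic runs over the 15 IUPAC nucleotide
codes plus inosine, treated as a 16th symbol. Inosine base-pairs with
all four DNA bases but is a single physical nucleoside, so it matches
like `N` while contributing a factor of 1 to *degeneracy* (oligo species
in the mixture) and a factor of 4 to *coverage fold* (concrete sequences
the primer can pair with). Its complement is defined as itself: an
inosine on either strand sits opposite an arbitrary base, and the
published reverse primers indeed carry I at the positions complementary
to inosine codons. Input is case-insensitive with uppercase canonical
output; `U` is rejected outright (DNA-only tool). Matching a degenerate
pattern to a concrete string is per-position set membership with no
transition/transversion weighting, and a template `N` matches nothing —
an unknown base cannot be certified to pair, so the conservative reading
costs a mismatch.

## Reverse translation

Each amino acid maps to one canonical degenerate codon derived from the
standard genetic code: 4-fold wobble → inosine, 2-fold → the two-base
IUPAC code, Met/Trp stay concrete, Ile keeps its native 3-fold ambiguity
as `ATH`. The six-codon amino acids use a single family each: Leu `CTI`
(CTN only), Arg `MGI` (CGN plus AGR), Ser `TCI` (TCN only). `CTI` and
`TCI` therefore miss the TTR and AGY codons of their residues, and `MGI`
additionally pairs with two Ser codons; every codon object carries its
exact covered residue set plus incomplete/widened-coverage flags, so
these compromises are reported rather than silent. The Ser choice is by
analogy with Leu (same family structure); Ser does not occur in the
shipped golden suite, so the analogy is the only guide, and the
incomplete-coverage flag always accompanies it.

Peptide positions that allow several residues (`[FY]`, `[DN]`) merge
their members' canonical codons base-by-base by IUPAC set union; a union
covering all four bases is written as inosine, consistent with the
convention above. Merging can widen coverage beyond the requested
residues; the widened set is computed by translating every expansion of
the merged triplet and is reported on the codon.

## Primer construction

The sense-strand encoding of the peptide is trimmed at its 3′ end while
the terminal base is degenerate or inosine — the polymerase extends from
the 3′ terminus, which must pair perfectly — then a forward primer takes
the trimmed core as is and a reverse primer takes its reverse
complement. Trimming before orientation places the removed wobble bases
tail-proximal in reverse primers; this single reading reproduces 18 of
the 20 published GH6/GH7/GH45 primers exactly, which is why it was
adopted over trimming each finished primer's own 3′ end. The trim is a
loop (merged codons can end in two degenerate bases) and refuses to
empty the core. A constant non-templated 5′ tail, default `CTGGAC`
(six bases), is prepended to improve the performance of short primers;
the golden suite stores each published row's tail verbatim because the
published set mixes `CAGGTC` and `CTGGAC` with no stated rule. The two
golden rows that no consistent rule reproduces (`GWLGWP`, one base
short; `WR[FY][DN]WF`, two positions narrowed within the rule's
degenerate sets) are flagged *deviant* and asserted against their
documented deviations — likely manual edits whose intent is not guessed.
Each primer record carries thermal-profile metadata (default 95 °C 5 min;
30–40 cycles of 95 °C 20 s / anneal 30 s / 72 °C 60 s; 72 °C 5 min) with
the annealing temperature left as the per-pair knob; the default of
55 °C is a placeholder midpoint, as both it and the cycle count must be
optimized per primer set at the bench.

## Motif mining

Conservation is alignment-free containment: a k-peptide's support is the
number of *distinct* sequences containing it, because a primer's value
lies in amplifying across species, not in repeated hits within one
sequence. Defaults: k = 6 (hexapeptides; 7 supported for the
heptapeptide motifs in the golden suite, 4–10 accepted),
`min_support_fraction` = 0.5, at most 10 reported patterns. Merging of
near-identical k-mers into an ambiguous pattern is off by default
(`max_variable_positions` = 0) and capped at 2 variable positions; when
enabled, a greedy pass seeded from the highest-support exact k-mer
absorbs candidates within the Hamming bound, in (support desc,
encoded-core degeneracy asc, lexicographic) order, as long as the merged
pattern stays within the variable-position cap. Merged patterns are
re-scored by direct pattern matching, since a union pattern can also
match recombinant variants of its members. Ranking is total — support
descending, then mixture degeneracy of the encoded core ascending (a
less dilute mixture needs less annealing-temperature rescue), then
pattern text — so results are reproducible including ties. The neighbor
search uses a pigeonhole chunk index (k-mers within Hamming distance d
share one of d+1 contiguous chunks), which keeps mining a 20 × 300
family well under a second; an independent brute-force miner in the test
suite checks exact equivalence on small inputs.

## In-silico PCR

Only the core is matched (tails are non-templated); a site needs total
mismatches within budget *and* a perfect match over the 3′-terminal
`anchor_len` bases. Defaults `max_mismatches` = 0 and `anchor_len` = 3
favor specificity — the method was built for primer sanity-checking, not
sensitive site discovery. Coordinates are 0-based half-open on the
template plus strand. A plus-strand product pairs a plus-strand forward
site with a downstream minus-strand reverse site; the minus-strand case
is the mirror image. Product length runs from forward-site 5′ end to
reverse-site 5′ end, tails excluded (+12 nt on a gel with the standard
six-base tails, noted in the output docs). Extracted products are
returned in product orientation with six-frame translations; because 3′
trimming removes the last motif codon's wobble bases, a product's
translation carries each boundary motif minus (possibly) its final
residue. Genomic templates with introns will of course run longer than
coding-sequence predictions; the tool predicts on the templates it is
given and makes no attempt at spliced alignment.

## Synthetic fixtures

The family generator draws a uniformly random ancestor, plants motifs at
fixed positions, and derives homologs by i.i.d. per-site substitution
(default 0.3) outside the motif spans — deliberately simpler than real
families: no phylogenetic correlation, no indels, no composition bias.
Each motif is retained in exactly `round(fraction × n)` sequences;
non-retaining sequences get the span substituted like background with
one position forced off-pattern if needed. Defaults (20 homologs, 300
residues) give a family where a unanimously conserved hexapeptide is
recoverable at rank 1 while background 6-mers rarely exceed support 2.

Templates back-translate each protein with uniformly random codon
choices, except inside the two primer-site spans, where codons are drawn
from the degenerate core's own family so that every template carries
exactly one perfect binding site per core (uniqueness over both strands
is verified and the template resampled, up to a logged bound, if a
second zero-mismatch site arises). Outside those spans the full codon
set is used on purpose: occurrences of Leu/Arg/Ser elsewhere can fall
outside the primer's covered family, exercising the coverage warnings.
The template layout is flank — coding(prefix through forward motif) —
spacer — coding(reverse motif through suffix) — flank; the trimmed
wobble bases of the forward motif's last codon are counted as part of
the spacer, so the recorded inter-primer distance equals the drawn
spacer length and the expected product is `len(fwd core) + spacer +
len(rev core)` exactly. Optional introns are inserted with GT…AG termini
at offsets measured into the spacer and shift the expected product by
their length. Passing tests on these fixtures demonstrates the
pipeline's internal consistency — motif recovery, primer-site
arithmetic, strand handling — not robustness to indels, intron-split
binding sites, or real codon-usage bias.

## Numerical and interface choices

Everything random takes an explicit integer seed (numpy `default_rng`);
there is no global random state, and identical inputs give byte-identical
outputs, tables included. Expansion of a degenerate sequence refuses to
enumerate above an explicit limit. Tables are TSV (no quoting, header
row, fixed column order); FASTA is written at 60 columns, and primer
FASTA uses plain uppercase `I` for inosine — a documented extension of
the nucleotide alphabet. The FASTA reader is a small strict parser that
reports line numbers for malformed input and rejects duplicate
identifiers, since primer files are often hand-edited. Logging goes to
standard error and results to standard output or files, so the CLI
subcommands (`mine`, `design`, `pcr`, `simulate`, `table2`) compose in
pipelines.

## Problem sizes

The shipped test and acceptance runs use the fixture defaults above:
1,000 randomized sequences for the algebra properties, 500 peptides for
the encode/translate round trip, 100 random templates up to 2 kb for the
scanning oracle, 100 seeded simulations for motif recovery, and 20
templates with a fixed 200-nt spacer (± one 80-nt intron) for the
end-to-end check.

## Known limitations

No melting-temperature or secondary-structure screening; no
codon-usage-biased back-translation; no spliced or gapped matching in
the in-silico PCR; mining is containment-based and will miss motifs
conserved only as alignment columns with shifting flanks; the Ser codon
family choice (TCI) is a convention, not a datum.
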