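# hexaprime

Degenerate, inosine-containing PCR primer design from conserved peptide
motifs, with in-silico PCR validation.

## The problem

Cloning new members of an enzyme family from non-model organisms — for
example cellulases of glycoside hydrolase families GH6, GH7 and GH45 from
thermophilic fungi — usually starts before any genome sequence exists.
The classical route is degenerate PCR: find short peptides (hexa- or
heptapeptides) conserved across the known homologs, reverse translate
them into mixed-base primers, and amplify the unknown gene between two
such motifs. `hexaprime` implements that workflow end to end:

1. **mine** the most conserved k-peptides from a protein family
   (alignment-free, counted by the number of distinct sequences that
   contain each peptide);
2. **design** primers from a peptide pattern: each residue becomes its
   canonical degenerate codon — a fully degenerate (4-fold) third
   position is synthesized as inosine (I), a 2-fold position as the IUPAC
   two-base code (Y, R, ...), Leu/Arg/Ser use one six-codon family each
   (CTI / MGI / TCI) — then degenerate bases are trimmed from the 3′ end
   of the sense encoding, reverse primers take the reverse complement,
   and a constant six-base 5′ tail (`CTGGAC` by default) is prepended;
3. **validate** a primer pair by in-silico PCR against DNA templates,
   honoring inosine wildcards, a mismatch budget, and a perfect-match
   3′ anchor.

Two degeneracy figures are tracked throughout: *degeneracy* (distinct
oligo species in the synthesized mixture; inosine counts 1) and
*coverage fold* (concrete sequences the primer can pair with; inosine
counts 4).

The package ships the published 20-primer GH6/GH7/GH45 cellulase set as a
golden suite: the rules above rebuild 18 of the 20 primers
character-for-character, and the remaining two are recorded with their
documented 1- and 2-base deviations (`hexaprime table2`).

## Worked example

Generate a synthetic family of 20 homologs (300 residues, 30% background
substitution) with the motifs YWDCCK and WDCCKP planted 200 nt apart on
matched DNA templates, then mine, design and amplify:

```text
$ hexaprime simulate --seed 7 --outdir fix
INFO hexaprime: seed 7: wrote 20 proteins and 20 templates to fix

$ hexaprime mine fix/proteins.fasta
1	WDCCKP	20/20	16
2	YWDCCK	20/20	32
3	DWDCCK	18/20	32
...
```

Both planted motifs are recovered with unanimous support (20/20); the
last column is the mixture degeneracy of each peptide's encoding (WDCCKP
ranks first on the lower-degeneracy tie-break). Build a forward primer:

```text
$ hexaprime design --peptide YWDCCK --direction forward
CTGGACTAYTGGGAYTGYTGYAA
```

— the six-base tail `CTGGAC`, then TAY-TGG-GAY-TGY-TGY encoding YWDCC,
then `AA`: the K codon AAR loses its degenerate R to the 3′ trim. Run
the pair against the templates:

```text
$ hexaprime pcr fix/templates.fasta --fwd-peptide YWDCCK --rev-peptide WDCCKP
syn01	+	234	0	0
syn02	+	234	0	0
...
```

One product per template on the plus strand, no mismatches, and
234 nt = 17 (forward core) + 200 (spacer) + 17 (reverse core) exactly as
constructed. Tails are non-templated and excluded: a gel would show each
band 12 nt longer.

The same steps are available as library calls (`mine_conserved`,
`build_primer`, `predict_amplicons`, ...); see the module docstrings.

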