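"""FASTA and TSV input/output plus run configuration.

All tables are tab-separated UTF-8 with a header row and a stable column
order; FASTA is written at 60 columns.  Primer FASTA may contain an
uppercase ``I`` for inosine — a documented extension of the nucleotide
alphabet, kept uppercase so records survive round-trips unchanged.

FASTA reading is deliberately strict (a line-numbered parse error beats a
silently skipped record when the input is a hand-edited primer file), so
the reader is a small validating parser rather than a permissive one.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, TextIO

import yaml

from .codons import AMINO_ACIDS
from .mining import ConservedPeptideHit, ProteinSet
from .pcr import AmpliconHit, ProductRecord, TemplateSeq
from .primers import DEFAULT_TAIL, PrimerRecord

__all__ = [
    "FastaParseError",
    "RunConfig",
    "read_fasta",
    "read_protein_fasta",
    "read_dna_fasta",
    "write_fasta",
    "write_primer_tsv",
    "write_hits_tsv",
    "write_amplicon_tsv",
    "write_truth_tsv",
]

_FASTA_WIDTH = 60


class FastaParseError(ValueError):
    """Malformed FASTA input; the message carries the offending line."""


@dataclass
class RunConfig:
    """Pipeline parameters, serializable to YAML with full round-trip
    fidelity."""

    k: int = 6
    min_support_fraction: float = 0.5
    max_variable_positions: int = 0
    max_patterns: int = 10
    tail: str = DEFAULT_TAIL
    max_mismatches: int = 0
    anchor_len: int = 3
    min_product_len: int = 30
    max_product_len: int = 10_000
    seed: int = 0
    output_dir: str = "."

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} does not hold a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _parse_fasta(handle: TextIO) -> Iterator[tuple[str, str, str, int]]:
    """Yield (identifier, description, sequence, header_line_no)."""
    ident: str | None = None
    desc = ""
    chunks: list[str] = []
    start_line = 0
    for line_no, raw in enumerate(handle, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            if ident is not None:
                yield ident, desc, "".join(chunks), start_line
            head = line[1:].strip()
            if not head:
                raise FastaParseError(f"line {line_no}: empty FASTA header")
            ident, _, desc = head.partition(" ")
            chunks = []
            start_line = line_no
        else:
            if ident is None:
                raise FastaParseError(
                    f"line {line_no}: sequence data before any FASTA header"
                )
            chunks.append(line.upper())
    if ident is not None:
        yield ident, desc, "".join(chunks), start_line


def read_fasta(path: str | Path) -> list[tuple[str, str, str]]:
    """Read FASTA as (identifier, description, uppercase sequence) triples,
    rejecting duplicate identifiers and empty records."""
    out: list[tuple[str, str, str]] = []
    seen: set[str] = set()
    with open(path) as handle:
        for ident, desc, seq, line_no in _parse_fasta(handle):
            if ident in seen:
                raise FastaParseError(
                    f"line {line_no}: duplicate identifier {ident!r}"
                )
            if not seq:
                raise FastaParseError(
                    f"line {line_no}: record {ident!r} has no sequence"
                )
            seen.add(ident)
            out.append((ident, desc, seq))
    if not out:
        raise FastaParseError(f"{path}: no FASTA records found")
    return out


def read_protein_fasta(path: str | Path) -> ProteinSet:
    records = []
    allowed = AMINO_ACIDS | {"X"}
    for ident, _, seq in read_fasta(path):
        bad = set(seq) - allowed
        if bad:
            raise FastaParseError(
                f"record {ident!r}: invalid protein residue(s) {sorted(bad)}"
            )
        records.append((ident, seq))
    return ProteinSet(tuple(records))


def read_dna_fasta(path: str | Path) -> list[TemplateSeq]:
    templates = []
    for ident, desc, seq in read_fasta(path):
        bad = set(seq) - set("ACGTN")
        if bad:
            raise FastaParseError(
                f"record {ident!r}: invalid DNA character(s) {sorted(bad)}"
            )
        templates.append(TemplateSeq(ident, seq, desc))
    return templates


def write_fasta(
    path: str | Path, records: Iterable[tuple[str, str]], width: int = _FASTA_WIDTH
) -> None:
    """Write (identifier, sequence) pairs as wrapped FASTA."""
    with open(path, "w") as handle:
        for ident, seq in records:
            handle.write(f">{ident}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


def _write_tsv(path: str | Path, header: list[str], rows: Iterable[list]) -> None:
    with open(path, "w") as handle:
        handle.write("\t".join(header) + "\n")
        for row in rows:
            handle.write("\t".join(str(x) for x in row) + "\n")


def write_primer_tsv(path: str | Path, primers: Iterable[PrimerRecord]) -> None:
    _write_tsv(
        path,
        ["name", "family", "peptide", "direction", "tail", "core",
         "full_sequence", "length", "degeneracy", "coverage_fold"],
        (
            [p.name, p.family, p.peptide.text, p.direction, p.tail, p.core,
             p.full_sequence, p.length, p.degeneracy, p.coverage_fold]
            for p in primers
        ),
    )


def write_hits_tsv(path: str | Path, hits: Iterable[ConservedPeptideHit]) -> None:
    _write_tsv(
        path,
        ["rank", "pattern", "k", "support", "support_fraction", "degeneracy",
         "occurrences"],
        (
            [h.rank, h.pattern.text, len(h.pattern), h.support,
             f"{h.support_fraction:.4f}", h.degeneracy,
             ";".join(f"{sid}:{off}" for sid, off in h.positions)]
            for h in hits
        ),
    )


def write_amplicon_tsv(path: str | Path, hits: Iterable[AmpliconHit]) -> None:
    _write_tsv(
        path,
        ["template", "fwd_primer", "fwd_start", "fwd_end", "rev_primer",
         "rev_start", "rev_end", "strand", "product_length",
         "mismatches_forward", "mismatches_reverse"],
        (
            [h.template_id, h.fwd_name, h.fwd_start, h.fwd_end, h.rev_name,
             h.rev_start, h.rev_end, h.strand, h.product_length,
             h.mismatches_forward, h.mismatches_reverse]
            for h in hits
        ),
    )


def write_truth_tsv(path: str | Path, truths: Iterable) -> None:
    _write_tsv(
        path,
        ["template", "fwd_start", "fwd_end", "rev_start", "rev_end",
         "inter_primer_distance", "expected_product_length"],
        (
            [t.template_id, t.fwd_start, t.fwd_end, t.rev_start, t.rev_end,
             t.inter_primer_distance, t.expected_product_length]
            for t in truths
        ),
    )


def write_product_fasta(path: str | Path, products: Iterable[ProductRecord]) -> None:
    write_fasta(path, ((p.identifier, p.sequence) for p in products))
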