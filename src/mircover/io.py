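"""Readers and writers for the plain-text formats the pipeline consumes.

Evidence tables are TSV with header
``mirna_id  gene_id  source_name  source_class  direction  confidence``
(the confidence column may be omitted; it then defaults to 1.0).
Sequences are FASTA (read through Biopython, T→U normalised on input),
annotations are GMT, Ct measurements and PI intensities are CSV.
All parse errors name the offending line.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Set, Union

import pandas as pd
from Bio import SeqIO

from .model import (
    Direction,
    EvidenceRecord,
    EvidenceTable,
    GeneSet,
    SequenceSet,
    SourceClass,
)

PathLike = Union[str, Path]

EVIDENCE_COLUMNS = ["mirna_id", "gene_id", "source_name", "source_class", "direction", "confidence"]


class ParseError(ValueError):
    """Raised for malformed input files; the message names the line."""


def read_gene_set(path: PathLike) -> GeneSet:
    """Read a gene set: one symbol per line, blank lines and '#' comments skipped."""
    symbols = []
    for line in Path(path).read_text().splitlines():
        s = line.strip()
        if s and not s.startswith("#"):
            symbols.append(s)
    return GeneSet(symbols)


def write_gene_set(genes: GeneSet, path: PathLike) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def read_evidence_table(path: PathLike) -> EvidenceTable:
    """Read a TSV evidence table, validating header, enums, bounds and key uniqueness."""
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file, expected a header line") from None
        header = [h.strip() for h in header]
        if header not in (EVIDENCE_COLUMNS, EVIDENCE_COLUMNS[:-1]):
            raise ParseError(
                f"{path}: line 1: malformed header {header!r}; "
                f"expected {EVIDENCE_COLUMNS} (confidence optional)"
            )
        has_conf = len(header) == len(EVIDENCE_COLUMNS)
        records: List[EvidenceRecord] = []
        seen: Set[tuple] = set()
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(header):
                raise ParseError(
                    f"{path}: line {lineno}: expected {len(header)} fields, got {len(row)}"
                )
            mirna_id, gene_id, source_name = (f.strip() for f in row[:3])
            try:
                source_class = SourceClass(row[3].strip().lower())
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}: unknown source_class {row[3]!r}"
                ) from None
            try:
                direction = Direction(row[4].strip().lower())
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}: unknown direction {row[4]!r}"
                ) from None
            if has_conf:
                try:
                    confidence = float(row[5])
                except ValueError:
                    raise ParseError(
                        f"{path}: line {lineno}: confidence {row[5]!r} is not a number"
                    ) from None
            else:
                confidence = 1.0
            try:
                rec = EvidenceRecord(
                    mirna_id, gene_id, source_name, source_class, direction, confidence
                )
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
            if rec.key in seen:
                raise ParseError(
                    f"{path}: line {lineno}: duplicate (miRNA, gene, source) key {rec.key}"
                )
            seen.add(rec.key)
            records.append(rec)
    return EvidenceTable(records)


def write_evidence_table(table: EvidenceTable, path: PathLike) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(EVIDENCE_COLUMNS)
        for rec in table.records:
            writer.writerow(
                [
                    rec.mirna_id,
                    rec.gene_id,
                    rec.source_name,
                    rec.source_class.value,
                    rec.direction.value,
                    repr(rec.confidence),
                ]
            )


def read_fasta(path: PathLike, role: str) -> SequenceSet:
    """Read FASTA into a :class:`SequenceSet`; sequences are T→U normalised."""
    path = Path(path)
    entries: Dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in entries:
            raise ParseError(f"{path}: duplicate FASTA id {record.id!r}")
        seq = str(record.seq)
        if not seq:
            raise ParseError(f"{path}: empty sequence for record {record.id!r}")
        entries[record.id] = seq
    if not entries:
        raise ParseError(f"{path}: no FASTA records found")
    return SequenceSet(entries, role=role)


def write_fasta(seqs: SequenceSet, path: PathLike, width: int = 60) -> None:
    with Path(path).open("w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_gmt(path: PathLike) -> Dict[str, Set[str]]:
    """Read a GMT annotation file into a term → gene-set mapping.

    GMT lines are ``term<TAB>description<TAB>gene1<TAB>gene2...``; the
    description is discarded, gene symbols are upper-cased.
    """
    path = Path(path)
    terms: Dict[str, Set[str]] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ParseError(
                f"{path}: line {lineno}: GMT record needs term, description and >=1 gene"
            )
        term = fields[0].strip()
        if term in terms:
            raise ParseError(f"{path}: line {lineno}: duplicate term {term!r}")
        genes = {g.strip().upper() for g in fields[2:] if g.strip()}
        if not genes:
            raise ParseError(f"{path}: line {lineno}: term {term!r} has no genes")
        terms[term] = genes
    return terms


def write_gmt(terms: Dict[str, Set[str]], path: PathLike, descriptions: Dict[str, str] = None) -> None:
    descriptions = descriptions or {}
    with Path(path).open("w") as fh:
        for term, genes in terms.items():
            desc = descriptions.get(term, "na")
            fh.write("\t".join([term, desc] + sorted(genes)) + "\n")


def write_tsv(rows: Iterable[Sequence], path: PathLike, header: Sequence[str] = None) -> None:
    """Write rows of plain values as TSV (used by the CLI for stage outputs)."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        if header is not None:
            writer.writerow(list(header))
        for row in rows:
            writer.writerow(list(row))


def read_ct_csv(path: PathLike) -> pd.DataFrame:
    """Read replicate Ct measurements: columns sample_id, group, assay, ct."""
    df = pd.read_csv(path)
    required = ["sample_id", "group", "assay", "ct"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing Ct columns {missing}")
    return df[required]


def read_intensity_csv(path: PathLike) -> pd.DataFrame:
    """Read per-cell PI intensities: columns condition, intensity."""
    df = pd.read_csv(path)
    required = ["condition", "intensity"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing intensity columns {missing}")
    return df[required]
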