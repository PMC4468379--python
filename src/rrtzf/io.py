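"""Reading and writing the external formats the pipeline touches.

Sequence input is plain (optionally aligned) FASTA or Clustal; tabular
input is TSV.  All records are normalised into :class:`SequenceRecord` /
:class:`Alignment` containers, and every coordinate reported anywhere in
the package is 1-based inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import AlignIO

log = logging.getLogger(__name__)

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY") | {"X"}
DNA_ALPHABET = set("ACGT") | {"N"}

CT_COLUMNS = ("gene", "group", "bio_rep", "tech_rep", "ct")
GERMINATION_COLUMNS = ("genotype", "condition", "replicate", "germinated", "total")


class ParseError(ValueError):
    """Raised on malformed input, naming the offending line or record."""


@dataclass(frozen=True)
class SequenceRecord:
    """One named protein or nucleotide sequence.

    ``id`` is the first whitespace-delimited header token; the full header
    is kept in ``description``.  Residues are stored uppercase.
    """

    id: str
    residues: str
    description: str = ""
    alphabet: str = "protein"

    def __post_init__(self) -> None:
        if not self.residues:
            raise ParseError(f"record {self.id!r}: empty sequence")
        allowed = PROTEIN_ALPHABET if self.alphabet == "protein" else DNA_ALPHABET
        bad = set(self.residues) - allowed - {"-"}
        if "." in bad:
            raise ParseError(
                f"record {self.id!r} uses '.' — only '-' is accepted as gap symbol"
            )
        if bad:
            raise ParseError(
                f"record {self.id!r}: symbols {sorted(bad)} outside the "
                f"{self.alphabet} alphabet"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def ungapped(self) -> str:
        return self.residues.replace("-", "")


@dataclass(frozen=True)
class Alignment:
    """An ordered set of equal-length gapped sequences (gap symbol '-')."""

    records: tuple[SequenceRecord, ...]

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.records}
        if len(lengths) > 1:
            ragged = [r.id for r in self.records if len(r) != len(self.records[0])]
            raise ParseError(f"ragged alignment: rows {ragged} differ in length")

    @property
    def column_count(self) -> int:
        return len(self.records[0]) if self.records else 0

    def column(self, j: int) -> str:
        """Residues of 1-based column ``j``, gaps included."""
        return "".join(r.residues[j - 1] for r in self.records)

    def degapped(self) -> list[SequenceRecord]:
        return [
            SequenceRecord(r.id, r.ungapped(), r.description, r.alphabet)
            for r in self.records
        ]


def _check_unique_ids(records: Sequence[SequenceRecord]) -> None:
    seen: set[str] = set()
    for r in records:
        if r.id in seen:
            raise ParseError(f"duplicate sequence id {r.id!r}")
        seen.add(r.id)


def read_fasta(path: str | Path, alphabet: str = "protein") -> list[SequenceRecord]:
    """Read a FASTA file into a list of :class:`SequenceRecord`.

    Order is preserved; residues are uppercased.  Malformed headers and
    empty sequences raise :class:`ParseError` naming the line.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        seq = "".join(chunks).upper()
        if not seq:
            raise ParseError(f"{path}:{header_line}: record {header!r} has no sequence")
        ident = header.split()[0]
        records.append(SequenceRecord(ident, seq, header, alphabet))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                if not header:
                    raise ParseError(f"{path}:{lineno}: empty FASTA header")
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise ParseError(
                        f"{path}:{lineno}: sequence data before any '>' header"
                    )
                chunks.append(line)
    flush()
    if not records:
        log.warning("%s: empty FASTA file, returning no records", path)
    _check_unique_ids(records)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.description or r.id}\n")
            for i in range(0, len(r.residues), width):
                fh.write(r.residues[i : i + width] + "\n")


def read_alignment(path: str | Path, dialect: str = "aligned-fasta",
                   alphabet: str = "protein") -> Alignment:
    """Read an alignment in ``aligned-fasta`` or ``clustal`` dialect.

    Only '-' is accepted as the gap symbol; '.' is rejected explicitly
    because Clustal dialects vary on its meaning.
    """
    if dialect == "aligned-fasta":
        records = read_fasta(path, alphabet="protein")
        records = [
            SequenceRecord(r.id, r.residues, r.description, alphabet) if alphabet != "protein" else r
            for r in records
        ]
    elif dialect == "clustal":
        msa = AlignIO.read(str(path), "clustal")
        records = [
            SequenceRecord(rec.id, str(rec.seq).upper(), rec.description or rec.id, alphabet)
            for rec in msa
        ]
    else:
        raise ValueError(f"unknown alignment dialect {dialect!r}")
    for r in records:
        if "." in r.residues:
            raise ParseError(
                f"record {r.id!r} uses '.' — only '-' is accepted as gap symbol"
            )
    _check_unique_ids(records)
    return Alignment(tuple(records))


def write_alignment(alignment: Alignment, path: str | Path) -> None:
    write_fasta(alignment.records, path)


def _read_typed_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    return df


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Long-format qPCR CT table (gene, group, bio_rep, tech_rep, ct).

    Technical replicates are kept as separate rows; averaging happens in
    the expression module.
    """
    df = _read_typed_tsv(path, CT_COLUMNS)
    if (df["ct"] <= 0).any():
        raise ParseError(f"{path}: CT values must be positive")
    return df


def read_germination_table(path: str | Path) -> pd.DataFrame:
    """Germination counts (genotype, condition, replicate, germinated, total)."""
    df = _read_typed_tsv(path, GERMINATION_COLUMNS)
    if (df["total"] <= 0).any():
        raise ParseError(f"{path}: 'total' must be positive")
    if ((df["germinated"] < 0) | (df["germinated"] > df["total"])).any():
        raise ParseError(f"{path}: 'germinated' must lie in [0, total]")
    return df


def write_tsv_report(report: pd.DataFrame, path: str | Path,
                     columns: Sequence[str] | None = None) -> None:
    """Write a report with a deterministic column order (one row per item)."""
    if columns is not None:
        report = report.loc[:, list(columns)]
    report.to_csv(path, sep="\t", index=False)
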