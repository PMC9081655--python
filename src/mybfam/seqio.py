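"""FASTA and TSV input/output with validation.

Protein sequences use the 20 standard residues plus ``X`` (unknown), always
uppercase. The FASTA header convention is the de facto standard: the record
id is the first whitespace-delimited token, the remainder of the header line
is the description.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
ALPHABET = AMINO_ACIDS | {"X"}

NUCLEOTIDE_LETTERS = frozenset("ACGTUN")


class SeqIOError(ValueError):
    """Raised for malformed sequence or table input."""


@dataclass(frozen=True)
class ProteinRecord:
    """One amino-acid sequence with id and free-text description."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise SeqIOError(f"invalid record id {self.id!r}")
        if len(self.sequence) < 1:
            raise SeqIOError(f"record {self.id!r}: empty sequence")
        bad = [
            (i, c) for i, c in enumerate(self.sequence) if c not in ALPHABET
        ]
        if bad:
            i, c = bad[0]
            raise SeqIOError(
                f"record {self.id!r}: non-amino-acid character {c!r} "
                f"at position {i + 1}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def _looks_nucleotide(seq: str) -> bool:
    # heuristic guard: long sequences made almost entirely of ACGTUN are
    # nucleotide, not protein
    if len(seq) <= 50:
        return False
    frac = sum(c in NUCLEOTIDE_LETTERS for c in seq) / len(seq)
    return frac > 0.90


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA file into a validated record list.

    Sequences are uppercased and trailing ``*`` stop symbols are stripped.
    Duplicate ids, non-amino-acid characters, apparent nucleotide input and
    empty files all raise :class:`SeqIOError`.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SeqIOError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().rstrip("*")
        if _looks_nucleotide(seq):
            raise SeqIOError(
                f"{path}: record {rec.id!r} looks like a nucleotide sequence "
                "(>90% ACGTUN); translate to protein first"
            )
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        try:
            records.append(ProteinRecord(rec.id, seq, desc))
        except SeqIOError as exc:
            raise SeqIOError(f"{path}: {exc}") from None
    if not records:
        raise SeqIOError(f"{path}: no FASTA records found")
    return records


def write_fasta(
    records: Iterable[ProteinRecord], path: str | Path, wrap: int = 60
) -> None:
    """Write records as wrapped multi-FASTA."""
    records = list(records)
    if not records:
        logger.warning("write_fasta: empty record list -> empty file %s", path)
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), wrap):
                fh.write(rec.sequence[i : i + wrap] + "\n")


def read_table(path: str | Path, kind: Literal["tpm", "ct"]) -> pd.DataFrame:
    """Read a TSV table (first column = row id, header row required).

    ``kind="tpm"`` forbids negative cells; ``kind="ct"`` forbids
    non-positive cells.
    """
    if kind not in ("tpm", "ct"):
        raise ValueError(f"unknown table kind {kind!r}")
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError:
        raise SeqIOError(f"{path}: empty table") from None
    def _is_number(x: object) -> bool:
        try:
            float(str(x))
            return True
        except ValueError:
            return False

    if len(df.columns) and all(_is_number(c) for c in df.columns):
        raise SeqIOError(
            f"{path}: header row appears to be numeric data; a header with "
            "sample labels is required"
        )
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise SeqIOError(f"{path}: duplicate row id {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise SeqIOError(f"{path}: duplicate column label {dup!r}")
    for col in df.columns:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            row = df.index[(bad | df[col].isna())][0]
            raise SeqIOError(
                f"{path}: non-numeric or missing cell at row {row!r}, "
                f"column {col!r}"
            )
        df[col] = parsed
    if kind == "tpm" and (df.values < 0).any():
        r, c = next(zip(*((df.values < 0).nonzero())))
        raise SeqIOError(
            f"{path}: negative TPM at row {df.index[r]!r}, "
            f"column {df.columns[c]!r}"
        )
    if kind == "ct" and (df.values <= 0).any():
        r, c = next(zip(*((df.values <= 0).nonzero())))
        raise SeqIOError(
            f"{path}: non-positive Ct at row {df.index[r]!r}, "
            f"column {df.columns[c]!r}"
        )
    return df


def to_seqrecords(records: Iterable[ProteinRecord]) -> list[SeqRecord]:
    """Convert to Biopython SeqRecords (for interop)."""
    return [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
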