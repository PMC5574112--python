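"""Reading and writing the standard text formats used by the tool.

FASTA for sequences (via Biopython), TSV for fold labels (id, fold) and
supervision pairs (id1, id2, Y), and the labeled whitespace matrix dialect
of :mod:`wseqkernel.matrices` for substitution matrices.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .matrices import AminoAlphabet, CANONICAL_ALPHABET
from .string_kernel import SequenceRecord, sanitize_residues

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_labels_tsv",
    "write_labels_tsv",
    "read_pairs_tsv",
    "write_pairs_tsv",
]


def read_fasta(path: str | Path, alphabet: AminoAlphabet = CANONICAL_ALPHABET,
               *, drop_unknown: bool = False) -> list[SequenceRecord]:
    """Load FASTA records; ids are header tokens up to the first whitespace.

    Residues are uppercased.  Letters outside the alphabet raise a parse
    error naming the letter and position unless ``drop_unknown`` is set, in
    which case they are removed (and counted in the log).
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        residues = sanitize_residues(str(rec.seq), alphabet,
                                     drop_unknown=drop_unknown, seq_id=rec.id)
        records.append(SequenceRecord(rec.id, residues, alphabet))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def _read_tsv(path: Path, ncols: int) -> list[list[str]]:
    rows = []
    with path.open() as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < ncols:
                raise ValueError(f"{path}:{lineno}: expected {ncols} columns, got {len(row)}")
            rows.append(row)
    if not rows:
        raise ValueError(f"{path}: empty table")
    return rows


def read_labels_tsv(path: str | Path) -> dict[str, str]:
    """Fold labels: two columns, id and fold label (optional header line)."""
    path = Path(path)
    rows = _read_tsv(path, 2)
    if rows and rows[0][0].lower() in ("id", "seq_id", "sequence_id"):
        rows = rows[1:]
    labels = {}
    for row in rows:
        if row[0] in labels:
            raise ValueError(f"{path}: duplicate id {row[0]!r}")
        labels[row[0]] = row[1]
    return labels


def write_labels_tsv(ids: Sequence[str], labels: Sequence[str], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("id\tfold\n")
        for i, l in zip(ids, labels):
            fh.write(f"{i}\t{l}\n")


def read_pairs_tsv(path: str | Path) -> list[tuple[str, str, float]]:
    """Supervision pairs: three columns, id1, id2, structure score Y."""
    path = Path(path)
    rows = _read_tsv(path, 3)
    if rows and rows[0][0].lower() in ("id1", "seq_id_1"):
        rows = rows[1:]
    out = []
    for row in rows:
        try:
            out.append((row[0], row[1], float(row[2])))
        except ValueError:
            raise ValueError(f"{path}: non-numeric score {row[2]!r} for pair "
                             f"({row[0]}, {row[1]})") from None
    return out


def write_pairs_tsv(pairs: Iterable[tuple[str, str, float]], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("id1\tid2\tY\n")
        for a, b, y in pairs:
            fh.write(f"{a}\t{b}\t{y:.6g}\n")
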