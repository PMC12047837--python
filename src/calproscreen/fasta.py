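"""FASTA reading/writing with strict amino-acid validation.

Sequences are stored as plain one-letter strings restricted to the 20
canonical amino acids plus X (unknown). Parsing is delegated to
:mod:`Bio.SeqIO`; this module adds the validation layer the downstream
alignment code relies on (uppercase, unique ids, no non-residue characters).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")


class FastaError(ValueError):
    """Raised for malformed or invalid FASTA input."""


@dataclass(frozen=True)
class SequenceRecord:
    """A protein sequence with its FASTA header.

    Attributes
    ----------
    id : str
        First whitespace-delimited token of the header; unique within a file.
    description : str
        Remainder of the header line (may be empty).
    residues : str
        Uppercase one-letter amino-acid string (canonical 20 plus X).
    """

    id: str
    description: str = ""
    residues: str = field(default="")

    def __post_init__(self) -> None:
        if not self.residues:
            raise FastaError(f"sequence {self.id!r} is empty")
        if not self.residues.isupper():
            object.__setattr__(self, "residues", self.residues.upper())
        for pos, ch in enumerate(self.residues, start=1):
            if ch not in VALID_RESIDUES:
                raise FastaError(
                    f"sequence {self.id!r}: invalid residue {ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into a list of validated :class:`SequenceRecord`.

    Wrapped lines are concatenated, residues are uppercased and record order
    is preserved. Raises :class:`FastaError` on an empty file, duplicate ids,
    or non-amino-acid characters (reported with their 1-based position).
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(SequenceRecord(id=rec.id, description=desc, residues=str(rec.seq)))
    if not records:
        raise FastaError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    """Write records to ``path`` wrapping sequence lines at ``width`` columns."""
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def parse_fasta_string(text: str) -> list[SequenceRecord]:
    """Parse FASTA from an in-memory string (same validation as read_fasta)."""
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        if rec.id in seen:
            raise FastaError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(SequenceRecord(id=rec.id, description=desc, residues=str(rec.seq)))
    if not records:
        raise FastaError("no FASTA records found")
    return records
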