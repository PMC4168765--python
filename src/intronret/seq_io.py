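"""Sequence I/O and pre-alignment sequence editing.

Conventions used throughout the package:

* user-facing coordinates are 1-based inclusive (NCBI style); internal
  slicing converts to 0-based half-open only at the point of use;
* DNA is uppercased on read, ``U`` is mapped to ``T`` with a warning;
* edits (known variants applied before comparing a predicted sequence to an
  observed one) are specified against the *unedited* sequence and applied
  from the highest position downward so coordinates stay valid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "SequenceRecord",
    "SequenceEdit",
    "FastaFormatError",
    "EditConflictError",
    "read_fasta",
    "write_fasta",
    "apply_sequence_edits",
    "read_edits_tsv",
    "reverse_complement",
]

logger = logging.getLogger(__name__)

_DNA_ALPHABET = set("ACGTNRYSWKMBDHV")
_PROTEIN_ONLY = set("EFILPQZ*")  # letters that cannot occur in IUPAC DNA


class FastaFormatError(ValueError):
    """Raised for malformed FASTA input; the message names the line number."""


class EditConflictError(ValueError):
    """Raised when an edit's expected reference bases do not match the sequence."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named sequence (DNA or protein).

    ``origin`` is the 1-based coordinate of the first residue on the parent
    molecule, used when the record is a slice of a larger reference (e.g. a
    chromosome window); it defaults to 1 for stand-alone sequences.
    """

    id: str
    residues: str
    description: str = ""
    origin: int = 1

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.residues:
            raise ValueError(f"record {self.id!r}: residues must be non-empty")
        if self.origin < 1:
            raise ValueError(f"record {self.id!r}: origin must be >= 1")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def is_dna(self) -> bool:
        letters = set(self.residues)
        return not (letters & _PROTEIN_ONLY) and letters <= _DNA_ALPHABET

    def slice_1based(self, start: int, end: int) -> str:
        """Residues for the parent-molecule interval [start, end], 1-based inclusive."""
        lo = start - self.origin
        hi = end - self.origin + 1
        if lo < 0 or hi > len(self.residues) or start > end:
            raise IndexError(
                f"interval {start}-{end} outside record {self.id!r} "
                f"(covers {self.origin}-{self.origin + len(self.residues) - 1})"
            )
        return self.residues[lo:hi]


@dataclass(frozen=True)
class SequenceEdit:
    """A known variant to apply before comparison: substitution, deletion or insertion.

    ``position`` is 1-based on the unedited target sequence. For insertions the
    inserted bases go immediately *after* ``position`` and ``ref`` is empty.
    """

    kind: str  # substitution | deletion | insertion
    position: int
    ref: str = ""
    alt: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("substitution", "deletion", "insertion"):
            raise ValueError(f"unknown edit kind {self.kind!r}")
        if self.position < 1:
            raise ValueError("edit position must be >= 1")
        if self.kind == "substitution" and len(self.ref) != len(self.alt):
            raise ValueError("substitution requires len(ref) == len(alt)")
        if self.kind == "deletion" and self.alt:
            raise ValueError("deletion must have empty alt")
        if self.kind == "insertion" and self.ref:
            raise ValueError("insertion must have empty ref")


def _normalise(raw: str, record_id: str) -> str:
    seq = "".join(raw.split()).upper()
    if "U" in seq:
        logger.warning("record %r: RNA base U mapped to T", record_id)
        seq = seq.replace("U", "T")
    return seq


def _validate_fasta_layout(path: Path) -> None:
    """Single pass over the raw text to give line-numbered format errors."""
    header_line = None
    saw_residues = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith(">"):
                if header_line is not None and not saw_residues:
                    raise FastaFormatError(
                        f"{path}: empty record at line {header_line}"
                    )
                if not stripped[1:].strip():
                    raise FastaFormatError(
                        f"{path}: header with empty id at line {lineno}"
                    )
                header_line = lineno
                saw_residues = False
            else:
                if header_line is None:
                    raise FastaFormatError(
                        f"{path}: sequence data before any header at line {lineno}"
                    )
                saw_residues = True
    if header_line is not None and not saw_residues:
        raise FastaFormatError(f"{path}: empty record at line {header_line}")


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (multi-record) FASTA file into :class:`SequenceRecord` objects.

    Residues are uppercased and whitespace-stripped; records come back in file
    order. Malformed input raises :class:`FastaFormatError` naming the line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _validate_fasta_layout(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(
            SequenceRecord(id=rec.id, residues=_normalise(str(rec.seq), rec.id),
                           description=desc)
        )
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                line_width: int = 60) -> None:
    """Write records as wrapped FASTA. Round-trips with :func:`read_fasta`."""
    if line_width < 1:
        raise ValueError("line_width must be >= 1")
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), line_width):
                fh.write(rec.residues[i:i + line_width] + "\n")


def apply_sequence_edits(record: SequenceRecord,
                         edits: Sequence[SequenceEdit]) -> SequenceRecord:
    """Apply known variants to ``record`` (positions on the unedited sequence).

    Edits are applied high-to-low position so earlier coordinates stay valid.
    A ``ref`` mismatch raises :class:`EditConflictError` reporting expected vs
    found bases.
    """
    seq = record.residues
    for edit in sorted(edits, key=lambda e: e.position, reverse=True):
        i = edit.position - 1
        if edit.kind == "insertion":
            if i + 1 > len(seq):
                raise EditConflictError(
                    f"insertion after position {edit.position} beyond sequence "
                    f"end {len(seq)}"
                )
            seq = seq[: i + 1] + edit.alt.upper() + seq[i + 1:]
            continue
        end = i + len(edit.ref)
        if end > len(seq):
            raise EditConflictError(
                f"{edit.kind} at {edit.position} extends past sequence end {len(seq)}"
            )
        found = seq[i:end]
        if found != edit.ref.upper():
            raise EditConflictError(
                f"{edit.kind} at {edit.position}: expected {edit.ref!r}, "
                f"found {found!r}"
            )
        seq = seq[:i] + edit.alt.upper() + seq[end:]
    return replace(record, residues=seq)


def read_edits_tsv(path: str | Path) -> list[SequenceEdit]:
    """Read edits from a 4-column TSV: position, kind, ref, alt ('.' for empty)."""
    edits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            pos, kind, ref, alt = parts
            edits.append(SequenceEdit(
                kind=kind, position=int(pos),
                ref="" if ref == "." else ref,
                alt="" if alt == "." else alt,
            ))
    return edits


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())
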