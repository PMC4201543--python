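"""Protein sequence and cleavage-annotation I/O.

Coordinates are 1-based throughout and the scissile bond sits between P1 and
P1' (Schechter-Berger nomenclature): a cleavage annotated at position ``p``
cuts the backbone after residue ``p``.  Candidate-site context is the
fixed-width 8-mer spanning P5..P3'; positions that fall off either terminus
are padded with ``'X'`` so every window has identical shape downstream.
"""

from __future__ import annotations

import gzip
import io
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: The 20 standard amino acids, in the fixed index order used by the PWM.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Pad / unknown-residue symbol.
PAD = "X"

#: Ambiguity and rare-letter codes folded into 'X' on input.
AMBIGUOUS_LETTERS = frozenset("BZJUO")

#: Window position names, N- to C-terminal across the scissile bond.
WINDOW_POSITIONS = ("P5", "P4", "P3", "P2", "P1", "P1'", "P2'", "P3'")
WINDOW_SIZE = len(WINDOW_POSITIONS)
#: Index of P1 within a window (0-based).
P1_INDEX = 4

_ALLOWED = frozenset(AMINO_ACIDS + PAD)


class SequenceFormatError(ValueError):
    """Raised for unreadable FASTA input."""


class AnnotationError(ValueError):
    """Raised for cleavage annotations that fail validation."""


class CoordinateError(ValueError):
    """Raised for out-of-range sequence positions."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with its accession.

    ``sequence`` is uppercase over the 20 standard letters plus ``'X'``.
    """

    id: str
    sequence: str
    name: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein record requires a non-empty id")
        if not self.sequence:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(self.sequence) - _ALLOWED
        if bad:
            raise ValueError(
                f"{self.id}: disallowed sequence letters {sorted(bad)}; "
                "use clean_sequence() or read_fasta() to normalize input"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CleavageAnnotation:
    """An annotated scissile bond: cleavage after residue ``p1_position``."""

    protein_id: str
    p1_position: int
    label: str = "positive"
    source: str = ""

    def __post_init__(self) -> None:
        if self.p1_position < 1:
            raise AnnotationError(
                f"{self.protein_id}: p1_position must be >= 1, got {self.p1_position}"
            )
        if self.label not in ("positive", "negative"):
            raise AnnotationError(f"{self.protein_id}: bad label {self.label!r}")


@dataclass(frozen=True)
class CleavageWindow:
    """The 8-residue P5..P3' context of a candidate scissile bond."""

    residues: str
    p1_position: int
    padded_left: int = 0
    padded_right: int = 0

    def __post_init__(self) -> None:
        if len(self.residues) != WINDOW_SIZE:
            raise ValueError(f"window must have {WINDOW_SIZE} residues: {self.residues!r}")
        bad = set(self.residues) - _ALLOWED
        if bad:
            raise ValueError(f"window contains disallowed letters {sorted(bad)}")

    @property
    def p1_residue(self) -> str:
        return self.residues[P1_INDEX]


def clean_sequence(raw: str, record_id: str = "?") -> str:
    """Uppercase a sequence and fold non-standard letters into 'X'.

    B, Z, J, U, O (ambiguity codes, selenocysteine, pyrrolysine) are mapped
    to 'X' with a logged warning; '*' (stop) and gap characters are rejected.
    """
    seq = raw.upper()
    mapped = set(seq) & AMBIGUOUS_LETTERS
    if mapped:
        logger.warning(
            "%s: mapping non-standard letters %s to 'X'", record_id, sorted(mapped)
        )
        seq = "".join(PAD if c in AMBIGUOUS_LETTERS else c for c in seq)
    bad = set(seq) - _ALLOWED
    if bad:
        raise SequenceFormatError(
            f"{record_id}: unrecognized sequence characters {sorted(bad)}"
        )
    return seq


def _open_text(path: str | Path, mode: str = "rt"):
    """Open plain or gzip-compressed text transparently (sniffs magic bytes)."""
    path = Path(path)
    if "r" in mode:
        with open(path, "rb") as fh:
            magic = fh.read(2)
        if magic == b"\x1f\x8b":
            return gzip.open(path, mode)
        return open(path, mode)
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a (possibly gzipped) multi-record FASTA into ProteinRecords.

    Sequences are uppercased and non-standard letters mapped to 'X'.
    Raises :class:`SequenceFormatError` on empty or malformed input.
    """
    records: list[ProteinRecord] = []
    with _open_text(path) as fh:
        text = fh.read()
    if not text.strip():
        raise SequenceFormatError(f"{path}: empty FASTA file")
    first = next(line for line in text.splitlines() if line.strip())
    if not first.startswith(">"):
        raise SequenceFormatError(
            f"{path}: not FASTA — first non-blank line is not a header: {first[:40]!r}"
        )
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        if not str(rec.seq):
            raise SequenceFormatError(f"{path}: record {rec.id!r} has an empty sequence")
        records.append(
            ProteinRecord(
                id=rec.id,
                sequence=clean_sequence(str(rec.seq), rec.id),
                name=rec.description,
            )
        )
    if not records:
        raise SequenceFormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records as wrapped FASTA; round-trips standard-letter input."""
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.name if r.name != r.id else "")
        for r in records
    ]
    with _open_text(path, "wt") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


def read_annotations(
    path: str | Path,
    records: Sequence[ProteinRecord] | None = None,
    delimiter: str | None = None,
) -> list[CleavageAnnotation]:
    """Read a cleavage-annotation table.

    Expected columns: protein id, 1-based P1 position, then optionally a
    label (positive/negative, default positive) and a free-text source tag.
    ``delimiter=None`` splits on any whitespace (covers both space- and
    tab-delimited files); lines starting with '#' are comments.

    Rows that cannot be parsed (non-integer or non-positive position, too few
    columns) are rejected with row-numbered warnings.  When ``records`` is
    supplied, positions beyond the sequence end or unknown protein ids raise
    :class:`AnnotationError` listing every offending row.  Duplicate rows are
    deduplicated with the dropped count logged.
    """
    by_id = {r.id: r for r in records} if records is not None else None
    anns: list[CleavageAnnotation] = []
    rejects: list[str] = []
    fatal: list[str] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(delimiter) if delimiter else line.split()
            if len(parts) < 2:
                rejects.append(f"row {lineno}: too few columns ({line!r})")
                continue
            pid = parts[0]
            try:
                pos = int(parts[1])
            except ValueError:
                rejects.append(f"row {lineno}: position {parts[1]!r} is not an integer")
                continue
            if pos < 1:
                rejects.append(f"row {lineno}: position {pos} violates 1-based coordinates")
                continue
            label = parts[2] if len(parts) > 2 else "positive"
            if label not in ("positive", "negative"):
                # tolerate tables whose third column is a source tag
                label, source = "positive", " ".join(parts[2:])
            else:
                source = " ".join(parts[3:])
            if by_id is not None:
                rec = by_id.get(pid)
                if rec is None:
                    fatal.append(f"row {lineno}: unknown protein id {pid!r}")
                    continue
                if pos > len(rec):
                    fatal.append(
                        f"row {lineno}: position {pos} outside {pid} (length {len(rec)})"
                    )
                    continue
            anns.append(CleavageAnnotation(pid, pos, label, source))
    for msg in rejects:
        logger.warning("%s: rejected %s", path, msg)
    if fatal:
        raise AnnotationError(f"{path}: " + "; ".join(fatal))
    unique = list(dict.fromkeys(anns))
    if len(unique) < len(anns):
        logger.info("%s: dropped %d duplicate annotation rows", path, len(anns) - len(unique))
    return unique


def write_annotations(anns: Iterable[CleavageAnnotation], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("#protein_id\tp1_position\tlabel\tsource\n")
        for a in anns:
            fh.write(f"{a.protein_id}\t{a.p1_position}\t{a.label}\t{a.source}\n")


def extract_window(
    record: ProteinRecord, p1_position: int, allow_out_of_range: bool = False
) -> CleavageWindow:
    """Extract the P5..P3' window around a (putative) scissile bond.

    Returns residues p1-4 .. p1+3 as an 8-mer; positions before the
    N-terminus or past the C-terminus are filled with 'X' and counted in
    ``padded_left`` / ``padded_right``.  ``p1_position`` must lie within the
    sequence unless ``allow_out_of_range`` is set (used by the sliding-window
    negative builder, whose pseudo-P1 may fall just outside a short protein).
    """
    n = len(record.sequence)
    if not allow_out_of_range and not (1 <= p1_position <= n):
        raise CoordinateError(
            f"{record.id}: p1_position {p1_position} outside sequence of length {n}"
        )
    chars = []
    padded_left = padded_right = 0
    for pos in range(p1_position - 4, p1_position + 4):  # 1-based inclusive span
        if pos < 1:
            chars.append(PAD)
            padded_left += 1
        elif pos > n:
            chars.append(PAD)
            padded_right += 1
        else:
            chars.append(record.sequence[pos - 1])
    return CleavageWindow(
        residues="".join(chars),
        p1_position=p1_position,
        padded_left=padded_left,
        padded_right=padded_right,
    )


def display_window(record: ProteinRecord, p1_position: int) -> str:
    """P5-P5' 10-mer display string with '-' at the scissile bond.

    Example: the MEFV site at 330 renders as ``TCVRD-SCSFP``.
    """
    n = len(record.sequence)
    chars = []
    for pos in range(p1_position - 4, p1_position + 6):
        chars.append(record.sequence[pos - 1] if 1 <= pos <= n else PAD)
    return "".join(chars[:5]) + "-" + "".join(chars[5:])
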