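"""Sequence and annotation I/O.

FASTA/FASTQ parsing goes through Biopython's SeqIO; annotations use a
six-column BED-like TSV (seq_id, start, end, subfamily, fragment_group,
strand) with 0-based half-open coordinates. The fragment_group column links
the pieces of one biological TE copy that was split by a later nested
insertion — nesting detection depends on it, which is why it replaces the
BED score slot.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, TextIO, Union

from Bio import SeqIO

PathLike = Union[str, Path]

_COMPLEMENT = str.maketrans("ACGTN-", "TGCAN-")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Sequence:
    """A DNA sequence (possibly aligned, '-' allowed) with an identifier."""

    id: str
    residues: str
    placeholder: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        self.residues = self.residues.upper()
        if not self.residues and not self.placeholder:
            raise ValueError(f"empty residues for {self.id!r} (not a placeholder)")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class TECopyAnnotation:
    """One annotated TE copy interval, 0-based half-open."""

    seq_id: str
    start: int
    end: int
    subfamily: str
    fragment_group: Optional[str]
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start},{self.end}) on {self.seq_id}"
            )
        if self.strand not in {"+", "-"}:
            raise ValueError(f"unknown strand {self.strand!r}")
        if not self.subfamily:
            raise ValueError("subfamily must be non-empty")

    @property
    def length(self) -> int:
        return self.end - self.start


class FormatError(ValueError):
    pass


def _open(source: Union[PathLike, TextIO], mode: str = "r") -> TextIO:
    if hasattr(source, "read") or hasattr(source, "write"):
        return source  # type: ignore[return-value]
    return open(source, mode)


def read_fasta(source: Union[PathLike, TextIO]) -> list[Sequence]:
    """Read FASTA records; residues are upper-cased, line breaks removed."""
    handle = _open(source)
    close = handle is not source
    try:
        records = list(SeqIO.parse(handle, "fasta"))
    finally:
        if close:
            handle.close()
    if not records:
        raise FormatError("empty or non-FASTA input")
    seqs, seen = [], set()
    for rec in records:
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        seqs.append(Sequence(id=rec.id, residues=str(rec.seq)))
    return seqs


def write_fasta(seqs: Iterable[Sequence], dest: Union[PathLike, TextIO], width: int = 70) -> None:
    handle = _open(dest, "w")
    close = handle is not dest
    try:
        for s in seqs:
            handle.write(f">{s.id}\n")
            for i in range(0, len(s.residues), width):
                handle.write(s.residues[i : i + width] + "\n")
    finally:
        if close:
            handle.close()


def read_fastq(source: Union[PathLike, TextIO]) -> list[Sequence]:
    """Read FASTQ records; qualities are discarded."""
    handle = _open(source)
    close = handle is not source
    try:
        records = list(SeqIO.parse(handle, "fastq"))
    finally:
        if close:
            handle.close()
    if not records:
        raise FormatError("empty or non-FASTQ input")
    return [Sequence(id=r.id, residues=str(r.seq)) for r in records]


def fasta_string(seqs: Iterable[Sequence]) -> str:
    buf = _stdio.StringIO()
    write_fasta(seqs, buf)
    return buf.getvalue()


def read_te_annotation(source: Union[PathLike, TextIO]) -> list[TECopyAnnotation]:
    """Read BED6-like TE annotations, validated and sorted by (seq_id, start).

    Columns: seq_id, start, end, subfamily, fragment_group, strand.
    A fragment_group of '.' means the copy is unfragmented.
    """
    handle = _open(source)
    close = handle is not source
    annos = []
    try:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(f"line {lineno}: expected >=6 columns, got {len(fields)}")
            seq_id, start_s, end_s, subfam, fgroup, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"line {lineno}: non-integer coordinates") from exc
            try:
                annos.append(
                    TECopyAnnotation(
                        seq_id=seq_id,
                        start=start,
                        end=end,
                        subfamily=subfam,
                        fragment_group=None if fgroup == "." else fgroup,
                        strand=strand,
                    )
                )
            except ValueError as exc:
                raise FormatError(f"line {lineno}: {exc}") from exc
    finally:
        if close:
            handle.close()
    annos.sort(key=lambda a: (a.seq_id, a.start, a.end))
    return annos


def write_te_annotation(annos: Iterable[TECopyAnnotation], dest: Union[PathLike, TextIO]) -> None:
    handle = _open(dest, "w")
    close = handle is not dest
    try:
        for a in sorted(annos, key=lambda a: (a.seq_id, a.start, a.end)):
            fgroup = a.fragment_group if a.fragment_group is not None else "."
            handle.write(
                f"{a.seq_id}\t{a.start}\t{a.end}\t{a.subfamily}\t{fgroup}\t{a.strand}\n"
            )
    finally:
        if close:
            handle.close()
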