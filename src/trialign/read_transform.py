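"""Keyed read records and their in-silico CT/GA conversions.

Reads enter the pipeline as ``(read_id, sequence)`` key-value records and are
expanded into their two three-letter conversions; the original sequence is
carried alongside so methylation can later be called without re-joining the
input.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterator, List, Optional, Tuple

from .genome_prep import (
    RULE_CT,
    RULE_GA,
    InvalidParameterError,
    convert_sequence,
    normalize_sequence,
)


class ParseError(ValueError):
    """Malformed FASTQ/FASTA input."""


@dataclass(frozen=True)
class ReadRecord:
    """A raw sequencing read keyed by its identifier; ``qual`` is None for FASTA."""

    read_id: str
    seq: str
    qual: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.read_id:
            raise ParseError("empty read id")
        if not self.seq:
            raise ParseError(f"read {self.read_id!r}: empty sequence")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ParseError(
                f"read {self.read_id!r}: quality length {len(self.qual)} "
                f"!= sequence length {len(self.seq)}"
            )


@dataclass(frozen=True)
class TransformedRead:
    """A read after one three-letter conversion, with the original kept."""

    read_id: str
    conv: str  # RULE_CT or RULE_GA
    conv_seq: str
    orig_seq: str


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fastx(path: str | Path) -> Iterator[ReadRecord]:
    """Stream reads from a FASTQ or FASTA file (gzip accepted).

    The format is auto-detected from the first character ('@' FASTQ, '>'
    FASTA).  Read ids are taken up to the first whitespace and must be unique
    within the file.  Malformed records raise :class:`ParseError` with an
    approximate line number.
    """
    with _open_text(path) as fh:
        first = fh.read(1)
        if not first:
            return
        fh.seek(0)
        if first == "@":
            yield from _read_fastq(fh, path)
        elif first == ">":
            yield from _read_fasta(fh, path)
        else:
            raise ParseError(
                f"{path}: unrecognized format (first character {first!r})"
            )


def _read_fastq(fh: IO[str], path: str | Path) -> Iterator[ReadRecord]:
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    seen = set()
    n = 0
    try:
        for title, seq, qual in FastqGeneralIterator(fh):
            n += 1
            read_id = title.split()[0]
            if read_id in seen:
                raise ParseError(
                    f"{path}: duplicate read id {read_id!r} (record {n}, "
                    f"near line {4 * n - 3})"
                )
            seen.add(read_id)
            seq = normalize_sequence(seq, name=read_id)
            _check_qual(qual, read_id, 4 * n - 3)
            yield ReadRecord(read_id=read_id, seq=seq, qual=qual)
    except ValueError as exc:
        if isinstance(exc, ParseError):
            raise
        raise ParseError(
            f"{path}: malformed FASTQ near line {4 * n + 1}: {exc}"
        ) from exc


def _read_fasta(fh: IO[str], path: str | Path) -> Iterator[ReadRecord]:
    from Bio.SeqIO.FastaIO import SimpleFastaParser

    seen = set()
    n = 0
    for title, seq in SimpleFastaParser(fh):
        n += 1
        read_id = title.split()[0]
        if read_id in seen:
            raise ParseError(f"{path}: duplicate read id {read_id!r} (record {n})")
        seen.add(read_id)
        yield ReadRecord(read_id=read_id, seq=normalize_sequence(seq, name=read_id))


def _check_qual(qual: str, read_id: str, line: int) -> None:
    for ch in qual:
        if not (33 <= ord(ch) <= 126):
            raise ParseError(
                f"read {read_id!r} near line {line}: non-printable quality "
                f"character {ch!r}"
            )


def mean_quality(qual: str) -> float:
    """Mean Phred(+33) quality of a quality string."""
    if not qual:
        return 0.0
    return sum(ord(c) - 33 for c in qual) / len(qual)


def quality_filter(record: ReadRecord, min_mean_q: float) -> bool:
    """True if the read should be kept.

    FASTA records (no qualities) are always kept; ``min_mean_q == 0``
    disables the filter entirely.
    """
    if min_mean_q <= 0 or record.qual is None:
        return True
    return mean_quality(record.qual) >= min_mean_q


def transform_read(record: ReadRecord) -> Tuple[TransformedRead, TransformedRead]:
    """Produce the CT- and GA-converted forms of a read (original preserved)."""
    return (
        TransformedRead(
            read_id=record.read_id,
            conv=RULE_CT,
            conv_seq=convert_sequence(record.seq, RULE_CT),
            orig_seq=record.seq,
        ),
        TransformedRead(
            read_id=record.read_id,
            conv=RULE_GA,
            conv_seq=convert_sequence(record.seq, RULE_GA),
            orig_seq=record.seq,
        ),
    )


def transforms_for_library(record: ReadRecord, library: str) -> List[TransformedRead]:
    """Conversions actually needed for a library mode.

    Directional libraries sequence only the converted original strands, so
    only the CT form of the read is mapped; non-directional libraries map
    both forms.
    """
    ct, ga = transform_read(record)
    if library == "directional":
        return [ct]
    if library == "non-directional":
        return [ct, ga]
    raise InvalidParameterError(f"unknown library mode {library!r}")


def write_fastq(records, path: str | Path) -> None:
    """Serialize records to FASTQ ('I' qualities when absent)."""
    with open(path, "w") as fh:
        for r in records:
            qual = r.qual if r.qual is not None else "I" * len(r.seq)
            fh.write(f"@{r.read_id}\n{r.seq}\n+\n{qual}\n")
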