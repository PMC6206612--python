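"""FASTQ input/output for every layout the trimmer accepts.

Supports paired two-file, interleaved and single-end FASTQ, plain or
gzip-compressed (detected from the 1f 8b magic bytes).  Identifiers,
descriptions and quality bytes are preserved exactly; quality encoding is
fixed to Phred+33.  Interleaved files are strict F,R,F,R order.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Union

from Bio.SeqIO.QualityIO import FastqGeneralIterator

PHRED_OFFSET = 33

_VALID_BASES = frozenset("ACGTN")

LAYOUTS = ("paired2file", "interleaved", "single")


class FastqParseError(ValueError):
    """Raised on malformed FASTQ input (bad 4-line block, length mismatch...)."""


@dataclass
class FastqRecord:
    """One sequencing read: identifier, DNA sequence and Phred+33 quality.

    ``id`` is the header token before the first whitespace (no leading '@');
    ``description`` is the remainder of the header line (may be empty).
    """

    id: str
    sequence: str
    quality: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or self.id.startswith("@"):
            raise FastqParseError(f"invalid record id {self.id!r}")
        if len(self.sequence) != len(self.quality):
            raise FastqParseError(
                f"record {self.id!r}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.quality)}"
            )
        if not _VALID_BASES.issuperset(self.sequence.upper()):
            bad = set(self.sequence.upper()) - _VALID_BASES
            raise FastqParseError(f"record {self.id!r}: non-DNA characters {sorted(bad)}")
        for c in self.quality:
            if not 33 <= ord(c) <= 126:
                raise FastqParseError(
                    f"record {self.id!r}: quality character {c!r} outside Phred+33 range"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def phred(self) -> list[int]:
        """Quality as integer Phred scores."""
        return [ord(c) - PHRED_OFFSET for c in self.quality]

    @property
    def header(self) -> str:
        return f"{self.id} {self.description}".rstrip()


def mate_key(read_id: str) -> str:
    """Identifier with a trailing '/1' or '/2' mate token stripped.

    Covers both legacy ('read7/1') and Casava 1.8 headers (mate lives in the
    description, so the id itself already matches).
    """
    if len(read_id) > 2 and read_id[-2] == "/" and read_id[-1] in "12":
        return read_id[:-2]
    return read_id


@dataclass
class ReadPair:
    """A forward/reverse mate pair with matching identifiers."""

    forward: FastqRecord
    reverse: FastqRecord

    def __post_init__(self) -> None:
        if mate_key(self.forward.id) != mate_key(self.reverse.id):
            raise FastqParseError(
                f"mate identifiers do not match: {self.forward.id!r} vs {self.reverse.id!r}"
            )

    @property
    def id(self) -> str:
        return mate_key(self.forward.id)


PathLike = Union[str, Path]


def _is_gzip(path: PathLike) -> bool:
    with open(path, "rb") as handle:
        return handle.read(2) == b"\x1f\x8b"


def open_maybe_gzip(path: PathLike, mode: str = "rt") -> IO[str]:
    """Open plain or gzipped text transparently (gzip sniffed on read)."""
    if "r" in mode:
        if _is_gzip(path):
            return gzip.open(path, mode)
        return open(path, mode)
    raise ValueError("open_maybe_gzip is read-only; use write_records for output")


def parse_fastq(handle: IO[str]) -> Iterator[FastqRecord]:
    """Yield records from an open FASTQ text handle."""
    try:
        for title, seq, qual in FastqGeneralIterator(handle):
            parts = title.split(None, 1)
            rid = parts[0]
            desc = parts[1] if len(parts) == 2 else ""
            yield FastqRecord(id=rid, sequence=seq.upper(), quality=qual, description=desc)
    except ValueError as exc:  # biopython signals malformed blocks with ValueError
        raise FastqParseError(str(exc)) from exc


def read_single(path: PathLike) -> Iterator[FastqRecord]:
    with open_maybe_gzip(path) as handle:
        yield from parse_fastq(handle)


def read_paired(path_fwd: PathLike, path_rev: PathLike) -> Iterator[ReadPair]:
    with open_maybe_gzip(path_fwd) as fh, open_maybe_gzip(path_rev) as rh:
        fwd_iter = parse_fastq(fh)
        rev_iter = parse_fastq(rh)
        for fwd in fwd_iter:
            rev = next(rev_iter, None)
            if rev is None:
                raise FastqParseError(f"forward read {fwd.id!r} has no mate in reverse file")
            yield ReadPair(fwd, rev)
        leftover = next(rev_iter, None)
        if leftover is not None:
            raise FastqParseError(f"reverse read {leftover.id!r} has no mate in forward file")


def read_interleaved(path: PathLike) -> Iterator[ReadPair]:
    with open_maybe_gzip(path) as handle:
        it = parse_fastq(handle)
        for fwd in it:
            rev = next(it, None)
            if rev is None:
                raise FastqParseError(
                    f"interleaved file ends with unpaired read {fwd.id!r}"
                )
            yield ReadPair(fwd, rev)


def read_records(
    path: PathLike,
    layout: str,
    path2: PathLike | None = None,
) -> Iterator[Union[FastqRecord, ReadPair]]:
    """Read records in the requested layout.

    ``paired2file`` requires ``path2``; ``interleaved`` and ``single`` take one
    file.  Yields ``ReadPair`` for paired layouts, ``FastqRecord`` for single.
    """
    if layout not in LAYOUTS:
        raise ValueError(f"unknown layout {layout!r}; expected one of {LAYOUTS}")
    if layout == "paired2file":
        if path2 is None:
            raise ValueError("paired2file layout requires a second file")
        yield from read_paired(path, path2)
    elif layout == "interleaved":
        yield from read_interleaved(path)
    else:
        yield from read_single(path)


def format_record(record: FastqRecord) -> str:
    return f"@{record.header}\n{record.sequence}\n+\n{record.quality}\n"


def write_records(
    records: Iterable[FastqRecord], path: PathLike, gzip_out: bool | None = None
) -> int:
    """Write records as 4-line FASTQ, gzipped when requested (or when the
    path ends in .gz).  Returns the number of records written."""
    path = Path(path)
    if gzip_out is None:
        gzip_out = path.suffix == ".gz"
    opener = gzip.open if gzip_out else open
    n = 0
    with opener(path, "wt") as handle:
        for record in records:
            handle.write(format_record(record))
            n += 1
    return n


def interleave(pairs: Iterable[ReadPair]) -> Iterator[FastqRecord]:
    for pair in pairs:
        yield pair.forward
        yield pair.reverse


def deinterleave(records: Iterable[FastqRecord]) -> Iterator[ReadPair]:
    it = iter(records)
    for fwd in it:
        rev = next(it, None)
        if rev is None:
            raise FastqParseError(f"unpaired trailing read {fwd.id!r}")
        yield ReadPair(fwd, rev)
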