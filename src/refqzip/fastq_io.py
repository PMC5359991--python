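"""FASTQ/FASTA I/O and the record <-> stream splitting at the front of the
compression pipeline.

A FASTQ file is treated strictly as a sequence of 4-line records.  Parsing
and serialization form a bijection on well-formed input: the decompressor
reproduces the original file byte for byte, so nothing here normalizes,
re-wraps or re-orders anything.  Inputs using CRLF line endings or wrapped
sequence lines are rejected rather than silently rewritten.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import BinaryIO, Iterable, Sequence

from .errors import CorruptionError, FastaFormatError, FastqParseError


def checksum64(data: bytes) -> int:
    """64-bit digest used for reference identity and stream integrity."""
    return int.from_bytes(hashlib.blake2b(data, digest_size=8).digest(), "little")


@dataclass(frozen=True)
class FastqRecord:
    """One 4-line FASTQ record, newlines stripped."""

    meta: bytes
    seq: bytes
    plus: bytes
    qual: bytes

    def __post_init__(self) -> None:
        if not self.meta.startswith(b"@"):
            raise FastqParseError("metadata line must begin with '@'")
        if not self.plus.startswith(b"+"):
            raise FastqParseError("separator line must begin with '+'")
        if len(self.seq) != len(self.qual):
            raise FastqParseError(
                f"sequence length {len(self.seq)} != quality length {len(self.qual)}"
            )


@dataclass(frozen=True)
class Reference:
    """An uppercased reference sequence; multi-record FASTA inputs are
    concatenated and the junction offsets kept so the mapper never aligns a
    read across the seam between two source records."""

    name: str
    bases: bytes
    junctions: tuple[int, ...] = ()
    checksum: int = field(default=-1)

    def __post_init__(self) -> None:
        if self.checksum == -1:
            object.__setattr__(self, "checksum", checksum64(self.bases))


def _as_bytes(source: bytes | bytearray | BinaryIO) -> bytes:
    if isinstance(source, (bytes, bytearray)):
        return bytes(source)
    return source.read()


def read_fastq(source: bytes | bytearray | BinaryIO) -> list[FastqRecord]:
    """Parse 4-line FASTQ records in file order.

    Raises FastqParseError (with the 1-based record index) on structural
    problems.  CRLF input is rejected: a byte-exact round trip could not
    otherwise distinguish newline conventions.
    """
    data = _as_bytes(source)
    if not data:
        return []
    if b"\r" in data:
        raise FastqParseError("CRLF / carriage returns are not supported; "
                              "convert the input to LF line endings")
    if not data.endswith(b"\n"):
        raise FastqParseError("input does not end with a newline")
    lines = data.split(b"\n")[:-1]
    if len(lines) % 4:
        raise FastqParseError(
            f"line count {len(lines)} is not a multiple of 4",
            record_index=len(lines) // 4 + 1,
        )
    records = []
    for i in range(0, len(lines), 4):
        idx = i // 4 + 1
        meta, seq, plus, qual = lines[i : i + 4]
        if not meta.startswith(b"@"):
            raise FastqParseError("metadata line must begin with '@'", idx)
        if not plus.startswith(b"+"):
            raise FastqParseError("separator line must begin with '+'", idx)
        if len(seq) != len(qual):
            raise FastqParseError(
                f"sequence length {len(seq)} != quality length {len(qual)}", idx
            )
        records.append(FastqRecord(meta, seq, plus, qual))
    return records


def serialize_record(record: FastqRecord) -> bytes:
    return b"\n".join((record.meta, record.seq, record.plus, record.qual)) + b"\n"


def write_fastq(records: Iterable[FastqRecord], sink: BinaryIO) -> int:
    """Serialize records to `sink`; returns the byte count written."""
    total = 0
    for record in records:
        total += sink.write(serialize_record(record))
    return total


def read_fasta(source: bytes | bytearray | BinaryIO) -> Reference:
    """Read a (possibly multi-record, possibly wrapped) FASTA reference.

    Records are concatenated in order; bases are uppercased; junction offsets
    between concatenated records are recorded on the Reference.
    """
    data = _as_bytes(source)
    if not data.strip():
        raise FastaFormatError("empty FASTA input")
    name = None
    parts: list[bytes] = []
    junctions: list[int] = []
    length = 0
    in_record = False
    for line in data.replace(b"\r\n", b"\n").split(b"\n"):
        line = line.strip()
        if not line:
            continue
        if line.startswith(b">"):
            if in_record and length:
                junctions.append(length)
            if name is None:
                name = line[1:].split()[0].decode("ascii", "replace") if len(line) > 1 else ""
            in_record = True
        else:
            if not in_record:
                raise FastaFormatError("sequence data before any '>' header")
            chunk = line.upper()
            parts.append(chunk)
            length += len(chunk)
    if name is None:
        raise FastaFormatError("no FASTA header line found")
    # drop a trailing junction produced by an empty final record
    junctions = [j for j in junctions if 0 < j < length]
    return Reference(name=name, bases=b"".join(parts), junctions=tuple(junctions))


# -- stream splitting ---------------------------------------------------------

#: plus-line descriptor entries: True = bare '+', False = annotated '+...'
PlusDescriptor = Sequence[bool]


def split_streams(
    records: Sequence[FastqRecord],
) -> tuple[list[bytes], list[bytes], list[bytes], list[bool], list[bytes]]:
    """Split records into metadata / sequence / quality streams.

    Returns (metadata lines, sequences, qualities, plus_bare flags,
    plus literals).  The plus descriptor is one flag per record; annotated
    '+' lines are stored verbatim in the literals list (in record order) so
    the split stays lossless.
    """
    metas, seqs, quals, flags, literals = [], [], [], [], []
    for r in records:
        metas.append(r.meta)
        seqs.append(r.seq)
        quals.append(r.qual)
        bare = r.plus == b"+"
        flags.append(bare)
        if not bare:
            literals.append(r.plus)
    return metas, seqs, quals, flags, literals


def merge_streams(
    metas: Sequence[bytes],
    seqs: Sequence[bytes],
    quals: Sequence[bytes],
    flags: Sequence[bool],
    literals: Sequence[bytes],
) -> list[FastqRecord]:
    """Exact inverse of :func:`split_streams`."""
    if not len(metas) == len(seqs) == len(quals) == len(flags):
        raise CorruptionError(
            "stream record counts disagree: "
            f"{len(metas)} metas, {len(seqs)} seqs, {len(quals)} quals, {len(flags)} flags"
        )
    expected_literals = sum(1 for f in flags if not f)
    if expected_literals != len(literals):
        raise CorruptionError(
            f"plus-line literal count {len(literals)} != expected {expected_literals}"
        )
    out = []
    lit = iter(literals)
    for meta, seq, qual, bare in zip(metas, seqs, quals, flags):
        plus = b"+" if bare else next(lit)
        out.append(FastqRecord(meta, seq, plus, qual))
    return out
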