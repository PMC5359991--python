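"""End-to-end compression: blocking, the six intermediate streams, and the
archive format.

Archive layout (bit-exact):

    magic "LWF2" | version u8 | varint record_count | u8 block_count |
    mapper config (varint k, L, e*1e6, prefix, segment_len) |
    RLL params (u8 run_min, u8 run_cap) | u64 reference checksum |
    u8 flags (bit0: embedded assembled reference) |
    [embedded reference: varint name + framed bases] |
    per block: varint record_count + six framed stream payloads |
    u64 trailer checksum

The six per-block streams are (1) metadata deltas, (2) quality RLL planes,
(3) mapped-segment positions (zigzag delta varints), (4) structure (match
types, flags, read lengths, run lengths), (5) mismatch bases (2-bit packed,
order-28 model), (6) raw literal sequences.  Streams 1-4 and 6 use the
order-32 model.

Blocks are contiguous runs of records; they may be *mapped* concurrently
but are always collected and encoded in block order, so the archive bytes
are a pure function of (input, reference, config) — independent of thread
count.  Read order is never permuted.
"""

from __future__ import annotations

import io
import logging
import os

import numpy as np
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass
from typing import BinaryIO, Sequence

from . import field_codecs as fc
from ._varint import read_uvarint, unzigzag, write_uvarint, zigzag
from .entropy import (
    GENERAL,
    MISMATCH,
    decode_bases_at,
    decode_stream_at,
    encode_bases,
    encode_stream,
)
from .errors import CorruptionError, RefqzipError, WrongReferenceError
from .fastq_io import (
    FastqRecord,
    Reference,
    checksum64,
    merge_streams,
    read_fastq,
    split_streams,
    write_fastq,
)
from .mapper import (
    MapperConfig,
    MatchRecord,
    MatchType,
    RawSegment,
    SegmentMatch,
    assemble_reference,
    build_index,
    map_read,
    reconstruct_read,
)

logger = logging.getLogger(__name__)

MAGIC = b"LWF2"
VERSION = 1
DEFAULT_BLOCKS = 10  # b, the number of equal-sized blocks

_FLAG_EMBEDDED_REF = 0x01


@dataclass(frozen=True)
class ArchiveHeader:
    record_count: int
    block_count: int
    config: MapperConfig
    run_min: int
    run_cap: int
    ref_checksum: int
    embedded_reference: bool


def partition_blocks(records: Sequence, b: int) -> list[Sequence]:
    """Split into at most b contiguous blocks of ceil(n/b) records each."""
    if b < 1:
        raise ValueError("b must be >= 1")
    n = len(records)
    if n == 0:
        return []
    size = -(-n // b)
    return [records[i : i + size] for i in range(0, n, size)]


# -- per-block bundle encoding -------------------------------------------------

def _write_runs(out: bytearray, seg: SegmentMatch) -> None:
    # the final run is derivable from the segment length, so it is omitted;
    # FULL_EXACT segments (single run, no mismatch) need no run data at all
    write_uvarint(out, len(seg.run_lengths))
    for run in seg.run_lengths[:-1]:
        write_uvarint(out, run)


def _encode_structure(matches: Sequence[MatchRecord]) -> bytes:
    out = bytearray()
    for match in matches:
        mtype = match.match_type
        head = int(mtype)
        if mtype in (MatchType.FULL_EXACT, MatchType.FULL_SUB):
            if match.segments[0].palindrome:
                head |= 0x04
        out.append(head)
        write_uvarint(out, match.read_length)
        if mtype is MatchType.FULL_SUB:
            _write_runs(out, match.segments[0])
        elif mtype is MatchType.SEGMENTED:
            for seg in match.segments:
                if isinstance(seg, RawSegment):
                    out.append(0)
                else:
                    out.append(2 if seg.palindrome else 1)
                    _write_runs(out, seg)
    return bytes(out)


def encode_bundle(
    records: Sequence[FastqRecord],
    matches: Sequence[MatchRecord],
    config: MapperConfig,
    run_min: int = fc.DEFAULT_RUN_MIN,
    run_cap: int = fc.DEFAULT_RUN_CAP,
) -> tuple[list[bytes], dict]:
    """Serialize one block into the six framed stream payloads."""
    metas, _seqs, quals, plus_flags, plus_literals = split_streams(records)

    meta_lines: list[bytes] = []
    lit = iter(plus_literals)
    for meta, bare in zip(metas, plus_flags):
        meta_lines.append(meta)
        if not bare:
            meta_lines.append(next(lit))
    # the plus-line descriptor travels with the metadata stream: one bit per
    # record (1 = bare '+'), packed, followed by the incremental deltas
    flag_bits = np.packbits(
        np.fromiter((1 if f else 0 for f in plus_flags), dtype=np.uint8,
                    count=len(plus_flags))
    ).tobytes()
    meta_payload = flag_bits + fc.serialize_deltas(fc.meta_encode(meta_lines))

    qual_payload = fc.serialize_rll(fc.rll_encode(b"".join(quals), run_min, run_cap))

    deltas: list[int] = []
    mismatches = bytearray()
    raws = bytearray()
    prev_pos = 0
    for match in matches:
        if match.match_type is MatchType.RAW:
            raws += match.raw_bases
            continue
        for seg in match.segments:
            if isinstance(seg, RawSegment):
                raws += seg.bases
            else:
                deltas.append(zigzag(seg.ref_pos - prev_pos))
                prev_pos = seg.ref_pos
                mismatches += seg.mismatch_bases

    # positions: zigzag deltas at a fixed per-block byte width, stored as
    # byte planes (all low bytes, then the next plane, ...).  Within one
    # plane consecutive bytes share statistics, which the rolling bit
    # context can learn; interleaved variable-width bytes would give it a
    # noise context and forfeit the skew of the high planes.
    positions = bytearray()
    if deltas:
        width = max(1, (max(deltas).bit_length() + 7) // 8)
        write_uvarint(positions, len(deltas))
        positions.append(width)
        for plane in range(width):
            shift = 8 * plane
            positions += bytes((z >> shift) & 0xFF for z in deltas)

    structure = _encode_structure(matches)

    payloads = [
        encode_stream(meta_payload, GENERAL),
        encode_stream(qual_payload, GENERAL),
        encode_stream(bytes(positions), GENERAL),
        encode_stream(structure, GENERAL),
        encode_bases(bytes(mismatches), MISMATCH),
        encode_stream(bytes(raws), GENERAL),
    ]
    stats = {
        "raw_sizes": [
            len(meta_payload),
            len(qual_payload),
            len(positions),
            len(structure),
            len(mismatches),
            len(raws),
        ],
        "coded_sizes": [len(p) for p in payloads],
    }
    return payloads, stats


def _piece_lengths(read_len: int, segment_len: int) -> list[int]:
    out = [segment_len] * (read_len // segment_len)
    if read_len % segment_len:
        out.append(read_len % segment_len)
    return out


def decode_bundle(
    buf: bytes,
    pos: int,
    n_records: int,
    header: ArchiveHeader,
    reference: Reference,
    block_index: int,
) -> tuple[list[FastqRecord], int]:
    """Decode one block back into FASTQ records."""
    try:
        meta_payload, pos = decode_stream_at(buf, pos, GENERAL)
        qual_payload, pos = decode_stream_at(buf, pos, GENERAL)
        positions_buf, pos = decode_stream_at(buf, pos, GENERAL)
        structure, pos = decode_stream_at(buf, pos, GENERAL)
        mismatches, pos = decode_bases_at(buf, pos, MISMATCH)
        raws, pos = decode_stream_at(buf, pos, GENERAL)
    except CorruptionError as exc:
        raise CorruptionError(f"block {block_index}: {exc}") from exc

    seg_len = header.config.segment_len

    # unpack the byte-planed position deltas first
    if positions_buf:
        n_pos, ppos = read_uvarint(positions_buf, 0)
        if ppos >= len(positions_buf):
            raise CorruptionError(f"block {block_index}: positions stream truncated")
    else:
        n_pos, ppos = 0, 0
    if n_pos:
        width = positions_buf[ppos]
        ppos += 1
        if ppos + width * n_pos != len(positions_buf):
            raise CorruptionError(f"block {block_index}: positions stream size mismatch")
    elif positions_buf:
        raise CorruptionError(f"block {block_index}: positions stream size mismatch")
    if n_pos:
        zz = [0] * n_pos
        for plane in range(width):
            shift = 8 * plane
            base = ppos + plane * n_pos
            for i in range(n_pos):
                zz[i] |= positions_buf[base + i] << shift
        ref_positions = []
        prev = 0
        for z in zz:
            prev += unzigzag(z)
            ref_positions.append(prev)
    else:
        ref_positions = []
    pos_iter = iter(ref_positions)

    # structure drives everything else
    matches: list[MatchRecord] = []
    spos = 0
    mpos = 0
    rpos = 0

    def next_segment(length: int, palindrome: bool, exact: bool) -> SegmentMatch:
        nonlocal spos, mpos
        if exact:
            runs = [length]
        else:
            n_runs, spos2 = read_uvarint(structure, spos)
            spos = spos2
            runs = []
            for _ in range(n_runs - 1):
                run, spos2 = read_uvarint(structure, spos)
                spos = spos2
                runs.append(run)
            # final run is implied by the segment length
            last = length - sum(runs) - (n_runs - 1)
            if last < 0:
                raise CorruptionError(f"block {block_index}: run lengths exceed segment")
            runs.append(last)
        ref_pos = next(pos_iter, None)
        if ref_pos is None:
            raise CorruptionError(f"block {block_index}: positions stream exhausted")
        n_mm = len(runs) - 1
        mm = mismatches[mpos : mpos + n_mm]
        if len(mm) != n_mm:
            raise CorruptionError(f"block {block_index}: mismatch stream exhausted")
        mpos += n_mm
        return SegmentMatch(ref_pos, palindrome, tuple(runs), mm)

    try:
        for _ in range(n_records):
            head = structure[spos]
            spos += 1
            mtype = MatchType(head & 0x03)
            palindrome = bool(head & 0x04)
            read_len, spos = read_uvarint(structure, spos)
            if mtype in (MatchType.FULL_EXACT, MatchType.FULL_SUB):
                seg = next_segment(read_len, palindrome, mtype is MatchType.FULL_EXACT)
                matches.append(MatchRecord(mtype, segments=(seg,)))
            elif mtype is MatchType.SEGMENTED:
                segments: list[SegmentMatch | RawSegment] = []
                for plen in _piece_lengths(read_len, seg_len):
                    tag = structure[spos]
                    spos += 1
                    if tag == 0:
                        piece = raws[rpos : rpos + plen]
                        if len(piece) != plen:
                            raise CorruptionError(
                                f"block {block_index}: raw stream exhausted"
                            )
                        rpos += plen
                        segments.append(RawSegment(piece))
                    else:
                        seg = next_segment(plen, tag == 2, False)
                        if seg.length != plen:
                            raise CorruptionError(
                                f"block {block_index}: segment length mismatch"
                            )
                        segments.append(seg)
                matches.append(MatchRecord(mtype, segments=tuple(segments)))
            else:  # RAW
                raw = raws[rpos : rpos + read_len]
                if len(raw) != read_len:
                    raise CorruptionError(f"block {block_index}: raw stream exhausted")
                rpos += read_len
                matches.append(MatchRecord(mtype, raw_bases=raw))
    except (IndexError, ValueError) as exc:
        raise CorruptionError(f"block {block_index}: malformed structure stream") from exc

    if spos != len(structure) or next(pos_iter, None) is not None:
        raise CorruptionError(f"block {block_index}: stream sizes inconsistent")
    if mpos != len(mismatches) or rpos != len(raws):
        raise CorruptionError(f"block {block_index}: stream sizes inconsistent")

    seqs = [reconstruct_read(m, reference) for m in matches]

    # plus-line flags (bit-packed) then metadata lines, with annotated '+'
    # lines interleaved after their record's line
    n_flag_bytes = -(-n_records // 8)
    if len(meta_payload) < n_flag_bytes:
        raise CorruptionError(f"block {block_index}: metadata stream too short")
    if n_records:
        flag_arr = np.unpackbits(
            np.frombuffer(meta_payload[:n_flag_bytes], dtype=np.uint8)
        )[:n_records]
        plus_flags = [bool(b) for b in flag_arr]
    else:
        plus_flags = []
    lines = fc.meta_decode(fc.parse_deltas(meta_payload[n_flag_bytes:]))
    metas: list[bytes] = []
    plus_literals: list[bytes] = []
    it = iter(lines)
    try:
        for bare in plus_flags:
            metas.append(next(it))
            if not bare:
                plus_literals.append(next(it))
    except StopIteration:
        raise CorruptionError(f"block {block_index}: metadata stream exhausted") from None
    if next(it, None) is not None:
        raise CorruptionError(f"block {block_index}: trailing metadata lines")

    qual_cat = fc.rll_decode(
        fc.parse_rll(qual_payload, header.run_min, header.run_cap),
        header.run_min,
        header.run_cap,
    )
    quals: list[bytes] = []
    qpos = 0
    for seq in seqs:
        quals.append(qual_cat[qpos : qpos + len(seq)])
        qpos += len(seq)
    if qpos != len(qual_cat):
        raise CorruptionError(f"block {block_index}: quality stream size mismatch")

    records = merge_streams(metas, seqs, quals, plus_flags, plus_literals)
    return records, pos


# -- whole-archive compress / decompress --------------------------------------

def _map_block(
    block: Sequence[FastqRecord], index, reference: Reference, config: MapperConfig
) -> list[MatchRecord]:
    return [map_read(r.seq, index, reference, config) for r in block]


def compress(
    source: bytes | bytearray | BinaryIO,
    reference: Reference | None = None,
    config: MapperConfig = MapperConfig(),
    b: int = DEFAULT_BLOCKS,
    threads: int | None = None,
    assemble: bool = False,
    assemble_target_len: int = 100_000,
    run_min: int = fc.DEFAULT_RUN_MIN,
    run_cap: int = fc.DEFAULT_RUN_CAP,
    stats: dict | None = None,
) -> bytes:
    """Compress FASTQ bytes against a reference into archive bytes.

    With assemble=True the reference is pseudo-assembled from the reads and
    embedded in the archive, so decompression is self-contained.  The output
    is a pure function of (input, reference, config) regardless of `threads`.
    """
    records = read_fastq(source)
    if assemble:
        reference = assemble_reference(
            [r.seq for r in records], config, assemble_target_len
        )
    if reference is None:
        raise RefqzipError("a reference is required unless assemble=True")
    if not reference.bases:
        raise RefqzipError("reference has no bases")
    if not 1 <= b <= 255:
        raise ValueError("b must be in [1, 255]")

    index = build_index(reference, config)
    blocks = partition_blocks(records, b)
    if threads is None:
        threads = min(b, os.cpu_count() or 1)
    threads = max(1, min(threads, b))

    if threads == 1 or len(blocks) <= 1:
        mapped = [_map_block(blk, index, reference, config) for blk in blocks]
    else:
        with ThreadPoolExecutor(max_workers=threads) as pool:
            mapped = list(
                pool.map(lambda blk: _map_block(blk, index, reference, config), blocks)
            )

    out = bytearray()
    out += MAGIC
    out.append(VERSION)
    write_uvarint(out, len(records))
    out.append(len(blocks))
    write_uvarint(out, config.k)
    write_uvarint(out, config.L)
    write_uvarint(out, round(config.e * 1_000_000))
    write_uvarint(out, len(config.prefix))
    out += config.prefix
    write_uvarint(out, config.segment_len)
    out.append(run_min)
    out.append(run_cap)
    out += reference.checksum.to_bytes(8, "little")
    out.append(_FLAG_EMBEDDED_REF if assemble else 0)
    if assemble:
        name = reference.name.encode()
        write_uvarint(out, len(name))
        out += name
        out += encode_stream(reference.bases, GENERAL)

    type_counts = {t.name: 0 for t in MatchType}
    stream_sizes = [0] * 6
    raw_sizes = [0] * 6
    for blk, blk_matches in zip(blocks, mapped):
        for m in blk_matches:
            type_counts[m.match_type.name] += 1
        write_uvarint(out, len(blk))
        payloads, bstats = encode_bundle(blk, blk_matches, config, run_min, run_cap)
        for i, payload in enumerate(payloads):
            stream_sizes[i] += len(payload)
            raw_sizes[i] += bstats["raw_sizes"][i]
            out += payload

    out += checksum64(bytes(out)).to_bytes(8, "little")

    if stats is not None:
        n = max(1, len(records))
        stats.update(
            record_count=len(records),
            block_count=len(blocks),
            match_counts=type_counts,
            match_fractions={k: v / n for k, v in type_counts.items()},
            stream_coded_sizes=stream_sizes,
            stream_raw_sizes=raw_sizes,
            archive_size=len(out),
        )
    logger.info(
        "compressed %d records in %d blocks -> %d bytes (types: %s)",
        len(records), len(blocks), len(out), type_counts,
    )
    return bytes(out)


def read_header(archive: bytes) -> tuple[ArchiveHeader, int]:
    """Parse and validate the archive header; returns (header, body offset)."""
    if len(archive) < 13:
        raise CorruptionError("archive too short")
    if archive[:4] != MAGIC:
        raise CorruptionError(f"bad magic {archive[:4]!r}; not a refqzip archive")
    if archive[4] != VERSION:
        raise CorruptionError(f"unsupported archive version {archive[4]}")
    pos = 5
    record_count, pos = read_uvarint(archive, pos)
    block_count = archive[pos]
    pos += 1
    k, pos = read_uvarint(archive, pos)
    L, pos = read_uvarint(archive, pos)
    e_ppm, pos = read_uvarint(archive, pos)
    plen, pos = read_uvarint(archive, pos)
    prefix = archive[pos : pos + plen]
    pos += plen
    segment_len, pos = read_uvarint(archive, pos)
    run_min = archive[pos]
    run_cap = archive[pos + 1]
    pos += 2
    ref_checksum = int.from_bytes(archive[pos : pos + 8], "little")
    pos += 8
    flags = archive[pos]
    pos += 1
    config = MapperConfig(
        k=k, prefix=prefix, L=L, e=e_ppm / 1_000_000, segment_len=segment_len
    )
    header = ArchiveHeader(
        record_count=record_count,
        block_count=block_count,
        config=config,
        run_min=run_min,
        run_cap=run_cap,
        ref_checksum=ref_checksum,
        embedded_reference=bool(flags & _FLAG_EMBEDDED_REF),
    )
    return header, pos


def decompress(
    archive: bytes | bytearray, reference: Reference | None = None
) -> bytes:
    """Reconstruct the original FASTQ bytes, in original record order.

    Verifies the whole-archive trailer checksum, then that the supplied
    reference matches the checksum recorded at compression time (unless the
    archive carries an embedded assembled reference).
    """
    archive = bytes(archive)
    if len(archive) < 8:
        raise CorruptionError("archive too short")
    body, trailer = archive[:-8], archive[-8:]
    if checksum64(body).to_bytes(8, "little") != trailer:
        raise CorruptionError("archive trailer checksum mismatch")

    header, pos = read_header(archive)
    if header.embedded_reference:
        nlen, pos = read_uvarint(archive, pos)
        name = archive[pos : pos + nlen].decode()
        pos += nlen
        bases, pos = decode_stream_at(archive, pos, GENERAL)
        reference = Reference(name=name, bases=bases)
    else:
        if reference is None:
            raise RefqzipError("archive requires an external reference")
        if reference.checksum != header.ref_checksum:
            raise WrongReferenceError(header.ref_checksum, reference.checksum)

    out = io.BytesIO()
    total = 0
    for block_index in range(header.block_count):
        n_records, pos = read_uvarint(archive, pos)
        records, pos = decode_bundle(
            archive, pos, n_records, header, reference, block_index
        )
        total += len(records)
        write_fastq(records, out)
    if total != header.record_count:
        raise CorruptionError(
            f"decoded {total} records, header promises {header.record_count}"
        )
    if pos != len(body):
        raise CorruptionError("trailing bytes after final block")
    return out.getvalue()
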