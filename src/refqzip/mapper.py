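"""Light-weight reference mapping model.

Reads are anchored to the reference through a hash index of k-mers that
start with a short fixed prefix (default "CG"), then extended as ungapped
alignments over the whole read.  A read that fails to map on the forward
strand is retried as its reverse complement ("palindrome" match); a read
that still fails is cut into fixed-length segments that are mapped
independently, and anything left over is carried as literal bases.  The
result vocabulary per mapped segment is (reference position, palindrome
flag, match-run lengths, mismatch bases), which the container turns into
the archive's nucleotide-derived streams.

Everything is deterministic: candidate anchors are tried in (read offset,
reference position) order and the first anchor whose extension satisfies
the minimum length L and the mismatch tolerance e wins.
"""

from __future__ import annotations

import logging
import re
from bisect import bisect_right
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Sequence

import numpy as np

from .errors import AssemblyError, CorruptionError
from .fastq_io import Reference

logger = logging.getLogger(__name__)

_ACGT_ONLY = re.compile(b"[ACGT]*\\Z")
_ACGTN_ONLY = re.compile(b"[ACGTN]*\\Z")
_COMPLEMENT = bytes.maketrans(b"ACGTN", b"TGCAN")


@dataclass(frozen=True)
class MapperConfig:
    """Mapping-model parameters.

    k            k-mer length used for index anchors (bases)
    prefix       short nucleotide string anchoring indexed k-mers
    L            minimum length a read/segment must have to be matched
    e            mismatch tolerance rate (mismatches <= e * segment length)
    segment_len  piece size used when re-mapping unmapped reads
    """

    k: int = 12
    prefix: bytes = b"CG"
    L: int = 16
    e: float = 0.05
    segment_len: int = 32

    def __post_init__(self) -> None:
        if not _ACGT_ONLY.match(self.prefix) or not self.prefix:
            raise ValueError("prefix must be a non-empty ACGT string")
        if len(self.prefix) >= self.k:
            raise ValueError("prefix must be shorter than k")
        if self.L < self.k:
            raise ValueError("L must be >= k")
        if not 0.0 <= self.e < 0.5:
            raise ValueError("e must be in [0, 0.5)")
        if self.segment_len < self.L:
            raise ValueError("segment_len must be >= L")


class MatchType(IntEnum):
    FULL_EXACT = 0   # whole read matches the reference with no mismatch
    FULL_SUB = 1     # whole read matches with >= 1 substitution
    SEGMENTED = 2    # read mapped piece-wise; unmapped pieces carried raw
    RAW = 3          # read stored literally


@dataclass(frozen=True)
class SegmentMatch:
    """One ungapped alignment: alternating match runs and single-base
    substitutions against the forward reference strand.  For palindrome
    matches the runs/mismatches describe the reverse complement of the read
    segment, laid on the forward strand."""

    ref_pos: int
    palindrome: bool
    run_lengths: tuple[int, ...]
    mismatch_bases: bytes

    def __post_init__(self) -> None:
        if len(self.mismatch_bases) != len(self.run_lengths) - 1:
            raise ValueError("need exactly one mismatch base between consecutive runs")
        if any(r < 0 for r in self.run_lengths):
            raise ValueError("run lengths must be non-negative")

    @property
    def length(self) -> int:
        return sum(self.run_lengths) + len(self.mismatch_bases)


@dataclass(frozen=True)
class RawSegment:
    """Sentinel segment carrying literal bases for an unmapped piece."""

    bases: bytes

    @property
    def length(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class MatchRecord:
    match_type: MatchType
    segments: tuple[SegmentMatch | RawSegment, ...] = ()
    raw_bases: bytes = b""

    @property
    def read_length(self) -> int:
        if self.match_type is MatchType.RAW:
            return len(self.raw_bases)
        return sum(s.length for s in self.segments)


@dataclass
class ReferenceIndex:
    """The prefix-anchored k-mer hash table I_R: k-mer -> ascending
    0-based reference positions."""

    table: dict[bytes, list[int]]
    config: MapperConfig
    junctions: tuple[int, ...] = ()


def _crosses_junction(junctions: Sequence[int], start: int, length: int) -> bool:
    if not junctions:
        return False
    i = bisect_right(junctions, start)
    return i < len(junctions) and junctions[i] < start + length


def build_index(reference: Reference, config: MapperConfig) -> ReferenceIndex:
    """Index every position of a length-k ACGT substring of the reference
    that begins with the configured prefix and does not span a FASTA
    junction."""
    bases = reference.bases
    k = config.k
    table: dict[bytes, list[int]] = {}
    if k > len(bases):
        logger.warning("k=%d exceeds reference length %d; index is empty", k, len(bases))
        return ReferenceIndex(table, config, reference.junctions)
    prefix = config.prefix
    limit = len(bases) - k
    pos = bases.find(prefix)
    while 0 <= pos <= limit:
        kmer = bases[pos : pos + k]
        if _ACGT_ONLY.match(kmer) and not _crosses_junction(reference.junctions, pos, k):
            table.setdefault(kmer, []).append(pos)
        pos = bases.find(prefix, pos + 1)
    return ReferenceIndex(table, config, reference.junctions)


def reverse_complement(seq: bytes) -> bytes:
    """Watson-Crick reverse complement over {A,C,G,T,N}."""
    if not _ACGTN_ONLY.match(seq):
        raise ValueError("sequence contains a character outside {A,C,G,T,N}")
    return seq.translate(_COMPLEMENT)[::-1]


def find_seeds(read: bytes, index: ReferenceIndex) -> list[tuple[int, int]]:
    """Candidate anchors (read_offset, ref_pos), ordered by read offset then
    reference position."""
    k = index.config.k
    prefix = index.config.prefix
    table = index.table
    anchors: list[tuple[int, int]] = []
    limit = len(read) - k
    off = read.find(prefix)
    while 0 <= off <= limit:
        positions = table.get(read[off : off + k])
        if positions:
            anchors.extend((off, p) for p in positions)
        off = read.find(prefix, off + 1)
    return anchors


def extend_seed(
    read: bytes,
    ref: Reference,
    anchor: tuple[int, int],
    config: MapperConfig,
) -> SegmentMatch | None:
    """Ungapped extension of an anchor across the full read.

    Returns None (failure) when the read is shorter than L, the implied
    alignment falls outside the reference or crosses a junction, or the
    mismatch count exceeds e * read length.  The palindrome flag of the
    returned match is False; callers mapping a reverse complement set it.
    """
    off, ref_pos = anchor
    n = len(read)
    start = ref_pos - off
    if n < config.L:
        return None
    if start < 0 or start + n > len(ref.bases):
        return None
    if _crosses_junction(ref.junctions, start, n):
        return None
    window = ref.bases[start : start + n]
    if window == read:
        return SegmentMatch(start, False, (n,), b"")
    a = np.frombuffer(read, dtype=np.uint8)
    b = np.frombuffer(window, dtype=np.uint8)
    mm = np.flatnonzero(a != b)
    if len(mm) > config.e * n:
        return None
    runs: list[int] = []
    prev = 0
    for p in mm:
        runs.append(int(p) - prev)
        prev = int(p) + 1
    runs.append(n - prev)
    return SegmentMatch(start, False, tuple(runs), bytes(a[mm]))


def _with_palindrome(match: SegmentMatch) -> SegmentMatch:
    return SegmentMatch(match.ref_pos, True, match.run_lengths, match.mismatch_bases)


def _map_piece(
    piece: bytes, index: ReferenceIndex, ref: Reference, config: MapperConfig
) -> SegmentMatch | None:
    for anchor in find_seeds(piece, index):
        match = extend_seed(piece, ref, anchor, config)
        if match is not None:
            return match
    rc = piece.translate(_COMPLEMENT)[::-1]
    for anchor in find_seeds(rc, index):
        match = extend_seed(rc, ref, anchor, config)
        if match is not None:
            return _with_palindrome(match)
    return None


def map_read(
    read: bytes, index: ReferenceIndex, ref: Reference, config: MapperConfig
) -> MatchRecord:
    """Map one read: forward, then reverse complement, then segment-wise;
    reads containing non-ACGT characters (or failing everywhere) go RAW."""
    if not read:
        raise ValueError("read must be non-empty")
    if not _ACGT_ONLY.match(read):
        return MatchRecord(MatchType.RAW, raw_bases=read)

    match = _map_piece(read, index, ref, config)
    if match is not None:
        mtype = MatchType.FULL_EXACT if not match.mismatch_bases else MatchType.FULL_SUB
        return MatchRecord(mtype, segments=(match,))

    seg_len = config.segment_len
    if len(read) > seg_len:
        pieces = [read[i : i + seg_len] for i in range(0, len(read), seg_len)]
        segments: list[SegmentMatch | RawSegment] = []
        mapped_any = False
        for piece in pieces:
            m = _map_piece(piece, index, ref, config)
            if m is None:
                segments.append(RawSegment(piece))
            else:
                segments.append(m)
                mapped_any = True
        if mapped_any:
            return MatchRecord(MatchType.SEGMENTED, segments=tuple(segments))
    return MatchRecord(MatchType.RAW, raw_bases=read)


def _rebuild_segment(seg: SegmentMatch, ref: Reference) -> bytes:
    end = seg.ref_pos + seg.length
    if seg.ref_pos < 0 or end > len(ref.bases):
        raise CorruptionError(
            f"segment [{seg.ref_pos}, {end}) exceeds reference length {len(ref.bases)}"
        )
    out = bytearray()
    pos = seg.ref_pos
    mm = seg.mismatch_bases
    for i, run in enumerate(seg.run_lengths):
        out += ref.bases[pos : pos + run]
        pos += run
        if i < len(mm):
            out.append(mm[i])
            pos += 1
    rebuilt = bytes(out)
    if seg.palindrome:
        rebuilt = rebuilt.translate(_COMPLEMENT)[::-1]
    return rebuilt


def reconstruct_read(record: MatchRecord, ref: Reference) -> bytes:
    """Exact inverse of :func:`map_read` for the same reference."""
    if record.match_type is MatchType.RAW:
        return record.raw_bases
    parts = []
    for seg in record.segments:
        if isinstance(seg, RawSegment):
            parts.append(seg.bases)
        else:
            parts.append(_rebuild_segment(seg, ref))
    return b"".join(parts)


def assemble_reference(
    reads: Sequence[bytes],
    config: MapperConfig,
    target_len: int,
    min_overlap: int = 3,
) -> Reference:
    """Deterministic pseudo-assembly used when no external reference is
    available: greedily merge prefix-containing reads by exact suffix/prefix
    overlap, concatenate non-overlapping contigs, truncate at target_len.

    The quality of this assembly only affects compression ratio, never
    losslessness.  Contig joints are recorded as junctions.
    """
    candidates = [r for r in reads if _ACGT_ONLY.match(r)]
    first = next((i for i, r in enumerate(candidates) if config.prefix in r), None)
    if first is None:
        raise AssemblyError(
            f"no read contains the prefix {config.prefix.decode()}; "
            "supply an external reference instead"
        )
    # a contig must *start* from a prefix-containing read; any read may
    # extend a contig by exact suffix/prefix overlap
    contigs: list[bytes] = []
    cur = bytearray(candidates[first])
    total = len(cur)
    for read in candidates[first + 1 :]:
        if total >= target_len:
            break
        tail = bytes(cur[-len(read):])
        overlap = 0
        for o in range(min(len(tail), len(read)), min_overlap - 1, -1):
            if tail[-o:] == read[:o]:
                overlap = o
                break
        if overlap:
            cur += read[overlap:]
            total += len(read) - overlap
        elif config.prefix in read:
            contigs.append(bytes(cur))
            cur = bytearray(read)
            total += len(read)
    contigs.append(bytes(cur))
    junctions = []
    acc = 0
    for c in contigs[:-1]:
        acc += len(c)
        junctions.append(acc)
    bases = b"".join(contigs)[:target_len]
    junctions = [j for j in junctions if 0 < j < len(bases)]
    return Reference(name="assembled", bases=bases, junctions=tuple(junctions))


def dump_matches_tsv(records: Sequence[MatchRecord]) -> bytes:
    """Debug dump of match records (read index, type, per-segment details)."""
    lines = [b"read\ttype\tsegment\tref_pos\tpalindrome\truns\tmismatches"]
    for i, rec in enumerate(records):
        if rec.match_type is MatchType.RAW:
            lines.append(f"{i}\tRAW\t-\t-\t-\t-\t-".encode())
            continue
        for j, seg in enumerate(rec.segments):
            if isinstance(seg, RawSegment):
                lines.append(f"{i}\t{rec.match_type.name}\t{j}\traw\t-\t-\t-".encode())
            else:
                runs = ",".join(map(str, seg.run_lengths))
                mm = seg.mismatch_bases.decode() or "-"
                lines.append(
                    f"{i}\t{rec.match_type.name}\t{j}\t{seg.ref_pos}\t"
                    f"{int(seg.palindrome)}\t{runs}\t{mm}".encode()
                )
    return b"\n".join(lines) + b"\n"
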