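"""Reversible pre-transforms for the non-nucleotide streams.

Metadata lines are incrementally encoded: each line is stored as the length
of its longest common prefix with the previous line plus the remaining
suffix.  Sequencer read headers share long, slowly-varying prefixes, so most
lines shrink to a few bytes before entropy coding.

Quality strings get run-length-limited (RLL) encoding: maximal runs of one
symbol of length >= run_min become RUN tokens, capped at run_cap (longer
runs split); everything else stays literal.  Tokens are serialized into two
parallel planes — a symbols plane and a control plane with one byte per
token (0 = literal, otherwise the run count; counts are >= run_min >= 2, so
the scheme needs no escapes).  Both transforms are exact bijections.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

from ._varint import read_uvarint, write_uvarint
from .errors import CorruptionError

DEFAULT_RUN_MIN = 3
DEFAULT_RUN_CAP = 255


@dataclass(frozen=True)
class MetaDelta:
    """One incrementally-encoded line: shared-prefix length + suffix."""

    lcp: int
    suffix: bytes


class TokenKind(Enum):
    LITERAL = 0
    RUN = 1


@dataclass(frozen=True)
class RllToken:
    kind: TokenKind
    symbol: int
    count: int = 1


def _lcp(a: bytes, b: bytes) -> int:
    n = min(len(a), len(b))
    i = 0
    while i < n and a[i] == b[i]:
        i += 1
    return i


def meta_encode(lines: Sequence[bytes]) -> list[MetaDelta]:
    """Incremental encoding; the first line is delta'd against the empty
    string (lcp 0)."""
    out = []
    prev = b""
    for line in lines:
        k = _lcp(prev, line)
        out.append(MetaDelta(k, line[k:]))
        prev = line
    return out


def meta_decode(stream: Sequence[MetaDelta]) -> list[bytes]:
    """Exact inverse of :func:`meta_encode`."""
    out: list[bytes] = []
    prev = b""
    for delta in stream:
        if delta.lcp > len(prev):
            raise CorruptionError(
                f"metadata delta lcp {delta.lcp} exceeds previous line length {len(prev)}"
            )
        line = prev[: delta.lcp] + delta.suffix
        out.append(line)
        prev = line
    return out


def serialize_deltas(stream: Sequence[MetaDelta]) -> bytes:
    """Wire format: varint count, then per delta varint lcp + length-prefixed
    suffix."""
    out = bytearray()
    write_uvarint(out, len(stream))
    for delta in stream:
        write_uvarint(out, delta.lcp)
        write_uvarint(out, len(delta.suffix))
        out += delta.suffix
    return bytes(out)


def parse_deltas(buf: bytes) -> list[MetaDelta]:
    count, pos = read_uvarint(buf, 0)
    out = []
    for _ in range(count):
        lcp, pos = read_uvarint(buf, pos)
        n, pos = read_uvarint(buf, pos)
        if pos + n > len(buf):
            raise CorruptionError("truncated metadata delta suffix")
        out.append(MetaDelta(lcp, buf[pos : pos + n]))
        pos += n
    if pos != len(buf):
        raise CorruptionError("trailing bytes after metadata deltas")
    return out


def rll_encode(
    qual: bytes, run_min: int = DEFAULT_RUN_MIN, run_cap: int = DEFAULT_RUN_CAP
) -> list[RllToken]:
    """Maximal-munch left-to-right run-length-limited encoding."""
    if run_min < 2:
        raise ValueError("run_min must be >= 2")
    if not run_min <= run_cap <= 255:
        raise ValueError("run_cap must be in [run_min, 255]")
    tokens: list[RllToken] = []
    if not qual:
        return tokens
    arr = np.frombuffer(qual, dtype=np.uint8)
    boundaries = np.flatnonzero(arr[1:] != arr[:-1]) + 1
    starts = [0, *boundaries.tolist()]
    ends = [*boundaries.tolist(), len(arr)]
    for start, end in zip(starts, ends):
        symbol = qual[start]
        remaining = end - start
        if remaining < run_min:
            tokens.extend(RllToken(TokenKind.LITERAL, symbol) for _ in range(remaining))
            continue
        while remaining:
            chunk = min(remaining, run_cap)
            if chunk >= run_min:
                tokens.append(RllToken(TokenKind.RUN, symbol, chunk))
            else:
                tokens.extend(RllToken(TokenKind.LITERAL, symbol) for _ in range(chunk))
            remaining -= chunk
    return tokens


def rll_decode(
    tokens: Sequence[RllToken],
    run_min: int = DEFAULT_RUN_MIN,
    run_cap: int = DEFAULT_RUN_CAP,
) -> bytes:
    """Exact inverse of :func:`rll_encode`; validates run counts."""
    out = bytearray()
    for tok in tokens:
        if tok.kind is TokenKind.LITERAL:
            out.append(tok.symbol)
        else:
            if not run_min <= tok.count <= run_cap:
                raise CorruptionError(
                    f"run count {tok.count} outside [{run_min}, {run_cap}]"
                )
            out += bytes([tok.symbol]) * tok.count
    return bytes(out)


def serialize_rll(tokens: Sequence[RllToken]) -> bytes:
    """Two-plane wire format: varint token count, symbols plane, control
    plane (0 = literal, else the run count)."""
    out = bytearray()
    write_uvarint(out, len(tokens))
    out += bytes(tok.symbol for tok in tokens)
    out += bytes(0 if tok.kind is TokenKind.LITERAL else tok.count for tok in tokens)
    return bytes(out)


def parse_rll(
    buf: bytes, run_min: int = DEFAULT_RUN_MIN, run_cap: int = DEFAULT_RUN_CAP
) -> list[RllToken]:
    count, pos = read_uvarint(buf, 0)
    if pos + 2 * count != len(buf):
        raise CorruptionError("RLL plane sizes inconsistent with token count")
    symbols = buf[pos : pos + count]
    control = buf[pos + count : pos + 2 * count]
    tokens = []
    for symbol, ctl in zip(symbols, control):
        if ctl == 0:
            tokens.append(RllToken(TokenKind.LITERAL, symbol))
        else:
            if not run_min <= ctl <= run_cap:
                raise CorruptionError(f"run count {ctl} outside [{run_min}, {run_cap}]")
            tokens.append(RllToken(TokenKind.RUN, symbol, ctl))
    return tokens
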