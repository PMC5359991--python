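"""Bitwise context modeling ("PPM-style") plus binary arithmetic coding.

Every payload in the archive is coded one bit at a time.  A fixed-order bit
context (the last `order_bits` coded bits) selects a pair of adaptive
counters (n0, n1); the predicted probability of the next bit being 1 is the
Laplace-smoothed ratio

    p1 = (n1 + delta) / (n0 + n1 + 2*delta)

and the bit is then coded with a 32-bit integer binary arithmetic coder.
General streams use a 32-bit context (4 coded bytes); the mismatch-base
stream, whose alphabet is exactly {A,C,G,T} packed 2 bits/base, uses a
28-bit context (14 bases).

Counter maintenance supports two regimes:

* adaptive (default for FASTQ streams): on each update the opposing counter
  is halved once it exceeds a small threshold, so the model tracks
  non-stationary statistics;
* stationary: no opposing halving; both counters are rescaled (halved
  together) when one reaches the cap, which preserves the learned ratio on
  long streams.  This is the right regime for benchmarking the coder against
  the entropy of a memoryless source.

The arithmetic coder uses 32-bit low/high registers, 16-bit quantized
probabilities, bit-wise renormalization with an underflow-pending counter,
and integer arithmetic only, so its output is bit-exact across platforms.

Module-level `encode_stream` / `decode_stream` (bytes) and `encode_bases` /
`decode_bases` (2-bit packed nucleotides) add the archive frame:

    [varint raw_len][varint coded_len][coded bytes][u64 payload checksum]
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._varint import read_uvarint, write_uvarint
from .errors import CorruptionError
from .fastq_io import checksum64

_HALF = 1 << 31
_QUARTER = 1 << 30
_THREEQ = 3 << 30
_TOP = (1 << 32) - 1


@dataclass(frozen=True)
class PredictorConfig:
    """Configuration of a per-context bit predictor.

    order_bits      context length in bits (32 general / 28 mismatch bases)
    counter_cap     counters are rescaled (both halved) when one exceeds this
    delta           Laplace smoothing constant (integer, > 0)
    halve_threshold opposing counter is halved when it exceeds this value;
                    None disables the rule (stationary regime)
    """

    order_bits: int = 32
    counter_cap: int = 255
    delta: int = 1
    halve_threshold: int | None = 2

    def __post_init__(self) -> None:
        if not 1 <= self.order_bits <= 32:
            raise ValueError("order_bits must be in [1, 32]")
        if not 2 <= self.counter_cap <= 65535:
            raise ValueError("counter_cap must be in [2, 65535]")
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if self.halve_threshold is not None and self.halve_threshold < 1:
            raise ValueError("halve_threshold must be >= 1 or None")


#: default model for metadata / quality / structure / raw streams
GENERAL = PredictorConfig(order_bits=32)
#: default model for the 2-bit packed mismatch-base stream
MISMATCH = PredictorConfig(order_bits=28)
#: stationary order-0-like model (single-bit context, no opposing halving);
#: appropriate for memoryless sources and entropy benchmarking
STATIONARY = PredictorConfig(order_bits=1, halve_threshold=None)


class BitPredictor:
    """Adaptive per-context bit probability model.

    The context register holds the last `order_bits` coded bits; the store
    maps context values to (n0, n1) counter pairs, allocated lazily.
    """

    __slots__ = ("config", "context", "store", "_mask")

    def __init__(self, config: PredictorConfig = GENERAL):
        self.config = config
        self.context = 0
        self.store: dict[int, int] = {}
        self._mask = (1 << config.order_bits) - 1

    def counts(self) -> tuple[int, int]:
        pair = self.store.get(self.context, 0)
        return pair >> 16, pair & 0xFFFF

    def predict(self) -> float:
        """Probability that the next bit is 1; 0.5 for an unseen context."""
        n0, n1 = self.counts()
        d = self.config.delta
        return (n1 + d) / (n0 + n1 + 2 * d)

    def predict16(self) -> int:
        """predict() quantized to 16 bits and clamped into [1, 65535]."""
        n0, n1 = self.counts()
        d = self.config.delta
        p = ((n1 + d) << 16) // (n0 + n1 + 2 * d)
        return min(max(p, 1), 65535)

    def update(self, bit: int) -> None:
        if bit not in (0, 1):
            raise ValueError("bit must be 0 or 1")
        cfg = self.config
        thr = cfg.halve_threshold if cfg.halve_threshold is not None else cfg.counter_cap + 1
        n0, n1 = self.counts()
        if bit:
            n1 += 1
            if n0 > thr:
                n0 = (n0 >> 1) + 1
            if n1 > cfg.counter_cap:
                n1 = (n1 + 1) >> 1
                n0 = (n0 + 1) >> 1
        else:
            n0 += 1
            if n1 > thr:
                n1 = (n1 >> 1) + 1
            if n0 > cfg.counter_cap:
                n0 = (n0 + 1) >> 1
                n1 = (n1 + 1) >> 1
        self.store[self.context] = (n0 << 16) | n1
        self.context = ((self.context << 1) | bit) & self._mask


class ArithmeticEncoder:
    """Binary arithmetic encoder over 16-bit probabilities."""

    def __init__(self) -> None:
        self.low = 0
        self.high = _TOP
        self.pending = 0
        self._bits = bytearray()

    def encode_bit(self, p1: int, bit: int) -> None:
        """Code one bit under P(bit=1) = p1 / 65536, p1 in [1, 65535]."""
        if not 0 < p1 < 65536:
            raise ValueError("p1 must be in (0, 65536)")
        low, high, bits = self.low, self.high, self._bits
        s0 = ((high - low + 1) * (65536 - p1)) >> 16
        if bit:
            low += s0
        else:
            high = low + s0 - 1
        pending = self.pending
        while True:
            if high < _HALF:
                bits.append(0)
                if pending:
                    bits.extend(b"\x01" * pending)
                    pending = 0
            elif low >= _HALF:
                bits.append(1)
                if pending:
                    bits.extend(b"\x00" * pending)
                    pending = 0
                low -= _HALF
                high -= _HALF
            elif low >= _QUARTER and high < _THREEQ:
                pending += 1
                low -= _QUARTER
                high -= _QUARTER
            else:
                break
            low <<= 1
            high = (high << 1) | 1
        self.low, self.high, self.pending = low, high, pending

    def finish(self) -> bytes:
        """Flush and return the coded bytes (bits packed MSB-first)."""
        bits = self._bits
        pending = self.pending + 1
        if self.low < _QUARTER:
            bits.append(0)
            bits.extend(b"\x01" * pending)
        else:
            bits.append(1)
            bits.extend(b"\x00" * pending)
        if not bits:
            return b""
        return np.packbits(np.frombuffer(bytes(bits), dtype=np.uint8)).tobytes()


class ArithmeticDecoder:
    """Mirror of :class:`ArithmeticEncoder`; must be driven with the same
    probability sequence the encoder used."""

    def __init__(self, coded: bytes):
        if coded:
            self._bits = np.unpackbits(np.frombuffer(coded, dtype=np.uint8)).tobytes()
        else:
            self._bits = b""
        self._pos = 0
        self.low = 0
        self.high = _TOP
        self.value = 0
        for _ in range(32):
            self.value = (self.value << 1) | self._next_bit()

    def _next_bit(self) -> int:
        bits, pos = self._bits, self._pos
        self._pos = pos + 1
        return bits[pos] if pos < len(bits) else 0

    def decode_bit(self, p1: int) -> int:
        if not 0 < p1 < 65536:
            raise ValueError("p1 must be in (0, 65536)")
        low, high, value = self.low, self.high, self.value
        s0 = ((high - low + 1) * (65536 - p1)) >> 16
        if value < low + s0:
            bit = 0
            high = low + s0 - 1
        else:
            bit = 1
            low += s0
        while True:
            if high < _HALF:
                pass
            elif low >= _HALF:
                low -= _HALF
                high -= _HALF
                value -= _HALF
            elif low >= _QUARTER and high < _THREEQ:
                low -= _QUARTER
                high -= _QUARTER
                value -= _QUARTER
            else:
                break
            low <<= 1
            high = (high << 1) | 1
            value = (value << 1) | self._next_bit()
        self.low, self.high, self.value = low, high, value
        return bit


# -- fast whole-payload paths -------------------------------------------------
#
# The loops below inline the predictor and coder for throughput.  A lockstep
# test asserts that they produce exactly the bytes the class-based API does.

def encode_bits(bits: bytes | bytearray, config: PredictorConfig) -> bytes:
    """Arithmetic-code a sequence of bits (one 0/1 value per byte)."""
    mask = (1 << config.order_bits) - 1
    cap = config.counter_cap
    thr = config.halve_threshold if config.halve_threshold is not None else cap + 1
    d = config.delta
    dd = 2 * d
    store: dict[int, int] = {}
    get = store.get
    ctx = 0
    low = 0
    high = _TOP
    pending = 0
    out = bytearray()
    append = out.append
    extend = out.extend
    for bit in bits:
        pair = get(ctx, 0)
        n0 = pair >> 16
        n1 = pair & 0xFFFF
        p1 = ((n1 + d) << 16) // (n0 + n1 + dd)
        if p1 < 1:
            p1 = 1
        elif p1 > 65535:
            p1 = 65535
        s0 = ((high - low + 1) * (65536 - p1)) >> 16
        if bit:
            low += s0
            n1 += 1
            if n0 > thr:
                n0 = (n0 >> 1) + 1
            if n1 > cap:
                n1 = (n1 + 1) >> 1
                n0 = (n0 + 1) >> 1
            store[ctx] = (n0 << 16) | n1
            ctx = ((ctx << 1) | 1) & mask
        else:
            high = low + s0 - 1
            n0 += 1
            if n1 > thr:
                n1 = (n1 >> 1) + 1
            if n0 > cap:
                n0 = (n0 + 1) >> 1
                n1 = (n1 + 1) >> 1
            store[ctx] = (n0 << 16) | n1
            ctx = (ctx << 1) & mask
        while True:
            if high < _HALF:
                append(0)
                if pending:
                    extend(b"\x01" * pending)
                    pending = 0
            elif low >= _HALF:
                append(1)
                if pending:
                    extend(b"\x00" * pending)
                    pending = 0
                low -= _HALF
                high -= _HALF
            elif low >= _QUARTER and high < _THREEQ:
                pending += 1
                low -= _QUARTER
                high -= _QUARTER
            else:
                break
            low <<= 1
            high = (high << 1) | 1
    pending += 1
    if low < _QUARTER:
        append(0)
        extend(b"\x01" * pending)
    else:
        append(1)
        extend(b"\x00" * pending)
    return np.packbits(np.frombuffer(bytes(out), dtype=np.uint8)).tobytes()


def decode_bits(coded: bytes, nbits: int, config: PredictorConfig) -> bytearray:
    """Inverse of :func:`encode_bits`; returns `nbits` 0/1 values."""
    result = bytearray(nbits)
    if nbits == 0:
        return result
    inbits = (
        np.unpackbits(np.frombuffer(coded, dtype=np.uint8)).tobytes() if coded else b""
    )
    nin = len(inbits)
    mask = (1 << config.order_bits) - 1
    cap = config.counter_cap
    thr = config.halve_threshold if config.halve_threshold is not None else cap + 1
    d = config.delta
    dd = 2 * d
    store: dict[int, int] = {}
    get = store.get
    ctx = 0
    low = 0
    high = _TOP
    value = 0
    pos = 0
    for _ in range(32):
        value = (value << 1) | (inbits[pos] if pos < nin else 0)
        pos += 1
    for i in range(nbits):
        pair = get(ctx, 0)
        n0 = pair >> 16
        n1 = pair & 0xFFFF
        p1 = ((n1 + d) << 16) // (n0 + n1 + dd)
        if p1 < 1:
            p1 = 1
        elif p1 > 65535:
            p1 = 65535
        s0 = ((high - low + 1) * (65536 - p1)) >> 16
        if value < low + s0:
            high = low + s0 - 1
            n0 += 1
            if n1 > thr:
                n1 = (n1 >> 1) + 1
            if n0 > cap:
                n0 = (n0 + 1) >> 1
                n1 = (n1 + 1) >> 1
            store[ctx] = (n0 << 16) | n1
            ctx = (ctx << 1) & mask
        else:
            result[i] = 1
            low += s0
            n1 += 1
            if n0 > thr:
                n0 = (n0 >> 1) + 1
            if n1 > cap:
                n1 = (n1 + 1) >> 1
                n0 = (n0 + 1) >> 1
            store[ctx] = (n0 << 16) | n1
            ctx = ((ctx << 1) | 1) & mask
        while True:
            if high < _HALF:
                pass
            elif low >= _HALF:
                low -= _HALF
                high -= _HALF
                value -= _HALF
            elif low >= _QUARTER and high < _THREEQ:
                low -= _QUARTER
                high -= _QUARTER
                value -= _QUARTER
            else:
                break
            low <<= 1
            high = (high << 1) | 1
            value = (value << 1) | (inbits[pos] if pos < nin else 0)
            pos += 1
    return result


# -- framed byte-payload streams ---------------------------------------------

def encode_stream(payload: bytes, config: PredictorConfig = GENERAL) -> bytes:
    """Code a byte payload into a self-describing frame (deterministic)."""
    frame = bytearray()
    write_uvarint(frame, len(payload))
    if payload:
        bits = np.unpackbits(np.frombuffer(payload, dtype=np.uint8)).tobytes()
        coded = encode_bits(bits, config)
    else:
        coded = b""
    write_uvarint(frame, len(coded))
    frame += coded
    frame += checksum64(payload).to_bytes(8, "little")
    return bytes(frame)


def decode_stream_at(
    buf: bytes, pos: int, config: PredictorConfig = GENERAL
) -> tuple[bytes, int]:
    """Decode one frame starting at `pos`; returns (payload, new_pos)."""
    raw_len, pos = read_uvarint(buf, pos)
    coded_len, pos = read_uvarint(buf, pos)
    if pos + coded_len + 8 > len(buf):
        raise CorruptionError("truncated stream frame")
    coded = buf[pos : pos + coded_len]
    pos += coded_len
    expected = int.from_bytes(buf[pos : pos + 8], "little")
    pos += 8
    if raw_len:
        bits = decode_bits(coded, raw_len * 8, config)
        payload = np.packbits(np.frombuffer(bytes(bits), dtype=np.uint8)).tobytes()
    else:
        payload = b""
    if checksum64(payload) != expected:
        raise CorruptionError("stream payload checksum mismatch")
    return payload, pos


def decode_stream(frame: bytes, config: PredictorConfig = GENERAL) -> bytes:
    payload, pos = decode_stream_at(frame, 0, config)
    if pos != len(frame):
        raise CorruptionError("trailing bytes after stream frame")
    return payload


# -- 2-bit packed nucleotide streams ------------------------------------------

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
_CODE_BASE = np.frombuffer(b"ACGT", dtype=np.uint8)


def encode_bases(bases: bytes, config: PredictorConfig = MISMATCH) -> bytes:
    """Code an {A,C,G,T} payload at 2 bits/base under the mismatch model."""
    codes = _BASE_CODE[np.frombuffer(bases, dtype=np.uint8)] if bases else np.empty(0, np.uint8)
    if codes.size and int(codes.max()) > 3:
        raise ValueError("encode_bases payload contains a non-ACGT byte")
    frame = bytearray()
    write_uvarint(frame, len(bases))
    if bases:
        bits = np.empty(2 * codes.size, dtype=np.uint8)
        bits[0::2] = codes >> 1
        bits[1::2] = codes & 1
        coded = encode_bits(bits.tobytes(), config)
    else:
        coded = b""
    write_uvarint(frame, len(coded))
    frame += coded
    frame += checksum64(bases).to_bytes(8, "little")
    return bytes(frame)


def decode_bases_at(
    buf: bytes, pos: int, config: PredictorConfig = MISMATCH
) -> tuple[bytes, int]:
    n_bases, pos = read_uvarint(buf, pos)
    coded_len, pos = read_uvarint(buf, pos)
    if pos + coded_len + 8 > len(buf):
        raise CorruptionError("truncated base-stream frame")
    coded = buf[pos : pos + coded_len]
    pos += coded_len
    expected = int.from_bytes(buf[pos : pos + 8], "little")
    pos += 8
    if n_bases:
        bits = np.frombuffer(bytes(decode_bits(coded, 2 * n_bases, config)), dtype=np.uint8)
        codes = (bits[0::2] << 1) | bits[1::2]
        bases = _CODE_BASE[codes].tobytes()
    else:
        bases = b""
    if checksum64(bases) != expected:
        raise CorruptionError("base-stream payload checksum mismatch")
    return bases, pos


def decode_bases(frame: bytes, config: PredictorConfig = MISMATCH) -> bytes:
    bases, pos = decode_bases_at(frame, 0, config)
    if pos != len(frame):
        raise CorruptionError("trailing bytes after base-stream frame")
    return bases


def order0_entropy_size(data: bytes) -> float:
    """Order-0 (byte histogram) Shannon size of `data`, in bytes.

    Used as the generic baseline a byte-wise memoryless coder would reach.
    """
    if not data:
        return 0.0
    counts = np.bincount(np.frombuffer(data, dtype=np.uint8), minlength=256)
    probs = counts[counts > 0] / len(data)
    bits = -float(np.sum(counts[counts > 0] * np.log2(probs)))
    return bits / 8.0


def binary_entropy(p: float) -> float:
    """H(p) in bits for a Bernoulli(p) source."""
    if p <= 0.0 or p >= 1.0:
        return 0.0
    return -p * math.log2(p) - (1 - p) * math.log2(1 - p)
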