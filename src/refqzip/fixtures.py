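"""Deterministic synthetic references and FASTQ data with ground truth.

The generator emulates the regimes the compressor targets: fixed-length
short reads (Illumina-style) and variable-length long reads (PacBio/
nanopore-style), with controlled substitution divergence from the
reference, reverse-complemented reads, reference-free "junk" reads,
occasional N bases, and three quality-string shapes (constant, run-rich,
uniform-random).  Every read carries ground truth (origin position, strand,
mutated offsets) so mapper output can be checked against a brute-force
oracle.  Everything is a pure function of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .fastq_io import FastqRecord, Reference, serialize_record

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class QualityModel(Enum):
    CONSTANT = "constant"
    RUNNY = "runny"      # geometric run lengths, slowly drifting symbol
    UNIFORM = "uniform"  # i.i.d. printable Phred+33 symbols


class MetaStyle(Enum):
    SRA = "sra"
    ILLUMINA = "illumina"
    PACBIO = "pacbio"


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 0
    ref_len: int = 50_000
    n_reads: int = 1_000
    read_len: int | tuple[int, int] = 100
    sub_rate: float = 0.01
    revcomp_frac: float = 0.0
    junk_frac: float = 0.0
    n_frac: float = 0.0
    quality_model: QualityModel = QualityModel.RUNNY
    meta_style: MetaStyle = MetaStyle.SRA
    prefix: bytes = b"CG"

    def __post_init__(self) -> None:
        for name in ("sub_rate", "revcomp_frac", "junk_frac", "n_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass(frozen=True)
class ReadTruth:
    """Ground truth for one generated read.

    origin           0-based reference start of the forward-strand interval
                     the read was drawn from; -1 for junk reads
    strand           '+' or '-' (read is the reverse complement of the
                     reference interval)
    mutated_offsets  substituted offsets, on the forward reference strand
    n_offsets        offsets (in the final read) overwritten with 'N'
    """

    index: int
    origin: int
    strand: str
    mutated_offsets: tuple[int, ...] = ()
    n_offsets: tuple[int, ...] = ()


def gen_reference(spec: FixtureSpec) -> Reference:
    """I.i.d. uniform ACGT reference with the mapper prefix guaranteed to
    occur at least once per 1 kb (injected deterministically if absent)."""
    if spec.ref_len <= 0:
        raise ValueError("ref_len must be positive")
    rng = np.random.default_rng(spec.seed)
    arr = _BASES[rng.integers(0, 4, spec.ref_len)]
    bases = bytearray(arr.tobytes())
    prefix = spec.prefix
    if len(prefix) <= spec.ref_len:
        for w in range(0, spec.ref_len, 1000):
            window = bytes(bases[w : w + 1000])
            if len(window) < len(prefix):
                break
            if prefix not in window:
                at = w + int(rng.integers(0, len(window) - len(prefix) + 1))
                bases[at : at + len(prefix)] = prefix
    return Reference(name=f"synthetic_seed{spec.seed}", bases=bytes(bases))


def _read_length(spec: FixtureSpec, rng: np.random.Generator) -> int:
    if isinstance(spec.read_len, int):
        return spec.read_len
    lo, hi = spec.read_len
    return int(rng.integers(lo, hi + 1))


def _quality(spec: FixtureSpec, length: int, rng: np.random.Generator) -> bytes:
    model = spec.quality_model
    if model is QualityModel.CONSTANT:
        return b"I" * length
    if model is QualityModel.UNIFORM:
        return rng.integers(33, 75, length, dtype=np.uint8).tobytes()
    out = bytearray()
    level = 70
    while len(out) < length:
        run = min(length - len(out), int(rng.geometric(0.2)))
        level = int(np.clip(level + rng.integers(-4, 5), 35, 74))
        out += bytes([level]) * run
    return bytes(out)


def _meta(spec: FixtureSpec, index: int, length: int, rng: np.random.Generator) -> bytes:
    if spec.meta_style is MetaStyle.SRA:
        return f"@SRR{spec.seed % 1_000_000:06d}.{index + 1} {index + 1} length={length}".encode()
    if spec.meta_style is MetaStyle.ILLUMINA:
        tile = 1101 + (index // 5000)
        x = 1000 + (index * 37) % 20000
        y = 1000 + (index * 91) % 20000
        return f"@M00001:1:000000000-AAAAA:1:{tile}:{x}:{y} 1:N:0:1".encode()
    hole = 10000 + index
    return f"@m54006_160504_020705/{hole}/0_{length}".encode()


def gen_records(
    spec: FixtureSpec, reference: Reference
) -> tuple[list[FastqRecord], list[ReadTruth]]:
    """Generate reads plus ground truth.  Deterministic under spec.seed."""
    rng = np.random.default_rng(spec.seed + 0x5EED)
    ref = np.frombuffer(reference.bases, dtype=np.uint8)
    records: list[FastqRecord] = []
    truths: list[ReadTruth] = []
    for i in range(spec.n_reads):
        length = min(_read_length(spec, rng), len(ref))
        if rng.random() < spec.junk_frac:
            seq_arr = _BASES[rng.integers(0, 4, length)].copy()
            origin = -1
            mutated: tuple[int, ...] = ()
        else:
            origin = int(rng.integers(0, len(ref) - length + 1))
            seq_arr = ref[origin : origin + length].copy()
            mask = rng.random(length) < spec.sub_rate
            offs = np.flatnonzero(mask)
            for off in offs:
                # substitute with one of the three other bases
                cur = seq_arr[off]
                choices = _BASES[_BASES != cur]
                seq_arr[off] = choices[rng.integers(0, 3)]
            mutated = tuple(int(o) for o in offs)
        strand = "+"
        if rng.random() < spec.revcomp_frac:
            # reverse complement: A<->T (65<->84), C<->G (67<->71)
            comp = seq_arr.copy()
            comp[seq_arr == 65] = 84
            comp[seq_arr == 84] = 65
            comp[seq_arr == 67] = 71
            comp[seq_arr == 71] = 67
            seq_arr = comp[::-1].copy()
            strand = "-"
        n_offsets: tuple[int, ...] = ()
        if rng.random() < spec.n_frac:
            count = int(rng.integers(1, 4))
            positions = rng.choice(length, size=min(count, length), replace=False)
            seq_arr[positions] = ord("N")
            n_offsets = tuple(sorted(int(p) for p in positions))
        seq = seq_arr.tobytes()
        records.append(
            FastqRecord(_meta(spec, i, length, rng), seq, b"+", _quality(spec, length, rng))
        )
        truths.append(ReadTruth(i, origin, strand, mutated, n_offsets))
    return records, truths


def gen_fastq(spec: FixtureSpec, reference: Reference) -> bytes:
    """FASTQ bytes for the generated read set."""
    records, _ = gen_records(spec, reference)
    return b"".join(serialize_record(r) for r in records)


def truth_tsv(truths: list[ReadTruth]) -> bytes:
    """Ground-truth sidecar in TSV form."""
    lines = [b"index\torigin\tstrand\tmutated_offsets\tn_offsets"]
    for t in truths:
        mut = ",".join(map(str, t.mutated_offsets)) or "-"
        ns = ",".join(map(str, t.n_offsets)) or "-"
        lines.append(f"{t.index}\t{t.origin}\t{t.strand}\t{mut}\t{ns}".encode())
    return b"\n".join(lines) + b"\n"
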