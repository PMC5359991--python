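"""Blocking, archive round trips, determinism, and failure modes."""

import hashlib

import pytest

from refqzip import (
    CorruptionError,
    MapperConfig,
    RefqzipError,
    WrongReferenceError,
    compress,
    decompress,
    partition_blocks,
    read_header,
)
from refqzip.fastq_io import serialize_record
from refqzip.fixtures import FixtureSpec, MetaStyle, QualityModel, gen_fastq, gen_reference


class TestPartitionBlocks:
    def test_ten_records_ten_blocks(self):
        blocks = partition_blocks(list(range(10)), 10)
        assert [len(b) for b in blocks] == [1] * 10

    def test_ceiling_rule(self):
        assert [len(b) for b in partition_blocks(list(range(7)), 3)] == [3, 3, 1]

    def test_empty(self):
        assert partition_blocks([], 10) == []

    def test_concatenation_preserves_order(self):
        items = list(range(23))
        blocks = partition_blocks(items, 4)
        assert [x for b in blocks for x in b] == items


@pytest.fixture(scope="module")
def dataset():
    spec = FixtureSpec(seed=21, ref_len=20_000, n_reads=120, read_len=101,
                       sub_rate=0.02, revcomp_frac=0.3, junk_frac=0.1, n_frac=0.03)
    ref = gen_reference(spec)
    return ref, gen_fastq(spec, ref)


class TestRoundTrip:
    def test_lossless(self, dataset):
        ref, data = dataset
        assert decompress(compress(data, ref), ref) == data

    def test_empty_file(self, dataset):
        ref, _ = dataset
        archive = compress(b"", ref)
        header, _ = read_header(archive)
        assert header.record_count == 0 and header.block_count == 0
        assert decompress(archive, ref) == b""

    def test_single_record(self, dataset):
        ref, _ = dataset
        data = b"@only read\nACGTACGTNN\n+\n!!!!IIII!!\n"
        assert decompress(compress(data, ref), ref) == data

    def test_annotated_plus_lines(self, dataset):
        ref, _ = dataset
        data = (b"@r1 x\nACGT\n+r1 x\nIIII\n"
                b"@r2 y\nGGGG\n+\nJJJJ\n"
                b"@r3\nTTTTT\n+custom note\nKKKKK\n")
        assert decompress(compress(data, ref), ref) == data

    def test_all_raw_block(self, dataset):
        """Reads that cannot map at all still round trip (raw stream only)."""
        ref, _ = dataset
        data = b"".join(
            f"@junk{i}\n{'N' * 40}\n+\n{'#' * 40}\n".encode() for i in range(10)
        )
        assert decompress(compress(data, ref), ref) == data

    def test_variable_length_long_reads(self):
        spec = FixtureSpec(seed=22, ref_len=30_000, n_reads=8, read_len=(2000, 6000),
                           sub_rate=0.1, quality_model=QualityModel.RUNNY,
                           meta_style=MetaStyle.PACBIO)
        ref = gen_reference(spec)
        data = gen_fastq(spec, ref)
        assert decompress(compress(data, ref), ref) == data

    def test_assembled_reference_is_self_contained(self):
        spec = FixtureSpec(seed=23, ref_len=5000, n_reads=150, read_len=90, sub_rate=0.0)
        ref = gen_reference(spec)
        data = gen_fastq(spec, ref)
        archive = compress(data, assemble=True, assemble_target_len=20_000)
        assert decompress(archive) == data  # no external reference needed


class TestDeterminism:
    def test_thread_count_does_not_change_archive(self, dataset):
        ref, data = dataset
        digests = {
            hashlib.sha256(compress(data, ref, b=10, threads=t)).hexdigest()
            for t in (1, 4, 10)
        }
        assert len(digests) == 1

    def test_repeated_runs_identical(self, dataset):
        ref, data = dataset
        assert compress(data, ref) == compress(data, ref)


class TestFailureModes:
    def test_wrong_reference_rejected_with_digests(self, dataset):
        ref, data = dataset
        archive = compress(data, ref)
        other = gen_reference(FixtureSpec(seed=999, ref_len=10_000))
        with pytest.raises(WrongReferenceError, match="[0-9a-f]{16}"):
            decompress(archive, other)

    def test_missing_reference_rejected(self, dataset):
        ref, data = dataset
        with pytest.raises(RefqzipError, match="reference"):
            decompress(compress(data, ref), None)

    def test_truncated_archive_detected(self, dataset):
        ref, data = dataset
        archive = compress(data, ref)
        with pytest.raises(CorruptionError):
            decompress(archive[: len(archive) // 2], ref)

    def test_flipped_byte_detected(self, dataset):
        ref, data = dataset
        archive = bytearray(compress(data, ref))
        archive[len(archive) // 2] ^= 0xFF
        with pytest.raises(CorruptionError):
            decompress(bytes(archive), ref)

    def test_bad_magic_rejected(self):
        with pytest.raises(CorruptionError, match="magic"):
            read_header(b"NOPE" + bytes(20))

    def test_compress_without_reference_rejected(self):
        with pytest.raises(RefqzipError):
            compress(b"@r\nACGT\n+\nIIII\n", None)


class TestStreamShapes:
    def test_all_raw_reads_leave_position_and_mismatch_streams_empty(self, dataset):
        ref, _ = dataset
        data = b"".join(
            f"@j{i}\n{'N' * 30}\n+\n{'I' * 30}\n".encode() for i in range(6)
        )
        stats = {}
        compress(data, ref, stats=stats)
        # streams: meta, qual, positions, structure, mismatch, raw
        assert stats["stream_raw_sizes"][2] == 0
        assert stats["stream_raw_sizes"][4] == 0
        assert stats["stream_raw_sizes"][5] == 6 * 30
        assert stats["match_counts"]["RAW"] == 6

    def test_identical_reads_give_tiny_position_stream(self, dataset):
        ref, _ = dataset
        read = ref.bases[5000:5100]
        data = b"".join(
            b"@r%d\n%s\n+\n%s\n" % (i, read, b"I" * 100) for i in range(50)
        )
        stats = {}
        archive = compress(data, ref, b=1, stats=stats)
        assert stats["match_counts"]["FULL_EXACT"] == 50
        # after delta coding the positions stream is near-constant: one
        # non-zero delta then zeros, far below a naive 4-byte-per-read cost
        assert stats["stream_coded_sizes"][2] < 0.2 * 50 * 4
        assert decompress(archive, ref) == data
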