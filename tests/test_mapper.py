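"""Index construction, seed-and-extend mapping, and the brute-force oracle
equivalence of everything the mapper emits."""

import numpy as np
import pytest

from refqzip import (
    AssemblyError,
    MapperConfig,
    MatchType,
    RawSegment,
    Reference,
    assemble_reference,
    build_index,
    extend_seed,
    find_seeds,
    map_read,
    reconstruct_read,
    reverse_complement,
)
from refqzip.fixtures import FixtureSpec, gen_records, gen_reference


def brute_force_index(bases: bytes, k: int, prefix: bytes) -> dict:
    """Independent oracle: scan every position for prefix-anchored ACGT k-mers."""
    table = {}
    for p in range(len(bases) - k + 1):
        kmer = bases[p : p + k]
        if kmer.startswith(prefix) and all(c in b"ACGT" for c in kmer):
            table.setdefault(kmer, []).append(p)
    return table


class TestBuildIndex:
    def test_small_reference(self, small_config):
        cfg = MapperConfig(k=3, prefix=b"CG", L=3, e=0.1, segment_len=8)
        idx = build_index(Reference("r", b"CGACGA"), cfg)
        assert idx.table == {b"CGA": [0, 3]}

    def test_no_prefix_occurrence_gives_empty_table(self, small_config):
        idx = build_index(Reference("r", b"AAAATTTT"), small_config)
        assert idx.table == {}

    def test_kmers_containing_n_are_excluded(self):
        cfg = MapperConfig(k=2, prefix=b"C", L=2, e=0.1, segment_len=4)
        idx = build_index(Reference("r", b"CGNCG"), cfg)
        assert idx.table == {b"CG": [0, 3]}

    def test_k_longer_than_reference_yields_empty_index(self, default_config):
        idx = build_index(Reference("r", b"CGA"), default_config)
        assert idx.table == {}

    @pytest.mark.parametrize("k", [4, 8, 12])
    @pytest.mark.parametrize("prefix", [b"CG", b"AT"])
    def test_agrees_with_brute_force_on_random_references(self, k, prefix):
        rng = np.random.default_rng(k * 31 + prefix[0])
        for trial in range(5):
            n = int(rng.integers(50, 5000))
            bases = np.frombuffer(b"ACGT", np.uint8)[rng.integers(0, 4, n)].tobytes()
            cfg = MapperConfig(k=k, prefix=prefix, L=k, e=0.1, segment_len=max(k, 8))
            idx = build_index(Reference("r", bases), cfg)
            assert idx.table == brute_force_index(bases, k, prefix)

    def test_junction_spanning_kmers_are_excluded(self):
        cfg = MapperConfig(k=4, prefix=b"CG", L=4, e=0.1, segment_len=8)
        ref = Reference("r", b"ACGTCGTA", junctions=(4,))
        idx = build_index(ref, cfg)
        # CGTC at 1 and CGTA at 4 both exist; CGTC spans the junction at 4
        assert idx.table == {b"CGTA": [4]}


class TestReverseComplement:
    @pytest.mark.parametrize(
        "seq,expected",
        [(b"ACGT", b"ACGT"), (b"AAAA", b"TTTT"), (b"GATTACA", b"TGTAATC"), (b"ANT", b"ANT")],
    )
    def test_known_values(self, seq, expected):
        assert reverse_complement(seq) == expected

    def test_involution(self):
        rng = np.random.default_rng(2)
        s = np.frombuffer(b"ACGTN", np.uint8)[rng.integers(0, 5, 500)].tobytes()
        assert reverse_complement(reverse_complement(s)) == s

    def test_alphabet_enforced(self):
        with pytest.raises(ValueError):
            reverse_complement(b"ACGX")


class TestFindSeeds:
    def test_all_anchor_pairs_reported_in_order(self):
        cfg = MapperConfig(k=3, prefix=b"CG", L=3, e=0.1, segment_len=8)
        ref = Reference("r", b"CGACGA")
        idx = build_index(ref, cfg)
        assert find_seeds(b"CGACGA", idx) == [(0, 0), (0, 3), (3, 0), (3, 3)]

    def test_unrelated_read_has_no_seeds(self, small_config):
        idx = build_index(Reference("r", b"CGACGACG"), small_config)
        assert find_seeds(b"TTTT", idx) == []

    def test_read_shorter_than_k_has_no_seeds(self, default_config):
        spec = FixtureSpec(seed=1, ref_len=2000)
        idx = build_index(gen_reference(spec), default_config)
        assert find_seeds(b"CG", idx) == []


class TestExtendSeed:
    def _setup(self):
        spec = FixtureSpec(seed=42, ref_len=5000)
        ref = gen_reference(spec)
        cfg = MapperConfig()
        return ref, cfg

    def test_exact_substring_is_single_run(self):
        ref, cfg = self._setup()
        read = ref.bases[100:160]
        off = read.find(b"CG")
        m = extend_seed(read, ref, (off, 100 + off), cfg)
        assert m is not None
        assert (m.ref_pos, m.run_lengths, m.mismatch_bases) == (100, (60,), b"")

    def test_single_substitution_splits_runs(self):
        # 20-base read, one substitution at offset 5, e=0.1 -> 1 <= 2 allowed
        window = b"AAAGTCAACGTACCATTGGA"  # CG anchor at offset 8
        ref = Reference("r", b"TTTT" + window + b"TTTT")
        cfg = MapperConfig(k=4, prefix=b"CG", L=10, e=0.1, segment_len=16)
        read = bytearray(window)
        read[5] = ord(b"A")  # was 'C'
        m = extend_seed(bytes(read), ref, (8, 4 + 8), cfg)
        assert m is not None
        assert m.ref_pos == 4
        assert m.run_lengths == (5, 14)
        assert m.mismatch_bases == b"A"

    def test_tolerance_exceeded_fails(self):
        ref, cfg = self._setup()
        read = bytearray(ref.bases[300:320])
        for i in (0, 4, 8, 12, 16):
            read[i] = b"ACGT"[(b"ACGT".index(bytes(read[i:i+1])) + 1) % 4]
        m = extend_seed(bytes(read), ref, (2, 302), MapperConfig(e=0.1))
        assert m is None  # 5 mismatches > 0.1 * 20

    def test_never_crosses_fasta_junction(self):
        bases = b"ACGTACGTAC" + b"GTACGTACGT"
        ref = Reference("r", bases, junctions=(10,))
        cfg = MapperConfig(k=4, prefix=b"CG", L=4, e=0.0, segment_len=8)
        read = bases[8:14]  # spans the junction
        assert extend_seed(read, ref, (read.find(b"CG"), 8 + read.find(b"CG")), cfg) is None


class TestMapRead:
    def test_exact_substring_maps_full_exact(self, std_fixture):
        spec, ref, _, _ = std_fixture
        cfg = MapperConfig()
        idx = build_index(ref, cfg)
        read = ref.bases[1000:1100]
        rec = map_read(read, idx, ref, cfg)
        assert rec.match_type is MatchType.FULL_EXACT
        assert reconstruct_read(rec, ref) == read

    def test_reverse_complement_read_sets_palindrome_flag(self, std_fixture):
        spec, ref, _, _ = std_fixture
        cfg = MapperConfig()
        idx = build_index(ref, cfg)
        read = reverse_complement(ref.bases[2000:2100])
        rec = map_read(read, idx, ref, cfg)
        assert rec.match_type in (MatchType.FULL_EXACT, MatchType.FULL_SUB)
        assert rec.segments[0].palindrome
        assert reconstruct_read(rec, ref) == read

    def test_non_acgt_read_goes_raw(self, std_fixture):
        _, ref, _, _ = std_fixture
        cfg = MapperConfig()
        idx = build_index(ref, cfg)
        rec = map_read(b"NNNN", idx, ref, cfg)
        assert rec.match_type is MatchType.RAW
        assert rec.raw_bases == b"NNNN"

    def test_half_matching_read_is_segmented(self):
        spec = FixtureSpec(seed=8, ref_len=10_000)
        ref = gen_reference(spec)
        cfg = MapperConfig()
        idx = build_index(ref, cfg)
        rng = np.random.default_rng(9)
        junk = np.frombuffer(b"ACGT", np.uint8)[rng.integers(0, 4, 32)].tobytes()
        read = ref.bases[500:532] + junk
        rec = map_read(read, idx, ref, cfg)
        if rec.match_type is MatchType.SEGMENTED:
            kinds = [isinstance(s, RawSegment) for s in rec.segments]
            assert not kinds[0] and any(kinds)
        assert reconstruct_read(rec, ref) == read

    def test_reconstruction_inverts_mapping_across_divergence_levels(self):
        cfg = MapperConfig()
        for sub in (0.0, 0.05, 0.15):
            spec = FixtureSpec(seed=int(sub * 100) + 3, ref_len=20_000, n_reads=300,
                               read_len=100, sub_rate=sub, revcomp_frac=0.4,
                               junk_frac=0.1, n_frac=0.05)
            ref = gen_reference(spec)
            records, _ = gen_records(spec, ref)
            idx = build_index(ref, cfg)
            for r in records:
                rec = map_read(r.seq, idx, ref, cfg)
                assert reconstruct_read(rec, ref) == r.seq

    def test_determinism(self, std_fixture):
        _, ref, records, _ = std_fixture
        cfg = MapperConfig()
        idx = build_index(ref, cfg)
        first = [map_read(r.seq, idx, ref, cfg) for r in records[:50]]
        second = [map_read(r.seq, idx, ref, cfg) for r in records[:50]]
        assert first == second


class TestSegmentOracle:
    def test_every_emitted_segment_verifies_against_reference(self, std_fixture):
        """Brute-force check: run positions match, mismatch positions differ,
        and the per-segment tolerance rule holds."""
        _, ref, records, _ = std_fixture
        cfg = MapperConfig()
        idx = build_index(ref, cfg)
        for r in records:
            rec = map_read(r.seq, idx, ref, cfg)
            offset = 0
            for seg in rec.segments:
                if isinstance(seg, RawSegment):
                    offset += seg.length
                    continue
                piece = r.seq[offset : offset + seg.length]
                aligned = reverse_complement(piece) if seg.palindrome else piece
                window = ref.bases[seg.ref_pos : seg.ref_pos + seg.length]
                pos = 0
                n_mm = 0
                for i, run in enumerate(seg.run_lengths):
                    assert aligned[pos : pos + run] == window[pos : pos + run]
                    pos += run
                    if i < len(seg.mismatch_bases):
                        assert aligned[pos] == seg.mismatch_bases[i]
                        assert aligned[pos] != window[pos]
                        pos += 1
                        n_mm += 1
                assert n_mm <= cfg.e * seg.length
                offset += seg.length


class TestAssembleReference:
    def test_identical_reads_collapse_to_one(self):
        cfg = MapperConfig(k=4, prefix=b"CG", L=4, e=0.1, segment_len=8)
        ref = assemble_reference([b"CGAATTCC"] * 5, cfg, target_len=100)
        assert ref.bases == b"CGAATTCC"

    def test_greedy_overlap_merge(self):
        cfg = MapperConfig(k=3, prefix=b"CG", L=3, e=0.1, segment_len=8)
        ref = assemble_reference([b"CGAAAT", b"AATTTG"], cfg, target_len=100, min_overlap=3)
        assert ref.bases == b"CGAAATTTG"

    def test_no_prefix_read_raises(self, default_config):
        with pytest.raises(AssemblyError, match="reference"):
            assemble_reference([b"AAAA", b"TTTT"], default_config, target_len=100)

    def test_assembled_reference_is_indexable(self):
        spec = FixtureSpec(seed=5, ref_len=3000, n_reads=100, read_len=80, sub_rate=0.0)
        ref = gen_reference(spec)
        records, _ = gen_records(spec, ref)
        cfg = MapperConfig()
        asm = assemble_reference([r.seq for r in records], cfg, target_len=5000)
        idx = build_index(asm, cfg)
        assert idx.table
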