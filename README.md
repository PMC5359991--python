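# refqzip

Lossless reference-based compression of FASTQ sequencing data.

FASTQ files from high-throughput sequencers are huge and highly redundant:
read headers differ only in counters, nucleotide sequences largely restate
a genome, and quality strings are run-rich.  Generic compressors exploit
none of this structure.  `refqzip` is a library and command-line tool for
long-term archiving of FASTQ data that does, while guaranteeing an exact
byte-for-byte round trip — sequences, qualities, headers, `+` lines, and
read order are all reproduced unchanged.

It is aimed at people who keep raw reads around: sequencing cores, archive
maintainers, and anyone who wants reference-based ratios without running an
external aligner.

## How it works

A FASTQ file is split into metadata, nucleotide, and quality streams.

**Nucleotides** are mapped to an external reference (FASTA) with a
light-weight model: a hash table *I*<sub>R</sub> indexes every reference
position of each *k*-mer that begins with a fixed prefix (default `CG`,
*k* = 12).  A read *X* is anchored at a shared *k*-mer and extended as an
ungapped alignment; the first anchor with at most *e*·|X| mismatches wins.
If *X* fails, its reverse complement (a "palindrome" match) is tried; then
*X* is re-cut into short segments that are mapped independently; anything
left is stored literally.  Each mapped read costs only (position,
palindrome flag, match-run lengths, mismatch bases) instead of its bases.

**Metadata** lines are incrementally encoded (shared-prefix length +
suffix against the previous line).  **Qualities** get run-length-limited
encoding: runs of ≥ 3 equal symbols become (symbol, count) tokens, capped
at 255.

All resulting streams are entropy-coded by a bitwise context model driving
a binary arithmetic coder: the last 32 coded bits (28 for the 2-bit packed
mismatch-base stream) select adaptive counters (n₀, n₁), the next bit is
coded with probability p₁ = (n₁+1)/(n₀+n₁+2), and the counters are
updated.  The coder is integer-only and bit-exact across platforms.

Input records are processed in *b* = 10 contiguous blocks.  Blocks can be
mapped in parallel, but results are always collected in block order: the
archive bytes are a pure function of (input, reference, parameters),
independent of thread count.

See `docs/methods.md` for the model details and design rationale.

## Worked example

Generate a small synthetic dataset (2 000 × 101 bp reads at 1 %
divergence from a 50 kb reference) and compress it:

```python
from refqzip.fixtures import FixtureSpec, gen_fastq, gen_reference
spec = FixtureSpec(seed=11, ref_len=50_000, n_reads=2_000, read_len=101, sub_rate=0.01)
ref = gen_reference(spec)
open("reads.fastq", "wb").write(gen_fastq(spec, ref))
open("ref.fa", "wb").write(b">" + ref.name.encode() + b"\n" + ref.bases + b"\n")
```

    $ refqzip -v compress -i reads.fastq -r ref.fa -o reads.lwf2 --verify
    INFO compressed 2000 records in 10 blocks -> 96410 bytes (types: {'FULL_EXACT': 738, 'FULL_SUB': 1245, 'SEGMENTED': 1, 'RAW': 16})
    reads.fastq: 473786 -> 96410 bytes (ratio 4.91x, 2000 records)
    INFO stream metadata  raw     37518 coded     12819
    INFO stream quality   raw     79310 coded     70447
    INFO stream positions raw      5982 coded      4639
    INFO stream structure raw      7176 coded      6214
    INFO stream mismatch  raw      1926 coded       598
    INFO stream raw       raw      1685 coded      1637
    verify: round trip is byte-identical

    $ refqzip decompress -i reads.lwf2 -r ref.fa -o restored.fastq
    reads.lwf2: restored 473786 bytes to restored.fastq
    $ cmp reads.fastq restored.fastq && echo IDENTICAL
    IDENTICAL

Reading the numbers: 99.2 % of reads mapped (738 exactly, 1 245 with
substitutions), so 200 kB of bases shrank to ~13 kB of positions, structure
and mismatches; quality strings dominate the archive, as they always do in
lossless FASTQ compression.  The `--verify` flag re-decompresses the
archive and byte-compares it against the input.

Decompression requires the same reference; a mismatched one is rejected
before any output is produced:

    error: wrong reference: archive expects checksum 9d9a7d0f97051c7e, supplied reference has 733a222f36b1b14c

With no reference at hand, `refqzip compress -a` pseudo-assembles one from
the reads and embeds it, making the archive self-contained.

The same functionality is available as a library: `refqzip.compress`,
`refqzip.decompress`, plus the building blocks (`build_index`, `map_read`,
`encode_stream`, `rll_encode`, ...).

## Scope

`refqzip` does not do gapped alignment, mapping-quality estimation,
SAM/BAM/CRAM, paired-end joint modeling, lossy quality quantization, or
random access into archives.
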