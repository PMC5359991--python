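# Methods

## Problem and approach

High-throughput sequencing output in FASTQ format is dominated by three
very different byte populations: read identifiers (highly repetitive
line-to-line), nucleotide sequences (largely redundant against a genome of
the same species), and per-base quality strings (noisy, but run-rich on
many platforms).  `refqzip` compresses each population with a transform
suited to it and a single shared entropy-coding back end, while keeping the
whole pipeline strictly lossless: `decompress(compress(f, R), R) == f` byte
for byte, including read order, separator lines, and newline placement.

The pipeline is:

1. split 4-line records into metadata / base / quality streams;
2. map each read against an external reference with a light-weight
   k-mer model and record (position, palindrome flag, match runs, mismatch
   bases) instead of the bases;
3. pre-transform metadata (incremental/shared-prefix coding) and qualities
   (run-length-limited coding);
4. entropy-code the six resulting intermediate streams with a bitwise
   context model driving a binary arithmetic coder.

## The light-weight mapping model

A hash table `I_R` indexes every position of each length-`k` ACGT substring
of the reference that begins with a short fixed prefix (default `CG`).
Restricting the index to prefix-anchored k-mers shrinks it by roughly
`4^len(prefix)` at a proportional cost in seed density; the synthetic
reference generator guarantees at least one prefix occurrence per kilobase
so anchoring stays exercised.

Mapping a read `X`:

* collect candidate anchors — (read offset, reference position) pairs whose
  k-mers agree — ordered by read offset then reference position;
* extend each anchor as an ungapped alignment across the whole read; accept
  the **first** anchor whose extension has at most `e·|X|` mismatches (and
  `|X| >= L`).  First-acceptance makes mapping deterministic and fast, and
  a wrong anchor from a duplicated k-mer simply fails its extension and
  falls through to the next candidate;
* on failure, retry with the reverse complement of `X` ("palindrome"
  match); the match record stores the forward-strand interval plus a flag;
* on failure, cut `X` into `segment_len` pieces and map each piece
  independently (forward, then reverse complement); unmapped pieces are
  carried as literal bases;
* reads that still fail, and any read containing a non-ACGT character, are
  stored literally (RAW).  The mismatch alphabet is thereby exactly
  {A,C,G,T}, which keeps the mismatch stream 2-bit packable.

Alignment is substitution-only.  The match vocabulary (position, run
lengths, mismatch bases) has no indel field; indel-divergent reads degrade
to SEGMENTED or RAW, which costs ratio but never correctness.

Defaults: `k=12`, `prefix=CG`, `L=16`, `e=0.05`, `segment_len=32`.  These
are ordinary short-read values — `k=12` keeps random 12-mer collisions rare
on megabase references, `e=0.05` accepts typical platform error, and
`segment_len=32` is the smallest piece that still amortizes its per-segment
record.  All are configurable; archives record the values used.

Multi-record FASTA references are concatenated with recorded junction
offsets, and neither the index nor extension will cross a junction, so no
chimeric matches are produced.  With `-a`/`assemble=True` a reference is
pseudo-assembled from the reads themselves by greedy exact suffix/prefix
overlap (contigs must start from a prefix-containing read) and embedded in
the archive, making it self-contained.

## Field codecs

*Metadata*: each line is stored as (longest-common-prefix length with the
previous line, suffix).  Sequencer headers differ only in trailing counters,
so most lines reduce to a couple of bytes.  State resets at block
boundaries so blocks stay independently decodable.

*Qualities*: run-length-limited coding.  Maximal runs of one symbol with
length ≥ `run_min` (default 3) become run tokens capped at `run_cap`
(default 255); cap overflow splits the run, and a sub-`run_min` remainder
falls back to literals.  Tokens serialize into two planes — symbols, and a
one-byte control plane (0 = literal, else the run count) — which is
escape-free because run counts are always ≥ 2.

## Entropy coding

Each stream is coded bit by bit.  A context register holds the last
`order_bits` coded bits (32 for general streams ≈ 4 bytes of history; 28
for the 2-bit packed mismatch stream ≈ 14 bases).  Each context owns a
counter pair (n0, n1), held in a lazily allocated map keyed by the context
value, and predicts

    p1 = (n1 + δ) / (n0 + n1 + 2δ),   δ = 1,

so an unseen context predicts exactly 1/2.  Two maintenance regimes exist:

* **adaptive** (stream default): after incrementing the observed counter,
  the opposing counter is halved (x → x/2 + 1) once it exceeds 2.  This
  shortens the memory so the model tracks non-stationary data — the right
  behaviour for real FASTQ streams.
* **stationary**: no opposing halving; when a counter exceeds the cap
  (255) both are halved together, preserving the learned ratio.  This is
  the regime used when benchmarking the coder against the entropy of a
  memoryless source, where opposing-halving would systematically waste
  code length on rare symbols.

The arithmetic coder uses 32-bit low/high registers, probabilities
quantized to 16 bits, and the classic bit-wise renormalization with an
underflow-pending counter.  We chose bit-wise renormalization over
byte-wise top-byte emission because the latter needs an extra
interval-narrowing rule to exclude zero-width-range corner cases, while the
bit-wise invariant (the active interval always spans more than a quarter of
the register range) rules them out by construction.  The coder is pure
integer arithmetic, so output is bit-exact across platforms.  Output bits
are packed MSB-first into bytes with numpy.

Measured behaviour (also asserted by the test suite): a rate-exact
Bernoulli stream of 10⁶ bits codes within 2 % (+512 B) of `n·H(p)` for
p ∈ {0.5, 0.9, 0.99}; a 64 KiB stream repeating one 4-byte pattern codes
below 1 % of its size under the 32-bit context (the period fits the
context exactly); 64 KiB of uniform random bytes codes to ~100.02 %.
The entropy benchmark fixes the number of ones at `round(n·p)` and
shuffles: with truly i.i.d. draws the realized code length tracks the
*empirical* entropy, whose sampling fluctuation (~10³ bits at p = 0.9,
n = 10⁶) is larger than a near-optimal coder's redundancy, so pinning the
empirical rate is what makes a two-sided bound meaningful for any seed.

Every framed payload is `[varint raw_len][varint coded_len][coded
bytes][u64 BLAKE2b-8 digest of the raw payload]`.  The explicit coded
length is what lets a sequential archive parser skip to the next frame
without decoding.

## Archive and blocking

Records are split into `b` (default 10) contiguous blocks of
`ceil(n/b)` records.  Blocks may be mapped concurrently, but results are
always collected and encoded in block order, so the archive bytes are
independent of thread count and scheduling — parallelism is a contract,
not a format feature.  Each block contributes six framed payloads:

1. metadata: bit-packed bare-'+' flags, then the incremental deltas
   (annotated '+' lines travel here, after their record's header line);
2. qualities: RLL planes;
3. positions: zigzag deltas of mapped-segment positions at a fixed
   per-block byte width, stored as byte planes.  Byte planes matter: the
   low bytes of successive positions are near-uniform, so any context that
   mixes them with other fields is noise; keeping each plane contiguous
   gives the model a stationary context and lets the (mostly constant)
   high planes collapse;
4. structure: one head byte (match type + palindrome flag), read length,
   and run lengths per segment.  The final run of each segment is omitted
   (implied by the segment length) and FULL_EXACT records carry no run
   data at all;
5. mismatch bases, 2-bit packed under the 28-bit context model;
6. raw literal sequences.

The header records the mapper and RLL parameters and a 64-bit digest of
the reference bases; decompression refuses to run against a reference with
a different digest.  A whole-archive trailer digest detects truncation and
corruption before any stream is decoded.  Self-contained (assembled-
reference) archives embed the reference as an ordinary framed stream.

## What the synthetic generator does and does not emulate

`refqzip.fixtures` generates uniform random references with guaranteed
prefix density, reads drawn at uniform positions with i.i.d. substitutions,
optional reverse-complement and junk (reference-free) reads, optional N
injection, three quality shapes (constant, run-rich with geometric run
lengths, uniform), and three header dialects, with per-read ground truth.
It does not emulate platform error profiles (indels, homopolymer errors,
chimeras), coverage bias, or paired-end structure.  Consequently the test
suite demonstrates losslessness, determinism, and the coder/mapper
contracts on realistic-shaped data; measured compression ratios on real
instrument output will differ (real headers and qualities are usually more
compressible than the uniform model, real reads less mappable than the
substitution-only model).

## Problem sizes used in the test suite

The round-trip grid covers read lengths {51, 101, 70–600, 2000–6000} ×
substitution rates {0, 1, 5, 15 %} with 8–120 reads per file against 25 kb
references; the mapper oracle runs on 10⁴ reads against a 60 kb reference;
the compression envelope uses 10⁴ × 100 bp reads at 1 % divergence against
100 kb.  These sizes exercise every code path (including block parallelism
with b = 10) while keeping the suite fast; all generators scale to larger
inputs unchanged.

## Known limitations

* No random access into archives; decoding is sequential per block.
* Ungapped matching only; heavily indel-divergent long reads fall back to
  SEGMENTED/RAW and compress accordingly.
* The context store is a per-stream hash map; pathological streams can
  allocate up to one entry per coded bit.  A truncated-context memory
  guard is configurable through `PredictorConfig.order_bits`.
* The pluggable-backend seam exposes only the native coder; no external
  compressor is shipped.
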