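# Methods

## Model and procedure

The codec assumes nothing about its input beyond the four-letter
alphabet; every step is an exact bijection, so losslessness holds for
any sequence, skewed or not. What the transform *exploits* is
compositional skew: when the most frequent base x1 dominates, the
indicator stream `fr1` is mostly 1s with short zero-runs, run-length
halving shortens it, and the residual stream `f1` is only the non-x1
minority. The design target is bacterial-style composition where
c1 > c3 + c4 for descending base counts.

Pipeline (forward): rank → primary split (`fr1`, `f1`) → zero-run
halving (`fr1a`, `fr1b`) → pair merge (`f2`, `fr2a`, `fr2b`, leftover)
→ prefix recode (`fr3`) → 6-bit ASCII packing (six files) → per-file
LZ77 → archive. Each stage's inverse is implemented next to it and
property-tested as an identity; the pair `(operation, inverse)` is the
unit of correctness, not the operation alone.

### Invertibility notes

- Zero-run halving maps a run of length L to ⌈L/2⌉ zeros plus a parity
  bit. Runs in `fr1a` correspond one-to-one with runs in `fr1` because
  every run contributes at least one zero and 1-bits separate runs;
  expansion is 2k − parity.
- Pair orientation (`fr2b`) compares *rank positions* (x2 > x3 > x4),
  never raw counts, so tied counts cannot make encoding ambiguous once
  the rank is fixed: 0 means the pair was in descending frequency
  order, 1 ascending.
- The code {x2→0, x3→10, x4→11} is prefix-free; decoding rejects a
  truncated trailing codeword.
- The original length is not stored anywhere: it is implied by
  `fr1a`/`fr1b` (which reproduce `fr1`, whose length is the sequence
  length). Stream-length cross-checks (zeros of `fr1` vs `|f1|`,
  `|fr2a|` vs `|f2|`, ones of `fr2a` vs `|fr2b|`) are enforced on
  decode and turn corruption into explicit errors.
- 6-bit groups are packed most-significant-bit first (forced by the
  packing example 100011 → 35 → `_`); payload bytes lie in code range
  60–123, which cannot collide with the `#` delimiter (35) of the f0
  side file.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `sample_size` | 1000 residues | leading window counted for the rank; short sequences are fully sampled |
| rank tie-break | alphabetical (A<C<G<T) | deterministic; the rank used is stored in f0, so decompression never re-derives it |
| `window` | 32768 bytes | LZ77 sliding window; offset field width is sized from it |
| `min_match` / `max_match` | 3 / 258 | greedy matcher bounds; classic sliding-window conventions |

All LZ77 parameters are recorded in each member's stream header, and
the rank, leftover base, and remainders live in f0, so `decompress`
takes no options. Non-ACGT handling is strict by default; the escape
policy removes offenders into a `(position, codepoint)` side member and
reinserts them on decompression. Multi-record FASTA is compressed
record-by-record, each with its own rank.

### LZ77 details

Greedy longest-match parsing with ties broken toward the most recent
occurrence (smallest offset). Candidates are found through a hash index
on the `min_match`-byte prefix and match extension uses binary search
over slice comparisons, so parsing is exact (identical token-by-token
to a brute-force longest-match scanner, which the tests check) yet fast
enough for megabase inputs. Serialization is a 17-byte header (magic,
version, window, min/max match, uncompressed length) followed by
flag-bit tokens: `1` + 8-bit literal, or `0` + fixed-width offset−1 and
length−min fields, zero-padded to a byte. Decoding stops at the
declared uncompressed length, so padding is never misread; overlapping
matches copy byte-sequentially.

### Known discrepancy in the pair-orientation stream

The published worked example prints `fr2b = 01101`, which is consistent
neither with the stated orientation rule nor with the example's own
`fr3` under the stated rank TCAG. This package implements the rule as
stated — descending pair → 0 — which yields `10101` for that example;
golden tests assert the rule-derived value and tag the printed one as
inconsistent (`synthetic.golden_examples`). Since encoder and decoder
share one convention, losslessness is unaffected.

## Synthetic data

`CompositionSpec` draws i.i.d. bases from per-base probabilities
(default A 0.45, C 0.10, G 0.10, T 0.35 — a skewed, AT-rich,
bacterial-like composition in which the dominant base outnumbers the
two rarest combined), then overwrites a `repeat_fraction` of the
sequence with copies of earlier windows (segments of 200–2000 bases,
scaled down for short inputs) to plant literal repeats for the LZ77
phase. It emulates only composition and copy-repeat structure — not GC
islands, repeat families, coding bias, or chromosome organization — so
round-trip and size results on it demonstrate correctness and
bit-accounting behaviour, not ratios attainable on real genomes.

## Problem sizes used in the test suite

Exhaustive oracles run where enumeration is feasible: all bitstrings to
length 12 for run-length halving, to 18 for 6-bit packing, all
prefix-code strings to 10 symbols, all binary byte strings to length 10
for LZ77, plus brute-force greedy agreement to 64 bytes. End-to-end
losslessness runs over 1000 seeded sequences at lengths 0–10^5 across
uniform and skewed compositions, with named degenerate cases (empty,
homopolymers, the published examples).

## Compression behaviour and limitations

On the default skewed synthetic composition the five transform streams
total ≈ 1.89 bits per base — below the 2-bit flat bound, which is the
transform's whole margin. The packing and framing then work against it:
6-bit ASCII packing stores 6 payload bits per 8-bit byte (×4/3), and an
LZ77 literal costs 9 bits per byte, so on packed streams that are close
to incompressible the second phase *expands* its input by up to an
eighth. Repeat copies planted at arbitrary positions survive 6-bit
packing with probability about 1/6 (the bit offset between the two
occurrences must be ≡ 0 mod 6; pair merging adds a further factor of
1/2 for the f2-derived streams), so 30 % repeat content recovers only a
few percent. The net effect, measured by the acceptance suite on the
100 kb default-skew fixture, is an archive of ≈ 2.7 bits per base —
*above* the flat 2-bit encoding even though the stage-1 streams are
below it. The codec therefore earns its keep against 8-bit text
(ratio ≈ 0.66 on that fixture) and as a fully inspectable, invertible
pipeline, but undercutting 2 bits per base requires either byte-aligned
long-range redundancy in the packed members or an entropy coder in
place of the fixed-width token framing — both outside this design.

Other limitations: lowercase soft-masking is lost; whole-sequence
in-memory processing; the fixed prefix code does no context modelling.
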