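"""Nour-Sharawi three-file splitter (phase 1) and its bit accounting.

The baseline this codec builds on splits a sequence into three binary
files by frequency rank: b1 marks x1 positions over the whole sequence;
b2 marks x2 among the non-x1 residues; b3 marks x3 among the remaining
x3/x4 residues. Total bits are n + (n - c1) + (n - c1 - c2) for
descending counts c1 >= c2 >= c3 >= c4, which beats the flat 2-bit
encoding exactly when c1 > c3 + c4 — the skew typical of bacterial
genomes. Only phase 1 is implemented here; the baseline's second phase
(bzip2 on the three files) is an external general-purpose compressor
and plays no part in the bit accounting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .errors import StreamConsistencyError
from .rank import RankOrder, compute_rank

__all__ = ["NsmSplit", "nsm_encode", "nsm_decode", "nsm_total_bits", "nsm_bits_for_sequence"]


@dataclass(frozen=True)
class NsmSplit:
    """The three indicator bitstreams plus the rank that produced them."""

    b1: str
    b2: str
    b3: str
    rank: RankOrder

    @property
    def total_bits(self) -> int:
        return len(self.b1) + len(self.b2) + len(self.b3)


def nsm_encode(residues: str, rank: RankOrder) -> NsmSplit:
    """Split ``residues`` into the three rank-indicator bitstreams."""
    x1, x2, x3 = rank.x1, rank.x2, rank.x3
    b1: list[str] = []
    b2: list[str] = []
    b3: list[str] = []
    for c in residues:
        if c not in rank.order:
            raise StreamConsistencyError(f"residue {c!r} outside rank alphabet")
        if c == x1:
            b1.append("1")
            continue
        b1.append("0")
        if c == x2:
            b2.append("1")
            continue
        b2.append("0")
        b3.append("1" if c == x3 else "0")
    return NsmSplit(b1="".join(b1), b2="".join(b2), b3="".join(b3), rank=rank)


def nsm_decode(split: NsmSplit) -> str:
    """Exact inverse of :func:`nsm_encode`."""
    if split.b1.count("0") != len(split.b2):
        raise StreamConsistencyError("b2 length does not match zeros of b1")
    if split.b2.count("0") != len(split.b3):
        raise StreamConsistencyError("b3 length does not match zeros of b2")
    x1, x2, x3, x4 = split.rank.order
    out: list[str] = []
    it2 = iter(split.b2)
    it3 = iter(split.b3)
    for bit in split.b1:
        if bit == "1":
            out.append(x1)
        elif next(it2) == "1":
            out.append(x2)
        else:
            out.append(x3 if next(it3) == "1" else x4)
    return "".join(out)


def nsm_total_bits(counts: Iterable[int], n: int) -> int:
    """Total phase-1 bits for a length-n sequence with the given base counts.

    ``counts`` are the four base counts in any order; they must sum to n.
    """
    cs = sorted(counts, reverse=True)
    if len(cs) != 4 or any(c < 0 for c in cs):
        raise StreamConsistencyError("counts must be four non-negative integers")
    if sum(cs) != n:
        raise StreamConsistencyError(f"counts sum to {sum(cs)}, expected n={n}")
    c1, c2 = cs[0], cs[1]
    return n + (n - c1) + (n - c1 - c2)


def nsm_bits_for_sequence(residues: str, sample_size: int = 1000) -> tuple[NsmSplit, int]:
    """Rank, encode, and account a sequence in one call.

    Returns the split and its total bit count. The rank uses the same
    leading-sample convention as the main codec; the accounting is the
    actual stream lengths (which equal the count formula whenever the
    sample covers the whole sequence).
    """
    rank = compute_rank(residues, sample_size=sample_size)
    split = nsm_encode(residues, rank)
    return split, split.total_bits
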