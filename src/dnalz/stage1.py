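"""Stage-1 transform: from a DNA sequence to five bitstreams.

The forward direction runs four sub-transforms, each with an exact
inverse:

1. *Primary split* — an indicator bitstream ``fr1`` marks positions of
   the most frequent base x1 (1 = x1, 0 = other); the non-x1 residues
   are collected in order into ``f1``.
2. *Run-length halving* — each maximal zero-run of length L in ``fr1``
   becomes ceil(L/2) zeros in ``fr1a`` plus one parity bit in ``fr1b``
   (0 = L even, 1 = L odd); 1-bits copy through unchanged.
3. *Pair merging* — consecutive pairs of ``f1`` (an alphabet of three
   symbols x2, x3, x4) map to single characters in ``f2``: an equal pair
   (a, a) emits a with a 0 in ``fr2a``; an unequal pair (a, b) emits the
   third symbol with a 1 in ``fr2a`` and a bit in ``fr2b`` — 0 when a
   outranks b in frequency (descending pair), 1 otherwise. An odd final
   character is carried verbatim as the leftover.
4. *Prefix-free recoding* — ``f2`` is encoded into ``fr3`` with the code
   x2 -> 0, x3 -> 10, x4 -> 11.

The five surviving streams (fr1a, fr1b, fr2a, fr2b, fr3) plus the rank
and leftover form a :class:`Stage1Bundle`, from which the sequence is
reconstructed exactly. All operations accept empty inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import groupby

from .errors import StreamConsistencyError
from .rank import RankOrder

__all__ = [
    "Stage1Bundle",
    "split_primary",
    "merge_primary",
    "rle_halve",
    "rle_expand",
    "pair_merge",
    "pair_expand",
    "encode_fr3",
    "decode_fr3",
    "transform",
    "reconstruct",
]


@dataclass(frozen=True)
class Stage1Bundle:
    """The five final bitstreams plus rank and leftover base."""

    fr1a: str
    fr1b: str
    fr2a: str
    fr2b: str
    fr3: str
    rank: RankOrder
    leftover: str = ""

    @property
    def streams(self) -> tuple[str, str, str, str, str]:
        return (self.fr1a, self.fr1b, self.fr2a, self.fr2b, self.fr3)

    @property
    def total_bits(self) -> int:
        """Total stage-1 payload size in bits (excluding rank/leftover)."""
        return sum(len(s) for s in self.streams)


def _check_bits(name: str, bits: str) -> None:
    if bits.strip("01"):
        raise StreamConsistencyError(f"{name} contains non-binary symbols")


def split_primary(residues: str, rank: RankOrder) -> tuple[str, str]:
    """Split a sequence into the x1 indicator ``fr1`` and residual ``f1``."""
    x1 = rank.x1
    table = {ord(b): ("1" if b == x1 else "0") for b in rank.order}
    fr1 = residues.translate(table)
    if fr1.strip("01"):
        bad = next(c for c in residues if c not in rank.order)
        raise StreamConsistencyError(f"residue {bad!r} outside rank alphabet")
    f1 = residues.replace(x1, "")
    return fr1, f1


def merge_primary(fr1: str, f1: str, rank: RankOrder) -> str:
    """Inverse of :func:`split_primary`."""
    _check_bits("fr1", fr1)
    if fr1.count("0") != len(f1):
        raise StreamConsistencyError(
            f"fr1 has {fr1.count('0')} zeros but f1 has {len(f1)} residues"
        )
    x1 = rank.x1
    it = iter(f1)
    return "".join(x1 if bit == "1" else next(it) for bit in fr1)


def rle_halve(fr1: str) -> tuple[str, str]:
    """Halve zero-runs of ``fr1``: run of L -> ceil(L/2) zeros + parity bit."""
    _check_bits("fr1", fr1)
    out_a: list[str] = []
    out_b: list[str] = []
    for bit, group in groupby(fr1):
        run = sum(1 for _ in group)
        if bit == "1":
            out_a.append("1" * run)
        else:
            out_a.append("0" * ((run + 1) // 2))
            out_b.append("1" if run % 2 else "0")
    return "".join(out_a), "".join(out_b)


def rle_expand(fr1a: str, fr1b: str) -> str:
    """Inverse of :func:`rle_halve`: run of k zeros + parity p -> 2k - p zeros."""
    _check_bits("fr1a", fr1a)
    _check_bits("fr1b", fr1b)
    out: list[str] = []
    parity_index = 0
    for bit, group in groupby(fr1a):
        run = sum(1 for _ in group)
        if bit == "1":
            out.append("1" * run)
        else:
            if parity_index >= len(fr1b):
                raise StreamConsistencyError("fr1b exhausted before zero-runs of fr1a")
            odd = fr1b[parity_index] == "1"
            parity_index += 1
            out.append("0" * (2 * run - (1 if odd else 0)))
    if parity_index != len(fr1b):
        raise StreamConsistencyError(
            f"fr1b has {len(fr1b)} parity bits but fr1a has {parity_index} zero-runs"
        )
    return "".join(out)


def pair_merge(f1: str, rank: RankOrder) -> tuple[str, str, str, str]:
    """Merge consecutive pairs of ``f1`` into ``f2`` with side bits.

    Returns ``(f2, fr2a, fr2b, leftover)``. ``f1`` must contain only the
    three non-primary bases. fr2b records pair orientation: 0 when the
    first character of an unequal pair has the higher frequency rank
    (descending), 1 when ascending.
    """
    x2, x3, x4 = rank.x2, rank.x3, rank.x4
    pos = {x2: 0, x3: 1, x4: 2}
    third = {
        frozenset((x2, x3)): x4,
        frozenset((x2, x4)): x3,
        frozenset((x3, x4)): x2,
    }
    if rank.x1 in f1:
        raise StreamConsistencyError(f"primary base {rank.x1!r} present in f1")
    f2: list[str] = []
    fr2a: list[str] = []
    fr2b: list[str] = []
    for i in range(0, len(f1) - 1, 2):
        a, b = f1[i], f1[i + 1]
        if a not in pos or b not in pos:
            raise StreamConsistencyError("f1 residue outside rank alphabet")
        if a == b:
            f2.append(a)
            fr2a.append("0")
        else:
            f2.append(third[frozenset((a, b))])
            fr2a.append("1")
            fr2b.append("0" if pos[a] < pos[b] else "1")
    leftover = f1[-1] if len(f1) % 2 else ""
    return "".join(f2), "".join(fr2a), "".join(fr2b), leftover


def pair_expand(f2: str, fr2a: str, fr2b: str, rank: RankOrder, leftover: str = "") -> str:
    """Inverse of :func:`pair_merge`; appends the leftover character."""
    _check_bits("fr2a", fr2a)
    _check_bits("fr2b", fr2b)
    if len(fr2a) != len(f2):
        raise StreamConsistencyError(f"|fr2a|={len(fr2a)} does not match |f2|={len(f2)}")
    if fr2a.count("1") != len(fr2b):
        raise StreamConsistencyError(
            f"fr2a has {fr2a.count('1')} unequal pairs but |fr2b|={len(fr2b)}"
        )
    x2, x3, x4 = rank.x2, rank.x3, rank.x4
    pos = {x2: 0, x3: 1, x4: 2}
    # For each merged character c, the unequal pair is the other two
    # symbols in descending frequency order.
    others = {
        x2: (x3, x4),
        x3: (x2, x4),
        x4: (x2, x3),
    }
    out: list[str] = []
    j = 0
    for c, flag in zip(f2, fr2a):
        if c not in pos:
            raise StreamConsistencyError("f2 residue outside rank alphabet")
        if flag == "0":
            out.append(c + c)
        else:
            p, q = others[c]
            out.append(p + q if fr2b[j] == "0" else q + p)
            j += 1
    if leftover:
        out.append(leftover)
    return "".join(out)


def encode_fr3(f2: str, rank: RankOrder) -> str:
    """Encode ``f2`` with the prefix-free code x2 -> 0, x3 -> 10, x4 -> 11."""
    if rank.x1 in f2:
        raise StreamConsistencyError(f"primary base {rank.x1!r} present in f2")
    table = {ord(rank.x2): "0", ord(rank.x3): "10", ord(rank.x4): "11"}
    out = f2.translate(table)
    if out.strip("01"):
        bad = next(c for c in f2 if c not in rank.order)
        raise StreamConsistencyError(f"f2 residue {bad!r} outside rank alphabet")
    return out


def decode_fr3(fr3: str, rank: RankOrder) -> str:
    """Inverse of :func:`encode_fr3`; rejects a truncated trailing codeword."""
    _check_bits("fr3", fr3)
    out: list[str] = []
    i = 0
    n = len(fr3)
    while i < n:
        if fr3[i] == "0":
            out.append(rank.x2)
            i += 1
        else:
            if i + 1 >= n:
                raise StreamConsistencyError("truncated codeword at end of fr3")
            out.append(rank.x3 if fr3[i + 1] == "0" else rank.x4)
            i += 2
    return "".join(out)


def transform(residues: str, rank: RankOrder) -> Stage1Bundle:
    """Run the full stage-1 forward transform."""
    fr1, f1 = split_primary(residues, rank)
    fr1a, fr1b = rle_halve(fr1)
    f2, fr2a, fr2b, leftover = pair_merge(f1, rank)
    fr3 = encode_fr3(f2, rank)
    return Stage1Bundle(
        fr1a=fr1a, fr1b=fr1b, fr2a=fr2a, fr2b=fr2b, fr3=fr3,
        rank=rank, leftover=leftover,
    )


def reconstruct(bundle: Stage1Bundle) -> str:
    """Exact inverse of :func:`transform`."""
    f2 = decode_fr3(bundle.fr3, bundle.rank)
    f1 = pair_expand(f2, bundle.fr2a, bundle.fr2b, bundle.rank, bundle.leftover)
    fr1 = rle_expand(bundle.fr1a, bundle.fr1b)
    return merge_primary(fr1, f1, bundle.rank)
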