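"""6-bit ASCII packing and the f0 side-channel file.

Each bitstream is cut into 6-bit groups, most-significant-bit first;
every group value (0-63) plus 60 gives a printable character in code
range 60-123 ('<' .. '{'). The 0-5 trailing bits that do not fill a
group travel as a remainder token in f0. f0 holds, '#'-delimited: the
five remainder tokens (for fr1a, fr1b, fr2a, fr2b, fr3 in that order),
the rank string, and an optional single leftover base. The delimiter
'#' (code 35) is outside the payload code range, so parsing is
unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import StreamConsistencyError
from .rank import BASES, RankOrder
from .stage1 import Stage1Bundle

OFFSET = 60
MEMBER_NAMES = ("f1aa", "f1bb", "f2aa", "f2bb", "f3", "f0")

_SIX_BITS = {chr(v + OFFSET): format(v, "06b") for v in range(64)}

__all__ = [
    "MEMBER_NAMES",
    "PackedSet",
    "pack_bits",
    "unpack_bits",
    "build_f0",
    "parse_f0",
    "pack_bundle",
    "unpack_set",
]


@dataclass(frozen=True)
class PackedSet:
    """The six text payloads ready for the LZ77 phase."""

    f1aa: str
    f1bb: str
    f2aa: str
    f2bb: str
    f3: str
    f0: str

    def members(self) -> dict[str, str]:
        return {name: getattr(self, name) for name in MEMBER_NAMES}


def pack_bits(bits: str) -> tuple[str, str]:
    """Pack a bitstring into (payload, remainder of 0-5 bits)."""
    if bits.strip("01"):
        raise StreamConsistencyError("pack_bits input contains non-binary symbols")
    cut = len(bits) - len(bits) % 6
    payload = "".join(
        chr(int(bits[i : i + 6], 2) + OFFSET) for i in range(0, cut, 6)
    )
    return payload, bits[cut:]


def unpack_bits(payload: str, remainder: str = "") -> str:
    """Inverse of :func:`pack_bits`: expand each character to 6 bits, append remainder."""
    if remainder.strip("01") or len(remainder) > 5:
        raise StreamConsistencyError(f"invalid remainder token {remainder!r}")
    try:
        body = "".join(_SIX_BITS[c] for c in payload)
    except KeyError as exc:
        raise StreamConsistencyError(
            f"payload character {exc.args[0]!r} outside code range 60-123"
        ) from None
    return body + remainder


def build_f0(remainders: tuple[str, str, str, str, str], rank: RankOrder, leftover: str = "") -> str:
    """Assemble the f0 side channel; inverse of :func:`parse_f0`."""
    if len(remainders) != 5:
        raise StreamConsistencyError("f0 takes exactly five remainder tokens")
    for r in remainders:
        if r.strip("01") or len(r) > 5:
            raise StreamConsistencyError(f"invalid remainder token {r!r}")
    if leftover and (len(leftover) != 1 or leftover not in BASES):
        raise StreamConsistencyError(f"invalid leftover base {leftover!r}")
    return "#".join([*remainders, str(rank), leftover])


def parse_f0(text: str) -> tuple[tuple[str, str, str, str, str], RankOrder, str]:
    """Split f0 into remainder tokens, rank, and the optional leftover base."""
    parts = text.split("#")
    if len(parts) != 7:
        raise StreamConsistencyError(
            f"f0 must contain exactly six '#' delimiters, found {len(parts) - 1}"
        )
    remainders = tuple(parts[:5])
    for r in remainders:
        if r.strip("01") or len(r) > 5:
            raise StreamConsistencyError(f"invalid remainder token {r!r} in f0")
    rank = RankOrder.from_string(parts[5])
    leftover = parts[6]
    if leftover and (len(leftover) != 1 or leftover not in BASES):
        raise StreamConsistencyError(f"invalid leftover base {leftover!r} in f0")
    return remainders, rank, leftover


def pack_bundle(bundle: Stage1Bundle) -> PackedSet:
    """Pack all five stage-1 streams and assemble f0."""
    payloads = []
    remainders = []
    for bits in bundle.streams:
        payload, rem = pack_bits(bits)
        payloads.append(payload)
        remainders.append(rem)
    f0 = build_f0(tuple(remainders), bundle.rank, bundle.leftover)
    return PackedSet(*payloads, f0=f0)


def unpack_set(packed: PackedSet) -> Stage1Bundle:
    """Inverse of :func:`pack_bundle`."""
    remainders, rank, leftover = parse_f0(packed.f0)
    streams = [
        unpack_bits(payload, rem)
        for payload, rem in zip(
            (packed.f1aa, packed.f1bb, packed.f2aa, packed.f2bb, packed.f3),
            remainders,
        )
    ]
    return Stage1Bundle(*streams, rank=rank, leftover=leftover)
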