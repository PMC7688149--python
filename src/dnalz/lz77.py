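"""Self-contained LZ77 sliding-window codec.

Greedy longest-match parsing, left to right: at each position the
longest match of length >= ``min_match`` within the last ``window``
bytes is emitted as (offset, length); ties on length are broken toward
the most recent occurrence (smallest offset). Overlapping matches
(offset < length) are allowed and decode by sequential byte copy.

Serialized stream layout (all integers little-endian):

====== ======= =====================================
bytes  field   meaning
====== ======= =====================================
0-3    magic   b"LZ77"
4      version 1
5-8    window  sliding-window size
9-10   min     minimum match length
11-12  max     maximum match length
13-20  ulen    uncompressed length
21-    tokens  bit-packed, MSB-first, zero-padded
====== ======= =====================================

Each token starts with one flag bit: 1 = literal, followed by 8 bits of
the byte; 0 = match, followed by a fixed-width offset field (offset-1,
width sized from ``window``) and length field (length-min, width sized
from ``max - min``). Decoding stops after ``ulen`` output bytes, so the
zero padding is never misread.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from typing import NamedTuple, Union

from .errors import Lz77FormatError

MAGIC = b"LZ77"
VERSION = 1
_HEADER = struct.Struct("<4sBIHHQ")

__all__ = [
    "Lz77Params",
    "Literal",
    "Match",
    "tokenize",
    "detokenize",
    "compress",
    "decompress",
    "header_info",
]


@dataclass(frozen=True)
class Lz77Params:
    """Sliding-window parameters; recorded in every stream header."""

    window: int = 32768
    min_match: int = 3
    max_match: int = 258

    def __post_init__(self) -> None:
        if self.window <= 0 or self.min_match <= 0 or self.max_match <= 0:
            raise Lz77FormatError("LZ77 parameters must be positive")
        if self.min_match > self.max_match:
            raise Lz77FormatError("min_match must not exceed max_match")
        if self.window > 0xFFFFFFFF or self.max_match > 0xFFFF:
            raise Lz77FormatError("LZ77 parameters exceed header field widths")

    @property
    def offset_bits(self) -> int:
        return max(1, (self.window - 1).bit_length())

    @property
    def length_bits(self) -> int:
        return max(1, (self.max_match - self.min_match).bit_length())


class Literal(NamedTuple):
    byte: int


class Match(NamedTuple):
    offset: int
    length: int


Token = Union[Literal, Match]


def _match_length(data: bytes, i: int, j: int, limit: int) -> int:
    """Length of the common prefix of data[i:] and data[j:], capped at limit.

    Binary search over slice equality: each probe is one C-level memcmp,
    so extension is O(log limit) comparisons instead of one per byte.
    """
    if data[j : j + limit] == data[i : i + limit]:
        return limit
    lo, hi = 0, limit  # equal up to lo, mismatch strictly before hi
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if data[j : j + mid] == data[i : i + mid]:
            lo = mid
        else:
            hi = mid
    return lo


def tokenize(data: bytes, params: Lz77Params = Lz77Params()) -> list[Token]:
    """Greedy longest-match parse of ``data`` into literal/match tokens."""
    n = len(data)
    window, min_match, max_match = params.window, params.min_match, params.max_match
    tokens: list[Token] = []
    # Positions sharing the same min_match-byte prefix, most recent first.
    index: dict[bytes, list[int]] = {}

    def insert(p: int) -> None:
        if p + min_match <= n:
            index.setdefault(data[p : p + min_match], []).append(p)

    i = 0
    while i < n:
        best_len = 0
        best_j = -1
        limit = min(max_match, n - i)
        if limit >= min_match:
            chain = index.get(data[i : i + min_match])
            if chain:
                lo_bound = i - window
                for j in reversed(chain):  # most recent candidate first
                    if j < lo_bound:
                        continue
                    length = _match_length(data, i, j, limit)
                    if length > best_len:
                        best_len, best_j = length, j
                        if length == limit:
                            break
        if best_len >= min_match:
            tokens.append(Match(offset=i - best_j, length=best_len))
            for p in range(i, i + best_len):
                insert(p)
            i += best_len
        else:
            tokens.append(Literal(data[i]))
            insert(i)
            i += 1
    return tokens


def detokenize(tokens: list[Token]) -> bytes:
    """Replay tokens into the byte sequence they encode."""
    out = bytearray()
    for tok in tokens:
        if isinstance(tok, Literal):
            out.append(tok.byte)
        else:
            if tok.offset > len(out):
                raise Lz77FormatError(
                    f"match offset {tok.offset} exceeds decoded prefix {len(out)}"
                )
            start = len(out) - tok.offset
            for k in range(tok.length):
                out.append(out[start + k])
    return bytes(out)


class _BitWriter:
    def __init__(self) -> None:
        self.buf = bytearray()
        self.acc = 0
        self.nbits = 0

    def write(self, value: int, width: int) -> None:
        self.acc = (self.acc << width) | (value & ((1 << width) - 1))
        self.nbits += width
        while self.nbits >= 8:
            self.nbits -= 8
            self.buf.append((self.acc >> self.nbits) & 0xFF)
        self.acc &= (1 << self.nbits) - 1

    def getvalue(self) -> bytes:
        if self.nbits:
            self.buf.append((self.acc << (8 - self.nbits)) & 0xFF)
            self.acc = 0
            self.nbits = 0
        return bytes(self.buf)


class _BitReader:
    def __init__(self, data: bytes) -> None:
        self.data = data
        self.pos = 0
        self.acc = 0
        self.nbits = 0

    def read(self, width: int) -> int:
        while self.nbits < width:
            if self.pos >= len(self.data):
                raise Lz77FormatError("truncated LZ77 token stream")
            self.acc = (self.acc << 8) | self.data[self.pos]
            self.pos += 1
            self.nbits += 8
        self.nbits -= width
        value = (self.acc >> self.nbits) & ((1 << width) - 1)
        self.acc &= (1 << self.nbits) - 1
        return value


def compress(data: bytes, params: Lz77Params = Lz77Params()) -> bytes:
    """Compress ``data`` into a self-delimiting LZ77 stream."""
    tokens = tokenize(data, params)
    writer = _BitWriter()
    off_bits, len_bits = params.offset_bits, params.length_bits
    for tok in tokens:
        if isinstance(tok, Literal):
            writer.write(1, 1)
            writer.write(tok.byte, 8)
        else:
            writer.write(0, 1)
            writer.write(tok.offset - 1, off_bits)
            writer.write(tok.length - params.min_match, len_bits)
    header = _HEADER.pack(
        MAGIC, VERSION, params.window, params.min_match, params.max_match, len(data)
    )
    return header + writer.getvalue()


def header_info(blob: bytes) -> tuple[Lz77Params, int]:
    """Parse a stream header; returns (params, uncompressed length)."""
    if len(blob) < _HEADER.size:
        raise Lz77FormatError("LZ77 stream shorter than its header")
    magic, version, window, min_match, max_match, ulen = _HEADER.unpack_from(blob)
    if magic != MAGIC:
        raise Lz77FormatError(f"bad LZ77 magic {magic!r}")
    if version != VERSION:
        raise Lz77FormatError(f"unsupported LZ77 stream version {version}")
    try:
        params = Lz77Params(window=window, min_match=min_match, max_match=max_match)
    except Lz77FormatError as exc:
        raise Lz77FormatError(f"corrupt LZ77 header: {exc}") from None
    return params, ulen


def decompress(blob: bytes) -> bytes:
    """Exact inverse of :func:`compress`."""
    params, ulen = header_info(blob)
    reader = _BitReader(blob[_HEADER.size :])
    off_bits, len_bits = params.offset_bits, params.length_bits
    out = bytearray()
    while len(out) < ulen:
        if reader.read(1):
            out.append(reader.read(8))
        else:
            offset = reader.read(off_bits) + 1
            length = reader.read(len_bits) + params.min_match
            if offset > len(out):
                raise Lz77FormatError(
                    f"match offset {offset} exceeds decoded prefix {len(out)}"
                )
            if len(out) + length > ulen:
                raise Lz77FormatError("token stream overruns declared length")
            start = len(out) - offset
            if offset >= length:
                out += out[start : start + length]
            else:
                for k in range(length):
                    out.append(out[start + k])
    return bytes(out)
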