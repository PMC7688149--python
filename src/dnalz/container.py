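"""Archive container: the six LZ77-compressed members plus metadata.

A single archive file replaces the six loose files of the original
scheme. Layout (little-endian):

* 4-byte magic ``DNZ1``, 1-byte version, 4-byte record count;
* per record: 1 flag byte (bit 0: FASTA header present, bit 1: escape
  member present), an optional length-prefixed UTF-8 header, then the
  six members f1aa, f1bb, f2aa, f2bb, f3, f0 in fixed order, each a
  4-byte length followed by a self-delimiting LZ77 stream, then the
  optional escape member.

Everything needed to decompress (rank, leftover, LZ77 parameters) lives
in f0 and the per-member LZ77 headers, so decompression takes no
options. Multi-record FASTA compresses each record independently with
its own rank.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

from . import lz77, pack6, stage1
from .errors import ArchiveFormatError, StreamConsistencyError
from .lz77 import Lz77Params
from .pack6 import MEMBER_NAMES, PackedSet
from .rank import RankOrder, compute_rank
from .sequence_io import DnaSequence, Format, Policy, read_sequence, write_sequence

ARCHIVE_MAGIC = b"DNZ1"
ARCHIVE_VERSION = 1
_FLAG_HEADER = 0x01
_FLAG_ESCAPE = 0x02
ESCAPE_MEMBER = "esc"

__all__ = [
    "MemberInfo",
    "RecordReport",
    "ArchiveReport",
    "encode_archive",
    "decode_archive",
    "inspect_archive",
    "compress_file",
    "decompress_file",
    "inspect_file",
    "format_inspect_table",
]


@dataclass(frozen=True)
class MemberInfo:
    name: str
    raw_size: int        # bytes before LZ77
    compressed_size: int  # serialized LZ77 stream bytes


@dataclass(frozen=True)
class RecordReport:
    rank: str
    leftover: str
    members: tuple[MemberInfo, ...]
    header: str | None = None
    sequence_length: int | None = None
    escaped: int = 0
    lz77_params: Lz77Params = field(default_factory=Lz77Params)

    @property
    def compressed_size(self) -> int:
        return sum(m.compressed_size for m in self.members)


@dataclass(frozen=True)
class ArchiveReport:
    original_size: int
    archive_size: int
    records: tuple[RecordReport, ...]

    @property
    def ratio(self) -> float:
        """(uncompressed - compressed) / uncompressed; 0 for empty input."""
        if self.original_size <= 0:
            return 0.0
        return (self.original_size - self.archive_size) / self.original_size


def _escape_text(escapes: tuple[tuple[int, str], ...]) -> str:
    return ";".join(f"{pos}:{ord(char)}" for pos, char in escapes)


def _parse_escape_text(text: str) -> tuple[tuple[int, str], ...]:
    if not text:
        return ()
    out = []
    for token in text.split(";"):
        pos_s, _, code_s = token.partition(":")
        try:
            out.append((int(pos_s), chr(int(code_s))))
        except ValueError:
            raise ArchiveFormatError(f"corrupt escape token {token!r}") from None
    return tuple(out)


def _pack_record(
    seq: DnaSequence,
    sample_size: int,
    rank_override: str | None,
) -> PackedSet:
    if rank_override is not None:
        rank = RankOrder.from_string(rank_override)
    elif seq.residues:
        rank = compute_rank(seq.residues, sample_size=sample_size)
    else:
        rank = RankOrder.from_string("ACGT")  # empty record: any rank works
    bundle = stage1.transform(seq.residues, rank)
    return pack6.pack_bundle(bundle)


def _encode_record(
    seq: DnaSequence,
    sample_size: int,
    rank_override: str | None,
    params: Lz77Params,
) -> tuple[bytes, RecordReport]:
    packed = _pack_record(seq, sample_size, rank_override)
    members = packed.members()
    flags = 0
    chunks: list[bytes] = []
    if seq.header is not None:
        flags |= _FLAG_HEADER
    if seq.escapes:
        flags |= _FLAG_ESCAPE
    chunks.append(struct.pack("<B", flags))
    if seq.header is not None:
        hdr = seq.header.encode("utf-8")
        chunks.append(struct.pack("<H", len(hdr)) + hdr)
    infos: list[MemberInfo] = []
    names = list(MEMBER_NAMES) + ([ESCAPE_MEMBER] if seq.escapes else [])
    texts = {**members, ESCAPE_MEMBER: _escape_text(seq.escapes)}
    for name in names:
        raw = texts[name].encode("utf-8")
        blob = lz77.compress(raw, params)
        chunks.append(struct.pack("<I", len(blob)) + blob)
        infos.append(MemberInfo(name=name, raw_size=len(raw), compressed_size=len(blob)))
    _, rank, leftover = pack6.parse_f0(members["f0"])
    report = RecordReport(
        rank=str(rank),
        leftover=leftover,
        members=tuple(infos),
        header=seq.header,
        sequence_length=len(seq),
        escaped=len(seq.escapes),
        lz77_params=params,
    )
    return b"".join(chunks), report


def encode_archive(
    seqs: list[DnaSequence],
    *,
    sample_size: int = 1000,
    rank_override: str | None = None,
    params: Lz77Params = Lz77Params(),
) -> tuple[bytes, tuple[RecordReport, ...]]:
    """Compress sequences into archive bytes; returns (blob, per-record reports)."""
    chunks = [ARCHIVE_MAGIC, struct.pack("<BI", ARCHIVE_VERSION, len(seqs))]
    reports = []
    for seq in seqs:
        body, report = _encode_record(seq, sample_size, rank_override, params)
        chunks.append(body)
        reports.append(report)
    return b"".join(chunks), tuple(reports)


class _Cursor:
    def __init__(self, data: bytes) -> None:
        self.data = data
        self.pos = 0

    def take(self, n: int) -> bytes:
        if self.pos + n > len(self.data):
            raise ArchiveFormatError("archive truncated")
        out = self.data[self.pos : self.pos + n]
        self.pos += n
        return out

    def u8(self) -> int:
        return self.take(1)[0]

    def u16(self) -> int:
        return struct.unpack("<H", self.take(2))[0]

    def u32(self) -> int:
        return struct.unpack("<I", self.take(4))[0]


def _walk_records(blob: bytes):
    """Yield (flags, header, {name: compressed blob}) per record."""
    cur = _Cursor(blob)
    if cur.take(4) != ARCHIVE_MAGIC:
        raise ArchiveFormatError("not a dnalz archive (bad magic)")
    version = cur.u8()
    if version != ARCHIVE_VERSION:
        raise ArchiveFormatError(f"unsupported archive version {version}")
    count = cur.u32()
    for _ in range(count):
        flags = cur.u8()
        header = cur.take(cur.u16()).decode("utf-8") if flags & _FLAG_HEADER else None
        names = list(MEMBER_NAMES) + ([ESCAPE_MEMBER] if flags & _FLAG_ESCAPE else [])
        members = {name: bytes(cur.take(cur.u32())) for name in names}
        yield flags, header, members
    if cur.pos != len(blob):
        raise ArchiveFormatError("trailing bytes after last record")


def decode_archive(blob: bytes) -> list[DnaSequence]:
    """Restore the exact original sequences from archive bytes."""
    out: list[DnaSequence] = []
    for flags, header, members in _walk_records(blob):
        texts = {name: lz77.decompress(b).decode("utf-8") for name, b in members.items()}
        packed = PackedSet(**{name: texts[name] for name in MEMBER_NAMES})
        try:
            bundle = pack6.unpack_set(packed)
            residues = stage1.reconstruct(bundle)
        except StreamConsistencyError as exc:
            raise ArchiveFormatError(f"inconsistent archive members: {exc}") from exc
        escapes = _parse_escape_text(texts.get(ESCAPE_MEMBER, ""))
        out.append(DnaSequence(residues=residues, header=header, escapes=escapes))
    return out


def inspect_archive(blob: bytes) -> tuple[RecordReport, ...]:
    """Summarize an archive without decompressing the large members.

    Member raw sizes come from the LZ77 stream headers; rank and
    leftover come from f0 (the only member decompressed here).
    """
    reports = []
    for _, header, members in _walk_records(blob):
        infos = []
        params = None
        for name, b in members.items():
            p, ulen = lz77.header_info(b)
            params = params or p
            infos.append(MemberInfo(name=name, raw_size=ulen, compressed_size=len(b)))
        f0_text = lz77.decompress(members["f0"]).decode("utf-8")
        _, rank, leftover = pack6.parse_f0(f0_text)
        escaped = 0
        if ESCAPE_MEMBER in members:
            esc_text = lz77.decompress(members[ESCAPE_MEMBER]).decode("utf-8")
            escaped = len(_parse_escape_text(esc_text))
        reports.append(
            RecordReport(
                rank=str(rank),
                leftover=leftover,
                members=tuple(infos),
                header=header,
                escaped=escaped,
                lz77_params=params or Lz77Params(),
            )
        )
    return tuple(reports)


def compress_file(
    in_path: str | Path,
    out_path: str | Path,
    *,
    format: Format = "auto",
    policy: Policy = "strict",
    sample_size: int = 1000,
    rank_override: str | None = None,
    params: Lz77Params = Lz77Params(),
    split_dir: str | Path | None = None,
) -> ArchiveReport:
    """Compress a raw/FASTA file into an archive; returns the size report.

    ``split_dir``, if given, additionally writes the six uncompressed
    stage-1 member files per record (the original scheme's loose files).
    """
    in_path, out_path = Path(in_path), Path(out_path)
    seqs = read_sequence(in_path, format=format, policy=policy)
    blob, reports = encode_archive(
        seqs, sample_size=sample_size, rank_override=rank_override, params=params
    )
    out_path.write_bytes(blob)
    if split_dir is not None:
        split_dir = Path(split_dir)
        split_dir.mkdir(parents=True, exist_ok=True)
        for i, seq in enumerate(seqs):
            packed = _pack_record(seq, sample_size, rank_override)
            suffix = "" if len(seqs) == 1 else f".{i}"
            for name, text in packed.members().items():
                (split_dir / f"{name}{suffix}").write_text(text)
    return ArchiveReport(
        original_size=in_path.stat().st_size,
        archive_size=len(blob),
        records=reports,
    )


def decompress_file(
    in_path: str | Path,
    out_path: str | Path,
    format: Format = "auto",
) -> list[DnaSequence]:
    """Restore the original sequence(s) from an archive file.

    ``format="auto"`` writes FASTA when the archive carries headers or
    multiple records, raw text otherwise.
    """
    seqs = decode_archive(Path(in_path).read_bytes())
    if format == "auto":
        format = "fasta" if (len(seqs) != 1 or seqs[0].header is not None) else "raw"
    write_sequence(seqs, out_path, format=format)
    return seqs


def inspect_file(in_path: str | Path) -> tuple[RecordReport, ...]:
    return inspect_archive(Path(in_path).read_bytes())


def format_inspect_table(reports: tuple[RecordReport, ...]) -> str:
    """Human-readable member table for the inspect command."""
    lines = []
    for i, rec in enumerate(reports):
        p = rec.lz77_params
        head = f"record {i}: rank={rec.rank}"
        if rec.leftover:
            head += f" leftover={rec.leftover}"
        if rec.header:
            head += f" header={rec.header!r}"
        lines.append(head)
        lines.append(
            f"  lz77: window={p.window} min_match={p.min_match} max_match={p.max_match}"
        )
        lines.append(f"  {'member':8} {'raw':>10} {'compressed':>10}")
        for m in rec.members:
            lines.append(f"  {m.name:8} {m.raw_size:>10} {m.compressed_size:>10}")
        total_raw = sum(m.raw_size for m in rec.members)
        lines.append(f"  {'total':8} {total_raw:>10} {rec.compressed_size:>10}")
    return "\n".join(lines)
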