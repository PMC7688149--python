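import pytest

from dnalz.container import (
    compress_file,
    decode_archive,
    decompress_file,
    encode_archive,
    inspect_archive,
    inspect_file,
    format_inspect_table,
)
from dnalz.errors import ArchiveFormatError, SequenceAlphabetError
from dnalz.lz77 import Lz77Params
from dnalz.pack6 import MEMBER_NAMES
from dnalz.sequence_io import DnaSequence, read_sequence
from dnalz.synthetic import CompositionSpec, generate_sequence


def test_worked_example_file_roundtrip(tmp_path, worked_sequence, golden):
    src = tmp_path / "in.txt"
    src.write_text(worked_sequence + "\n")
    arc = tmp_path / "out.dnz"
    report = compress_file(src, arc, rank_override="TCAG")
    assert report.original_size == src.stat().st_size
    assert report.archive_size == arc.stat().st_size
    assert report.ratio == pytest.approx(
        (report.original_size - report.archive_size) / report.original_size
    )
    assert report.records[0].rank == "TCAG"
    raw_sizes = {m.name: m.raw_size for m in report.records[0].members}
    assert raw_sizes == {name: len(golden[name].value) for name in MEMBER_NAMES}
    out = tmp_path / "restored.txt"
    (seq,) = decompress_file(arc, out)
    assert seq.residues == worked_sequence
    assert out.read_text().strip() == worked_sequence


def test_empty_record_archive(tmp_path):
    src = tmp_path / "empty.txt"
    src.write_text("")
    arc = tmp_path / "empty.dnz"
    report = compress_file(src, arc)
    assert report.ratio == 0.0
    (seq,) = decompress_file(arc, tmp_path / "restored.txt")
    assert seq.residues == ""


def test_multi_record_fasta_independent_ranks(tmp_path):
    src = tmp_path / "two.fa"
    src.write_text(">a mostly T\n" + "TTTTTTAC" * 5 + "\n>b mostly G\n" + "GGGGGGAC" * 5 + "\n")
    arc = tmp_path / "two.dnz"
    report = compress_file(src, arc)
    assert [r.rank[0] for r in report.records] == ["T", "G"]
    out = tmp_path / "restored.fa"
    seqs = decompress_file(arc, out)
    assert [s.header for s in seqs] == ["a mostly T", "b mostly G"]
    back = read_sequence(out, format="fasta")
    assert [s.residues for s in back] == [s.residues for s in seqs]


def test_escape_policy_preserves_non_acgt(tmp_path):
    src = tmp_path / "messy.fa"
    src.write_text(">r with Ns\nACGTNNACGTRYACGT\n")
    arc = tmp_path / "messy.dnz"
    with pytest.raises(SequenceAlphabetError):
        compress_file(src, arc)  # strict default refuses
    report = compress_file(src, arc, policy="escape")
    assert report.records[0].escaped == 4
    out = tmp_path / "restored.fa"
    (seq,) = decompress_file(arc, out)
    assert seq.restore_text() == "ACGTNNACGTRYACGT"
    assert "ACGTNNACGTRYACGT" in out.read_text()


def test_inspect_reports_members_and_rank(tmp_path, worked_sequence):
    src = tmp_path / "in.txt"
    src.write_text(worked_sequence + "\n")
    arc = tmp_path / "out.dnz"
    compress_file(src, arc, rank_override="TCAG")
    reports = inspect_file(arc)
    assert [m.name for m in reports[0].members] == list(MEMBER_NAMES)
    assert reports[0].rank == "TCAG"
    compressed = {m.name: m.compressed_size for m in reports[0].members}
    # member sizes plus structural overhead account for the whole file
    overhead = 4 + 1 + 4 + 1 + 4 * len(MEMBER_NAMES)  # magic/version/count/flags/lengths
    assert sum(compressed.values()) + overhead == arc.stat().st_size
    table = format_inspect_table(reports)
    assert "rank=TCAG" in table and "f1aa" in table


def test_split_writes_loose_member_files(tmp_path, worked_sequence, golden):
    src = tmp_path / "in.txt"
    src.write_text(worked_sequence + "\n")
    arc = tmp_path / "out.dnz"
    split = tmp_path / "members"
    compress_file(src, arc, rank_override="TCAG", split_dir=split)
    for name in MEMBER_NAMES:
        assert (split / name).read_text() == golden[name].value


def test_custom_lz77_params_are_self_describing(tmp_path):
    seq = generate_sequence(CompositionSpec(length=3000, seed=9, repeat_fraction=0.4))
    params = Lz77Params(window=512, min_match=2, max_match=20)
    blob, reports = encode_archive([seq], params=params)
    assert reports[0].lz77_params == params
    assert decode_archive(blob)[0].residues == seq.residues
    assert inspect_archive(blob)[0].lz77_params == params


def test_bad_archives_rejected(tmp_path):
    with pytest.raises(ArchiveFormatError):
        decode_archive(b"NOPE" + b"\x00" * 10)
    blob, _ = encode_archive([DnaSequence(residues="ACGTACGT")])
    with pytest.raises(ArchiveFormatError):
        decode_archive(blob[:-3])  # truncated member
    with pytest.raises(ArchiveFormatError):
        decode_archive(blob + b"\x00")  # trailing bytes


def test_end_to_end_random_archive_identity():
    seqs = [
        generate_sequence(CompositionSpec(length=n, seed=n, repeat_fraction=0.2))
        for n in (0, 1, 2, 13, 500, 4097)
    ]
    seqs = [DnaSequence(residues=s.residues, header=f"n={len(s)}") for s in seqs]
    blob, _ = encode_archive(seqs)
    restored = decode_archive(blob)
    assert [s.residues for s in restored] == [s.residues for s in seqs]
    assert [s.header for s in restored] == [s.header for s in seqs]
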