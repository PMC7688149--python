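"""Reading and writing DNA sequences (raw text and FASTA).

The codec operates on uppercase sequences over {A, C, G, T}. Input is
normalized (whitespace stripped, case folded up) before validation.
Residues outside the alphabet are a hard error by default; with the
``escape`` policy they are removed from the stream and recorded as
(position, character) pairs so decompression can reinsert them. Case
folding is not reversed on output (soft-masking is lost).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO

from .errors import DnalzError, SequenceAlphabetError
from .rank import BASES

Format = Literal["auto", "raw", "fasta"]
Policy = Literal["strict", "escape"]

_ALPHABET = set(BASES)

__all__ = ["DnaSequence", "read_sequence", "write_sequence", "normalize"]


@dataclass(frozen=True)
class DnaSequence:
    """A validated DNA sequence over {A, C, G, T}.

    ``escapes`` holds (position, character) pairs for residues that were
    removed under the escape policy; positions index into the *restored*
    string (normalized input with the escaped characters still present),
    in strictly ascending order.
    """

    residues: str
    header: str | None = None
    escapes: tuple[tuple[int, str], ...] = field(default=())

    def __post_init__(self) -> None:
        bad = [(i, c) for i, c in enumerate(self.residues) if c not in _ALPHABET]
        if bad:
            raise SequenceAlphabetError([p for p, _ in bad], [c for _, c in bad])
        last = -1
        for pos, char in self.escapes:
            if pos <= last or len(char) != 1:
                raise DnalzError("escape records must be ascending (position, char) pairs")
            last = pos

    def __len__(self) -> int:
        return len(self.residues)

    def restore_text(self) -> str:
        """Normalized sequence text with escaped characters reinserted."""
        if not self.escapes:
            return self.residues
        out: list[str] = []
        it = iter(self.residues)
        esc = dict(self.escapes)
        total = len(self.residues) + len(self.escapes)
        for i in range(total):
            out.append(esc[i] if i in esc else next(it))
        return "".join(out)


def normalize(text: str) -> str:
    """Strip all whitespace and fold to uppercase."""
    return "".join(text.split()).upper()


def _build(text: str, header: str | None, policy: Policy) -> DnaSequence:
    clean = normalize(text)
    bad = [(i, c) for i, c in enumerate(clean) if c not in _ALPHABET]
    if not bad:
        return DnaSequence(residues=clean, header=header)
    if policy == "strict":
        raise SequenceAlphabetError([p for p, _ in bad], [c for _, c in bad])
    kept = "".join(c for c in clean if c in _ALPHABET)
    return DnaSequence(residues=kept, header=header, escapes=tuple(bad))


def _sniff_format(path: Path) -> Format:
    with open(path, "r") as fh:
        for line in fh:
            if line.strip():
                return "fasta" if line.lstrip().startswith(">") else "raw"
    return "raw"


def read_sequence(
    path: str | Path,
    format: Format = "auto",
    policy: Policy = "strict",
) -> list[DnaSequence]:
    """Read one or more sequences from ``path``.

    ``format="raw"`` reads the whole file as one sequence (whitespace
    ignored); ``"fasta"`` yields one ``DnaSequence`` per record with the
    description preserved as header; ``"auto"`` sniffs for a leading '>'.
    Under ``policy="strict"`` any non-ACGT residue raises
    :class:`SequenceAlphabetError` with its positions; under ``"escape"``
    such residues are removed and recorded on the returned sequences.
    """
    path = Path(path)
    if format == "auto":
        format = _sniff_format(path)
    if format == "raw":
        return [_build(path.read_text(), None, policy)]
    if format == "fasta":
        return [
            _build(str(rec.seq), rec.description, policy)
            for rec in SeqIO.parse(str(path), "fasta")
        ]
    raise DnalzError(f"unknown sequence format {format!r}")


def write_sequence(
    seqs: DnaSequence | Iterable[DnaSequence],
    path: str | Path,
    format: Literal["raw", "fasta"] = "raw",
    line_width: int = 70,
) -> None:
    """Write sequence(s) to ``path``; inverse of :func:`read_sequence`.

    Raw format accepts exactly one sequence and writes its text followed
    by a newline. FASTA wraps residues at ``line_width`` columns.
    """
    if isinstance(seqs, DnaSequence):
        seqs = [seqs]
    seqs = list(seqs)
    if line_width <= 0:
        raise DnalzError("line_width must be positive")
    buf = io.StringIO()
    if format == "raw":
        if len(seqs) != 1:
            raise DnalzError("raw format holds exactly one sequence")
        buf.write(seqs[0].restore_text())
        buf.write("\n")
    elif format == "fasta":
        for seq in seqs:
            buf.write(f">{seq.header or ''}\n")
            text = seq.restore_text()
            for i in range(0, len(text), line_width):
                buf.write(text[i : i + line_width])
                buf.write("\n")
    else:
        raise DnalzError(f"unknown sequence format {format!r}")
    Path(path).write_text(buf.getvalue())
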