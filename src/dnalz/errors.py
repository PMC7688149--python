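"""Exception hierarchy for the dnalz codec."""


class DnalzError(Exception):
    """Base class for all dnalz errors."""


class SequenceAlphabetError(DnalzError, ValueError):
    """A sequence contains residues outside {A, C, G, T}.

    Carries the offending positions (0-based, on the normalized,
    whitespace-stripped sequence) so callers can report or escape them.
    """

    def __init__(self, positions, characters, message=None):
        self.positions = tuple(positions)
        self.characters = tuple(characters)
        if message is None:
            shown = ", ".join(
                f"{c!r}@{p}" for p, c in list(zip(self.positions, self.characters))[:10]
            )
            more = "" if len(self.positions) <= 10 else f" (+{len(self.positions) - 10} more)"
            message = f"non-ACGT residues: {shown}{more}"
        super().__init__(message)


class StreamConsistencyError(DnalzError, ValueError):
    """Bitstreams or side channels disagree in length or structure."""


class Lz77FormatError(DnalzError, ValueError):
    """A serialized LZ77 stream is corrupt, truncated, or has a bad header."""


class ArchiveFormatError(DnalzError, ValueError):
    """An archive file is corrupt or not a dnalz archive."""
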