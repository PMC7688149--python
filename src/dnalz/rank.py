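"""Base-frequency rank order.

The codec orders the four bases by descending frequency in a leading
sample of the sequence (default 1000 residues). The most frequent base
is x1, then x2, x3, x4. The rank drives every later stage: the x1
indicator split, the pair-merge side bits, and the prefix-free code on
the merged stream. Every archive stores the rank actually used, so
decompression never re-derives it.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .errors import DnalzError

BASES = "ACGT"

__all__ = ["BASES", "RankOrder", "compute_rank"]


@dataclass(frozen=True)
class RankOrder:
    """A total order on {A, C, G, T} by descending sample frequency.

    Parameters
    ----------
    order:
        Four-character permutation of ``ACGT``; ``order[0]`` is x1.
    counts:
        Sample counts aligned with ``order`` (non-increasing), or ``None``
        when the order was supplied as an explicit override.
    sample_size:
        Number of residues actually counted, or ``None`` for overrides.
    """

    order: str
    counts: tuple[int, int, int, int] | None = None
    sample_size: int | None = None

    def __post_init__(self) -> None:
        if sorted(self.order) != sorted(BASES):
            raise DnalzError(f"rank order {self.order!r} is not a permutation of ACGT")
        if self.counts is not None:
            if len(self.counts) != 4 or any(c < 0 for c in self.counts):
                raise DnalzError(f"invalid rank counts {self.counts!r}")
            if list(self.counts) != sorted(self.counts, reverse=True):
                raise DnalzError("rank counts must be non-increasing along the order")

    @classmethod
    def from_string(cls, order: str) -> "RankOrder":
        """Build an override rank (no counts) from a string like ``"TCAG"``."""
        return cls(order=order.upper())

    @property
    def x1(self) -> str:
        return self.order[0]

    @property
    def x2(self) -> str:
        return self.order[1]

    @property
    def x3(self) -> str:
        return self.order[2]

    @property
    def x4(self) -> str:
        return self.order[3]

    def position(self, base: str) -> int:
        """0-based frequency rank of ``base`` (0 = most frequent)."""
        return self.order.index(base)

    def __str__(self) -> str:
        return self.order


def compute_rank(
    residues: str,
    sample_size: int = 1000,
    tie_break: str = BASES,
) -> RankOrder:
    """Count bases in the leading sample and sort them by descending count.

    The first ``sample_size`` residues are counted (the whole sequence when
    it is shorter). Ties are broken by position in ``tie_break`` (default
    alphabetical, A < C < G < T); bases absent from the sample sort last.

    Raises
    ------
    DnalzError
        If ``residues`` is empty or ``sample_size`` is not positive.
    """
    if not residues:
        raise DnalzError("cannot compute a rank order from an empty sequence")
    if sample_size <= 0:
        raise DnalzError("sample_size must be positive")
    if sorted(tie_break) != sorted(BASES):
        raise DnalzError(f"tie_break {tie_break!r} is not a permutation of ACGT")

    sample = residues[:sample_size]
    counts = Counter(sample)
    ordered = sorted(BASES, key=lambda b: (-counts[b], tie_break.index(b)))
    return RankOrder(
        order="".join(ordered),
        counts=tuple(counts[b] for b in ordered),
        sample_size=len(sample),
    )
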