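"""Synthetic sequence generation and pinned worked-example fixtures.

The generator emulates the two features the codec exploits: skewed base
composition (bacterial-style, where the top base outnumbers the third
and fourth combined) and repeat content (earlier windows copied forward,
giving the LZ77 phase back-references to find). It makes no attempt at
realistic genome structure — no GC islands, repeat families, coding
bias, or chromosomes.

``golden_examples`` pins every intermediate string of the published
worked example, each tagged with whether the published value is
consistent with the codec's own rules (the pair-orientation stream fr2b
is printed inconsistently in the source material; see the tag).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DnalzError
from .rank import BASES
from .sequence_io import DnaSequence

# Skewed bacterial-like default composition: the top base (A here)
# outnumbers the third and fourth combined, the regime where the
# rank-based split pays off.
SKEWED_COMPOSITION = (0.45, 0.10, 0.10, 0.35)  # A, C, G, T
UNIFORM_COMPOSITION = (0.25, 0.25, 0.25, 0.25)

# The published 30-base worked example and the two baseline examples.
WORKED_SEQUENCE = "TGGACCGTTAATCCTTTTTTGAAGGACCTT"
WORKED_RANK = "TCAG"
NSM_EXAMPLE_1 = "TTGAACGATAATCCGTATTTGAAAAAAATT"
# Printed with 28 characters but described with counts summing to 30;
# the stated descending counts drive the published bit-lengths 30/21/13.
NSM_EXAMPLE_2 = "TGGACCGATATCGTATTTGAAGGACCTT"
NSM_EXAMPLE_2_COUNTS = (9, 8, 7, 6)
NSM_EXAMPLE_2_N = 30

__all__ = [
    "CompositionSpec",
    "GoldenValue",
    "generate_sequence",
    "golden_examples",
    "SKEWED_COMPOSITION",
    "UNIFORM_COMPOSITION",
    "WORKED_SEQUENCE",
    "WORKED_RANK",
    "NSM_EXAMPLE_1",
    "NSM_EXAMPLE_2",
    "NSM_EXAMPLE_2_COUNTS",
    "NSM_EXAMPLE_2_N",
]


@dataclass(frozen=True)
class CompositionSpec:
    """Recipe for a synthetic sequence.

    ``probabilities`` are per-base sampling weights for (A, C, G, T) and
    must sum to 1 within 1e-9. ``repeat_fraction`` is the fraction of
    the sequence overwritten by copies of earlier windows (segments of
    200-2000 bases, scaled down for short sequences); copies preserve
    the marginal composition while planting literal repeats.
    """

    probabilities: tuple[float, float, float, float] = SKEWED_COMPOSITION
    length: int = 10_000
    repeat_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.probabilities) != 4 or any(p < 0 for p in self.probabilities):
            raise DnalzError("probabilities must be four non-negative numbers")
        if abs(sum(self.probabilities) - 1.0) > 1e-9:
            raise DnalzError(f"probabilities sum to {sum(self.probabilities)}, not 1")
        if self.length < 0:
            raise DnalzError("length must be non-negative")
        if not 0.0 <= self.repeat_fraction <= 1.0:
            raise DnalzError("repeat_fraction must be in [0, 1]")


def generate_sequence(spec: CompositionSpec) -> DnaSequence:
    """Draw a sequence from ``spec``; deterministic for a fixed seed."""
    rng = np.random.default_rng(spec.seed)
    if spec.length == 0:
        return DnaSequence(residues="")
    codes = rng.choice(4, size=spec.length, p=np.asarray(spec.probabilities))
    target = int(round(spec.repeat_fraction * spec.length))
    if target > 0 and spec.length >= 4:
        lo = max(1, min(200, spec.length // 4))
        hi = max(lo, min(2000, spec.length // 2))
        copied = 0
        while copied < target:
            seg = int(rng.integers(lo, hi + 1))
            seg = min(seg, spec.length - 1)
            src = int(rng.integers(0, spec.length - seg))
            dst = int(rng.integers(src + 1, spec.length - seg + 1))
            codes[dst : dst + seg] = codes[src : src + seg]
            copied += seg
    lut = np.frombuffer(BASES.encode(), dtype=np.uint8)
    residues = lut[codes].tobytes().decode()
    return DnaSequence(residues=residues)


@dataclass(frozen=True)
class GoldenValue:
    """One pinned intermediate of the worked example.

    ``value`` is what the codec's rules produce; ``published`` is the
    printed string, which differs from ``value`` only where
    ``consistent`` is False.
    """

    name: str
    value: str
    published: str = ""
    consistent: bool = True

    def __post_init__(self) -> None:
        if self.consistent and not self.published:
            object.__setattr__(self, "published", self.value)


def golden_examples() -> dict[str, GoldenValue]:
    """All printed intermediates of the 30-base worked example, rank TCAG.

    fr2b (and the fourth f0 token) as printed contradict both the
    stated pair-orientation rule and the example's own fr3; those two
    entries carry the rule-derived value with ``consistent=False``.
    """
    values = {
        "sequence": WORKED_SEQUENCE,
        "rank": WORKED_RANK,
        "fr1": "100000011001001111110000000011",
        "fr1a": "100011010111111000011",
        "fr1b": "0000",
        "f1": "GGACCGAACCGAAGGACC",
        "f2": "GGAACCCCC",
        "fr2a": "011001110",
        "fr3": "1111101000000",
        "f1aa": "_St",
        "f1bb": "",
        "f2aa": "U",
        "f2bb": "",
        "f3": "z\\",
    }
    out = {name: GoldenValue(name=name, value=v) for name, v in values.items()}
    out["fr2b"] = GoldenValue(
        name="fr2b", value="10101", published="01101", consistent=False
    )
    out["f0"] = GoldenValue(
        name="f0",
        value="011#0000#110#10101#0#TCAG#",
        published="011#0000#110#01101#0#TCAG#",
        consistent=False,
    )
    return out
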