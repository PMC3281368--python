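"""Sequence records and interval types shared across the pipeline.

All coordinates are 0-based, half-open.  Sequences are uppercase strings over
the IUPAC nucleotide alphabet; only A/C/G/T positions participate in distance
computation (ambiguity codes are treated like gaps downstream).
"""
from __future__ import annotations

from dataclasses import dataclass, field

GAP = "-"
ACGT = "ACGT"

#: IUPAC nucleotide one-letter codes and the concrete bases they stand for.
IUPAC_EXPANSIONS: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

IUPAC_LETTERS = frozenset(IUPAC_EXPANSIONS)

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)


def reverse_complement(seq: str) -> str:
    return complement(seq)[::-1]


def iupac_match(pattern: str, text: str) -> bool:
    """True if ``text`` (concrete bases) fits the IUPAC ``pattern``."""
    if len(pattern) != len(text):
        return False
    for p, t in zip(pattern, text):
        if t not in IUPAC_EXPANSIONS.get(p, ""):
            return False
    return True


def find_iupac(sequence: str, pattern: str, start: int = 0, end: int | None = None) -> list[int]:
    """All start positions in [start, end) where ``pattern`` matches."""
    if end is None:
        end = len(sequence)
    m = len(pattern)
    lo = max(0, start)
    hi = min(end, len(sequence) - m + 1)
    return [i for i in range(lo, hi) if iupac_match(pattern, sequence[i : i + m])]


def validate_nucleotides(seq: str, context: str = "sequence") -> None:
    """Raise ValueError naming the first offending position, if any."""
    for i, ch in enumerate(seq):
        if ch not in IUPAC_LETTERS:
            raise ValueError(
                f"{context}: non-IUPAC character {ch!r} at position {i}"
            )


@dataclass
class SpacerRecord:
    """One named spacer sequence (an ITS2 with optional rRNA-gene stubs)."""

    id: str
    sequence: str
    species_code: str = ""
    flank5: tuple[int, int] | None = None
    flank3: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        self.sequence = self.sequence.upper()
        validate_nucleotides(self.sequence, f"record {self.id!r}")
        if not self.species_code:
            self.species_code = self.id.split("_")[0]

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class RepeatUnit:
    """A delimited repeat copy inside a spacer.

    ``boundary`` records how the 5' cut was placed: ``"motif"`` when anchored on
    a terminal-motif occurrence, ``"periodic"`` when it fell back to the grid.
    """

    parent_id: str
    index: int  # 1-based ordinal, 5.8S -> 28S order
    start: int
    end: int
    name: str
    sequence: str
    boundary: str = "motif"

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.sequence):
            raise ValueError(
                f"unit {self.name}: span {self.start}-{self.end} does not "
                f"match sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class RepeatArray:
    """An ordered tandem array of repeat units within one record."""

    parent_id: str
    start: int
    end: int
    period: float
    units: list[RepeatUnit] = field(default_factory=list)

    def __post_init__(self) -> None:
        prev_end = self.start
        for u in self.units:
            if u.start < prev_end:
                raise ValueError(f"unit {u.name} overlaps the previous unit")
            prev_end = u.end
        if self.units and (self.units[0].start < self.start or prev_end > self.end):
            raise ValueError("units fall outside the array span")

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    def __len__(self) -> int:
        return len(self.units)


@dataclass
class MaskedSpacer:
    """A spacer with its repeat array excised (flanking segments joined)."""

    id: str
    sequence: str
    source_id: str
    excised: tuple[int, int]

    def __len__(self) -> int:
        return len(self.sequence)
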