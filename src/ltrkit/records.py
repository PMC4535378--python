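"""Core domain records shared across the pipeline.

Coordinates are 0-based, half-open throughout the in-memory API; file
output (GFF3) is converted to 1-based inclusive at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

VALID_BASES = set("ACGTN")


@dataclass(frozen=True, order=True)
class Interval:
    """Half-open genomic interval [start, end)."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, other: "Interval") -> bool:
        return self.start <= other.start and other.end <= self.end

    def overlap(self, other: "Interval") -> int:
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def shift(self, offset: int) -> "Interval":
        return Interval(self.start + offset, self.end + offset)


@dataclass
class GenomeSequence:
    """A named DNA sequence over the {A,C,G,T,N} alphabet."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty genome sequence")
        bad = set(self.sequence.upper()) - VALID_BASES
        if bad:
            raise ValueError(f"invalid bases in {self.id}: {sorted(bad)}")
        self.sequence = self.sequence.upper()

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ReferenceElement:
    """A reference full-length LTR retrotransposon.

    The element starts at the first base of its 5' LTR and ends at the
    last base of its 3' LTR; LTR intervals are relative to ``sequence``.
    """

    family_name: str
    superfamily: str  # "Copia" or "Gypsy"
    lineage: str
    sequence: str
    ltr5_interval: Interval
    ltr3_interval: Interval

    def __post_init__(self) -> None:
        if self.superfamily not in ("Copia", "Gypsy"):
            raise ValueError(f"unknown superfamily {self.superfamily!r}")
        n = len(self.sequence)
        if self.ltr5_interval.start != 0 or self.ltr3_interval.end != n:
            raise ValueError("element must start at 5' LTR and end at 3' LTR")
        if self.ltr5_interval.end > self.ltr3_interval.start:
            raise ValueError("LTR intervals overlap")
        self.sequence = self.sequence.upper()

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def ltr5(self) -> str:
        return self.sequence[self.ltr5_interval.start : self.ltr5_interval.end]

    @property
    def ltr3(self) -> str:
        return self.sequence[self.ltr3_interval.start : self.ltr3_interval.end]

    @property
    def internal(self) -> str:
        return self.sequence[self.ltr5_interval.end : self.ltr3_interval.start]


# Status labels for mined copies.
FULL_LENGTH = "full_length"
REJECTED_IDENTITY = "rejected_identity"
REJECTED_COVERAGE = "rejected_coverage"
REJECTED_TERMINI = "rejected_termini"


@dataclass
class ElementCopy:
    """A located genomic copy of a reference element.

    ``identity`` is matches over alignment columns (internal gaps count,
    terminal gaps do not); ``coverage`` is aligned reference positions
    over reference length. A copy is ``full_length`` only when it passes
    the identity and coverage thresholds and carries canonical TG..CA
    termini after boundary refinement.
    """

    copy_id: str
    genome_id: str
    family_name: str
    interval: Interval
    strand: str
    identity: float
    coverage: float
    ltr5_interval: Optional[Interval] = None
    ltr3_interval: Optional[Interval] = None
    termini_ok: bool = False
    tsd: Optional[str] = None
    status: str = REJECTED_IDENTITY

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        if not (0.0 <= self.identity <= 1.0 and 0.0 <= self.coverage <= 1.0):
            raise ValueError("identity/coverage outside [0, 1]")

    @property
    def is_full_length(self) -> bool:
        return self.status == FULL_LENGTH

    @property
    def is_intact(self) -> bool:
        """Intact = full length with both LTRs and a TSD (dating criterion)."""
        return (
            self.is_full_length
            and self.ltr5_interval is not None
            and self.ltr3_interval is not None
            and self.tsd is not None
        )


@dataclass
class TruthRecord:
    """Ground truth for one planted insertion (simulator bookkeeping)."""

    copy_id: str
    family_name: str
    insertion_age: float  # years
    genome_interval: Interval
    tsd_sequence: str
    ltr5_interval: Interval
    ltr3_interval: Interval
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.insertion_age < 0:
            raise ValueError("insertion age must be >= 0")
        if not self.genome_interval.contains(self.ltr5_interval):
            raise ValueError("5' LTR outside element interval")
        if not self.genome_interval.contains(self.ltr3_interval):
            raise ValueError("3' LTR outside element interval")


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]
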