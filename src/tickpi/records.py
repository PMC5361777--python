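"""Domain types: protease-inhibitor sequence records and sequencing libraries.

A :class:`ProteinRecord` is one putative protease inhibitor (PI) sequence from
one tick species, together with the set of transcriptome libraries it was
observed in.  A :class:`Library` describes one transcriptome: which species it
came from, the sex and feeding state of the ticks, and — for dissected
salivary-gland (SG) or midgut (MG) libraries — the feeding time point in hours.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional

#: Canonical amino acids.
CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
#: Full sequence alphabet: canonical residues plus X (unknown) and * (stop).
AA_ALPHABET = frozenset(CANONICAL_AA) | {"X", "*"}

SEXES = ("F", "M", "NA")
FEEDING_STATES = ("fed", "unfed", "NA")
TISSUES = ("SG", "MG", "whole")
TIMEPOINTS = (48, 96, 120)


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (half-up), as used for all reported
    percentages.  Python's built-in ``round`` is banker's rounding, which
    would report 82.5% -> 82 instead of 83."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def validate_sequence(sequence: str, *, where: str = "sequence") -> None:
    """Raise ``ValueError`` (with the offending position) if *sequence* is
    empty or contains a character outside the amino-acid alphabet."""
    if not sequence:
        raise ValueError(f"{where}: empty sequence")
    for pos, ch in enumerate(sequence):
        if ch not in AA_ALPHABET:
            raise ValueError(
                f"{where}: invalid character {ch!r} at position {pos}"
            )


@dataclass
class ProteinRecord:
    """One putative PI sequence and the libraries it was observed in."""

    record_id: str
    species_code: str
    sequence: str
    library_ids: frozenset[str] = field(default_factory=frozenset)
    annotation_hint: Optional[str] = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        validate_sequence(self.sequence, where=f"record {self.record_id}")
        self.library_ids = frozenset(self.library_ids)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Library:
    """One transcriptome library.

    Dissected-tissue libraries (SG/MG) must carry a feeding time point of
    48, 96 or 120 h; whole-body libraries carry none.
    """

    library_id: str
    species_code: str
    sex: str = "NA"
    feeding_state: str = "NA"
    tissue: str = "whole"
    timepoint_h: Optional[int] = None

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"library {self.library_id}: bad sex {self.sex!r}")
        if self.feeding_state not in FEEDING_STATES:
            raise ValueError(
                f"library {self.library_id}: bad feeding_state "
                f"{self.feeding_state!r}"
            )
        if self.tissue not in TISSUES:
            raise ValueError(
                f"library {self.library_id}: bad tissue {self.tissue!r}"
            )
        if self.tissue in ("SG", "MG"):
            if self.timepoint_h not in TIMEPOINTS:
                raise ValueError(
                    f"library {self.library_id}: {self.tissue} library needs a "
                    f"time point in {TIMEPOINTS}, got {self.timepoint_h!r}"
                )
        elif self.timepoint_h is not None:
            raise ValueError(
                f"library {self.library_id}: whole-body library cannot carry "
                f"a time point"
            )


def check_unique_ids(items: Iterable[str], *, what: str) -> None:
    seen: set[str] = set()
    for item in items:
        if item in seen:
            raise ValueError(f"duplicate {what}: {item!r}")
        seen.add(item)
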