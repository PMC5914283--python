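"""Shared sequence record types and validation rules.

Conventions used throughout the package:

* coordinates are 0-based, half-open;
* quality scores are Sanger-scale Phred integers (offset 33 on disk);
* taxonomy lineages are 7-rank Greengenes-style tuples whose labels keep
  their rank prefixes (``k__`` ... ``s__``); a label equal to its bare
  prefix, or the empty string, counts as empty.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

IUPAC_DNA = frozenset("ACGTRYSWKMBDHVN")
READ_ALPHABET = frozenset("ACGTN")

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")

EMPTY_LINEAGE = tuple(RANK_PREFIXES)


class FormatError(ValueError):
    """Raised when an input file or record violates its format contract."""


class Platform(str, enum.Enum):
    FLX = "flx"
    MISEQ = "miseq"
    PACBIO_CCS = "pacbio_ccs"
    SHOTGUN = "shotgun"


def is_empty_label(label: str) -> bool:
    """True for labels that carry no taxon name (e.g. ``""`` or ``"s__"``)."""
    return label == "" or label in RANK_PREFIXES


def validate_lineage(lineage: tuple[str, ...]) -> None:
    if len(lineage) != len(RANKS):
        raise FormatError(
            f"lineage must have exactly {len(RANKS)} ranks, got {len(lineage)}"
        )
    seen_empty = False
    for label in lineage:
        if is_empty_label(label):
            seen_empty = True
        elif seen_empty:
            raise FormatError(
                f"non-empty label {label!r} below an empty rank in {lineage}"
            )


@dataclass(frozen=True)
class ReferenceRecord:
    """One database sequence with its lineage and (optional) truth cluster."""

    id: str
    sequence: str
    lineage: tuple[str, ...] = EMPTY_LINEAGE
    truth_cluster: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("reference record with empty id")
        if not self.sequence:
            raise FormatError(f"record {self.id!r} has an empty sequence")
        bad = set(self.sequence) - IUPAC_DNA
        if bad:
            raise FormatError(
                f"record {self.id!r} contains non-IUPAC characters {sorted(bad)}"
            )
        validate_lineage(tuple(self.lineage))

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Read:
    """A sequencing read: bases, per-base Phred qualities and platform tag."""

    id: str
    bases: str
    quals: tuple[int, ...]
    platform: Platform = Platform.MISEQ

    def __post_init__(self) -> None:
        if len(self.quals) != len(self.bases):
            raise FormatError(
                f"read {self.id!r}: {len(self.bases)} bases but "
                f"{len(self.quals)} quality values"
            )
        bad = set(self.bases) - READ_ALPHABET
        if bad:
            raise FormatError(
                f"read {self.id!r} contains non-ACGTN characters {sorted(bad)}"
            )
        if self.quals and not all(0 <= q <= 93 for q in self.quals):
            raise FormatError(f"read {self.id!r}: Phred values outside [0, 93]")

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def mean_quality(self) -> float:
        return sum(self.quals) / len(self.quals) if self.quals else 0.0


def read_stem(read_id: str) -> str:
    """Strip common mate suffixes (``/1``, ``/2``, ``_R1``, ``_R2``)."""
    for suffix in ("/1", "/2", "_R1", "_R2", ".1", ".2"):
        if read_id.endswith(suffix):
            return read_id[: -len(suffix)]
    return read_id


@dataclass(frozen=True)
class ReadPair:
    """A mate pair; r2 is stored as sequenced, i.e. on the reverse strand.

    ``overlaps`` records whether the simulated fragment was long enough for
    the mates to overlap; it is advisory truth information, not a QC result.
    """

    r1: Read
    r2: Read
    overlaps: bool = True

    def __post_init__(self) -> None:
        if read_stem(self.r1.id) != read_stem(self.r2.id):
            raise FormatError(
                f"mate ids {self.r1.id!r} / {self.r2.id!r} share no common stem"
            )

    @property
    def id(self) -> str:
        return read_stem(self.r1.id)


SOURCE_SEPARATOR = "|"


def source_of(read_id: str) -> str | None:
    """Source record id encoded in a simulated read id, if present."""
    if SOURCE_SEPARATOR in read_id:
        return read_stem(read_id.rsplit(SOURCE_SEPARATOR, 1)[1])
    return None
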