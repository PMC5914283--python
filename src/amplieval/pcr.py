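"""In-silico PCR: degenerate primer matching and hypervariable-region extraction.

The five shipped primer pairs are the ones commonly used to target the
V1-3, V3-4, V4, V1-4 and V1-9 regions of the bacterial 16S rRNA gene
(27F/519R, 341F/805R, 515F/806R, 27F/800R and 27F/1492R families, written
5'->3' as synthesized; reverse primers are reverse-strand oligos).

Extracted amplicons are primer-INCLUSIVE: the amplicon runs from the first
base of the forward-primer site through the last base of the
reverse-primer site, which is what a sequenced amplicon physically
contains and what makes the V4 amplicon length fall in the 286-298 bp
window used for merged-read size filtering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .records import IUPAC_DNA, ReferenceRecord

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(sequence: str) -> str:
    """Reverse complement extended to IUPAC ambiguity codes."""
    bad = set(sequence) - IUPAC_DNA
    if bad:
        raise ValueError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PrimerPair:
    """A named region's forward/reverse primers, both written 5'->3'."""

    region: str
    forward: str
    reverse: str

    def __post_init__(self) -> None:
        for name, primer in (("forward", self.forward), ("reverse", self.reverse)):
            if not primer:
                raise ValueError(f"{self.region}: empty {name} primer")
            bad = set(primer) - IUPAC_DNA
            if bad:
                raise ValueError(f"{self.region} {name} primer: non-IUPAC {sorted(bad)}")

    @property
    def reverse_site(self) -> str:
        """The reverse primer's binding site on the forward strand."""
        return reverse_complement(self.reverse)


#: The five region-defining primer pairs shipped by default.
DEFAULT_PRIMER_PAIRS: dict[str, PrimerPair] = {
    "V1-3": PrimerPair("V1-3", "AGAGTTTGATCCTGGCTCAG", "GTATTACCGCGGCTGCTGG"),
    "V3-4": PrimerPair("V3-4", "CCTACGGGNGGCWGCAG", "GACTACHVGGGTATCTAATCC"),
    "V4": PrimerPair("V4", "GTGCCAGCMGCCGCGGTAA", "GGACTACHVGGGTWTCTAAT"),
    "V1-4": PrimerPair("V1-4", "GAGTTTGATCMTGGCTCAG", "TACCAGGGTATCTAATCC"),
    "V1-9": PrimerPair("V1-9", "AGRGTTYGATYMTGGCTCAG", "RGYTACCTTGTTACGACTT"),
}

REGIONS = tuple(DEFAULT_PRIMER_PAIRS)

#: Merged-read expected-size windows (bp, inclusive) for the MiSeq regions,
#: as derived from full-length reference databases.
REFERENCE_SIZE_RANGES: dict[str, tuple[int, int]] = {
    "V1-3": (463, 553),
    "V3-4": (438, 469),
    "V4": (286, 298),
}


@dataclass(frozen=True)
class Amplicon:
    """A primer-inclusive extracted region on the source's forward strand."""

    source_id: str
    start: int
    end: int
    sequence: str

    def __post_init__(self) -> None:
        if self.start < 0 or self.end - self.start != len(self.sequence):
            raise ValueError(
                f"amplicon {self.source_id}: coordinates [{self.start}, {self.end}) "
                f"inconsistent with sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def _iupac_match_matrix(sequence: str, primer: str) -> np.ndarray:
    """Boolean [position, primer_index] array: does base match primer code?"""
    seq = np.frombuffer(sequence.encode(), dtype=np.uint8)
    cols = []
    for code in primer:
        allowed = np.frombuffer("".join(sorted(IUPAC_SETS[code])).encode(), dtype=np.uint8)
        cols.append(np.isin(seq, allowed))
    return np.column_stack(cols)


def match_primer(sequence: str, primer: str, max_mismatch: int = 0) -> list[tuple[int, int]]:
    """All ungapped placements of a degenerate primer with <= max_mismatch.

    Returns (position, mismatches) pairs sorted by position. An IUPAC code
    in the primer matches any base in its set; ambiguity codes in the
    subject sequence match only if the subject base is a concrete base in
    the primer code's set (subject N never matches, conservatively).
    """
    n, m = len(sequence), len(primer)
    if m > n:
        return []
    matches = _iupac_match_matrix(sequence, primer)
    n_windows = n - m + 1
    mismatches = np.zeros(n_windows, dtype=np.int32)
    for j in range(m):
        mismatches += ~matches[j : n_windows + j, j]
    hits = np.nonzero(mismatches <= max_mismatch)[0]
    return [(int(pos), int(mismatches[pos])) for pos in hits]


def extract_region(
    record: ReferenceRecord | str,
    pair: PrimerPair,
    max_mismatch: int = 0,
) -> Amplicon | None:
    """Extract the primer-inclusive amplicon defined by ``pair``, or None.

    The leftmost forward-primer match is used; the reverse site is the
    nearest match downstream of the forward primer's 3' end. This yields
    the shortest plausible amplicon and is deterministic.
    """
    if isinstance(record, ReferenceRecord):
        seq_id, sequence = record.id, record.sequence
    else:
        seq_id, sequence = "<anonymous>", record
    fwd_hits = match_primer(sequence, pair.forward, max_mismatch)
    if not fwd_hits:
        return None
    fwd_start = fwd_hits[0][0]
    fwd_end = fwd_start + len(pair.forward)
    rev_site = pair.reverse_site
    rev_hits = match_primer(sequence, rev_site, max_mismatch)
    rev_hits = [h for h in rev_hits if h[0] >= fwd_end]
    if not rev_hits:
        return None
    rev_start = rev_hits[0][0]
    end = rev_start + len(rev_site)
    return Amplicon(
        source_id=seq_id,
        start=fwd_start,
        end=end,
        sequence=sequence[fwd_start:end],
    )


def select_full_primer_set(
    db: Sequence[ReferenceRecord],
    region_pairs: Iterable[PrimerPair] | None = None,
    max_mismatch: int = 0,
) -> list[ReferenceRecord]:
    """Records on which every listed primer pair yields an amplicon.

    This is the mock-database selection step: keep only sequences that
    carry binding sites for all primers of all targeted regions, so every
    region can be extracted from every retained record. Order is preserved.
    """
    pairs = list(region_pairs) if region_pairs is not None else list(DEFAULT_PRIMER_PAIRS.values())
    if not pairs:
        raise ValueError("at least one primer pair is required")
    selected = []
    for record in db:
        if all(extract_region(record, pair, max_mismatch) is not None for pair in pairs):
            selected.append(record)
    return selected


def expected_size_range(
    lengths: Sequence[int],
    outlier_frac: float = 0.01,
    per_tail: bool = False,
) -> tuple[int, int]:
    """Min/max amplicon length after trimming a fraction of outliers.

    ``outlier_frac`` is the total fraction removed, split evenly over the
    two tails (floor(outlier_frac/2 * n) values dropped from each end).
    With ``per_tail=True`` the full fraction is dropped from each tail
    instead.
    """
    if len(lengths) == 0:
        raise ValueError("expected_size_range needs at least one length")
    if not 0 <= outlier_frac < 1:
        raise ValueError("outlier_frac must be in [0, 1)")
    ordered = sorted(lengths)
    n = len(ordered)
    drop = int((outlier_frac if per_tail else outlier_frac / 2) * n)
    drop = min(drop, (n - 1) // 2)
    kept = ordered[drop : n - drop]
    return kept[0], kept[-1]
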