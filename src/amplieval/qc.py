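"""Platform-specific read quality control and paired-end merging.

Implements the filtering rules each platform's data receive before
clustering: ambiguity/quality/length filters for GS FLX+ reads, a paired
minimum-length filter plus overlap merging and expected-size filtering for
MiSeq pairs, and forward-primer/minimum-length selection with internal
reverse-primer trimming for PacBio CCS reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .pcr import match_primer, reverse_complement
from .records import Read, ReadPair

FAIL_REASONS = (
    "ambiguous",
    "low_quality",
    "too_short",
    "too_long",
    "primer_missing",
    "no_overlap",
)


@dataclass
class QCResult:
    passed: bool
    reason: str | None = None

    def __bool__(self) -> bool:
        return self.passed


PASS = QCResult(True)


def fail(reason: str) -> QCResult:
    if reason not in FAIL_REASONS:
        raise ValueError(f"unknown fail reason {reason!r}")
    return QCResult(False, reason)


@dataclass
class QCReport:
    """Per-reason accounting; input = pass + sum(fail counts) always."""

    input_count: int = 0
    pass_count: int = 0
    fail_counts: dict[str, int] = field(default_factory=dict)

    def record(self, result: QCResult) -> None:
        self.input_count += 1
        if result.passed:
            self.pass_count += 1
        else:
            assert result.reason is not None
            self.fail_counts[result.reason] = self.fail_counts.get(result.reason, 0) + 1

    @property
    def total_failed(self) -> int:
        return sum(self.fail_counts.values())

    def check_conservation(self) -> bool:
        return self.input_count == self.pass_count + self.total_failed

    def as_dict(self) -> dict[str, int]:
        out = {"input": self.input_count, "pass": self.pass_count}
        for reason in FAIL_REASONS:
            out[reason] = self.fail_counts.get(reason, 0)
        return out


def filter_flx(
    read: Read,
    min_len: int = 200,
    min_mean_q: float = 25.0,
    max_ambiguous: int = 1,
) -> QCResult:
    """Pyrosequencing QC: ambiguity, then mean quality, then length.

    A read fails on more than ``max_ambiguous`` N calls, a mean Phred
    strictly below ``min_mean_q`` (exactly 25.0 passes), or fewer than
    ``min_len`` bases; the first failing rule in that order is reported.
    """
    if read.bases.count("N") > max_ambiguous:
        return fail("ambiguous")
    if read.mean_quality < min_mean_q:
        return fail("low_quality")
    if len(read) < min_len:
        return fail("too_short")
    return PASS


def _encode(s: str) -> np.ndarray:
    return np.frombuffer(s.encode(), dtype=np.uint8)


def merge_pairs(
    pair: ReadPair,
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.25,
) -> Read | None:
    """Merge a mate pair by its best ungapped overlap, or None.

    r2 is reverse-complemented; among overlap lengths ``o`` from
    ``min_overlap`` to ``min(len(r1), len(r2))`` the one maximizing
    (matches - mismatches) wins, ties going to the longer overlap. None is
    returned when the best overlap's mismatch fraction exceeds
    ``max_mismatch_frac``. Disagreeing positions take the higher-quality
    base; merged qualities are the max of the two mates' qualities.
    """
    r1, r2 = pair.r1, pair.r2
    if not r1.bases or not r2.bases:
        return None
    b2 = reverse_complement(r2.bases)
    q2 = tuple(reversed(r2.quals))
    a1, a2 = _encode(r1.bases), _encode(b2)
    l1, l2 = len(a1), len(a2)
    best: tuple[float, int] | None = None  # (score, overlap)
    max_o = min(l1, l2)
    for o in range(min_overlap, max_o + 1):
        matches = int(np.count_nonzero(a1[l1 - o :] == a2[:o]))
        score = 2 * matches - o  # matches - mismatches
        if best is None or score > best[0] or (score == best[0] and o > best[1]):
            best = (score, o)
    if best is None:
        return None
    score, o = best
    matches = (score + o) // 2
    mismatches = o - matches
    if mismatches / o > max_mismatch_frac:
        return None
    head = r1.bases[: l1 - o]
    head_q = r1.quals[: l1 - o]
    tail = b2[o:]
    tail_q = q2[o:]
    mid_bases = []
    mid_quals = []
    for i in range(o):
        c1, c2 = r1.bases[l1 - o + i], b2[i]
        qa, qb = r1.quals[l1 - o + i], q2[i]
        mid_bases.append(c1 if (c1 == c2 or qa >= qb) else c2)
        mid_quals.append(max(qa, qb))
    return Read(
        id=pair.id,
        bases=head + "".join(mid_bases) + tail,
        quals=tuple(head_q) + tuple(mid_quals) + tuple(tail_q),
        platform=r1.platform,
    )


def filter_merged_size(
    read: Read, region: str, ranges: dict[str, tuple[int, int]]
) -> QCResult:
    """Keep merged reads inside the region's expected size window (inclusive)."""
    if region not in ranges:
        raise KeyError(f"no size range for region {region!r}")
    lo, hi = ranges[region]
    if len(read) < lo:
        return fail("too_short")
    if len(read) > hi:
        return fail("too_long")
    return PASS


def filter_pacbio_ccs(
    read: Read,
    fwd_primer: str,
    rev_primer: str,
    min_len: int = 1300,
    max_mismatch: int = 2,
    search_window: int = 100,
) -> Read | None:
    """CCS selection: forward primer near the 5' end, 1,300 bp minimum.

    The forward primer must match (<= ``max_mismatch``) starting within the
    first ``search_window`` bases. If the reverse primer's complement is
    found internally the read is truncated at the end of that (leftmost)
    match. None is returned when either the forward primer is absent or
    the post-trim read is shorter than ``min_len``.
    """
    window = read.bases[: search_window + len(fwd_primer)]
    fwd_hits = [h for h in match_primer(window, fwd_primer, max_mismatch) if h[0] < search_window]
    if not fwd_hits:
        return None
    rev_site = reverse_complement(rev_primer)
    fwd_end = fwd_hits[0][0] + len(fwd_primer)
    rev_hits = [h for h in match_primer(read.bases, rev_site, max_mismatch) if h[0] >= fwd_end]
    if rev_hits:
        cut = rev_hits[0][0] + len(rev_site)
        read = Read(read.id, read.bases[:cut], read.quals[:cut], read.platform)
    if len(read) < min_len:
        return None
    return read


def _trim_trailing_n(read: Read) -> Read:
    bases = read.bases.rstrip("N")
    return Read(read.id, bases, read.quals[: len(bases)], read.platform)


def filter_miseq(pair: ReadPair, min_len: int = 150) -> QCResult:
    """Paired filter: both mates >= ``min_len`` bp after trailing-N trimming."""
    for mate in (pair.r1, pair.r2):
        if len(_trim_trailing_n(mate)) < min_len:
            return fail("too_short")
    return PASS


def run_flx_qc(reads: Iterable[Read], **kwargs) -> tuple[list[Read], QCReport]:
    report = QCReport()
    passed = []
    for read in reads:
        result = filter_flx(read, **kwargs)
        report.record(result)
        if result:
            passed.append(read)
    return passed, report


def run_miseq_qc(
    pairs: Iterable[ReadPair],
    region: str,
    ranges: dict[str, tuple[int, int]],
    min_len: int = 150,
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.25,
) -> tuple[list[Read], QCReport]:
    """Full MiSeq path: pair length filter -> merge -> expected-size filter."""
    report = QCReport()
    merged_reads = []
    for pair in pairs:
        result = filter_miseq(pair, min_len=min_len)
        if not result:
            report.record(result)
            continue
        merged = merge_pairs(pair, min_overlap=min_overlap, max_mismatch_frac=max_mismatch_frac)
        if merged is None:
            report.record(fail("no_overlap"))
            continue
        size_result = filter_merged_size(merged, region, ranges)
        report.record(size_result)
        if size_result:
            merged_reads.append(merged)
    return merged_reads, report


def run_pacbio_qc(
    reads: Iterable[Read],
    fwd_primer: str,
    rev_primer: str,
    min_len: int = 1300,
    max_mismatch: int = 2,
) -> tuple[list[Read], QCReport]:
    report = QCReport()
    passed = []
    for read in reads:
        out = filter_pacbio_ccs(
            read, fwd_primer, rev_primer, min_len=min_len, max_mismatch=max_mismatch
        )
        if out is None:
            # distinguish the two failure modes for the report
            window = read.bases[: 100 + len(fwd_primer)]
            if not match_primer(window, fwd_primer, max_mismatch):
                report.record(fail("primer_missing"))
            else:
                report.record(fail("too_short"))
        else:
            report.record(PASS)
            passed.append(out)
    return passed, report
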