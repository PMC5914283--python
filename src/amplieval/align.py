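"""Pairwise alignment, best-hit search and indel/substitution error profiling.

Alignment is global over the query with free end gaps on the subject
(linear gap penalty), so a partial-region read aligned against a
full-length reference is not charged for the reference's flanks. From one
alignment three summary metrics are derived:

* ``identity_all``            - matches / (matches + mismatches + ins + del);
* ``identity_mismatch_only``  - matches / (matches + mismatches), i.e. the
  identity after ignoring indel columns;
* per-read insertion/deletion/mismatch ratios, normalized by read length.

Insertions are query-relative: an inserted base is present in the read and
absent from the reference.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .records import Read, ReferenceRecord


@dataclass(frozen=True)
class PairwiseAlignment:
    query_id: str
    subject_id: str
    n_match: int
    n_mismatch: int
    n_ins: int
    n_del: int
    score: float = 0.0

    def __post_init__(self) -> None:
        if min(self.n_match, self.n_mismatch, self.n_ins, self.n_del) < 0:
            raise ValueError("alignment counts must be non-negative")

    @property
    def columns(self) -> int:
        return self.n_match + self.n_mismatch + self.n_ins + self.n_del

    @property
    def identity_all(self) -> float:
        return self.n_match / self.columns if self.columns else 0.0

    @property
    def identity_mismatch_only(self) -> float:
        denom = self.n_match + self.n_mismatch
        return self.n_match / denom if denom else 0.0


def align_global(
    query: str,
    subject: str,
    match: float = 2.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
    query_id: str = "query",
    subject_id: str = "subject",
) -> PairwiseAlignment:
    """Optimal global alignment of ``query`` against ``subject``.

    The query aligns end-to-end; subject end gaps are unpenalized and
    excluded from the counts, so ``identity_all`` of a perfect partial
    read against a full-length reference is 1.0. Traceback ties are
    broken diagonal > up > left, i.e. a co-optimal mismatch
    representation is always preferred over an insertion+deletion pair
    (substitution-only differences never report spurious indels).
    """
    if not query or not subject:
        raise ValueError("align_global requires non-empty sequences")
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    s = np.frombuffer(subject.encode(), dtype=np.uint8)
    n, m = len(q), len(s)
    js = np.arange(m + 1, dtype=np.float64)
    gap_ramp = gap * js
    H = np.empty((n + 1, m + 1), dtype=np.float64)
    H[0, :] = 0.0  # leading subject overhang is free
    for i in range(1, n + 1):
        sub = np.where(s == q[i - 1], match, mismatch)
        best = np.empty(m + 1, dtype=np.float64)
        best[0] = gap * i
        np.maximum(H[i - 1, :-1] + sub, H[i - 1, 1:] + gap, out=best[1:])
        # fold in the left (gap-in-query) chain with a running max
        t = best - gap_ramp
        np.maximum.accumulate(t, out=t)
        H[i] = t + gap_ramp
    j = int(np.argmax(H[n]))  # trailing subject overhang is free
    score = float(H[n, j])
    i = n
    n_match = n_mismatch = n_ins = n_del = 0
    while i > 0:
        if j > 0 and H[i, j] == H[i - 1, j - 1] + (match if q[i - 1] == s[j - 1] else mismatch):
            if q[i - 1] == s[j - 1]:
                n_match += 1
            else:
                n_mismatch += 1
            i -= 1
            j -= 1
        elif H[i, j] == H[i - 1, j] + gap:
            n_ins += 1  # base present in the query only
            i -= 1
        else:
            n_del += 1  # base present in the subject only
            j -= 1
    return PairwiseAlignment(
        query_id=query_id,
        subject_id=subject_id,
        n_match=n_match,
        n_mismatch=n_mismatch,
        n_ins=n_ins,
        n_del=n_del,
        score=score,
    )


class ReferenceIndex:
    """A k-mer prescreen over a reference set for best-hit search."""

    def __init__(self, db: Sequence[ReferenceRecord], k: int = 8):
        self.k = k
        self.records = list(db)
        self._kmer_sets = [self._kmers(rec.sequence) for rec in self.records]

    def _kmers(self, sequence: str) -> set[str]:
        k = self.k
        return {sequence[i : i + k] for i in range(len(sequence) - k + 1)}

    def candidates(self, sequence: str, n_candidates: int) -> list[ReferenceRecord]:
        """Top records by shared k-mer count; ties broken by record id."""
        query_kmers = self._kmers(sequence)
        scored = [
            (len(query_kmers & kmers), rec.id, i)
            for i, (rec, kmers) in enumerate(zip(self.records, self._kmer_sets))
        ]
        scored.sort(key=lambda t: (-t[0], t[1]))
        return [self.records[i] for _, _, i in scored[:n_candidates]]

    def top_hits(
        self,
        query: str,
        query_id: str = "query",
        min_identity: float = 0.0,
        n_candidates: int = 20,
    ) -> list[PairwiseAlignment]:
        """Alignments to the prescreened candidates, best identity first."""
        hits = [
            align_global(query, rec.sequence, query_id=query_id, subject_id=rec.id)
            for rec in self.candidates(query, n_candidates)
        ]
        hits = [h for h in hits if h.identity_all >= min_identity]
        hits.sort(key=lambda h: (-h.identity_all, h.subject_id))
        return hits


def best_hit(
    read: Read | str,
    db: Sequence[ReferenceRecord],
    min_identity: float = 0.80,
    k: int = 8,
    n_candidates: int = 20,
    index: ReferenceIndex | None = None,
) -> tuple[str, PairwiseAlignment] | None:
    """Highest-identity reference for a read, or None below ``min_identity``.

    Candidates are prescreened by shared k-mer count (ties by id); the full
    alignment with the highest ``identity_all`` wins, ties again by id.
    Pass a prebuilt :class:`ReferenceIndex` to amortize indexing in loops.
    """
    if index is None:
        index = ReferenceIndex(db, k=k)
    sequence = read.bases if isinstance(read, Read) else read
    query_id = read.id if isinstance(read, Read) else "query"
    hits = index.top_hits(
        sequence, query_id=query_id, min_identity=min_identity, n_candidates=n_candidates
    )
    if not hits:
        return None
    return hits[0].subject_id, hits[0]


def _per_read_alignments(
    reads: Iterable[Read],
    db: Sequence[ReferenceRecord],
    min_identity: float,
    n_candidates: int,
) -> tuple[list[tuple[Read, PairwiseAlignment]], list[str]]:
    idx = ReferenceIndex(db)
    aligned, unaligned = [], []
    for read in reads:
        hit = best_hit(read, db, min_identity=min_identity, n_candidates=n_candidates, index=idx)
        if hit is None:
            unaligned.append(read.id)
        else:
            aligned.append((read, hit[1]))
    return aligned, unaligned


def error_profile(
    reads: Iterable[Read],
    db: Sequence[ReferenceRecord],
    min_identity: float = 0.80,
    n_candidates: int = 20,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-read insertion/deletion/mismatch ratios against best-hit references.

    Ratios are normalized by read length. The summary reports the mean
    insertion and deletion ratios and their quotient (deletion weighting);
    reads with no hit are counted in ``n_unaligned`` and excluded from the
    means.
    """
    aligned, unaligned = _per_read_alignments(reads, db, min_identity, n_candidates)
    rows = []
    for read, aln in aligned:
        length = len(read.bases)
        rows.append(
            {
                "read_id": read.id,
                "subject_id": aln.subject_id,
                "read_length": length,
                "n_match": aln.n_match,
                "n_mismatch": aln.n_mismatch,
                "n_ins": aln.n_ins,
                "n_del": aln.n_del,
                "mismatch_ratio": aln.n_mismatch / length,
                "ins_ratio": aln.n_ins / length,
                "del_ratio": aln.n_del / length,
                "identity_all": aln.identity_all,
                "identity_mismatch_only": aln.identity_mismatch_only,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "read_id",
            "subject_id",
            "read_length",
            "n_match",
            "n_mismatch",
            "n_ins",
            "n_del",
            "mismatch_ratio",
            "ins_ratio",
            "del_ratio",
            "identity_all",
            "identity_mismatch_only",
        ],
    )
    mean_ins = float(table["ins_ratio"].mean()) if len(table) else float("nan")
    mean_del = float(table["del_ratio"].mean()) if len(table) else float("nan")
    summary = {
        "n_reads": float(len(table)),
        "n_unaligned": float(len(unaligned)),
        "mean_mismatch_ratio": float(table["mismatch_ratio"].mean()) if len(table) else float("nan"),
        "mean_ins_ratio": mean_ins,
        "mean_del_ratio": mean_del,
        "del_ins_ratio": mean_del / mean_ins if mean_ins > 0 else float("nan"),
    }
    return table, summary


def similarity_distributions(
    reads: Iterable[Read],
    db: Sequence[ReferenceRecord],
    min_identity: float = 0.80,
    n_candidates: int = 20,
) -> tuple[dict[str, float], pd.DataFrame]:
    """Mean identity with and without indel columns, plus the per-read table.

    ``identity_mismatch_only`` is the similarity the reads would show if
    indel errors were removed, so the gap between the two means measures
    how much indels depress apparent similarity.
    """
    table, _ = error_profile(reads, db, min_identity=min_identity, n_candidates=n_candidates)
    summary = {
        "mean_identity_all": float(table["identity_all"].mean()) if len(table) else float("nan"),
        "mean_identity_mismatch_only": (
            float(table["identity_mismatch_only"].mean()) if len(table) else float("nan")
        ),
        "n_reads": float(len(table)),
    }
    return summary, table
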