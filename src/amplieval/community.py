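"""Taxonomy assignment and community-level summary statistics.

Covers the downstream comparisons made between platform datasets:
best-hit consensus taxonomy assignment, the fraction of reads resolved at
a given rank, relative-abundance profiles, Bray-Curtis dissimilarity with
UPGMA dendrograms, Spearman rank correlation, and alpha-diversity /
rarefaction utilities (observed OTUs, bias-corrected Chao1, Shannon
entropy, Pielou evenness).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy
import scipy.spatial.distance
import scipy.stats
from skbio.diversity import alpha as skbio_alpha

from .align import ReferenceIndex
from .records import RANKS, RANK_PREFIXES, Read, ReferenceRecord, is_empty_label

Lineage = tuple[str, ...]

_RANK_INDEX = {rank: i for i, rank in enumerate(RANKS)}


@dataclass
class CommunityProfile:
    """Taxon counts and relative abundances for one sample."""

    sample_id: str
    counts: dict[str, int]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("negative taxon counts")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def relative(self) -> dict[str, float]:
        total = self.total
        if total == 0:
            return {taxon: 0.0 for taxon in self.counts}
        return {taxon: count / total for taxon, count in self.counts.items()}


def assign_taxonomy(
    read: Read | str,
    db: Sequence[ReferenceRecord],
    min_identity: float = 0.90,
    top_n: int = 3,
    consensus_frac: float = 2 / 3,
    index: ReferenceIndex | None = None,
    n_candidates: int = 20,
) -> Lineage | None:
    """Best-hit consensus lineage for a read, or None when unassigned.

    The ``top_n`` hits at or above ``min_identity`` vote rank by rank from
    kingdom downward; a label is kept iff it is non-empty and at least
    ``consensus_frac`` of the hits carry it, and the lineage is truncated
    at the first failing rank.
    """
    if index is None:
        index = ReferenceIndex(db)
    sequence = read.bases if isinstance(read, Read) else read
    hits = index.top_hits(sequence, min_identity=min_identity, n_candidates=n_candidates)
    if not hits:
        return None
    hits = hits[:top_n]
    lineage_by_id = {rec.id: rec.lineage for rec in db}
    hit_lineages = [lineage_by_id[h.subject_id] for h in hits]
    out: list[str] = []
    for rank_idx, prefix in enumerate(RANK_PREFIXES):
        labels = [lin[rank_idx] for lin in hit_lineages]
        votes: dict[str, int] = {}
        for label in labels:
            if not is_empty_label(label):
                votes[label] = votes.get(label, 0) + 1
        winner = max(votes.items(), key=lambda kv: (kv[1], kv[0]), default=None)
        if winner is None or winner[1] < consensus_frac * len(labels):
            break
        out.append(winner[0])
    return tuple(out) + tuple(RANK_PREFIXES[len(out) :])


def assigned_fraction(assignments: Sequence[Lineage | None], rank: str) -> float:
    """Fraction of reads with a non-empty label at ``rank``.

    Unassigned reads count in the denominator.
    """
    if rank not in _RANK_INDEX:
        raise KeyError(f"unknown rank {rank!r}; expected one of {RANKS}")
    if not assignments:
        raise ValueError("no assignments given")
    idx = _RANK_INDEX[rank]
    hit = sum(
        1
        for lineage in assignments
        if lineage is not None and not is_empty_label(lineage[idx])
    )
    return hit / len(assignments)


def profile_from_assignments(
    sample_id: str, assignments: Sequence[Lineage | None], rank: str = "family"
) -> CommunityProfile:
    """Aggregate read-level lineages into taxon counts at one rank."""
    idx = _RANK_INDEX[rank]
    counts: dict[str, int] = {}
    for lineage in assignments:
        if lineage is None or is_empty_label(lineage[idx]):
            continue
        taxon = "; ".join(lineage[: idx + 1])
        counts[taxon] = counts.get(taxon, 0) + 1
    return CommunityProfile(sample_id=sample_id, counts=counts)


def _align_profiles(
    p: Mapping[str, float] | CommunityProfile, q: Mapping[str, float] | CommunityProfile
) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(p, CommunityProfile):
        p = p.counts
    if isinstance(q, CommunityProfile):
        q = q.counts
    taxa = sorted(set(p) | set(q))
    x = np.array([p.get(t, 0) for t in taxa], dtype=float)
    y = np.array([q.get(t, 0) for t in taxa], dtype=float)
    if (x < 0).any() or (y < 0).any():
        raise ValueError("negative counts in community profiles")
    return x, y


def bray_curtis(
    p: Mapping[str, float] | CommunityProfile, q: Mapping[str, float] | CommunityProfile
) -> float:
    """Bray-Curtis dissimilarity, 1 - 2*sum(min)/sum(total), in [0, 1]."""
    x, y = _align_profiles(p, q)
    if x.sum() == 0 and y.sum() == 0:
        return 0.0
    return float(scipy.spatial.distance.braycurtis(x, y))


def distance_matrix(
    profiles: Sequence[CommunityProfile],
) -> tuple[np.ndarray, list[str]]:
    labels = [p.sample_id for p in profiles]
    n = len(profiles)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = bray_curtis(profiles[i], profiles[j])
    return dist, labels


def upgma(
    dist: np.ndarray, labels: Sequence[str] | None = None
) -> list[tuple[int, int, float, int]]:
    """UPGMA merge list from a symmetric distance matrix.

    Returns (node_i, node_j, height, size) per merge, where leaves are
    numbered 0..n-1, internal nodes continue from n, and a node's height
    is half the distance between the merged clusters (ultrametric leaf
    depth).
    """
    dist = np.asarray(dist, dtype=float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(dist, dist.T) or not np.allclose(np.diag(dist), 0.0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    condensed = scipy.spatial.distance.squareform(dist, checks=False)
    linkage = scipy.cluster.hierarchy.linkage(condensed, method="average")
    return [
        (int(row[0]), int(row[1]), float(row[2]) / 2.0, int(row[3]))
        for row in linkage
    ]


def upgma_newick(dist: np.ndarray, labels: Sequence[str]) -> str:
    """Newick string of the UPGMA dendrogram with ultrametric branch lengths."""
    merges = upgma(dist)
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}
    subtrees = {i: labels[i] for i in range(n)}
    for k, (i, j, height, _size) in enumerate(merges):
        node = n + k
        left = f"{subtrees[i]}:{height - heights[i]:.6g}"
        right = f"{subtrees[j]}:{height - heights[j]:.6g}"
        subtrees[node] = f"({left},{right})"
        heights[node] = height
    return subtrees[n + len(merges) - 1] + ";" if merges else f"({labels[0]});"


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman's rank correlation (ties get average ranks).

    Returns NaN when either input has zero variance (undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("spearman needs two equal-length vectors of length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    rho, _p = scipy.stats.spearmanr(x, y)
    return float(rho)


def alpha_diversity(counts: Sequence[int]) -> dict[str, float]:
    """Observed OTUs, bias-corrected Chao1, Shannon (nats) and evenness."""
    arr = np.asarray(counts)
    if (arr < 0).any() or not np.issubdtype(arr.dtype, np.integer):
        raise ValueError("counts must be non-negative integers")
    observed = int(np.count_nonzero(arr))
    chao1 = float(skbio_alpha.chao1(arr, bias_corrected=True)) if observed else 0.0
    shannon = float(skbio_alpha.shannon(arr, base=math.e)) if observed else 0.0
    evenness = shannon / math.log(observed) if observed > 1 else float("nan")
    return {
        "observed": float(observed),
        "chao1": chao1,
        "shannon": shannon,
        "evenness": evenness,
    }


def rarefy(counts: Sequence[int], depth: int, seed: int = 0) -> np.ndarray:
    """Subsample a count vector to ``depth`` observations without replacement."""
    arr = np.asarray(counts, dtype=np.int64)
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    total = int(arr.sum())
    if depth > total:
        raise ValueError(f"depth {depth} exceeds total count {total}")
    rng = np.random.default_rng(seed)
    return rng.multivariate_hypergeometric(arr, depth)


def rarefaction_curve(
    counts: Sequence[int], depths: Sequence[int], seed: int = 0, n_draws: int = 10
) -> pd.DataFrame:
    """Mean observed OTUs at each depth over ``n_draws`` subsamples."""
    rows = []
    for depth in depths:
        observed = [
            int(np.count_nonzero(rarefy(counts, depth, seed=[seed, depth, d])))
            for d in range(n_draws)
        ]
        rows.append({"depth": depth, "mean_observed": float(np.mean(observed))})
    return pd.DataFrame(rows)
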