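"""Greedy centroid OTU clustering and precision/recall evaluation.

Sequences are clustered UCLUST-style: processed in order of decreasing
length (ties by id), each either joins the first existing centroid (in
creation order) it matches at >= the identity threshold, or founds a new
centroid. Precision and recall are computed against database-defined
truth clusters by mapping each computed cluster to the truth cluster
holding the plurality of its members:

* precision = sum over computed clusters of members from the mapped truth
  cluster, divided by the total number of clustered sequences;
* recall = for each truth cluster, the largest such member count among
  the computed clusters mapped to it, summed and divided by the total
  truth-cluster membership.

Both are micro-averages; per-cluster macro averages are also reported.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .align import align_global

SequenceMap = Mapping[str, str]


@dataclass
class ClusterSet:
    """Centroid ids in creation order plus the id -> centroid membership map."""

    centroids: list[str]
    members: dict[str, str]

    def __post_init__(self) -> None:
        for centroid in self.centroids:
            if self.members.get(centroid) != centroid:
                raise ValueError(f"centroid {centroid!r} is not its own member")

    def clusters(self) -> dict[str, list[str]]:
        grouped: dict[str, list[str]] = {c: [] for c in self.centroids}
        for seq_id, centroid in self.members.items():
            grouped[centroid].append(seq_id)
        return grouped

    def sizes(self) -> dict[str, int]:
        return {c: len(ids) for c, ids in self.clusters().items()}

    def __len__(self) -> int:
        return len(self.centroids)


@dataclass(frozen=True)
class PRResult:
    replicate: int
    precision: float
    recall: float
    n_sampled: int
    seed: int
    macro_precision: float = float("nan")
    macro_recall: float = float("nan")

    def __post_init__(self) -> None:
        if not (0.0 <= self.precision <= 1.0 and 0.0 <= self.recall <= 1.0):
            raise ValueError("precision and recall must lie in [0, 1]")


def cluster_greedy(seqs: SequenceMap, threshold: float = 0.97) -> ClusterSet:
    """Greedy centroid clustering at the given identity threshold.

    ``seqs`` maps unique ids to sequences. Identity is ``identity_all``
    of the global alignment of the candidate against each centroid.
    """
    ids = list(seqs)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    order = sorted(ids, key=lambda i: (-len(seqs[i]), i))
    centroids: list[str] = []
    members: dict[str, str] = {}
    for seq_id in order:
        sequence = seqs[seq_id]
        assigned = None
        for centroid in centroids:
            aln = align_global(sequence, seqs[centroid])
            if aln.identity_all >= threshold:
                assigned = centroid
                break
        if assigned is None:
            centroids.append(seq_id)
            members[seq_id] = seq_id
        else:
            members[seq_id] = assigned
    return ClusterSet(centroids=centroids, members=members)


def remove_singletons(clusters: ClusterSet) -> ClusterSet:
    """Drop clusters with a single member (singleton OTUs)."""
    grouped = clusters.clusters()
    kept = [c for c in clusters.centroids if len(grouped[c]) >= 2]
    members = {
        seq_id: centroid
        for seq_id, centroid in clusters.members.items()
        if centroid in set(kept)
    }
    return ClusterSet(centroids=kept, members=members)


def _map_to_truth(
    computed: ClusterSet, truth: Mapping[str, str]
) -> dict[str, tuple[str, int]]:
    """Computed centroid -> (plurality truth cluster, member count from it).

    Plurality ties are broken toward the larger truth cluster, then
    lexicographically by truth-cluster id.
    """
    truth_sizes = Counter(truth.values())
    mapping: dict[str, tuple[str, int]] = {}
    for centroid, ids in computed.clusters().items():
        counts = Counter(truth[i] for i in ids)
        best = min(
            counts.items(),
            key=lambda kv: (-kv[1], -truth_sizes[kv[0]], kv[0]),
        )
        mapping[centroid] = (best[0], best[1])
    return mapping


def precision_recall(
    computed: ClusterSet, truth: Mapping[str, str]
) -> tuple[float, float]:
    """Micro-averaged precision and recall of ``computed`` against truth."""
    missing = [i for i in computed.members if i not in truth]
    if missing:
        raise KeyError(f"ids without truth labels: {missing[:5]}")
    if not computed.members:
        return 0.0, 0.0
    mapping = _map_to_truth(computed, truth)
    sizes = computed.sizes()
    tp_total = sum(tp for _, tp in mapping.values())
    precision = tp_total / sum(sizes.values())

    best_tp: dict[str, int] = defaultdict(int)
    for centroid, (truth_cluster, tp) in mapping.items():
        best_tp[truth_cluster] = max(best_tp[truth_cluster], tp)
    truth_sizes = Counter(truth.values())
    recall = sum(best_tp.values()) / sum(truth_sizes.values())
    return precision, recall


def macro_precision_recall(
    computed: ClusterSet, truth: Mapping[str, str]
) -> tuple[float, float]:
    """Unweighted per-cluster averages, reported alongside the micro values."""
    if not computed.members:
        return 0.0, 0.0
    mapping = _map_to_truth(computed, truth)
    sizes = computed.sizes()
    precision = float(
        np.mean([tp / sizes[c] for c, (_, tp) in mapping.items()])
    )
    best_tp: dict[str, int] = defaultdict(int)
    for centroid, (truth_cluster, tp) in mapping.items():
        best_tp[truth_cluster] = max(best_tp[truth_cluster], tp)
    truth_sizes = Counter(truth.values())
    recall = float(
        np.mean([best_tp.get(t, 0) / n for t, n in truth_sizes.items()])
    )
    return precision, recall


def bootstrap_eval(
    region_seqs: SequenceMap,
    truth: Mapping[str, str],
    n_seqs: int = 10_000,
    B: int = 100,
    threshold: float = 0.97,
    seed: int = 0,
    with_replacement: bool = False,
    drop_singletons: bool = False,
) -> list[PRResult]:
    """Repeated-subsample clustering evaluation against truth clusters.

    Each of the ``B`` replicates samples ``n_seqs`` sequences (without
    replacement by default: resampling identical sequences would trivially
    inflate cluster purity), clusters them greedily at ``threshold`` and
    scores precision/recall. Replicate seeds are derived from the master
    seed, so results are reproducible.
    """
    ids = sorted(region_seqs)
    if not with_replacement and n_seqs > len(ids):
        raise ValueError(f"n_seqs={n_seqs} exceeds population size {len(ids)}")
    results: list[PRResult] = []
    for b in range(B):
        rng = np.random.default_rng([seed, b])
        chosen = rng.choice(len(ids), size=n_seqs, replace=with_replacement)
        if with_replacement:
            # resampled copies get distinct ids but share sequence and truth
            sample = {f"{ids[i]}#{k}": region_seqs[ids[i]] for k, i in enumerate(chosen)}
            sample_truth = {f"{ids[i]}#{k}": truth[ids[i]] for k, i in enumerate(chosen)}
        else:
            sample_ids = [ids[i] for i in sorted(chosen)]
            sample = {i: region_seqs[i] for i in sample_ids}
            sample_truth = {i: truth[i] for i in sample_ids}
        clusters = cluster_greedy(sample, threshold=threshold)
        if drop_singletons:
            clusters = remove_singletons(clusters)
        precision, recall = precision_recall(clusters, sample_truth)
        macro_p, macro_r = macro_precision_recall(clusters, sample_truth)
        results.append(
            PRResult(
                replicate=b,
                precision=precision,
                recall=recall,
                n_sampled=len(sample),
                seed=seed,
                macro_precision=macro_p,
                macro_recall=macro_r,
            )
        )
    return results
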