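"""Synthetic 16S reference databases and platform-conditioned read simulation.

The generator builds a mock full-length 16S-like database with known
ground truth: clusters of near-identical sequences (species-level truth
clusters) derived from cluster templates that themselves diverge from a
shared ancestor. Five conserved blocks are pasted into every template at
E. coli-like coordinates; they carry verbatim binding sites for all five
shipped primer pairs (27F variants, 341F, 515F, the 785-806 reverse-primer
complex, and 1492R) and are never mutated, so every record yields every
region by in-silico PCR with zero mismatches.

Read simulation emulates the platforms' characteristic error composition:

* ``miseq``   - substitution-dominant, error rate rising linearly toward
  the read 3' end, near-zero indel rates;
* ``flx``     - pyrosequencing-style homopolymer over/under-calls (runs of
  length >= ``homopolymer_min`` lengthened or shortened by one) on top of
  a low uniform substitution/indel floor;
* ``pacbio_ccs`` - indel-dominant with deletions three times as frequent
  as insertions, uniformly placed.

The numeric defaults are stylized rates chosen to reproduce each
platform's error *composition* and magnitude order, not trained
instrument profiles; all of them are configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .pcr import DEFAULT_PRIMER_PAIRS, extract_region, reverse_complement
from .records import Platform, RANK_PREFIXES, Read, ReadPair, ReferenceRecord

# Conserved primer-anchor blocks: name -> (start at template length 1500,
# literal sequence). Each literal simultaneously satisfies every shipped
# degenerate primer that binds there (verified in the test suite).
CONSERVED_BLOCKS: dict[str, tuple[int, str]] = {
    "27F": (8, "AGAGTTTGATCCTGGCTCAG"),
    "341F": (341, "CCTACGGGAGGCAGCAG"),
    "515F": (511, "GTGCCAGCAGCCGCGGTAATAC"),
    "785R": (785, "GGATTAGATACCCTGGTAGTCC"),
    "1492R": (1474, "AAGTCGTAACAAGGTAACC"),
}

_CANONICAL_TEMPLATE_LENGTH = 1500

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the mock reference database.

    ``within_cluster_sub_rate`` is the per-base substitution probability
    applied independently to each cluster member, so two members of one
    cluster differ at about twice that rate. ``between_cluster_divergence``
    is the per-base substitution probability from the shared ancestor to
    each cluster template; ``template_indel_rate`` additionally applies
    small insertion/deletion events to cluster templates (outside the
    conserved blocks), giving clusters realistic amplicon-length spread.
    """

    n_clusters: int = 20
    seqs_per_cluster: int = 5
    template_length: int = 1500
    within_cluster_sub_rate: float = 0.01
    between_cluster_divergence: float = 0.10
    template_indel_rate: float = 0.01
    indel_size_p: float = 0.3
    empty_species_frac: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "within_cluster_sub_rate",
            "between_cluster_divergence",
            "template_indel_rate",
            "empty_species_frac",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name}={value} outside [0, 1]")
        if self.n_clusters < 1 or self.seqs_per_cluster < 1:
            raise ValueError("n_clusters and seqs_per_cluster must be >= 1")
        last_end = -1
        for name, (start, literal) in self.conserved_blocks.items():
            if start <= last_end:
                raise ValueError(f"conserved block {name} overlaps its predecessor")
            last_end = start + len(literal)
        if last_end > self.template_length:
            raise ValueError(
                f"conserved blocks exceed template_length={self.template_length}"
            )

    @property
    def conserved_blocks(self) -> dict[str, tuple[int, str]]:
        """Block coordinates scaled from the canonical 1500 bp layout."""
        scale = self.template_length / _CANONICAL_TEMPLATE_LENGTH
        return {
            name: (int(round(start * scale)), literal)
            for name, (start, literal) in CONSERVED_BLOCKS.items()
        }

    @property
    def primer_anchor_map(self) -> dict[str, tuple[int, int]]:
        """Region -> (forward-primer start, reverse-site end) on the ancestor."""
        blocks = self.conserved_blocks
        b27, b341, b515, b785, b1492 = (blocks[k][0] for k in CONSERVED_BLOCKS)
        return {
            "V1-3": (b27, b515 + 22),
            "V3-4": (b341, b785 + 21),
            "V4": (b515, b785 + 22),
            "V1-4": (b27 + 1, b785 + 18),
            "V1-9": (b27, b1492 + 19),
        }


@dataclass(frozen=True)
class ErrorModel:
    """Per-platform read error parameters (all rates per base).

    The per-position substitution probability is
    ``sub_rate * (1 + sub_slope * pos / len)``, so ``sub_slope`` controls
    how strongly errors concentrate toward the 3' end. Homopolymer
    parameters only act when ``homopolymer_indel_rate > 0``: each run of
    length >= ``homopolymer_min`` is lengthened or shortened by one base
    with that per-run probability. ``read_length`` of None means the read
    covers the full amplicon (long-read style).
    """

    platform: Platform
    sub_rate: float = 0.0
    sub_slope: float = 0.0
    ins_rate: float = 0.0
    del_rate: float = 0.0
    homopolymer_indel_rate: float = 0.0
    homopolymer_min: int = 4
    read_length: int | None = None

    def __post_init__(self) -> None:
        for name in ("sub_rate", "ins_rate", "del_rate", "homopolymer_indel_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.read_length is not None and self.read_length <= 0:
            raise ValueError("read_length must be positive")


MISEQ_MODEL = ErrorModel(
    Platform.MISEQ, sub_rate=0.004, sub_slope=3.0, ins_rate=1e-4, del_rate=1e-4
)
FLX_MODEL = ErrorModel(
    Platform.FLX,
    sub_rate=0.001,
    sub_slope=0.5,
    ins_rate=2e-4,
    del_rate=2e-4,
    homopolymer_indel_rate=0.02,
    homopolymer_min=4,
    read_length=800,
)
# Deletions three times as frequent as insertions, the hallmark of the
# circular-consensus datasets this package evaluates.
PACBIO_CCS_MODEL = ErrorModel(
    Platform.PACBIO_CCS, sub_rate=0.002, sub_slope=0.0, ins_rate=0.002, del_rate=0.006
)

ERROR_MODELS: dict[str, ErrorModel] = {
    "miseq": MISEQ_MODEL,
    "flx": FLX_MODEL,
    "pacbio_ccs": PACBIO_CCS_MODEL,
}


def error_free_model(platform: Platform = Platform.MISEQ) -> ErrorModel:
    """An all-zero-rate model; reads equal their source amplicons."""
    return ErrorModel(platform)


# ---------------------------------------------------------------------------
# reference generation


def _lineage_for_cluster(cluster_idx: int, empty_species: bool) -> tuple[str, ...]:
    genus = cluster_idx // 2
    family = genus // 2
    order = family // 2
    klass = order // 2
    phylum = klass // 2
    labels = (
        "k__Bacteria",
        f"p__Phylum{phylum:02d}",
        f"c__Class{klass:02d}",
        f"o__Order{order:02d}",
        f"f__Family{family:02d}",
        f"g__Genus{genus:02d}",
        RANK_PREFIXES[6] if empty_species else f"s__species_{cluster_idx:03d}",
    )
    return labels


def _mutate_substitutions(
    seq: np.ndarray, mutable: np.ndarray, rate: float, rng: np.random.Generator
) -> np.ndarray:
    out = seq.copy()
    hit = (rng.random(len(seq)) < rate) & mutable
    idx = np.nonzero(hit)[0]
    if len(idx):
        # shift each hit base by 1..3 within ACGT: always a different base
        current = np.searchsorted(_BASES, out[idx])
        shifted = (current + rng.integers(1, 4, size=len(idx))) % 4
        out[idx] = _BASES[shifted]
    return out


def _apply_template_indels(
    seq: np.ndarray,
    mutable: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Insert/delete short stretches at mutable positions; keep mask in sync."""
    n_mutable = int(mutable.sum())
    n_events = rng.poisson(config.template_indel_rate * n_mutable)
    seq = seq.copy()
    mutable = mutable.copy()
    for _ in range(n_events):
        size = int(rng.geometric(config.indel_size_p))
        candidates = np.nonzero(mutable)[0]
        if len(candidates) == 0:
            break
        pos = int(candidates[rng.integers(len(candidates))])
        if rng.random() < 0.5:  # insertion before pos
            insert = _BASES[rng.integers(0, 4, size=size)]
            seq = np.concatenate([seq[:pos], insert, seq[pos:]])
            mutable = np.concatenate(
                [mutable[:pos], np.ones(size, dtype=bool), mutable[pos:]]
            )
        else:  # deletion of mutable bases only, starting at pos
            run_end = pos
            deleted = 0
            while run_end < len(seq) and deleted < size and mutable[run_end]:
                run_end += 1
                deleted += 1
            keep = np.ones(len(seq), dtype=bool)
            keep[pos:run_end] = False
            seq = seq[keep]
            mutable = mutable[keep]
    return seq, mutable


def generate_reference(config: SimConfig) -> list[ReferenceRecord]:
    """Generate the mock reference database described by ``config``.

    Returns ``n_clusters * seqs_per_cluster`` records in cluster order.
    Conserved primer blocks are identical in every record; lineages are
    nested hierarchically and the species label is shared exactly within a
    truth cluster. Fully deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    length = config.template_length
    ancestor = _BASES[rng.integers(0, 4, size=length)]
    mutable = np.ones(length, dtype=bool)
    for start, literal in config.conserved_blocks.values():
        block = np.frombuffer(literal.encode(), dtype=np.uint8)
        ancestor[start : start + len(block)] = block
        mutable[start : start + len(block)] = False

    n_empty_species = int(round(config.empty_species_frac * config.n_clusters))
    records: list[ReferenceRecord] = []
    for c in range(config.n_clusters):
        template = _mutate_substitutions(
            ancestor, mutable, config.between_cluster_divergence, rng
        )
        template, template_mutable = _apply_template_indels(
            template, mutable, config, rng
        )
        lineage = _lineage_for_cluster(c, empty_species=c < n_empty_species)
        truth = f"C{c:03d}"
        for s in range(config.seqs_per_cluster):
            member = _mutate_substitutions(
                template, template_mutable, config.within_cluster_sub_rate, rng
            )
            records.append(
                ReferenceRecord(
                    id=f"{truth}_S{s:02d}",
                    sequence=member.tobytes().decode(),
                    lineage=lineage,
                    truth_cluster=truth,
                )
            )
    return records


# ---------------------------------------------------------------------------
# read simulation


def _quality_for(p_error: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Phred values tracking the local injected error probability."""
    q = np.round(-10.0 * np.log10(p_error + 1e-4)).astype(np.int64)
    q += rng.integers(-2, 3, size=len(q))
    return np.clip(q, 2, 40)


def _homopolymer_runs(seq: np.ndarray, min_len: int) -> list[tuple[int, int]]:
    """(start, end) spans of runs of one base with length >= min_len."""
    runs = []
    start = 0
    for i in range(1, len(seq) + 1):
        if i == len(seq) or seq[i] != seq[start]:
            if i - start >= min_len:
                runs.append((start, i))
            start = i
    return runs


def apply_errors(
    sequence: str, model: ErrorModel, rng: np.random.Generator
) -> tuple[str, tuple[int, ...]]:
    """Inject platform errors into one source sequence; returns bases, quals."""
    seq = np.frombuffer(sequence.encode(), dtype=np.uint8)
    n = len(seq)
    positions = np.arange(n)
    sub_p = model.sub_rate * (1.0 + model.sub_slope * positions / max(n, 1))
    sub_mask = rng.random(n) < sub_p
    del_mask = rng.random(n) < model.del_rate
    ins_mask = rng.random(n) < model.ins_rate

    if model.homopolymer_indel_rate > 0:
        for start, end in _homopolymer_runs(seq, model.homopolymer_min):
            if rng.random() < model.homopolymer_indel_rate:
                middle = (start + end) // 2
                if rng.random() < 0.5:
                    ins_mask[middle] = True  # run lengthened by one
                else:
                    del_mask[middle] = True  # run shortened by one

    p_error = sub_p + model.ins_rate + model.del_rate
    quals = _quality_for(p_error, rng)

    out_bases: list[int] = []
    out_quals: list[int] = []
    for i in range(n):
        if ins_mask[i]:
            if model.homopolymer_indel_rate > 0 and i > 0 and seq[i] == seq[i - 1]:
                inserted = int(seq[i])  # homopolymer-style duplication
            else:
                inserted = int(_BASES[rng.integers(0, 4)])
            out_bases.append(inserted)
            out_quals.append(int(quals[i]))
        if del_mask[i]:
            continue
        base = int(seq[i])
        if sub_mask[i]:
            current = int(np.searchsorted(_BASES, base))
            base = int(_BASES[(current + int(rng.integers(1, 4))) % 4])
        out_bases.append(base)
        out_quals.append(int(quals[i]))

    if model.read_length is not None and len(out_bases) > model.read_length:
        out_bases = out_bases[: model.read_length]
        out_quals = out_quals[: model.read_length]
    return bytes(out_bases).decode(), tuple(out_quals)


def _region_amplicons(
    db: list[ReferenceRecord], region: str
) -> dict[str, str]:
    pair = DEFAULT_PRIMER_PAIRS[region]
    amplicons: dict[str, str] = {}
    for rec in db:
        amp = extract_region(rec, pair)
        if amp is None:
            raise ValueError(f"region {region} not extractable from record {rec.id}")
        amplicons[rec.id] = amp.sequence
    return amplicons


def simulate_reads(
    db: list[ReferenceRecord],
    region: str,
    model: ErrorModel,
    n_reads: int,
    seed: int,
) -> list[Read]:
    """Simulate single-end reads from uniformly drawn records of ``db``.

    The source record id is appended to each read id after ``|`` so that
    downstream truth tracking (:func:`amplieval.records.source_of`) works.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    rng = np.random.default_rng(seed)
    amplicons = _region_amplicons(db, region)
    reads: list[Read] = []
    for i in range(n_reads):
        rec = db[int(rng.integers(len(db)))]
        bases, quals = apply_errors(amplicons[rec.id], model, rng)
        reads.append(
            Read(
                id=f"r{i:06d}|{rec.id}",
                bases=bases,
                quals=quals,
                platform=model.platform,
            )
        )
    return reads


def simulate_pairs(
    db: list[ReferenceRecord],
    region: str,
    read_len: int,
    model: ErrorModel,
    n_pairs: int,
    seed: int,
    min_overlap: int = 10,
) -> list[ReadPair]:
    """Simulate paired-end reads: r1 from the amplicon 5' end, r2 from the
    reverse strand 3' end, each of ``read_len`` bases before errors.

    Pairs whose amplicon is longer than ``2 * read_len - min_overlap`` are
    flagged ``overlaps=False`` (their mates cannot be merged).
    """
    if read_len <= 0:
        raise ValueError("read_len must be positive")
    if n_pairs <= 0:
        raise ValueError("n_pairs must be positive")
    rng = np.random.default_rng(seed)
    amplicons = _region_amplicons(db, region)
    pair_model = replace(model, read_length=None)
    pairs: list[ReadPair] = []
    for i in range(n_pairs):
        rec = db[int(rng.integers(len(db)))]
        amp = amplicons[rec.id]
        overlaps = 2 * read_len >= len(amp) + min_overlap
        r1_src = amp[:read_len]
        r2_src = reverse_complement(amp)[:read_len]
        b1, q1 = apply_errors(r1_src, pair_model, rng)
        b2, q2 = apply_errors(r2_src, pair_model, rng)
        stem = f"p{i:06d}|{rec.id}"
        pairs.append(
            ReadPair(
                r1=Read(f"{stem}/1", b1[:read_len], q1[:read_len], model.platform),
                r2=Read(f"{stem}/2", b2[:read_len], q2[:read_len], model.platform),
                overlaps=overlaps,
            )
        )
    return pairs
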