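"""End-to-end in-silico platform comparison benchmark.

One call simulates a mock reference database, extracts the five 16S
regions, simulates platform-conditioned reads for each platform/region
combination, runs the platform QC paths, profiles indel/substitution
errors against the reference, evaluates OTU clustering precision/recall,
assigns taxonomy, and summarizes community structure (assigned fractions,
alpha diversity, Bray-Curtis + UPGMA). All randomness derives from one
master seed; a rerun with the same configuration writes byte-identical
tables.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as aio
from .align import error_profile, ReferenceIndex
from .community import (
    alpha_diversity,
    assign_taxonomy,
    assigned_fraction,
    distance_matrix,
    profile_from_assignments,
    upgma_newick,
)
from .otu import bootstrap_eval, cluster_greedy, precision_recall
from .pcr import DEFAULT_PRIMER_PAIRS, expected_size_range, extract_region
from .qc import run_flx_qc, run_miseq_qc, run_pacbio_qc
from .records import Platform, Read, source_of
from .simulate import (
    ERROR_MODELS,
    ErrorModel,
    SimConfig,
    generate_reference,
    simulate_pairs,
    simulate_reads,
)


def derive_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (master_seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass(frozen=True)
class Condition:
    """One platform/region dataset of the benchmark.

    ``read_len`` models the *effective* paired-end read length after
    quality trimming (2x300 chemistry typically yields ~250 usable
    bases), which is what determines whether mates of a long amplicon
    can still overlap.
    """

    name: str
    platform: str  # key into the error-model map
    region: str
    paired: bool = False
    read_len: int = 250


DEFAULT_CONDITIONS: tuple[Condition, ...] = (
    Condition("flx_V1-4", "flx", "V1-4"),
    Condition("miseq_V1-3", "miseq", "V1-3", paired=True),
    Condition("miseq_V3-4", "miseq", "V3-4", paired=True),
    Condition("miseq_V4", "miseq", "V4", paired=True),
    Condition("pacbio_V1-9", "pacbio_ccs", "V1-9"),
)


@dataclass
class RunConfig:
    """Benchmark configuration; the defaults are a desk-scale experiment."""

    out_dir: str | Path = "results"
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    conditions: tuple[Condition, ...] = DEFAULT_CONDITIONS
    n_reads: int = 240
    profile_cap: int = 80
    cluster_cap: int = 100
    assign_cap: int = 80
    bootstrap_n_seqs: int = 50
    bootstrap_reps: int = 3
    cluster_threshold: float = 0.97
    error_models: dict[str, ErrorModel] = field(default_factory=lambda: dict(ERROR_MODELS))

    def echo(self) -> dict:
        out = dataclasses.asdict(self)
        out["out_dir"] = str(self.out_dir)
        return out


def _write_tsv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_benchmark(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Run all stages and write the result bundle under ``config.out_dir``."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    master = config.seed

    # stage 1: reference database with ground truth
    sim = dataclasses.replace(config.sim, seed=derive_seed(master, "reference"))
    db = generate_reference(sim)
    truth = {rec.id: rec.truth_cluster for rec in db}
    aio.write_fasta(db, out_dir / "reference.fasta")
    aio.write_taxonomy(db, out_dir / "taxonomy.tsv")
    aio.write_truth(db, out_dir / "truth.tsv")

    # stage 2: region extraction and expected sizes
    region_seqs: dict[str, dict[str, str]] = {}
    size_rows = []
    for region, pair in DEFAULT_PRIMER_PAIRS.items():
        amps = {}
        for rec in db:
            amp = extract_region(rec, pair)
            if amp is None:
                raise RuntimeError(f"stage extract: region {region} missing in {rec.id}")
            amps[rec.id] = amp.sequence
        region_seqs[region] = amps
        lo, hi = expected_size_range([len(s) for s in amps.values()])
        size_rows.append({"region": region, "min_len": lo, "max_len": hi})
    size_table = pd.DataFrame(size_rows)
    size_ranges = {row["region"]: (row["min_len"], row["max_len"]) for row in size_rows}
    _write_tsv(size_table, out_dir / "size_ranges.tsv")

    # stage 3: per-condition simulate -> QC -> profile -> cluster -> taxonomy
    qc_rows, error_rows, alpha_rows, assign_rows, read_pr_rows = [], [], [], [], []
    profiles = []
    ref_index = ReferenceIndex(db)
    for cond in config.conditions:
        model = config.error_models[cond.platform]
        seed = derive_seed(master, f"reads:{cond.name}")
        if cond.paired:
            pairs = simulate_pairs(db, cond.region, cond.read_len, model, config.n_reads, seed)
            passed, report = run_miseq_qc(pairs, cond.region, size_ranges)
        elif cond.platform == "pacbio_ccs":
            reads = simulate_reads(db, cond.region, model, config.n_reads, seed)
            pair = DEFAULT_PRIMER_PAIRS[cond.region]
            passed, report = run_pacbio_qc(reads, pair.forward, pair.reverse)
        else:
            reads = simulate_reads(db, cond.region, model, config.n_reads, seed)
            passed, report = run_flx_qc(reads)
        row = {"condition": cond.name, "region": cond.region, **report.as_dict()}
        row["merge_efficiency"] = report.pass_count / report.input_count if report.input_count else 0.0
        qc_rows.append(row)
        if not report.check_conservation():
            raise RuntimeError(f"stage qc: read accounting broken for {cond.name}")

        subset = passed[: config.profile_cap]
        if subset:
            _table, summary = error_profile(subset, db, n_candidates=5)
            error_rows.append({"condition": cond.name, **summary})

        cluster_subset = passed[: config.cluster_cap]
        if cluster_subset:
            seqs = {r.id: r.bases for r in cluster_subset}
            clusters = cluster_greedy(seqs, threshold=config.cluster_threshold)
            read_truth = {r.id: truth[source_of(r.id)] for r in cluster_subset}
            precision, recall = precision_recall(clusters, read_truth)
            read_pr_rows.append(
                {
                    "condition": cond.name,
                    "n_reads": len(cluster_subset),
                    "n_otus": len(clusters),
                    "precision": precision,
                    "recall": recall,
                }
            )
            otu_counts = np.array(sorted(clusters.sizes().values()), dtype=int)
            alpha_rows.append({"condition": cond.name, **alpha_diversity(otu_counts)})

        assign_subset = passed[: config.assign_cap]
        if assign_subset:
            assignments = [
                assign_taxonomy(read, db, index=ref_index, n_candidates=5)
                for read in assign_subset
            ]
            fractions = {
                rank: assigned_fraction(assignments, rank)
                for rank in ("family", "genus", "species")
            }
            assign_rows.append({"condition": cond.name, **fractions})
            profiles.append(profile_from_assignments(cond.name, assignments, rank="family"))

    # stage 4: clustering precision/recall on error-free region sequences
    pr_rows = []
    for region, seqs in region_seqs.items():
        n_seqs = min(config.bootstrap_n_seqs, len(seqs))
        results = bootstrap_eval(
            seqs,
            truth,
            n_seqs=n_seqs,
            B=config.bootstrap_reps,
            threshold=config.cluster_threshold,
            seed=derive_seed(master, f"bootstrap:{region}"),
        )
        for res in results:
            pr_rows.append(
                {
                    "region": region,
                    "replicate": res.replicate,
                    "n_sampled": res.n_sampled,
                    "precision": res.precision,
                    "recall": res.recall,
                    "macro_precision": res.macro_precision,
                    "macro_recall": res.macro_recall,
                }
            )

    # stage 5: beta diversity across condition profiles
    newick = ""
    beta = pd.DataFrame()
    if len(profiles) >= 2:
        dist, labels = distance_matrix(profiles)
        beta = pd.DataFrame(dist, columns=labels)
        beta.insert(0, "sample", labels)
        newick = upgma_newick(dist, labels)
        (out_dir / "upgma.nwk").write_text(newick + "\n")

    tables = {
        "qc": pd.DataFrame(qc_rows),
        "size_ranges": size_table,
        "error_profile": pd.DataFrame(error_rows),
        "read_cluster_pr": pd.DataFrame(read_pr_rows),
        "bootstrap_pr": pd.DataFrame(pr_rows),
        "assigned_fractions": pd.DataFrame(assign_rows),
        "alpha_diversity": pd.DataFrame(alpha_rows),
        "beta_distance": beta,
    }
    for name, frame in tables.items():
        _write_tsv(frame, out_dir / f"{name}.tsv")
    (out_dir / "config.json").write_text(json.dumps(config.echo(), indent=2, default=str) + "\n")
    return tables
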