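# amplieval

Evaluation machinery for comparing 16S rRNA amplicon sequencing platforms
and primer choices, for microbiome researchers who need to know how much
of a community profile is method rather than biology.

Different platforms target different spans of the ~1.5 kb 16S gene —
short-read paired-end kits cover V1-3, V3-4 or V4, pyrosequencing-era
chemistry covers V1-4, and long-read circular consensus sequencing (CCS)
covers V1-9 — and each brings its own error signature: substitution
errors rising toward read 3' ends (Illumina), homopolymer-length indels
(454-style), and deletion-weighted indels (PacBio CCS). `amplieval`
provides the pieces needed to quantify how these choices propagate into
OTU tables and taxonomic profiles:

* **in-silico PCR** with the five standard degenerate primer pairs
  (27F/519R, 341F/805R, 515F/806R, 27F/800R, 27F/1492R), primer-inclusive
  amplicon extraction, and expected-size windows with outlier trimming;
* **platform read QC**: ambiguity/quality/length filters, paired-end
  overlap merging with expected-size filtering, and CCS forward-primer /
  minimum-length selection with internal reverse-primer trimming;
* **error profiling** from query-end-to-end pairwise alignment (free
  reference end gaps): identity with and without indel columns, and
  per-read insertion/deletion/mismatch ratios normalized by read length —
  so indel-dominant and substitution-dominant data are told apart;
* **OTU clustering evaluation**: greedy 97%-identity centroid clustering,
  with bootstrap precision/recall against database-defined truth clusters
  (precision = fraction of a computed cluster truly belonging to its
  matched truth cluster; recall = fraction of a truth cluster recovered);
* **community summaries**: best-hit consensus taxonomy, assigned
  fractions per rank, Bray-Curtis dissimilarity with UPGMA dendrograms,
  Spearman correlation, Chao1/Shannon/evenness and rarefaction;
* a **synthetic data generator** producing mock reference databases with
  ground-truth clusters, conserved primer anchor sites at E. coli-like
  coordinates, and platform-conditioned reads — so the whole pipeline is
  testable without downloading any reference database.

## Worked example

Simulate a 60-sequence mock database (12 species-level truth clusters),
generate CCS-style full-length reads, and profile their errors:

```python
from amplieval import (SimConfig, generate_reference, simulate_reads,
                       ERROR_MODELS, error_profile)

db = generate_reference(SimConfig(n_clusters=12, seqs_per_cluster=5,
                                  within_cluster_sub_rate=0.006,
                                  between_cluster_divergence=0.12, seed=11))
reads = simulate_reads(db, "V1-9", ERROR_MODELS["pacbio_ccs"],
                       n_reads=100, seed=7)
table, summary = error_profile(reads, db, n_candidates=5)
print(f"mean mismatch ratio : {summary['mean_mismatch_ratio']:.5f}")
print(f"mean insertion ratio: {summary['mean_ins_ratio']:.5f}")
print(f"mean deletion ratio : {summary['mean_del_ratio']:.5f}")
print(f"deletion/insertion  : {summary['del_ins_ratio']:.2f}")
```

```
mean mismatch ratio : 0.00186
mean insertion ratio: 0.00211
mean deletion ratio : 0.00558
deletion/insertion  : 2.65
```

The CCS error model injects deletions at three times the insertion rate
(0.006 vs 0.002 per base); the alignment-based profile recovers the
configured rates and the ~3:1 deletion weighting that distinguishes CCS
data from substitution-dominant short reads.

Clustering the error-free V1-9 amplicons of the same database and scoring
them against the known truth clusters:

```python
from amplieval import (bootstrap_eval, extract_region, DEFAULT_PRIMER_PAIRS)

truth = {r.id: r.truth_cluster for r in db}
seqs = {r.id: extract_region(r, DEFAULT_PRIMER_PAIRS["V1-9"]).sequence
        for r in db}
pr = bootstrap_eval(seqs, truth, n_seqs=40, B=5, seed=21)
print("precision:", [round(r.precision, 3) for r in pr])
print("recall   :", [round(r.recall, 3) for r in pr])
```

```
precision: [1.0, 1.0, 1.0, 1.0, 1.0]
recall   : [1.0, 1.0, 1.0, 1.0, 1.0]
```

With error-free full-length sequences, whose within-cluster identities
all exceed the 0.97 threshold and whose between-cluster identities all
fall below it, greedy clustering recovers the truth partition exactly in
every replicate — the calibrated baseline against which shorter regions
and error-bearing reads are compared.

## Command line

A thin CLI wraps the library:

```sh
amplieval simulate-ref ref --n-clusters 20 --seed 1
amplieval extract ref.fasta v4.fasta --region V4
amplieval simulate-reads ref.fasta reads.fastq --region V1-9 --platform pacbio_ccs --seed 1
amplieval qc reads.fastq passed.fastq --platform pacbio --report report.tsv
amplieval profile-errors passed.fastq ref.fasta --out profile.tsv --summary summary.tsv
amplieval cluster-eval v4.fasta ref.truth.tsv --n 50 --reps 10 --seed 1 --out pr.tsv
amplieval run results/ --seed 1          # full benchmark bundle
```

`amplieval run` executes the end-to-end benchmark — reference generation,
region extraction, per-platform read simulation (GS FLX+-style on V1-4,
MiSeq-style pairs on V1-3/V3-4/V4, CCS-style on V1-9), QC, error
profiles, clustering evaluation, taxonomy and diversity summaries — and
writes TSV tables, a Newick UPGMA dendrogram, and the effective
configuration. Reruns with the same seed are byte-identical.

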