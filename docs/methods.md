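# Methods

`amplieval` evaluates how sequencing platform and primer-pair choice shape
16S rRNA amplicon profiling results. It reimplements, as a tested library,
the in-silico evaluation machinery of such comparisons: degenerate-primer
region extraction, platform-conditioned read simulation, platform QC paths,
alignment-based error decomposition, OTU-clustering precision/recall
against database truth, and community-level summaries. This note records
the models, the defaults, and the design choices that were genuinely open.

## Synthetic reference databases

`simulate.generate_reference` builds a mock full-length 16S-like database
with known ground truth:

* A random ancestor template (default 1,500 bp) carries five **conserved
  blocks** at E. coli-like coordinates (starts 8, 341, 511, 785, 1474 on
  the 1,500 bp layout, scaled for other template lengths). Each block is a
  literal sequence chosen to satisfy, simultaneously and with zero
  mismatches, every shipped degenerate primer that binds there — e.g. the
  27F block `AGAGTTTGATCCTGGCTCAG` matches all three 27F variants
  (V1-3's exact 27F, the V1-4 `GAGTTTGATCMTGGCTCAG`, and the degenerate
  long-read `AGRGTTYGATYMTGGCTCAG`), and the block at 785 carries the
  overlapping 800R/805R/806R reverse-primer complex exactly as real 16S
  does. Blocks are never mutated, so every record yields every region by
  in-silico PCR at `max_mismatch=0`.
* Each of `n_clusters` cluster templates diverges from the ancestor by
  per-base substitutions at `between_cluster_divergence` (default 0.10)
  plus short indel events (`template_indel_rate`, default 0.01 events per
  mutable base; sizes geometric, p = 0.3) outside the conserved blocks.
  The indels give clusters realistic region-length spread — full-length
  databases show wide amplicon-length windows (V1-3 spans ~463–553 bp) —
  and are what makes expected-size filtering and merge-efficiency
  comparisons non-degenerate.
* Each of `seqs_per_cluster` members is mutated from its cluster template
  by substitutions at `within_cluster_sub_rate` (default 0.01), so two
  members differ at ≈2% of sites: clusters sit just inside the 97%
  OTU radius while distinct clusters sit far outside (~80% identity).
  Lineages are generated hierarchically (clusters nest into genera,
  families, … by integer division), with the species label shared exactly
  within a truth cluster.

Because two members of one cluster differ at ≈2% of positions in
expectation, short regions (V4, ~292 bp) put the within-cluster pairwise
identity only ~2–3 SD above the 0.97 threshold; exact truth recovery on
short regions is therefore not guaranteed at the default rate. Evaluation
fixtures that assert exact recovery use `within_cluster_sub_rate = 0.006`
(margin > 4 SD) and verify the separation with an independent
edit-distance oracle before relying on it.

### Region nesting

With the verbatim primers, strict interval nesting of primer-inclusive
amplicons is impossible: 806R's binding site extends 1–2 bp beyond 805R's
and 800R's (on real 16S as well), so V4's right edge overhangs V3-4's
inside the conserved block. The nesting property that does hold — and is
tested — is that the **primer-free interior** of each shorter region lies
inside the primer-inclusive interval of every enclosing region.

## Read simulation

`ErrorModel` captures each platform's error composition rather than a
trained instrument profile:

| platform | substitutions | indels | signature |
|---|---|---|---|
| `miseq` | 0.004/base, rising linearly 3' (slope 3 ⇒ ×4 at the 3' end) | 1e-4 each | substitution-dominant, 3'-heavy |
| `flx` | 0.001/base, slope 0.5 | 2e-4 each + homopolymer ±1 per run ≥ 4 bp at 0.02/run | homopolymer indels |
| `pacbio_ccs` | 0.002/base, flat | ins 0.002, del 0.006 | indel-dominant, deletions 3× insertions |

The 3:1 deletion:insertion weighting of the CCS model is the one
quantitative error trait the evaluated comparison established; the other
rates are stylized order-of-magnitude defaults and are configurable (the
GS FLX+ homopolymer rate in particular is a labeled placeholder).
Per-base qualities are derived from the local injected error probability
(Phred ≈ −10·log₁₀ p, ±2 jitter, clipped to [2, 40]); they decay toward
the 3' end for `miseq` and are flat (~27–31) otherwise. The quality model
exists to exercise QC filters, not to mimic instrument quality profiles.

Paired simulation reads `read_len` bases from the amplicon 5' end (R1) and
from the reverse strand 3' end (R2), applies the error model per mate with
its own 3' slope, and flags pairs whose amplicon exceeds
`2·read_len − min_overlap` as non-overlapping. The benchmark pipeline uses
2×250 bp as the *effective* read length of 2×300 chemistry after quality
trimming (observed filtered read lengths in practice are ~243–262 bp);
quality trimming itself is out of scope, so the trim is modeled by the
shorter effective length.

## In-silico PCR

Primer matching is an exhaustive ungapped scan with IUPAC-aware
position-wise comparison; `max_mismatch` defaults to 0 and is configurable
to 3. Amplicons are **primer-inclusive** (forward-primer start through
reverse-primer-site end): the expected V4 window of 286–298 bp brackets
the primer-inclusive V4 amplicon (~292 bp), not the interior. Multiple
hits resolve as leftmost forward match + nearest downstream reverse match
(shortest plausible amplicon, deterministic). `expected_size_range` sorts
lengths and drops `floor(outlier_frac/2 · n)` from each tail (1% total by
default; a per-tail variant is available by flag since the convention is
ambiguous).

## Read QC

* **flx**: fail on >1 ambiguous call, then mean Phred < 25 (exactly 25
  passes), then length < 200 bp; first failing rule is the reported
  reason.
* **miseq**: both mates ≥ 150 bp after trailing-N trimming; merging finds
  the ungapped overlap ≥ 10 bp maximizing matches − mismatches (ties to
  the longer overlap), rejects overlaps with > 25% mismatches, takes the
  higher-quality base at disagreements and the max quality per column;
  merged reads must fall inside the region's expected-size window
  (inclusive bounds — the convention is unstated upstream, inclusive
  chosen). The statistical overlap test used by PEAR is deliberately
  replaced by this simpler mismatch-fraction rule.
* **pacbio_ccs**: forward primer must match (≤ 2 mismatches) starting
  within the first 100 bp (a window prevents spurious mid-read hits);
  an internal reverse-primer site truncates the read at the *end* of the
  leftmost such match (whether the original pipeline kept or removed the
  primer bases is unstated; retained-through-match-end chosen); post-trim
  length must be ≥ 1,300 bp.

QC reports satisfy exact accounting: input = passed + Σ per-reason fails.

## Pairwise alignment and error decomposition

`align_global` is a linear-gap dynamic program (match +2, mismatch −1,
gap −2) with the query aligned end-to-end and **free end gaps on the
subject**, so partial-region reads are not charged for full-length
reference flanks. The left-gap recurrence is folded into a running-maximum
scan, making the forward pass a vectorized O(nm) with ~6 ms for a 300×1500
problem. A linear (not affine) gap penalty is used because the error
metrics count inserted/deleted *bases*, not gap openings.

Traceback ties break diagonal > up > left: a co-optimal mismatch
representation is always preferred over an insertion+deletion pair. This
matters — under this scoring, two substitutions straddling a repeat tie
with a gap-pair representation, and without the tie rule substitution-only
reads would show spurious indels. Two recodings remain that no tie rule
can remove, because the gapped form scores strictly higher: a terminal
substitution can be absorbed into the free subject flank as
deletion+shifted match, and an adjacent insertion+deletion pair is cheaper
as a single mismatch. Both occur at ~1e-5/base under realistic rates —
orders of magnitude below platform error rates — and are why the
substitution/indel separation checks assert margins rather than bit-exact
zeros.

From one alignment three metrics are derived: `identity_all`
(matches/columns), `identity_mismatch_only` (matches/(matches+mismatches),
i.e. identity after ignoring indel columns), and per-read
insertion/deletion/mismatch ratios normalized by read length (insertions
are query-relative: extra bases in the read). `best_hit` prescreens
candidates by shared 8-mer count (top 20, ties by id) and returns the
highest-`identity_all` alignment at ≥ 0.80 identity, ties by id; it is
deterministic and, on the fixture sizes tested, identical to exhaustive
all-vs-all search.

## OTU clustering and precision/recall

`cluster_greedy` is a UCLUST-style greedy centroid pass: sequences in
decreasing-length order (ties by id) join the first centroid (creation
order) at ≥ 97% `identity_all`, else found a new centroid. Centroid
comparison is exhaustive over centroids (the k-mer prescreen is
unnecessary at evaluation scale). Singleton removal is a separate
operation and off by default in `bootstrap_eval`, since dropping
singletons would silently lower recall for truth clusters sampled once.

Evaluation maps each computed cluster to the truth cluster holding the
plurality of its members (ties → larger truth cluster, then lexicographic;
the matching rule is not specified upstream and this is one defensible
reading). Micro-averages: precision = Σ plurality-members / Σ cluster
sizes; recall = Σ (largest plurality count per truth cluster) / Σ truth
sizes. Macro (per-cluster unweighted) averages are reported alongside.
`bootstrap_eval` defaults to the standard protocol — 100 replicates of
10,000 sequences — but samples **without** replacement despite the name:
with replacement, duplicated identical sequences would trivially inflate
cluster purity (a `with_replacement` flag restores the literal protocol).
Replicate seeds derive deterministically from the master seed.

## Community summaries

Taxonomy assignment is a best-hit consensus: top-3 hits at ≥ 0.90
identity vote rank by rank from kingdom down; a label is kept iff
non-empty and ≥ 2/3 of hits agree, truncating at the first failure.
Assigned fractions count reads with a non-empty label at the rank over
*all* reads (unassigned included in the denominator — the usual figure
leaves this unstated). Bray-Curtis, UPGMA (scipy average linkage; node
heights are half the merge distance, making leaf depths ultrametric),
Spearman (ties averaged; NaN on zero variance), observed OTUs,
bias-corrected Chao1 (S + F1(F1−1)/(2(F2+1))), Shannon in natural log
(base configurable), Pielou evenness, and seeded multivariate-
hypergeometric rarefaction are delegated to scipy/scikit-bio behind the
module surface.

## The benchmark pipeline

`run_benchmark` chains all stages — reference generation, region
extraction with computed expected-size windows, per-condition simulation
(GS FLX+ on V1-4, MiSeq pairs on V1-3/V3-4/V4, CCS on V1-9), platform QC,
error profiling, read clustering with truth-based precision/recall,
error-free bootstrap clustering evaluation per region, taxonomy
assignment, alpha diversity, and Bray-Curtis/UPGMA across conditions —
and writes TSV tables plus a Newick dendrogram. Every stage's seed derives
deterministically from the master seed and stage name; reruns are
byte-identical.

Desk-scale default sizes (100-record database, 240 reads per condition,
80–100 reads for the alignment-heavy stages, bootstrap 3×50) keep a full
run in single-digit minutes on one CPU; they are configuration, not
protocol — `bootstrap_eval` retains the 100×10,000 defaults for use
against real databases.

## What the synthetic data does and does not show

The generator reproduces the *structural* features the machinery needs:
conserved primer sites flanking variable regions, species-level truth
clusters inside the 97% radius, region-length spread, and platform error
composition (substitution-dominant 3'-heavy vs homopolymer vs
deletion-weighted indels). It does not model chimeras (generation exists
behind an off-by-default option; detection is out of scope), PCR
amplification bias, abundance skew (records are sampled uniformly),
instrument-accurate quality profiles, or database incompleteness. Passing
tests therefore demonstrate the correctness of the evaluation machinery
and the qualitative direction of platform effects, not quantitative
reproduction of any real dataset's headline numbers.

## Known limitations

* Degenerate-primer matching is ungapped; a primer site disrupted by an
  indel (as CCS reads often have) counts as missing, which is visible as
  a realistic `primer_missing` fraction in CCS QC.
* The greedy clusterer is order-dependent by construction (as is the tool
  it mirrors); only the documented length/id ordering is supported.
* `best_hit`'s k-mer prescreen can in principle miss the true best hit in
  large, highly repetitive databases; the exhaustive-equivalence guarantee
  is only tested at fixture scale (candidate count is configurable).
* Alpha/beta diversity summaries operate on OTU/assignment tables produced
  within the pipeline; no BIOM import/export is provided.
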