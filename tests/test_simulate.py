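"""Generator contracts: determinism, primer conservation, cluster separation,
region nesting and read/pair simulation identities."""

import itertools

import numpy as np
import pytest

from amplieval.align import align_global
from amplieval.pcr import DEFAULT_PRIMER_PAIRS, extract_region, match_primer
from amplieval.qc import merge_pairs
from amplieval.records import Platform, source_of
from amplieval.simulate import (
    ErrorModel,
    PACBIO_CCS_MODEL,
    SimConfig,
    error_free_model,
    generate_reference,
    simulate_pairs,
    simulate_reads,
)


class TestGenerateReference:
    def test_counts_and_truth_labels(self):
        db = generate_reference(SimConfig(n_clusters=3, seqs_per_cluster=5, seed=2))
        assert len(db) == 15
        assert len({r.truth_cluster for r in db}) == 3
        species = {r.truth_cluster: r.lineage[6] for r in db}
        for rec in db:
            assert rec.lineage[6] == species[rec.truth_cluster]

    def test_same_seed_byte_identical(self):
        config = SimConfig(n_clusters=2, seqs_per_cluster=3, seed=9)
        one = generate_reference(config)
        two = generate_reference(config)
        assert [(r.id, r.sequence, r.lineage) for r in one] == [
            (r.id, r.sequence, r.lineage) for r in two
        ]

    def test_all_primer_sites_conserved_with_zero_mismatches(self, small_db):
        for rec in small_db:
            for pair in DEFAULT_PRIMER_PAIRS.values():
                assert any(m == 0 for _, m in match_primer(rec.sequence, pair.forward, 0))
                assert any(
                    m == 0 for _, m in match_primer(rec.sequence, pair.reverse_site, 0)
                )

    def test_default_rates_separate_clusters_at_97_percent(self, small_db):
        """Exhaustive pairwise alignment: within >= 0.97, between < 0.97."""
        for a, b in itertools.combinations(small_db, 2):
            identity = align_global(a.sequence, b.sequence).identity_all
            if a.truth_cluster == b.truth_cluster:
                assert identity >= 0.97
            else:
                assert identity < 0.97

    def test_variable_regions_nest_inside_longer_regions(self, small_db):
        """The primer-free interior of each shorter region lies inside the
        primer-inclusive interval of every enclosing region."""
        nesting = [("V4", "V3-4"), ("V3-4", "V1-4"), ("V1-3", "V1-4"), ("V1-4", "V1-9")]
        for rec in small_db:
            spans = {
                region: extract_region(rec, pair)
                for region, pair in DEFAULT_PRIMER_PAIRS.items()
            }
            for inner, outer in nesting:
                pair = DEFAULT_PRIMER_PAIRS[inner]
                interior = (
                    spans[inner].start + len(pair.forward),
                    spans[inner].end - len(pair.reverse),
                )
                assert spans[outer].start <= interior[0] < interior[1] <= spans[outer].end

    def test_anchors_must_fit_template(self):
        with pytest.raises(ValueError, match="template_length"):
            SimConfig(template_length=800)

    def test_empty_species_fraction(self):
        db = generate_reference(
            SimConfig(n_clusters=4, seqs_per_cluster=2, empty_species_frac=0.5, seed=5)
        )
        empties = {r.truth_cluster for r in db if r.lineage[6] == "s__"}
        assert len(empties) == 2


class TestSimulateReads:
    def test_zero_error_reads_equal_source_amplicons(self, small_db):
        reads = simulate_reads(small_db, "V4", error_free_model(), 30, seed=4)
        amplicons = {
            r.id: extract_region(r, DEFAULT_PRIMER_PAIRS["V4"]).sequence for r in small_db
        }
        for read in reads:
            assert read.bases == amplicons[source_of(read.id)]

    def test_seeded_rerun_identical(self, small_db):
        model = ErrorModel(Platform.MISEQ, sub_rate=0.01, ins_rate=1e-3, del_rate=1e-3)
        one = simulate_reads(small_db, "V3-4", model, 50, seed=8)
        two = simulate_reads(small_db, "V3-4", model, 50, seed=8)
        assert one == two

    def test_rejects_nonpositive_counts(self, small_db):
        with pytest.raises(ValueError):
            simulate_reads(small_db, "V4", error_free_model(), 0, seed=1)

    def test_substitution_rate_recovered_against_sources(self, small_db):
        """Empirical mismatch rate vs known sources within 3 binomial SE."""
        rate = 0.01
        model = ErrorModel(Platform.MISEQ, sub_rate=rate)
        reads = simulate_reads(small_db, "V1-9", model, 45, seed=13)
        amplicons = {
            r.id: extract_region(r, DEFAULT_PRIMER_PAIRS["V1-9"]).sequence for r in small_db
        }
        mismatches = bases = 0
        for read in reads:
            aln = align_global(read.bases, amplicons[source_of(read.id)])
            mismatches += aln.n_mismatch
            bases += len(read.bases)
        assert bases >= 60_000
        se = (rate * (1 - rate) / bases) ** 0.5
        assert abs(mismatches / bases - rate) <= 3 * se

    def test_miseq_errors_concentrate_at_three_prime_end(self, small_db):
        model = ErrorModel(Platform.MISEQ, sub_rate=0.01, sub_slope=4.0)
        reads = simulate_reads(small_db, "V1-4", model, 120, seed=21)
        amplicons = {
            r.id: extract_region(r, DEFAULT_PRIMER_PAIRS["V1-4"]).sequence for r in small_db
        }
        first = last = 0
        for read in reads:
            src = amplicons[source_of(read.id)]
            half = len(src) // 2
            first += sum(a != b for a, b in zip(read.bases[:half], src[:half]))
            last += sum(a != b for a, b in zip(read.bases[half:], src[half:]))
        assert last > first

    def test_flx_homopolymer_indels_land_in_runs(self, small_db):
        model = ErrorModel(
            Platform.FLX, homopolymer_indel_rate=0.5, homopolymer_min=4
        )
        reads = simulate_reads(small_db, "V1-4", model, 60, seed=17)
        amplicons = {
            r.id: extract_region(r, DEFAULT_PRIMER_PAIRS["V1-4"]).sequence for r in small_db
        }
        changed = 0
        for read in reads:
            src = amplicons[source_of(read.id)]
            if len(read.bases) != len(src):
                changed += 1
                # pure homopolymer +-1 events: only indel ops, no substitutions
                aln = align_global(read.bases, src)
                assert aln.n_mismatch == 0
                assert aln.n_ins - aln.n_del == len(read.bases) - len(src)
        assert changed > 0


class TestSimulatePairs:
    def test_error_free_pair_merges_back_to_amplicon(self, small_db):
        pairs = simulate_pairs(small_db, "V4", 250, error_free_model(), 15, seed=3)
        amplicons = {
            r.id: extract_region(r, DEFAULT_PRIMER_PAIRS["V4"]).sequence for r in small_db
        }
        for pair in pairs:
            merged = merge_pairs(pair)
            assert merged is not None
            assert merged.bases == amplicons[source_of(pair.r1.id)]

    def test_long_amplicon_flagged_non_overlapping(self, small_db):
        pairs = simulate_pairs(small_db, "V1-3", 250, error_free_model(), 10, seed=3)
        amplicons = {
            r.id: extract_region(r, DEFAULT_PRIMER_PAIRS["V1-3"]).sequence for r in small_db
        }
        for pair in pairs:
            expected = 2 * 250 >= len(amplicons[source_of(pair.r1.id)]) + 10
            assert pair.overlaps == expected
        assert not any(p.overlaps for p in pairs)  # V1-3 amplicons exceed 490 bp

    def test_seeded_rerun_identical(self, small_db):
        model = ErrorModel(Platform.MISEQ, sub_rate=0.005, sub_slope=2.0)
        one = simulate_pairs(small_db, "V3-4", 250, model, 20, seed=6)
        two = simulate_pairs(small_db, "V3-4", 250, model, 20, seed=6)
        assert one == two

    def test_pacbio_default_is_deletion_weighted(self):
        assert PACBIO_CCS_MODEL.del_rate == pytest.approx(3 * PACBIO_CCS_MODEL.ins_rate)
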