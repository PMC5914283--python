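"""Platform QC rules: ambiguity/quality/length filters, pair merging,
expected-size windows and CCS primer selection/trimming."""

import numpy as np
import pytest

from amplieval.pcr import DEFAULT_PRIMER_PAIRS, REFERENCE_SIZE_RANGES, reverse_complement
from amplieval.qc import (
    QCReport,
    filter_flx,
    filter_merged_size,
    filter_miseq,
    filter_pacbio_ccs,
    merge_pairs,
    run_flx_qc,
)
from amplieval.records import Platform, Read, ReadPair


def _read(bases: str, q: int = 40, id: str = "r") -> Read:
    return Read(id=id, bases=bases, quals=(q,) * len(bases))


def _random_dna(n: int, seed: int = 0) -> str:
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=n))


class TestFilterFlx:
    def test_short_read_fails_even_with_perfect_quality(self):
        result = filter_flx(_read(_random_dna(199)))
        assert not result and result.reason == "too_short"

    def test_two_ambiguous_calls_fail(self):
        result = filter_flx(_read("N" * 2 + _random_dna(250)))
        assert not result and result.reason == "ambiguous"

    def test_one_ambiguous_call_passes(self):
        assert filter_flx(_read("N" + _random_dna(250)))

    def test_mean_quality_exactly_25_passes(self):
        read = _read(_random_dna(250), q=25)
        assert read.mean_quality == 25.0
        assert filter_flx(read)
        assert filter_flx(_read(_random_dna(250), q=24)).reason == "low_quality"

    def test_first_failing_rule_wins(self):
        # both ambiguous and short: ambiguity is checked first
        result = filter_flx(_read("NN" + _random_dna(100)))
        assert result.reason == "ambiguous"


class TestMergePairs:
    def _pair_from(self, fragment: str, read_len: int, q1=40, q2=40):
        r1 = Read("p/1", fragment[:read_len], (q1,) * min(read_len, len(fragment)))
        rc = reverse_complement(fragment)[:read_len]
        r2 = Read("p/2", rc, (q2,) * len(rc))
        return ReadPair(r1, r2)

    def test_error_free_overlap_reconstructs_fragment(self):
        fragment = _random_dna(290, seed=1)
        merged = merge_pairs(self._pair_from(fragment, 250))
        assert merged is not None and merged.bases == fragment

    def test_overlap_below_minimum_returns_none(self):
        # true overlap is 4 bp < min_overlap; every candidate offset >= 10
        # aligns the A-block against the C-block and fails the mismatch cap
        fragment = "A" * 246 + "C" * 250
        assert merge_pairs(self._pair_from(fragment, 250), min_overlap=10) is None

    def test_disagreement_takes_higher_quality_base(self):
        fragment = _random_dna(300, seed=3)
        r1_bases = fragment[:250]
        # corrupt one overlap position in r1 but give r1 higher quality
        pos = 100
        corrupted = r1_bases[:pos] + ("A" if r1_bases[pos] != "A" else "C") + r1_bases[pos + 1 :]
        r1 = Read("p/1", corrupted, (40,) * 250)
        rc = reverse_complement(fragment)[:250]
        r2 = Read("p/2", rc, (10,) * 250)
        merged = merge_pairs(ReadPair(r1, r2))
        assert merged is not None
        assert merged.bases[pos] == corrupted[pos]  # r1's base retained

    def test_merged_quality_is_pairwise_max(self):
        fragment = _random_dna(260, seed=4)
        merged = merge_pairs(self._pair_from(fragment, 250, q1=20, q2=35))
        overlap = 2 * 250 - 260
        mid = merged.quals[250 - overlap : 250]
        assert set(mid) == {35}

    def test_monotone_efficiency_past_overlap_limit(self):
        """Merge success is non-increasing in fragment length at fixed 2x250."""
        rates = []
        for length in (450, 480, 492, 510, 540):
            merged = [
                merge_pairs(self._pair_from(_random_dna(length, seed=s), 250))
                for s in range(20)
            ]
            rates.append(sum(m is not None for m in merged) / 20)
        assert rates == sorted(rates, reverse=True)
        assert rates[0] == 1.0 and rates[-1] == 0.0


class TestFilterMergedSize:
    @pytest.mark.parametrize(
        "length,region,reason",
        [
            (462, "V1-3", "too_short"),
            (463, "V1-3", None),
            (553, "V1-3", None),
            (554, "V1-3", "too_long"),
            (299, "V4", "too_long"),
            (286, "V4", None),
        ],
    )
    def test_inclusive_window(self, length, region, reason):
        result = filter_merged_size(_read(_random_dna(length)), region, REFERENCE_SIZE_RANGES)
        assert result.reason == reason

    def test_unknown_region_is_error(self):
        with pytest.raises(KeyError):
            filter_merged_size(_read("ACGT"), "V5", REFERENCE_SIZE_RANGES)


class TestFilterPacbioCCS:
    FWD = DEFAULT_PRIMER_PAIRS["V1-9"].forward
    REV = DEFAULT_PRIMER_PAIRS["V1-9"].reverse

    def _ccs_read(self, n_after_primer: int, lead: str = "") -> Read:
        fwd_site = "AGAGTTTGATCCTGGCTCAG"  # concrete 27F site
        bases = lead + fwd_site + _random_dna(n_after_primer, seed=5)
        return _read(bases, id="ccs")

    def test_1299_bp_read_rejected(self):
        read = self._ccs_read(1299 - 20)
        assert len(read) == 1299
        assert filter_pacbio_ccs(read, self.FWD, self.REV) is None

    def test_1300_bp_read_accepted(self):
        read = self._ccs_read(1300 - 20)
        assert filter_pacbio_ccs(read, self.FWD, self.REV) is not None

    def test_internal_reverse_site_trims_read(self):
        rev_site = reverse_complement("AGTTACCTTGTTACGACTT")  # concrete 1492R site
        bases = "AGAGTTTGATCCTGGCTCAG" + _random_dna(1411, seed=6) + rev_site + _random_dna(150, seed=7)
        read = _read(bases, id="ccs")
        out = filter_pacbio_ccs(read, self.FWD, self.REV)
        assert out is not None and len(out) == 1450

    def test_missing_forward_primer_rejected(self):
        read = _read(_random_dna(1600, seed=8), id="ccs")
        assert filter_pacbio_ccs(read, self.FWD, self.REV) is None

    def test_output_has_no_internal_reverse_site(self):
        rev_site = reverse_complement("AGTTACCTTGTTACGACTT")
        bases = (
            "AGAGTTTGATCCTGGCTCAG"
            + _random_dna(1500, seed=9)
            + rev_site
            + _random_dna(300, seed=10)
            + rev_site
            + _random_dna(50, seed=11)
        )
        out = filter_pacbio_ccs(_read(bases, id="ccs"), self.FWD, self.REV, max_mismatch=0)
        assert out is not None
        internal = out.bases[:-len(rev_site)]
        assert rev_site not in internal


class TestFilterMiseq:
    def test_short_mate_fails_pair(self):
        pair = ReadPair(_read(_random_dna(149), id="a/1"), _read(_random_dna(250), id="a/2"))
        assert not filter_miseq(pair)

    def test_boundary_lengths_pass(self):
        pair = ReadPair(_read(_random_dna(150), id="a/1"), _read(_random_dna(150), id="a/2"))
        assert filter_miseq(pair)

    def test_trailing_n_trimmed_before_length_test(self):
        bases = _random_dna(148) + "NNNNN"
        pair = ReadPair(_read(bases, id="a/1"), _read(_random_dna(200), id="a/2"))
        result = filter_miseq(pair)
        assert not result and result.reason == "too_short"


class TestQCReport:
    def test_conservation_invariant(self):
        reads = [_read(_random_dna(250))] * 5 + [_read(_random_dna(100))] * 3
        reads += [_read("NNN" + _random_dna(250))] * 2
        _passed, report = run_flx_qc(reads)
        assert report.check_conservation()
        assert report.as_dict()["pass"] == 5
        assert report.fail_counts == {"too_short": 3, "ambiguous": 2}
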