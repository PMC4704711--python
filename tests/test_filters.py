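"""Zygosity calling, strain-specific filtering, spectra, lethal candidates."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mmcsig.filters import (
    DeletionRecord,
    SnvRecord,
    SpectrumCounts,
    call_zygosity,
    classify_snv_spectrum,
    compare_spectra_chisq,
    filter_strain_specific_deletions,
    filter_strain_specific_snvs,
    identify_lethal_candidates,
    reciprocal_overlap,
)


class TestCallZygosity:
    @pytest.mark.parametrize(
        "depth,variant,expected",
        [
            (20, 19, "hom"),     # 0.95 — clearly homozygous
            (20, 18, "hom"),     # 0.90 threshold is inclusive
            (20, 10, "het"),     # the balancer's ~50% signature
            (20, 7, "het"),      # 0.35 band edge
            (20, 13, "het"),     # 0.65 band edge
            (20, 15, "ambiguous"),
            (20, 2, "ref"),
            (20, 5, "ambiguous"),  # 0.25: between ref and het bands
        ],
    )
    def test_band_assignment(self, depth, variant, expected):
        assert call_zygosity(depth, variant) == expected

    def test_zero_depth_is_error(self):
        with pytest.raises(ValueError):
            call_zygosity(0, 0)


def snv(strain, pos, depth=20, alt_reads=20, chrom="chrI", ref="A", alt="G"):
    return SnvRecord(strain, chrom, pos, ref, alt, depth, alt_reads)


class TestFilterStrainSpecificSnvs:
    def test_unique_homozygous_retained(self):
        cohort = {"s1": [snv("s1", 100)], "s2": [snv("s2", 100, alt_reads=0)]}
        kept = filter_strain_specific_snvs(cohort)
        assert [r.pos for r in kept["s1"]] == [100]
        assert kept["s2"] == []

    def test_shared_site_removed_from_both(self):
        cohort = {"s1": [snv("s1", 100)], "s2": [snv("s2", 100)], "s3": []}
        kept = filter_strain_specific_snvs(cohort)
        assert kept["s1"] == [] and kept["s2"] == []

    def test_depth_threshold_is_strictly_greater_than_seven(self):
        cohort = {
            "s1": [snv("s1", 100, depth=7, alt_reads=7), snv("s1", 200, depth=8, alt_reads=8)],
            "s2": [],
        }
        kept = filter_strain_specific_snvs(cohort)
        assert [r.pos for r in kept["s1"]] == [200]

    def test_parental_variants_removed(self):
        cohort = {"s1": [snv("s1", 100)], "s2": []}
        kept = filter_strain_specific_snvs(cohort, parental=[snv("parental", 100)])
        assert kept["s1"] == []

    def test_non_homozygous_not_retained(self):
        cohort = {"s1": [snv("s1", 100, alt_reads=10)], "s2": []}
        assert filter_strain_specific_snvs(cohort)["s1"] == []

    def test_same_position_different_alt_is_distinct(self):
        cohort = {"s1": [snv("s1", 100, alt="G")], "s2": [snv("s2", 100, alt="T")]}
        kept = filter_strain_specific_snvs(cohort)
        assert len(kept["s1"]) == 1 and len(kept["s2"]) == 1

    def test_single_strain_cohort_rejected(self):
        with pytest.raises(ValueError):
            filter_strain_specific_snvs({"s1": []})


def deletion(strain, start, end, depth=20, support=20, chrom="chrI"):
    return DeletionRecord(strain, chrom, start, end, depth, support)


class TestFilterStrainSpecificDeletions:
    genome = {"chrI": "ACGTACGTGC" * 20 + "A" * 8 + "CGTACGTACG" * 20}

    def test_unique_deletion_retained_with_zygosity(self):
        cohort = {"s1": [deletion("s1", 5, 54)], "s2": []}
        kept = filter_strain_specific_deletions(cohort, genome=self.genome)
        assert len(kept["s1"]) == 1 and kept["s1"][0].zygosity_call == "hom"

    def test_shared_event_removed_by_reciprocal_overlap(self):
        # jittered coordinates, >= 80% reciprocal overlap: same event
        cohort = {"s1": [deletion("s1", 10, 109)], "s2": [deletion("s2", 13, 112)]}
        kept = filter_strain_specific_deletions(cohort, genome=self.genome)
        assert kept["s1"] == [] and kept["s2"] == []

    def test_distinct_events_kept_apart(self):
        cohort = {"s1": [deletion("s1", 10, 29)], "s2": [deletion("s2", 150, 169)]}
        kept = filter_strain_specific_deletions(cohort, genome=self.genome)
        assert len(kept["s1"]) == 1 and len(kept["s2"]) == 1

    def test_homopolymer_deletion_removed(self):
        # AAA deleted inside the 8-A run at positions 201-208
        cohort = {"s1": [deletion("s1", 203, 205)], "s2": []}
        assert filter_strain_specific_deletions(cohort, genome=self.genome)["s1"] == []

    def test_homopolymer_threshold_configurable(self):
        cohort = {"s1": [deletion("s1", 203, 205)], "s2": []}
        kept = filter_strain_specific_deletions(cohort, genome=self.genome, homopolymer_run=9)
        assert len(kept["s1"]) == 1

    def test_parental_match_removed(self):
        cohort = {"s1": [deletion("s1", 10, 59)], "s2": []}
        kept = filter_strain_specific_deletions(
            cohort, parental=[deletion("parental", 10, 59)], genome=self.genome
        )
        assert kept["s1"] == []

    def test_het_events_not_in_strain_specific_set(self):
        cohort = {"s1": [deletion("s1", 10, 59, support=10)], "s2": []}
        assert filter_strain_specific_deletions(cohort, genome=self.genome)["s1"] == []

    def test_out_of_reference_coordinates_rejected(self):
        cohort = {"s1": [deletion("s1", 10_000, 10_050)], "s2": []}
        assert filter_strain_specific_deletions(cohort, genome=self.genome)["s1"] == []

    def test_reciprocal_overlap_metric(self):
        a, b = deletion("a", 1, 100), deletion("b", 51, 150)
        assert reciprocal_overlap(a, b) == pytest.approx(0.5)
        assert reciprocal_overlap(a, deletion("b", 200, 300)) == 0.0


class TestSpectrum:
    @pytest.mark.parametrize(
        "ref,alt,cls",
        [
            ("G", "A", "G:C>A:T"),
            ("C", "T", "G:C>A:T"),  # reverse complement, same class
            ("A", "T", "A:T>T:A"),
            ("G", "C", "G:C>C:G"),
            ("A", "C", "A:T>C:G"),
            ("T", "C", "A:T>G:C"),
        ],
    )
    def test_class_assignment(self, ref, alt, cls):
        spec = classify_snv_spectrum([SnvRecord("s", "c", 1, ref, alt, 10, 10)])
        assert spec.counts[cls] == 1 and spec.total == 1

    @given(
        st.lists(
            st.tuples(st.sampled_from("ACGT"), st.sampled_from("ACGT")).filter(
                lambda t: t[0] != t[1]
            ),
            max_size=30,
        )
    )
    def test_total_conserved_and_revcomp_invariant(self, pairs):
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        fwd = classify_snv_spectrum(
            SnvRecord("s", "c", i + 1, r, a, 10, 10) for i, (r, a) in enumerate(pairs)
        )
        rev = classify_snv_spectrum(
            SnvRecord("s", "c", i + 1, comp[r], comp[a], 10, 10)
            for i, (r, a) in enumerate(pairs)
        )
        assert fwd.total == len(pairs)
        assert fwd.counts == rev.counts

    def test_identical_spectra_give_unit_p(self):
        spec = SpectrumCounts.from_array([10, 5, 8, 3, 7, 12])
        res = compare_spectra_chisq(spec, spec)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)
        assert res.df == 5

    def test_divergent_spectra_rejected(self):
        uniform = SpectrumCounts.from_array([10] * 6)
        skewed = SpectrumCounts.from_array([60, 0, 0, 0, 0, 0])
        res = compare_spectra_chisq(uniform, skewed)
        assert res.p_value < 0.05

    def test_empty_classes_dropped_with_df_adjusted(self):
        a = SpectrumCounts.from_array([10, 10, 0, 0, 0, 0])
        b = SpectrumCounts.from_array([8, 12, 0, 0, 0, 0])
        res = compare_spectra_chisq(a, b)
        assert res.df == 1

    def test_zero_total_is_error(self):
        with pytest.raises(ValueError):
            compare_spectra_chisq(SpectrumCounts(), SpectrumCounts.from_array([1] * 6))

    def test_low_expected_flagged(self):
        a = SpectrumCounts.from_array([2, 1, 1, 1, 1, 1])
        b = SpectrumCounts.from_array([1, 2, 1, 1, 1, 1])
        assert compare_spectra_chisq(a, b).low_expected


class TestLethalCandidates:
    interval = ("chrI", 1000, 5000)

    def make(self, zyg, start=2000, end=2400, strain="s1"):
        support = {"het": 10, "hom": 20, "ref": 0}[zyg]
        rec = DeletionRecord(strain, "chrI", start, end, 20, support, zygosity_call=zyg)
        return rec

    def test_het_unique_inside_interval_is_candidate(self):
        cands = identify_lethal_candidates([self.make("het")], self.interval)
        assert len(cands) == 1

    def test_homozygous_excluded(self):
        assert identify_lethal_candidates([self.make("hom")], self.interval) == []

    def test_outside_interval_excluded(self):
        rec = self.make("het", start=9000, end=9400)
        assert identify_lethal_candidates([rec], self.interval) == []

    def test_shared_with_cohort_excluded(self):
        rec = self.make("het")
        cohort = {"s1": [rec], "s2": [self.make("het", strain="s2")]}
        assert identify_lethal_candidates([rec], self.interval, cohort=cohort) == []

    def test_empty_interval_is_error(self):
        with pytest.raises(ValueError):
            identify_lethal_candidates([self.make("het")], ("chrI", 5000, 1000))
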