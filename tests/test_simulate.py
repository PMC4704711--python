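"""Synthetic-data generator: composition targets, truth integrity, read models."""

import numpy as np
import pytest

from mmcsig.context import dinucleotide_profile, extract_flanks, fold_enrichment, microhomology
from mmcsig.simulate import (
    SimConfig,
    SimulationError,
    default_dinuc_freqs,
    inject_deletions,
    simulate_brood,
    simulate_cohort,
    simulate_depth_track,
    simulate_genome,
)


class TestSimulateGenome:
    def test_fixed_seed_is_byte_identical(self):
        a = simulate_genome(5000, seed=7)
        b = simulate_genome(5000, seed=7)
        assert a.sequences == b.sequences
        assert set(a.sequences["chrI"]) <= set("ACGT")

    def test_tiny_genome_over_acgt(self):
        g = simulate_genome(6, np.full(16, 1 / 16), seed=3)
        assert len(g.sequences["chrI"]) == 6

    def test_length_below_two_rejected(self):
        with pytest.raises(ValueError):
            simulate_genome(1, seed=0)

    def test_realized_cg_tracks_low_target(self):
        """With a 1% CG target the emitted 100-kb sequence lands within ±0.003."""
        freqs = np.full(16, (1 - 0.01) / 15)
        freqs[6] = 0.01  # CG
        g = simulate_genome(100_000, freqs, seed=11)
        realized = dinucleotide_profile(g.sequences["chrI"]).proportion("CG")
        assert realized == pytest.approx(0.01, abs=0.003)

    def test_default_composition_is_cpg_depleted(self):
        g = simulate_genome(100_000, default_dinuc_freqs(), seed=5)
        prof = dinucleotide_profile(g.sequences["chrI"])
        assert prof.proportion("CG") < 0.02
        assert prof.proportion("AA") > prof.proportion("CG")

    def test_non_normalizable_frequencies_rejected(self):
        freqs = np.zeros(16)
        freqs[0] = 0.5  # AA
        freqs[1] = 0.5  # AC: C entered but never left
        with pytest.raises(ValueError, match="never left"):
            simulate_genome(100, freqs, seed=0)

    def test_invalid_frequency_vector_rejected(self):
        with pytest.raises(ValueError):
            simulate_genome(100, np.full(16, 1.0), seed=0)


class TestInjectDeletions:
    def make_config(self, **kw):
        base = dict(
            genome_length=200_000, n_strains=2, n_deletions_per_strain=30,
            deletion_size_dist=("fixed", {"size": 50}),
            mh_length_dist=("fixed", {"length": 0}),
            n_het_deletions_per_strain=0, cpg_bias=1.0, seed=0,
        )
        base.update(kw)
        return SimConfig(**base)

    def test_engineered_microhomology_is_lower_bound(self):
        g = simulate_genome(200_000, seed=3)
        cfg = self.make_config(mh_length_dist=("fixed", {"length": 5}))
        edited, truth = inject_deletions(g, cfg, rng=7)
        for d in truth:
            ctx = extract_flanks(edited, d.chrom, d.start, d.end, k=25)
            assert microhomology(ctx).five_prime_len >= 5
            assert d.engineered_mh == 5

    def test_deletions_do_not_overlap(self):
        g = simulate_genome(200_000, seed=3)
        _, truth = inject_deletions(g, self.make_config(), rng=1)
        intervals = sorted((d.start, d.end) for d in truth)
        assert all(b[0] > a[1] for a, b in zip(intervals, intervals[1:]))
        assert len(truth) == 60

    def test_unbiased_placement_has_unit_enrichment(self):
        g = simulate_genome(1_000_000, seed=11)
        cfg = self.make_config(genome_length=1_000_000, n_strains=1, n_deletions_per_strain=200)
        edited, truth = inject_deletions(g, cfg, rng=5)
        deleted = [edited.fetch(d.chrom, d.start, d.end) for d in truth]
        background = dinucleotide_profile(edited.sequences["chrI"])
        fold = fold_enrichment(dinucleotide_profile(deleted), background)
        assert fold == pytest.approx(1.0, abs=0.2)

    def test_biased_placement_enriches_cpg(self):
        g = simulate_genome(1_000_000, seed=11)
        cfg = self.make_config(genome_length=1_000_000, n_strains=1,
                               n_deletions_per_strain=200, cpg_bias=10.0)
        edited, truth = inject_deletions(g, cfg, rng=5)
        deleted = [edited.fetch(d.chrom, d.start, d.end) for d in truth]
        fold = fold_enrichment(
            dinucleotide_profile(deleted), dinucleotide_profile(edited.sequences["chrI"])
        )
        assert fold > 1.2

    def test_oversized_deletion_is_simulation_error(self):
        g = simulate_genome(1000, seed=0)
        cfg = self.make_config(genome_length=1000, n_strains=1, n_deletions_per_strain=1,
                               deletion_size_dist=("fixed", {"size": 5000}))
        with pytest.raises(SimulationError):
            inject_deletions(g, cfg, rng=0)

    def test_crowded_genome_exhausts_retries(self):
        g = simulate_genome(2000, seed=0)
        cfg = self.make_config(genome_length=2000, n_strains=1, n_deletions_per_strain=50,
                               deletion_size_dist=("fixed", {"size": 400}))
        with pytest.raises(SimulationError):
            inject_deletions(g, cfg, rng=0)


class TestStrainTables:
    def test_homozygous_sites_concentrate_near_one(self, noiseless_cohort):
        sim = noiseless_cohort
        own = {(t.strain, t.pos) for t in sim.truth.snvs}
        for strain, records in sim.snv_tables.items():
            for r in records:
                f = r.alt_reads / r.depth
                if (strain, r.pos) in own or r.pos in {t.pos for t in sim.truth.shared_snvs}:
                    assert f == 1.0  # error-free, fixed depth
                else:
                    assert f == 0.0

    def test_heterozygous_deletions_concentrate_near_half(self):
        cfg = SimConfig(seed=8, genome_length=200_000, n_strains=4, n_deletions_per_strain=10,
                        n_het_deletions_per_strain=10, n_snvs_per_strain=0,
                        deletion_size_dist=("uniform", {"low": 10, "high": 100}),
                        mean_depth=200.0, track_breakpoint=100_001)
        sim = simulate_cohort(cfg)
        fracs = [r.supporting_reads / r.depth for recs in sim.del_tables.values() for r in recs]
        assert np.mean(fracs) == pytest.approx(0.5, abs=0.02)
        assert all(0.3 < f < 0.7 for f in fracs)

    def test_parental_table_holds_only_shared_background(self, noiseless_cohort):
        sim = noiseless_cohort
        shared_pos = {t.pos for t in sim.truth.shared_snvs}
        assert {r.pos for r in sim.parental_snvs} == shared_pos

    def test_cohort_is_deterministic_under_seed(self):
        cfg = dict(seed=21, genome_length=50_000, n_strains=2, n_deletions_per_strain=3,
                   n_snvs_per_strain=4, deletion_size_dist=("uniform", {"low": 5, "high": 50}),
                   track_breakpoint=25_000)
        a, b = simulate_cohort(SimConfig(**cfg)), simulate_cohort(SimConfig(**cfg))
        assert a.genome.sequences == b.genome.sequences
        assert a.truth.deletions == b.truth.deletions
        assert a.truth.snvs == b.truth.snvs
        assert [vars(r) for recs in a.snv_tables.values() for r in recs] == \
               [vars(r) for recs in b.snv_tables.values() for r in recs]
        assert np.array_equal(a.depth_track.means, b.depth_track.means)
        assert a.broods == b.broods


class TestDepthTrackSimulation:
    def test_noiseless_track_is_exact(self):
        track, truth_bin = simulate_depth_track(100_000, 5000, 50_001, 0.5, 30.0, sigma=0.0, seed=0)
        assert truth_bin == 10
        assert np.allclose(track.means[:10], 30.0)
        assert np.allclose(track.means[10:], 15.0)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            simulate_depth_track(1000, 0, 500, 0.5, 30.0)
        with pytest.raises(ValueError):
            simulate_depth_track(1000, 100, 500, 0.0, 30.0)
        with pytest.raises(ValueError):
            simulate_depth_track(1000, 100, 5000, 0.5, 30.0)


class TestSimulateBrood:
    def test_no_recombination_gives_no_dpy_unc(self):
        for seed in range(5):
            brood = simulate_brood(0.0, 10_000, seed=seed)
            assert brood.dpy_unc == 0
            assert brood.wt > 0

    def test_free_recombination_viable_fraction(self):
        """At p = 0.5 the viable Dpy-Unc zygote fraction is p/2 - p^2/4 = 3/16."""
        brood = simulate_brood(0.5, 200_000, seed=4)
        assert brood.dpy_unc / 200_000 == pytest.approx(3 / 16, abs=0.005)

    def test_survivors_exclude_dead_zygotes(self):
        p = 0.1
        brood = simulate_brood(p, 100_000, seed=0)
        survivors = brood.wt + brood.dpy_unc + brood.dpy + brood.unc
        expected = 100_000 * (1 - ((1 - p) / 2) ** 2)
        assert survivors == pytest.approx(expected, rel=0.01)

    def test_out_of_domain_p_rejected(self):
        with pytest.raises(ValueError):
            simulate_brood(0.6, 100)
        with pytest.raises(ValueError):
            simulate_brood(-0.01, 100)


class TestSimConfigValidation:
    def test_frequency_sum_enforced(self):
        bad = np.full(16, 1 / 16)
        bad[0] += 1e-3
        with pytest.raises(ValueError):
            SimConfig(dinuc_freqs=bad)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_strains=-1)

    def test_depth_and_bias_bounds(self):
        with pytest.raises(ValueError):
            SimConfig(mean_depth=0.0)
        with pytest.raises(ValueError):
            SimConfig(cpg_bias=0.5)
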