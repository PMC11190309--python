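import dataclasses

import numpy as np
import pytest
from scipy import stats

import niptcnv as nc
from niptcnv.simulate import CnvTruth, CohortSpec, expected_bin_intensity


class TestIntensityModel:
    @pytest.mark.parametrize("kind,origin,ff,factor", [
        ("deletion", "fetal", 0.20, 0.90),        # 1 - ff/2
        ("deletion", "fetal", 0.0, 1.0),          # no fetal signal at ff=0
        ("duplication", "maternal", 0.10, 1.45),  # 1 + (1-ff)/2
        ("duplication", "placental_only", 0.20, 1.10),
    ])
    def test_heterozygous_dosage_factors(self, mini_genome, kind, origin, ff,
                                         factor):
        truth = CnvTruth("1", 1_000_000, 2_000_000, kind, origin)
        base = expected_bin_intensity(mini_genome, [], ff, gc_bias_amplitude=0)
        with_cnv = expected_bin_intensity(mini_genome, [truth], ff,
                                          gc_bias_amplitude=0)
        sl = mini_genome.chrom_slice("1")
        inside = slice(sl.start + 50, sl.start + 100)
        assert np.allclose(with_cnv[inside] / base[inside], factor)
        # outside the segment the baseline is untouched
        assert np.allclose(with_cnv[sl.start + 200:sl.start + 300],
                           base[sl.start + 200:sl.start + 300])

    def test_overlapping_segments_multiply(self, mini_genome):
        a = CnvTruth("1", 1_000_000, 3_000_000, "duplication", "fetal")
        b = CnvTruth("1", 2_000_000, 4_000_000, "duplication", "maternal")
        inten = expected_bin_intensity(mini_genome, [a, b], 0.2,
                                       gc_bias_amplitude=0)
        sl = mini_genome.chrom_slice("1")
        overlap_bin = sl.start + 110  # inside both
        assert np.isclose(inten[overlap_bin], (1 + 0.1) * (1 + 0.4))

    def test_off_genome_truth_rejected(self, mini_genome):
        bad = CnvTruth("1", 55_000_000, 65_000_000, "deletion")
        with pytest.raises(ValueError):
            expected_bin_intensity(mini_genome, [bad], 0.1)

    def test_male_fetus_sex_chromosome_dosage(self, mini_genome):
        inten = expected_bin_intensity(mini_genome, [], 0.2, "male",
                                       gc_bias_amplitude=0)
        x, y = mini_genome.chrom_slice("X"), mini_genome.chrom_slice("Y")
        assert np.allclose(inten[x], 0.9)   # (1-ff) + ff/2
        assert np.allclose(inten[y], 0.1)   # ff/2


class TestBinCounts:
    def test_poisson_mean_matches_uniform_intensity(self, mini_genome):
        inten = np.ones(mini_genome.n_bins)
        counts = nc.simulate_bin_counts(inten, 3_500_000, 1)
        mean = counts.mean()
        expected = 3_500_000 / mini_genome.n_bins
        se = np.sqrt(expected / mini_genome.n_bins)
        assert abs(mean - expected) < 3 * se

    def test_doubling_reads_doubles_mean(self, mini_genome):
        inten = np.ones(mini_genome.n_bins)
        m1 = nc.simulate_bin_counts(inten, 1_000_000, 2).mean()
        m2 = nc.simulate_bin_counts(inten, 2_000_000, 3).mean()
        assert abs(m2 / m1 - 2.0) < 0.02

    def test_seed_determinism(self):
        inten = np.ones(1000)
        assert np.array_equal(nc.simulate_bin_counts(inten, 10_000, 9),
                              nc.simulate_bin_counts(inten, 10_000, 9))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            nc.simulate_bin_counts(np.zeros(10), 100, 0)
        with pytest.raises(ValueError):
            nc.simulate_bin_counts(np.ones(10), 0, 0)

    def test_euploid_dispersion_near_one(self, mini_genome):
        """Poisson counts at mean >= 20: index of dispersion 1 +/- 0.1."""
        inten = expected_bin_intensity(mini_genome, [], 0.15,
                                       gc_bias_amplitude=0)
        auto = mini_genome.autosome_bin_mask
        counts = nc.simulate_bin_counts(inten, 3_500_000, 5)[auto]
        disp = counts.var() / counts.mean()
        assert counts.mean() >= 20
        assert 0.9 < disp < 1.1

    def test_duplication_region_enriched(self, mini_genome):
        """Mean count in a 1,000-bin fetal duplication exceeds baseline
        (one-sided Poisson test at alpha=0.001)."""
        truth = CnvTruth("3", 10_000_000, 30_000_000, "duplication", "fetal")
        inten = expected_bin_intensity(mini_genome, [truth], 0.2,
                                       gc_bias_amplitude=0)
        counts = nc.simulate_bin_counts(inten, 3_500_000, 11)
        sl = mini_genome.chrom_slice("3")
        region = counts[sl.start + 500:sl.start + 1500]
        baseline = counts[mini_genome.chrom_slice("1")].mean()
        z = (region.mean() - baseline) / np.sqrt(baseline / region.size)
        assert z > stats.norm.isf(0.001)


class TestCohort:
    def test_counts_conservation_and_determinism(self, mini_genome):
        spec = nc.euploid_spec(5, seed=42)
        c1 = nc.simulate_cohort(spec, mini_genome)
        c2 = nc.simulate_cohort(spec, mini_genome)
        for a, b in zip(c1, c2):
            assert a.total_reads == int(a.counts.sum())  # conservation
            assert np.array_equal(a.counts, b.counts)    # bit-identical
            assert a.fetal_fraction == b.fetal_fraction

    def test_zero_prevalence_all_euploid(self, mini_genome):
        cohort = nc.simulate_cohort(nc.euploid_spec(50, seed=1), mini_genome,
                                    with_counts=False)
        assert all(not s.truth for s in cohort)

    def test_empty_cohort_allowed(self, mini_genome):
        assert nc.simulate_cohort(nc.euploid_spec(0, seed=1), mini_genome) == []

    def test_post_era_ff_matches_cohort_mean(self, mini_genome):
        """200 post-era samples: empirical ff mean ~= 18.44% within 3 SE."""
        spec = dataclasses.replace(nc.euploid_spec(200, seed=77),
                                   era_pre_fraction=0.0)
        cohort = nc.simulate_cohort(spec, mini_genome, with_counts=False)
        ffs = np.array([s.fetal_fraction for s in cohort])
        assert abs(ffs.mean() - 0.1844) < 3 * 0.058 / np.sqrt(200)

    def test_deletion_share_matches_weights(self, mini_genome):
        """del:dup drawn 193:88 -> deletion share ~68.7% among positives."""
        spec = dataclasses.replace(CohortSpec(n_samples=600, seed=13),
                                   cnv_prevalence=1.0)
        cohort = nc.simulate_cohort(spec, mini_genome, with_counts=False)
        kinds = [s.truth[0].kind for s in cohort if s.truth]
        share = np.mean([k == "deletion" for k in kinds])
        se = np.sqrt(0.687 * 0.313 / len(kinds))
        assert abs(share - 193 / 281) < 3 * se

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(cnv_prevalence=1.5)
        with pytest.raises(ValueError):
            CohortSpec(size_weights={"~1": 0.5})  # weights must sum to 1


class TestCnvTruth:
    def test_size_and_validation(self):
        t = CnvTruth("1", 1_000_000, 3_500_000, "deletion")
        assert t.size == 2_500_000 and t.size_mb == 2.5
        assert t.copy_state == 1  # default heterozygous
        with pytest.raises(ValueError):
            CnvTruth("1", 5, 5, "deletion")
        with pytest.raises(ValueError):
            CnvTruth("1", 0, 10, "inversion")

    def test_placental_only_leaves_fetus_unaffected(self):
        t = CnvTruth("1", 0, 10_000_000, "duplication", "placental_only")
        assert not t.fetal_affected
        assert CnvTruth("1", 0, 10_000_000, "duplication", "fetal").fetal_affected
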