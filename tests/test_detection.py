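import dataclasses

import numpy as np
import pytest

import niptcnv as nc
from niptcnv.detection import (CallerParams, ZProfile, call_aneuploidy,
                               call_cnv, compute_chr_ratio, gc_correct,
                               size_stratum, zscore)
from niptcnv.genome import build_genome
from niptcnv.simulate import (CnvTruth, expected_bin_intensity,
                              simulate_bin_counts)


class TestChrRatio:
    def test_direct_division_on_two_autosomes(self):
        g = build_genome({"1": 1_000_000, "2": 1_000_000}, bin_size=100_000)
        counts = np.concatenate([np.full(10, 30), np.full(10, 70)])
        p = compute_chr_ratio(counts, g)
        assert p.chrom_pct["1"] == pytest.approx(30.0)
        assert p.chrom_pct["2"] == pytest.approx(70.0)

    def test_all_reads_on_one_chromosome(self):
        g = build_genome({c: 1_000_000 for c in "1234"}, bin_size=100_000)
        counts = np.zeros(40)
        counts[:10] = 5
        p = compute_chr_ratio(counts, g)
        assert p.chrom_pct["1"] == 100.0
        assert p.chrom_pct["2"] == 0.0

    def test_equal_counts_across_22_autosomes(self):
        g = build_genome({str(i): 2_000_000 for i in range(1, 23)},
                         bin_size=100_000)
        p = compute_chr_ratio(np.ones(g.n_bins), g)
        assert p.chrom_pct["7"] == pytest.approx(100 / 22, abs=1e-9)
        assert round(p.chrom_pct["7"], 4) == 4.5455

    def test_autosomal_percentages_sum_to_100(self, mini_genome):
        rng = np.random.default_rng(0)
        counts = rng.poisson(20, mini_genome.n_bins)
        p = compute_chr_ratio(counts, mini_genome)
        total = sum(v for k, v in p.chrom_pct.items() if k not in ("X", "Y"))
        assert total == pytest.approx(100.0, abs=1e-9)

    def test_zero_autosomal_total_rejected(self, mini_genome):
        with pytest.raises(ValueError):
            compute_chr_ratio(np.zeros(mini_genome.n_bins), mini_genome)


class TestGcCorrection:
    def test_no_bias_gives_identity_curve(self, mini_genome):
        spec = nc.euploid_spec(30, seed=55, gc_bias_amplitude=0.0)
        panel = nc.build_panel(nc.simulate_cohort(spec, mini_genome),
                               mini_genome)
        auto = mini_genome.autosome_bin_mask
        factors, _ = panel.gc_curve.predict(mini_genome.gc[auto])
        assert np.abs(factors - 1.0).max() < 0.01

    def test_bias_slope_removed(self, mini_genome, euploid_cohort,
                                reference_panel):
        """With a +/-5% GC bias, the corrected bin means have <10% of the
        raw slope against GC."""
        auto = mini_genome.autosome_bin_mask
        gc = mini_genome.gc[auto]
        ratios = np.vstack([compute_chr_ratio(s.counts, mini_genome).bin_ratio[auto]
                            for s in euploid_cohort])
        raw_mean = ratios.mean(axis=0)
        corr = np.vstack([gc_correct(r, gc, reference_panel.gc_curve)[0]
                          for r in ratios]).mean(axis=0)
        slope_raw = np.polyfit(gc, raw_mean, 1)[0]
        slope_corr = np.polyfit(gc, corr, 1)[0]
        assert abs(slope_corr) < 0.1 * abs(slope_raw)

    def test_median_correction_factor_is_one(self, mini_genome,
                                             reference_panel):
        auto = mini_genome.autosome_bin_mask
        factors, _ = reference_panel.gc_curve.predict(mini_genome.gc[auto])
        assert abs(np.median(factors) - 1.0) < 0.01

    def test_out_of_range_gc_flagged(self, reference_panel):
        _, flagged = gc_correct(np.array([1.0, 1.0]), np.array([0.9, 0.41]),
                                reference_panel.gc_curve)
        assert flagged[0] and not flagged[1]

    def test_single_bin_passthrough_with_warning(self, reference_panel):
        with pytest.warns(UserWarning, match="single-bin"):
            out, _ = gc_correct(np.array([2.5]), np.array([0.4]),
                                reference_panel.gc_curve)
        assert out[0] == 2.5


class TestReferencePanel:
    def test_single_sample_panel_rejected(self, mini_genome, euploid_cohort):
        with pytest.raises(ValueError):
            nc.build_panel(euploid_cohort[:1], mini_genome)

    def test_identical_samples_floored_sd(self, mini_genome, euploid_cohort):
        twins = [euploid_cohort[0],
                 dataclasses.replace(euploid_cohort[0], sample_id="copy")]
        panel = nc.build_panel(twins, mini_genome)
        auto = mini_genome.autosome_bin_mask
        assert np.all(panel.bin_sd[auto] > 0)  # floor engaged everywhere
        with pytest.raises(ValueError):
            nc.build_panel(twins, mini_genome, sd_floor_frac=None)

    def test_panel_mean_matches_generative_expectation(self, mini_genome,
                                                       reference_panel,
                                                       euploid_cohort):
        inten = expected_bin_intensity(mini_genome, [], 0.15, "female")
        auto = mini_genome.autosome_bin_mask
        for i, name in enumerate(mini_genome.autosome_names):
            sl = mini_genome.chrom_slice(name)
            expected = inten[sl].sum() / inten[auto].sum() * 100
            m, s = reference_panel.chrom_stats(name)
            se = s / np.sqrt(len(euploid_cohort))
            assert abs(m - expected) < 3 * se

    def test_json_roundtrip(self, tmp_path, reference_panel):
        path = tmp_path / "panel.json"
        reference_panel.to_json(path)
        back = nc.ReferencePanel.from_json(path)
        assert np.allclose(back.chrom_mean, reference_panel.chrom_mean)
        assert np.allclose(back.bin_sd, reference_panel.bin_sd,
                           equal_nan=True)


class TestZScore:
    def test_panel_mean_sample_scores_zero(self, mini_genome, euploid_cohort,
                                           reference_panel):
        p = compute_chr_ratio(euploid_cohort[0].counts, mini_genome)
        mean_profile = dataclasses.replace(
            p, chrom_pct={n: reference_panel.chrom_stats(n)[0]
                          for n in mini_genome.chrom_names})
        zp = zscore(mean_profile, reference_panel, mini_genome)
        assert all(v == pytest.approx(0.0) for v in zp.chrom_z.values())

    def test_loo_null_mean_zero_sd_one(self, mini_genome):
        """Leave-one-out Z over a 100-sample euploid panel: empirically
        mean ~ 0 and SD ~ 1 within 3 SE."""
        cohort = nc.simulate_cohort(nc.euploid_spec(100, seed=31), mini_genome)
        pct = np.array([[compute_chr_ratio(s.counts, mini_genome).chrom_pct[c]
                         for c in mini_genome.autosome_names]
                        for s in cohort])
        z = nc.loo_zscores(pct)
        n = z.size
        assert abs(z.mean()) < 3 / np.sqrt(n)
        assert abs(z.std() - 1.0) < 3 / np.sqrt(2 * n)

    def test_missing_panel_unit_rejected(self, mini_genome, euploid_cohort,
                                         reference_panel):
        p = compute_chr_ratio(euploid_cohort[0].counts, mini_genome)
        small = dataclasses.replace(reference_panel,
                                    chrom_names=("1", "2", "3"))
        with pytest.raises(KeyError):
            zscore(p, small, mini_genome)


class TestAneuploidyCalls:
    def test_strict_threshold(self):
        zp = ZProfile("s", {"1": 3.01, "2": 3.00, "3": -3.2, "4": 0.5},
                      np.empty(0))
        flags = dict(call_aneuploidy(zp))
        assert flags == {"1": "gain", "3": "loss"}  # 3.00 exactly: negative

    def test_all_below_threshold_empty(self):
        zp = ZProfile("s", {"1": 2.9, "2": -2.99}, np.empty(0))
        assert call_aneuploidy(zp) == []

    def test_sex_chromosomes_excluded_by_default(self):
        zp = ZProfile("s", {"1": 1.0, "X": 5.0, "Y": -8.0}, np.empty(0))
        assert call_aneuploidy(zp) == []


class TestCnvCalls:
    def test_strong_deletion_called_with_sign_and_stratum(self, mini_genome,
                                                          reference_panel):
        truth = CnvTruth("2", 10_000_000, 20_000_000, "deletion", "fetal")
        inten = expected_bin_intensity(mini_genome, [truth], 0.18, "female")
        counts = simulate_bin_counts(inten, 3_500_000, 77)
        zp = zscore(compute_chr_ratio(counts, mini_genome), reference_panel,
                    mini_genome)
        calls = call_cnv(zp, mini_genome)
        match = [c for c in calls if c.chrom == "2"]
        assert len(match) == 1
        c = match[0]
        assert c.kind == "deletion" and c.mean_z < 0 and c.stouffer_z < 0
        assert c.stratum == "10-20"
        assert abs(c.start - truth.start) <= 3 * mini_genome.bin_size
        assert abs(c.end - truth.end) <= 3 * mini_genome.bin_size

    def test_duplication_sign(self, mini_genome, reference_panel):
        truth = CnvTruth("3", 5_000_000, 15_000_000, "duplication", "fetal")
        inten = expected_bin_intensity(mini_genome, [truth], 0.18, "female")
        counts = simulate_bin_counts(inten, 3_500_000, 78)
        zp = zscore(compute_chr_ratio(counts, mini_genome), reference_panel,
                    mini_genome)
        dups = [c for c in call_cnv(zp, mini_genome) if c.chrom == "3"]
        assert dups and all(c.kind == "duplication" and c.stouffer_z > 0
                            for c in dups)

    def test_typical_euploid_sample_has_no_calls(self, mini_genome,
                                                 reference_panel):
        cohort = nc.simulate_cohort(nc.euploid_spec(20, seed=301), mini_genome)
        n_calls = sum(
            len(call_cnv(zscore(compute_chr_ratio(s.counts, mini_genome,
                                                  s.sample_id),
                                reference_panel, mini_genome), mini_genome))
            for s in cohort)
        assert n_calls <= 2  # family-wise false-call rate at the % level

    def test_size_strata_assignment(self):
        assert size_stratum(4.99) == "0-5"
        assert size_stratum(5.0) == "5-10"
        assert size_stratum(19.99) == "10-20"
        assert size_stratum(20.0) == ">=20"
        with pytest.raises(ValueError):
            size_stratum(-1.0)


class TestPowerMonotonicity:
    def test_power_nondecreasing_in_ff_size_and_reads(self):
        """Detection power over a (ff x size x reads) grid is nondecreasing
        along each axis, up to paired binomial noise (150 reps/cell on a
        1,000-bin single-chromosome genome)."""
        g = build_genome({"1": 20_000_000}, seed=2)
        reps = 150
        ffs, sizes, reads_list = (0.10, 0.14, 0.18), (1.0, 2.0, 5.0), \
            (24_300, 48_600)
        panels = {r: nc.build_euploid_panel(g, 60, seed=8_000 + r,
                                            total_reads=r)
                  for r in reads_list}
        power = {}
        for r in reads_list:
            for ff in ffs:
                for mb in sizes:
                    truth = CnvTruth("1", 8_000_000,
                                     8_000_000 + int(mb * 1e6), "deletion")
                    hits = 0
                    root = np.random.SeedSequence(
                        [17, r, int(ff * 100), int(mb * 10)])
                    for ss in root.spawn(reps):
                        rng = np.random.default_rng(ss)
                        inten = expected_bin_intensity(g, [truth], ff,
                                                       "female")
                        counts = simulate_bin_counts(inten, r, rng)
                        zp = zscore(compute_chr_ratio(counts, g), panels[r], g)
                        hits += any(c.kind == "deletion"
                                    and c.start < truth.end
                                    and truth.start < c.end
                                    for c in call_cnv(zp, g))
                    power[(r, ff, mb)] = hits / reps
        slack = 3 * np.sqrt(0.25 / reps)
        for r in reads_list:
            for mb in sizes:
                assert power[(r, 0.14, mb)] >= power[(r, 0.10, mb)] - slack
                assert power[(r, 0.18, mb)] >= power[(r, 0.14, mb)] - slack
            for ff in ffs:
                assert power[(r, ff, 2.0)] >= power[(r, ff, 1.0)] - slack
                assert power[(r, ff, 5.0)] >= power[(r, ff, 2.0)] - slack
        for ff in ffs:
            for mb in sizes:
                assert power[(48_600, ff, mb)] >= power[(24_300, ff, mb)] - slack


class TestFetalFractionEstimate:
    def test_male_recovery_within_tolerance(self, mini_genome):
        ests = []
        for r in range(150):
            inten = expected_bin_intensity(mini_genome, [], 0.15, "male")
            counts = simulate_bin_counts(inten, 3_500_000, 4_000 + r)
            est, flag = nc.estimate_fetal_fraction(counts, mini_genome, "male")
            assert flag == "ok"
            ests.append(est)
        assert abs(np.mean(ests) - 0.15) < 0.03

    def test_female_passthrough_flagged(self, mini_genome):
        est, flag = nc.estimate_fetal_fraction(np.ones(mini_genome.n_bins),
                                               mini_genome, "female",
                                               truth_ff=0.12)
        assert est == 0.12 and flag == "not_estimated"

    def test_zero_ff_male_estimates_near_zero(self, mini_genome):
        inten = expected_bin_intensity(mini_genome, [], 0.0, "male")
        counts = simulate_bin_counts(inten, 3_500_000, 5)
        est, _ = nc.estimate_fetal_fraction(counts, mini_genome, "male")
        assert est == pytest.approx(0.0, abs=1e-6)
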