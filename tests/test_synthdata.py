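"""Generator contracts: determinism, cohort structure, lesion and noise models."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tbiharm import (CohortConfig, generate_cohort, generate_univariate_counts)


class TestCohortStructure:
    def test_default_design_yields_two_scans_per_subject(self):
        cfg = CohortConfig(shape=(12, 10, 14), seed=0)
        cohort = generate_cohort(cfg)
        n_subjects = sum(cfg.sham_counts) + sum(cfg.tbi_counts)
        assert n_subjects == 186
        assert len(cohort.metadata) == 2 * n_subjects
        # per-site group sizes match the configured design
        counts = cohort.metadata.groupby(["site", "group", "day"]).size()
        assert counts.loc[(1, "sham", 3)] == 17
        assert counts.loc[(4, "tbi", 30)] == 27

    def test_metadata_domains_and_uniqueness(self, small_cohort):
        meta = small_cohort.metadata
        assert meta["scan_id"].is_unique
        assert set(meta["group"]) <= {"sham", "tbi"}
        assert set(meta["sex"]) <= {"M", "F"}
        assert set(meta["day"]) <= {3, 30}
        assert np.isfinite(small_cohort.scans[:, small_cohort.mask]).all()

    def test_determinism_bit_identical(self, small_config):
        a = generate_cohort(small_config)
        b = generate_cohort(small_config)
        assert np.array_equal(a.scans, b.scans)
        pd.testing.assert_frame_equal(a.metadata, b.metadata)

    def test_different_seed_changes_data(self, small_config, small_cohort):
        import dataclasses
        other = dataclasses.replace(small_config, seed=small_config.seed + 1)
        assert not np.array_equal(generate_cohort(other).scans,
                                  small_cohort.scans)

    def test_dropout_removes_scans(self, small_config):
        import dataclasses
        cfg = dataclasses.replace(small_config, dropout_rate=0.3)
        dropped = generate_cohort(cfg)
        full = generate_cohort(small_config)
        assert len(dropped.metadata) < len(full.metadata)

    def test_baseline_field_levels(self, clean_cohort):
        """Sham scans: band voxels near 0.6, tissue near 0.25 at site 1 (no effects)."""
        sham1 = clean_cohort.site_scans(1, group="sham")
        mean_map = sham1.mean(axis=0)
        inside = mean_map[clean_cohort.mask]
        assert 0.2 < np.median(inside) < 0.45
        assert 0.5 < inside.max() < 0.7

    def test_invalid_configs_error(self):
        with pytest.raises(ValueError, match="sham counts"):
            CohortConfig(sham_counts=(1, 4, 4, 4))
        with pytest.raises(ValueError, match="scale"):
            CohortConfig(site_scales=(0.0, 1, 1, 1))
        with pytest.raises(ValueError, match="shape"):
            CohortConfig(shape=(0, 4, 4))

    def test_lesion_outside_brain_errors(self):
        cfg = CohortConfig(shape=(16, 12, 16), sham_counts=(2, 2, 2, 2),
                           tbi_counts=(2, 2, 2, 2),
                           lesion_center=(0, 0, 0), seed=1)
        with pytest.raises(ValueError, match="lesion not in brain"):
            generate_cohort(cfg)


class TestLesionModel:
    def test_lesion_reduces_signal_monotonically_with_atrophy(self):
        """Mean in-lesion value of injured scans decreases with atrophy."""
        cfg = CohortConfig(n_sites=2, shape=(20, 16, 24),
                          sham_counts=(4, 4), tbi_counts=(12, 12),
                          site_offsets=(0.0, 0.0), site_scales=(1.0, 1.0),
                          hemisphere=("left", "left"),
                          outlier_site=None, noise_sd=0.01,
                          subject_sd=0.0, seed=2)
        cohort = generate_cohort(cfg)
        meta = cohort.metadata
        tbi = meta[(meta["group"] == "tbi") & (meta["day"] == 3)]
        core = cohort.lesion_mask
        means = [cohort.scans[i][core].mean() for i in tbi.index]
        rho = stats.spearmanr(tbi["atrophy"], means).statistic
        assert rho < -0.9

    def test_day_effect_scales_lesion(self):
        cfg = CohortConfig(n_sites=2, shape=(20, 16, 24),
                          sham_counts=(4, 4), tbi_counts=(10, 10),
                          site_offsets=(0.0, 0.0), site_scales=(1.0, 1.0),
                          hemisphere=("left", "left"),
                          outlier_site=None, noise_sd=0.005,
                          subject_sd=0.0, seed=3)
        cohort = generate_cohort(cfg)
        meta = cohort.metadata
        core = cohort.lesion_mask
        m3 = cohort.scans[np.asarray((meta.group == "tbi")
                                     & (meta.day == 3))][:, core].mean()
        m30 = cohort.scans[np.asarray((meta.group == "tbi")
                                      & (meta.day == 30))][:, core].mean()
        assert m3 < m30  # partial recovery at day 30 (smaller FA drop)


class TestOutlierSite:
    def test_heavy_tailed_site_has_high_kurtosis_and_outliers(self):
        from tbiharm import excess_kurtosis, outlier_screen
        cfg = CohortConfig(shape=(20, 16, 24), sham_counts=(6, 6, 6, 6),
                          tbi_counts=(8, 8, 8, 8), seed=4)
        cohort = generate_cohort(cfg)
        vals = {s: cohort.site_scans(s)[:, cohort.mask]
                for s in (1, 2, 3, 4)}
        assert excess_kurtosis(vals[4].ravel()) > 0.4
        report = outlier_screen(vals, mode="per-voxel")
        assert report.proportions[4] > 0.05
        assert all(report.proportions[s] < 0.05 for s in (1, 2, 3))

    def test_null_config_sites_exchangeable(self):
        """Zero site effects: KS across sites rejects at the nominal rate.

        Subject-level random offsets are switched off here: with a handful
        of subjects per site those offsets make the site value distributions
        genuinely differ, which is real (finite-subject) signal rather than
        a miscalibration of the test.
        """
        from tbiharm.pipeline import site_value_samples
        rejections = 0
        reps = 120
        for seed in range(reps):
            cfg = CohortConfig(n_sites=2, shape=(10, 10, 10),
                              sham_counts=(3, 3), tbi_counts=(2, 2),
                              site_offsets=(0.0, 0.0),
                              site_scales=(1.0, 1.0),
                              hemisphere=("left", "left"),
                              lesion_slope=0.0, outlier_site=None,
                              subject_sd=0.0, seed=1000 + seed)
            cohort = generate_cohort(cfg)
            samples = site_value_samples(cohort, n_per_site=250,
                                         seed=seed)
            p = stats.ks_2samp(samples[1], samples[2]).pvalue
            rejections += p < 0.05
        # binomial(120, 0.05): ~3-sigma band around 6
        assert 0 <= rejections <= 14


class TestCountGenerator:
    def test_multiplier_recovered_in_feature_means(self):
        annot = pd.DataFrame({"site": np.repeat([1, 2], 50),
                              "group": ["sham"] * 100})
        table = generate_univariate_counts(
            500, annot, {1: 1.0, 2: 2.0}, dispersion=0.1, seed=7)
        c = table.counts.astype(float)
        ratio = (c[:, 50:].mean(axis=1) / c[:, :50].mean(axis=1))
        assert abs(np.median(ratio) - 2.0) < 0.15

    def test_exchangeable_null_means_equal(self):
        annot = pd.DataFrame({"site": np.repeat([1, 2], 200),
                              "group": ["sham"] * 400})
        table = generate_univariate_counts(
            200, annot, {1: 1.0, 2: 1.0}, dispersion=0.05, seed=8)
        c = table.counts.astype(float)
        ratio = c[:, 200:].mean(axis=1) / c[:, :200].mean(axis=1)
        assert abs(np.median(ratio) - 1.0) < 0.05

    def test_poisson_limit_variance_mean_ratio(self):
        annot = pd.DataFrame({"site": [1] * 2000, "group": ["sham"] * 2000})
        table = generate_univariate_counts(
            50, annot, {1: 1.0}, dispersion=0.0, seed=9)
        c = table.counts.astype(float)
        vmr = c.var(axis=1, ddof=1) / c.mean(axis=1)
        assert abs(np.median(vmr) - 1.0) < 0.1

    def test_seeded_reproducibility_and_errors(self, count_annotations):
        a = generate_univariate_counts(20, count_annotations, {1: 1, 2: 2},
                                       seed=5)
        b = generate_univariate_counts(20, count_annotations, {1: 1, 2: 2},
                                       seed=5)
        assert np.array_equal(a.counts, b.counts)
        with pytest.raises(ValueError, match="n_features"):
            generate_univariate_counts(0, count_annotations, {1: 1, 2: 2})
        with pytest.raises(ValueError, match="multipliers"):
            generate_univariate_counts(5, count_annotations, {1: 1, 2: -2})
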