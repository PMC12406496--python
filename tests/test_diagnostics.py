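"""Outlier screen, kurtosis, agreement, rank tests and FDR adjustment."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from tbiharm import (bh_fdr, bland_altman, cohens_d, excess_kurtosis,
                     kruskal_effects, ks_site_pairs, outlier_screen)
from tbiharm.diagnostics import cohens_d_bootstrap, variance_heterogeneity
import pandas as pd


class TestOutlierScreen:
    def test_gaussian_null_proportion_near_theory(self):
        """Identical Gaussian sites: proportion ~ 2 Phi(-2.698) ~ 0.7%."""
        rng = np.random.default_rng(1)
        vals = {s: rng.normal(0, 1, 40_000) for s in (1, 2, 3)}
        report = outlier_screen(vals, mode="pooled")
        for p in report.proportions.values():
            assert 0.003 < p < 0.015
        assert report.flagged_sites == []

    def test_heavy_tailed_site_flagged(self):
        rng = np.random.default_rng(2)
        vals = {s: rng.normal(0, 1, 20_000) for s in (1, 2, 3)}
        vals[4] = rng.standard_t(3, 20_000) * 1.6
        report = outlier_screen(vals, mode="pooled")
        assert report.flagged[4]
        assert not any(report.flagged[s] for s in (1, 2, 3))

    def test_constant_data_zero_proportion(self):
        vals = {s: np.full(100, 2.0) for s in (1, 2)}
        report = outlier_screen(vals, mode="pooled")
        assert all(p == 0.0 for p in report.proportions.values())

    def test_per_voxel_mode_uses_voxelwise_fences(self):
        rng = np.random.default_rng(3)
        base = rng.normal(0, 1, (1, 500))  # strong voxel-wise structure
        vals = {s: base * 5 + rng.normal(0, 0.1, (20, 500))
                for s in (1, 2, 3)}
        # per-voxel: matched structure cancels -> near-null proportions
        report = outlier_screen(vals, mode="per-voxel")
        assert all(p < 0.05 for p in report.proportions.values())

    def test_empty_site_rejected(self):
        with pytest.raises(ValueError, match="no values"):
            outlier_screen({1: np.ones(5), 2: np.array([])})


class TestKurtosis:
    def test_normal_uniform_and_t5(self):
        rng = np.random.default_rng(4)
        assert abs(excess_kurtosis(rng.normal(0, 1, 10**6))) < 0.02
        assert excess_kurtosis(rng.uniform(0, 1, 10**6)) == pytest.approx(
            -1.2, abs=0.02)
        # t(5): analytic excess kurtosis 6/(df-4) = 6; slow convergence
        assert excess_kurtosis(rng.standard_t(5, 2 * 10**6)) > 3.0

    def test_errors(self):
        with pytest.raises(ValueError, match="n >= 4"):
            excess_kurtosis([1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="zero-variance"):
            excess_kurtosis(np.ones(10))


class TestBlandAltman:
    def test_identical_sets(self):
        a = np.arange(10.0)
        s = bland_altman(a, a)
        assert s.bias == 0 and s.loa_low == 0 and s.loa_high == 0

    def test_pure_offset(self):
        a = np.arange(10.0)
        s = bland_altman(a + 0.1, a)
        assert s.bias == pytest.approx(0.1)
        assert s.sd_diff == pytest.approx(0.0, abs=1e-12)
        assert s.loa_low == pytest.approx(0.1)

    def test_bias_equals_difference_of_means(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=500), rng.normal(size=500)
        s = bland_altman(a, b)
        assert s.bias == pytest.approx(a.mean() - b.mean(), abs=1e-12)
        assert s.loa_low <= s.bias <= s.loa_high

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length mismatch"):
            bland_altman(np.ones(3), np.ones(4))


class TestKS:
    def test_self_pair_is_null(self):
        x = np.random.default_rng(6).normal(size=300)
        df = ks_site_pairs({1: x, 2: x})
        assert df["D"].iloc[0] == 0.0
        assert df["p"].iloc[0] == 1.0

    def test_shifted_distribution_detected(self):
        rng = np.random.default_rng(7)
        df = ks_site_pairs({1: rng.normal(0, 1, 500),
                            2: rng.normal(1, 1, 500)})
        assert df["p"].iloc[0] < 1e-6

    def test_null_sites_not_rejected_on_average(self):
        rng = np.random.default_rng(8)
        ps = []
        for _ in range(40):
            vals = {s: rng.normal(0, 1, 200) for s in (1, 2, 3)}
            ps.append(ks_site_pairs(vals, fdr=False)["p"].mean())
        assert np.mean(ps) > 0.3

    def test_small_site_rejected(self):
        with pytest.raises(ValueError, match="< 2 values"):
            ks_site_pairs({1: np.ones(5), 2: np.array([1.0])})


class TestKruskal:
    def test_hand_computed_h_statistic(self):
        """Two groups {1..5} vs {6..10}: H = 6.818, p ~ 0.009."""
        table = pd.DataFrame({"y": np.arange(1.0, 11.0),
                              "g": ["a"] * 5 + ["b"] * 5})
        r = kruskal_effects(table, "y", "g")
        assert r["H"] == pytest.approx(6.818, abs=0.001)
        assert r["p"] == pytest.approx(0.009, abs=0.001)

    def test_exact_permutation_oracle_small_n(self):
        """chi-square p vs exhaustive permutation at total n = 8."""
        from itertools import combinations
        y = np.array([1.2, 3.4, 2.2, 5.1, 4.4, 6.0, 0.5, 2.8])
        labels = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        table = pd.DataFrame({"y": y, "g": labels})
        r = kruskal_effects(table, "y", "g")
        obs_h = r["H"]
        # permutation distribution of H over all 70 assignments
        count = 0
        total = 0
        idx = np.arange(8)
        for comb in combinations(idx, 4):
            lab = np.zeros(8, dtype=int)
            lab[list(comb)] = 1
            h = stats.kruskal(y[lab == 0], y[lab == 1]).statistic
            count += h >= obs_h - 1e-12
            total += 1
        p_perm = count / total
        # the chi-square reference is an approximation to the exact
        # permutation distribution at n=8; they agree in order of magnitude
        # and in the accept/reject decision, not to fine precision
        assert abs(r["p"] - p_perm) < 0.15
        assert (r["p"] < 0.05) == (p_perm < 0.05)

    def test_significant_case_against_exact_permutation(self):
        """{1..5} vs {6..10}: exact permutation p = 2/252, chi-square ~0.009."""
        from itertools import combinations
        y = np.arange(1.0, 11.0)
        table = pd.DataFrame({"y": y, "g": ["a"] * 5 + ["b"] * 5})
        obs_h = kruskal_effects(table, "y", "g")["H"]
        count = total = 0
        for comb in combinations(range(10), 5):
            lab = np.zeros(10, dtype=bool)
            lab[list(comb)] = True
            h = stats.kruskal(y[lab], y[~lab]).statistic
            count += h >= obs_h - 1e-12
            total += 1
        assert count / total == pytest.approx(2 / 252, abs=1e-12)

    def test_identical_values_defined_as_null(self):
        table = pd.DataFrame({"y": np.ones(10),
                              "g": ["a", "b"] * 5})
        r = kruskal_effects(table, "y", "g")
        assert r["H"] == 0.0 and r["p"] == 1.0

    def test_single_level_rejected(self):
        table = pd.DataFrame({"y": np.arange(5.0), "g": ["a"] * 5})
        with pytest.raises(ValueError, match="single level"):
            kruskal_effects(table, "y", "g")


class TestCohensD:
    def test_hand_cases(self):
        assert cohens_d([1, 2, 3], [1, 2, 3]) == 0.0
        rng = np.random.default_rng(9)
        a = rng.normal(1, 1, 20_000)
        b = rng.normal(0, 1, 20_000)
        assert cohens_d(a, b) == pytest.approx(1.0, abs=0.05)
        # injured (5,7,9), sham (1,3): d = 5 / sqrt(10/3)
        assert cohens_d([5, 7, 9], [1, 3]) == pytest.approx(
            5 / np.sqrt(10 / 3), abs=1e-12)

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(ValueError, match="pooled SD"):
            cohens_d([2, 2, 2], [2, 2])

    def test_bootstrap_significance_calibrated_under_null(self):
        """False-positive rate of the bootstrap CI within 2x nominal."""
        rng = np.random.default_rng(10)
        hits = 0
        reps = 60
        for i in range(reps):
            a = rng.normal(0, 1, 15)
            b = rng.normal(0, 1, 15)
            r = cohens_d_bootstrap(a, b, n_boot=400, alpha=0.05, seed=i)
            hits += r["significant"]
        assert hits / reps <= 0.10  # 2 x alpha

    def test_bootstrap_detects_large_effect(self):
        rng = np.random.default_rng(11)
        r = cohens_d_bootstrap(rng.normal(2, 1, 30), rng.normal(0, 1, 30),
                               n_boot=1000, seed=1)
        assert r["significant"] and r["ci_low"] > 0


class TestVarianceAndFDR:
    def test_fligner_detects_spread_difference(self):
        rng = np.random.default_rng(12)
        r = variance_heterogeneity({1: rng.normal(0, 1, 200),
                                    2: rng.normal(0, 3, 200)})
        assert r["p"] < 1e-6

    def test_bh_stepup_arithmetic(self):
        adj = bh_fdr(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(adj, 0.04)
        assert bh_fdr(np.array([0.2]))[0] == 0.2

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_bh_properties(self, ps):
        p = np.array(ps)
        adj = bh_fdr(p)
        assert (adj >= p - 1e-12).all()
        assert (adj <= 1.0 + 1e-12).all()
        # order preservation on sorted input
        s = np.sort(p)
        adj_s = bh_fdr(s)
        assert (np.diff(adj_s) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="\\[0, 1\\]"):
            bh_fdr(np.array([0.5, 1.2]))
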