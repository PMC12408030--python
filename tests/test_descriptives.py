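"""Mann-Whitney rank tests and behavior correlation matrices."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import neuroridge as nr
from neuroridge.descriptives import compare_groups, mann_whitney_u, measure_correlations


def exact_two_sided_p(x, y):
    """Exhaustive-enumeration oracle: proportion of rank assignments whose U
    is at least as far from n1*n2/2 as the observed U (no ties assumed)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = np.argsort(np.argsort(pooled)) + 1
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    center = n1 * n2 / 2
    count = total = 0
    for idx in combinations(range(n1 + n2), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
        total += 1
        if abs(u - center) >= abs(u_obs - center):
            count += 1
    return count / total


class TestMannWhitneyU:
    def test_complete_separation(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.u_statistic == 0.0

    def test_identical_multisets_give_central_u(self):
        res = mann_whitney_u([1, 2, 3, 4], [4, 3, 2, 1])
        assert res.u_statistic == 4 * 4 / 2

    def test_complementarity(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=8), rng.normal(size=5)
        u_xy = mann_whitney_u(x, y).u_statistic
        u_yx = mann_whitney_u(y, x).u_statistic
        assert u_xy + u_yx == pytest.approx(8 * 5)

    def test_exact_small_sample_matches_enumeration(self):
        x, y = [1.0, 3.0], [2.0, 4.0]
        res = mann_whitney_u(x, y)
        assert res.p == pytest.approx(exact_two_sided_p(x, y))

    def test_empty_group_raises(self):
        with pytest.raises(ValueError, match="nonempty"):
            mann_whitney_u([], [1.0])

    @settings(deadline=None, max_examples=30)
    @given(st.integers(2, 5), st.integers(2, 5), st.integers(0, 1000))
    def test_u_bounds_and_complementarity_property(self, n1, n2, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=n1), rng.normal(size=n2)
        res = mann_whitney_u(x, y)
        assert 0 <= res.u_statistic <= n1 * n2
        assert res.u_statistic + mann_whitney_u(y, x).u_statistic == pytest.approx(n1 * n2)

    def test_returned_p_matches_enumeration_for_small_untied_samples(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            x, y = rng.normal(size=6), rng.normal(size=6)
            res = mann_whitney_u(x, y)  # exact path: n1+n2 <= 12, no ties
            assert res.p == pytest.approx(exact_two_sided_p(x, y), abs=1e-12)

    def test_normal_approximation_quality_at_n6(self):
        # worst-case deviation of the continuity-corrected normal
        # approximation from exact enumeration at n1=n2=6 is ~0.0155
        rng = np.random.default_rng(1)
        from scipy import stats

        for _ in range(20):
            x, y = rng.normal(size=6), rng.normal(size=6)
            exact = exact_two_sided_p(x, y)
            approx = stats.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic", use_continuity=True
            ).pvalue
            assert approx == pytest.approx(exact, abs=0.016)


class TestMeasureCorrelations:
    def test_unit_diagonal_and_symmetry(self, small_cohort):
        cohort, _, _ = small_cohort
        corr = measure_correlations(cohort, "all", "baseline")
        assert corr.shape == (9, 9)
        np.testing.assert_allclose(np.diag(corr), 1.0)
        np.testing.assert_allclose(corr.values, corr.values.T, atol=1e-12)
        assert ((corr.values >= -1) & (corr.values <= 1)).all()

    def test_positive_semidefinite_on_complete_cases(self, small_cohort):
        cohort, _, _ = small_cohort
        corr = measure_correlations(cohort, "all", "baseline")
        assert np.linalg.eigvalsh(corr.values).min() > -1e-10

    def test_shared_latent_gives_product_of_loadings(self):
        """Two measures driven by the same features at signal fraction 0.5
        each correlate ~0.5 (product of the sqrt-fraction loadings)."""
        cov = nr.datasets.default_region_covariance()
        w = np.zeros(68)
        w[5] = 1.0
        w *= np.sqrt(0.5 / (w @ cov @ w))
        cfg = nr.GenerativeConfig(
            n_participants=5000,
            true_weights_shared={("CT", "bas_drive"): w, ("CT", "bis_inhibition"): w},
            true_weights_sex_delta={},
            sex_mean_shift=np.zeros(68),
            noise_sd=np.sqrt(0.5),
            followup_retention=0.01,
            seed=17,
        )
        cohort, _ = nr.generate_cohort(cfg)
        corr = measure_correlations(cohort, "all", "baseline")
        assert corr.loc["bas_drive", "bis_inhibition"] == pytest.approx(0.5, abs=0.05)

    def test_independent_measures_near_zero(self):
        cohort, _ = nr.generate_cohort(nr.null_config(4000, seed=2, followup_retention=0.01))
        corr = measure_correlations(cohort, "all", "baseline")
        off = corr.values[~np.eye(9, dtype=bool)]
        assert np.abs(off).max() < 3 / np.sqrt(4000)

    def test_constant_measure_flagged_not_zero_filled(self, small_cohort):
        cohort, _, _ = small_cohort
        cohort = cohort.copy()
        cohort["bas_drive"] = 1.0
        corr = measure_correlations(cohort, "all", "baseline")
        assert corr.loc["bas_drive"].drop("bas_drive").isna().all()


class TestCompareGroups:
    def test_induced_sex_shift_is_detected(self):
        """A ~0.5 SD behavioral sex difference at n=2000 is flagged."""
        cov = nr.datasets.default_region_covariance()
        w = np.zeros(68)
        w[0:4] = 1.0
        w *= np.sqrt(0.09 / (w @ cov @ w))
        # male-female behavior difference = shift . w; calibrate to 0.5 SD
        sd_y = np.sqrt(w @ cov @ w + 1.0)
        shift = np.full(68, 0.5 * sd_y / w.sum())
        hits = 0
        for seed in range(10):
            cfg = nr.GenerativeConfig(
                n_participants=2000,
                sex_mean_shift=shift,
                true_weights_shared={("CT", "bas_drive"): w},
                true_weights_sex_delta={},
                noise_sd=1.0,
                followup_retention=0.01,
                seed=seed,
            )
            cohort, _ = nr.generate_cohort(cfg)
            table = compare_groups(cohort[cohort.timepoint == "baseline"])
            row = table[(table.measure == "bas_drive") & (table.contrast == "F_vs_M@baseline")]
            hits += bool(row["significant"].iloc[0])
        assert hits >= 9

    def test_no_difference_calibrated_rejections(self):
        rejections = total = 0
        for seed in range(20):
            cohort, _ = nr.generate_cohort(
                nr.null_config(600, seed=100 + seed, followup_retention=0.01)
            )
            table = compare_groups(cohort[cohort.timepoint == "baseline"])
            rejections += int(table["significant"].sum())
            total += len(table)
        assert rejections / total < 0.15

    def test_contrast_structure_and_fdr_fields(self, small_cohort):
        cohort, _, _ = small_cohort
        table = compare_groups(cohort)
        contrasts = set(table["contrast"])
        assert contrasts == {"F_vs_M@baseline", "F_vs_M@year2", "baseline_vs_year2"}
        assert len(table) == 27
        assert (table["p_fdr"] >= table["p"] - 1e-15).all()
        assert (table["significant"] == (table["p_fdr"] <= 0.05)).all()

    def test_paired_timepoint_option_runs(self, small_cohort):
        cohort, _, _ = small_cohort
        table = compare_groups(cohort, paired_timepoints=True)
        assert "baseline_vs_year2_paired" in set(table["contrast"])
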