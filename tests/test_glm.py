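"""Interaction design construction, voxelwise fitting, slope-difference t."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from amycov.glm import (build_interaction_design, fit_voxelwise,
                        slope_difference_t)
from conftest import contrast_t_oracle, ols_normal_equations


def _toy_cohort(n_scz=2, n_hc=2, rng=None):
    rng = rng or np.random.default_rng(0)
    n = n_scz + n_hc
    return pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(n)],
        "site_id": 1,
        "group": ["SCZ"] * n_scz + ["HC"] * n_hc,
        "age": rng.uniform(20, 50, n),
        "sex": rng.choice(["M", "F"], n),
        "tiv": rng.normal(1.4e6, 1e5, n),
    })


def _random_cohort(n, rng):
    c = _toy_cohort(n // 2, n - n // 2, rng)
    return c


class TestDesign:
    def test_toy_construction_cell_by_cell(self):
        cohort = pd.DataFrame({
            "subject_id": list("abcd"), "site_id": 1,
            "group": ["SCZ", "SCZ", "HC", "HC"],
            "age": [30.0, 40.0, 20.0, 50.0],
            "sex": ["M", "F", "M", "F"],
            "tiv": [1.0e6, 1.2e6, 1.1e6, 1.3e6],
        })
        vols = pd.Series([10.0, 20.0, 30.0, 40.0], name="seed")
        d = build_interaction_design(cohort, vols)
        assert d.X.shape == (4, 4 + 3)
        np.testing.assert_array_equal(d.X[:, 0], [1, 1, 0, 0])
        np.testing.assert_array_equal(d.X[:, 1], [0, 0, 1, 1])
        np.testing.assert_array_equal(d.X[:, 2], [10, 20, 0, 0])
        np.testing.assert_array_equal(d.X[:, 3], [0, 0, 30, 40])
        np.testing.assert_allclose(d.X[:, 4], [-5, 5, -15, 15])   # age
        np.testing.assert_allclose(d.X[:, 5], [-0.5, 0.5, -0.5, 0.5])
        np.testing.assert_allclose(d.X[:, 6],
                                   [-1.5e5, 0.5e5, -0.5e5, 1.5e5])

    def test_default_covariates_give_seven_columns(self):
        rng = np.random.default_rng(1)
        cohort = _random_cohort(20, rng)
        vols = pd.Series(rng.normal(100, 10, 20))
        d = build_interaction_design(cohort, vols)
        assert d.n_columns == 7
        assert np.linalg.matrix_rank(d.X) == 7

    def test_constant_seed_in_group_rejected(self):
        cohort = _toy_cohort(3, 3)
        vols = pd.Series([5.0, 5.0, 5.0, 1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="distinct seed"):
            build_interaction_design(cohort, vols)

    def test_group_columns_sum_to_ones(self):
        rng = np.random.default_rng(2)
        cohort = _random_cohort(12, rng)
        d = build_interaction_design(cohort, pd.Series(rng.normal(50, 5, 12)))
        np.testing.assert_allclose(d.X[:, 0] + d.X[:, 1], 1.0)


class TestFit:
    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(3)
        cohort = _random_cohort(50, rng)
        vols = pd.Series(rng.normal(100, 15, 50))
        d = build_interaction_design(cohort, vols)
        Y = rng.standard_normal((50, 100)) + 5.0
        fit = fit_voxelwise(Y, d)
        beta_ref, rss_ref, _ = ols_normal_equations(d.X, Y)
        np.testing.assert_allclose(fit.beta, beta_ref, rtol=1e-8, atol=1e-10)
        np.testing.assert_allclose(fit.rss, rss_ref, rtol=1e-8)

    def test_no_covariates_slope_is_per_group_ols(self):
        rng = np.random.default_rng(4)
        cohort = _random_cohort(40, rng)
        vols = rng.normal(100, 15, 40)
        y = 2.0 + 0.3 * vols + rng.standard_normal(40)
        d = build_interaction_design(cohort, pd.Series(vols), covariates=())
        fit = fit_voxelwise(y, d)
        scz = (cohort.group == "SCZ").to_numpy()
        slope_scz = np.polyfit(vols[scz], y[scz], 1)[0]
        slope_hc = np.polyfit(vols[~scz], y[~scz], 1)[0]
        assert abs(fit.beta[2, 0] - slope_scz) <= 1e-10
        assert abs(fit.beta[3, 0] - slope_hc) <= 1e-10

    def test_collinear_design_rejected(self):
        rng = np.random.default_rng(5)
        cohort = _random_cohort(20, rng)
        vols = pd.Series(rng.normal(100, 15, 20))
        d = build_interaction_design(cohort, vols)
        d.X = np.column_stack([d.X, d.X[:, 2]])  # duplicated column
        with pytest.raises(ValueError, match="rank deficient"):
            fit_voxelwise(rng.standard_normal((20, 5)), d)

    def test_nonfinite_data_rejected(self):
        rng = np.random.default_rng(6)
        cohort = _random_cohort(10, rng)
        d = build_interaction_design(cohort,
                                     pd.Series(rng.normal(100, 15, 10)))
        Y = rng.standard_normal((10, 3))
        Y[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            fit_voxelwise(Y, d)


class TestSlopeDifference:
    def test_eight_subject_hand_oracle(self):
        cohort = pd.DataFrame({
            "subject_id": list("abcdefgh"), "site_id": 1,
            "group": ["SCZ"] * 4 + ["HC"] * 4,
            "age": [25.0, 35.0, 45.0, 30.0, 28.0, 38.0, 48.0, 33.0],
            "sex": ["M", "F", "M", "F", "M", "F", "M", "F"],
            "tiv": [1.1e6, 1.2e6, 1.3e6, 1.15e6,
                    1.05e6, 1.25e6, 1.35e6, 1.2e6],
        })
        vols = pd.Series([50.0, 60.0, 70.0, 55.0, 52.0, 63.0, 71.0, 58.0])
        y = np.array([3.1, 4.0, 4.9, 3.4, 3.0, 3.5, 4.1, 3.2])
        d = build_interaction_design(cohort, vols, covariates=("age",))
        fit = fit_voxelwise(y, d)
        sm = slope_difference_t(fit)
        c = np.array([0.0, 0.0, 1.0, -1.0, 0.0])
        t_ref, df_ref = contrast_t_oracle(d.X, y, c)
        assert sm.df == df_ref
        assert abs(sm.t[0] - t_ref) <= 1e-10

    def test_null_t_distribution_calibrated(self):
        # no group slope difference anywhere: the t field must follow
        # Student t(df)
        rng = np.random.default_rng(7)
        n, V = 60, 10_000
        cohort = _random_cohort(n, rng)
        vols = rng.normal(100.0, 12.0, n)
        Y = (4.0 + 0.02 * vols[:, None]
             + rng.standard_normal((n, V)) * 0.5)
        d = build_interaction_design(cohort, pd.Series(vols))
        sm = slope_difference_t(fit_voxelwise(Y, d))
        ks = stats.kstest(sm.t, stats.t(df=sm.df).cdf)
        assert ks.pvalue > 0.01

    def test_df_equals_n_minus_columns(self, small_cohort,
                                       small_seed_volumes):
        d = build_interaction_design(small_cohort, "L_CAT",
                                     seed_table=small_seed_volumes)
        rng = np.random.default_rng(8)
        fit = fit_voxelwise(rng.standard_normal((len(small_cohort), 4)), d)
        assert fit.df == len(small_cohort) - 7

    def test_matches_statsmodels_oracle(self):
        statsmodels = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(9)
        cohort = _random_cohort(45, rng)
        vols = rng.normal(80.0, 10.0, 45)
        y = 1.0 + 0.1 * vols + rng.standard_normal(45)
        d = build_interaction_design(cohort, pd.Series(vols))
        sm_map = slope_difference_t(fit_voxelwise(y, d))
        res = statsmodels.OLS(y, d.X).fit()
        tt = res.t_test(np.array([0, 0, 1, -1, 0, 0, 0]))
        assert abs(sm_map.t[0] - float(np.squeeze(tt.tvalue))) < 1e-8


class TestInvariances:
    def test_location_invariance(self):
        rng = np.random.default_rng(10)
        cohort = _random_cohort(30, rng)
        vols = rng.normal(100, 10, 30)
        d = build_interaction_design(cohort, pd.Series(vols))
        y = rng.standard_normal(30)
        a = fit_voxelwise(y, d)
        b = fit_voxelwise(y + 7.5, d)
        # only the group intercepts move
        np.testing.assert_allclose(b.beta[2:], a.beta[2:], atol=1e-9)
        np.testing.assert_allclose(slope_difference_t(b).t,
                                   slope_difference_t(a).t, atol=1e-9)

    def test_seed_rescaling_equivariance(self):
        rng = np.random.default_rng(11)
        cohort = _random_cohort(30, rng)
        vols = rng.normal(100, 10, 30)
        y = rng.standard_normal(30)
        k = 3.7
        a = fit_voxelwise(y, build_interaction_design(cohort,
                                                      pd.Series(vols)))
        b = fit_voxelwise(y, build_interaction_design(cohort,
                                                      pd.Series(vols * k)))
        np.testing.assert_allclose(b.beta[2:4], a.beta[2:4] / k, rtol=1e-8)
        np.testing.assert_allclose(slope_difference_t(b).t,
                                   slope_difference_t(a).t, rtol=1e-8)

    def test_zero_residual_variance_rejected(self):
        rng = np.random.default_rng(12)
        cohort = _random_cohort(20, rng)
        vols = rng.normal(100, 10, 20)
        d = build_interaction_design(cohort, pd.Series(vols))
        y = d.X @ np.ones(d.n_columns)  # exactly in the column span
        with pytest.raises(ValueError, match="residual variance"):
            slope_difference_t(fit_voxelwise(y, d))
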