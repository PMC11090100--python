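"""Fingerprint cells, Hedges g*, per-center and sex-stratified validation,
subregion volume comparisons."""

import logging

import numpy as np
import pandas as pd
import pytest

from amycov import (GridSpec, SeedVolumeParams, TruthSpec, generate_cohort,
                    generate_gmv_stack, generate_seed_volumes)
from amycov.fingerprints import (compare_subregion_volumes,
                                 fingerprint_matrix, hedges_correction,
                                 hedges_g, per_center_effects,
                                 roi_covariance_glm,
                                 sex_stratified_fingerprints)
from amycov.glm import build_interaction_design, fit_voxelwise, \
    slope_difference_t
from amycov.labels import SEED_COLUMNS


@pytest.fixture(scope="module")
def cohort():
    return generate_cohort(30, 3, rng_seed=31)


@pytest.fixture(scope="module")
def seed_table(cohort):
    return generate_seed_volumes(cohort, rng_seed=131)


def _roi_values(cohort, seed_values, rng, slope_scz=0.0, slope_hc=0.0,
                noise=0.3):
    is_scz = (cohort["group"] == "SCZ").to_numpy()
    slope = np.where(is_scz, slope_scz, slope_hc)
    v = np.asarray(seed_values, float)
    return 4.0 + slope * (v - v.mean()) + rng.standard_normal(len(v)) * noise


class TestHedges:
    def test_closed_form_value(self):
        # t=2, n=50/50, df=93: g* = 2*sqrt(0.04)*(1 - 3/371)
        g = hedges_g(2.0, 50, 50, 93)
        assert np.isclose(g, 2 * np.sqrt(0.04) * (1 - 3 / 371))
        assert np.isclose(g, 0.396765, atol=1e-6)

    def test_zero_t_gives_zero(self):
        assert hedges_g(0.0, 30, 40, 60) == 0.0

    def test_correction_below_one_increasing(self):
        js = [hedges_correction(df) for df in (2, 10, 100, 10_000)]
        assert all(j < 1 for j in js)
        assert js == sorted(js)
        assert js[-1] > 0.9999

    def test_magnitude_increasing_in_t(self):
        gs = [abs(hedges_g(t, 40, 40, 75)) for t in (0.5, 1.0, 2.0, 4.0)]
        assert gs == sorted(gs)


class TestRoiGLM:
    def test_matches_single_voxel_stack_path(self, cohort, seed_table):
        rng = np.random.default_rng(0)
        roi = _roi_values(cohort, seed_table["L_CAT"], rng, 0.02, 0.0)
        cell = roi_covariance_glm(roi, seed_table["L_CAT"], cohort,
                                  seed_label="L_CAT")
        design = build_interaction_design(cohort, "L_CAT",
                                          seed_table=seed_table)
        sm = slope_difference_t(fit_voxelwise(roi, design))
        assert abs(cell.t - sm.t[0]) <= 1e-10
        assert cell.df == sm.df

    def test_sign_consistency_and_counts(self, cohort, seed_table):
        rng = np.random.default_rng(1)
        roi = _roi_values(cohort, seed_table["R_Ba"], rng, 0.05, 0.0)
        cell = roi_covariance_glm(roi, seed_table["R_Ba"], cohort)
        assert np.sign(cell.g) == np.sign(cell.t)
        assert cell.n_scz + cell.n_hc == len(cohort)

    def test_too_few_subjects_rejected(self):
        c = generate_cohort(2, 1, rng_seed=1)
        with pytest.raises(ValueError, match="3 subjects"):
            roi_covariance_glm(np.ones(4), np.arange(4.0), c)


class TestFingerprintMatrix:
    def test_grid_shape_and_order(self, cohort, seed_table):
        rng = np.random.default_rng(2)
        seeds = list(SEED_COLUMNS[:5])
        rois = [f"roi{k}" for k in range(28)]
        roi_table = pd.DataFrame(
            {r: _roi_values(cohort, seed_table["L_AAA"], rng)
             for r in rois})
        fp = fingerprint_matrix(roi_table, seed_table, cohort, seeds, rois)
        assert len(fp.cells) == 140
        assert fp.matrix("t").shape == (5, 28)

    def test_roi_permutation_permutes_columns(self, cohort, seed_table):
        rng = np.random.default_rng(3)
        rois = ["a", "b", "c"]
        roi_table = pd.DataFrame(
            {r: _roi_values(cohort, seed_table["L_AAA"], rng)
             for r in rois})
        fp1 = fingerprint_matrix(roi_table, seed_table, cohort,
                                 ["L_AAA"], rois)
        fp2 = fingerprint_matrix(roi_table, seed_table, cohort,
                                 ["L_AAA"], rois[::-1])
        m1, m2 = fp1.matrix("t"), fp2.matrix("t")
        np.testing.assert_allclose(m1[rois].to_numpy(),
                                   m2[rois].to_numpy())


class TestPerCenter:
    def test_single_center_equals_pooled(self):
        cohort = generate_cohort(40, 1, rng_seed=5)
        sv = generate_seed_volumes(cohort, rng_seed=105)
        rng = np.random.default_rng(5)
        roi = _roi_values(cohort, sv["L_AAA"], rng, 0.03, 0.0)
        pooled, effects = per_center_effects(roi, sv["L_AAA"], cohort)
        assert len(effects) == 1
        assert np.isclose(effects[0].g, pooled.g)

    def test_homogeneous_effect_across_centers(self):
        cohort = generate_cohort(60, 6, rng_seed=6)
        sv = generate_seed_volumes(cohort, rng_seed=106)
        rng = np.random.default_rng(6)
        roi = _roi_values(cohort, sv["L_AAA"], rng, 0.04, 0.0, noise=0.25)
        pooled, effects = per_center_effects(roi, sv["L_AAA"], cohort)
        assert len(effects) == 6
        n_ok = sum(abs(e.g - pooled.g) < 1.96 * e.se for e in effects)
        assert n_ok >= 5

    def test_small_center_excluded_with_warning(self, caplog):
        big = generate_cohort(30, 1, rng_seed=7)
        tiny = generate_cohort(2, 1, rng_seed=8)
        tiny["site_id"] = 2
        tiny["subject_id"] = tiny["subject_id"] + "_b"
        cohort = pd.concat([big, tiny], ignore_index=True)
        sv = generate_seed_volumes(cohort, rng_seed=107)
        rng = np.random.default_rng(7)
        roi = _roi_values(cohort, sv["L_AAA"], rng, 0.03, 0.0)
        with caplog.at_level(logging.WARNING):
            _, effects = per_center_effects(roi, sv["L_AAA"], cohort)
        assert {e.center for e in effects} == {1}
        assert any("excluded" in r.message for r in caplog.records)


class TestSexStratified:
    def test_planted_female_only_difference_detected(self):
        # strong female-specific slope difference: interaction must fire
        # in most replicates
        hits = 0
        n_rep = 40
        for rep in range(n_rep):
            cohort = generate_cohort(150, 1, rng_seed=100 + rep)
            sv = generate_seed_volumes(cohort, rng_seed=1100 + rep)
            rng = np.random.default_rng(200 + rep)
            sex = cohort["sex"].to_numpy()
            is_scz = (cohort["group"] == "SCZ").to_numpy()
            v = sv["L_AAA"].to_numpy()
            slope = np.where((sex == "F") & is_scz, 0.04, 0.0)
            roi = 4.0 + slope * (v - v.mean()) \
                + rng.standard_normal(len(v)) * 0.3
            res = sex_stratified_fingerprints(roi, v, cohort)
            hits += res.interaction_p < 0.05
        assert hits / n_rep >= 0.8

    def test_single_sex_rejected(self):
        cohort = generate_cohort(30, 1, rng_seed=9)
        cohort["sex"] = "M"
        sv = generate_seed_volumes(cohort, rng_seed=9)
        with pytest.raises(ValueError, match="both sexes"):
            sex_stratified_fingerprints(np.ones(len(cohort)),
                                        sv["L_AAA"], cohort)

    def test_subset_sizes_sum_to_total(self, cohort, seed_table):
        rng = np.random.default_rng(10)
        roi = _roi_values(cohort, seed_table["L_AAA"], rng)
        res = sex_stratified_fingerprints(roi, seed_table["L_AAA"], cohort)
        assert res.male.n_scz + res.female.n_scz \
            == (cohort.group == "SCZ").sum()
        assert res.male.n_hc + res.female.n_hc \
            == (cohort.group == "HC").sum()


class TestVolumeComparisons:
    def test_planted_deficit_detected(self):
        cohort = generate_cohort(400, 1, rng_seed=11)
        params = SeedVolumeParams(scz_deficit={"L_AAA": 0.10})
        sv = generate_seed_volumes(cohort, params, rng_seed=111)
        res = compare_subregion_volumes(sv, cohort, "all",
                                        volume_columns=["L_AAA"])
        assert res.loc[0, "significant"]
        assert res.loc[0, "t"] < 0  # patients smaller

    def test_tiv_driven_difference_adjusted_away(self):
        # volumes proportional to TIV, groups differing only through TIV:
        # adjustment must absorb the difference in most replicates
        n_sig = 0
        for rep in range(40):
            cohort = generate_cohort(100, 1, rng_seed=300 + rep,
                                     matched=False)
            rng = np.random.default_rng(400 + rep)
            tiv = cohort["tiv"].to_numpy()
            # make patient TIV systematically smaller
            tiv = np.where(cohort["group"] == "SCZ", tiv * 0.95, tiv)
            cohort["tiv"] = tiv
            vol = 60.0 * tiv / tiv.mean() + rng.standard_normal(len(tiv))
            sv = pd.DataFrame({"subject_id": cohort.subject_id,
                               "L_AAA": vol})
            res = compare_subregion_volumes(sv, cohort, "all", alpha=0.05,
                                            volume_columns=["L_AAA"])
            n_sig += bool(res.loc[0, "significant"])
        assert n_sig <= 2  # >= 95% adjusted away

    def test_sex_subsets_and_errors(self, cohort, seed_table):
        res_m = compare_subregion_volumes(seed_table, cohort, "M")
        res_f = compare_subregion_volumes(seed_table, cohort, "F")
        assert "interaction_p" not in res_m.columns
        assert len(res_m) == len(res_f) == 20
        with pytest.raises(ValueError):
            compare_subregion_volumes(seed_table, cohort, "X")
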