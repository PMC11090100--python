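"""Generator correctness: bookkeeping, matching, planted structure, determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from amycov import (GridSpec, PlantedEffect, SeedVolumeParams, TruthSpec,
                    generate_cohort, generate_gmv_stack,
                    generate_parcellation, generate_seed_volumes)
from amycov.demographics import chisq_2x2
from amycov.labels import SEED_COLUMNS, VOLUME_COLUMNS


class TestCohort:
    def test_counts_and_unique_ids(self):
        c = generate_cohort(10, 2, rng_seed=1)
        assert len(c) == 40
        assert (c.group == "SCZ").sum() == 20
        assert (c.group == "HC").sum() == 20
        assert c.subject_id.is_unique

    def test_sex_matched_within_sites(self):
        c = generate_cohort(50, 11, rng_seed=7)
        n_ok = 0
        for _, sub in c.groupby("site_id"):
            scz, hc = sub[sub.group == "SCZ"], sub[sub.group == "HC"]
            _, p = chisq_2x2((scz.sex == "M").sum(), (scz.sex == "F").sum(),
                             (hc.sex == "M").sum(), (hc.sex == "F").sum())
            n_ok += p > 0.05
        assert n_ok >= 10

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            generate_cohort(0, 3, rng_seed=1)

    def test_clinical_scores_patients_only(self):
        c = generate_cohort(8, 3, rng_seed=2)
        assert c.loc[c.group == "SCZ", "panss_total"].notna().all()
        assert c.loc[c.group == "HC", "panss_total"].isna().all()

    def test_age_within_bounds(self):
        c = generate_cohort(200, 3, rng_seed=3)
        assert c.age.between(16, 70).all()


class TestSeedVolumes:
    def test_all_columns_positive(self, small_cohort):
        sv = generate_seed_volumes(small_cohort, rng_seed=5)
        assert list(sv.columns[1:]) == list(VOLUME_COLUMNS)
        assert (sv[list(VOLUME_COLUMNS)] > 0).all().all()

    def test_planted_deficit_recovered(self):
        # d = 0.10 on L_AAA only: the SCZ/HC mean ratio must sit within
        # 3 SE (delta method) of 0.90
        c = generate_cohort(500, 1, rng_seed=9)
        params = SeedVolumeParams(
            scz_deficit={"L_AAA": 0.10})
        sv = generate_seed_volumes(c, params, rng_seed=90)
        scz = sv.loc[(c.group == "SCZ").to_numpy(), "L_AAA"]
        hc = sv.loc[(c.group == "HC").to_numpy(), "L_AAA"]
        ratio = scz.mean() / hc.mean()
        se = ratio * np.sqrt(scz.var() / len(scz) / scz.mean() ** 2
                             + hc.var() / len(hc) / hc.mean() ** 2)
        assert abs(ratio - 0.90) < 3 * se

    def test_planted_block_correlation(self):
        c = generate_cohort(500, 1, rng_seed=4)  # 1000 subjects total
        corr = np.full((18, 18), 0.2)
        np.fill_diagonal(corr, 1.0)
        block = [SEED_COLUMNS.index(x) for x in ("L_Ba", "L_La", "L_AB")]
        for i in block:
            for j in block:
                if i != j:
                    corr[i, j] = 0.8
        sv = generate_seed_volumes(
            c, SeedVolumeParams(correlation=corr, scz_deficit={}), rng_seed=4)
        sample = np.corrcoef(sv[["L_Ba", "L_La", "L_AB"]].to_numpy(),
                             rowvar=False)
        off = sample[np.triu_indices(3, 1)]
        assert np.all(np.abs(off - 0.8) < 0.05)

    def test_non_psd_correlation_rejected(self, small_cohort):
        corr = np.full((18, 18), 0.99)
        np.fill_diagonal(corr, 1.0)
        corr[0, 1] = corr[1, 0] = -0.99
        with pytest.raises(ValueError):
            generate_seed_volumes(small_cohort,
                                  SeedVolumeParams(correlation=corr))

    def test_empty_cohort_errors(self):
        with pytest.raises(ValueError):
            generate_seed_volumes(pd.DataFrame(columns=["group"]))


class TestGMVStack:
    def test_shapes_and_mask(self):
        c = generate_cohort(50, 1, rng_seed=3)
        sv = generate_seed_volumes(c, rng_seed=3)
        stack, _ = generate_gmv_stack(c, sv, grid=GridSpec((16, 16, 16)),
                                      rng_seed=3)
        assert stack.n_subjects == 100
        assert stack.mask.sum() == 14 ** 3
        assert (stack.masked_matrix() >= 0).all()

    def test_noiseless_ols_recovery(self):
        # with sigma -> 0 and no site effects, per-voxel OLS on the true
        # design recovers the generating coefficients almost exactly
        c = generate_cohort(40, 1, rng_seed=6)
        sv = generate_seed_volumes(c, rng_seed=6)
        # intercept large enough that beta * (vol - mean) never drives GMV
        # through the non-negativity floor
        truth = TruthSpec(
            effects=(PlantedEffect("L_AAA", beta_scz=0.5, beta_hc=0.1),),
            base_intercept=30.0,
            sigma=1e-8, site_additive_sd=0.0, site_log_scale_sd=0.0,
            common_slope=0.0)
        grid = GridSpec((10, 10, 10))
        stack, gt = generate_gmv_stack(c, sv, truth, grid, rng_seed=6)
        vox = np.asarray(gt.effects[0]["voxel_indices"])
        flat = stack.data.reshape(stack.n_subjects, -1)
        age = c.age.to_numpy() - c.age.mean()
        sex = (c.sex == "F").to_numpy(float)
        tiv = c.tiv.to_numpy() - c.tiv.mean()
        vol = sv["L_AAA"].to_numpy()
        volc = vol - vol.mean()
        is_scz = (c.group == "SCZ").to_numpy(float)
        X = np.column_stack([is_scz, 1 - is_scz, age, sex, tiv,
                             volc * is_scz, volc * (1 - is_scz)])
        beta = np.linalg.lstsq(X, flat[:, vox], rcond=None)[0]
        assert np.allclose(beta[0], truth.base_intercept, rtol=1e-6)
        assert np.allclose(beta[1], truth.base_intercept, rtol=1e-6)
        assert np.allclose(beta[2], truth.age_effect, rtol=1e-6)
        assert np.allclose(beta[3], truth.sex_effect, rtol=1e-6)
        assert np.allclose(beta[4], truth.tiv_effect, rtol=1e-6)
        assert np.allclose(beta[5], 0.5, rtol=1e-6)
        assert np.allclose(beta[6], 0.1, rtol=1e-6)

    def test_site_shifts_recoverable(self):
        c = generate_cohort(60, 4, rng_seed=8)
        sv = generate_seed_volumes(c, rng_seed=8)
        truth = TruthSpec(common_slope=0.0, site_log_scale_sd=0.0)
        stack, gt = generate_gmv_stack(c, sv, truth, GridSpec((10, 10, 10)),
                                       rng_seed=8)
        Y = stack.masked_matrix().mean(axis=1)
        age = c.age.to_numpy() - c.age.mean()
        sex = (c.sex == "F").to_numpy(float)
        tiv = c.tiv.to_numpy() - c.tiv.mean()
        resid = Y - (truth.base_intercept + truth.age_effect * age
                     + truth.sex_effect * sex + truth.tiv_effect * tiv)
        for site, gamma in gt.site_additive.items():
            sel = (c.site_id == site).to_numpy()
            est = resid[sel].mean()
            se = resid[sel].std(ddof=1) / np.sqrt(sel.sum())
            assert abs(est - gamma) < 3 * max(se, 1e-3)

    def test_cluster_outside_mask_errors(self, small_cohort,
                                         small_seed_volumes):
        truth = TruthSpec(effects=(
            PlantedEffect("L_AAA", 0.5, 0.0, center=(0, 5, 5)),))
        with pytest.raises(ValueError):
            generate_gmv_stack(small_cohort, small_seed_volumes, truth,
                               GridSpec((12, 12, 12)))

    def test_regeneration_bit_identical(self, small_cohort,
                                        small_seed_volumes):
        a, _ = generate_gmv_stack(small_cohort, small_seed_volumes,
                                  rng_seed=42)
        b, _ = generate_gmv_stack(small_cohort, small_seed_volumes,
                                  rng_seed=42)
        assert np.array_equal(a.data, b.data)

    def test_smoothing_changes_maps(self, small_cohort, small_seed_volumes):
        t0 = TruthSpec(smoothing_fwhm_mm=None)
        t1 = TruthSpec(smoothing_fwhm_mm=4.0)
        a, _ = generate_gmv_stack(small_cohort, small_seed_volumes, t0,
                                  rng_seed=1)
        b, _ = generate_gmv_stack(small_cohort, small_seed_volumes, t1,
                                  rng_seed=1)
        assert not np.allclose(a.data, b.data)
        # smoothing reduces voxelwise variance
        assert b.masked_matrix().std(axis=0).mean() \
            < a.masked_matrix().std(axis=0).mean()


class TestParcellation:
    def test_partition_of_mask(self):
        grid = GridSpec((16, 16, 16))
        parc = generate_parcellation(grid, 8, rng_seed=3)
        mask = grid.brain_mask()
        assert (parc.labels > 0).sum() == mask.sum()
        assert ((parc.labels > 0) == mask).all()
        sizes = np.bincount(parc.labels[mask])
        assert len(parc.names) == 8
        assert (sizes[1:9] > 0).all()
        assert sizes[1:9].sum() == mask.sum()

    def test_determinism(self):
        grid = GridSpec((12, 12, 12))
        a = generate_parcellation(grid, 5, rng_seed=9)
        b = generate_parcellation(grid, 5, rng_seed=9)
        assert np.array_equal(a.labels, b.labels)

    def test_too_many_regions_errors(self):
        grid = GridSpec((6, 6, 6))
        with pytest.raises(ValueError):
            generate_parcellation(grid, 10_000)
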