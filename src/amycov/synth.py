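"""Synthetic multi-site cohorts, seed volumes, GMV stacks and toy parcellations.

Emulates the *outputs* of a VBM + subfield-segmentation pipeline on a small
grid so that every downstream stage (harmonization, interaction GLMs,
permutation inference, ROI selection, fingerprints) can be exercised against
known ground truth. Nothing upstream of those outputs — raw T1 images,
segmentation, registration — is simulated.

The voxelwise generating model, for subject ``j`` of site ``i`` at voxel ``v``:

    GMV_jv = alpha_v + a*age_j + s*sex_j + t*tiv_j
             + sum_seeds beta_{group(j),seed,v} * Vol_{seed,j}
             + gamma_i + delta_i * eps_jv

with ``eps ~ N(0, sigma^2)`` i.i.d., site effects additive (``gamma_i``) and
multiplicative (``delta_i``), and group-specific covariance slopes ``beta``
differing between groups only on planted voxel clusters. Optional Gaussian
smoothing is applied last.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage, spatial

from .labels import NUCLEI, SEED_COLUMNS, VOLUME_COLUMNS, WHOLE_AMYGDALA_COLUMNS

__all__ = [
    "DemographicsParams",
    "SeedVolumeParams",
    "GridSpec",
    "PlantedEffect",
    "TruthSpec",
    "GroundTruth",
    "GMVStack",
    "Parcellation",
    "generate_cohort",
    "generate_seed_volumes",
    "generate_gmv_stack",
    "generate_parcellation",
    "plant_clinical_link",
]


# --------------------------------------------------------------------------
# cohort
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DemographicsParams:
    """Distributional parameters for cohort generation.

    Ages are normal, truncated to ``age_bounds`` (years); TIV is normal with a
    sex-dependent mean (mm^3); sex is coded ``M``/``F`` with ``male_fraction``
    the probability of ``M``. Clinical scores (PANSS subscales, illness
    duration in months, chlorpromazine-equivalent dose in mg/day) are drawn
    for patients only and, by default, independently of everything else.
    """

    age_mean: float = 33.0
    age_sd: float = 10.0
    age_bounds: tuple[float, float] = (16.0, 70.0)
    male_fraction: float = 0.58
    tiv_mean_male: float = 1.55e6
    tiv_mean_female: float = 1.35e6
    tiv_sd: float = 1.3e5
    panss_pos_mean: float = 20.0
    panss_pos_sd: float = 5.0
    panss_neg_mean: float = 21.0
    panss_neg_sd: float = 6.0
    panss_gen_mean: float = 40.0
    panss_gen_sd: float = 9.0
    duration_mean_months: float = 96.0
    duration_sd_months: float = 80.0
    cpz_mean: float = 420.0
    cpz_sd: float = 220.0
    #: jitter (years) added to patient ages when matching controls
    match_age_jitter: float = 1.5

    def __post_init__(self) -> None:
        if self.age_sd <= 0 or self.tiv_sd <= 0:
            raise ValueError("scale parameters must be positive")
        if not 0.0 < self.male_fraction < 1.0:
            raise ValueError("male_fraction must lie in (0, 1)")
        lo, hi = self.age_bounds
        if not lo < hi:
            raise ValueError("age_bounds must be an increasing pair")


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      bounds: tuple[float, float], size: int) -> np.ndarray:
    lo, hi = bounds
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def generate_cohort(n_per_group_per_site: int, n_sites: int,
                    params: DemographicsParams | None = None,
                    rng_seed: int = 0, *, matched: bool = True) -> pd.DataFrame:
    """Generate a multi-site case/control cohort table.

    Parameters
    ----------
    n_per_group_per_site
        Subjects per group per site; every site contains both groups.
    n_sites
        Number of acquisition sites (batch levels for harmonization).
    params
        Distributional parameters; defaults emulate an adult schizophrenia
        cohort (mean age ~33 y, slight male excess).
    matched
        If True (default), each site's controls are matched to its patients:
        control ages are patient ages plus small jitter and control sexes are
        a permutation of patient sexes, mirroring per-site case-control
        matching. If False, both groups are drawn independently.

    Returns
    -------
    pandas.DataFrame
        Columns ``subject_id, site_id, group, age, sex, tiv`` plus clinical
        columns (``panss_pos/neg/gen/total, duration, cpz``) that are NaN for
        controls.
    """
    if n_per_group_per_site < 1:
        raise ValueError("n_per_group_per_site must be >= 1")
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    p = params or DemographicsParams()
    rng = np.random.default_rng(rng_seed)

    rows: list[dict] = []
    for site in range(1, n_sites + 1):
        n = n_per_group_per_site
        scz_age = _truncated_normal(rng, p.age_mean, p.age_sd, p.age_bounds, n)
        scz_sex = np.where(rng.random(n) < p.male_fraction, "M", "F")
        if matched:
            hc_age = np.clip(scz_age + rng.normal(0.0, p.match_age_jitter, n),
                             *p.age_bounds)
            hc_sex = rng.permutation(scz_sex)
        else:
            hc_age = _truncated_normal(rng, p.age_mean, p.age_sd, p.age_bounds, n)
            hc_sex = np.where(rng.random(n) < p.male_fraction, "M", "F")
        for group, ages, sexes in (("SCZ", scz_age, scz_sex),
                                   ("HC", hc_age, hc_sex)):
            tiv_mean = np.where(sexes == "M", p.tiv_mean_male, p.tiv_mean_female)
            tiv = rng.normal(tiv_mean, p.tiv_sd)
            tiv = np.clip(tiv, 0.6 * p.tiv_mean_female, None)
            for k in range(n):
                row = {
                    "subject_id": f"site{site:02d}_{group.lower()}{k + 1:04d}",
                    "site_id": site,
                    "group": group,
                    "age": float(ages[k]),
                    "sex": str(sexes[k]),
                    "tiv": float(tiv[k]),
                    "panss_pos": np.nan, "panss_neg": np.nan,
                    "panss_gen": np.nan, "panss_total": np.nan,
                    "duration": np.nan, "cpz": np.nan,
                }
                if group == "SCZ":
                    pos = max(7.0, rng.normal(p.panss_pos_mean, p.panss_pos_sd))
                    neg = max(7.0, rng.normal(p.panss_neg_mean, p.panss_neg_sd))
                    gen = max(16.0, rng.normal(p.panss_gen_mean, p.panss_gen_sd))
                    row.update(
                        panss_pos=pos, panss_neg=neg, panss_gen=gen,
                        panss_total=pos + neg + gen,
                        duration=max(1.0, rng.normal(p.duration_mean_months,
                                                     p.duration_sd_months)),
                        cpz=max(0.0, rng.normal(p.cpz_mean, p.cpz_sd)),
                    )
                rows.append(row)
    cohort = pd.DataFrame(rows)
    assert cohort["subject_id"].is_unique
    return cohort


# --------------------------------------------------------------------------
# seed volumes
# --------------------------------------------------------------------------

#: Typical subfield volumes (mm^3) per hemisphere, FreeSurfer-style scale.
_DEFAULT_NUCLEUS_MEANS = {
    "La": 700.0, "Ba": 450.0, "AB": 255.0, "AAA": 60.0, "Ce": 55.0,
    "Me": 30.0, "Co": 30.0, "CAT": 190.0, "PL": 55.0,
}


@dataclass(frozen=True)
class SeedVolumeParams:
    """Parameters of the subregion-volume generator.

    ``means`` maps nucleus code to its per-hemisphere mean volume (mm^3);
    ``cv`` is the coefficient of variation applied to every nucleus;
    ``correlation`` is the 18x18 inter-subregion correlation matrix (default
    exchangeable with ``base_correlation`` off-diagonal); ``scz_deficit``
    maps seed columns (e.g. ``"L_AAA"``) to the fractional volume deficit in
    patients, so the patient mean is ``(1 - d)`` times the control mean.
    """

    means: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_NUCLEUS_MEANS))
    cv: float = 0.12
    base_correlation: float = 0.5
    correlation: np.ndarray | None = None
    scz_deficit: Mapping[str, float] = field(
        default_factory=lambda: {c: 0.05 for c in SEED_COLUMNS})
    whole_amygdala_noise_sd: float = 30.0

    def correlation_matrix(self) -> np.ndarray:
        if self.correlation is not None:
            corr = np.asarray(self.correlation, float)
        else:
            corr = np.full((18, 18), self.base_correlation)
            np.fill_diagonal(corr, 1.0)
        if corr.shape != (18, 18) or not np.allclose(corr, corr.T):
            raise ValueError("correlation must be a symmetric 18x18 matrix")
        if np.linalg.eigvalsh(corr).min() < -1e-10:
            raise ValueError("correlation matrix is not positive semi-definite")
        return corr

    def mean_vector(self, group: str) -> np.ndarray:
        mu = []
        for col in SEED_COLUMNS:
            nucleus = col.split("_", 1)[1]
            m = float(self.means[nucleus])
            if m <= 0:
                raise ValueError(f"mean volume for {nucleus} must be positive")
            if group == "SCZ":
                m *= 1.0 - float(self.scz_deficit.get(col, 0.0))
            mu.append(m)
        return np.asarray(mu)


def generate_seed_volumes(cohort: pd.DataFrame,
                          params: SeedVolumeParams | None = None,
                          rng_seed: int = 0) -> pd.DataFrame:
    """Generate the 18 subregion + 2 whole-amygdala volumes per subject.

    Subregion volumes are multivariate normal with the planted correlation
    structure; whole-amygdala volumes are each hemisphere's nucleus sum plus
    independent noise (segmentations need not tile the structure exactly).
    Row order matches the cohort.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    p = params or SeedVolumeParams()
    rng = np.random.default_rng(rng_seed)
    corr = p.correlation_matrix()

    n = len(cohort)
    sds_hc = p.mean_vector("HC") * p.cv
    cov = corr * np.outer(sds_hc, sds_hc)
    chol = np.linalg.cholesky(cov + 1e-9 * np.eye(18) * cov.diagonal().mean())
    z = rng.standard_normal((n, 18)) @ chol.T
    mu = np.where((cohort["group"] == "SCZ").to_numpy()[:, None],
                  p.mean_vector("SCZ")[None, :], p.mean_vector("HC")[None, :])
    vols = np.maximum(mu + z, 1.0)

    table = pd.DataFrame(vols, columns=list(SEED_COLUMNS))
    for hemi, col in zip("LR", WHOLE_AMYGDALA_COLUMNS):
        nucleus_cols = [f"{hemi}_{nuc}" for nuc in NUCLEI]
        noise = rng.normal(0.0, p.whole_amygdala_noise_sd, n)
        table[col] = np.maximum(table[nucleus_cols].sum(axis=1) + noise, 1.0)
    table.insert(0, "subject_id", cohort["subject_id"].to_numpy())
    table.index = cohort.index
    return table


# --------------------------------------------------------------------------
# GMV stacks
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GridSpec:
    """Shared voxel grid for all subjects: shape, isotropic voxel size (mm)
    and brain mask (default: the interior box one voxel in from each face)."""

    shape: tuple[int, int, int] = (16, 16, 16)
    voxel_size_mm: float = 2.0
    mask: np.ndarray | None = None

    def brain_mask(self) -> np.ndarray:
        if self.mask is not None:
            m = np.asarray(self.mask, bool)
            if m.shape != tuple(self.shape):
                raise ValueError("mask shape does not match grid shape")
            return m
        m = np.zeros(self.shape, bool)
        m[1:-1, 1:-1, 1:-1] = True
        return m

    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = self.voxel_size_mm
        return aff

    @property
    def voxel_volume_mm3(self) -> float:
        return float(self.voxel_size_mm ** 3)


@dataclass
class GMVStack:
    """Per-subject 3-D gray-matter-volume maps on a shared grid.

    ``data`` has shape ``(n_subjects, nx, ny, nz)`` (modulated GMV, mm^3 per
    voxel, >= 0 inside the mask); ``mask`` is the shared brain mask;
    ``affine`` the shared voxel-to-world transform.
    """

    data: np.ndarray
    mask: np.ndarray
    affine: np.ndarray
    subject_ids: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, float)
        self.mask = np.asarray(self.mask, bool)
        if self.data.ndim != 4 or self.data.shape[1:] != self.mask.shape:
            raise ValueError("data must be (n_subjects, nx, ny, nz) on the mask grid")
        if len(self.subject_ids) != self.data.shape[0]:
            raise ValueError("one map per subject required")
        inside = self.data[:, self.mask]
        if not np.isfinite(inside).all():
            raise ValueError("non-finite GMV inside mask")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def masked_matrix(self) -> np.ndarray:
        """Subjects x in-mask-voxels data matrix (view order = C-order of mask)."""
        return self.data[:, self.mask]

    def with_masked_matrix(self, matrix: np.ndarray) -> "GMVStack":
        """Return a copy whose in-mask values are replaced by ``matrix``."""
        if matrix.shape != (self.n_subjects, self.n_voxels):
            raise ValueError("matrix shape mismatch")
        data = self.data.copy()
        data[:, self.mask] = matrix
        return GMVStack(data, self.mask, self.affine, list(self.subject_ids))


@dataclass(frozen=True)
class PlantedEffect:
    """A planted group difference in covariance slope for one seed.

    A cubic cluster of ``side**3`` voxels centred at ``center`` (mask centre
    by default) where the seed->voxel slope is ``beta_scz`` in patients and
    ``beta_hc`` in controls, in mm^3 GMV per mm^3 seed volume.
    """

    seed: str
    beta_scz: float
    beta_hc: float
    side: int = 3
    center: tuple[int, int, int] | None = None

    def voxel_indices(self, grid: GridSpec) -> np.ndarray:
        """Flat (C-order) indices of the affected voxels in the full grid."""
        mask = grid.brain_mask()
        if self.center is None:
            center = tuple(int(round(c)) for c in
                           np.array(np.nonzero(mask)).mean(axis=1))
        else:
            center = self.center
        half = self.side // 2
        sel = np.zeros(grid.shape, bool)
        lo = [c - half for c in center]
        hi = [c - half + self.side for c in center]
        sel[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
        if int(sel.sum()) != self.side ** 3 or not mask[sel].all():
            raise ValueError("planted cluster extends outside the brain mask")
        return np.flatnonzero(sel.ravel())


@dataclass(frozen=True)
class TruthSpec:
    """Generating parameters of the voxelwise model.

    ``effects`` lists planted group-difference clusters. ``common_slope``
    couples every voxel to the whole-amygdala volumes identically in both
    groups, so each subregion seed sees a nonzero but group-equal nuisance
    slope through inter-volume correlation. ``site_additive_sd`` is the SD
    of the additive site offsets gamma_i; site scale factors delta_i are
    log-normal with ``site_log_scale_sd``. ``smoothing_fwhm_mm`` optionally
    applies Gaussian smoothing after noise (VBM-style, reduced kernel for
    small grids).
    """

    effects: tuple[PlantedEffect, ...] = ()
    base_intercept: float = 4.0
    age_effect: float = -0.012      # mm^3 per year
    sex_effect: float = 0.10        # mm^3, F minus M
    tiv_effect: float = 1.5e-6      # mm^3 per mm^3 TIV
    common_slope: float = 0.001     # mm^3 per mm^3 whole-amygdala volume
    sigma: float = 0.4
    site_additive_sd: float = 0.5
    site_log_scale_sd: float = 0.2
    smoothing_fwhm_mm: float | None = None

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.site_additive_sd < 0 or self.site_log_scale_sd < 0:
            raise ValueError("site effect scales must be non-negative")


@dataclass
class GroundTruth:
    """Exactly what was planted: affected voxels and slopes per seed, site
    batch parameters, covariate effects, noise scale and smoothing."""

    effects: list[dict]                 # seed, voxel_indices, beta_scz, beta_hc
    site_additive: dict[int, float]     # gamma_i
    site_scale: dict[int, float]        # delta_i (> 0)
    age_effect: float
    sex_effect: float
    tiv_effect: float
    common_slope: float
    base_intercept: float
    sigma: float
    smoothing_fwhm_mm: float | None

    def affected_union(self, shape: tuple[int, int, int]) -> np.ndarray:
        """Boolean grid marking every planted voxel of any seed."""
        out = np.zeros(int(np.prod(shape)), bool)
        for eff in self.effects:
            out[np.asarray(eff["voxel_indices"], int)] = True
        return out.reshape(shape)


def generate_gmv_stack(cohort: pd.DataFrame, seed_volumes: pd.DataFrame,
                       truth: TruthSpec | None = None,
                       grid: GridSpec | None = None,
                       rng_seed: int = 0) -> tuple[GMVStack, GroundTruth]:
    """Generate per-subject GMV maps following the voxelwise generating model.

    Returns the stack together with a :class:`GroundTruth` recording exactly
    the planted voxels and parameters, enabling recovery and calibration
    tests downstream.
    """
    truth = truth or TruthSpec()
    grid = grid or GridSpec()
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    if len(seed_volumes) != len(cohort):
        raise ValueError("seed_volumes row count must match cohort")
    rng = np.random.default_rng(rng_seed)
    mask = grid.brain_mask()
    n = len(cohort)
    n_full = int(np.prod(grid.shape))

    sites = cohort["site_id"].to_numpy()
    site_levels = np.unique(sites)
    gamma = {int(s): float(rng.normal(0.0, truth.site_additive_sd))
             for s in site_levels}
    delta = {int(s): float(np.exp(rng.normal(0.0, truth.site_log_scale_sd)))
             for s in site_levels}

    age = cohort["age"].to_numpy(float)
    sex01 = (cohort["sex"].to_numpy() == "F").astype(float)  # M=0, F=1
    tiv = cohort["tiv"].to_numpy(float)
    is_scz = (cohort["group"] == "SCZ").to_numpy()

    # subject-level part, identical at every voxel
    subject_term = (truth.base_intercept
                    + truth.age_effect * (age - age.mean())
                    + truth.sex_effect * sex01
                    + truth.tiv_effect * (tiv - tiv.mean()))
    whole = seed_volumes[list(WHOLE_AMYGDALA_COLUMNS)].to_numpy(float)
    subject_term = subject_term + truth.common_slope * (
        whole - whole.mean(axis=0)).sum(axis=1)
    gamma_j = np.array([gamma[int(s)] for s in sites])
    delta_j = np.array([delta[int(s)] for s in sites])

    flat = np.tile((subject_term + gamma_j)[:, None], (1, n_full))

    effects_record: list[dict] = []
    for eff in truth.effects:
        if eff.seed not in seed_volumes.columns:
            raise ValueError(f"unknown seed column {eff.seed!r}")
        vox = eff.voxel_indices(grid)
        vol = seed_volumes[eff.seed].to_numpy(float)
        vol_c = vol - vol.mean()
        beta_j = np.where(is_scz, eff.beta_scz, eff.beta_hc)
        flat[:, vox] += (beta_j * vol_c)[:, None]
        effects_record.append({
            "seed": eff.seed,
            "voxel_indices": vox.tolist(),
            "beta_scz": float(eff.beta_scz),
            "beta_hc": float(eff.beta_hc),
        })

    eps = rng.standard_normal((n, n_full)) * truth.sigma
    flat = flat + delta_j[:, None] * eps

    data = flat.reshape((n,) + tuple(grid.shape))
    if truth.smoothing_fwhm_mm:
        sd_vox = truth.smoothing_fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) \
            / grid.voxel_size_mm
        for j in range(n):
            data[j] = ndimage.gaussian_filter(data[j], sd_vox)
    data[:, ~mask] = 0.0
    np.maximum(data, 0.0, out=data)

    stack = GMVStack(data, mask, grid.affine(),
                     cohort["subject_id"].astype(str).tolist())
    gt = GroundTruth(
        effects=effects_record, site_additive=gamma, site_scale=delta,
        age_effect=truth.age_effect, sex_effect=truth.sex_effect,
        tiv_effect=truth.tiv_effect, common_slope=truth.common_slope,
        base_intercept=truth.base_intercept, sigma=truth.sigma,
        smoothing_fwhm_mm=truth.smoothing_fwhm_mm,
    )
    return stack, gt


def plant_clinical_link(cohort: pd.DataFrame, target_values: np.ndarray,
                        variable: str, spearman_rho: float,
                        rng_seed: int = 0) -> pd.DataFrame:
    """Re-link one clinical variable to a target quantity monotonically.

    By default clinical scores are independent of imaging (null
    association); this helper plants a monotone association of strength
    ``spearman_rho`` between ``variable`` and ``target_values`` among
    patients, preserving the variable's marginal distribution exactly: the
    existing patient values are re-assigned by the ranks of a latent
    Gaussian correlated with the normal scores of the target.
    """
    if not -1.0 < spearman_rho < 1.0:
        raise ValueError("spearman_rho must lie in (-1, 1)")
    rng = np.random.default_rng(rng_seed)
    out = cohort.copy()
    is_scz = (out["group"] == "SCZ").to_numpy()
    target = np.asarray(target_values, float)
    if target.shape[0] == len(out):
        target = target[is_scz]
    elif target.shape[0] != int(is_scz.sum()):
        raise ValueError("target_values must align with the cohort or with "
                         "its patients")
    n = target.shape[0]
    # Pearson latent correlation giving the requested Spearman value
    rho_p = 2.0 * np.sin(spearman_rho * np.pi / 6.0)
    from scipy.stats import norm
    ranks = pd.Series(target).rank(method="average").to_numpy()
    z_target = norm.ppf((ranks - 0.5) / n)
    latent = rho_p * z_target + np.sqrt(1 - rho_p ** 2) * rng.standard_normal(n)
    old = np.sort(out.loc[is_scz, variable].to_numpy(float))
    new = np.empty(n)
    new[np.argsort(latent)] = old
    out.loc[is_scz, variable] = new
    if variable in ("panss_pos", "panss_neg", "panss_gen"):
        out.loc[is_scz, "panss_total"] = (
            out.loc[is_scz, ["panss_pos", "panss_neg", "panss_gen"]]
            .sum(axis=1))
    return out


# --------------------------------------------------------------------------
# parcellation
# --------------------------------------------------------------------------

@dataclass
class Parcellation:
    """Integer-labelled grid (0 = background) with a label -> name table."""

    labels: np.ndarray
    names: dict[int, str]
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer-valued")
        present = set(np.unique(self.labels[self.labels > 0]).tolist())
        missing = set(self.names) - present
        if missing:
            raise ValueError(f"named labels absent from the grid: {sorted(missing)}")

    def region_mask(self, label: int) -> np.ndarray:
        return self.labels == label


def generate_parcellation(grid: GridSpec, n_regions: int,
                          rng_seed: int = 0) -> Parcellation:
    """Voronoi-style random parcellation of the brain mask.

    ``n_regions`` distinct mask voxels are drawn as centroids and every mask
    voxel is assigned to its nearest centroid (first minimum on ties), so the
    regions partition the mask exactly and regeneration with the same seed is
    bit-identical.
    """
    mask = grid.brain_mask()
    n_mask = int(mask.sum())
    if not 1 <= n_regions <= n_mask:
        raise ValueError("n_regions must be in [1, mask voxel count]")
    rng = np.random.default_rng(rng_seed)
    coords = np.array(np.nonzero(mask)).T
    centroids = coords[rng.choice(n_mask, size=n_regions, replace=False)]
    dist = spatial.distance.cdist(coords, centroids)
    assign = dist.argmin(axis=1)
    labels = np.zeros(grid.shape, np.int32)
    labels[tuple(coords.T)] = assign + 1
    names = {k + 1: f"region_{k + 1:03d}" for k in range(n_regions)}
    return Parcellation(labels, names, grid.affine())
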