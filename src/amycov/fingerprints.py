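"""ROI-wise covariance fingerprints, Hedges g* effect sizes and validation.

For each (seed subregion, target ROI) pair the interaction GLM yields a
slope-difference t; the standardized effect size is Hedges' adjusted g*:

    g* = t * sqrt(1/n_SCZ + 1/n_HC) * J,   J = 1 - 3 / (4*df - 1)

with J the small-sample bias correction. Fingerprints collect these cells
over a seeds x ROIs grid; validation refits them per acquisition center
(forest plots) and within each sex, with a formal group x sex x volume
interaction test for sex differences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .glm import build_interaction_design, fit_voxelwise, slope_difference_t

logger = logging.getLogger(__name__)

__all__ = ["FingerprintCell", "FingerprintResult", "CenterEffect",
           "SexStratifiedResult", "hedges_correction", "hedges_g",
           "roi_covariance_glm", "fingerprint_matrix", "per_center_effects",
           "sex_stratified_fingerprints", "compare_subregion_volumes"]


def hedges_correction(df: int) -> float:
    """Small-sample bias factor J = 1 - 3/(4 df - 1); J < 1, J -> 1 as df grows."""
    if df < 1:
        raise ValueError("df must be >= 1")
    return 1.0 - 3.0 / (4.0 * df - 1.0)


def hedges_g(t: float, n1: int, n2: int, df: int) -> float:
    """Hedges' adjusted g* from a contrast t statistic."""
    return float(t) * np.sqrt(1.0 / n1 + 1.0 / n2) * hedges_correction(df)


def hedges_g_se(g: float, n1: int, n2: int, df: int) -> float:
    """Standard error of g* (standard Hedges approximation)."""
    return float(np.sqrt((1.0 / n1 + 1.0 / n2) + g ** 2 / (2.0 * df)))


@dataclass(frozen=True)
class FingerprintCell:
    """One seed x ROI covariance comparison."""

    seed: str
    roi: str
    t: float
    p: float
    g: float
    n_scz: int
    n_hc: int
    df: int


@dataclass
class FingerprintResult:
    """Complete seeds x ROIs grid of fingerprint cells."""

    seeds: list[str]
    rois: list[str]
    cells: dict[tuple[str, str], FingerprintCell]

    def matrix(self, attr: str = "t") -> pd.DataFrame:
        data = [[getattr(self.cells[(s, r)], attr) for r in self.rois]
                for s in self.seeds]
        return pd.DataFrame(data, index=self.seeds, columns=self.rois)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.cells[(s, r)].__dict__
                             for s in self.seeds for r in self.rois])


def roi_covariance_glm(roi_values, seed_values, cohort: pd.DataFrame,
                       covariates: tuple[str, ...] = ("age", "sex", "tiv"),
                       seed_label: str = "seed",
                       roi_label: str = "roi") -> FingerprintCell:
    """Fit the interaction model for one seed against one ROI mean-GMV column."""
    is_scz = (cohort["group"] == "SCZ").to_numpy()
    n_scz, n_hc = int(is_scz.sum()), int((~is_scz).sum())
    if min(n_scz, n_hc) < 3:
        raise ValueError("need at least 3 subjects per group")
    seed_series = pd.Series(np.asarray(seed_values, float), name=seed_label)
    design = build_interaction_design(cohort.reset_index(drop=True),
                                      seed_series, covariates)
    fit = fit_voxelwise(np.asarray(roi_values, float), design)
    sm = slope_difference_t(fit)
    t = float(sm.t[0])
    p = float(2.0 * stats.t.sf(abs(t), sm.df))
    return FingerprintCell(seed=seed_label, roi=roi_label, t=t, p=p,
                           g=hedges_g(t, n_scz, n_hc, sm.df),
                           n_scz=n_scz, n_hc=n_hc, df=sm.df)


def fingerprint_matrix(roi_table: pd.DataFrame, seed_table: pd.DataFrame,
                       cohort: pd.DataFrame, seeds: list[str],
                       rois: list[str],
                       covariates: tuple[str, ...] = ("age", "sex", "tiv"),
                       ) -> FingerprintResult:
    """All seed x ROI fingerprint cells, in the given deterministic order."""
    missing = [s for s in seeds if s not in seed_table.columns]
    missing += [r for r in rois if r not in roi_table.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    cells = {}
    for s in seeds:
        for r in rois:
            cells[(s, r)] = roi_covariance_glm(
                roi_table[r].to_numpy(float), seed_table[s].to_numpy(float),
                cohort, covariates, seed_label=s, roi_label=r)
    return FingerprintResult(seeds=list(seeds), rois=list(rois), cells=cells)


@dataclass(frozen=True)
class CenterEffect:
    """Per-center effect size for one seed x ROI covariance comparison."""

    center: object
    seed: str
    roi: str
    g: float
    se: float
    t: float
    p: float
    n_scz: int
    n_hc: int


def per_center_effects(roi_values, seed_values, cohort: pd.DataFrame,
                       covariates: tuple[str, ...] = ("age", "sex", "tiv"),
                       min_per_group: int = 3,
                       seed_label: str = "seed", roi_label: str = "roi",
                       ) -> tuple[FingerprintCell, list[CenterEffect]]:
    """Pooled cell plus one :class:`CenterEffect` per qualifying center.

    Centers with fewer than ``min_per_group`` subjects in either group are
    excluded with a logged warning.
    """
    roi_values = np.asarray(roi_values, float)
    seed_values = np.asarray(seed_values, float)
    pooled = roi_covariance_glm(roi_values, seed_values, cohort, covariates,
                                seed_label, roi_label)
    effects = []
    for center, idx in cohort.groupby("site_id").groups.items():
        sub = cohort.loc[idx]
        pos = cohort.index.get_indexer(idx)
        counts = sub["group"].value_counts()
        if counts.get("SCZ", 0) < min_per_group or \
                counts.get("HC", 0) < min_per_group:
            logger.warning("center %s excluded: fewer than %d subjects "
                           "per group", center, min_per_group)
            continue
        cell = roi_covariance_glm(roi_values[pos], seed_values[pos],
                                  sub, covariates, seed_label, roi_label)
        effects.append(CenterEffect(
            center=center, seed=seed_label, roi=roi_label, g=cell.g,
            se=hedges_g_se(cell.g, cell.n_scz, cell.n_hc, cell.df),
            t=cell.t, p=cell.p, n_scz=cell.n_scz, n_hc=cell.n_hc))
    if not effects:
        raise ValueError("no center qualifies for per-center validation")
    return pooled, effects


@dataclass
class SexStratifiedResult:
    """Within-sex fingerprint cells and the formal sex-interaction test."""

    male: FingerprintCell
    female: FingerprintCell
    interaction_t: float
    interaction_p: float
    df: int


def sex_stratified_fingerprints(roi_values, seed_values, cohort: pd.DataFrame,
                                seed_label: str = "seed",
                                roi_label: str = "roi",
                                ) -> SexStratifiedResult:
    """Fit the covariance comparison within each sex, plus the pooled
    group x sex x volume interaction contrast ((b3-b4)_M - (b3-b4)_F).

    The pooled model is a full group-by-sex factorial: one intercept and one
    volume slope per (group, sex) cell, with age and TIV as covariates.
    The interaction p is reported uncorrected.
    """
    roi_values = np.asarray(roi_values, float)
    seed_values = np.asarray(seed_values, float)
    sex = cohort["sex"].to_numpy()
    group = cohort["group"].to_numpy()
    for s in ("M", "F"):
        for g in ("SCZ", "HC"):
            if ((sex == s) & (group == g)).sum() < 3:
                raise ValueError("both sexes must be present in both groups")

    cells = {}
    for s in ("M", "F"):
        sel = sex == s
        cells[s] = roi_covariance_glm(roi_values[sel], seed_values[sel],
                                      cohort.loc[sel], ("age", "tiv"),
                                      seed_label, roi_label)

    # pooled factorial model
    vols = seed_values - seed_values.mean()
    cell_cols, slope_cols = [], []
    for g in ("SCZ", "HC"):
        for s in ("M", "F"):
            ind = ((group == g) & (sex == s)).astype(float)
            cell_cols.append(ind)
            slope_cols.append(ind * vols)
    age = cohort["age"].to_numpy(float)
    tiv = cohort["tiv"].to_numpy(float)
    X = np.column_stack(cell_cols + slope_cols
                        + [age - age.mean(), tiv - tiv.mean()])
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("factorial design is rank deficient")
    beta, *_ = np.linalg.lstsq(X, roi_values, rcond=None)
    resid = roi_values - X @ beta
    df = n - p
    sigma2 = float(resid @ resid) / df
    # slope columns order: SCZ_M, SCZ_F, HC_M, HC_F at offsets 4..7
    c = np.zeros(p)
    c[4], c[5], c[6], c[7] = 1.0, -1.0, -1.0, 1.0
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(sigma2 * float(c @ xtx_inv @ c))
    t_int = float(c @ beta) / se
    p_int = float(2.0 * stats.t.sf(abs(t_int), df))
    return SexStratifiedResult(male=cells["M"], female=cells["F"],
                               interaction_t=t_int, interaction_p=p_int,
                               df=df)


def compare_subregion_volumes(seed_table: pd.DataFrame, cohort: pd.DataFrame,
                              sex_subset: str = "all",
                              alpha: float = 0.0081,
                              volume_columns: list[str] | None = None,
                              ) -> pd.DataFrame:
    """Group differences in subregion (and whole-amygdala) volumes.

    Within the chosen subset (``"M"``, ``"F"`` or ``"all"``) each volume is
    modelled as ``volume ~ group + age + TIV``; significance is declared at
    the multiplicity-adjusted ``alpha``. With ``sex_subset="all"`` an
    additional group x sex interaction test
    (``volume ~ group*sex + age + TIV``) is reported per volume.
    """
    if sex_subset not in ("M", "F", "all"):
        raise ValueError("sex_subset must be 'M', 'F' or 'all'")
    cols = volume_columns or [c for c in seed_table.columns
                              if c != "subject_id"]
    if sex_subset == "all":
        sel = np.ones(len(cohort), bool)
    else:
        sel = (cohort["sex"] == sex_subset).to_numpy()
    if sel.sum() == 0:
        raise ValueError("empty sex subset")
    sub = cohort.loc[sel]
    is_scz = (sub["group"] == "SCZ").to_numpy(float)
    age = sub["age"].to_numpy(float)
    tiv = sub["tiv"].to_numpy(float)
    X = np.column_stack([np.ones(sel.sum()), is_scz,
                         age - age.mean(), tiv - tiv.mean()])

    full_is_scz = (cohort["group"] == "SCZ").to_numpy(float)
    full_sexF = (cohort["sex"] == "F").to_numpy(float)
    full_age = cohort["age"].to_numpy(float)
    full_tiv = cohort["tiv"].to_numpy(float)
    X_int = np.column_stack([
        np.ones(len(cohort)), full_is_scz, full_sexF,
        full_is_scz * full_sexF,
        full_age - full_age.mean(), full_tiv - full_tiv.mean()])

    rows = []
    for col in cols:
        y = seed_table.loc[sel, col].to_numpy(float)
        t, p = _ols_t(X, y, 1)
        row = {"volume": col, "t": t, "p": p, "significant": p < alpha}
        if sex_subset == "all":
            y_full = seed_table[col].to_numpy(float)
            t_i, p_i = _ols_t(X_int, y_full, 3)
            row["interaction_t"] = t_i
            row["interaction_p"] = p_i
        rows.append(row)
    return pd.DataFrame(rows)


def _ols_t(X: np.ndarray, y: np.ndarray, coef_idx: int) -> tuple[float, float]:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df = X.shape[0] - X.shape[1]
    sigma2 = float(resid @ resid) / df
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(sigma2 * xtx_inv[coef_idx, coef_idx])
    t = float(beta[coef_idx]) / se
    return t, float(2.0 * stats.t.sf(abs(t), df))
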