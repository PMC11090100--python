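"""Clinical association of covariance-level proxies via Spearman correlation.

Group-level covariance has no direct per-subject value, so a subject-level
proxy is formed as the product of z-scores of the seed volume and the target
ROI's mean GMV (population normalization within the analyzed patient
sample): a subject whose seed and ROI volumes deviate concordantly scores
positive, and the proxy's sample mean equals the Pearson correlation of the
two inputs. The proxies are then rank-correlated against clinical features
(PANSS subscales, illness duration, antipsychotic dose), pairwise-complete,
reported uncorrected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["AssociationResult", "covariance_proxy", "spearman_assoc",
           "associate_clinical"]


@dataclass(frozen=True)
class AssociationResult:
    """One Spearman association between a covariance proxy and a clinical
    variable."""

    seed: str
    roi: str
    clinical: str
    rho: float
    p: float
    n: int


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()  # population (1/n) normalization
    if sd == 0:
        raise ValueError("constant input: z-score undefined")
    return (x - x.mean()) / sd


def covariance_proxy(seed_values, roi_values,
                     adjust: pd.DataFrame | np.ndarray | None = None,
                     ) -> np.ndarray:
    """Per-subject covariance-level proxy ``z(seed) * z(roi)``.

    ``adjust``, if given, is a matrix of nuisance columns (e.g. age, sex,
    TIV); both inputs are residualized on it (with intercept) before
    z-scoring. The proxy is invariant to affine rescaling of either input.
    """
    seed = np.asarray(seed_values, float)
    roi = np.asarray(roi_values, float)
    if seed.shape != roi.shape or seed.ndim != 1:
        raise ValueError("seed and roi values must be equal-length vectors")
    if adjust is not None:
        Z = np.asarray(adjust, float)
        X = np.column_stack([np.ones(seed.shape[0]), Z])
        for arr in (seed, roi):
            beta, *_ = np.linalg.lstsq(X, arr, rcond=None)
            arr -= X @ beta
    return _zscore(seed) * _zscore(roi)


def spearman_assoc(proxy, clinical_values, seed: str = "seed",
                   roi: str = "roi", clinical: str = "clinical",
                   ) -> AssociationResult:
    """Tie-corrected Spearman correlation, two-sided p via the t
    approximation, pairwise-complete over non-missing pairs."""
    x = np.asarray(proxy, float)
    y = np.asarray(clinical_values, float)
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < 3:
        raise ValueError("need at least 3 pairwise-complete observations")
    xs, ys = x[ok], y[ok]
    if np.unique(xs).size < 2 or np.unique(ys).size < 2:
        raise ValueError("zero variance after ranking")
    rho, p = stats.spearmanr(xs, ys)
    return AssociationResult(seed=seed, roi=roi, clinical=clinical,
                             rho=float(rho), p=float(p), n=n)


def associate_clinical(roi_table: pd.DataFrame, seed_table: pd.DataFrame,
                       cohort: pd.DataFrame,
                       pairs: list[tuple[str, str]],
                       clinical_vars: tuple[str, ...] = (
                           "panss_pos", "panss_neg", "panss_gen",
                           "panss_total", "duration", "cpz"),
                       adjust_covariates: bool = True) -> pd.DataFrame:
    """Long-format association table over (seed, roi) pairs and clinical
    variables, computed in patients only."""
    is_scz = (cohort["group"] == "SCZ").to_numpy()
    if is_scz.sum() < 3:
        raise ValueError("need at least 3 patients")
    sub = cohort.loc[is_scz]
    adjust = None
    if adjust_covariates:
        adjust = np.column_stack([
            sub["age"].to_numpy(float),
            (sub["sex"].to_numpy() == "F").astype(float),
            sub["tiv"].to_numpy(float)])
    rows = []
    for seed, roi in pairs:
        proxy = covariance_proxy(
            seed_table.loc[is_scz, seed].to_numpy(float),
            roi_table.loc[is_scz, roi].to_numpy(float), adjust)
        for var in clinical_vars:
            res = spearman_assoc(proxy, sub[var].to_numpy(float),
                                 seed=seed, roi=roi, clinical=var)
            rows.append(res.__dict__)
    return pd.DataFrame(rows)
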