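"""Parametric empirical-Bayes location/scale harmonization across sites (ComBat).

Removes additive and multiplicative batch (site) effects from a
subjects-by-features matrix while preserving the biological covariates
supplied in the design (here: group, age, sex, TIV). Per-batch location and
scale estimates are shrunk toward common priors — normal for the additive
effects, inverse-gamma for the variance scales — with hyperparameters fitted
across features by the method of moments and posteriors obtained by the
standard iterated conditional-means update.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["HarmonizationModel", "fit_combat", "apply_combat",
           "biological_design"]


@dataclass
class HarmonizationModel:
    """Fitted harmonization parameters for one data matrix layout.

    Attributes hold, per feature ``v`` and batch ``i``: the full-cohort fit
    (``alpha_hat``, covariate coefficients ``beta_hat``, pooled variance
    ``sigma2_hat``), the naive per-batch location/scale estimates
    (``gamma_hat``, ``delta2_hat``), the across-feature hyperparameters and
    the posterior (EB-shrunk) ``gamma_star``, ``delta2_star``.
    """

    batch_levels: np.ndarray
    batch_sizes: np.ndarray
    alpha_hat: np.ndarray          # (V,)
    beta_hat: np.ndarray           # (k, V) biological coefficients
    sigma2_hat: np.ndarray         # (V,)
    gamma_hat: np.ndarray          # (I, V)
    delta2_hat: np.ndarray         # (I, V)
    gamma_bar: np.ndarray          # (I,)
    tau2_bar: np.ndarray           # (I,)
    lambda_bar: np.ndarray         # (I,) inverse-gamma shape
    theta_bar: np.ndarray          # (I,) inverse-gamma scale
    gamma_star: np.ndarray         # (I, V)
    delta2_star: np.ndarray        # (I, V)
    eb: bool = True
    n_iter: int = 0

    @property
    def n_features(self) -> int:
        return self.alpha_hat.shape[0]


def biological_design(cohort: pd.DataFrame,
                      covariates: tuple[str, ...] = ("age", "sex", "tiv"),
                      include_group: bool = True) -> np.ndarray:
    """Covariate matrix preserved by harmonization: group indicator plus
    the named cohort columns, with sex coded M=0 / F=1. No intercept column
    (the batch indicators span it)."""
    cols = []
    if include_group:
        cols.append((cohort["group"] == "SCZ").to_numpy(float))
    for name in covariates:
        if name == "sex":
            cols.append((cohort["sex"].to_numpy() == "F").astype(float))
        else:
            cols.append(cohort[name].to_numpy(float))
    return np.column_stack(cols) if cols else np.empty((len(cohort), 0))


def _batch_onehot(batch: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    levels, inverse = np.unique(batch, return_inverse=True)
    onehot = np.zeros((batch.shape[0], levels.shape[0]))
    onehot[np.arange(batch.shape[0]), inverse] = 1.0
    return levels, inverse, onehot


def fit_combat(data: np.ndarray, batch: np.ndarray,
               design: np.ndarray | None = None, *,
               eb: bool = True, tol: float = 1e-6,
               max_iter: int = 1000) -> HarmonizationModel:
    """Fit the harmonization model on a subjects x features matrix.

    Parameters
    ----------
    data
        ``(n_subjects, n_features)`` matrix; features may be in-mask voxels
        or ROI/seed-volume columns.
    batch
        Batch (site) label per subject; every batch needs >= 2 subjects.
    design
        Biological covariates to preserve, ``(n_subjects, k)``; the batch
        indicator block is appended internally. Must be full rank together
        with the batch block.
    eb
        If False, skip empirical-Bayes shrinkage (``gamma* = gamma_hat``,
        ``delta2* = delta2_hat``), giving exact per-batch standardization.
    """
    Y = np.asarray(data, float)
    if Y.ndim != 2:
        raise ValueError("data must be 2-D (subjects x features)")
    if not np.isfinite(Y).all():
        raise ValueError("data contains non-finite values")
    batch = np.asarray(batch)
    if batch.shape[0] != Y.shape[0]:
        raise ValueError("batch length must match subject count")
    levels, inverse, onehot = _batch_onehot(batch)
    n, V = Y.shape
    I = levels.shape[0]
    n_i = onehot.sum(axis=0)
    if (n_i < 2).any():
        bad = levels[n_i < 2]
        raise ValueError(f"batches with fewer than 2 subjects: {bad.tolist()}")

    if design is None:
        design = np.empty((n, 0))
    X_bio = np.asarray(design, float)
    X = np.hstack([onehot, X_bio])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("batch + biological design is rank deficient")

    B = np.linalg.lstsq(X, Y, rcond=None)[0]
    # grand intercept: batch-size-weighted mean of per-batch intercepts,
    # so that sum_i n_i * gamma_hat_iv = 0 per feature
    alpha_hat = (n_i / n) @ B[:I]
    beta_hat = B[I:]
    stand_mean = alpha_hat[None, :] + X_bio @ beta_hat
    resid = Y - X @ B
    sigma2_hat = (resid ** 2).sum(axis=0) / n
    if (sigma2_hat <= 0).any():
        raise ValueError("zero pooled variance for some features")
    Z = (Y - stand_mean) / np.sqrt(sigma2_hat)[None, :]

    gamma_hat = (onehot.T @ Z) / n_i[:, None]
    # population (divisor n_i) scale estimates, consistent with the divisor-n
    # pooled variance: a single batch then standardizes to exactly (0, 1)
    delta2_hat = np.empty((I, V))
    for i in range(I):
        zi = Z[inverse == i]
        delta2_hat[i] = ((zi - gamma_hat[i][None, :]) ** 2).mean(axis=0)
    if (delta2_hat <= 0).any():
        raise ValueError("zero within-batch variance for some features")

    gamma_bar = gamma_hat.mean(axis=1)
    tau2_bar = gamma_hat.var(axis=1, ddof=1) if V > 1 else np.ones(I)
    # inverse-gamma hyperparameters by method of moments
    m = delta2_hat.mean(axis=1)
    s2 = delta2_hat.var(axis=1, ddof=1) if V > 1 else np.ones(I)
    with np.errstate(divide="ignore", invalid="ignore"):
        lambda_bar = (m ** 2 + 2 * s2) / np.where(s2 > 0, s2, np.nan)
        theta_bar = (m ** 3 + m * s2) / np.where(s2 > 0, s2, np.nan)
    lambda_bar = np.where(np.isfinite(lambda_bar), lambda_bar, 2.0)
    theta_bar = np.where(np.isfinite(theta_bar), theta_bar, m)

    if eb:
        gamma_star = gamma_hat.copy()
        delta2_star = delta2_hat.copy()
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            g_old, d_old = gamma_star.copy(), delta2_star.copy()
            num = (n_i[:, None] * tau2_bar[:, None] * gamma_hat
                   + delta2_star * gamma_bar[:, None])
            den = n_i[:, None] * tau2_bar[:, None] + delta2_star
            gamma_star = num / den
            ssq = np.empty((I, V))
            for i in range(I):
                zi = Z[inverse == i]
                ssq[i] = ((zi - gamma_star[i][None, :]) ** 2).sum(axis=0)
            delta2_star = ((theta_bar[:, None] + 0.5 * ssq)
                           / (n_i[:, None] / 2.0 + lambda_bar[:, None] - 1.0))
            change = max(np.abs(gamma_star - g_old).max(),
                         np.abs(delta2_star - d_old).max())
            if change < tol:
                break
        else:
            raise RuntimeError("EB update failed to converge")
    else:
        gamma_star, delta2_star = gamma_hat.copy(), delta2_hat.copy()
        n_iter = 0

    return HarmonizationModel(
        batch_levels=levels, batch_sizes=n_i.astype(int),
        alpha_hat=alpha_hat, beta_hat=beta_hat, sigma2_hat=sigma2_hat,
        gamma_hat=gamma_hat, delta2_hat=delta2_hat,
        gamma_bar=gamma_bar, tau2_bar=tau2_bar,
        lambda_bar=lambda_bar, theta_bar=theta_bar,
        gamma_star=gamma_star, delta2_star=delta2_star,
        eb=eb, n_iter=n_iter,
    )


def apply_combat(data: np.ndarray, batch: np.ndarray,
                 design: np.ndarray | None,
                 model: HarmonizationModel) -> np.ndarray:
    """Harmonize a data matrix with a fitted model.

    ``output = sigma_hat * (z - gamma*_i) / delta*_i + alpha_hat + X beta_hat``
    where ``z`` is the standardized datum; biological covariate effects are
    added back unchanged.
    """
    Y = np.asarray(data, float)
    if Y.ndim != 2 or Y.shape[1] != model.n_features:
        raise ValueError("data feature count does not match the model")
    batch = np.asarray(batch)
    if batch.shape[0] != Y.shape[0]:
        raise ValueError("batch length must match subject count")
    level_index = {lev: i for i, lev in enumerate(model.batch_levels.tolist())}
    try:
        idx = np.array([level_index[b] for b in batch.tolist()])
    except KeyError as exc:
        raise ValueError(f"unknown batch label {exc.args[0]!r}") from None
    if design is None:
        design = np.empty((Y.shape[0], 0))
    X_bio = np.asarray(design, float)
    if X_bio.shape[1] != model.beta_hat.shape[0]:
        raise ValueError("design column count does not match the model")

    sigma = np.sqrt(model.sigma2_hat)[None, :]
    stand_mean = model.alpha_hat[None, :] + X_bio @ model.beta_hat
    Z = (Y - stand_mean) / sigma
    Z_adj = (Z - model.gamma_star[idx]) / np.sqrt(model.delta2_star[idx])
    return sigma * Z_adj + stand_mean


def harmonize(data: np.ndarray, batch: np.ndarray,
              design: np.ndarray | None = None, *,
              eb: bool = True) -> tuple[np.ndarray, HarmonizationModel]:
    """Fit and apply in one step (the common case)."""
    model = fit_combat(data, batch, design, eb=eb)
    return apply_combat(data, batch, design, model), model
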