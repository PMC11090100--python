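"""Seed-to-voxel structural-covariance interaction GLM.

The model, fitted independently at every voxel (or ROI column) ``v``:

    GMV_v = b1*SCZ + b2*HC + b3*(VolS x SCZ) + b4*(VolS x HC) + b_covs*Covs

``SCZ``/``HC`` are group indicator columns, ``VolS`` the seed (subregion)
volume, and ``Covs`` the nuisance covariates (age, sex, TIV by default,
mean-centered). ``b3`` and ``b4`` are the group-specific covariance slopes;
the effect of interest is the slope difference ``b3 - b4``, tested with the
contrast ``[0, 0, 1, -1, 0, ...]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .labels import DEFAULT_COVARIATES

__all__ = ["DesignMatrix", "GLMFit", "StatMap",
           "build_interaction_design", "fit_voxelwise", "slope_difference_t"]

_RANK_TOL = 1e-10


@dataclass
class DesignMatrix:
    """Interaction design with fixed column order
    ``[SCZ, HC, VolS*SCZ, VolS*HC, covariates...]``."""

    X: np.ndarray
    columns: list[str]
    seed_label: str
    is_scz: np.ndarray                # boolean group indicator
    vols: np.ndarray                  # raw seed volumes
    covs: np.ndarray                  # centered covariate block (n, k)

    IDX_SCZ = 0
    IDX_HC = 1
    IDX_INT_SCZ = 2
    IDX_INT_HC = 3

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    @property
    def n_columns(self) -> int:
        return self.X.shape[1]

    def contrast_slope_difference(self) -> np.ndarray:
        c = np.zeros(self.n_columns)
        c[self.IDX_INT_SCZ] = 1.0
        c[self.IDX_INT_HC] = -1.0
        return c

    def reduced_common_slope(self) -> np.ndarray:
        """Design under the null b3 = b4: the two interaction columns merge
        into a single common VolS column (used by Freedman-Lane)."""
        return np.column_stack([
            self.X[:, self.IDX_SCZ], self.X[:, self.IDX_HC],
            self.vols, self.covs,
        ])

    def with_group(self, is_scz: np.ndarray) -> "DesignMatrix":
        """Rebuild the design with a different group assignment (same
        subjects, volumes and covariates) — used by label-permutation."""
        return _assemble(is_scz, self.vols, self.covs,
                         list(self.columns), self.seed_label)


def _assemble(is_scz: np.ndarray, vols: np.ndarray, covs: np.ndarray,
              columns: list[str], seed_label: str) -> DesignMatrix:
    scz = is_scz.astype(float)
    hc = 1.0 - scz
    X = np.column_stack([scz, hc, vols * scz, vols * hc, covs])
    return DesignMatrix(X, columns, seed_label, is_scz.astype(bool),
                        vols, covs)


def build_interaction_design(cohort: pd.DataFrame,
                             seed_volumes: pd.Series | np.ndarray | str,
                             covariates: tuple[str, ...] = DEFAULT_COVARIATES,
                             seed_table: pd.DataFrame | None = None,
                             ) -> DesignMatrix:
    """Build the interaction design for one seed.

    ``seed_volumes`` may be a column name (resolved in ``seed_table``), a
    Series or an array aligned with the cohort. Covariates are mean-centered;
    sex is coded M=0 / F=1. Raises if either group has fewer than two
    distinct seed values (the fit would be rank deficient).
    """
    if isinstance(seed_volumes, str):
        if seed_table is None:
            raise ValueError("seed_table required when passing a column name")
        label = seed_volumes
        vols = seed_table[seed_volumes].to_numpy(float)
    else:
        label = getattr(seed_volumes, "name", None) or "seed"
        vols = np.asarray(seed_volumes, float)
    if vols.shape[0] != len(cohort):
        raise ValueError("seed volumes must align with the cohort")

    is_scz = (cohort["group"] == "SCZ").to_numpy()
    for grp, sel in (("SCZ", is_scz), ("HC", ~is_scz)):
        if sel.sum() < 2 or np.unique(vols[sel]).size < 2:
            raise ValueError(
                f"group {grp} needs >= 2 subjects with distinct seed values")

    cov_cols = []
    for name in covariates:
        if name == "sex":
            col = (cohort["sex"].to_numpy() == "F").astype(float)
        else:
            col = cohort[name].to_numpy(float)
        cov_cols.append(col - col.mean())
    covs = (np.column_stack(cov_cols) if cov_cols
            else np.empty((len(cohort), 0)))
    columns = ["SCZ", "HC", "VolSxSCZ", "VolSxHC", *covariates]
    return _assemble(is_scz, vols, covs, columns, str(label))


@dataclass
class GLMFit:
    """Per-feature least-squares fit of one design."""

    beta: np.ndarray               # (p, V)
    rss: np.ndarray                # (V,)
    tss: np.ndarray                # (V,) total sum of squares of the data
    df: int
    xtx_inv: np.ndarray            # (p, p)
    design: DesignMatrix

    @property
    def n_features(self) -> int:
        return self.beta.shape[1]


def fit_voxelwise(data, design: DesignMatrix) -> GLMFit:
    """Fit the design to every feature column by QR least squares.

    ``data`` is a subjects x features matrix, a 1-D per-subject vector
    (single ROI) or a :class:`~amycov.synth.GMVStack` (its in-mask matrix is
    used). One factorization is shared by all features.
    """
    if hasattr(data, "masked_matrix"):
        Y = data.masked_matrix()
    else:
        Y = np.asarray(data, float)
        if Y.ndim == 1:
            Y = Y[:, None]
    if Y.shape[0] != design.n_subjects:
        raise ValueError("data row count must match the design")
    if not np.isfinite(Y).all():
        raise ValueError("non-finite values in data")
    X = design.X
    Q, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    if diag.min() < _RANK_TOL * max(diag.max(), 1.0):
        raise ValueError("design matrix is rank deficient")
    beta = np.linalg.solve(R, Q.T @ Y)
    resid = Y - X @ beta
    rss = np.einsum("ij,ij->j", resid, resid)
    tss = np.einsum("ij,ij->j", Y, Y)
    Rinv = np.linalg.solve(R, np.eye(R.shape[0]))
    xtx_inv = Rinv @ Rinv.T
    df = X.shape[0] - X.shape[1]
    if df < 1:
        raise ValueError("non-positive residual degrees of freedom")
    return GLMFit(beta=beta, rss=rss, tss=tss, df=df, xtx_inv=xtx_inv,
                  design=design)


@dataclass
class StatMap:
    """A per-feature t statistic for one contrast of one seed's model."""

    t: np.ndarray
    df: int
    contrast: np.ndarray
    seed_label: str

    def to_volume(self, mask: np.ndarray) -> np.ndarray:
        """Embed the in-mask t vector into a 3-D volume, NaN outside."""
        out = np.full(mask.shape, np.nan)
        out[mask] = self.t
        return out


def slope_difference_t(fit: GLMFit,
                       contrast: np.ndarray | None = None) -> StatMap:
    """t statistic of the slope difference ``b3 - b4`` (or a custom contrast).

    ``t_v = c'beta_v / sqrt(sigma2_v * c'(X'X)^-1 c)`` with
    ``sigma2_v = RSS_v / df``.
    """
    c = (fit.design.contrast_slope_difference() if contrast is None
         else np.asarray(contrast, float))
    if c.shape != (fit.beta.shape[0],):
        raise ValueError("contrast length must equal the coefficient count")
    cc = float(c @ fit.xtx_inv @ c)
    sigma2 = fit.rss / fit.df
    # an RSS at round-off level relative to the data is numerically zero
    if (fit.rss <= 1e-24 * np.maximum(fit.tss, 1e-300)).any() or cc <= 0:
        raise ValueError("zero residual variance: t undefined")
    t = (c @ fit.beta) / np.sqrt(sigma2 * cc)
    return StatMap(t=t, df=fit.df, contrast=c, seed_label=fit.design.seed_label)
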