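"""Permutation-based family-wise-error inference and Meff alpha adjustment.

Significance of the slope-difference contrast is assessed non-parametrically:
each permutation refits the model, the signed t map is TFCE-enhanced in both
directions, and the image-wide maximum enhanced statistic is recorded. The
FWE-corrected p value at a voxel compares its observed enhancement against
this max-statistic null:

    p_FWE(v) = (1 + #{permutation max >= observed(v)}) / (n_perm + 1)

so the smallest attainable p is ``1/(n_perm + 1)`` (the observed data count
as the "+1" permutation). Testing one contrast per seed subregion inflates
the family further; the Li-Ji effective number of independent tests (Meff),
computed from the eigenvalues of the seeds' correlation matrix, supplies a
Bonferroni-style adjusted alpha = alpha / Meff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .glm import DesignMatrix, fit_voxelwise, slope_difference_t
from .tfce import TFCEngine, TFCEParams

__all__ = ["PermutationResult", "EffectiveTests", "permutation_fwe",
           "meff_li_ji", "significance_mask"]

SCHEMES = ("freedman_lane", "group_label")


@dataclass
class PermutationResult:
    """Observed maps and the max-statistic null for one seed's contrast."""

    t_obs: np.ndarray              # (V,) observed t, in-mask
    tfce_obs: np.ndarray           # (V,) signed TFCE of the observed t
    null_max: np.ndarray           # (n_perm,) image-wide max enhancement
    fwe_p: np.ndarray              # (V,)
    n_perm: int
    rng_seed: int
    scheme: str
    df: int
    seed_label: str

    def to_volume(self, mask: np.ndarray, which: str = "fwe_p") -> np.ndarray:
        fill = np.nan
        out = np.full(mask.shape, fill)
        out[mask] = getattr(self, which)
        return out


def _t_for_design(Y: np.ndarray, X: np.ndarray, c: np.ndarray,
                  df: int) -> np.ndarray:
    """Contrast t for a fixed design, vectorized over feature columns."""
    Q, R = np.linalg.qr(X)
    beta = np.linalg.solve(R, Q.T @ Y)
    resid = Y - X @ beta
    rss = np.einsum("ij,ij->j", resid, resid)
    Rinv = np.linalg.solve(R, np.eye(R.shape[0]))
    cc = float(c @ (Rinv @ Rinv.T) @ c)
    denom = np.sqrt(np.maximum(rss, 1e-300) / df * cc)
    return (c @ beta) / denom


def permutation_fwe(stack_or_matrix, design: DesignMatrix,
                    tfce_params: TFCEParams | None = None,
                    n_perm: int = 5000, scheme: str = "freedman_lane",
                    rng_seed: int = 0, *,
                    mask: np.ndarray | None = None,
                    engine: TFCEngine | None = None) -> PermutationResult:
    """Permutation TFCE-FWE inference for the slope-difference contrast.

    Parameters
    ----------
    stack_or_matrix
        A :class:`~amycov.synth.GMVStack`, or a subjects x voxels matrix (in
        which case ``mask`` or a prebuilt ``engine`` must be given).
    design
        The full interaction design for one seed.
    scheme
        ``"freedman_lane"`` (default): fit the reduced common-slope model,
        permute its residuals, add back the reduced fit, refit the full
        model — the standard approach for interaction contrasts with nuisance
        covariates. ``"group_label"``: exchange whole-subject group labels
        and rebuild the design each permutation.
    n_perm
        Number of random permutations (>= 100).
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    tfce_params = tfce_params or TFCEParams()

    if hasattr(stack_or_matrix, "masked_matrix"):
        Y = stack_or_matrix.masked_matrix()
        if engine is None:
            engine = TFCEngine(stack_or_matrix.mask, tfce_params)
    else:
        Y = np.asarray(stack_or_matrix, float)
        if engine is None:
            if mask is None:
                raise ValueError("mask or engine required with a raw matrix")
            engine = TFCEngine(mask, tfce_params)
    if Y.shape[1] != engine.n_voxels:
        raise ValueError("voxel count does not match the mask")
    n = design.n_subjects
    if Y.shape[0] != n:
        raise ValueError("subject count does not match the design")

    rng = np.random.default_rng(rng_seed)
    c = design.contrast_slope_difference()
    X_full = design.X
    df = n - X_full.shape[1]

    t_obs = _t_for_design(Y, X_full, c, df)
    tfce_obs = engine.enhance_signed(t_obs)
    abs_obs = np.abs(tfce_obs)

    null_max = np.empty(n_perm)
    buf = np.empty(engine.n_voxels)
    if scheme == "freedman_lane":
        X_red = design.reduced_common_slope()
        Qr, Rr = np.linalg.qr(X_red)
        fitted = Qr @ (Qr.T @ Y)
        resid = Y - fitted
        for k in range(n_perm):
            perm = rng.permutation(n)
            t_k = _t_for_design(fitted + resid[perm], X_full, c, df)
            m1 = engine.enhance_positive(np.clip(t_k, 0.0, None), buf).max()
            m2 = engine.enhance_positive(np.clip(-t_k, 0.0, None), buf).max()
            null_max[k] = max(m1, m2)
    else:  # group_label
        for k in range(n_perm):
            perm = rng.permutation(n)
            d_k = design.with_group(design.is_scz[perm])
            t_k = _t_for_design(Y, d_k.X, c, df)
            m1 = engine.enhance_positive(np.clip(t_k, 0.0, None), buf).max()
            m2 = engine.enhance_positive(np.clip(-t_k, 0.0, None), buf).max()
            null_max[k] = max(m1, m2)

    exceed = (null_max[None, :] >= abs_obs[:, None]).sum(axis=1)
    fwe_p = (1.0 + exceed) / (n_perm + 1.0)
    return PermutationResult(
        t_obs=t_obs, tfce_obs=tfce_obs, null_max=null_max, fwe_p=fwe_p,
        n_perm=n_perm, rng_seed=rng_seed, scheme=scheme, df=df,
        seed_label=design.seed_label,
    )


@dataclass
class EffectiveTests:
    """Li-Ji effective number of independent tests and the adjusted alpha."""

    M: int
    eigenvalues: np.ndarray
    meff: float
    alpha: float
    adjusted_alpha: float


def meff_li_ji(correlation: np.ndarray, alpha: float = 0.05) -> EffectiveTests:
    """Effective number of independent tests from a correlation matrix.

    ``Meff = sum_i f(|lambda_i|)`` with ``f(x) = 1{x >= 1} + (x - floor(x))``
    over the eigenvalues; the multiplicity-adjusted threshold is
    ``alpha / Meff``. Meff ranges from 1 (perfect correlation) to M
    (independence).
    """
    R = np.asarray(correlation, float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("correlation must be a square matrix")
    if not np.allclose(R, R.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(R), 1.0, atol=1e-8):
        raise ValueError("correlation matrix must have unit diagonal")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    M = R.shape[0]
    lam = np.linalg.eigvalsh((R + R.T) / 2.0)
    if lam.min() < -1e-6 * M:
        raise ValueError("correlation matrix is not PSD within tolerance")
    x = np.abs(lam)
    near_int = np.abs(x - np.round(x)) < 1e-9 * M
    x = np.where(near_int, np.round(x), x)
    meff = float(np.sum((x >= 1.0).astype(float) + (x - np.floor(x))))
    meff = min(max(meff, 1.0), float(M))
    return EffectiveTests(M=M, eigenvalues=lam, meff=meff, alpha=alpha,
                          adjusted_alpha=alpha / meff)


def significance_mask(fwe_p: np.ndarray, adjusted_alpha: float) -> np.ndarray:
    """Boolean significance decision: strictly ``p < adjusted_alpha``."""
    if not 0.0 < adjusted_alpha < 1.0:
        raise ValueError("adjusted_alpha must lie in (0, 1)")
    return np.asarray(fwe_p) < adjusted_alpha
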