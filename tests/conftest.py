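import numpy as np
import pandas as pd
import pytest

from amycov import (GridSpec, TruthSpec, generate_cohort, generate_gmv_stack,
                    generate_seed_volumes)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(15, 2, rng_seed=11)


@pytest.fixture(scope="session")
def small_seed_volumes(small_cohort):
    return generate_seed_volumes(small_cohort, rng_seed=11)


@pytest.fixture(scope="session")
def small_stack(small_cohort, small_seed_volumes):
    stack, gt = generate_gmv_stack(small_cohort, small_seed_volumes,
                                   TruthSpec(), GridSpec((12, 12, 12)),
                                   rng_seed=11)
    return stack, gt


def ols_normal_equations(X, y):
    """Independent least-squares oracle via explicit normal equations."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ y
    resid = y - X @ beta
    rss = float(resid @ resid) if y.ndim == 1 else (resid ** 2).sum(axis=0)
    return beta, rss, xtx_inv


def contrast_t_oracle(X, y, c):
    """Contrast t statistic by the normal-equations route."""
    beta, rss, xtx_inv = ols_normal_equations(X, y)
    df = X.shape[0] - X.shape[1]
    sigma2 = rss / df
    se = np.sqrt(sigma2 * (c @ xtx_inv @ c))
    return (c @ beta) / se, df
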