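"""Independent oracles used by the test suite.

These deliberately avoid the package's sampling path: the logistic oracle
integrates the two-parameter posterior on a deterministic grid, and the
Cox oracle is lifelines' Newton-Raphson fitter.
"""

from __future__ import annotations

import numpy as np


def grid_posterior_two_param(
    deaths: tuple[int, int],
    totals: tuple[int, int],
    prior_loc: float,
    prior_scale: float,
    intercept_scale: float = 2.5,
    n_grid: int = 1201,
    half_width: float = 4.0,
):
    """Deterministic quadrature for the single-site treatment-only model.

    Data are (deaths, totals) per arm (usual, high); parameters are the
    intercept alpha (usual-arm log-odds) and treatment log-OR beta.
    Returns the beta grid, its normalised marginal weights, a quantile
    function, and P(beta > 0).
    """
    k0, k1 = deaths
    n0, n1 = totals
    alpha = np.linspace(-half_width, half_width, n_grid)
    beta = np.linspace(-half_width, half_width, n_grid)
    A, B = np.meshgrid(alpha, beta, indexing="ij")
    eta0, eta1 = A, A + B
    loglik = (
        k0 * eta0 - n0 * np.logaddexp(0.0, eta0)
        + k1 * eta1 - n1 * np.logaddexp(0.0, eta1)
    )
    logprior = -0.5 * (A / intercept_scale) ** 2 - 0.5 * ((B - prior_loc) / prior_scale) ** 2
    logpost = loglik + logprior
    post = np.exp(logpost - logpost.max())
    marg_beta = post.sum(axis=0)
    marg_beta /= marg_beta.sum()
    # midpoint-corrected CDF keeps the quantile error well below the grid step
    cdf = np.cumsum(marg_beta) - 0.5 * marg_beta

    def quantile(q: float) -> float:
        return float(np.interp(q, cdf, beta))

    p_positive = float(
        marg_beta[beta > 0].sum() + 0.5 * marg_beta[beta == 0].sum()
    )
    return beta, marg_beta, quantile, p_positive
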