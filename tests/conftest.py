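"""Shared fixtures and independent oracles.

The joint-Gaussian oracle builds the full (TD + TN)-dimensional
Gaussian of a linear state-space model explicitly and conditions on the
stacked observations — slow but independent of the Kalman recursions it
checks.
"""

import numpy as np
import pytest

from driftssm.lds import LDSParams


def joint_gaussian(params: LDSParams, T: int):
    """Explicit joint distribution of (x_{1:T}, y_{1:T}).

    Returns (mu_x, Sig_x, mu_y, Sig_y, Sig_xy) with x stacked time-major.
    """
    D, N = params.D, params.N
    mu_x = np.zeros(T * D)
    mu_x[:D] = params.mu_x1
    for t in range(1, T):
        mu_x[t * D : (t + 1) * D] = params.A @ mu_x[(t - 1) * D : t * D] + params.b
    V = [params.Sigma_x1]
    for t in range(1, T):
        V.append(params.A @ V[-1] @ params.A.T + params.Q)
    Sig_x = np.zeros((T * D, T * D))
    for t in range(T):
        Sig_x[t * D : (t + 1) * D, t * D : (t + 1) * D] = V[t]
        Cts = V[t]
        for s in range(t + 1, T):
            Cts = Cts @ params.A.T  # Cov(x_t, x_s) = V_t (A')^{s-t}
            Sig_x[t * D : (t + 1) * D, s * D : (s + 1) * D] = Cts
            Sig_x[s * D : (s + 1) * D, t * D : (t + 1) * D] = Cts.T
    Cbig = np.kron(np.eye(T), params.C)
    mu_y = Cbig @ mu_x
    Sig_y = Cbig @ Sig_x @ Cbig.T + np.kron(np.eye(T), params.R)
    Sig_xy = Sig_x @ Cbig.T
    return mu_x, Sig_x, mu_y, Sig_y, Sig_xy


def condition_joint(params: LDSParams, y: np.ndarray):
    """Posterior mean/covariance of stacked states and log-likelihood,
    by direct conditioning of the explicit joint Gaussian."""
    from scipy.stats import multivariate_normal

    T = y.shape[0]
    mu_x, Sig_x, mu_y, Sig_y, Sig_xy = joint_gaussian(params, T)
    yv = y.ravel()
    sol = np.linalg.solve(Sig_y, yv - mu_y)
    post_mu = mu_x + Sig_xy @ sol
    post_S = Sig_x - Sig_xy @ np.linalg.solve(Sig_y, Sig_xy.T)
    ll = multivariate_normal(mu_y, Sig_y, allow_singular=False).logpdf(yv)
    return post_mu, post_S, float(ll)


@pytest.fixture
def small_lds():
    """A well-conditioned random D=2, N=3 model."""
    rng = np.random.default_rng(42)
    A = 0.7 * np.eye(2) + 0.1 * rng.normal(size=(2, 2))
    return LDSParams(
        A=A,
        b=0.1 * rng.normal(size=2),
        Q=0.3 * np.eye(2),
        C=rng.normal(size=(3, 2)),
        R=np.diag(rng.uniform(0.2, 0.5, 3)),
        mu_x1=rng.normal(size=2),
        Sigma_x1=0.5 * np.eye(2),
    )


def similarity_transform(params: LDSParams, T: np.ndarray) -> LDSParams:
    """The latent change of basis that leaves the observation law fixed."""
    Ti = np.linalg.inv(T)
    return LDSParams(
        A=T @ params.A @ Ti,
        b=T @ params.b,
        Q=T @ params.Q @ T.T,
        C=params.C @ Ti,
        R=params.R,
        mu_x1=T @ params.mu_x1,
        Sigma_x1=T @ params.Sigma_x1 @ T.T,
    )
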