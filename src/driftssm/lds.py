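"""Linear-Gaussian state-space model (LDS): sampling, exact Kalman
smoothing, marginal likelihood, and EM.

The model, per trial k:

    x_1 ~ N(mu_x1, Sigma_x1)
    x_{t+1} = A x_t + b + q_t,   q_t ~ N(0, Q)
    y_t = C x_t + r_t,           r_t ~ N(0, R)

This module is both the stand-alone baseline and the within-trial
engine of the drift model: all trials of equal length that share one
emission matrix are smoothed in a single batched pass (the covariance
recursions are data-independent, so only the means are per-trial).
Covariance updates use the Joseph form.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from sklearn.base import BaseEstimator

from .datasets import TrialDataset

__all__ = [
    "LDSParams",
    "StatePosterior",
    "sample_lds",
    "kalman_smooth",
    "smooth_dataset",
    "marginal_log_likelihood",
    "em_fit_lds",
    "LinearGaussianSSM",
]

_JITTER = 1e-9


def _check_spd(M: np.ndarray, name: str) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if not np.allclose(M, M.T, atol=1e-8):
        raise ValueError(f"{name} must be symmetric")
    try:
        np.linalg.cholesky(M + _JITTER * np.eye(M.shape[0]))
    except np.linalg.LinAlgError:
        raise ValueError(f"{name} must be positive definite") from None
    return 0.5 * (M + M.T)


@dataclass
class LDSParams:
    """Parameters of a linear-Gaussian state-space model."""

    A: np.ndarray
    b: np.ndarray
    Q: np.ndarray
    C: np.ndarray
    R: np.ndarray
    mu_x1: np.ndarray
    Sigma_x1: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
        self.C = np.atleast_2d(np.asarray(self.C, dtype=float))
        self.b = np.asarray(self.b, dtype=float).ravel()
        self.mu_x1 = np.asarray(self.mu_x1, dtype=float).ravel()
        D, N = self.A.shape[0], self.C.shape[0]
        if self.A.shape != (D, D) or self.C.shape != (N, D):
            raise ValueError("inconsistent A/C shapes")
        if self.b.shape != (D,) or self.mu_x1.shape != (D,):
            raise ValueError("b and mu_x1 must have length D")
        self.Q = _check_spd(np.atleast_2d(self.Q), "Q")
        self.R = _check_spd(np.atleast_2d(self.R), "R")
        self.Sigma_x1 = _check_spd(np.atleast_2d(self.Sigma_x1), "Sigma_x1")
        if self.Q.shape != (D, D) or self.Sigma_x1.shape != (D, D) or self.R.shape != (N, N):
            raise ValueError("covariance shapes inconsistent with A/C")

    @property
    def D(self) -> int:
        return self.A.shape[0]

    @property
    def N(self) -> int:
        return self.C.shape[0]

    def with_emission(self, C: np.ndarray) -> "LDSParams":
        """Copy of the parameters with a different emission matrix."""
        return replace(self, C=np.asarray(C, dtype=float))


@dataclass
class StatePosterior:
    """Smoothed Gaussian posterior for a batch of equal-length trials.

    ``means`` is (M, T, D); ``covs`` (T, D, D) and ``cross`` (T-1, D, D)
    are shared across the batch because covariance recursions do not
    depend on the data. ``cross[t] = Cov(x_t, x_{t+1})``. ``loglik`` is
    the exact per-trial marginal log-likelihood.
    """

    means: np.ndarray
    covs: np.ndarray
    cross: np.ndarray
    loglik: np.ndarray

    @property
    def n_trials(self) -> int:
        return self.means.shape[0]

    @property
    def T(self) -> int:
        return self.means.shape[1]

    def second_moment_sum(self) -> np.ndarray:
        """Sum over trials and timesteps of E[x_t x_t']."""
        M, T, _ = self.means.shape
        return M * self.covs.sum(axis=0) + np.einsum("mti,mtj->ij", self.means, self.means)


def sample_lds(
    params: LDSParams, T: int, K: int, seed=None
) -> tuple[TrialDataset, np.ndarray]:
    """Draw K independent trials of length T; returns (dataset, latents)."""
    rng = np.random.default_rng(seed)
    D, N = params.D, params.N
    X = np.empty((K, T, D))
    X[:, 0] = rng.multivariate_normal(params.mu_x1, params.Sigma_x1, size=K)
    cq = np.linalg.cholesky(params.Q + _JITTER * np.eye(D))
    for t in range(1, T):
        X[:, t] = X[:, t - 1] @ params.A.T + params.b + rng.standard_normal((K, D)) @ cq.T
    cr = np.linalg.cholesky(params.R + _JITTER * np.eye(N))
    Y = np.einsum("ktd,nd->ktn", X, params.C) + rng.standard_normal((K, T, N)) @ cr.T
    data = TrialDataset(list(Y), np.zeros(K, dtype=int))
    return data, X


def _filter(params: LDSParams, Y: np.ndarray):
    """Batched Kalman filter. Y is (M, T, N)."""
    A, b, Q, C, R = params.A, params.b, params.Q, params.C, params.R
    M, T, N = Y.shape
    D = params.D
    m_pred = np.broadcast_to(params.mu_x1, (M, D)).copy()
    P_pred = params.Sigma_x1.copy()
    mf = np.empty((M, T, D))
    Pf = np.empty((T, D, D))
    m_preds = np.empty((M, T, D))
    P_preds = np.empty((T, D, D))
    ll = np.zeros(M)
    eye = np.eye(D)
    for t in range(T):
        m_preds[:, t] = m_pred
        P_preds[t] = P_pred
        S = C @ P_pred @ C.T + R
        cho = cho_factor(0.5 * (S + S.T), lower=True)
        v = Y[:, t] - m_pred @ C.T
        sol = cho_solve(cho, v.T)  # (N, M)
        logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
        ll += -0.5 * (N * np.log(2 * np.pi) + logdet + np.sum(v.T * sol, axis=0))
        K_gain = cho_solve(cho, (P_pred @ C.T).T).T  # (D, N)
        mf[:, t] = m_pred + v @ K_gain.T
        IKC = eye - K_gain @ C
        Pf[t] = IKC @ P_pred @ IKC.T + K_gain @ R @ K_gain.T
        m_pred = mf[:, t] @ A.T + b
        P_pred = A @ Pf[t] @ A.T + Q
    return mf, Pf, m_preds, P_preds, ll


def _filter_multi(params: LDSParams, Cs: np.ndarray, Y: np.ndarray):
    """Kalman filter over B independent chains that share everything but
    the emission matrix. Cs is (B, N, D); Y is (B, M, T, N)."""
    A, b, Q, R = params.A, params.b, params.Q, params.R
    B, M, T, N = Y.shape
    D = params.D
    m_pred = np.broadcast_to(params.mu_x1, (B, M, D)).copy()
    P_pred = np.broadcast_to(params.Sigma_x1, (B, D, D)).copy()
    mf = np.empty((B, M, T, D))
    Pf = np.empty((B, T, D, D))
    m_preds = np.empty((B, M, T, D))
    P_preds = np.empty((B, T, D, D))
    ll = np.zeros((B, M))
    eye = np.eye(D)
    CsT = np.swapaxes(Cs, 1, 2)  # (B, D, N)
    for t in range(T):
        m_preds[:, :, t] = m_pred
        P_preds[:, t] = P_pred
        S = Cs @ P_pred @ CsT + R  # (B, N, N)
        S = 0.5 * (S + np.swapaxes(S, 1, 2))
        v = Y[:, :, t] - np.einsum("bmd,bnd->bmn", m_pred, Cs)  # (B, M, N)
        sol = np.linalg.solve(S, np.swapaxes(v, 1, 2))  # (B, N, M)
        _, logdet = np.linalg.slogdet(S)
        quad = np.einsum("bmn,bnm->bm", v, sol)
        ll += -0.5 * (N * np.log(2 * np.pi) + logdet[:, None] + quad)
        PC = P_pred @ CsT  # (B, D, N)
        K = np.swapaxes(np.linalg.solve(S, np.swapaxes(PC, 1, 2)), 1, 2)  # (B, D, N)
        mf[:, :, t] = m_pred + np.einsum("bmn,bdn->bmd", v, K)
        IKC = eye - K @ Cs
        Pf[:, t] = IKC @ P_pred @ np.swapaxes(IKC, 1, 2) + K @ R @ np.swapaxes(K, 1, 2)
        m_pred = np.einsum("bmd,ed->bme", mf[:, :, t], A) + b
        P_pred = A @ Pf[:, t] @ A.T + Q
    return mf, Pf, m_preds, P_preds, ll


def kalman_smooth_multi(params: LDSParams, Cs: np.ndarray, Y: np.ndarray):
    """RTS smoothing of B equal-shaped blocks with per-block emissions.

    Returns per-block StatePosterior objects; numerically identical to
    running :func:`kalman_smooth` block by block, but with the block
    axis vectorized (the per-iteration hot path of the drift fit).
    """
    B, M, T, N = Y.shape
    D = params.D
    A = params.A
    mf, Pf, m_preds, P_preds, ll = _filter_multi(params, Cs, Y)
    ms = np.empty_like(mf)
    Ps = np.empty_like(Pf)
    cross = np.empty((B, max(T - 1, 0), D, D))
    ms[:, :, T - 1] = mf[:, :, T - 1]
    Ps[:, T - 1] = Pf[:, T - 1]
    for t in range(T - 2, -1, -1):
        Ppred = P_preds[:, t + 1]
        Ppred = 0.5 * (Ppred + np.swapaxes(Ppred, 1, 2))
        G = np.swapaxes(np.linalg.solve(Ppred, A @ Pf[:, t]), 1, 2)  # (B, D, D)
        ms[:, :, t] = mf[:, :, t] + np.einsum(
            "bmd,bed->bme", ms[:, :, t + 1] - m_preds[:, :, t + 1], G
        )
        Ps[:, t] = Pf[:, t] + G @ (Ps[:, t + 1] - P_preds[:, t + 1]) @ np.swapaxes(G, 1, 2)
        cross[:, t] = G @ Ps[:, t + 1]
    return [
        StatePosterior(means=ms[b], covs=Ps[b], cross=cross[b], loglik=ll[b])
        for b in range(B)
    ]


def kalman_smooth(params: LDSParams, Y: np.ndarray) -> StatePosterior:
    """Exact smoothed posterior for one trial (T, N) or a batch (M, T, N).

    All trials in the batch must share the parameters (in particular the
    emission matrix) and the length T. Uses the Rauch-Tung-Striebel
    backward recursion; the returned per-trial log-likelihoods come from
    the innovations of the forward pass.
    """
    Y = np.asarray(Y, dtype=float)
    single = Y.ndim == 2
    if single:
        Y = Y[None]
    if Y.ndim != 3 or Y.shape[2] != params.N:
        raise ValueError(f"expected (M, T, {params.N}) observations, got {Y.shape}")
    mf, Pf, m_preds, P_preds, ll = _filter(params, Y)
    M, T, D = mf.shape
    A = params.A
    ms = np.empty_like(mf)
    Ps = np.empty_like(Pf)
    cross = np.empty((max(T - 1, 0), D, D))
    ms[:, T - 1] = mf[:, T - 1]
    Ps[T - 1] = Pf[T - 1]
    for t in range(T - 2, -1, -1):
        Ppred = P_preds[t + 1]
        G = np.linalg.solve(0.5 * (Ppred + Ppred.T), A @ Pf[t]).T  # Pf A' Ppred^-1
        ms[:, t] = mf[:, t] + (ms[:, t + 1] - m_preds[:, t + 1]) @ G.T
        Ps[t] = Pf[t] + G @ (Ps[t + 1] - Ppred) @ G.T
        cross[t] = G @ Ps[t + 1]
    return StatePosterior(means=ms, covs=Ps, cross=cross, loglik=ll)


def _length_groups(data: TrialDataset, idx=None):
    """Group trial indices by length so each group can be batch-smoothed."""
    idx = np.arange(data.n_trials) if idx is None else np.asarray(idx)
    lengths = data.lengths[idx]
    for T in np.unique(lengths):
        sel = idx[lengths == T]
        Y = np.stack([data.trials[k] for k in sel])
        yield sel, Y


def smooth_dataset(params: LDSParams, data: TrialDataset) -> tuple[list[StatePosterior], np.ndarray]:
    """Smooth every trial; returns per-trial posteriors (batch of 1 views)
    grouped internally by length, and the per-trial log-likelihoods."""
    posts: list[StatePosterior | None] = [None] * data.n_trials
    ll = np.empty(data.n_trials)
    for sel, Y in _length_groups(data):
        post = kalman_smooth(params, Y)
        for j, k in enumerate(sel):
            posts[k] = StatePosterior(
                means=post.means[j : j + 1], covs=post.covs, cross=post.cross,
                loglik=post.loglik[j : j + 1],
            )
            ll[k] = post.loglik[j]
    return posts, ll


def marginal_log_likelihood(params: LDSParams, data: TrialDataset) -> float:
    """Exact log p(y) summed over trials (trials are independent)."""
    total = 0.0
    for _, Y in _length_groups(data):
        total += float(_filter(params, Y)[4].sum())
    return total


# ---------------------------------------------------------------------------
# EM
# ---------------------------------------------------------------------------

def _init_params(
    data: TrialDataset, D: int, r_mode: str = "diag", seed=None
) -> LDSParams:
    """PCA emission, slow near-identity dynamics, residual-variance R."""
    Y = data.pooled()
    Yc = Y - Y.mean(axis=0, keepdims=True)
    _, s, Vt = np.linalg.svd(Yc, full_matrices=False)
    C = Vt[:D].T
    resid = Yc - (Yc @ C) @ C.T
    rvar = np.maximum(resid.var(axis=0), 1e-4)
    R = np.diag(rvar) if r_mode == "diag" else np.diag(rvar).astype(float)
    return LDSParams(
        A=0.99 * np.eye(D), b=np.zeros(D), Q=np.eye(D), C=C, R=R,
        mu_x1=np.zeros(D), Sigma_x1=np.eye(D),
    )


def _dynamics_mstep(stats: dict, learn_bias: bool, D: int):
    """Closed-form update of (A, b, Q) from pairwise sufficient statistics."""
    n = stats["n_pairs"]
    if learn_bias:
        G = np.zeros((D + 1, D + 1))
        G[:D, :D] = stats["Sxx0"]
        G[:D, D] = stats["mu0"]
        G[D, :D] = stats["mu0"]
        G[D, D] = n
        H = np.concatenate([stats["Sx1x0"], stats["mu1"][:, None]], axis=1)
        Ab = _solve_reg(G, H.T, "dynamics").T
        A, b = Ab[:, :D], Ab[:, D]
        Q = (stats["Sxx1"] - Ab @ H.T - H @ Ab.T + Ab @ G @ Ab.T) / n
    else:
        A = _solve_reg(stats["Sxx0"], stats["Sx1x0"].T, "dynamics").T
        b = np.zeros(D)
        Q = (
            stats["Sxx1"] - A @ stats["Sx1x0"].T - stats["Sx1x0"] @ A.T
            + A @ stats["Sxx0"] @ A.T
        ) / n
    Q = 0.5 * (Q + Q.T) + 1e-8 * np.eye(D)
    return A, b, Q


def _solve_reg(G: np.ndarray, H: np.ndarray, what: str) -> np.ndarray:
    try:
        return np.linalg.solve(G, H)
    except np.linalg.LinAlgError:
        warnings.warn(f"singular sufficient statistics in {what} update; regularizing")
        return np.linalg.solve(G + 1e-6 * np.trace(G) / G.shape[0] * np.eye(G.shape[0]), H)


def _pair_stats(post: StatePosterior) -> dict:
    """Accumulate the (x_t, x_{t+1}) pair statistics from one batch."""
    m, P, X = post.means, post.covs, post.cross
    M, T, D = m.shape
    if T < 2:
        return dict(Sxx0=np.zeros((D, D)), Sxx1=np.zeros((D, D)), Sx1x0=np.zeros((D, D)),
                    mu0=np.zeros(D), mu1=np.zeros(D), n_pairs=0)
    Exx = M * P + np.einsum("mti,mtj->tij", m, m)  # (T, D, D)
    Sx1x0 = M * X.sum(axis=0).T + np.einsum("mti,mtj->ij", m[:, 1:], m[:, :-1])
    return dict(
        Sxx0=Exx[:-1].sum(axis=0),
        Sxx1=Exx[1:].sum(axis=0),
        Sx1x0=Sx1x0,
        mu0=m[:, :-1].sum(axis=(0, 1)),
        mu1=m[:, 1:].sum(axis=(0, 1)),
        n_pairs=M * (T - 1),
    )


def _add_stats(total: dict | None, s: dict) -> dict:
    if total is None:
        return {k: (v.copy() if isinstance(v, np.ndarray) else v) for k, v in s.items()}
    for k, v in s.items():
        total[k] = total[k] + v
    return total


def em_fit_lds(
    data: TrialDataset,
    D: int,
    init: LDSParams | None = None,
    max_iter: int = 50,
    tol: float = 1e-6,
    r_mode: str = "diag",
    learn_bias: bool = True,
    seed=None,
) -> tuple[LDSParams, np.ndarray]:
    """Fit an LDS by EM with closed-form M-steps.

    Returns the fitted parameters and the log-likelihood trace (one
    entry per iteration, evaluated before the M-step; nondecreasing up
    to numerical slack). ``tol`` is the relative LL change stopping rule.
    """
    if D > data.n_channels:
        raise ValueError(f"D={D} exceeds the number of channels N={data.n_channels}")
    params = init if init is not None else _init_params(data, D, r_mode, seed)
    N = data.n_channels
    trace = []
    for it in range(max_iter):
        pair = None
        Sxx_all = np.zeros((D, D))
        Myx = np.zeros((N, D))
        Syy = np.zeros((N, N))
        T_tot = 0
        m1_sum = np.zeros(D)
        S1_sum = np.zeros((D, D))
        M_tot = 0
        ll = 0.0
        for sel, Y in _length_groups(data):
            post = kalman_smooth(params, Y)
            ll += float(post.loglik.sum())
            pair = _add_stats(pair, _pair_stats(post))
            Sxx_all += post.second_moment_sum()
            Myx += np.einsum("mtn,mtd->nd", Y, post.means)
            Syy += np.einsum("mtn,mtj->nj", Y, Y)
            T_tot += Y.shape[0] * Y.shape[1]
            m1_sum += post.means[:, 0].sum(axis=0)
            S1_sum += Y.shape[0] * post.covs[0] + np.einsum(
                "mi,mj->ij", post.means[:, 0], post.means[:, 0]
            )
            M_tot += Y.shape[0]
        trace.append(ll)
        if it > 0 and abs(trace[-1] - trace[-2]) < tol * abs(trace[-2]):
            break
        # M-step
        A, b, Q = _dynamics_mstep(pair, learn_bias, D)
        C = _solve_reg(Sxx_all, Myx.T, "emission").T
        R = (Syy - C @ Myx.T - Myx @ C.T + C @ Sxx_all @ C.T) / T_tot
        R = 0.5 * (R + R.T)
        if r_mode == "diag":
            R = np.diag(np.maximum(np.diag(R), 1e-8))
        else:
            R += 1e-8 * np.eye(N)
        mu_x1 = m1_sum / M_tot
        Sigma_x1 = S1_sum / M_tot - np.outer(mu_x1, mu_x1)
        Sigma_x1 = 0.5 * (Sigma_x1 + Sigma_x1.T) + 1e-8 * np.eye(D)
        params = LDSParams(A=A, b=b, Q=Q, C=C, R=R, mu_x1=mu_x1, Sigma_x1=Sigma_x1)
    return params, np.asarray(trace)


class LinearGaussianSSM(BaseEstimator):
    """Linear-Gaussian state-space model, scikit-learn style.

    Parameters
    ----------
    n_components : int
        Latent state dimension D.
    max_iter, tol : EM stopping rule (relative log-likelihood change).
    r_mode : {"diag", "full"}
        Structure of the observation noise covariance.
    learn_bias : bool
        Whether to learn the dynamics bias b.

    Attributes
    ----------
    params_ : LDSParams
    loglik_trace_ : ndarray, per-iteration training log-likelihood.

    Examples
    --------
    >>> model = LinearGaussianSSM(n_components=2).fit(X, lengths)
    >>> model.score(X_new, lengths_new)
    """

    def __init__(self, n_components: int = 2, max_iter: int = 50, tol: float = 1e-6,
                 r_mode: str = "diag", learn_bias: bool = True, random_state=None):
        self.n_components = n_components
        self.max_iter = max_iter
        self.tol = tol
        self.r_mode = r_mode
        self.learn_bias = learn_bias
        self.random_state = random_state

    def _as_dataset(self, X, lengths=None, blocks=None) -> TrialDataset:
        if isinstance(X, TrialDataset):
            return X
        return TrialDataset.from_concatenated(X, lengths, blocks)

    def fit(self, X, lengths=None):
        data = self._as_dataset(X, lengths)
        self.params_, self.loglik_trace_ = em_fit_lds(
            data, self.n_components, max_iter=self.max_iter, tol=self.tol,
            r_mode=self.r_mode, learn_bias=self.learn_bias, seed=self.random_state,
        )
        return self

    def score(self, X, lengths=None) -> float:
        """Total exact marginal log-likelihood of the given trials."""
        return marginal_log_likelihood(self.params_, self._as_dataset(X, lengths))

    def smooth(self, X, lengths=None) -> list[StatePosterior]:
        """Per-trial smoothed posteriors under the fitted parameters."""
        return smooth_dataset(self.params_, self._as_dataset(X, lengths))[0]

    def sample(self, T: int, K: int = 1, seed=None):
        return sample_lds(self.params_, T, K, seed)
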