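"""Variational EM for the drifting-subspace state-space model.

Inference uses a structured mean-field posterior
``q(x) q(z) = q({z^(k)}) prod_k q(x^(k))`` and coordinate ascent:

1. **States.** With the emissions fixed at the current posterior-mean
   displacements, ``C^(k) = h(z_hat^(k))``, each trial reduces to an LDS
   and ``q(x^(k))`` is obtained by exact Kalman smoothing
   (:mod:`driftssm.lds`). Conditioning on the point estimate rather
   than propagating the full ``q(z)`` uncertainty is a deliberate,
   simpler approximation.

2. **Displacements.** The expected log-likelihood of a block, as a
   function of z, collapses into a single Gaussian *pseudo-observation*
   of ``vec(h(z))``: with ``S = sum_t E[x_t x_t']`` and
   ``M = sum_t y_t E[x_t]'`` per block,

       precision  = S (x) R^{-1}        (column-stacking vec)
       R_hat      = S^{-1} (x) R
       y_hat      = vec(M S^{-1}),

   so ``log N(y_hat; vec(h(z)), R_hat)`` equals the expected
   log-likelihood up to a z-independent constant. The chain of blocks
   with random-walk prior ``z^(k+1) = z^(k) + e^(k)`` and these
   nonlinear Gaussian observations is then smoothed with an extended
   Kalman smoother (first-order linearization of ``vec(h(.))`` at the
   predicted mean, RTS backward pass).

3. **M-step.** Dynamics and noise parameters update in closed form as
   in a standard LDS (with the per-block emissions fixed at
   ``h(z_hat^(k))``); ``m_z, S_z`` come from the first block's
   posterior; each drift rate ``tau2_i`` is set to the mode of its
   conjugate Inverse-Gamma posterior given the expected squared
   increments, then clipped at ``tau2_clip`` (the EKS linearization
   degrades when drift rates grow).

Model selection uses the estimated marginal log-likelihood on held-out
blocks: emissions at held-out blocks are predicted by linearly
interpolating the posterior-mean displacements of the flanking training
blocks (the random-walk bridge mean), then scored exactly as an LDS.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from sklearn.base import BaseEstimator

from .datasets import TrialDataset, make_splits
from .geometry import (
    EmissionFrame,
    displacement_dim,
    displacement_to_emission,
    emission_jacobian,
    vec,
)
from .lds import (
    StatePosterior,
    _add_stats,
    _dynamics_mstep,
    _length_groups,
    _pair_stats,
    em_fit_lds,
    kalman_smooth,
    kalman_smooth_multi,
    marginal_log_likelihood,
)
from .smds import SMDSParams

__all__ = [
    "PseudoObservation",
    "DisplacementPosterior",
    "FitConfig",
    "FitResult",
    "estep_states",
    "build_pseudo_observations",
    "eks_displacements",
    "mstep",
    "fit_smds",
    "heldout_log_likelihood",
    "predict_heldout_displacements",
    "dimension_sweep",
    "select_dimension",
    "StiefelDriftSSM",
]


@dataclass
class PseudoObservation:
    """Per-block Gaussian summary of the expected log-likelihood in z."""

    y_hat: np.ndarray  # (N*D,)
    R_hat: np.ndarray  # (N*D, N*D), SPD
    S: np.ndarray      # sum_t E[x x'] for the block (kept for the M-step)
    M: np.ndarray      # sum_t y E[x]'


@dataclass
class DisplacementPosterior:
    """Gaussian smoothed posterior over the block displacement chain."""

    means: np.ndarray   # (B, P)
    covs: np.ndarray    # (B, P, P)
    cross: np.ndarray   # (B-1, P, P), Cov(z^(k), z^(k+1))
    block_labels: np.ndarray  # (B,) original session block labels

    @property
    def n_blocks(self) -> int:
        return self.means.shape[0]


@dataclass
class FitConfig:
    """Tunables of the variational EM fit."""

    max_iter: int = 50
    tol: float = 1e-5
    ig_alpha: float = 2.0
    ig_beta: float = 1e-3
    tau2_clip: float = 1e-2
    tau2_init: float = 1e-4
    s_z_init: float = 1e-2
    r_mode: str = "diag"
    learn_bias: bool = True
    retraction: str = "cayley"


@dataclass
class FitResult:
    """Everything the downstream analyses need from one fit."""

    params: SMDSParams
    z_post: DisplacementPosterior
    state_groups: list  # [(block_position, Y, StatePosterior), ...]
    elbo_trace: np.ndarray
    diagnostics: list[dict] = field(default_factory=list)

    @property
    def emissions(self) -> np.ndarray:
        """Fitted per-block emission matrices h(z_hat^(k)), (B, N, D)."""
        return np.stack(
            [displacement_to_emission(z, self.params.frame) for z in self.z_post.means]
        )

    def state_posteriors(self) -> list[StatePosterior]:
        """Per-trial smoothed state posteriors, in dataset trial order."""
        out = {}
        for _, sel, _, post in self.state_groups:
            for j, k in enumerate(sel):
                out[k] = StatePosterior(
                    means=post.means[j : j + 1], covs=post.covs,
                    cross=post.cross, loglik=post.loglik[j : j + 1],
                )
        return [out[k] for k in sorted(out)]


# ---------------------------------------------------------------------------
# E-steps
# ---------------------------------------------------------------------------

def estep_states(params: SMDSParams, data: TrialDataset, z_means: np.ndarray):
    """Smooth all trials with emissions fixed at the given displacements.

    ``z_means`` has one row per block label in ``data.block_labels``
    order. Returns ``(groups, loglik)`` where ``groups`` is a list of
    ``(block_position, trial_indices, Y, StatePosterior)`` batches and
    ``loglik`` the exact total log-likelihood at the point estimate.
    """
    z_means = np.atleast_2d(z_means)
    labels = data.block_labels
    if z_means.shape[0] != labels.size:
        raise ValueError(
            f"need one displacement per block: got {z_means.shape[0]} for {labels.size} blocks"
        )
    Cs = np.stack([displacement_to_emission(z, params.frame) for z in z_means])
    groups = []
    total = 0.0
    # fast path: uniform trial lengths and equal-sized blocks let the
    # covariance recursions run batched over the block axis
    lengths = data.lengths
    counts = np.array([np.sum(data.block_of_trial == lab) for lab in labels])
    if lengths.min() == lengths.max() and counts.min() == counts.max():
        M, T = int(counts[0]), int(lengths[0])
        sels = [np.flatnonzero(data.block_of_trial == lab) for lab in labels]
        Y = np.stack([np.stack([data.trials[k] for k in sel]) for sel in sels])
        posts = kalman_smooth_multi(params.lds_view(Cs[0]), Cs, Y)
        for bi in range(labels.size):
            groups.append((bi, sels[bi], Y[bi], posts[bi]))
            total += float(posts[bi].loglik.sum())
        return groups, total
    for bi, lab in enumerate(labels):
        lds = params.lds_view(Cs[bi])
        sel_block = np.flatnonzero(data.block_of_trial == lab)
        for sel, Y in _length_groups(data, sel_block):
            post = kalman_smooth(lds, Y)
            groups.append((bi, sel, Y, post))
            total += float(post.loglik.sum())
    return groups, total


def build_pseudo_observations(
    Y_blocks, posts, R: np.ndarray
) -> PseudoObservation:
    """Collapse a block's expected log-likelihood into one Gaussian
    observation of vec(h(z)).

    Parameters
    ----------
    Y_blocks : list of (M, T, N) arrays — the block's trials.
    posts : matching list of StatePosterior batches.
    R : observation noise covariance.
    """
    N = np.atleast_2d(R).shape[0]
    D = posts[0].means.shape[2]
    S = np.zeros((D, D))
    M = np.zeros((N, D))
    for Y, post in zip(Y_blocks, posts):
        S += post.second_moment_sum()
        M += np.einsum("mtn,mtd->nd", Y, post.means)
    S = 0.5 * (S + S.T)
    try:
        S_inv = np.linalg.inv(S)
    except np.linalg.LinAlgError:
        warnings.warn("singular sum of state second moments; regularizing")
        S_inv = np.linalg.inv(S + 1e-8 * np.trace(S) / D * np.eye(D))
    R_hat = np.kron(S_inv, np.atleast_2d(R))  # (S (x) R^-1)^-1 under column-stacking vec
    y_hat = vec(M @ S_inv)
    return PseudoObservation(y_hat=y_hat, R_hat=0.5 * (R_hat + R_hat.T), S=S, M=M)


def _eks_chain(ys, Rs, g, J, m0, S0, Q):
    """Extended Kalman filter + RTS smoother on a chain with identity
    dynamics, process noise Q, prior N(m0, S0) and observation model
    y^(k) ~ N(g(z^(k)), Rs[k]) linearized at the predicted mean.

    Exact when g is affine. Returns (means, covs, cross)."""
    K = len(ys)
    P = m0.size
    mf = np.empty((K, P))
    Pf = np.empty((K, P, P))
    m_pred_prev = None
    for k in range(K):
        if k == 0:
            m_pred, P_pred = m0.copy(), S0.copy()
        else:
            m_pred, P_pred = mf[k - 1].copy(), Pf[k - 1] + Q
        H = J(m_pred)
        v = ys[k] - g(m_pred)
        S_inn = H @ P_pred @ H.T + Rs[k]
        try:
            cho = cho_factor(0.5 * (S_inn + S_inn.T), lower=True)
        except np.linalg.LinAlgError:
            raise np.linalg.LinAlgError(
                f"non-positive-definite innovation covariance at block {k}"
            ) from None
        K_gain = cho_solve(cho, H @ P_pred).T
        mf[k] = m_pred + K_gain @ v
        IKH = np.eye(P) - K_gain @ H
        Pf[k] = IKH @ P_pred @ IKH.T + K_gain @ Rs[k] @ K_gain.T
    ms = np.empty_like(mf)
    Ps = np.empty_like(Pf)
    cross = np.empty((max(K - 1, 0), P, P))
    ms[K - 1] = mf[K - 1]
    Ps[K - 1] = Pf[K - 1]
    for k in range(K - 2, -1, -1):
        P_pred = Pf[k] + Q
        G = np.linalg.solve(0.5 * (P_pred + P_pred.T), Pf[k]).T
        ms[k] = mf[k] + G @ (ms[k + 1] - mf[k])
        Ps[k] = Pf[k] + G @ (Ps[k + 1] - P_pred) @ G.T
        cross[k] = G @ Ps[k + 1]
    return ms, Ps, cross


def eks_displacements(
    params: SMDSParams,
    pseudo: list[PseudoObservation],
    block_labels=None,
    g=None,
    J=None,
) -> DisplacementPosterior:
    """Extended Kalman smoothing of the displacement chain.

    One pseudo-observation per block, in chain order. ``g``/``J``
    override the emission map and its Jacobian (used by tests to check
    exactness on affine maps); the defaults are ``vec(h(.))`` and its
    Cayley-differential Jacobian.
    """
    frame = params.frame
    if g is None:
        g = lambda z: vec(displacement_to_emission(z, frame))  # noqa: E731
    if J is None:
        J = lambda z: emission_jacobian(z, frame)  # noqa: E731
    Q = np.diag(params.tau2)
    ms, Ps, cross = _eks_chain(
        [p.y_hat for p in pseudo], [p.R_hat for p in pseudo], g, J,
        params.m_z, params.S_z, Q,
    )
    labels = np.arange(len(pseudo)) if block_labels is None else np.asarray(block_labels)
    return DisplacementPosterior(means=ms, covs=Ps, cross=cross, block_labels=labels)


# ---------------------------------------------------------------------------
# M-step
# ---------------------------------------------------------------------------

def expected_squared_increments(zpost: DisplacementPosterior) -> np.ndarray:
    """Per-coordinate sums over k of E[(z_i^(k+1) - z_i^(k))^2]."""
    m, P, X = zpost.means, zpost.covs, zpost.cross
    if zpost.n_blocks < 2:
        return np.zeros(m.shape[1])
    dm = np.diff(m, axis=0)
    var = np.einsum("kii->ki", P)
    cross = np.einsum("kii->ki", X)
    return np.sum(dm**2 + var[1:] + var[:-1] - 2 * cross, axis=0)


def mstep(
    groups,
    zpost: DisplacementPosterior,
    params: SMDSParams,
    config: FitConfig,
) -> tuple[SMDSParams, dict]:
    """Closed-form parameter updates given both posteriors.

    Returns the new parameters and a diagnostics dict (pre/post-clip
    tau2 ranges and whether the clip bound was active).
    """
    D, N, P = params.D, params.N, params.P
    pair = None
    Syy = np.zeros((N, N))
    RC_term = np.zeros((N, N))
    T_tot = 0
    m1_sum = np.zeros(D)
    S1_sum = np.zeros((D, D))
    M_tot = 0
    C_blocks = {bi: displacement_to_emission(zpost.means[bi], params.frame)
                for bi in range(zpost.n_blocks)}
    for bi, _, Y, post in groups:
        pair = _add_stats(pair, _pair_stats(post))
        C = C_blocks[bi]
        Sb = post.second_moment_sum()
        Mb = np.einsum("mtn,mtd->nd", Y, post.means)
        Syy += np.einsum("mtn,mtj->nj", Y, Y)
        RC_term += C @ Mb.T + Mb @ C.T - C @ Sb @ C.T
        T_tot += Y.shape[0] * Y.shape[1]
        m1_sum += post.means[:, 0].sum(axis=0)
        S1_sum += Y.shape[0] * post.covs[0] + np.einsum(
            "mi,mj->ij", post.means[:, 0], post.means[:, 0]
        )
        M_tot += Y.shape[0]
    A, b, Q = _dynamics_mstep(pair, config.learn_bias, D)
    if not config.learn_bias:
        b = np.zeros(D)
    R = (Syy - RC_term) / T_tot
    R = 0.5 * (R + R.T)
    if config.r_mode == "diag":
        R = np.diag(np.maximum(np.diag(R), 1e-8))
    else:
        R += 1e-8 * np.eye(N)
    mu_x1 = m1_sum / M_tot
    Sigma_x1 = S1_sum / M_tot - np.outer(mu_x1, mu_x1)
    Sigma_x1 = 0.5 * (Sigma_x1 + Sigma_x1.T) + 1e-8 * np.eye(D)
    # displacement prior: first-block posterior
    m_z = zpost.means[0].copy()
    S_z = 0.5 * (zpost.covs[0] + zpost.covs[0].T) + 1e-10 * np.eye(P)
    # drift rates: Inverse-Gamma posterior mode, then clip
    K = zpost.n_blocks
    if K > 1:
        ss = expected_squared_increments(zpost)
        tau2_raw = (config.ig_beta + 0.5 * ss) / (config.ig_alpha + 1.0 + 0.5 * (K - 1))
    else:
        tau2_raw = params.tau2.copy()
    tau2 = np.minimum(np.maximum(tau2_raw, 1e-12), config.tau2_clip)
    diag = dict(
        tau2_pre_clip=(float(tau2_raw.min()), float(tau2_raw.max())),
        tau2=(float(tau2.min()), float(tau2.max())),
        clip_active=bool(np.any(tau2_raw > config.tau2_clip)),
    )
    new = SMDSParams(
        A=A, b=b, Q=Q, R=R, mu_x1=mu_x1, Sigma_x1=Sigma_x1,
        frame=params.frame, m_z=m_z, S_z=S_z, tau2=tau2,
        ig_alpha=config.ig_alpha, ig_beta=config.ig_beta, tau2_clip=config.tau2_clip,
    )
    return new, diag


# ---------------------------------------------------------------------------
# Objective proxy
# ---------------------------------------------------------------------------

def _elbo_proxy(data_ll: float, zpost: DisplacementPosterior, params: SMDSParams,
                config: FitConfig) -> float:
    """Tractable stand-in for the ELBO: exact data log-likelihood at the
    posterior-mean displacements, plus the expected drift-prior log
    density and the (marginal) entropy of q(z), plus the log
    Inverse-Gamma prior on tau2. Monotone up to the EKS linearization
    and point-estimate approximations."""
    m, P, X = zpost.means, zpost.covs, zpost.cross
    Pdim = m.shape[1]
    sign, logdet_Sz = np.linalg.slogdet(params.S_z)
    d1 = m[0] - params.m_z
    Sz_inv_term = np.trace(np.linalg.solve(params.S_z, P[0] + np.outer(d1, d1)))
    lp = -0.5 * (Pdim * np.log(2 * np.pi) + logdet_Sz + Sz_inv_term)
    if zpost.n_blocks > 1:
        ss = expected_squared_increments(zpost)
        K1 = zpost.n_blocks - 1
        lp += -0.5 * (
            K1 * Pdim * np.log(2 * np.pi)
            + K1 * np.sum(np.log(params.tau2))
            + np.sum(ss / params.tau2)
        )
    ent = 0.5 * sum(
        np.linalg.slogdet(2 * np.pi * np.e * P[k])[1] for k in range(zpost.n_blocks)
    )
    a, bb = config.ig_alpha, config.ig_beta
    lp_tau = np.sum(
        a * np.log(bb) - math.lgamma(a) - (a + 1) * np.log(params.tau2) - bb / params.tau2
    )
    return float(data_ll + lp + ent + lp_tau)


# ---------------------------------------------------------------------------
# Full fit
# ---------------------------------------------------------------------------

def _init_smds(data: TrialDataset, D: int, config: FitConfig) -> SMDSParams:
    Y = data.pooled()
    frame = EmissionFrame.from_data(Y, D, retraction=config.retraction)
    P = displacement_dim(D, data.n_channels)
    Yc = Y - Y.mean(axis=0, keepdims=True)
    C0 = frame.U_base[:, :D]
    resid = Yc - (Yc @ C0) @ C0.T
    rvar = np.maximum(resid.var(axis=0), 1e-4)
    return SMDSParams(
        A=0.99 * np.eye(D), b=np.zeros(D), Q=np.eye(D),
        R=np.diag(rvar), mu_x1=np.zeros(D), Sigma_x1=np.eye(D),
        frame=frame, m_z=np.zeros(P), S_z=config.s_z_init * np.eye(P),
        tau2=np.full(P, min(config.tau2_init, config.tau2_clip)),
        ig_alpha=config.ig_alpha, ig_beta=config.ig_beta, tau2_clip=config.tau2_clip,
    )


def fit_smds(
    data: TrialDataset,
    D: int,
    config: FitConfig | None = None,
    init: SMDSParams | None = None,
    verbose: bool = False,
) -> FitResult:
    """Fit the drifting-subspace model by coordinate-ascent variational EM.

    The ambient frame U_base is set once from the principal components
    of the pooled training data; displacements start at zero (so the
    initial emission is the top-D principal subspace) and the loop
    alternates state smoothing, pseudo-observation construction,
    displacement EKS, and the closed-form M-step until the objective
    proxy changes by less than ``config.tol`` (relative) or
    ``config.max_iter`` iterations. Deterministic given the data.
    """
    config = config or FitConfig()
    if D > data.n_channels:
        raise ValueError(f"D={D} exceeds N={data.n_channels}")
    params = init if init is not None else _init_smds(data, D, config)
    labels = data.block_labels
    B = labels.size
    z_means = np.tile(params.m_z, (B, 1))
    zpost = DisplacementPosterior(
        means=z_means, covs=np.tile(params.S_z, (B, 1, 1)),
        cross=np.zeros((B - 1, params.P, params.P)), block_labels=labels,
    )
    trace = []
    diagnostics = []
    groups = None
    for it in range(config.max_iter):
        groups, data_ll = estep_states(params, data, zpost.means)
        if not np.isfinite(data_ll):
            raise RuntimeError(f"divergence at iteration {it}: non-finite log-likelihood")
        # collate per-block batches for the pseudo-observations
        pseudo = []
        for bi in range(B):
            Ys = [Y for (b, _, Y, _) in groups if b == bi]
            ps = [p for (b, _, _, p) in groups if b == bi]
            pseudo.append(build_pseudo_observations(Ys, ps, params.R))
        prev_means = zpost.means
        zpost = eks_displacements(params, pseudo, block_labels=labels)
        max_step = float(np.max(np.abs(zpost.means - prev_means)))
        params, mdiag = mstep(groups, zpost, params, config)
        proxy = _elbo_proxy(data_ll, zpost, params, config)
        trace.append(proxy)
        diagnostics.append(dict(iteration=it, elbo_proxy=proxy, data_loglik=data_ll,
                                max_z_step=max_step, **mdiag))
        if verbose:
            print(f"iter {it:3d}  proxy {proxy:.2f}  ll {data_ll:.2f}  "
                  f"max|dz| {max_step:.2e}  tau2 {mdiag['tau2']}")
        if it > 0 and abs(trace[-1] - trace[-2]) < config.tol * abs(trace[-2]):
            break
    # final state pass so posteriors are consistent with the last z update
    groups, data_ll = estep_states(params, data, zpost.means)
    return FitResult(params=params, z_post=zpost, state_groups=groups,
                     elbo_trace=np.asarray(trace), diagnostics=diagnostics)


# ---------------------------------------------------------------------------
# Held-out evaluation and model selection
# ---------------------------------------------------------------------------

def predict_heldout_displacements(
    zpost: DisplacementPosterior, heldout_labels
) -> np.ndarray:
    """Displacements at unseen block labels by linear interpolation of
    the training posterior means (the random-walk bridge mean between
    flanking blocks); nearest-end beyond the training range."""
    train = np.asarray(zpost.block_labels, dtype=float)
    held = np.asarray(heldout_labels, dtype=float)
    if held.size and (held.min() < train.min() or held.max() > train.max()):
        warnings.warn("held-out block outside the training range; using nearest-end value")
    return np.stack(
        [np.interp(held, train, zpost.means[:, i]) for i in range(zpost.means.shape[1])],
        axis=1,
    )


def heldout_log_likelihood(fit: FitResult, heldout: TrialDataset) -> float:
    """Exact LDS marginal log-likelihood of held-out trials under the
    shared dynamics and interpolated per-block emissions."""
    labels = heldout.block_labels
    z_pred = predict_heldout_displacements(fit.z_post, labels)
    total = 0.0
    for i, lab in enumerate(labels):
        C = displacement_to_emission(z_pred[i], fit.params.frame)
        sub = heldout.subset_blocks([lab])
        total += marginal_log_likelihood(fit.params.lds_view(C), sub)
    return total


def dimension_sweep(
    data: TrialDataset,
    dims,
    n_splits: int = 3,
    heldout_blocks_per_split: int | None = None,
    seed: int | None = 0,
    config: FitConfig | None = None,
    include_lds: bool = True,
    lds_max_iter: int = 50,
) -> pd.DataFrame:
    """Held-out log-likelihood over a grid of latent dimensions.

    Blocks are split ``n_splits`` times (default hold-out: ~10% of
    blocks, at least 2); for every split and every D the drift model —
    and optionally a baseline LDS — is fitted on the training blocks and
    scored on the held-out blocks. Returns a tidy DataFrame with columns
    (model, D, split, heldout_ll, n_heldout_trials).
    """
    config = config or FitConfig()
    if heldout_blocks_per_split is None:
        heldout_blocks_per_split = max(2, data.n_blocks // 10)
    splits = make_splits(data, n_splits, heldout_blocks_per_split, seed)
    rows = []
    for si, sp in enumerate(splits):
        train = data.subset_blocks(sp["train"])
        held = data.subset_blocks(sp["heldout"])
        for D in dims:
            fit = fit_smds(train, D, config)
            rows.append(dict(model="drift", D=D, split=si,
                             heldout_ll=heldout_log_likelihood(fit, held),
                             n_heldout_trials=held.n_trials))
            if include_lds:
                lparams, _ = em_fit_lds(
                    train, D, max_iter=lds_max_iter, r_mode=config.r_mode,
                    learn_bias=config.learn_bias,
                )
                rows.append(dict(model="lds", D=D, split=si,
                                 heldout_ll=marginal_log_likelihood(lparams, held),
                                 n_heldout_trials=held.n_trials))
    return pd.DataFrame(rows)


def select_dimension(sweep: pd.DataFrame, model: str = "drift") -> tuple[int, pd.DataFrame]:
    """Smallest dimension whose mean held-out LL is within one standard
    error (across splits) of the best dimension's mean."""
    sub = sweep[sweep["model"] == model]
    table = (
        sub.groupby("D")["heldout_ll"]
        .agg(mean="mean", se=lambda x: x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else 0.0)
        .reset_index()
    )
    best = table.loc[table["mean"].idxmax()]
    ok = table[table["mean"] >= best["mean"] - best["se"]]
    return int(ok["D"].min()), table


# ---------------------------------------------------------------------------
# scikit-learn estimator
# ---------------------------------------------------------------------------

class StiefelDriftSSM(BaseEstimator):
    """State-space model with a drifting orthonormal emission subspace.

    scikit-learn-style estimator over trial-structured data: ``X`` is
    the (sum T_k, N) concatenation of trials, ``lengths`` the per-trial
    lengths, and ``blocks`` one block label per trial (consecutive
    trials sharing an emission matrix).

    Parameters mirror :class:`FitConfig`; ``n_components`` is the latent
    state dimension D.

    Attributes
    ----------
    params_ : SMDSParams — fitted model parameters (incl. U_base, tau2).
    displacement_posterior_ : DisplacementPosterior
    emissions_ : (B, N, D) fitted per-block emission matrices.
    elbo_trace_ : per-iteration objective proxy.
    """

    def __init__(self, n_components: int = 2, max_iter: int = 50, tol: float = 1e-5,
                 ig_alpha: float = 2.0, ig_beta: float = 1e-3, tau2_clip: float = 1e-2,
                 r_mode: str = "diag", learn_bias: bool = True, retraction: str = "cayley"):
        self.n_components = n_components
        self.max_iter = max_iter
        self.tol = tol
        self.ig_alpha = ig_alpha
        self.ig_beta = ig_beta
        self.tau2_clip = tau2_clip
        self.r_mode = r_mode
        self.learn_bias = learn_bias
        self.retraction = retraction

    def _config(self) -> FitConfig:
        return FitConfig(
            max_iter=self.max_iter, tol=self.tol, ig_alpha=self.ig_alpha,
            ig_beta=self.ig_beta, tau2_clip=self.tau2_clip, r_mode=self.r_mode,
            learn_bias=self.learn_bias, retraction=self.retraction,
        )

    @staticmethod
    def _as_dataset(X, lengths=None, blocks=None) -> TrialDataset:
        if isinstance(X, TrialDataset):
            return X
        return TrialDataset.from_concatenated(X, lengths, blocks)

    def fit(self, X, lengths=None, blocks=None):
        data = self._as_dataset(X, lengths, blocks)
        self.fit_result_ = fit_smds(data, self.n_components, self._config())
        self.params_ = self.fit_result_.params
        self.displacement_posterior_ = self.fit_result_.z_post
        self.emissions_ = self.fit_result_.emissions
        self.elbo_trace_ = self.fit_result_.elbo_trace
        return self

    def score(self, X, lengths=None, blocks=None) -> float:
        """Held-out marginal log-likelihood with emissions interpolated
        from the fitted drift chain at the given block labels."""
        return heldout_log_likelihood(self.fit_result_, self._as_dataset(X, lengths, blocks))
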