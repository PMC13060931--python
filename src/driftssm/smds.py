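"""Generative model with a drifting orthonormal emission subspace.

The model keeps the linear-Gaussian latent dynamics of an LDS but lets
the emission matrix move across trial *blocks* on the Stiefel manifold:
a displacement vector z^(k) performs a Gaussian random walk,

    z^(1)   ~ N(m_z, S_z)
    z^(k+1) = z^(k) + e^(k),   e^(k) ~ N(0, diag(tau2)),

and each block's emission is C^(k) = h(z^(k)) = U_base f(B(z^(k))) O,
with per-coordinate drift rates tau2 so each subspace axis may rotate
at its own speed. Within a block all trials share C^(k); the dynamics
parameters (A, b, Q) are shared across the whole session.

An Inverse-Gamma(ig_alpha, ig_beta) prior regularizes each tau2 entry
during fitting, and tau2 is clipped at ``tau2_clip`` after every M-step
(the first-order smoother linearization degrades for large drift rates).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import TrialDataset
from .geometry import EmissionFrame, displacement_dim, displacement_to_emission
from .lds import LDSParams, _check_spd, _JITTER

__all__ = [
    "SMDSParams",
    "DriftPath",
    "sample_drift_path",
    "sample_smds",
    "block_conditional_loglik",
    "simulation_config",
    "tau2_for_block_angle",
]


@dataclass
class SMDSParams:
    """Parameters of the drifting-subspace state-space model."""

    A: np.ndarray
    b: np.ndarray
    Q: np.ndarray
    R: np.ndarray
    mu_x1: np.ndarray
    Sigma_x1: np.ndarray
    frame: EmissionFrame
    m_z: np.ndarray
    S_z: np.ndarray
    tau2: np.ndarray
    ig_alpha: float = 2.0
    ig_beta: float = 1e-3
    tau2_clip: float = 1e-2

    def __post_init__(self) -> None:
        D, N = self.frame.D, self.frame.N
        P = displacement_dim(D, N)
        self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
        self.b = np.asarray(self.b, dtype=float).ravel()
        self.mu_x1 = np.asarray(self.mu_x1, dtype=float).ravel()
        self.m_z = np.asarray(self.m_z, dtype=float).ravel()
        self.tau2 = np.broadcast_to(np.asarray(self.tau2, dtype=float), (P,)).copy()
        if self.A.shape != (D, D) or self.b.shape != (D,) or self.mu_x1.shape != (D,):
            raise ValueError("dynamics shapes inconsistent with the frame's D")
        if self.m_z.shape != (P,):
            raise ValueError(f"m_z must have length {P}")
        if np.any(self.tau2 < 0):
            raise ValueError("tau2 must be nonnegative")
        if np.any(self.tau2 > self.tau2_clip + 1e-12):
            raise ValueError("tau2 exceeds tau2_clip")
        self.Q = _check_spd(np.atleast_2d(self.Q), "Q")
        self.R = _check_spd(np.atleast_2d(self.R), "R")
        self.Sigma_x1 = _check_spd(np.atleast_2d(self.Sigma_x1), "Sigma_x1")
        self.S_z = np.atleast_2d(np.asarray(self.S_z, dtype=float))
        if self.S_z.shape != (P, P):
            raise ValueError(f"S_z must be {P} x {P}")

    @property
    def D(self) -> int:
        return self.frame.D

    @property
    def N(self) -> int:
        return self.frame.N

    @property
    def P(self) -> int:
        return displacement_dim(self.D, self.N)

    def lds_view(self, C: np.ndarray) -> LDSParams:
        """The block-conditional LDS obtained by fixing the emission at C."""
        return LDSParams(A=self.A, b=self.b, Q=self.Q, C=C, R=self.R,
                         mu_x1=self.mu_x1, Sigma_x1=self.Sigma_x1)


@dataclass
class DriftPath:
    """A realized drift trajectory: displacements and their emissions."""

    z_blocks: np.ndarray  # (B, P)
    C_blocks: np.ndarray  # (B, N, D)

    @property
    def n_blocks(self) -> int:
        return self.z_blocks.shape[0]


def sample_drift_path(params: SMDSParams, n_blocks: int, seed=None) -> DriftPath:
    """Draw a displacement random walk and its emission matrices."""
    if n_blocks < 1:
        raise ValueError("need at least one block")
    rng = np.random.default_rng(seed)
    P = params.P
    z = np.empty((n_blocks, P))
    # PSD square root: exact for singular S_z (e.g. a degenerate prior)
    evals, evecs = np.linalg.eigh(params.S_z)
    cS = evecs * np.sqrt(np.clip(evals, 0.0, None))
    z[0] = params.m_z + cS @ rng.standard_normal(P)
    step = np.sqrt(params.tau2)
    for k in range(1, n_blocks):
        z[k] = z[k - 1] + step * rng.standard_normal(P)
    C = np.stack([displacement_to_emission(zk, params.frame) for zk in z])
    return DriftPath(z_blocks=z, C_blocks=C)


def sample_smds(
    params: SMDSParams,
    n_blocks: int,
    trials_per_block: int,
    T: int,
    seed=None,
) -> tuple[TrialDataset, DriftPath, np.ndarray]:
    """Simulate a full session: drift path, latent states, observations.

    Returns (dataset, drift path, latents) with latents of shape
    (n_trials, T, D). All trials in block k use that block's emission.
    """
    rng = np.random.default_rng(seed)
    path = sample_drift_path(params, n_blocks, rng)
    D, N = params.D, params.N
    K = n_blocks * trials_per_block
    X = np.empty((K, T, D))
    X[:, 0] = rng.multivariate_normal(params.mu_x1, params.Sigma_x1, size=K)
    cq = np.linalg.cholesky(params.Q + _JITTER * np.eye(D))
    for t in range(1, T):
        X[:, t] = X[:, t - 1] @ params.A.T + params.b + rng.standard_normal((K, D)) @ cq.T
    cr = np.linalg.cholesky(params.R + _JITTER * np.eye(N))
    blocks = np.repeat(np.arange(n_blocks), trials_per_block)
    Y = np.einsum("ktd,knd->ktn", X, path.C_blocks[blocks]) + rng.standard_normal((K, T, N)) @ cr.T
    return TrialDataset(list(Y), blocks), path, X


def block_conditional_loglik(
    params: SMDSParams, data: TrialDataset, z_blocks: np.ndarray
) -> float:
    """log p(y | z) with the displacement chain fixed: exact LDS
    likelihood per block with C^(k) = h(z^(k))."""
    from .lds import marginal_log_likelihood

    labels = data.block_labels
    z_blocks = np.atleast_2d(z_blocks)
    if z_blocks.shape[0] != labels.size:
        raise ValueError("need one displacement per block present in the data")
    total = 0.0
    for i, lab in enumerate(labels):
        C = displacement_to_emission(z_blocks[i], params.frame)
        total += marginal_log_likelihood(params.lds_view(C), data.subset_blocks([lab]))
    return total


# ---------------------------------------------------------------------------
# Simulation recipes
# ---------------------------------------------------------------------------

def _rotation_dynamics(D: int, degrees_per_step, damping: float = 0.97) -> np.ndarray:
    """Block-diagonal damped rotations; one 2x2 plane per pair of dims."""
    degs = np.atleast_1d(np.asarray(degrees_per_step, dtype=float))
    A = np.eye(D)
    for p in range(D // 2):
        th = np.radians(degs[p % len(degs)])
        A[2 * p : 2 * p + 2, 2 * p : 2 * p + 2] = [
            [np.cos(th), -np.sin(th)],
            [np.sin(th), np.cos(th)],
        ]
    return damping * A


def tau2_for_block_angle(angle_deg: float, D: int, N: int) -> float:
    """Per-coordinate drift rate giving ~angle_deg of subspace rotation
    per block.

    For small displacements the Cayley map is I - 2B, so a step with
    i.i.d. coordinate noise of std tau tilts the subspace by roughly
    ||2 dV||_F = 2 tau sqrt(D(N-D)) radians of Grassmann distance.
    """
    tau = np.radians(angle_deg) / (2.0 * np.sqrt(D * (N - D)))
    return float(tau**2)


def simulation_config(
    name: str,
    n_trials: int | None = None,
    trials_per_block: int = 5,
    T: int = 30,
    drift_deg_per_block: float = 0.8,
) -> tuple[SMDSParams, dict]:
    """Fully-specified synthetic-session generators.

    ``"main"``: D=2 latent dimensions observed through N=10 channels,
    750 trials of 30 timesteps by default, with the emission subspace
    rotating smoothly across blocks. ``"highdim"``: the same recipe at
    D=8, N=24. Constants (damped rotational dynamics, noise scales, and
    a drift rate of ~0.8 degrees of subspace rotation per block) are
    package defaults chosen so that session-level drift is large while
    per-block steps stay in the small-displacement regime the smoother's
    linearization assumes.

    Returns (params, sizes) where sizes has n_blocks, trials_per_block, T.
    """
    if name == "main":
        D, N = 2, 10
        n_trials = 750 if n_trials is None else n_trials
        A = _rotation_dynamics(D, [15.0])
    elif name == "highdim":
        D, N = 8, 24
        n_trials = 750 if n_trials is None else n_trials
        A = _rotation_dynamics(D, [6.0, 10.0, 15.0, 21.0])
    else:
        raise ValueError(f"unknown simulation config {name!r}; use 'main' or 'highdim'")
    P = displacement_dim(D, N)
    tau2 = tau2_for_block_angle(drift_deg_per_block, D, N)
    params = SMDSParams(
        A=A,
        b=np.zeros(D),
        Q=0.05 * np.eye(D),
        R=0.1 * np.eye(N),
        mu_x1=np.zeros(D),
        Sigma_x1=np.eye(D),
        frame=EmissionFrame.identity(N, D),
        m_z=np.zeros(P),
        S_z=0.01 * np.eye(P),
        tau2=np.full(P, tau2),
        tau2_clip=max(1e-2, 2 * tau2),
    )
    n_blocks = int(np.ceil(n_trials / trials_per_block))
    sizes = dict(D=D, N=N, n_blocks=n_blocks, trials_per_block=trials_per_block, T=T,
                 n_trials=n_blocks * trials_per_block)
    return params, sizes
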