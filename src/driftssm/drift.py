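"""Drift quantification and diagnostics.

Summarizes how the emission subspace moves over a session: pairwise
normalized Grassmann distances between block emissions, a model-free
sliding-window PCA version computed on the raw data, per-dimension
drift angles in degrees, and per-dimension explained-variance
fractions (columns of an orthonormal emission contribute their latent
variance directly to the observed variance).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .datasets import TrialDataset
from .geometry import grassmann_distance, per_dimension_drift

__all__ = [
    "DriftReport",
    "pairwise_drift_matrix",
    "sliding_window_pca_drift",
    "variance_per_dimension",
    "drift_report",
]


def pairwise_drift_matrix(C_blocks) -> np.ndarray:
    """B x B matrix of normalized Grassmann distances between block
    emissions: symmetric, zero diagonal, entries in [0, 1]."""
    Cs = [np.asarray(C, dtype=float) for C in C_blocks]
    B = len(Cs)
    if B < 2:
        raise ValueError("need at least two blocks")
    out = np.zeros((B, B))
    for i in range(B):
        for j in range(i + 1, B):
            out[i, j] = out[j, i] = grassmann_distance(Cs[i], Cs[j], normalized=True)
    return out


def _window_subspace(Y: np.ndarray, n_components: int, center: bool) -> np.ndarray:
    if center:
        Y = Y - Y.mean(axis=0, keepdims=True)
    _, s, Vt = np.linalg.svd(Y, full_matrices=False)
    if np.sum(s > 1e-12) < n_components:
        raise ValueError(
            f"window data has rank < {n_components}; enlarge the window"
        )
    return Vt[:n_components].T


def sliding_window_pca_drift(
    data: TrialDataset,
    n_components: int,
    window: int,
    stride: int | None = None,
    center: bool = True,
) -> np.ndarray:
    """Model-free subspace drift from raw data.

    Trials within each sliding window (``window`` trials wide, sliding
    by ``stride``, default window/4) are concatenated in time; the top
    ``n_components`` principal subspace is extracted per window and the
    pairwise normalized Grassmann distance matrix between window
    subspaces is returned (1 x 1 zero matrix if one window covers all
    trials).
    """
    if window > data.n_trials:
        raise ValueError(f"window of {window} trials exceeds the {data.n_trials} available")
    if n_components > data.n_channels:
        raise ValueError("n_components exceeds the number of channels")
    stride = max(1, window // 4) if stride is None else stride
    starts = list(range(0, data.n_trials - window + 1, stride))
    subs = []
    for s in starts:
        Y = np.concatenate(data.trials[s : s + window], axis=0)
        subs.append(_window_subspace(Y, n_components, center))
    if len(subs) == 1:
        return np.zeros((1, 1))
    return pairwise_drift_matrix(subs)


def variance_per_dimension(state_posteriors) -> np.ndarray:
    """Fraction of total latent second moment per latent coordinate,
    pooled over trials and timesteps; sums to 1."""
    if not state_posteriors:
        raise ValueError("empty posterior list")
    D = state_posteriors[0].means.shape[2]
    total = np.zeros(D)
    for post in state_posteriors:
        total += np.diag(post.second_moment_sum())
    return total / total.sum()


@dataclass
class DriftReport:
    """Serializable drift summary for one fitted session.

    ``scores`` is an optional user-supplied per-dimension column (e.g.
    behavioral decoding accuracy) so external analyses can be joined.
    """

    pairwise: np.ndarray        # (B, B) normalized Grassmann distances
    per_dim: np.ndarray         # (B, D) drift angles, degrees
    peak_per_dim: np.ndarray    # (D,) degrees
    variance_per_dim: np.ndarray  # (D,) fractions, sum to 1
    scores: np.ndarray | None = field(default=None)

    def to_json(self, path=None) -> str:
        obj = {
            "pairwise": self.pairwise.tolist(),
            "per_dim": self.per_dim.tolist(),
            "peak_per_dim": self.peak_per_dim.tolist(),
            "variance_per_dim": self.variance_per_dim.tolist(),
            "scores": None if self.scores is None else np.asarray(self.scores).tolist(),
        }
        text = json.dumps(obj, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "DriftReport":
        p = Path(source)
        obj = json.loads(p.read_text() if p.exists() else source)
        return cls(
            pairwise=np.asarray(obj["pairwise"]),
            per_dim=np.asarray(obj["per_dim"]),
            peak_per_dim=np.asarray(obj["peak_per_dim"]),
            variance_per_dim=np.asarray(obj["variance_per_dim"]),
            scores=None if obj["scores"] is None else np.asarray(obj["scores"]),
        )


def drift_report(fit, reference: int = 0, mode: str = "reference",
                 scores=None) -> DriftReport:
    """Assemble the full drift summary from a fit result.

    Angles are measured against block ``reference`` by default;
    ``mode="max"`` reports all-pairs maxima instead.
    """
    C_blocks = fit.emissions
    per_dim = per_dimension_drift(C_blocks, reference=reference, mode=mode)
    return DriftReport(
        pairwise=pairwise_drift_matrix(C_blocks),
        per_dim=per_dim,
        peak_per_dim=per_dim.max(axis=0),
        variance_per_dim=variance_per_dimension(fit.state_posteriors()),
        scores=None if scores is None else np.asarray(scores, dtype=float),
    )


def plot_drift_matrix(matrix: np.ndarray, ax=None, **imshow_kw):
    """Tiny heatmap helper (requires matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    im = ax.imshow(matrix, vmin=0.0, cmap="viridis", **imshow_kw)
    ax.set_xlabel("block")
    ax.set_ylabel("block")
    ax.figure.colorbar(im, ax=ax, label="normalized Grassmann distance")
    return ax
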