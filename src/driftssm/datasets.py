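"""Trial-structured dataset container.

A recording session is a sequence of trials, each a (T_k x N) array of
N-channel observations, together with a map from trial to *block* — a
group of consecutive trials that shares one emission matrix in the
drift chain. Block size 1 recovers per-trial drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TrialDataset", "make_splits"]


@dataclass
class TrialDataset:
    """Observed trials plus their trial-to-block mapping.

    Parameters
    ----------
    trials : list of (T_k, N) float arrays
    block_of_trial : int array, one entry per trial, nondecreasing
    strict : bool
        When True (the default for freshly simulated or loaded data) the
        block labels must be exactly 0..B-1 contiguous. Subsets created
        by :meth:`subset_blocks` keep their original labels and are
        validated only for monotonicity.
    """

    trials: list[np.ndarray]
    block_of_trial: np.ndarray
    strict: bool = field(default=True)

    def __post_init__(self) -> None:
        self.trials = [np.atleast_2d(np.asarray(y, dtype=float)) for y in self.trials]
        self.block_of_trial = np.asarray(self.block_of_trial, dtype=int)
        if len(self.trials) == 0:
            raise ValueError("dataset must contain at least one trial")
        if self.block_of_trial.shape != (len(self.trials),):
            raise ValueError(
                f"block_of_trial has shape {self.block_of_trial.shape}, "
                f"expected ({len(self.trials)},)"
            )
        N = self.trials[0].shape[1]
        for k, y in enumerate(self.trials):
            if y.shape[1] != N:
                raise ValueError(f"trial {k} has {y.shape[1]} channels, expected {N}")
            if not np.all(np.isfinite(y)):
                t, n = np.argwhere(~np.isfinite(y))[0]
                raise ValueError(f"non-finite value in trial {k}, timestep {t}, channel {n}")
        if np.any(np.diff(self.block_of_trial) < 0):
            k = int(np.argwhere(np.diff(self.block_of_trial) < 0)[0, 0]) + 1
            raise ValueError(f"block indices must be nondecreasing; trial {k} violates this")
        if self.strict:
            labels = np.unique(self.block_of_trial)
            if not np.array_equal(labels, np.arange(labels.size)):
                raise ValueError(
                    f"block labels must be contiguous 0..B-1, got {labels.tolist()[:10]}..."
                )

    # -- basic structure ------------------------------------------------
    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_channels(self) -> int:
        return self.trials[0].shape[1]

    @property
    def lengths(self) -> np.ndarray:
        return np.array([y.shape[0] for y in self.trials])

    @property
    def block_labels(self) -> np.ndarray:
        """Sorted unique block labels present in the dataset."""
        return np.unique(self.block_of_trial)

    @property
    def n_blocks(self) -> int:
        return self.block_labels.size

    def trials_in_block(self, label: int) -> list[int]:
        return list(np.flatnonzero(self.block_of_trial == label))

    def pooled(self) -> np.ndarray:
        """All observations stacked into one (sum T_k, N) array."""
        return np.concatenate(self.trials, axis=0)

    # -- conversions ----------------------------------------------------
    @classmethod
    def from_concatenated(
        cls,
        X: np.ndarray,
        lengths: np.ndarray | None = None,
        blocks: np.ndarray | None = None,
    ) -> "TrialDataset":
        """Build from an (sum T_k, N) array plus per-trial lengths.

        This is the scikit-learn-facing layout (cf. hmmlearn's
        ``fit(X, lengths)``); ``blocks`` gives one block label per trial
        and defaults to a single block.
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if lengths is None:
            lengths = np.array([X.shape[0]])
        lengths = np.asarray(lengths, dtype=int)
        if lengths.sum() != X.shape[0]:
            raise ValueError(f"lengths sum to {lengths.sum()} but X has {X.shape[0]} rows")
        bounds = np.concatenate([[0], np.cumsum(lengths)])
        trials = [X[bounds[i] : bounds[i + 1]] for i in range(len(lengths))]
        if blocks is None:
            blocks = np.zeros(len(trials), dtype=int)
        return cls(trials, blocks)

    def subset_blocks(self, labels) -> "TrialDataset":
        """Dataset restricted to the given block labels (labels preserved)."""
        labels = set(int(b) for b in np.asarray(labels).ravel())
        keep = [k for k in range(self.n_trials) if int(self.block_of_trial[k]) in labels]
        if not keep:
            raise ValueError("no trials in the requested blocks")
        return TrialDataset(
            [self.trials[k] for k in keep], self.block_of_trial[keep], strict=False
        )


def make_splits(
    data: TrialDataset,
    n_splits: int,
    heldout_blocks_per_split: int,
    seed: int | None = None,
) -> list[dict]:
    """Reproducible block-level train/test splits.

    Each split holds out ``heldout_blocks_per_split`` blocks drawn
    uniformly without replacement; the remaining blocks form the
    training set. Returns a list of ``{"train": labels, "heldout":
    labels}`` dicts.
    """
    labels = data.block_labels
    if heldout_blocks_per_split >= labels.size:
        raise ValueError(
            f"cannot hold out {heldout_blocks_per_split} of {labels.size} blocks"
        )
    rng = np.random.default_rng(seed)
    splits = []
    for _ in range(n_splits):
        held = np.sort(rng.choice(labels, size=heldout_blocks_per_split, replace=False))
        train = np.setdiff1d(labels, held)
        splits.append({"train": train, "heldout": held})
    return splits
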