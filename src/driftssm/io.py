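"""HDF5 serialization of datasets and run configuration.

Dataset layout::

    /y/trial_00000 ... (T_k, N) float datasets, one per trial
    /block_of_trial    (K,) int
    /meta              attrs: n_channels, n_trials (+ user metadata)
    /truth             optional group for simulated data:
                       z_blocks (B, P), C_blocks (B, N, D), latents

HDF5 is used (rather than bare arrays) for ragged-trial support and
self-describing metadata.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import yaml

from .datasets import TrialDataset
from .smds import DriftPath

__all__ = ["write_dataset", "read_dataset", "write_params", "read_params", "RunConfig"]


def write_dataset(
    path,
    data: TrialDataset,
    truth: DriftPath | None = None,
    latents: np.ndarray | None = None,
    meta: dict | None = None,
) -> None:
    """Write a trial dataset (and optional simulation ground truth)."""
    with h5py.File(path, "w") as f:
        g = f.create_group("y")
        for k, y in enumerate(data.trials):
            g.create_dataset(f"trial_{k:05d}", data=y)
        f.create_dataset("block_of_trial", data=data.block_of_trial)
        m = f.create_group("meta")
        m.attrs["n_channels"] = data.n_channels
        m.attrs["n_trials"] = data.n_trials
        for key, val in (meta or {}).items():
            m.attrs[key] = val
        if truth is not None:
            t = f.create_group("truth")
            t.create_dataset("z_blocks", data=truth.z_blocks)
            t.create_dataset("C_blocks", data=truth.C_blocks)
            if latents is not None:
                t.create_dataset("latents", data=np.asarray(latents))


def read_dataset(path, return_truth: bool = False):
    """Read a trial dataset written by :func:`write_dataset`.

    Validates the schema (trial count consistency, finite values,
    nondecreasing contiguous blocks) and raises a descriptive error
    naming the offending trial/channel otherwise.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as f:
        if "y" not in f or "block_of_trial" not in f:
            raise ValueError(f"{path}: missing /y or /block_of_trial group")
        names = sorted(f["y"].keys())
        trials = [np.asarray(f["y"][n]) for n in names]
        blocks = np.asarray(f["block_of_trial"])
        if blocks.shape[0] != len(trials):
            raise ValueError(
                f"{path}: {len(trials)} trials but block vector of length {blocks.shape[0]}"
            )
        data = TrialDataset(trials, blocks)
        truth = None
        if "truth" in f:
            truth = DriftPath(
                z_blocks=np.asarray(f["truth"]["z_blocks"]),
                C_blocks=np.asarray(f["truth"]["C_blocks"]),
            )
    if return_truth:
        return data, truth
    return data


def write_params(path, params) -> None:
    """Serialize LDS or drift-model parameters to one HDF5 file."""
    from .geometry import EmissionFrame
    from .lds import LDSParams
    from .smds import SMDSParams

    with h5py.File(path, "w") as f:
        if isinstance(params, LDSParams):
            f.attrs["kind"] = "lds"
            for name in ("A", "b", "Q", "C", "R", "mu_x1", "Sigma_x1"):
                f.create_dataset(name, data=getattr(params, name))
        elif isinstance(params, SMDSParams):
            f.attrs["kind"] = "smds"
            for name in ("A", "b", "Q", "R", "mu_x1", "Sigma_x1",
                         "m_z", "S_z", "tau2"):
                f.create_dataset(name, data=getattr(params, name))
            f.create_dataset("U_base", data=params.frame.U_base)
            f.attrs["D"] = params.frame.D
            f.attrs["retraction"] = params.frame.retraction
            for name in ("ig_alpha", "ig_beta", "tau2_clip"):
                f.attrs[name] = getattr(params, name)
        else:
            raise TypeError(f"cannot serialize {type(params).__name__}")


def read_params(path):
    """Inverse of :func:`write_params`."""
    from .geometry import EmissionFrame
    from .lds import LDSParams
    from .smds import SMDSParams

    with h5py.File(path, "r") as f:
        kind = f.attrs["kind"]
        get = lambda n: np.asarray(f[n])  # noqa: E731
        if kind == "lds":
            return LDSParams(**{n: get(n) for n in
                                ("A", "b", "Q", "C", "R", "mu_x1", "Sigma_x1")})
        frame = EmissionFrame(get("U_base"), int(f.attrs["D"]),
                              retraction=str(f.attrs["retraction"]))
        return SMDSParams(
            frame=frame,
            **{n: get(n) for n in ("A", "b", "Q", "R", "mu_x1", "Sigma_x1",
                                   "m_z", "S_z", "tau2")},
            ig_alpha=float(f.attrs["ig_alpha"]), ig_beta=float(f.attrs["ig_beta"]),
            tau2_clip=float(f.attrs["tau2_clip"]),
        )


@dataclass
class RunConfig:
    """Validated configuration for simulate/fit/eval/drift runs."""

    # model
    dims: list[int] = field(default_factory=lambda: [2])
    retraction: str = "cayley"
    # inference
    max_iter: int = 50
    tol: float = 1e-5
    ig_alpha: float = 2.0
    ig_beta: float = 1e-3
    tau2_clip: float = 1e-2
    seed: int = 0
    # evaluation
    n_splits: int = 3
    heldout_blocks_per_split: int = 5
    # drift diagnostics
    window: int = 50
    stride: int | None = None
    n_components: int = 10
    # simulation
    sim_name: str = "main"
    n_trials: int | None = None
    trials_per_block: int = 5
    T: int = 30

    def __post_init__(self) -> None:
        if any(d < 1 for d in self.dims):
            raise ValueError("latent dimensions must be positive")
        for name in ("max_iter", "tol", "ig_alpha", "ig_beta", "tau2_clip",
                     "n_splits", "heldout_blocks_per_split", "window",
                     "n_components", "trials_per_block", "T"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.retraction not in ("cayley", "expm"):
            raise ValueError("retraction must be 'cayley' or 'expm'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        obj = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**obj)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self))
        if path is not None:
            Path(path).write_text(text)
        return text
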