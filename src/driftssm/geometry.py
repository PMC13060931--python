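"""Stiefel/Grassmann manifold primitives.

The drifting emission matrix lives on the Stiefel manifold
``Stiefel(N, D) = {C in R^{N x D} : C'C = I_D}``.  Its motion is
parametrized by a *displacement* vector ``z`` of length
``D(2N - D - 1)/2``: the first ``D(D-1)/2`` entries (``w``) fill the
strict upper triangle of a D x D matrix ``W`` and generate rotations
*within* the current subspace; the remaining ``D(N-D)`` entries are the
column-stacked matrix ``V`` (D x (N-D)) and generate rotations that move
the subspace itself, i.e. motion on the Grassmann manifold.

From ``(w, V)`` we build the skew-symmetric matrix

    B = [[W - W',  V],
         [-V'   ,  0]]

and map it to a rotation via the Cayley transform
``f(B) = (I - B)(I + B)^{-1}``.  The emission matrix is then

    C = h(z) = U_base f(B) O_readout,

where ``U_base`` is a fixed orthonormal frame for the ambient space and
``O_readout = [I_D; 0]`` reads out the first D rotated axes.

Vector convention: ``vec`` is **column stacking** (Fortran order)
throughout the package; the ``w`` entries fill the strict upper triangle
of ``W`` in row-major order (``numpy.triu_indices`` order).

Drift between subspaces is quantified by principal angles
``0 <= theta_1 <= ... <= theta_D <= pi/2`` (from the singular values of
``C1'C2``) and the geodesic Grassmann distance
``d_G = (sum_d theta_d^2)^{1/2}``, optionally normalized by its maximum
``(pi/2) sqrt(D)`` so that it lies in ``[0, 1]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

__all__ = [
    "displacement_dim",
    "split_displacement",
    "join_displacement",
    "Displacement",
    "EmissionFrame",
    "vec",
    "unvec",
    "build_skew",
    "cayley",
    "retract",
    "displacement_to_emission",
    "emission_jacobian",
    "principal_angles",
    "grassmann_distance",
    "per_dimension_drift",
]


def displacement_dim(D: int, N: int) -> int:
    """Length of the displacement vector: D(D-1)/2 + D(N-D) = D(2N-D-1)/2."""
    if not (0 < D <= N):
        raise ValueError(f"need 0 < D <= N, got D={D}, N={N}")
    return D * (2 * N - D - 1) // 2


def vec(A: np.ndarray) -> np.ndarray:
    """Column-stacking vectorization (the package-wide convention)."""
    return np.asarray(A).reshape(-1, order="F")


def unvec(v: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Inverse of :func:`vec`."""
    return np.asarray(v).reshape(shape, order="F")


def split_displacement(z: np.ndarray, D: int, N: int) -> tuple[np.ndarray, np.ndarray]:
    """Split ``z`` into its within-subspace part ``w`` and subspace part ``V``."""
    z = np.asarray(z, dtype=float)
    P = displacement_dim(D, N)
    if z.shape != (P,):
        raise ValueError(f"displacement must have shape ({P},), got {z.shape}")
    nw = D * (D - 1) // 2
    w = z[:nw]
    V = unvec(z[nw:], (D, N - D))
    return w, V


def join_displacement(w: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Concatenate ``[w; vec(V)]`` into a displacement vector."""
    return np.concatenate([np.asarray(w, dtype=float).ravel(), vec(V)])


@dataclass(frozen=True)
class Displacement:
    """A point in the displacement chart, with its (w, V) split.

    ``w`` holds the strict-upper-triangular entries of ``W`` (row-major)
    and rotates the basis within the subspace; ``V`` tilts the subspace.
    """

    z: np.ndarray
    D: int
    N: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "z", np.asarray(self.z, dtype=float))
        split_displacement(self.z, self.D, self.N)  # validates shape

    @property
    def w(self) -> np.ndarray:
        return split_displacement(self.z, self.D, self.N)[0]

    @property
    def V(self) -> np.ndarray:
        return split_displacement(self.z, self.D, self.N)[1]

    @property
    def B(self) -> np.ndarray:
        return build_skew(self.w, self.V, self.D, self.N)

    @classmethod
    def from_parts(cls, w: np.ndarray, V: np.ndarray) -> "Displacement":
        V = np.atleast_2d(np.asarray(V, dtype=float))
        D, NmD = V.shape
        return cls(join_displacement(w, V), D, D + NmD)


def build_skew(w: np.ndarray, V: np.ndarray, D: int | None = None, N: int | None = None) -> np.ndarray:
    """Assemble the skew-symmetric generator B from (w, V).

    Parameters
    ----------
    w : array of length D(D-1)/2
        Strict upper triangle of W, row-major.
    V : array of shape (D, N-D)
    D, N : optional ints
        Checked against the shapes of ``w`` and ``V`` when given.
    """
    w = np.asarray(w, dtype=float).ravel()
    V = np.atleast_2d(np.asarray(V, dtype=float))
    d, nmd = V.shape
    if D is not None and D != d:
        raise ValueError(f"V has {d} rows, expected D={D}")
    if N is not None and N != d + nmd:
        raise ValueError(f"V implies N={d + nmd}, expected N={N}")
    if w.size != d * (d - 1) // 2:
        raise ValueError(f"w has length {w.size}, expected {d * (d - 1) // 2} for D={d}")
    n = d + nmd
    W = np.zeros((d, d))
    iu, ju = np.triu_indices(d, k=1)
    W[iu, ju] = w
    B = np.zeros((n, n))
    B[:d, :d] = W - W.T
    B[:d, d:] = V
    B[d:, :d] = -V.T
    return B


def _check_skew(B: np.ndarray, tol: float) -> np.ndarray:
    B = np.asarray(B, dtype=float)
    if B.ndim != 2 or B.shape[0] != B.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {B.shape}")
    dev = np.max(np.abs(B + B.T)) if B.size else 0.0
    if dev > tol:
        raise ValueError(f"matrix is not skew-symmetric: max|B + B'| = {dev:.3g} > {tol:.3g}")
    return B


def cayley(B: np.ndarray, *, tol: float = 1e-8) -> np.ndarray:
    """Cayley transform ``(I - B)(I + B)^{-1}`` of a skew-symmetric matrix.

    For real skew-symmetric B the eigenvalues of I + B are 1 + i*lambda,
    so I + B is always invertible and the output is a rotation
    (orthogonal with determinant +1).
    """
    B = _check_skew(B, tol)
    n = B.shape[0]
    eye = np.eye(n)
    # (I-B)(I+B)^{-1} = solve((I+B)', (I-B)')'
    return np.linalg.solve((eye + B).T, (eye - B).T).T


def retract(B: np.ndarray, method: str = "cayley", *, tol: float = 1e-8) -> np.ndarray:
    """Map a skew-symmetric generator to a rotation.

    ``method="cayley"`` (default) uses the Cayley transform; ``"expm"``
    uses the matrix exponential. Both send skew matrices to SO(n); Cayley
    is cheaper and the default parametrization here.
    """
    if method == "cayley":
        return cayley(B, tol=tol)
    if method == "expm":
        return expm(_check_skew(B, tol))
    raise ValueError(f"unknown retraction {method!r}; use 'cayley' or 'expm'")


@dataclass(frozen=True)
class EmissionFrame:
    """Fixed orthonormal frame for the ambient space.

    ``U_base`` (N x N, orthonormal columns) fixes the coordinate axes in
    which displacements act; the readout ``[I_D; 0]`` selects the first D
    rotated axes. ``h(0)`` is therefore the first D columns of U_base.
    """

    U_base: np.ndarray
    D: int
    retraction: str = field(default="cayley")
    tolerance: float = field(default=1e-8)

    def __post_init__(self) -> None:
        U = np.asarray(self.U_base, dtype=float)
        object.__setattr__(self, "U_base", U)
        if U.ndim != 2 or U.shape[0] != U.shape[1]:
            raise ValueError(f"U_base must be square, got {U.shape}")
        if not (0 < self.D <= U.shape[0]):
            raise ValueError(f"need 0 < D <= N, got D={self.D}, N={U.shape[0]}")
        dev = np.max(np.abs(U.T @ U - np.eye(U.shape[0])))
        if dev > max(self.tolerance, 1e-6):
            raise ValueError(f"U_base is not orthonormal: max|U'U - I| = {dev:.3g}")

    @property
    def N(self) -> int:
        return self.U_base.shape[0]

    @property
    def O_readout(self) -> np.ndarray:
        O = np.zeros((self.N, self.D))
        O[: self.D, : self.D] = np.eye(self.D)
        return O

    @classmethod
    def identity(cls, N: int, D: int, **kw) -> "EmissionFrame":
        return cls(np.eye(N), D, **kw)

    @classmethod
    def from_data(cls, Y: np.ndarray, D: int, **kw) -> "EmissionFrame":
        """Frame whose axes are the principal components of pooled data Y (rows = samples)."""
        Y = np.asarray(Y, dtype=float)
        Yc = Y - Y.mean(axis=0, keepdims=True)
        # full orthonormal basis ordered by explained variance
        evals, evecs = np.linalg.eigh(Yc.T @ Yc)
        return cls(evecs[:, ::-1], D, **kw)


def displacement_to_emission(z: np.ndarray | Displacement, frame: EmissionFrame) -> np.ndarray:
    """Emission matrix ``C = U_base f(B(z)) O_readout`` on Stiefel(N, D)."""
    if isinstance(z, Displacement):
        if (z.D, z.N) != (frame.D, frame.N):
            raise ValueError(
                f"displacement is for (D={z.D}, N={z.N}), frame for (D={frame.D}, N={frame.N})"
            )
        z = z.z
    w, V = split_displacement(np.asarray(z, dtype=float), frame.D, frame.N)
    F = retract(build_skew(w, V), frame.retraction)
    return frame.U_base @ F[:, : frame.D]


def _coordinate_pairs(D: int, N: int) -> tuple[np.ndarray, np.ndarray]:
    """(row, col) positions in B of each displacement coordinate (+1 entry).

    w coordinates first (strict upper triangle of W, row-major), then the
    column-stacked V coordinates at B[d, D+m].
    """
    iu, ju = np.triu_indices(D, k=1)
    rows = [iu]
    cols = [ju]
    m_idx, d_idx = np.meshgrid(np.arange(N - D), np.arange(D), indexing="ij")
    rows.append(d_idx.ravel())  # column-stacking: d varies fastest
    cols.append(D + m_idx.ravel())
    return np.concatenate(rows), np.concatenate(cols)


def emission_jacobian(z: np.ndarray, frame: EmissionFrame) -> np.ndarray:
    """Jacobian of ``vec(h(z))`` with respect to z, shape (N*D, P).

    Uses the differential of the Cayley transform,
    ``dF = -(I + F) dB (I + B)^{-1}``, so each column is
    ``vec(-U (I+F) E_i (I+B)^{-1} O)`` with E_i the sparse skew basis
    matrix of coordinate i; evaluated with rank-2 outer products.
    Only defined for the Cayley retraction (the default).
    """
    if frame.retraction != "cayley":
        return _emission_jacobian_fd(z, frame)
    D, N = frame.D, frame.N
    w, V = split_displacement(np.asarray(z, dtype=float), D, N)
    B = build_skew(w, V)
    F = cayley(B)
    L = frame.U_base @ (np.eye(N) + F)          # N x N
    K = np.linalg.solve(np.eye(N) + B, frame.O_readout)  # N x D
    a, b = _coordinate_pairs(D, N)
    # dH_i = -(L[:,a_i] K[b_i,:] - L[:,b_i] K[a_i,:]); stack into (N, D, P)
    T = -(L[:, a][:, None, :] * K[b, :].T[None, :, :] - L[:, b][:, None, :] * K[a, :].T[None, :, :])
    return T.reshape(N * D, len(a), order="F")


def _emission_jacobian_fd(z: np.ndarray, frame: EmissionFrame, h: float = 1e-6) -> np.ndarray:
    """Central finite-difference Jacobian of vec(h(z)); fallback and test oracle."""
    z = np.asarray(z, dtype=float)
    P = z.size
    J = np.empty((frame.N * frame.D, P))
    for i in range(P):
        zp, zm = z.copy(), z.copy()
        zp[i] += h
        zm[i] -= h
        J[:, i] = (
            vec(displacement_to_emission(zp, frame)) - vec(displacement_to_emission(zm, frame))
        ) / (2 * h)
    return J


def _as_stiefel(C: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    C = np.asarray(C, dtype=float)
    if C.ndim != 2:
        raise ValueError(f"expected an N x D matrix, got shape {C.shape}")
    dev = np.max(np.abs(C.T @ C - np.eye(C.shape[1])))
    if dev > tol:
        raise ValueError(f"matrix is not orthonormal: max|C'C - I| = {dev:.3g} > {tol:.3g}")
    return C


def principal_angles(C1: np.ndarray, C2: np.ndarray) -> np.ndarray:
    """Principal angles between the column spaces of two Stiefel points.

    Returned ascending in [0, pi/2]; invariant to right-rotation of
    either argument. Singular values of C1'C2 are clipped into [-1, 1]
    before arccos for numerical safety.
    """
    C1, C2 = _as_stiefel(C1), _as_stiefel(C2)
    if C1.shape != C2.shape:
        raise ValueError(f"shape mismatch: {C1.shape} vs {C2.shape}")
    s = np.linalg.svd(C1.T @ C2, compute_uv=False)
    return np.sort(np.arccos(np.clip(s, -1.0, 1.0)))


def grassmann_distance(C1: np.ndarray, C2: np.ndarray, normalized: bool = False) -> float:
    """Geodesic Grassmann distance ``(sum theta_d^2)^{1/2}``.

    With ``normalized=True`` the distance is divided by its supremum
    ``(pi/2) sqrt(D)`` and lies in [0, 1].
    """
    theta = principal_angles(C1, C2)
    d = float(np.sqrt(np.sum(theta**2)))
    if normalized:
        d /= (np.pi / 2) * np.sqrt(len(theta))
    return d


def per_dimension_drift(
    C_list, reference: int = 0, mode: str = "reference"
) -> np.ndarray:
    """Per-dimension drift angles (degrees) across a sequence of Stiefel points.

    ``angle[k, d] = arccos(|c_d(ref)' c_d(k)|)`` in degrees, with columns
    identified by index (the within-subspace rotation is an explicit
    latent, so column identity is preserved across blocks) and sign
    ambiguity removed by the absolute inner product.

    ``mode="reference"`` (default) measures against block ``reference``;
    ``mode="max"`` returns, per block, the maximum angle to any other
    block (so ``angle.max(axis=0)`` is the all-pairs peak drift).
    """
    Cs = [np.asarray(C, dtype=float) for C in C_list]
    if not Cs:
        raise ValueError("empty sequence of Stiefel points")
    shape = Cs[0].shape
    if any(C.shape != shape for C in Cs):
        raise ValueError("all Stiefel points must share (N, D)")
    stack = np.stack(Cs)  # (B, N, D)
    if mode == "reference":
        if not (-len(Cs) <= reference < len(Cs)):
            raise ValueError(f"reference index {reference} out of range")
        cos = np.abs(np.einsum("nd,knd->kd", stack[reference], stack))
        return np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))
    if mode == "max":
        cos = np.abs(np.einsum("jnd,knd->jkd", stack, stack))
        ang = np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))
        return ang.max(axis=0)
    raise ValueError(f"unknown mode {mode!r}; use 'reference' or 'max'")
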