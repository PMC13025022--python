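"""Mode reproducibility across replicas and the quasiharmonic baseline.

Two modes are compared by the absolute inner product |a . b| in
mass-weighted space (1 for identical directions, sign-invariant); two
k-dimensional mode subspaces by the root-mean-square inner product

    RMSIP(A, B) = sqrt( (1/k) sum_ij (a_i . b_j)^2 ),

which is invariant to any orthogonal remixing within either set — so a
swap or mixing of, say, the second and third vibrational modes between
replicas leaves the subspace correlation unchanged.

Rigid-body content of a mode is measured by its projection norm onto the
6-dimensional mass-weighted translation/rotation subspace built at a
reference geometry.  The quasiharmonic baseline diagonalizes the
mass-weighted displacement covariance matrix (PCA) instead of the
velocity-correlation spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectral import ModeSet
from .trajectory import Trajectory

__all__ = [
    "CorrelationReport",
    "mode_correlation",
    "subspace_correlation",
    "rigid_body_basis",
    "classify_rigid_modes",
    "principal_component_modes",
    "replica_report",
]


def mode_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """|a . b| for two normalized mode vectors (sign-invariant)."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("mode vectors differ in dimension")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("zero mode vector")
    return float(abs(a @ b) / (na * nb))


def _check_orthonormal(S: np.ndarray, tol: float) -> None:
    g = S @ S.T
    if np.abs(g - np.eye(len(g))).max() > tol:
        raise ValueError("mode set is not orthonormal within tolerance")


def subspace_correlation(
    set_a: np.ndarray,
    set_b: np.ndarray,
    *,
    method: str = "rmsip",
    tol: float = 1e-6,
) -> float:
    """Similarity in [0, 1] of two k-dimensional orthonormal mode sets.

    ``rmsip`` (default) as defined above; ``prod_sv`` uses the geometric
    mean of the principal-angle cosines (singular values of A B^T).
    """
    A = np.atleast_2d(np.asarray(set_a, dtype=float))
    B = np.atleast_2d(np.asarray(set_b, dtype=float))
    if A.shape != B.shape:
        raise ValueError("subspaces must have equal dimension and size")
    _check_orthonormal(A, tol)
    _check_orthonormal(B, tol)
    M = A @ B.T
    if method == "rmsip":
        return float(np.sqrt(np.sum(M * M) / len(A)))
    if method == "prod_sv":
        sv = np.linalg.svd(M, compute_uv=False)
        return float(np.prod(sv) ** (1.0 / len(sv)))
    raise ValueError(f"unknown subspace correlation method {method!r}")


def rigid_body_basis(masses: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Orthonormal mass-weighted translation/rotation vectors (6, 3n).

    Translations are uniform displacements; rotations are r x e_alpha
    about the mass-weighted centroid, Gram-Schmidt orthonormalized.
    """
    masses = np.asarray(masses, dtype=float)
    reference = np.asarray(reference, dtype=float)
    n = len(masses)
    sqm = np.sqrt(masses)
    com = (masses[:, None] * reference).sum(axis=0) / masses.sum()
    d = reference - com
    vecs = []
    for alpha in range(3):
        t = np.zeros((n, 3))
        t[:, alpha] = 1.0
        vecs.append((sqm[:, None] * t).ravel())
    for alpha in range(3):
        e = np.zeros(3)
        e[alpha] = 1.0
        r = np.cross(e[None, :], d)
        vecs.append((sqm[:, None] * r).ravel())
    V = np.array(vecs).T  # (3n, 6)
    Q, R = np.linalg.qr(V)
    if np.abs(np.diag(R)).min() < 1e-10 * np.abs(np.diag(R)).max():
        raise ValueError("collinear reference: rotational vectors degenerate")
    return Q.T


def classify_rigid_modes(
    modes: ModeSet,
    reference: np.ndarray | None = None,
    threshold: float = 0.8,
):
    """Overlap of each mode with the 6D translation/rotation subspace.

    Returns ``(overlaps (k,), flags (k,) bool)``; a mode with projection
    norm above ``threshold`` is classified as rigid-body motion.
    """
    if reference is None:
        reference = modes.reference
    if reference is None:
        raise ValueError("a reference geometry is required")
    B = rigid_body_basis(modes.masses, reference)
    proj = modes.vectors @ B.T          # (k, 6)
    overlaps = np.linalg.norm(proj, axis=1)
    return overlaps, overlaps > threshold


def principal_component_modes(
    traj: Trajectory, masses: np.ndarray
) -> ModeSet:
    """Quasiharmonic (PCA) modes of an aligned trajectory.

    Eigenvectors of the mass-weighted displacement covariance matrix,
    sorted by variance (eigenvalue) descending.  Unlike the
    velocity-correlation modes these depend on the rare fluctuations
    actually visited, which is what limits their reproducibility.
    """
    import warnings

    F = traj.n_frames
    X = traj.positions.reshape(F, -1) * np.repeat(np.sqrt(masses), 3)[None, :]
    if F < X.shape[1]:
        warnings.warn(
            f"only {F} frames for {X.shape[1]} degrees of freedom: "
            "covariance is rank-deficient"
        )
    X = X - X.mean(axis=0)
    C = X.T @ X / F
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals, kind="stable")[::-1]
    from .spectral import _fix_signs

    return ModeSet(
        vectors=_fix_signs(evecs.T[order]),
        eigenvalues=evals[order],
        masses=np.asarray(masses, dtype=float),
        frequency=None,
        reference=traj.positions.mean(axis=0),
    )


@dataclass
class CorrelationReport:
    """Pairwise mode and subspace correlations between replicas."""

    indices: tuple[int, ...]                  # 1-based mode indices compared
    pair_matrices: dict                       # (i, j) -> (k, k) |dot| matrix
    subspace_2d: dict                         # (i, j) -> RMSIP of first two modes
    subspace_3d: dict | None                  # (i, j) -> RMSIP of first three

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (i, j), mat in self.pair_matrices.items():
            row = {"replica_a": i, "replica_b": j,
                   "subspace_2d": self.subspace_2d[(i, j)]}
            if self.subspace_3d is not None:
                row["subspace_3d"] = self.subspace_3d[(i, j)]
            for a, ma in enumerate(self.indices):
                for b, mb in enumerate(self.indices):
                    row[f"m{ma}_m{mb}"] = mat[a, b]
            rows.append(row)
        return pd.DataFrame(rows)


def replica_report(
    modesets: list[ModeSet],
    indices: tuple[int, ...] = (7, 8, 9),
) -> CorrelationReport:
    """All pairwise mode/subspace correlations among chosen mode indices.

    ``indices`` are 1-based eigenvalue ranks (the field convention where
    modes 1-6 are rigid-body and mode 7 is the leading vibration).
    """
    if len(modesets) < 2:
        raise ValueError("need at least two replicas")
    for ms in modesets:
        if max(indices) > ms.n_modes:
            raise IndexError(f"mode index {max(indices)} out of range")
    sel = [np.array([ms.mode(i) for i in indices]) for ms in modesets]
    pair, s2d, s3d = {}, {}, {}
    for i in range(len(modesets)):
        for j in range(i, len(modesets)):
            M = np.abs(sel[i] @ sel[j].T)
            pair[(i, j)] = M
            s2d[(i, j)] = subspace_correlation(sel[i][:2], sel[j][:2])
            if len(indices) >= 3:
                s3d[(i, j)] = subspace_correlation(sel[i][:3], sel[j][:3])
    return CorrelationReport(
        indices=tuple(indices),
        pair_matrices=pair,
        subspace_2d=s2d,
        subspace_3d=s3d if s3d else None,
    )
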