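"""Affine-invariant Riemannian operations on symmetric positive-definite matrices.

Functional-connectivity estimates are full-rank covariance matrices, i.e. points
on the SPD manifold.  Under the affine-invariant metric the distance between two
SPD matrices ``A`` and ``B`` is ``||log(A^{-1/2} B A^{-1/2})||_F``, which is
invariant to any invertible congruence (re-weighting or mixing of regions).
This module provides the primitives that the centering procedure is built from:

* matrix powers / log / exp through symmetric eigendecomposition,
* the Karcher (Frechet) geometric mean,
* tangent-space projection and retraction at an arbitrary base point,
* parallel transport of tangent vectors between base points,
* the subject-centering procedure that removes stable, subject-specific
  covariance signatures while preserving epoch-to-epoch variation.

Centering works in three steps.  With per-subject geometric means ``S_i`` and
grand geometric mean ``S_gm`` (over every subject and epoch), each epoch
covariance ``S_ij`` is (1) projected to the tangent space at the subject mean,
``T_ij = S_i^{1/2} log(S_i^{-1/2} S_ij S_i^{-1/2}) S_i^{1/2}``, (2) transported
to the grand mean, ``T_ij^c = G T_ij G^T`` with ``G = S_gm^{1/2} S_i^{-1/2}``,
and (3) retracted, ``S_ij^c = S_gm^{1/2} exp(S_gm^{-1/2} T_ij^c S_gm^{-1/2})
S_gm^{1/2}``.  After centering, each subject's geometric mean coincides with the
grand mean, so between-subject offsets are gone.

All eigendecompositions use symmetric solvers and every output is
re-symmetrized; the module is fully deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import linalg

logger = logging.getLogger(__name__)

# Relative eigenvalue floor applied before log/inverse powers: eigenvalues below
# 1e-10 * lambda_max are clipped (with a warning) so that numerically
# near-singular covariance estimates do not blow up the tangent maps.
EIG_FLOOR_REL = 1e-10

__all__ = [
    "SPDError",
    "GeometricMeanError",
    "validate_symmetric",
    "validate_spd",
    "matrix_power",
    "matrix_log",
    "matrix_exp",
    "geometric_mean",
    "tangent_project",
    "tangent_retract",
    "transport_map",
    "parallel_transport",
    "center_dataset",
    "CenteringResult",
    "affine_distance",
    "whitened_norm",
]


class SPDError(ValueError):
    """Raised when an input violates the symmetric positive-definite contract."""


class GeometricMeanError(RuntimeError):
    """Karcher-mean iteration failed to converge; carries the final residual."""

    def __init__(self, residual: float, max_iter: int):
        self.residual = residual
        self.max_iter = max_iter
        super().__init__(
            f"geometric mean did not converge within {max_iter} iterations "
            f"(final residual {residual:.3e})"
        )


def validate_symmetric(M: np.ndarray, *, rtol: float = 1e-10, name: str = "matrix") -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise SPDError(f"{name} must be square, got shape {M.shape}")
    scale = max(np.abs(M).max(), 1.0)
    if np.abs(M - M.T).max() > rtol * scale:
        raise SPDError(f"{name} is not symmetric within tolerance {rtol}")
    return 0.5 * (M + M.T)


def validate_spd(S: np.ndarray, *, rtol: float = 1e-10, name: str = "matrix") -> np.ndarray:
    """Symmetrize and check positive-definiteness; returns the symmetrized matrix."""
    S = validate_symmetric(S, rtol=rtol, name=name)
    w = linalg.eigvalsh(S)
    if w[0] <= 0:
        raise SPDError(f"{name} is not positive definite (min eigenvalue {w[0]:.3e})")
    return S


def _eigh_floored(S: np.ndarray, *, floor: bool) -> tuple[np.ndarray, np.ndarray]:
    w, V = linalg.eigh(S)
    if floor:
        lo = EIG_FLOOR_REL * w[-1]
        if w[0] < lo:
            logger.warning(
                "flooring %d eigenvalue(s) below %.3e before log/inverse power",
                int(np.sum(w < lo)), lo,
            )
            w = np.maximum(w, lo)
    return w, V


def _sym(M: np.ndarray) -> np.ndarray:
    return 0.5 * (M + M.T)


def matrix_power(S: np.ndarray, p: float) -> np.ndarray:
    """Eigendecomposition-based matrix power of an SPD matrix.

    For ``p > 0`` the result is SPD; any real ``p`` yields a symmetric matrix.
    """
    S = validate_spd(S)
    w, V = _eigh_floored(S, floor=p < 0 or (p != int(p)))
    return _sym((V * w**p) @ V.T)


def matrix_log(S: np.ndarray) -> np.ndarray:
    """Principal matrix logarithm of an SPD matrix (a symmetric matrix)."""
    S = validate_spd(S)
    w, V = _eigh_floored(S, floor=True)
    return _sym((V * np.log(w)) @ V.T)


def matrix_exp(T: np.ndarray) -> np.ndarray:
    """Matrix exponential of a symmetric matrix (always SPD)."""
    T = validate_symmetric(T, name="tangent matrix")
    w, V = linalg.eigh(T)
    return _sym((V * np.exp(w)) @ V.T)


def _whiten_factors(base: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return (base^{1/2}, base^{-1/2}) from one eigendecomposition."""
    w, V = _eigh_floored(base, floor=True)
    sq = np.sqrt(w)
    return _sym((V * sq) @ V.T), _sym((V / sq) @ V.T)


def geometric_mean(
    matrices: list[np.ndarray] | tuple[np.ndarray, ...],
    tol: float = 1e-8,
    max_iter: int = 50,
) -> np.ndarray:
    """Karcher (Frechet) mean under the affine-invariant metric.

    Initialized at the log-Euclidean mean, then fixed-point iteration
    ``M <- M^{1/2} exp(mean_k log(M^{-1/2} S_k M^{-1/2})) M^{1/2}`` with unit
    step until the Frobenius norm of the mean tangent falls below ``tol``.
    """
    if len(matrices) == 0:
        raise SPDError("geometric mean of an empty set is undefined")
    mats = [validate_spd(S, name=f"matrix {k}") for k, S in enumerate(matrices)]
    dims = {M.shape[0] for M in mats}
    if len(dims) != 1:
        raise SPDError(f"matrices have mixed dimensions {sorted(dims)}")
    if len(mats) == 1:
        return mats[0]

    M = matrix_exp(np.mean([matrix_log(S) for S in mats], axis=0))
    residual = np.inf
    for _ in range(max_iter):
        sq, isq = _whiten_factors(M)
        T_mean = np.mean([matrix_log(_sym(isq @ S @ isq)) for S in mats], axis=0)
        residual = float(np.linalg.norm(T_mean, "fro"))
        if residual <= tol:
            return _sym(sq @ matrix_exp(T_mean) @ sq)
        M = _sym(sq @ matrix_exp(T_mean) @ sq)
    raise GeometricMeanError(residual, max_iter)


def tangent_project(S: np.ndarray, base: np.ndarray) -> np.ndarray:
    """Log map: project SPD ``S`` to the tangent space at SPD ``base``.

    ``T = base^{1/2} log(base^{-1/2} S base^{-1/2}) base^{1/2}``.
    """
    S = validate_spd(S, name="S")
    base = validate_spd(base, name="base")
    if S.shape != base.shape:
        raise SPDError(f"dimension mismatch: S {S.shape} vs base {base.shape}")
    sq, isq = _whiten_factors(base)
    return _sym(sq @ matrix_log(_sym(isq @ S @ isq)) @ sq)


def tangent_retract(T: np.ndarray, base: np.ndarray) -> np.ndarray:
    """Exp map: retract symmetric tangent ``T`` at SPD ``base`` back to the manifold.

    ``S = base^{1/2} exp(base^{-1/2} T base^{-1/2}) base^{1/2}``.
    """
    T = validate_symmetric(T, name="tangent")
    base = validate_spd(base, name="base")
    if T.shape != base.shape:
        raise SPDError(f"dimension mismatch: T {T.shape} vs base {base.shape}")
    sq, isq = _whiten_factors(base)
    return _sym(sq @ matrix_exp(_sym(isq @ T @ isq)) @ sq)


def transport_map(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Parallel-transport matrix ``G = target^{1/2} source^{-1/2}``."""
    source = validate_spd(source, name="source")
    target = validate_spd(target, name="target")
    if source.shape != target.shape:
        raise SPDError("source/target dimension mismatch")
    sq_t, _ = _whiten_factors(target)
    _, isq_s = _whiten_factors(source)
    return sq_t @ isq_s


def parallel_transport(T: np.ndarray, source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Transport tangent ``T`` from base ``source`` to base ``target``: ``G T G^T``.

    Preserves the affine-invariant (whitened Frobenius) norm.
    """
    T = validate_symmetric(T, name="tangent")
    G = transport_map(source, target)
    return _sym(G @ T @ G.T)


def whitened_norm(T: np.ndarray, base: np.ndarray) -> float:
    """Affine-invariant norm of tangent ``T`` at ``base``: ``||base^{-1/2} T base^{-1/2}||_F``."""
    T = validate_symmetric(T, name="tangent")
    _, isq = _whiten_factors(validate_spd(base, name="base"))
    return float(np.linalg.norm(isq @ T @ isq, "fro"))


def affine_distance(A: np.ndarray, B: np.ndarray) -> float:
    """Affine-invariant Riemannian distance ``||log(A^{-1/2} B A^{-1/2})||_F``.

    Computed from the generalized eigenvalues of ``(B, A)``; symmetric in its
    arguments and zero iff ``A == B``.
    """
    A = validate_spd(A, name="A")
    B = validate_spd(B, name="B")
    if A.shape != B.shape:
        raise SPDError("dimension mismatch")
    w = linalg.eigvalsh(B, A)
    w = np.maximum(w, EIG_FLOOR_REL)
    return float(np.sqrt(np.sum(np.log(w) ** 2)))


def pairwise_affine_distance(matrices: Sequence[np.ndarray]) -> np.ndarray:
    """Symmetric matrix of affine-invariant distances between SPD matrices.

    Whitening factors are precomputed once per matrix, which makes the
    all-pairs computation feasible for a few hundred matrices.
    """
    mats = [validate_spd(S, name=f"matrix {k}") for k, S in enumerate(matrices)]
    isqs = [_whiten_factors(S)[1] for S in mats]
    n = len(mats)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            w = linalg.eigvalsh(isqs[i] @ mats[j] @ isqs[i])
            w = np.maximum(w, EIG_FLOOR_REL)
            D[i, j] = D[j, i] = np.sqrt(np.sum(np.log(w) ** 2))
    return D


@dataclass
class CenteringResult:
    """Output of :func:`center_dataset`.

    Attributes
    ----------
    centered : dict mapping each input key to its centered SPD matrix.
    grand_mean : the grand geometric mean ``S_gm`` over all matrices.
    subject_means : per-subject geometric means ``S_i``.
    """

    centered: dict
    grand_mean: np.ndarray
    subject_means: dict


def center_dataset(
    covs: Mapping,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> CenteringResult:
    """Riemannian subject-centering of a keyed set of covariance matrices.

    Parameters
    ----------
    covs : mapping from ``(subject, *rest)`` keys to SPD matrices.  The first
        element of each key identifies the subject; the remaining elements
        (day, epoch, ...) are carried through unchanged.

    Every matrix is projected to the tangent space at its subject's geometric
    mean, parallel-transported to the grand geometric mean (over all subjects
    and epochs) and retracted there.  On return, the geometric mean of each
    subject's centered matrices equals the grand mean to within ``tol``.
    """
    if not covs:
        raise SPDError("empty covariance set")
    by_subject: dict = {}
    for key in covs:
        if not isinstance(key, tuple) or len(key) < 2:
            raise SPDError(f"keys must be tuples (subject, epoch, ...); got {key!r}")
        by_subject.setdefault(key[0], []).append(key)

    subject_means = {}
    for subj, keys in by_subject.items():
        try:
            subject_means[subj] = geometric_mean([covs[k] for k in keys], tol=tol, max_iter=max_iter)
        except (SPDError, GeometricMeanError) as err:
            raise type(err)(f"subject {subj!r}: {err}") from err

    grand_mean = geometric_mean(list(covs.values()), tol=tol, max_iter=max_iter)

    sq_gm, isq_gm = _whiten_factors(grand_mean)
    centered: dict = {}
    for subj, keys in by_subject.items():
        S_i = subject_means[subj]
        sq_i, isq_i = _whiten_factors(S_i)
        G = sq_gm @ isq_i
        for key in keys:
            try:
                T = _sym(sq_i @ matrix_log(_sym(isq_i @ covs[key] @ isq_i)) @ sq_i)
                Tc = _sym(G @ T @ G.T)
                centered[key] = _sym(sq_gm @ matrix_exp(_sym(isq_gm @ Tc @ isq_gm)) @ sq_gm)
            except SPDError as err:
                raise SPDError(f"centering failed for {key!r}: {err}") from err
    return CenteringResult(centered=centered, grand_mean=grand_mean, subject_means=subject_means)
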