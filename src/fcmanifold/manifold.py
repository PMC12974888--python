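"""Connectivity-gradient manifold embedding and eccentricity.

Each centered covariance matrix is turned into a low-dimensional embedding of
regions: row-wise thresholding keeps each region's top 10% of connections,
cosine similarity between the sparse rows yields an affinity matrix, and PCA of
the affinity gives the manifold coordinates.  A template Baseline manifold
(geometric mean of subject-averaged baseline matrices) defines the common
space; every other embedding is aligned to it with a scale-free Procrustes
rotation.  A region's eccentricity is its Euclidean distance from the template
centroid (the origin after centering), a scalar index of functional
segregation (far from centroid) versus integration (close to centroid).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import linalg

from .spd import geometric_mean


class ManifoldError(ValueError):
    pass


@dataclass
class Embedding:
    """Regions x components coordinates plus per-component variance explained."""

    coordinates: np.ndarray
    variance_explained: np.ndarray
    aligned: bool = False

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.variance_explained = np.asarray(self.variance_explained, dtype=float)
        ve = self.variance_explained
        if np.any(ve < -1e-12) or np.any(ve > 1 + 1e-12) or ve.sum() > 1 + 1e-9:
            raise ManifoldError("variance_explained fractions must lie in [0, 1] and sum <= 1")
        if np.any(np.diff(ve) > 1e-12):
            raise ManifoldError("variance_explained must be non-increasing")

    @property
    def n_components(self) -> int:
        return self.coordinates.shape[1]


def row_threshold(M: np.ndarray, density: float = 0.10) -> np.ndarray:
    """Keep the top ``ceil(density * (n-1))`` off-diagonal entries of each row.

    The diagonal is excluded and zeroed; ties at the cutoff are broken in
    favour of the lower region index, so the output is deterministic.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ManifoldError("row_threshold expects a square matrix")
    if not (0 < density <= 1):
        raise ManifoldError("density must be in (0, 1]")
    n = M.shape[0]
    k = math.ceil(density * (n - 1))
    out = np.zeros_like(M)
    col_ix = np.arange(n)
    for i in range(n):
        row = M[i].copy()
        row[i] = -np.inf
        # sort by (-value, index): stable deterministic tie-break at the cutoff
        order = np.lexsort((col_ix, -row))
        keep = order[:k]
        out[i, keep] = M[i, keep]
    return out


def cosine_affinity(thresholded: np.ndarray) -> np.ndarray:
    """Cosine similarity between rows of the thresholded connectivity matrix."""
    T = np.asarray(thresholded, dtype=float)
    norms = np.linalg.norm(T, axis=1)
    bad = np.flatnonzero(norms == 0)
    if bad.size:
        raise ManifoldError(f"all-zero row(s) at region index {bad.tolist()}")
    A = (T / norms[:, None]) @ (T / norms[:, None]).T
    A = 0.5 * (A + A.T)
    np.fill_diagonal(A, 1.0)
    return np.clip(A, -1.0, 1.0)


def _fix_signs(scores: np.ndarray) -> np.ndarray:
    """Flip each component so the entry of largest magnitude is positive."""
    flips = np.sign(scores[np.argmax(np.abs(scores), axis=0), np.arange(scores.shape[1])])
    flips[flips == 0] = 1.0
    return scores * flips


def pca_embed(affinity: np.ndarray, n_components: int = 3) -> Embedding:
    """Column-centered PCA of an affinity matrix.

    Coordinates are the leading principal-component scores with a
    deterministic sign convention; variance_explained is each component's
    share of total variance.
    """
    A = np.asarray(affinity, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ManifoldError("affinity must be square")
    n = A.shape[0]
    if n_components > n:
        raise ManifoldError(f"n_components={n_components} exceeds matrix size {n}")
    X = A - A.mean(axis=0)
    U, s, _ = linalg.svd(X, full_matrices=False)
    var = s**2
    total = var.sum()
    scores = U[:, :n_components] * s[:n_components]
    return Embedding(
        coordinates=_fix_signs(scores),
        variance_explained=var[:n_components] / total if total > 0 else np.zeros(n_components),
        aligned=False,
    )


def embed_covariance(cov: np.ndarray, density: float = 0.10, n_components: int = 3) -> Embedding:
    """threshold -> cosine affinity -> PCA, the full per-matrix embedding step."""
    return pca_embed(cosine_affinity(row_threshold(cov, density)), n_components)


def build_template(
    baseline_covs: Mapping[str, Sequence[np.ndarray]],
    density: float = 0.10,
    n_components: int = 3,
) -> Embedding:
    """Template Baseline manifold from each subject's baseline matrices.

    For every subject the geometric mean of their (Day 1, Day 2) baseline
    matrices is taken, the geometric mean across subjects forms the template
    matrix, and the standard embedding pipeline is applied.  The resulting
    embedding is the common reference space, flagged as aligned.
    """
    if not baseline_covs:
        raise ManifoldError("no baseline covariances supplied")
    subject_means = [geometric_mean(list(mats)) for _, mats in sorted(baseline_covs.items())]
    template_cov = geometric_mean(subject_means)
    emb = embed_covariance(template_cov, density=density, n_components=n_components)
    emb.aligned = True
    return emb


def procrustes_align(source: Embedding, template: Embedding) -> Embedding:
    """Rotate/reflect (no scaling) a centered source embedding onto the template.

    Solves the orthogonal Procrustes problem min_R ||(X - mean(X)) R - Y||_F
    where Y is the centered template; scaling is deliberately excluded so that
    eccentricity magnitudes remain comparable across epochs.
    """
    X, Y = source.coordinates, template.coordinates
    if X.shape != Y.shape:
        raise ManifoldError(f"shape mismatch {X.shape} vs {Y.shape}")
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    U, _, Vt = linalg.svd(Xc.T @ Yc)
    R = U @ Vt
    return Embedding(
        coordinates=Xc @ R,
        variance_explained=source.variance_explained,
        aligned=True,
    )


def eccentricity(emb: Embedding, centroid: np.ndarray | None = None) -> np.ndarray:
    """Per-region Euclidean distance from the manifold centroid.

    Requires an aligned embedding (alignment guarantees a shared coordinate
    frame); the centroid defaults to the origin, i.e. the template centroid
    after centering.
    """
    if not emb.aligned:
        raise ManifoldError("eccentricity requires an aligned embedding")
    if centroid is None:
        centroid = np.zeros(emb.n_components)
    centroid = np.asarray(centroid, dtype=float)
    if centroid.shape != (emb.n_components,):
        raise ManifoldError("centroid dimension mismatch")
    return np.linalg.norm(emb.coordinates - centroid, axis=1)
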