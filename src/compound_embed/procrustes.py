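"""Scaled Procrustes alignment of samples onto the primary reference.

Each sample is aligned to the reference in PCA space using only the
centroids of cell types the two have in common: both K x P centroid
matrices are mean-centered and Frobenius-normalized, an orthogonal
rotation (optionally including reflection — PCA component signs are
arbitrary across samples) is fitted in closed form, and the resulting
similarity transform (translation + uniform scale + rotation) is applied
to the sample's full PCA matrix.  Because the transform is a similarity,
within-sample neighbor identities are untouched; only the embedding
initialization is affected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import orthogonal_procrustes, svd

from .core import MISSING_CODE


class DegenerateFitError(ValueError):
    """Procrustes fit attempted on fewer than two shared centroids."""


class MissingTypeError(ValueError):
    """A requested cell type has no member cells."""


@dataclass
class CentroidMatrix:
    """Per-cell-type mean coordinates, rows ordered by ``types``."""

    types: list[int]
    centers: np.ndarray  # (K, D)

    @property
    def K(self) -> int:
        return len(self.types)


@dataclass
class ProcrustesTransform:
    """Similarity transform mapping a sample's PCA frame onto the reference's.

    Applied as ``((X - pre_shift) / pre_scale) @ rotation * post_scale
    + post_shift``.  ``sse`` is the residual sum of squared errors on the
    centroid matrices the fit used.
    """

    pre_shift: np.ndarray
    pre_scale: float
    rotation: np.ndarray
    post_scale: float
    post_shift: np.ndarray
    sse: float = 0.0

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, float)
        if not np.allclose(R.T @ R, np.eye(R.shape[0]), atol=1e-8):
            raise ValueError("rotation must be orthogonal (tol 1e-8)")
        if self.pre_scale <= 0 or self.post_scale <= 0:
            raise ValueError("scales must be positive")

    @property
    def net_scale(self) -> float:
        return self.post_scale / self.pre_scale


def compute_type_centers(
    coords: np.ndarray, labels: np.ndarray, wanted_types: list[int]
) -> CentroidMatrix:
    """Mean coordinates per requested cell type.

    Works in any dimension (PCA space or 2-D embedding space).  Cells
    carrying the reserved missing code never contribute; requesting the
    missing code, or a type with zero member cells, is an error.
    """
    coords = np.asarray(coords, float)
    labels = np.asarray(labels, int)
    centers = np.empty((len(wanted_types), coords.shape[1]))
    for i, t in enumerate(wanted_types):
        if t == MISSING_CODE:
            raise MissingTypeError("the reserved missing code has no centroid")
        mask = labels == t
        if not mask.any():
            raise MissingTypeError(f"type code {t} has no member cells")
        centers[i] = coords[mask].mean(axis=0)
    return CentroidMatrix(list(wanted_types), centers)


def fit_procrustes(
    reference: CentroidMatrix,
    sample: CentroidMatrix,
    allow_reflection: bool = True,
) -> ProcrustesTransform:
    """Fit the scaled Procrustes transform taking ``sample`` onto ``reference``.

    Minimizes the summed squared error between transformed sample
    centroids and reference centroids over translation, positive uniform
    scale and orthogonal rotation (closed-form SVD solution).  With
    ``allow_reflection=False`` the rotation is constrained to
    determinant +1.

    Raises
    ------
    DegenerateFitError
        If the type lists differ or K < 2 (rotation unidentifiable).
    """
    if reference.types != sample.types:
        raise DegenerateFitError("centroid matrices must share ordered types")
    if reference.K < 2:
        raise DegenerateFitError("need at least 2 shared types to fit")
    A = np.asarray(sample.centers, float)
    B = np.asarray(reference.centers, float)
    mu_a, mu_b = A.mean(axis=0), B.mean(axis=0)
    Ac, Bc = A - mu_a, B - mu_b
    na, nb = np.linalg.norm(Ac), np.linalg.norm(Bc)
    if na == 0 or nb == 0:
        raise DegenerateFitError("coincident centroids: scale unidentifiable")
    An, Bn = Ac / na, Bc / nb
    if allow_reflection:
        R, s = orthogonal_procrustes(An, Bn)
    else:
        # Kabsch: force det(R) = +1 by flipping the smallest singular pair.
        U, S, Vt = svd(An.T @ Bn)
        d = np.sign(np.linalg.det(U @ Vt))
        D = np.ones(len(S))
        D[-1] = d
        R = (U * D) @ Vt
        s = float(np.sum(S * D))
    # a centered K x P matrix has rank <= K - 1 by construction; warn
    # only when the centroids are degenerate beyond that
    if np.linalg.matrix_rank(Ac, tol=1e-10) < min(Ac.shape[0] - 1,
                                                  Ac.shape[1]):
        warnings.warn("rank-deficient centroid matrix; rotation partly "
                      "unconstrained", RuntimeWarning, stacklevel=2)
    sse = float(np.sum((An @ R * s - Bn) ** 2) * nb**2)
    return ProcrustesTransform(
        pre_shift=mu_a,
        pre_scale=float(na),
        rotation=R,
        post_scale=float(s * nb),
        post_shift=mu_b,
        sse=sse,
    )


def identity_transform(P: int) -> ProcrustesTransform:
    return ProcrustesTransform(np.zeros(P), 1.0, np.eye(P), 1.0, np.zeros(P))


def apply_transform(t: ProcrustesTransform, full: np.ndarray) -> np.ndarray:
    """Apply a fitted transform to a full (n, P) coordinate matrix."""
    full = np.asarray(full, float)
    if full.shape[1] != t.rotation.shape[0]:
        raise ValueError(
            f"transform fitted for P={t.rotation.shape[0]}, "
            f"got P={full.shape[1]}")
    return ((full - t.pre_shift) / t.pre_scale) @ t.rotation * t.post_scale \
        + t.post_shift
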