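"""Evaluation metrics: cross-sample alignment and structure preservation.

*Alignment score.*  Each embedding is normalized (grand centroid
subtracted, coordinates divided by the root-mean-square cell distance
from it) so the score ignores the arbitrary origin and scale of
individual t-SNE runs.  For the cell types shared by the two samples,
``d`` is the sum of squared Euclidean distances between normalized type
centers, and the score is ``1 / (1 + d)``: 1 means the centers coincide.

*Locality preservation.*  For each cell, the fraction of its k nearest
neighbors in the sample's independent embedding that remain among its k
nearest neighbors in the aligned embedding.  1 everywhere when the
aligned embedding is an isometry (plus uniform scaling) of the
independent one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import MISSING_CODE, EmbeddingResult
from .procrustes import compute_type_centers


class UndefinedScoreError(ValueError):
    """The two samples share no cell types; alignment is undefined."""


def normalize_embedding(coords: np.ndarray) -> np.ndarray:
    """Center on the grand centroid and scale by the RMS cell radius."""
    coords = np.asarray(coords, float)
    centered = coords - coords.mean(axis=0)
    rms = np.sqrt(np.mean(np.sum(centered**2, axis=1)))
    if rms == 0.0:
        return centered
    return centered / rms


def alignment_score(emb_a: EmbeddingResult, labels_a: np.ndarray,
                    emb_b: EmbeddingResult, labels_b: np.ndarray) -> float:
    """1 / (1 + d) over shared-type centers of two normalized embeddings."""
    labels_a = np.asarray(labels_a, int)
    labels_b = np.asarray(labels_b, int)
    shared = sorted(
        ({int(c) for c in np.unique(labels_a)} &
         {int(c) for c in np.unique(labels_b)}) - {MISSING_CODE})
    if not shared:
        raise UndefinedScoreError("no shared cell types between embeddings")
    ca = compute_type_centers(normalize_embedding(emb_a.coords), labels_a,
                              shared).centers
    cb = compute_type_centers(normalize_embedding(emb_b.coords), labels_b,
                              shared).centers
    d = float(np.sum((ca - cb) ** 2))
    return 1.0 / (1.0 + d)


@dataclass
class LocalityResult:
    fractions: np.ndarray
    mean: float
    sd: float


def _knn_indices(coords: np.ndarray, k: int) -> np.ndarray:
    """Each cell's k nearest neighbors (self excluded), ties broken by
    cell index for determinism."""
    diff = coords[:, None, :] - coords[None, :, :]
    D = np.einsum("ijk,ijk->ij", diff, diff)
    np.fill_diagonal(D, np.inf)
    order = np.argsort(D, axis=1, kind="stable")
    return order[:, :k]


def locality_preservation(emb_independent: EmbeddingResult,
                          emb_aligned: EmbeddingResult,
                          k: int = 30) -> LocalityResult:
    """Per-cell fraction of shared k nearest neighbors, with mean and sd."""
    if emb_independent.n != emb_aligned.n:
        raise ValueError("embeddings must contain the same cells in the "
                         "same order")
    n = emb_independent.n
    if not (0 < k < n):
        raise ValueError(f"k must lie in (0, n); got k={k}, n={n}")
    nn_ind = _knn_indices(emb_independent.coords, k)
    nn_ali = _knn_indices(emb_aligned.coords, k)
    fractions = np.empty(n)
    for i in range(n):
        fractions[i] = len(set(nn_ind[i]) & set(nn_ali[i])) / k
    return LocalityResult(fractions, float(fractions.mean()),
                          float(fractions.std()))
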