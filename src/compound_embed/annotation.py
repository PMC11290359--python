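"""Fallback cluster annotations via reference k-means + MNN transfer.

When samples arrive without cell-type annotations, one sample is
clustered with k-means in PCA space and its cluster identities are
transferred to every other sample through mutual nearest neighbors
(MNN): the ``m`` cells closest to each reference centroid act as that
cluster's representatives; representative/other-cell pairs that are
mutually among each other's nearest cross-sample neighbors seed cluster
identities in the other sample (majority vote per cell), and the
remaining cells are assigned to the nearest seeded-cluster centroid
computed within the other sample.

These labels exist purely so the alignment has matched clusters to work
with; they carry no biological meaning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.neighbors import NearestNeighbors

from .core import SampleCollection, SampleData


@dataclass
class AnnotationConfig:
    """Knobs for the annotation fallback (all in PCA space, Euclidean).

    ``min_seed_fraction``: a cluster is treated as present in the other
    sample only if its MNN seed count reaches this fraction of the
    best-seeded cluster's count; weaker clusters are dropped as spurious
    (they arise when a cluster is absent and stray mutual pairs form
    with a distant one).
    """

    fallback_k: int = 10
    representatives_per_cluster: int = 20
    mnn_neighbors: int = 15
    min_seed_fraction: float = 0.25
    seed: int = 0


@dataclass
class ClusterModel:
    """k-means partition of the reference plus per-cluster representatives."""

    k: int
    centroids: np.ndarray              # (k, P)
    labels: np.ndarray                 # reference cells' cluster codes
    reference_sample_id: str
    representatives: list[np.ndarray]  # per cluster, indices of m nearest cells
    rep_coords: np.ndarray             # stacked PCA coords of representatives
    rep_cluster: np.ndarray            # cluster code of each representative row


def kmeans_cluster_reference(sample: SampleData, k: int, m: int,
                             seed: int) -> ClusterModel:
    """Cluster the reference sample and pick centroid-nearest representatives.

    Deterministic given ``seed``.  Representatives are the ``m`` member
    cells with smallest Euclidean distance to their cluster centroid
    (fewer if the cluster is smaller than ``m``).
    """
    if k > sample.n:
        raise ValueError(f"k ({k}) exceeds cell count ({sample.n})")
    if m < 1:
        raise ValueError("need at least one representative per cluster")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(sample.pca)
    if len(np.unique(labels)) < k:  # sklearn relocates empty clusters; guard anyway
        raise RuntimeError("k-means produced an empty cluster")
    reps: list[np.ndarray] = []
    for c in range(k):
        members = np.flatnonzero(labels == c)
        dist = np.linalg.norm(sample.pca[members] - km.cluster_centers_[c],
                              axis=1)
        order = members[np.argsort(dist, kind="stable")]
        reps.append(order[:m])
    rep_idx = np.concatenate(reps)
    rep_cluster = np.concatenate(
        [np.full(len(r), c, dtype=int) for c, r in enumerate(reps)])
    return ClusterModel(k=k, centroids=km.cluster_centers_, labels=labels,
                        reference_sample_id=sample.sample_id,
                        representatives=reps,
                        rep_coords=sample.pca[rep_idx].copy(),
                        rep_cluster=rep_cluster)


def match_clusters_mnn(model: ClusterModel, other: SampleData,
                       n_neighbors: int = 15,
                       min_seed_fraction: float = 0.25,
                       refine_sweeps: int = 10) -> np.ndarray:
    """Transfer reference cluster codes to ``other`` via mutual nearest
    neighbors between the representatives and the other sample's cells.

    A cell incident to mutual pairs is seeded with the cluster of its
    nearest mutual representative; clusters whose seed count falls below
    ``min_seed_fraction`` of the best-seeded cluster are treated as
    absent (warning).  Remaining cells are assigned to the nearest
    seeded-cluster centroid within the other sample, and the assignment
    is polished by a few Lloyd sweeps over the present clusters — the
    seeds decide which cluster a blob corresponds to, the within-sample
    geometry decides which cells form a blob.  If no mutual pairs exist
    at all, every cell falls back to its nearest reference centroid.
    Every cell receives exactly one reference cluster code.
    """
    if other.P != model.centroids.shape[1]:
        raise ValueError("PCA dimensionality mismatch with cluster model")
    R, X = model.rep_coords, other.pca
    n_rep, n_other = R.shape[0], X.shape[0]
    k_r = min(n_neighbors, n_other)
    k_o = min(n_neighbors, n_rep)
    rep_to_other = NearestNeighbors(n_neighbors=k_r).fit(X) \
        .kneighbors(R, return_distance=False)
    other_to_rep = NearestNeighbors(n_neighbors=k_o).fit(R) \
        .kneighbors(X, return_distance=False)
    in_rep_list = np.zeros((n_rep, n_other), dtype=bool)
    in_rep_list[np.repeat(np.arange(n_rep), k_r), rep_to_other.ravel()] = True
    assignment = np.full(n_other, -1, dtype=int)
    for j in range(n_other):
        for r in other_to_rep[j]:  # distance-ordered
            if in_rep_list[r, j]:
                assignment[j] = model.rep_cluster[r]
                break
    seeded = assignment >= 0
    if not seeded.any():
        warnings.warn("no mutual nearest-neighbor pairs; assigning all "
                      "cells by nearest reference centroid",
                      RuntimeWarning, stacklevel=2)
        d = np.linalg.norm(X[:, None, :] - model.centroids[None], axis=2)
        return d.argmin(axis=1)
    counts = np.bincount(assignment[seeded], minlength=model.k)
    threshold = max(1.0, min_seed_fraction * counts.max())
    present = np.flatnonzero(counts >= threshold)
    absent = sorted(set(range(model.k)) - set(int(c) for c in present))
    if absent:
        warnings.warn(f"clusters {absent} have too few mutual pairs in "
                      f"sample {other.sample_id!r}; treated as absent",
                      RuntimeWarning, stacklevel=2)
        weak = ~np.isin(assignment, present)
        assignment[weak] = -1
        seeded = assignment >= 0
    centroids = np.stack([X[assignment == c].mean(axis=0) for c in present])
    rest = ~seeded
    if rest.any():
        d = np.linalg.norm(X[rest, None, :] - centroids[None], axis=2)
        assignment[rest] = present[d.argmin(axis=1)]
    for _ in range(refine_sweeps):
        centroids = np.stack([
            X[assignment == c].mean(axis=0)
            if (assignment == c).any() else centroids[i]
            for i, c in enumerate(present)])
        d = np.linalg.norm(X[:, None, :] - centroids[None], axis=2)
        new = present[d.argmin(axis=1)]
        if (new == assignment).all():
            break
        assignment = new
    return assignment


def annotate_collection(collection: SampleCollection,
                        reference_id: str | None = None,
                        config: AnnotationConfig | None = None
                        ) -> SampleCollection:
    """Produce a fully labeled copy of an unannotated collection.

    The reference (largest sample unless named) is k-means clustered;
    every other sample receives matched cluster codes via MNN.  The
    vocabulary is ``cluster_00 .. cluster_{k-1}`` — alignment-only
    identities, not cell types.
    """
    config = config or AnnotationConfig()
    if reference_id is None:
        reference_id = max(collection.samples, key=lambda s: s.n).sample_id
    ref = collection[reference_id]
    k = min(config.fallback_k, ref.n)
    model = kmeans_cluster_reference(ref, k,
                                     config.representatives_per_cluster,
                                     config.seed)
    vocabulary = [f"cluster_{c:02d}" for c in range(k)]
    labeled = []
    for s in collection.samples:
        if s.sample_id == reference_id:
            labeled.append(s.with_labels(model.labels))
        else:
            labeled.append(s.with_labels(match_clusters_mnn(
                model, s, config.mnn_neighbors,
                min_seed_fraction=config.min_seed_fraction)))
    return SampleCollection(labeled, vocabulary)
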