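"""Synthetic multi-sample fixtures with known ground truth.

Samples are drawn from one shared Gaussian mixture in PCA space (one
component per cell type), then distorted per sample by a rigid planar
rotation in the first two components, a uniform scale, a translation,
and isotropic noise — mimicking batch-to-batch differences between
patients or modalities whose cell types nonetheless occupy one shared
latent geometry.  Per-sample type dropout emulates samples missing cell
types, and :func:`make_unbalanced_pair` emulates strongly unequal cell
counts.  Everything is reproducible from the spec's seed.

Default regime: 3 samples x 1000 cells, 5 types, P = 10, unit type sd
with inter-type separation about 6 sd, extra noise sd 0.3 — desk-scale
and cleanly separable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import SampleCollection, SampleData


def _default_type_means(n_types: int, P: int, separation: float) -> np.ndarray:
    """Type means on a regular polygon in the first two components
    (adjacent-type distance = ``separation``) plus a per-type offset of
    ``separation / 2`` on a higher component.

    Mirrors how leading PCs separate major cell types in real data: the
    PC1-2 plane carries most of the between-type structure (so the
    embedding initialization is informative) while higher components
    still distinguish types.
    """
    if n_types + 2 > P:
        raise ValueError("default layout needs n_types + 2 <= P")
    radius = separation / (2.0 * math.sin(math.pi / n_types))
    means = np.zeros((n_types, P))
    for t in range(n_types):
        theta = 2.0 * math.pi * t / n_types
        means[t, 0] = radius * math.cos(theta)
        means[t, 1] = radius * math.sin(theta)
        means[t, 2 + t] = separation / 2.0
    return means


@dataclass
class FixtureSpec:
    """Generation parameters for a multi-sample fixture."""

    n_samples: int = 3
    n_cells: tuple[int, ...] = (1000, 1000, 1000)
    n_types: int = 5
    P: int = 10
    separation: float = 6.0
    type_means: np.ndarray | None = None
    type_sds: float | tuple[float, ...] = 1.0
    batch_rotation_angle: tuple[float, ...] = (0.0, 0.5, -0.7)
    batch_scale: tuple[float, ...] = (1.0, 1.15, 0.9)
    batch_shift_scale: float = 1.0
    noise_sd: float = 0.3
    dropout: tuple[frozenset[int], ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_types < 2:
            raise ValueError("need at least 2 cell types")
        if len(self.n_cells) != self.n_samples:
            raise ValueError("n_cells must list one count per sample")
        if len(self.batch_rotation_angle) != self.n_samples \
                or len(self.batch_scale) != self.n_samples:
            raise ValueError("per-sample batch parameters must match "
                             "n_samples")
        if self.type_means is None:
            self.type_means = _default_type_means(self.n_types, self.P,
                                                  self.separation)
        self.type_means = np.asarray(self.type_means, float)
        if self.type_means.shape != (self.n_types, self.P):
            raise ValueError("type_means must be (n_types, P)")
        if self.dropout is not None:
            kept_anywhere = set()
            for s in range(self.n_samples):
                dropped = self.dropout[s] if s < len(self.dropout) else set()
                kept_anywhere |= set(range(self.n_types)) - set(dropped)
            if kept_anywhere != set(range(self.n_types)):
                missing = set(range(self.n_types)) - kept_anywhere
                raise ValueError(f"types {sorted(missing)} dropped from "
                                 "every sample")

    def sds(self) -> np.ndarray:
        if np.isscalar(self.type_sds):
            return np.full(self.n_types, float(self.type_sds))
        return np.asarray(self.type_sds, float)


@dataclass
class GroundTruth:
    """What the generator actually did, for oracle-style checks."""

    labels: list[np.ndarray]
    rotations: list[np.ndarray]      # (P, P) applied per sample
    scales: list[float]
    shifts: list[np.ndarray]
    separation_over_sd: float


def _planar_rotation(P: int, angle: float) -> np.ndarray:
    R = np.eye(P)
    c, s = math.cos(angle), math.sin(angle)
    R[0, 0], R[0, 1], R[1, 0], R[1, 1] = c, -s, s, c
    return R


def generate_multisample(spec: FixtureSpec
                         ) -> tuple[SampleCollection, GroundTruth]:
    """Draw the fixture; labels are attached to every sample.

    For fallback testing, strip them with :func:`withhold_labels`.
    """
    rng = np.random.default_rng(spec.seed)
    sds = spec.sds()
    vocabulary = [f"type_{t}" for t in range(spec.n_types)]
    samples, gt_labels, rotations, scales, shifts = [], [], [], [], []
    for s in range(spec.n_samples):
        dropped = set(spec.dropout[s]) if spec.dropout is not None \
            and s < len(spec.dropout) else set()
        kept = [t for t in range(spec.n_types) if t not in dropped]
        n = spec.n_cells[s]
        labels = rng.choice(kept, size=n)
        labels.sort()
        X = spec.type_means[labels] \
            + rng.normal(size=(n, spec.P)) * sds[labels][:, None]
        R = _planar_rotation(spec.P, spec.batch_rotation_angle[s])
        shift = rng.normal(scale=spec.batch_shift_scale, size=spec.P)
        X = X @ R.T * spec.batch_scale[s] + shift
        X += rng.normal(scale=spec.noise_sd, size=X.shape)
        cell_ids = [f"s{s}_c{i}" for i in range(n)]
        samples.append(SampleData(f"sample_{s}", cell_ids, X,
                                  labels.astype(int)))
        gt_labels.append(labels.astype(int))
        rotations.append(R)
        scales.append(float(spec.batch_scale[s]))
        shifts.append(shift)
    truth = GroundTruth(gt_labels, rotations, scales, shifts,
                        spec.separation / float(sds.max()))
    return SampleCollection(samples, vocabulary), truth


def withhold_labels(collection: SampleCollection) -> SampleCollection:
    """Copy of the collection with all annotations removed."""
    stripped = [SampleData(s.sample_id, list(s.cell_ids), s.pca.copy(), None)
                for s in collection.samples]
    return SampleCollection(stripped, [])


def make_unbalanced_pair(spec: FixtureSpec, fraction: float
                         ) -> SampleCollection:
    """Two-sample fixture with the second subsampled to ``fraction``.

    Subsampling is without replacement, seeded from the spec; the
    retained cell count is ``ceil(fraction * n)``.
    """
    if spec.n_samples != 2:
        raise ValueError("unbalanced pair needs a two-sample spec")
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie in (0, 1)")
    collection, _ = generate_multisample(spec)
    full, second = collection.samples
    keep = math.ceil(fraction * second.n)
    if keep < spec.n_types:
        raise ValueError(f"fraction {fraction} keeps only {keep} cells, "
                         f"fewer than the {spec.n_types} types")
    rng = np.random.default_rng(spec.seed + 1)
    idx = np.sort(rng.choice(second.n, size=keep, replace=False))
    sub = SampleData(second.sample_id,
                     [second.cell_ids[i] for i in idx],
                     second.pca[idx],
                     second.labels[idx])
    return SampleCollection([full, sub], list(collection.vocabulary))
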