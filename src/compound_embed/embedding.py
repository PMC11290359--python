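"""t-SNE embedding with cell-type center-attraction forces.

The embedding of a non-reference sample minimizes

    L_total = L_tsne + lambda * sum_i d_i,      d_i = ||c_ref_i - c_i||^2

where ``c_ref_i`` is the reference embedding center of cell type ``i``,
``c_i`` the sample's current embedding center of that type, and the sum
runs over the K types shared between sample and reference set.  The
optimizer alternates one standard t-SNE gradient step with one force
step that rigidly translates each shared type's cells by ``lambda``
times its center offset; a pure translation leaves within-type structure
untouched, which is what makes the alignment "soft".  With frozen t-SNE
forces, each force step shrinks every d_i by exactly (1 - lambda)^2.

Forces are disabled during early exaggeration (that phase establishes
cluster topology) and for cell types absent from the reference center
set.  With ``lam = 0`` the trajectory is identical to plain t-SNE from
the same initialization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import MISSING_CODE, EmbeddingResult, SampleData
from .procrustes import compute_type_centers
from .tsne import TsneOptimizer, joint_probabilities


class AlignmentImpossibleError(ValueError):
    """Sample and reference center set share no cell types."""


@dataclass
class EmbedConfig:
    """Embedding hyper-parameters.

    ``lam`` is the force weight (lambda in the loss above); 0 disables
    alignment forces.  ``learning_rate="auto"`` resolves to
    ``n / exaggeration_early``.  ``init_std`` is the standard deviation
    the first initialization column is rescaled to (the conventional
    1e-4 keeps early gradients in the attractive regime).
    """

    perplexity: float = 30.0
    n_iter_early: int = 250
    n_iter_main: int = 500
    exaggeration_early: float = 12.0
    lam: float = 0.1
    learning_rate: float | str = "auto"
    seed: int = 0
    init_std: float = 1e-4

    def __post_init__(self) -> None:
        if self.perplexity <= 0:
            raise ValueError("perplexity must be positive")
        if self.lam < 0:
            raise ValueError("force weight lambda must be non-negative")
        if self.init_std <= 0:
            raise ValueError("init_std must be positive")


@dataclass
class ReferenceCenters:
    """Embedding-space center per cell-type code, with provenance.

    ``source[code]`` names the reference sample (primary or a secondary)
    whose embedding contributed that center.
    """

    centers: dict[int, np.ndarray] = field(default_factory=dict)
    source: dict[int, str] = field(default_factory=dict)

    def codes(self) -> list[int]:
        return sorted(self.centers)

    def add(self, code: int, center: np.ndarray, source: str) -> None:
        if code in self.centers:
            raise ValueError(f"center for code {code} already present")
        self.centers[code] = np.asarray(center, float)
        self.source[code] = source

    def shared_with(self, labels: np.ndarray) -> list[int]:
        present = {int(c) for c in np.unique(labels) if c != MISSING_CODE}
        return sorted(present & set(self.centers))


@dataclass
class ForceState:
    """Final per-type squared center distances of a force embedding."""

    K: int
    codes: list[int]
    d: np.ndarray           # squared center distances, one per shared type
    sum_d_history: list[float]  # sum of d_i after each force iteration

    @property
    def sum_d(self) -> float:
        return float(self.d.sum())


def initialize_embedding(transformed_pca: np.ndarray,
                         config: EmbedConfig) -> np.ndarray:
    """First two PCA components, rescaled so column 1 has std ``init_std``.

    Both columns are scaled by the same factor, preserving the aspect
    ratio of the PCA plane.  A zero-variance first component falls back
    to a seeded Gaussian initialization (with a warning).
    """
    X = np.asarray(transformed_pca, float)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 components to initialize")
    Y = X[:, :2].copy()
    std = float(Y[:, 0].std())
    if std == 0.0:
        warnings.warn("zero-variance first component; using Gaussian "
                      "initialization", RuntimeWarning, stacklevel=2)
        rng = np.random.default_rng(config.seed)
        return rng.normal(scale=config.init_std, size=Y.shape)
    return Y * (config.init_std / std)


def force_step(Y: np.ndarray, labels: np.ndarray,
               centers: ReferenceCenters, lam: float) -> np.ndarray:
    """One center-attraction step: translate each shared type toward its
    reference center by fraction ``lam`` of the offset.  Pure per-type
    translation; returns a new array."""
    Y = np.array(Y, copy=True)
    for code in centers.shared_with(labels):
        mask = labels == code
        offset = centers.centers[code] - Y[mask].mean(axis=0)
        Y[mask] += lam * offset
    return Y


def _center_distances(Y: np.ndarray, labels: np.ndarray,
                      centers: ReferenceCenters) -> tuple[list[int], np.ndarray]:
    codes = centers.shared_with(labels)
    d = np.empty(len(codes))
    for i, code in enumerate(codes):
        c = Y[labels == code].mean(axis=0)
        d[i] = float(np.sum((centers.centers[code] - c) ** 2))
    return codes, d


def _run_tsne(sample: SampleData, config: EmbedConfig,
              centers: ReferenceCenters | None,
              lam: float) -> tuple[np.ndarray, list[float]]:
    """Shared optimization loop; ``centers=None`` means plain t-SNE."""
    if config.perplexity >= sample.n:
        raise ValueError(
            f"perplexity ({config.perplexity}) must be < n ({sample.n})")
    P = joint_probabilities(sample.pca, config.perplexity)
    Y0 = initialize_embedding(sample.pca, config)
    opt = TsneOptimizer(P, Y0, learning_rate=config.learning_rate,
                        exaggeration=config.exaggeration_early)
    for _ in range(config.n_iter_early):
        opt.step(exaggeration=config.exaggeration_early, momentum=0.5)
    history: list[float] = []
    for _ in range(config.n_iter_main):
        opt.step(exaggeration=1.0, momentum=0.8)
        if centers is not None:
            opt.Y = force_step(opt.Y, sample.labels, centers, lam)
            _, d = _center_distances(opt.Y, sample.labels, centers)
            history.append(float(d.sum()))
    return opt.Y, history


def embed_reference(sample: SampleData, config: EmbedConfig
                    ) -> tuple[EmbeddingResult, ReferenceCenters]:
    """Plain t-SNE of the reference sample, then its per-type centers."""
    if sample.labels is None:
        raise ValueError("reference sample must be labeled")
    Y, _ = _run_tsne(sample, config, centers=None, lam=0.0)
    result = EmbeddingResult(sample.sample_id, Y, "primary", config.seed)
    centers = ReferenceCenters()
    for code in sorted(sample.label_set()):
        cm = compute_type_centers(Y, sample.labels, [code])
        centers.add(code, cm.centers[0], sample.sample_id)
    return result, centers


def embed_plain(sample: SampleData, config: EmbedConfig,
                provenance: str = "independent") -> EmbeddingResult:
    """Plain t-SNE from the sample's own PCA initialization, no forces."""
    Y, _ = _run_tsne(sample, config, centers=None, lam=0.0)
    return EmbeddingResult(sample.sample_id, Y, provenance, config.seed)


def embed_with_forces(sample: SampleData, centers: ReferenceCenters,
                      config: EmbedConfig
                      ) -> tuple[EmbeddingResult, ForceState]:
    """Embed one sample with center-attraction forces toward ``centers``.

    Each main-phase iteration performs one t-SNE gradient step followed
    by one :func:`force_step`.  Types absent from the center set receive
    no force (warning).  Raises :class:`AlignmentImpossibleError` when
    no types are shared at all.
    """
    if sample.labels is None:
        raise ValueError("force embedding requires labels")
    shared = centers.shared_with(sample.labels)
    if not shared:
        raise AlignmentImpossibleError(
            f"sample {sample.sample_id!r} shares no cell types with the "
            "reference center set")
    unmatched = sample.label_set() - set(centers.centers)
    if unmatched:
        warnings.warn(
            f"sample {sample.sample_id!r}: no reference center for codes "
            f"{sorted(unmatched)}; those cells receive no force",
            RuntimeWarning, stacklevel=2)
    Y, history = _run_tsne(sample, config, centers=centers, lam=config.lam)
    codes, d = _center_distances(Y, sample.labels, centers)
    result = EmbeddingResult(sample.sample_id, Y, "force", config.seed)
    return result, ForceState(K=len(codes), codes=codes, d=d,
                              sum_d_history=history)


def build_complete_reference(
    primary_result: EmbeddingResult,
    primary_labels: np.ndarray,
    secondaries: list[SampleData],
    config: EmbedConfig,
) -> tuple[ReferenceCenters, dict[str, EmbeddingResult],
           dict[str, ForceState]]:
    """Chain secondary references to complete the center set.

    Starting from the primary's per-type centers, each secondary (in
    cover order) is force-embedded against the centers accumulated so
    far, and its embedding supplies centers for types not yet covered.
    Returns the complete center map plus the secondaries' embeddings and
    force states (the pipeline reuses them as those samples' final
    embeddings).
    """
    centers = ReferenceCenters()
    for code in sorted({int(c) for c in np.unique(primary_labels)
                        if c != MISSING_CODE}):
        cm = compute_type_centers(primary_result.coords, primary_labels,
                                  [code])
        centers.add(code, cm.centers[0], primary_result.sample_id)
    embeddings: dict[str, EmbeddingResult] = {}
    states: dict[str, ForceState] = {}
    for sec in secondaries:
        # A secondary is expected to carry types the center set does not
        # yet cover; the "no reference center" warning is noise here.
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res, state = embed_with_forces(sec, centers, config)
        embeddings[sec.sample_id] = res
        states[sec.sample_id] = state
        for code in sorted(sec.label_set() - set(centers.centers)):
            cm = compute_type_centers(res.coords, sec.labels, [code])
            centers.add(code, cm.centers[0], sec.sample_id)
    return centers, embeddings, states
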