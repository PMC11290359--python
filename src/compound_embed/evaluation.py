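"""Study procedures used for validating the alignment method.

Each function here *runs* the pipeline on synthetic fixtures with known
ground truth and measures a property of interest: optimality of the
Procrustes fit, exact reduction to plain t-SNE at lambda = 0, geometric
decay of the frozen force step, the independent < primary < force
alignment ordering and its structure-preservation trade-off, behavior
under strongly unbalanced sample sizes, accuracy of the annotation
fallback, and completeness of the chained reference center set.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.optimize import linear_sum_assignment

from .annotation import AnnotationConfig, annotate_collection
from .core import SampleCollection
from .embedding import EmbedConfig, embed_plain, embed_with_forces, force_step
from .pipeline import align_collection
from .procrustes import CentroidMatrix, fit_procrustes
from .references import select_primary, select_secondary
from .simulate import (FixtureSpec, generate_multisample,
                       make_unbalanced_pair, withhold_labels)


def _unbalanced_spec(seed: int) -> FixtureSpec:
    return FixtureSpec(n_samples=2, n_cells=(1000, 1000),
                       batch_rotation_angle=(0.0, 0.5),
                       batch_scale=(1.0, 1.15), seed=seed)


def alignment_study(
    seeds: list[int],
    unbalanced_fraction: float | None = None,
    use_fallback_labels: bool = False,
    k: int = 30,
    n_cells: tuple[int, ...] = (1000, 1000, 1000),
) -> dict:
    """Mean alignment score and locality preservation per embedding variant.

    For each seed a fresh default fixture is generated (or an unbalanced
    pair when ``unbalanced_fraction`` is set), optionally stripped of
    labels and re-annotated by the k-means + MNN fallback, and the full
    pipeline is run with independent, primary-variant and force
    embeddings.  Returned means aggregate over seeds and non-reference
    samples.
    """
    per_variant_alignment: dict[str, list[float]] = {
        "independent": [], "primary": [], "force": []}
    per_variant_locality: dict[str, list[float]] = {"primary": [],
                                                    "force": []}
    for seed in seeds:
        if unbalanced_fraction is not None:
            collection = make_unbalanced_pair(_unbalanced_spec(seed),
                                              unbalanced_fraction)
        else:
            spec = FixtureSpec(n_cells=n_cells, seed=seed)
            collection, _ = generate_multisample(spec)
        if use_fallback_labels:
            n_types = len(collection.vocabulary)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                collection = annotate_collection(
                    withhold_labels(collection),
                    config=AnnotationConfig(fallback_k=n_types, seed=seed))
        config = EmbedConfig(seed=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            result = align_collection(collection, config,
                                      include_independent=True,
                                      include_primary_variant=True, k=k)
        for variant, scores in result.metrics["alignment"].items():
            per_variant_alignment[variant].extend(scores.values())
        for variant, locs in result.metrics["locality"].items():
            per_variant_locality[variant].extend(
                v["mean"] for sid, v in locs.items()
                if sid != result.primary_id)
    return {
        "alignment": {v: float(np.mean(x))
                      for v, x in per_variant_alignment.items()},
        "locality": {v: float(np.mean(x))
                     for v, x in per_variant_locality.items()},
        "n_seeds": len(seeds),
    }


def procrustes_optimality(n_pairs: int = 100, n_candidates: int = 1000,
                          seed: int = 0) -> dict:
    """Fitted SSE vs random orthogonal candidates and a dense angle grid.

    ``sse_ratio_max``: worst ratio of fitted SSE to the best of
    ``n_candidates`` random orthogonal transforms (each given its own
    optimal translation and scale); a value <= 1 means the closed form
    beat every candidate on every pair.  ``grid_gap_max``: for P = 2
    pairs, worst (fitted - best-grid-angle) SSE gap.
    """
    rng = np.random.default_rng(seed)
    sse_ratio_max = 0.0
    grid_gap_max = 0.0
    for _ in range(n_pairs):
        K = int(rng.integers(3, 9))
        P = int(rng.integers(2, 11))
        ref = CentroidMatrix(list(range(K)), rng.normal(size=(K, P)))
        smp = CentroidMatrix(list(range(K)), rng.normal(size=(K, P)))
        t = fit_procrustes(ref, smp)
        A, B = smp.centers, ref.centers
        Ac, Bc = A - A.mean(0), B - B.mean(0)
        na2 = float(np.sum(Ac**2))
        best = np.inf
        for _ in range(n_candidates):
            Q, _ = np.linalg.qr(rng.normal(size=(P, P)))
            s = max(float(np.sum((Ac @ Q) * Bc)) / na2, 1e-12)
            best = min(best, float(np.sum((Ac @ Q * s - Bc) ** 2)))
        sse_ratio_max = max(sse_ratio_max, t.sse / best)
        if P == 2:
            gap = t.sse - _grid_search_sse(Bc, Ac, na2)
            grid_gap_max = max(grid_gap_max, gap)
    return {"sse_ratio_max": sse_ratio_max, "grid_gap_max": grid_gap_max,
            "n_pairs": n_pairs}


def _grid_search_sse(Bc: np.ndarray, Ac: np.ndarray, na2: float,
                     n_angles: int = 100001) -> float:
    angles = np.linspace(-np.pi, np.pi, n_angles)
    c, s = np.cos(angles), np.sin(angles)
    x = Ac[:, 0][None, :] * c[:, None] - Ac[:, 1][None, :] * s[:, None]
    y = Ac[:, 0][None, :] * s[:, None] + Ac[:, 1][None, :] * c[:, None]
    dot = x @ Bc[:, 0] + y @ Bc[:, 1]
    scale = dot / na2
    sse = (scale**2) * na2 - 2 * scale * dot + float(np.sum(Bc**2))
    return float(sse.min())


def lambda_zero_reduction(seed: int = 0, n: int = 1000) -> dict:
    """Max |coordinate difference| between a lambda=0 force embedding and
    a plain t-SNE run from the same initialization (expected: 0)."""
    spec = FixtureSpec(n_cells=(n, n, n), seed=seed)
    collection, _ = generate_multisample(spec)
    sample = collection.samples[0]
    config = EmbedConfig(seed=seed, lam=0.0)
    from .embedding import ReferenceCenters

    centers = ReferenceCenters()
    for code in sorted(sample.label_set()):
        centers.add(code, np.zeros(2), "dummy")
    forced, _ = embed_with_forces(sample, centers, config)
    plain = embed_plain(sample, config)
    return {"max_coord_diff": float(np.abs(forced.coords
                                           - plain.coords).max()),
            "n": sample.n}


def force_decay_error(lams=(0.1, 0.5, 1.0), n_steps: int = 8,
                      seed: int = 0) -> dict:
    """Worst deviation of frozen force-step decay from (1-lam)^(2j)."""
    rng = np.random.default_rng(seed)
    from .embedding import ReferenceCenters

    worst = 0.0
    for lam in lams:
        Y = rng.normal(size=(200, 2))
        labels = rng.integers(0, 4, size=200)
        centers = ReferenceCenters()
        for t in range(4):
            centers.add(t, rng.normal(size=2) * 5, "ref")

        def sum_d(Yc):
            return sum(float(((centers.centers[t]
                               - Yc[labels == t].mean(0)) ** 2).sum())
                       for t in range(4))

        d0 = sum_d(Y)
        Yj = Y
        for j in range(1, n_steps + 1):
            Yj = force_step(Yj, labels, centers, lam)
            expected = (1 - lam) ** (2 * j) * d0
            err = abs(sum_d(Yj) - expected) / max(d0, 1e-300)
            worst = max(worst, err)
    return {"max_rel_error": worst, "n": n_steps}


def fallback_label_accuracy(seeds: list[int],
                            n_cells: tuple[int, ...] = (1000, 1000, 1000)
                            ) -> dict:
    """Agreement of k-means + MNN fallback labels with generator truth,
    after the optimal cluster-to-type permutation (Hungarian), pooled
    over all cells of all samples and seeds."""
    correct = total = 0
    for seed in seeds:
        spec = FixtureSpec(n_cells=n_cells, seed=seed)
        collection, _ = generate_multisample(spec)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            ann = annotate_collection(
                withhold_labels(collection),
                config=AnnotationConfig(fallback_k=spec.n_types, seed=seed))
        for s_ann, s_true in zip(ann.samples, collection.samples):
            k = spec.n_types
            C = np.zeros((k, k), dtype=int)
            np.add.at(C, (s_ann.labels, s_true.labels), 1)
            r, c = linear_sum_assignment(-C)
            correct += int(C[r, c].sum())
            total += s_true.n
    return {"accuracy": correct / total, "n": total}


def secondary_coverage(seed: int = 0) -> dict:
    """Run the pipeline on a dropout fixture and check the chained center
    set covers every generated type; also verify the greedy cover equals
    the exhaustive optimum."""
    spec = FixtureSpec(n_cells=(400, 400, 400), seed=seed,
                       dropout=(frozenset({4}), frozenset({4}),
                                frozenset({3})))
    collection, _ = generate_multisample(spec)
    config = EmbedConfig(seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        result = align_collection(collection, config)
    covered = set(result.centers.codes()) == collection.all_types()
    primary = select_primary(collection)
    secs = select_secondary(collection, primary)
    # exhaustive optimum for this 3-sample instance
    from itertools import combinations

    uncovered = collection.all_types() - collection[primary].label_set()
    others = [s for s in collection.samples if s.sample_id != primary]
    optimum = 0
    if uncovered:
        for size in range(1, len(others) + 1):
            if any(uncovered <= set().union(*(s.label_set() for s in combo))
                   for combo in combinations(others, size)):
                optimum = size
                break
    return {"covered_fraction": float(covered),
            "greedy_is_optimal": float(len(secs) == optimum),
            "n": len(collection.all_types())}
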