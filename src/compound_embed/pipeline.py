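"""End-to-end alignment pipeline.

Order of stages: read/annotate -> reference selection -> Procrustes
primary alignment in PCA space -> reference embedding -> secondary
chaining -> force embeddings for remaining samples -> metrics.  The
result object carries every intermediate the metrics and run report
need; :func:`run_report` serializes it to plain JSON-able types.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .annotation import AnnotationConfig, annotate_collection
from .core import EmbeddingResult, SampleCollection
from .embedding import (
    EmbedConfig,
    ForceState,
    ReferenceCenters,
    build_complete_reference,
    embed_plain,
    embed_reference,
    embed_with_forces,
)
from .metrics import alignment_score, locality_preservation
from .procrustes import (
    ProcrustesTransform,
    apply_transform,
    compute_type_centers,
    fit_procrustes,
)
from .references import select_primary, select_secondary

logger = logging.getLogger("compound_embed")


@dataclass
class PipelineResult:
    """Everything one alignment run produced."""

    config: EmbedConfig
    primary_id: str
    secondary_ids: list[str]
    collection: SampleCollection            # labeled, Procrustes-transformed
    transforms: dict[str, ProcrustesTransform]
    centers: ReferenceCenters
    embeddings: dict[str, dict[str, EmbeddingResult]]  # variant -> sample
    force_states: dict[str, ForceState]
    metrics: dict = field(default_factory=dict)


def _procrustes_align(collection: SampleCollection, primary_id: str,
                      allow_reflection: bool
                      ) -> tuple[SampleCollection, dict[str, ProcrustesTransform]]:
    primary = collection[primary_id]
    primary_types = primary.label_set()
    transforms: dict[str, ProcrustesTransform] = {}
    aligned = []
    for s in collection.samples:
        if s.sample_id == primary_id:
            aligned.append(s)
            continue
        shared = sorted(primary_types & s.label_set())
        ref_cm = compute_type_centers(primary.pca, primary.labels, shared)
        smp_cm = compute_type_centers(s.pca, s.labels, shared)
        t = fit_procrustes(ref_cm, smp_cm, allow_reflection=allow_reflection)
        transforms[s.sample_id] = t
        logger.info("procrustes %s -> %s: K=%d sse=%.4g",
                    s.sample_id, primary_id, len(shared), t.sse)
        aligned.append(s.with_pca(apply_transform(t, s.pca)))
    return SampleCollection(aligned, list(collection.vocabulary)), transforms


def align_collection(
    collection: SampleCollection,
    config: EmbedConfig | None = None,
    reference: str | None = None,
    include_independent: bool = False,
    include_primary_variant: bool = False,
    auto_annotate: bool = False,
    annotation_config: AnnotationConfig | None = None,
    allow_reflection: bool = True,
    compute_metrics: bool = True,
    k: int = 30,
) -> PipelineResult:
    """Run the full soft-alignment pipeline on a collection.

    Produces force-aligned embeddings for every sample; optionally also
    ``independent`` embeddings (plain t-SNE, untransformed PCA) and the
    ``primary`` variant (plain t-SNE from the aligned initialization)
    for comparison.  Metrics (alignment score of each sample against the
    primary reference per variant; locality preservation against the
    independent embedding) are attached when requested and computable.
    """
    config = config or EmbedConfig()
    if not collection.all_labeled:
        if not auto_annotate:
            raise ValueError(
                "collection has unannotated samples; pass an annotation "
                "key or enable auto_annotate (--auto-annotate) for "
                "k-means + MNN fallback labels")
        logger.info("no annotations: deriving matched cluster labels")
        collection = annotate_collection(collection, reference,
                                         annotation_config)

    primary_id = select_primary(collection, reference)
    logger.info("primary reference: %s", primary_id)

    embeddings: dict[str, dict[str, EmbeddingResult]] = {"force": {}}
    if include_independent:
        embeddings["independent"] = {
            s.sample_id: embed_plain(s, config, "independent")
            for s in collection.samples}

    aligned, transforms = _procrustes_align(collection, primary_id,
                                            allow_reflection)
    primary_sample = aligned[primary_id]
    primary_emb, _ = embed_reference(primary_sample, config)
    embeddings["force"][primary_id] = EmbeddingResult(
        primary_id, primary_emb.coords, "force", config.seed)

    secondary_ids = select_secondary(aligned, primary_id)
    logger.info("secondary references: %s", secondary_ids or "none")
    centers, sec_embs, force_states = build_complete_reference(
        primary_emb, primary_sample.labels,
        [aligned[sid] for sid in secondary_ids], config)
    embeddings["force"].update(sec_embs)

    for s in aligned.samples:
        if s.sample_id in embeddings["force"]:
            continue
        res, state = embed_with_forces(s, centers, config)
        embeddings["force"][s.sample_id] = res
        force_states[s.sample_id] = state

    if include_primary_variant:
        embeddings["primary"] = {primary_id: primary_emb}
        for s in aligned.samples:
            if s.sample_id != primary_id:
                embeddings["primary"][s.sample_id] = embed_plain(
                    s, config, "primary")

    result = PipelineResult(config, primary_id, secondary_ids, aligned,
                            transforms, centers, embeddings, force_states)
    if compute_metrics:
        result.metrics = compute_run_metrics(result, k=k)
    return result


def compute_run_metrics(result: PipelineResult, k: int = 30) -> dict:
    """Alignment scores vs the primary, and locality preservation vs the
    independent embeddings, for every variant present."""
    coll = result.collection
    primary_id = result.primary_id
    out: dict = {"alignment": {}, "locality": {}}
    for variant, embs in result.embeddings.items():
        scores = {}
        for sid, emb in embs.items():
            if sid == primary_id:
                continue
            scores[sid] = alignment_score(
                embs[primary_id], coll[primary_id].labels,
                emb, coll[sid].labels)
        out["alignment"][variant] = scores
    if "independent" in result.embeddings:
        indep = result.embeddings["independent"]
        for variant in ("primary", "force"):
            if variant not in result.embeddings:
                continue
            loc = {}
            for sid, emb in result.embeddings[variant].items():
                n = emb.n
                res = locality_preservation(indep[sid], emb,
                                            k=min(k, n - 1))
                loc[sid] = {"mean": res.mean, "sd": res.sd}
            out["locality"][variant] = loc
    return out


def run_report(result: PipelineResult) -> dict:
    """JSON-serializable run report: config, references, fit quality,
    final per-type center distances, metrics."""
    cfg = result.config
    return {
        "config": {
            "perplexity": cfg.perplexity,
            "n_iter_early": cfg.n_iter_early,
            "n_iter_main": cfg.n_iter_main,
            "exaggeration_early": cfg.exaggeration_early,
            "lambda": cfg.lam,
            "learning_rate": cfg.learning_rate,
            "seed": cfg.seed,
            "init_std": cfg.init_std,
        },
        "primary_reference": result.primary_id,
        "secondary_references": list(result.secondary_ids),
        "procrustes_sse": {sid: t.sse for sid, t in result.transforms.items()},
        "force_distances": {
            sid: {"codes": st.codes, "d": [float(x) for x in st.d],
                  "sum_d": st.sum_d}
            for sid, st in result.force_states.items()},
        "center_sources": {str(c): s for c, s in result.centers.source.items()},
        "metrics": result.metrics,
    }
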