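# compound-embed

Soft alignment of t-SNE embeddings for multiple single-cell samples.

When several related single-cell datasets — patients, modalities, time
points — are visualized side by side, independent t-SNE runs place the
same cell types in unrelated positions, while data integration mixes
the samples so aggressively that each sample's own local structure
dissolves.  `compound-embed` takes a middle road: every sample keeps
its own embedding, computed from its own (unintegrated) PCA
representation, but the embeddings are pulled into a common frame

1. by a **scaled Procrustes transform** fitted on shared cell-type
   centroids in PCA space, which aligns each sample's embedding
   *initialization* to a primary reference without touching its
   neighborhood structure, and
2. by a **center-attraction force** added to the t-SNE optimization,
   minimizing

       L_total = L_tsne + λ Σᵢ dᵢ ,   dᵢ = ‖c_ref,i − c_sample,i‖² ,

   where the sum runs over the K cell types shared with the reference:
   each iteration alternates a t-SNE gradient step with a rigid
   translation of each type's cells by λ times its center offset.

Samples missing cell types are completed through a minimal chain of
secondary references.  Two metrics quantify the outcome: an
**alignment score** `1/(1+d)` on normalized cell-type centers, and
**locality preservation**, the per-cell fraction of k nearest neighbors
retained from the independent embedding.  Annotations can be derived
automatically (reference k-means + mutual-nearest-neighbor transfer)
when none exist.

See `docs/methods.md` for the model, defaults and limitations.

## Worked example

```python
import numpy as np
from compound_embed import (FixtureSpec, generate_multisample,
                            EmbedConfig, align_collection)

# three synthetic samples, 5 shared cell types, batch-distorted
collection, truth = generate_multisample(FixtureSpec(seed=0))

result = align_collection(collection, EmbedConfig(seed=0),
                          include_independent=True,
                          include_primary_variant=True)

print("primary reference:", result.primary_id)
for variant in ("independent", "primary", "force"):
    scores = result.metrics["alignment"][variant]
    print(f"alignment[{variant}] = {np.mean(list(scores.values())):.3f}")
for variant in ("primary", "force"):
    locs = result.metrics["locality"][variant]
    mean = np.mean([v["mean"] for k, v in locs.items()
                    if k != result.primary_id])
    print(f"locality[{variant}]  = {mean:.3f}")
```

Output (seed 0):

```
primary reference: sample_0
alignment[independent] = 0.365
alignment[primary] = 0.780
alignment[force] = 0.986
locality[primary]  = 0.578
locality[force]  = 0.539
```

Independent embeddings of the same cell types barely align (0.37);
aligning only the initializations already helps (0.78); the center
force brings the type centers nearly on top of each other (0.99) while
losing only a few percent of the neighborhoods preserved by the
initialization-only alignment (0.54 vs 0.58, both above the 0.5 mark
that separates preserved from reshuffled neighborhoods) — the
structure/alignment trade-off the method is built around.

## Command line

```
compound-embed simulate --preset default --seed 0 --out fixtures/
compound-embed align --input fixtures/sample_0.h5ad \
    --input fixtures/sample_1.h5ad --input fixtures/sample_2.h5ad \
    --annotation-key cell_type --lambda 0.1 --seed 0 \
    --also-independent --out out/
compound-embed metrics --independent out/ --aligned out/ --k 30 \
    --out metrics.json
```

`align` accepts `.h5ad` containers (PCA matrix in `obsm["X_pca"]`,
annotations in an `obs` column) or delimited matrices with a
`<stem>.labels.<ext>` sidecar, and writes per-sample embedding CSVs, a
centers table and a JSON run report (config, chosen references,
Procrustes residuals, final center distances, metrics).  Use
`--auto-annotate` when no annotations exist and `--reference` to force
the primary.

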