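# Methods

## Problem and approach

Visual comparison of several single-cell samples (patients, modalities,
time points) is awkward with independent t-SNE maps — each run has its
own arbitrary layout — while full data integration aligns samples at the
cost of dissolving the sample-specific local structure that independent
embeddings show.  This package implements a *soft alignment*: every
sample keeps its own embedding, but the embeddings are nudged into a
common frame in two stages.

1. **Primary alignment (PCA space).**  One sample is chosen as the
   primary reference — the one with the most unique cell types (ties:
   larger cell count, then input order), unless the user names one.
   For every other sample, the matrices of shared cell-type centroids
   (sample vs reference) are mean-centered and Frobenius-normalized,
   and the orthogonal rotation minimizing the residual sum of squares
   is obtained in closed form from the SVD of the cross-covariance
   (scaled Procrustes).  The resulting similarity transform
   (translation + uniform scale + rotation, reflections allowed by
   default because PCA component signs are arbitrary across samples) is
   applied to the sample's full PCA matrix.  Being a similarity, it
   changes within-sample distances only by a global factor, so t-SNE
   affinities — and therefore the embedding process proper — are
   unaffected; only the initialization moves.

2. **Center-attraction forces (embedding space).**  Each embedding is
   initialized from the first two components of the (transformed) PCA
   matrix, jointly rescaled so the first coordinate has standard
   deviation `init_std`.  The reference sample is embedded plainly and
   its per-type embedding centers recorded.  Every other sample then
   minimizes

       L_total = L_tsne + lambda * sum_i d_i,
       d_i = || c_ref,i - c_sample,i ||^2,

   where the sum runs over the K cell types shared with the reference
   center set.  The optimizer alternates one exact t-SNE gradient step
   with one *force step* that rigidly translates all cells of each
   shared type by `lambda` times the offset to the reference center.  A
   per-cell gradient of the penalty would point the same way (scaled by
   2/n_type); the translation form was chosen because it makes `lambda`
   directly interpretable: with the t-SNE forces frozen, each force
   step contracts every d_i by exactly (1 - lambda)^2, and `lambda = 0`
   reproduces the plain t-SNE trajectory bit for bit.  Because the step
   is a pure per-type translation it cannot distort within-type
   structure — that is what keeps the alignment "soft".

   Samples whose types are not all in the primary are handled by
   *secondary references*: the smallest set of additional samples that
   together cover all types (exhaustive set cover up to 12 candidate
   samples, greedy beyond).  Secondaries are force-aligned sequentially
   and each contributes embedding centers for the types still missing,
   after which all remaining samples are force-aligned against the
   complete center map.

## t-SNE engine

openTSNE-style batch APIs do not expose a per-iteration hook, and the
force step must interleave with individual gradient steps, so the
package carries a small exact t-SNE (`compound_embed.tsne`): Gaussian
affinities calibrated per point to the target perplexity by bisection
(64 iterations, tolerance 1e-5 in entropy), symmetrized and normalized;
Student-t kernel in the plane; gradient descent with per-parameter gains
(clipped at 0.01) and momentum 0.5 during early exaggeration, 0.8
afterwards.  Exact O(n^2) gradients are entirely adequate at the
desk scales this package targets (up to a few thousand cells per
sample) and make runs bit-reproducible given a seed in single-threaded
execution.

Defaults: perplexity 30, 250 early-exaggeration iterations at
exaggeration 12, 500 main iterations, learning rate `n / 12`,
`init_std = 1e-4`, `lambda = 0.1`.  The learning rate matters more than
usual here: `n / exaggeration` keeps the early phase in the regime where
the global arrangement inherited from the PCA initialization survives;
we verified that inflating it (e.g. to a floor of 50 at n = 300)
visibly scrambles cluster positions and destroys the benefit of the
primary alignment.  Forces are disabled during early exaggeration, which
is the phase that establishes cluster topology; they switch on for the
main phase.  Cells with a missing annotation (reserved code −1) are
embedded normally but excluded from all centroids and forces.

## Annotation fallback (k-means + MNN)

When samples arrive unannotated, matched cluster labels are derived:
the largest sample (or a user-named one) is k-means clustered in PCA
space (default k = 10, sklearn, deterministic given the seed), and for
each cluster the m = 20 cells nearest its centroid act as
representatives.  For every other sample, mutual nearest neighbors
(Euclidean, 15 neighbors each way) are computed between representatives
and that sample's cells.  Each cell incident to mutual pairs is seeded
with the cluster of its *nearest* mutual representative — a plain
majority over all incident pairs proved noticeably less reliable,
because distant spurious pairs vote too.  Clusters whose seed count is
below 25% of the best-seeded cluster are treated as absent from that
sample (this is what recognizes type dropout).  Remaining cells join the
nearest seeded-cluster centroid, and the assignment is polished by at
most ten Lloyd sweeps over the present clusters within the sample: the
seeds decide which reference cluster a blob corresponds to, the
within-sample geometry decides which cells form a blob.  These labels
exist only to drive alignment; they carry no biological identity.

Known limit: correspondence is purely geometric, so if a batch effect
displaces a cluster beyond half the distance to its neighbor, whole-
cluster mismatches become possible.  The synthetic study includes one
sample rotated by 0.7 rad — slightly beyond that limit for the 5-type
layout — and fallback accuracy on it occasionally drops to ~0.7 while
remaining ≥ 0.9 pooled over samples.

## Evaluation metrics

*Alignment score* between two samples: each embedding is normalized by
subtracting its grand centroid and dividing by the RMS cell distance
from it, then `d` = summed squared distances between shared-type centers
and the score is `1 / (1 + d)` (1 = centers coincide).  The
normalization removes each run's arbitrary origin and scale but
deliberately not its orientation — orientation is inherited from the
aligned initialization and is part of what alignment means here.

*Locality preservation*: per cell, the fraction of its k = 30 nearest
neighbors (self excluded, ties broken by cell index) in the sample's
independent embedding that are still among its k nearest neighbors in
the aligned embedding; reported per cell with mean and SD.  It is
invariant under any isometry plus uniform scaling of either embedding.

## Synthetic fixtures

Samples draw cells from one shared Gaussian mixture in PCA space (one
component per cell type, unit SD), then apply a per-sample planar
rotation in the first two components, a uniform scale, a random
translation, and isotropic noise (SD 0.3).  The default regime is 3
samples x 1000 cells, 5 types, P = 10, with type means on a regular
polygon in the PC1–2 plane (adjacent distance 6 SD) plus a per-type
offset of 3 SD on a higher component — leading components carry the
between-type structure, as in real PCA representations, so the
embedding initialization is informative.  Per-sample type dropout and
subsampling (`make_unbalanced_pair`, e.g. 1000 vs 100 cells) emulate
missing types and strongly unequal sample sizes.

What the generator does *not* emulate: count noise and library-size
variation (cells are Gaussian in PCA space, not sampled counts),
non-rigid batch effects, continuous trajectories or doublets, and
unbalanced type proportions.  Passing tests therefore demonstrate the
mechanics of the alignment under clean, separable geometry; they do not
certify performance on real data with overlapping types or nonlinear
batch distortions.

## Validation summary (what the study scripts compute)

On the default fixture over five seeds, mean alignment score rises
strictly from independent embeddings to aligned initializations to
force alignment, while locality preservation of the primary alignment
stays at or above the force variant and both remain well above 0.5 —
the structure/alignment trade-off.  Other checks: the closed-form
Procrustes fit beats 1000 random orthogonal candidates on every random
pair and matches a dense P = 2 angle grid to 1e-6; the lambda = 0 run
is element-wise identical to plain t-SNE; frozen force steps decay by
(1 - lambda)^(2j) to 1e-9 relative; the ordering survives 10x
subsampling of one sample and fallback-derived labels; dropout fixtures
yield a complete center map with a provably minimal secondary set.
Problem sizes used in the automated study: n = 1000 cells per sample
for embeddings, 100 random centroid pairs for the Procrustes check,
n = 20 instances for brute-force metric oracles.

## Degenerate inputs and numerical choices

Procrustes requires at least two shared types (rotation unidentifiable
at K = 1 → error) and warns on centroid matrices whose centered rank is
deficient beyond the structural K−1.  A zero-variance first PCA
component falls back to a seeded Gaussian initialization with a
warning.  Perplexity must be < n.  Affinities are floored at 1e-12;
orthogonality of fitted rotations is enforced to 1e-8.  Coordinates are
written with 17 significant digits and read back with round-trip float
parsing, so file round trips are bit-exact.
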