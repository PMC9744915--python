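# Methods

## Model

`lesiontrace` performs unsupervised domain adaptation for cell annotation.
The source domain is a labeled cells × genes matrix of primary-tumor (and
optionally blood) expression profiles on the log2(TPM+1) scale; the target
domain is an unlabeled matrix of circulating-tumor-cell profiles sharing an
unknown subset of the source classes. The working assumption is that cells
of the same semantic class form the mutually closest clusters across
domains in a learned embedding space, even under a systematic covariate
shift between measurements.

Two fully connected networks are learned jointly. The feature extractor is
four affine layers, n_genes → 1024 → 512 → 512 → embed_dim (200), with ReLU
between hidden layers and inverted dropout (rate 0.5) on hidden activations
during training. The stated architecture names four layers but only two
hidden widths; we read this as a repeated 512 before the output map and
keep every width configurable. The classifier maps embed_dim → 100 →
n_classes with one ReLU and returns raw scores. Weights are initialized
uniform with fan-in scaling from a fixed seed, so runs are exactly
reproducible.

## One training epoch

1. Both domains are embedded in evaluation mode and every embedding row is
   L2-normalized.
2. Source clusters come from the labels: one cluster per class, center =
   normalized mean embedding. The target is clustered by spherical k-means
   (cosine assignment, centers renormalized after every Lloyd update;
   greedy farthest-point seeding, 10 restarts, ≤300 iterations, relative
   tolerance 1e-4, empty clusters reseeded from the sample least similar to
   its center). The reported objective is the within-cluster pairwise
   squared deviation; the per-step history records the spherical criterion
   Σᵢ(1 − xᵢ·μ_{c(i)}), the quantity Lloyd provably never increases.
3. Cycle-consistent matching pairs cluster centers that are mutually
   nearest across domains by cosine similarity (ties to the lowest index).
   Each candidate pair (c,k) receives a domain consensus score: the source
   view Sˢ is the fraction of the pair's source samples whose most similar
   target center is k; the target view is symmetric; the pair score is
   their arithmetic mean. The target cluster count is optimized over a grid
   (default 2 … 2·|source classes|, restricted to k ≤ n_target) by the mean
   consensus score over matched pairs, ties to the smaller k. Infeasible k
   (degenerate data) are skipped. If no k yields a matched pair the epoch
   reuses the previous matching; after `patience` (20) consecutive failures
   the fit aborts with a diagnostic.
4. Cells in matched target clusters take the class of the paired source
   cluster as pseudo-label; unmatched clusters are "unassigned". All target
   cluster centers form the prototype bank M (unmatched rows are labeled
   "private").
5. d = max(1, n_target // batch_size) gradient steps follow. Each batch
   draws near-equal per-class counts from *all* source classes (the
   cross-entropy must see source-private classes) and from the
   pseudo-labeled target cells of the *shared* classes, plus up to 8
   unassigned target cells that enter only the regularizer (their cluster
   has a prototype even when private). The composite objective is
   l = l_ce + λ·l_cdd + γ·l_reg with λ = 0.1 and
   γ = exp(−ω·(i+(n−1)d)/(N·d)), ω = 3. l_ce and l_reg are batch *sums* as
   formulated, which couples their scale to the batch size (64). Updates
   use Adam (β₁ 0.9, β₂ 0.999; weight decay 5e-4 added to the gradient)
   with lr = initial_lr·(1+10·progress)^(−0.75), initial_lr 5e-5; the
   inductive pretraining mode sets the decay power to 10 to obtain a more
   general frozen model.

After the final epoch the clustering/matching step runs once more with the
fitted weights; those pseudo-labels and that prototype bank are the
reported estimates, consistent with what inference would produce.
Inference assigns each cell the class of its cosine-nearest prototype (no
clustering); the classifier softmax is returned alongside for scoring and
ROC analysis. Nearest-prototype and classifier-argmax calls are both
available; nearest-prototype is the default label.

## Loss terms

- **Cross-entropy** (source only): −Σᵢ log softmax(g(f(xᵢ)))_{yᵢ}, summed
  over the batch.
- **Contrastive domain discrepancy**: for classes c₁, c₂ the kernel mean
  embedding estimate D̂^{c₁c₂} = e₁ + e₂ − 2e₃ uses class-masked normalized
  kernel sums over source–source, target–target and source–target blocks;
  the loss is the mean intra-class D̂^{cc} minus the mean over ordered
  pairs c ≠ c′ of D̂^{cc′}. With a single shared class the inter mean is
  empty and defined as 0. Classes absent from either domain in a batch are
  dropped with a logged warning.
- **MMD estimator**: the biased three-double-sum form including diagonal
  terms. The kernel family is not pinned by the formulation; the default is
  Gaussian with the median heuristic — bandwidths {σ̂/2, σ̂, 2σ̂} where σ̂
  is the median pairwise distance of the joined batch, averaged over
  bandwidths. The bandwidth is treated as a constant of the batch (no
  gradient). A linear kernel is retained, for which MMD² = ‖μ_X − μ_Y‖²
  exactly (used as a closed-form check). The CDD is applied to the
  L2-normalized embedding layer by default; the classifier hidden layer can
  be added via `KernelSpec.layer_set`.
- **Prototype regularizer**: −Σᵢ log p̂_{(i,ŷᵢ)} with
  p̂_{(i,k)} = softmax_k(vᵢᵀμₖᵗ/τ), τ = 0.1, over L2-normalized target
  embeddings and the current prototype bank.

All losses run on the package's reverse-mode autodiff engine
(`_autodiff.Tensor`), whose gradients are validated against central finite
differences in the test suite; the losses accept plain arrays for
evaluation-only use.

## Synthetic data

The generator emulates exactly the structure the method assumes, not any
particular protocol. Each of `source_classes` lesion classes elevates a
disjoint block of `class_signature_size` marker genes by
`signature_strength` (default +4) above a per-gene baseline drawn once from
U(0.1, 2.0); cells add N(0, noise_sd²) noise on the log2 scale, clipped at
0. The target holds the first `common_classes` classes, displaced by one
domain-wide per-gene offset drawn N(0, shift_magnitude²) — the covariate
shift. Blood classes use marker blocks disjoint from all tumor signatures
and labels prefixed `blood:`. A `resample_seed` redraws cells from the same
population (baseline, signatures and shift are functions of `seed` only),
which is how held-out batches are made. CTC–WBC pseudo-aggregates de-log to
the linear TPM scale, mix one tumor and one WBC profile as
f·tumor + (1−f)·wbc, and re-log — physical aggregation sums transcripts,
not log values.

Defaults (500 genes; 6 source classes × 200 cells; 4 common target classes
× 50 cells; signature 20 genes; shift 1.0; noise 0.5; 3 blood classes)
define the standard desk-scale fixture used throughout the tests and the
acceptance script. What this fixture deliberately lacks: count noise
(dropout, library-size variation), batch structure within a domain,
overlapping class signatures, and class imbalance. Passing tests therefore
demonstrate the correctness and self-consistency of the machinery under
the method's own assumptions, not performance on real CTC data.

## Problem sizes and numerical choices

Benchmarks run the standard fixture with 100 training epochs for the
headline transductive run, 60 for the inductive comparison, 100 for the
background remover (its ROC score uses the classifier head, which is the
slowest part to converge at the small reference learning rate) and 40 for
the pseudo-aggregate scoring, whose nearest-prototype calls converge much
earlier; unit tests use a smaller 200-gene fixture with a narrower network
and a larger step size (1e-3), which converges in tens of epochs. On the
separable fixtures the pseudo-aggregate accuracy is near ceiling at every
tumor fraction, so the fraction trend appears as "non-decreasing with
ties" rather than the graded degradation expected on real mixtures.

Ties anywhere (nearest centers, k selection, argmax) break toward the
lowest index. Degenerate cases are errors, not silent results: zero rows
cannot be L2-normalized, empty clusters cannot be scored, k may not exceed
the sample count, τ must be positive. Targets with fewer than 30 cells
trigger a warning (transfer is less reliable there), not an error; the
few-cell test shows warm-started refinement still performs well on 5-cell
targets of the unit fixture.

## Other design choices

- Gene alignment uses the intersection of gene lists in source order;
  zero-filling missing genes would fabricate expression and distort cosine
  geometry. Below 30% overlap the reference is judged incompatible and
  alignment fails loudly.
- The marker test is the two-sided Wilcoxon rank-sum per gene, with logFC
  computed on linear means (pseudocount 1e-9); genes pass at raw p < 0.05
  and |logFC| > 4 (the filter is on the raw p exactly as specified;
  BH-adjusted values are reported alongside). The top 30 up-regulated
  markers feed a one-tailed hypergeometric over-representation test
  against user-supplied GMT gene sets filtered to 10–200 genes, BH
  adjustment plus a Storey-style q-value, significance at adjusted
  p < 0.05 and q < 0.2.
- 2-D diagnostics embed the raw matrix (before) and the classifier's
  penultimate activations (after) with t-SNE or UMAP at a fixed seed, and
  quantify domain distance as the squared MMD on the 2-D coordinates using
  the same estimator as the training objective.
- Checkpoints are single `.npz` archives holding all parameter tensors,
  the prototype bank, the class catalog, the gene list and both configs
  under a versioned schema id.

## Known limitations

- Pure-numpy training is single-threaded BLAS-bound; the reference-scale
  atlas (tens of thousands of cells) would be slow, though the desk-scale
  fixtures run in seconds to minutes.
- The consensus-based k selection scores only matched pairs, so a k whose
  single surviving pair scores highly can beat a k with many moderate
  pairs; the iterative refit corrects most such early mistakes, but a
  badly collapsed initial embedding can still mislead matching on very
  narrow networks.
- Enrichment q-values use a simple Storey π₀ estimate at λ = 0.5, which is
  conservative for small set collections.
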