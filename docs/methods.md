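# Methods

## The model

`mogic` integrates *paired* single-cell RNA-seq and ATAC-seq profiles — the
same physical cell measured in both assays — into one shared embedding by
cross-modality graph contrastive learning.

**Inputs.** An RNA count matrix and an ATAC gene-activity matrix over the
same cells (a raw peak-count matrix can be collapsed to gene activities by
summing peak counts over each gene body extended `promoter_upstream_bp`
(default 2000) upstream of the strand-aware TSS; coordinates are 0-based
half-open).

**Preprocessing.** Per modality: library-size normalization to
`target_sum` (default 1e4), log1p, highly-variable-feature selection by
variance of the log values (`n_hvg`, default 2000; a deliberately simple,
deterministic statistic rather than Seurat's mean-binned dispersion),
per-feature standardization with a population (n) denominator clipped at
±`scale_clip` (default 10), and exact-SVD PCA to `n_pca` = 30 dimensions
with a fixed sign convention (largest-|loading| entry of each component
positive).

**Graphs.** Within each modality a directed KNN graph (Euclidean distance
in PCA space, `k` = 20, ties broken toward the smaller index). Because a
fixed k reaches across type boundaries in small clusters, a fraction
`edge_drop_rate` (default 0.2) of *unidirectional* edges is removed at
random; mutual edges are always kept. The removal fraction is not fixed by
the published description ("a portion"), so it is exposed as a parameter.

**Encoder.** A three-layer GCN over the symmetrically normalized adjacency
Â = D^(−1/2) A D^(−1/2), where A is the 0/1 union-symmetrization of the
directed edges plus the identity (self-loops on by default; without them a
node's own features would be discarded after the first layer — a flag
disables them for the literal published form). Layers: H1 = ReLU(ÂXW0),
H2 = ReLU(ÂH1W1), H3 = ÂH2W2 (no activation on the last), hidden width
300, all layers bias-free. A two-layer projection head
Z = ReLU(H3·Wp1)·Wp2 maps to `out_dim` = 128 (the published head's output
width is unstated; 128 is a conventional contrastive-projector size). One
set of weights encodes both modalities (shared encoder). The MLP ablation
is the identical stack with Â = I.

**Objective.** The RNA-anchored InfoNCE loss over all N cells in one batch:

    L = −(1/N) Σ_i log [ exp(sim(z_i^R, z_i^A)/τ) / Σ_j exp(sim(z_i^R, z_j^A)/τ) ]

with cosine similarity and τ = 0.1; the ATAC-anchored symmetric average is
available but off by default (the published formula is one-directional).
The MSE ablation replaces the cross-entropy with
(softmax-diagonal − 1)² averaged over cells. Training is full-batch Adam
(lr 6e-4, betas 0.9/0.999), default 500 epochs with optional early
stopping (relative tolerance 1e-4); weights are Glorot-uniform,
deterministic given the seed. Forward, backward and Adam are implemented
in NumPy/SciPy (no deep-learning framework is required); the analytic
gradients are verified against central finite differences in the test
suite (relative error < 2e-7). Weights are float32, gradients accumulate
in float64; training is deterministic on a single thread.

**Embedding geometry.** The objective constrains only cosine directions, so
raw projector outputs carry arbitrary, modality-specific norms. `fit()`
therefore L2-normalizes Z_R and Z_A before any downstream step; all label
transfer and metrics operate on the unit sphere, where Euclidean and cosine
neighborhoods coincide. (`embed()` itself returns the raw forward pass.)

**Label transfer and evaluation.** Each ATAC cell takes the plurality label
of its `k_classify` = 30 nearest RNA cells in the joint embedding; ties go
to the single nearest neighbor. Metrics (conventions recorded in every
report): permutation-model ARI, NMI with arithmetic-mean normalization,
macro F1 (weighted optional), SUM = ARI + NMI + F1, batch entropy (base-2
neighborhood entropy of modality membership, `k_be` = 15, computed on the
joint embedding — never on the stochastic UMAP plane), Euclidean silhouette
with singleton clusters contributing 0, and signal loss = 1 − Pearson r
between two per-cell profiles of a feature. Signal loss is exposed as a
vector-vs-vector primitive only: the published construction ("original vs
integrated marker profiles") is ambiguous because integration yields
embeddings, not gene profiles, so the caller chooses the two vectors. UMAP
(n_neighbors = 30, fixed seed) is for figures only.

## The synthetic world

The generator emulates the paired-data premise: cell i in both matrices
derives from one latent state.

- Type labels are allocated by largest-remainder rounding of
  `type_proportions` (every type guaranteed ≥ 1 cell), then assigned by a
  seeded permutation. A single `default_rng(seed)` stream drives everything,
  so identical configs give bitwise-identical datasets.
- Per type: a unit-norm Gaussian centroid in `latent_dim` = 10 dimensions;
  per cell: centroid + isotropic Gaussian jitter (sd 0.1 per dimension).
- RNA mean = softplus(loading · latent), rescaled per cell to a library
  size of 2000 counts (≈10 counts/gene at 200 genes — generous relative to
  real data because the 200-gene world must carry in ~1% of the features
  the same decision-relevant signal); counts are negative-binomial via a
  gamma–Poisson mixture with shape r = 2 (variance μ + μ²/2, strongly
  overdispersed).
- Markers: `n_markers_per_type` = 10 genes per type get their loading row
  boosted by 3.0 × the type centroid, producing elevated means for the
  assigned type in both modalities (verified ≥ 95% of markers in tests).
- ATAC gene activity = log1p(RNA mean) + N(0, `atac_noise_sd` = 0.3),
  clipped at 0, then zeroed with probability `atac_dropout` = 0.02.

**Why dropout is small.** Real gene-activity matrices lose most entries to
dropout but spread their signal over ~20k genes; in a 200-gene world each
feature carries ~100× more of the per-cell information, so the *information
loss* of 30% dropout at 200 genes corresponds to a catastrophic, not a
typical, regime — it leaves the ATAC KNN graph unable to reflect cell types
(15-NN type accuracy ≈ 0.5), violating the method's own input premise.
The default therefore scales the per-feature rate down to 0.02, which keeps
ATAC-side structure recoverable (15-NN accuracy ≈ 0.89) while remaining a
genuine, modality-specific corruption.

**What a green test does and does not establish.** The generator produces
compact, convex, equally-noisy type clusters with no batch effects beyond
modality, no doublets, no trajectories, and marker signal that is perfectly
shared across modalities up to noise. Passing end-to-end tests therefore
establishes that the pipeline recovers a shared structure it is designed
for — not that it would rank well on real tissue atlases.

## Known behaviors and limitations

- **Within-pair cosine is not monotone for the GCN.** At initialization,
  three rounds of graph smoothing collapse all embeddings into a narrow
  cone (every pair's cosine ≈ 0.95, positive and negative alike). Training
  then widens the *alignment margin* — mean within-pair cosine minus mean
  cross-pair cosine, recorded per epoch as `trace.pair_margin` — from ≈0.18
  to ≈0.73, while the absolute within-pair cosine settles below its
  inflated start. The MLP ablation (no smoothing) shows the naive monotone
  increase. Judge alignment by the margin, not the raw diagonal.
- **Rare types below the classifier's k are unrecoverable by design.** With
  `k_classify` = 30, a class with fewer than ~k/2 cells in the reference
  modality cannot win the plurality vote against a contiguous majority
  cluster regardless of embedding quality. At 600 cells a 2% type has 12
  cells; its transfer accuracy is near zero. Recovering rare populations
  requires the dataset scale of the original application (2% of 10k = 200
  cells ≫ k) or a smaller k_classify.
- Exact KNN is computed chunk-wise with O(n·chunk) memory; no approximate
  index is provided, so beyond ~50k cells graph construction dominates
  runtime.
- CPU single-thread is the reproducibility contract; results are
  deterministic given (inputs, config, seed).
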