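# Methods

## Model

`momogp` implements a multi-output Gaussian-process latent variable model for
cell-by-feature matrices from one or more omics modalities measured on the
same cells.

For one view, let Y be the I x J matrix of log-normalized measurements.  Every
cell i carries a latent coordinate a_i in R^{r1} and every feature j a latent
coordinate b_j in R^{r2}; both are rows of plain embedding tables (lookup
layers) that are trained directly.  The observations are vectorized cell-major
through a triple store of records (i, j, y_ij), and the latent function value
f_ij for a grid entry has a zero-mean GP prior with separable covariance

    Cov(f_ij, f_i'j') = k_A(a_i, a_i') * k_B(b_j, b_j'),

i.e. the Kronecker product K_A (x) K_B over the vectorized grid, with

    k_A(a, a') = sigma_A^2 exp(-1/2 sum_r w_r (a_r - a'_r)^2)

an RBF kernel with automatic relevance determination (ARD) weights w_r, and
likewise k_B.  Observations are y_ij = f_ij + eps, eps ~ N(0, sigma^2) with
one noise variance per view.  Compared to a standard GP-LVM (which treats
features as independent outputs), the feature kernel gives the model an
explicit feature embedding: features with similar response profiles get
nearby coordinates, which is what makes metagene analysis possible.

In the multi-view model the cell embedding A is shared across views while
each view v keeps its own feature embedding, feature kernel, noise variance
and -- crucially -- its own ARD weight vector w_v on the *shared* cell
kernel.  This is manifold relevance determination (MRD): after training, a
dimension r with w_v^r above a small threshold delta in both views is shared,
above it in only one view private to that view, and below it everywhere
absent.

## Inference

Exact GP inference over the grid costs O((I J)^3).  We use sparse stochastic
variational inference with m inducing *pairs*: the u-th inducing point is a
pair (a_u, b_u) picked by fixed random cell/feature indices whose latents are
re-read from the embedding tables every step ("tied lookups").  Because
inducing points come in matched pairs, all required covariances collapse to
elementwise (Hadamard) products of two m x * kernel matrices; no Kronecker
product is ever materialized in training, and one epoch costs
O(|triples| m^2) -- linear in the number of observed entries.

The bound is the standard uncollapsed sparse-GP ELBO with a whitened
variational Gaussian q(u) = N(m_u, S S^T) (S lower-triangular):

    ELBO = (N/|B|) sum_{t in B} E_q[log N(y_t | mu_t, sigma^2)] - KL[q || N(0, I)],

optimized with Adam over embeddings, log-scale kernel parameters (variance,
ARD weights, noise) and the variational parameters.  All gradients are
derived analytically in reverse mode, including backprop through the Cholesky
factorization of K_uu; the test suite checks every gradient against central
finite differences and checks the bound itself against a dense Kronecker-GP
oracle on small grids.

Because the likelihood is Gaussian, the optimal q(u) for fixed embeddings and
hyperparameters is available in closed form.  `TrainConfig.analytic_q_every`
optionally interleaves this coordinate-ascent update into SGD; it ascends the
same ELBO and substantially accelerates convergence.  It is off by default so
that the plain-SGD trace is the reference behavior.

The ELBO surface of a GP-LVM is multi-modal.  The validation experiments
therefore fit a small number of random restarts (different init seeds) and
keep the run with the best full-batch ELBO -- model selection by the model's
own objective, never by ground truth.

## Defaults and parameters

| knob | default | meaning |
|---|---|---|
| r1, r2 | 2 | latent dims for cells / features (per view) |
| m | 64 | inducing pairs |
| embedding init | N(0, 0.1^2) | lookup-table initialization |
| kernel variance, ARD weights | 1.0 | initial values (log-parameterized) |
| noise variance | 0.1 | initial value, learned per view |
| learning rate | 1e-2 | Adam |
| batch size | 2048 | triples per minibatch |
| epochs | 200 | full passes over the triples |
| jitter | 1e-6 x kernel variance | added to K_uu diagonals; escalates to 1e-4 on Cholesky failure |
| delta | 0.05 x max weight | MRD threshold (relative; raw weights are unnormalized) |
| tau | 30 | relevance-link threshold, percent of a metagene's peak relevance |

Feature kernels default to a tied (isotropic) lengthscale because feature
latents have no a-priori preferred axes; per-dimension weights can be enabled
per view.

Indices are 0-based internally.  Inducing cell indices are drawn once and
shared by all views (mirroring the single shared A); feature indices are
drawn per view.  Individual inducing indices may repeat when m exceeds an
entity count -- only the (cell, feature) pairing must be matched -- and a
full-grid inducing constructor exists for exact-oracle comparisons on tiny
problems.

## MRD partitioning on the right scale

The kernel only ever sees w_r (a_r - a'_r)^2, so a latent dimension can
stretch while its raw weight shrinks: raw ARD weights are not comparable
across dimensions.  `effective_ard_weights` multiplies each view's weights by
the empirical variance of the cell embedding along each dimension --
equivalent to whitening the latent space to unit per-dimension variance --
and the partition of learned models is computed on these scale-adjusted
weights.  `partition_dimensions` itself is agnostic: it applies the
delta-rule to whatever weight vectors it is given.  Learned latent dimensions
are identifiable only up to permutation, so structure-recovery experiments
compare the multiset of dimension labels, not dimension indices.

## Interpretation machinery

Metagenes are Gaussian-mixture clusters of the feature embedding (component
count user-set or chosen by BIC over 2..15).  The relevance of a feature set
at a cell is the norm of the gradient of the GP posterior mean with respect
to that cell's latent coordinate, averaged over the set's features:

    rel(S, i) = mean_{j in S} || d mu_ij / d a_i ||_2 .

The gradient is analytic (the posterior mean is a weighted sum of RBF kernel
evaluations); a finite-difference oracle defines correctness in the tests.
Raw gradient norms carry a nonzero floor everywhere — the posterior mean
wiggles slightly even far from a set's active region — so scores are
background-subtracted at the per-set median over evaluated cells (values
below the median clip to zero) and then scaled so the peak is 100.  The link
threshold tau is therefore "tau% of the way from typical background to peak
relevance"; a degenerate all-equal column becomes all zero and links no
cells at any tau > 0.  The scale on which a relevance threshold lives is a
convention of this package, validated by the internal oracles and the
planted-marker pipeline experiments.
Cells above tau are summarized by their modal cell type (ties broken
lexicographically), and metagene/marker-set overlaps are tested with the
hypergeometric upper tail (over-representation analysis).

Two practical conditions govern how well gradient relevance localizes.
First, the GP prior has zero mean, so features should be centered before
fitting: a common positive baseline across features can only be explained as
between-cell correlation, which compresses the learned embedding and blurs
every relevance map.  Second, a feature set's predicted expression must
*change across* the cell group it characterizes — a group with uniformly
elevated but internally constant expression produces gradient only at its
boundary.  Graded within-group expression (the usual situation for real
marker programs) concentrates the gradient inside the group.  Localization
also improves with inducing capacity m, because the sparse bound's variance
penalty otherwise favors lengthscales so large that neighboring cell groups
stay correlated.

## Evaluation metrics

ACC clusters an embedding (GMM with full covariances by default, k = number
of cell types), assigns every cluster its modal true label -- independently
per cluster, so two clusters may predict the same label -- and reports the
percentage of correctly labeled entities.  ARI is the chance-adjusted Rand
index.  Features without a marker label enter as an explicit "unknown" class;
with a dominant "unknown" class ACC can be high while ARI is near zero, which
is why both are reported.

## Synthetic data

`simulate` is a forward sampler of exactly the generative model above: cell
latents from a mixture over scaled-simplex centers (center distance 2.0,
spread 0.15 x distance), per-view feature latents from block mixtures
(4 blocks in r2=3 by default, spread 2 x the cell spread, feature ARD weight
4.0), per-view 0/1 activity masks on the cell-kernel ARD weights (the ground
truth for shared/private structure), an exact Kronecker GP draw
(F = L_A Z L_B^T) for views up to 4000 cells/features and an inducing-pair
low-rank draw with diagonal residual correction above that, plus Gaussian
noise (variance 0.1).

Two generator regimes deserve comment, both fixed while designing the
generator:

* The feature side must be diverse.  With few, tight feature blocks the GP
  draws for all features are nearly collinear, and distinct cell clusters can
  map to nearly identical expression profiles -- clustering even the
  noiseless data fails.  The defaults above keep the recovery task solvable
  by any method that sees the information, while noise and cluster spread
  keep it non-trivial.
* For shared/private (MRD) fixtures the cell-latent dimensions must be
  statistically independent (`independent_dims=True`: each dimension an
  independent two-component mixture).  Under a single joint clustering every
  view can predict every latent dimension through the cluster identity, so
  "private" structure is not identifiable even in principle.

`make_marker_toy` plants per-type marker blocks (default 3 types x 8 markers
x 60 cells, effect +2.0, noise sd 0.3, plus 8 unstructured background
features) for end-to-end interpretation tests.

What the generator does *not* emulate: count distributions (negative
binomial, dropout), batch effects, per-cell depth variation, or
dataset-specific preprocessing.  Passing recovery tests therefore shows the
inference machinery is correct and well-calibrated for Gaussian,
model-generated data; it does not by itself certify performance on real
counts matrices.

## Validation experiment sizes

The canned experiments (`momogp.validation`, driven by
`scripts/acceptance.py`) use: 25 random instances for Kronecker/Hadamard
consistency; a 3x2 grid for bound tightness; 20x10 for trace monotonicity;
300 cells x 40 features, 3 clusters, 3 data seeds, best-of-3 restarts for
cluster recovery; 300 cells x 2 views x 50 features, 5 seeds for MRD
recovery; a 120-cell x 88-feature marker toy (2 planted types x 40 markers
plus 8 background features, m=88, features centered) for the interpretation
pipeline; and 2k/4k/8k
triples (fixed m=32, minibatch 512) for the timing slope.  These sizes keep
every experiment reproducible on a single CPU while leaving the conclusions
unchanged at larger scale.

## Known limitations

* Gaussian likelihood only; raw counts must be log-normalized upstream.
* Inducing latents are tied to randomly chosen entities; pathological draws
  (e.g. all inducing cells from one cluster) can slow convergence -- restarts
  mitigate this.
* MRD partitions depend on a threshold delta on continuous weights;
  borderline dimensions near delta are genuinely ambiguous.
* No priors on the embeddings (maximum-likelihood point estimates); a fully
  Bayesian treatment would change the KL structure.
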