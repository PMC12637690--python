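# Methods

## The adaptive-resampling weight ladder

Let `Z` be the `N x K` matrix of latent coordinates of the training set
under the current encoder. For each latent dimension `k` independently:

1. **Density.** A uniform-width histogram with `B` bins spans
   `[min(z_k), max(z_k)]` (`numpy.histogram` semantics: half-open bins,
   rightmost edge inclusive). Bin mass is `count / N`, so masses sum to 1
   per dimension. A constant dimension collapses to a single bin holding
   everything; such a dimension contributes a uniform score and is neutral
   under the max combiner.
2. **Smoothing and per-sample normalization.** Each sample's raw bin mass is
   smoothed by a constant `alpha` and normalized across samples:
   `p_s*(z_kn) = (p(z_kn) + alpha) / sum_i (p(z_ki) + alpha)`.
3. **Inversion.** `u_kn = 1 / p_s*(z_kn)`, row-normalized to `u*`: cells in
   sparse latent regions score high.

The final unnormalized weight of cell `n` is `w_n = max_k u*_kn` — a cell
counts as underrepresented if it is rare along *any* latent axis — and the
probability vector `w* = w / sum(w)` drives an `N`-sized with-replacement
redraw of the training multiset at the start of every epoch.

Because step 2 normalizes over samples, any constant factor on the raw
densities cancels; we normalize counts to masses anyway so that `alpha` has
the same meaning regardless of `N`. The histogram range is refit every
epoch since the latent space itself moves during training.

**Defaults and units.** `alpha = 1e-4` (dimensionless; bounds the dynamic
range of weights — as `alpha` grows, `w*` flattens toward uniform) and
`B = 50` bins per dimension (fine enough to separate modes at `N` in the
thousands, coarse enough that singleton bins do not dominate). Neither
value is critical; both are exposed everywhere.

**Which latent coordinates.** `TrainConfig.latent_mode` chooses between the
posterior mean (default) and a single stochastic draw `z ~ q(z|x)`. We
measured both at desk scale: with small models early in training the
posterior standard deviation is large relative to the separation between
populations, and a single draw injects enough noise into the per-dimension
histograms that weighting degenerates toward uniform (no paired benefit at
a 1% spike fraction). The posterior mean removes that sampling noise and
shows the full effect; the stochastic option remains for parity with the
resample-then-draw formulation.

**Frozen mode.** `compute_resampling_weights` accepts embeddings from any
source, so weights can be computed once from a frozen or pretrained encoder
and used to resample before training a downstream model (`scresample
weights` on the command line).

## The VAE

A compact NumPy implementation: dense encoder `D -> H -> 2K` (posterior
mean and log-variance), mirrored decoder, tanh hidden activation,
Glorot-uniform initialization, Adam. Gradients are closed-form and verified
against central finite differences in the test suite. Two observation
models:

* **Gaussian on log-normalized expression** (perturbation context): unit
  variance, so the reconstruction term is squared error plus the Gaussian
  constant.
* **Negative binomial on counts** (reconstruction context): the decoder's
  softmax gives per-gene proportions, the NB mean is the observed library
  size times those proportions, and a free gene-wise inverse-dispersion is
  learned jointly.

Defaults: `K = 64` latent dimensions in the library default (the usual
choice for this model family); desk-scale experiments in the experiment
layer use `K = 8`, `H = 64`. Dropout is not used — at these model sizes it
only adds run-to-run variance. `H=None` builds purely linear encoder and
decoder, used by the closed-form identity tests.

Training is for a fixed epoch count with no early stopping; the returned
model is the parameter snapshot with the best validation loss, where the
validation ELBO is evaluated at the posterior mean (no sampling) so that
model selection is deterministic. The library-default learning rate is
5e-5, matching the scale this model family typically trains at; the
desk-scale experiment configurations use 1e-3 so that runs converge within
tens of epochs at `N` of a few thousand.

Randomness is split into four independent streams — initialization, latent
sampling, resampling draws, minibatch shuffling — so an AR run and a
standard run can share initialization byte-identically and be compared as a
matched pair. `paired_run` trains such pairs across replicate seeds; the
two arms differ only in the epoch-start resampling block (asserted by a
test that stubs the redraw to identity and checks the arms' epoch multisets
coincide).

## Perturbation-response prediction

Latent vector arithmetic: the delta vector is the mean latent displacement
from control to perturbed training cells (pooled over all groups, encoded
at the posterior mean); a held-out control cell's prediction is
`decode(encode(x_c) + delta)`. The hold-one-group-out builder excludes the
held-out group's perturbed cells from training always, and includes exactly
`round(f * n_controls)` of its control cells for a requested inclusion
fraction `f`; the inference inputs (all of the group's control cells) are
identical across `f`. When `f > 0` the included controls are training cells
and therefore participate in delta estimation. A leakage assertion runs on
every split.

## Synthetic data

The count generator is gamma-Poisson: group drawn from specified
proportions, library size lognormal (`mu = log 2500`, `sigma = 0.35` —
a few thousand counts per cell with realistic spread), per-gene means =
library x normalized group profile, shared inverse-dispersion 2.0 (strong
overdispersion typical of UMI data; `inf` selects the Poisson limit).
Group profiles are a shared lognormal baseline with 5% of genes
up-regulated 4-fold per group (disjoint marker sets), giving controllable,
realistic separation.

* **Spike-in design**: a dominant base population plus rare groups at
  fractions 0–50% of a fixed total; a positive fraction that rounds to
  zero cells keeps one cell, so the rarest arm mirrors a
  one-cell-in-a-hundred-thousand mixture. Desk-scale default
  `total_n = 5000`.
* **Perturbation design**: every group emits control and perturbed cells;
  the perturbed profile is the control profile times
  `exp(shared_shift * group_modulation)` — an additive per-group response
  in log space.
* **Linear latent-shift design**: Gaussian clusters in a generative latent
  space mapped linearly to genes, with the perturbation an exact additive
  latent shift. This is the ground truth for delta-arithmetic recovery
  tests, since there the arithmetic is exactly correct by construction.

What these generators do *not* emulate: batch effects, doublets, ambient
RNA, and real gene-gene correlation structure. Passing tests therefore
demonstrate the resampling mathematics, the pairing methodology and the
directional behavior of AR under controlled imbalance — not performance on
any real atlas.

## Evaluation

* Reconstruction: per-cell Pearson r between log-normalized truth and the
  decoded expectation scaled to a 10,000-count library (log1p), averaged
  over cells; zero-variance cells are excluded with a logged count.
* Classification: seeded 50/50 split of embeddings, k = 5 Euclidean kNN,
  accuracy/precision/recall/micro/macro F1 (macro treats classes absent
  from the training half as F1 = 0, with a warning).
* DEGs: per-gene two-sided Wilcoxon rank-sum, p ascending, ties broken by
  absolute mean difference descending; top 100 by default.
* Perturbation: R² (squared Pearson) and MSE on per-gene *mean* profiles,
  over all genes and over DEGs; cosine similarity per predicted cell
  against the true mean perturbed profile, reported as a distribution.
  Mean-profile MSE (rather than per-cell) keeps the three metrics on the
  same averaged-expression object.
* Embedding structure: adjusted Rand index of 2-cluster K-means (10 seeded
  restarts) against control/perturbed labels.
* Arm comparison: two-sided Welch t-tests, stars at 0.05 / 0.01 / 0.001 /
  0.0001. Welch rather than pooled-variance because equal variances across
  arms is not something we want to assume.

## Numerical choices and degenerate inputs

* Weight ladder: all-equal latent values per dimension give a single bin
  and a uniform contribution; a zero per-sample probability (possible only
  at `alpha = 0` with an impossible empty-but-occupied bin) raises rather
  than producing infinities; resampling validates that weights sum to 1
  within 1e-9.
* NB likelihood: the mean is floored at 1e-10 before logs; dispersion is
  parameterized on the log scale.
* Adam decays weights only (not biases or dispersion) when weight decay is
  enabled.
* Ties in K-means and kNN follow scikit-learn's deterministic seeded
  behavior.

## Problem sizes

Desk-scale defaults used by the experiment layer and the acceptance
script: spike-in `total_n = 5000`, `D = 200` genes, `K = 8`, `H = 64`,
30 epochs, 5 paired seeds; rarity enrichment `N = 2000` cells at a 95/5
split, 40 epochs; perturbation `N = 3000`, 40–100 epochs. These sizes show
the paper-scale phenomena reliably while keeping full runs in minutes on
one CPU.

## Known limitations

* The VAE is deliberately minimal: no batch covariates, no size-factor
  inference variants, no dropout layers, single hidden layer. It is the
  context in which AR is demonstrated, not a replacement for full-featured
  single-cell VAEs.
* Directional AR benefits are stochastic properties over paired seeds, not
  guaranteed per-seed outcomes; at spike fractions near zero there is
  nothing for AR to upweight and the arms coincide.
* Histogram density estimation is per-dimension by design; jointly
  multivariate rarity (rare only as a combination of dimensions) is
  invisible to the max combiner.
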