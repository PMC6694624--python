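# Methods

## Model

The package implements a hybrid of denoising autoencoders and generalized
matrix factorization for implicit-feedback association prediction.

**Inputs.** A binary association matrix `R ∈ {0,1}^{m×n}` and two
similarity matrices `DrugSim ∈ [0,1]^{m×m}`, `DiseaseSim ∈ [0,1]^{n×n}`,
assumed symmetric with unit diagonal (asymmetric inputs are symmetrized as
`(S+Sᵀ)/2` with a warning rather than rejected, since both similarity
sources are nominally symmetric and small asymmetries are usually format
artifacts).

**Hidden features.** One single-layer "additional" autoencoder per entity
side. The drug encoder maps a corrupted interaction profile (length n) and
a corrupted similarity vector (length m) to a k-dimensional hidden
feature and decodes both back against their *clean* versions. The squared
reconstruction errors are balanced by α (drug side) / β (disease side);
weight matrices (never biases) carry an L2 penalty λ / δ. Corruption is
masking noise at level 0.3 by default — each coordinate zeroed
independently, survivors *not* rescaled, because the decoder targets are
the clean vectors; Gaussian corruption is available as an option. The
corruption pattern is resampled every epoch (denoising-autoencoder
convention); `CorruptionSpec(kind="none")` gives deterministic training
for tests.

**Predictor.** `r̂_ij = F_out(hᵀ(z_i ⊙ z_j))` with sigmoid `F_out`, scored
by binary cross-entropy with scores clipped to `[1e-12, 1-1e-12]`. The
per-pair log-likelihood is *negated* into a proper loss so that
minimization drives `r̂ → r`. There is no output bias, and the perceptron
is deliberately single-layer.

**Joint objective.** Per training pair (positive or sampled negative):
prediction cross-entropy plus φ times the drug's reconstruction loss plus
ψ times the disease's (φ = ψ = 0.5). Reconstruction terms are evaluated
once per pair occurrence, so frequently interacting entities are
reconstructed proportionally more often — the literal reading of the sum
over `R⁺ ∪ R⁻`.

**Negative sampling.** Each epoch draws `N × |R⁺|` distinct unobserved
cells uniformly (default N = 10), resampled per epoch. A negative is
asserted never to collide with a training positive, every epoch. If fewer
unobserved cells exist than requested, all are used with a warning.

## Optimization

Plain mini-batch SGD, all parameters updated jointly from hand-derived
analytic gradients (verified against central finite differences to
relative error ≤ 1e-4 in the test suite). Updates use the batch-mean
gradient of the summed objective, which makes the learning rate
insensitive to batch size; the reported loss is the literal sum so the
decomposition identity `total = pred + φ·drug + ψ·disease` can be checked
exactly on every batch.

Defaults: α = 0.7, β = 0.3, λ = 0.001, δ = 0.01, k = 128, N = 10, masking
level 0.3 — the validated configuration for this model family. Optimizer
defaults were chosen by convergence behaviour on planted data:

* **Encoder activation g = tanh** (decoders stay sigmoid, matching binary
  profiles and [0,1] similarities). With sigmoid hidden units the
  elementwise-product predictor is nearly inexpressive — all features are
  positive with small spread, and plain SGD needed hundreds of epochs to
  reach even training AUC 0.75. Zero-centered signed features restore the
  bilinear character of matrix factorization; the same budget then reaches
  validation AUC ≈ 0.88. Activations remain configurable.
* **lr = 0.3, batch 64, up to 100 epochs** with early stopping on
  validation AUC (patience 10). The validation set holds out one
  association per drug with ≥ 2 training positives (single-positive drugs
  are never touched, so cold-start experiments stay intact).
* Weight init is Glorot-uniform `±√(6/(fan_in+fan_out))`, biases zero,
  fully seeded. All randomness (init / corruption / negative sampling /
  shuffling / splits) flows from one seed through independent named
  streams, so two fits with the same seed are bit-identical.

Divergence (non-finite loss) aborts with a diagnostic rather than
returning garbage.

## Evaluation

* **AUC** by threshold sweep over the pooled test-positive and candidate
  scores (ties contribute ½; equivalent to the Mann–Whitney rank
  statistic — the suite checks this equivalence exhaustively).
* **AUPR** by non-interpolated step summation `Σ (R_i − R_{i−1}) P_i`.
  The step convention matters for small candidate pools and is therefore
  fixed and documented.
* **HR@n** ranks each test positive against the *candidate pairs of its
  own drug*, with pessimistic tie-breaking (tied candidates rank above
  the positive), so constant-score models earn no hits. A global-pool
  variant is available via `per_drug=False`.
* **Ten-fold CV** partitions verified associations into near-equal folds
  (sizes differ ≤ 1, by pair rather than by drug); every unverified pair
  joins each fold's test set as a candidate. The model is retrained from
  scratch per fold on a matrix with that fold's positives zeroed, so
  held-out positives remain eligible negative samples — consistent with
  their candidate status.
* **New-drug (cold-start) protocol** holds out the unique association of
  every single-association drug.

CV reports both per-fold means ± sd and per-fold values, since pooled and
averaged AUC can differ.

## Synthetic data

The generator plants rank-`k_true` structure: standard-normal factors
`U (m×k)`, `V (n×k)`, logits `UVᵀ` plus Gaussian observation noise
(sd 0.1 by default), shifted by a bisection-found constant so the mean of
the logistic link equals the target density, then Bernoulli-sampled
(default) or top-cell thresholded. Similarities are the row-cosine of the
same factors mapped affinely to [0,1], mixed with symmetric uniform noise
by `sim_signal`, diagonal forced to 1. The logistic link keeps the planted
model inside the family the predictor can represent, which is what makes
parameter-recovery experiments meaningful; with the default settings the
Bayes-optimal held-out AUC (scoring with the true probability matrix) is
≈ 0.94, so the model's ≈ 0.87–0.89 indicates substantial but not total
recovery.

Default shape (m = 200, n = 100, k_true = 8, density 0.05, sim_signal
0.8) is the desk-scale benchmark used throughout the tests and the
acceptance script; the published benchmark shapes (593×313 at ~1% density,
409×663 at ~0.9%) can be generated by passing those dimensions.

What the generator does *not* emulate: chemical structure (similarities
are not Tanimoto scores over real fingerprints), the long-tailed degree
distribution of real drug–disease data, or any disease ontology
structure. Passing the recovery tests shows the estimator works when its
assumptions hold — it does not certify performance on real pharmacological
data.

## Numerical choices

* Scores clipped at 1e-12 before logs; stable two-branch sigmoid.
* Similarity symmetry tolerance 1e-8; association entries must be exactly
  0 or 1.
* TSV round-trips use `repr` formatting and round-trip float parsing, so
  save → load is bit-exact.
* Ties in all ranking metrics are handled explicitly (½ credit in
  AUC/AUPR sweeps, pessimistic in HR).
* The GMF baseline freezes the similarity weight matrices at zero and
  drops the similarity reconstruction term (equivalent to α = β = 1);
  everything else, including seeding, is shared with the full model.

## Known limitations

* Plain SGD is sensitive to the learning rate; lr ≳ 1 with tanh encoders
  can diverge (caught and reported). No momentum/Adam by design.
* Hit-ratio pools require each test drug to have candidate pairs; a drug
  with a fully verified row contributes a guaranteed hit.
* Dense numpy matrices throughout: fine for the benchmark shapes
  (~600×700), not intended for corpus-scale (10⁵+) catalogs.
* The cold-start protocol evaluates drugs with exactly one association;
  drugs with zero associations have no test signal and are out of scope.
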