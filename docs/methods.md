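# Methods

## Model and losses

Molecular activity is modeled on the pChEMBL scale,
y = −log10(molar potency); conversions accept nanomolar inputs
(y = −log10(x·10⁻⁹)).  The cliff between two compounds is the L1
distance |y_i − y_j|, the nanomolar fold change is 10^cliff, and both
are pure functions validated on their closed forms (10-fold per unit,
100-fold per two units).

The ACA (activity-cliff awareness) loss couples a regression term with
a triplet contrastive term in the encoder's latent space:

* plain form: `L = L_mae + α · L_tsm`, with
  `L_tsm = (1/M′) Σ_j [d(A_j,P_j) − d(A_j,N_j) + m_j]₊`, latent
  distances in the Euclidean norm (a general p ≥ 1 is configurable for
  this term only) and the per-triplet soft margin
  `m_j = |y_A − y_N| − |y_A − y_P|`;
* squared form: `L = L_mse + α · L_tsm²`, with squared Euclidean
  distances and squared margins `m² = |y_A−y_N|² − |y_A−y_P|²`, so the
  contrastive term carries the same squared-label units as the MSE.

Defaults follow the loss's tunable-parameter conventions: α = 0.1,
cl = cu = 1.0 (the single-cut-off setting that maximizes the number of
mined triplets), squared off, p = 2.  The hinge subgradient at zero is
zero; when no triplet is mined, or none is violated, the contrastive
term is exactly zero, and at α = 0 the loss is bit-identical to the
regression loss.  Averaging divides by M′ (the violated count), not M:
the count of satisfied triplets should not dilute the penalty.

For matched-molecular-pair cliff classification the contrastive term
is a paired loss `Σ y(1 + sim) + (1 − y)(1 − sim)` with cosine
similarity — each pair contributes a value in [0, 2], zero-attaining
at sim = ∓1 — added to a binary cross-entropy on a single logit with
the same α weighting.  Cosine was chosen because the 1 ± sim form is
bounded and zero-attaining only for a bounded similarity, and it
matches the metric of the label-incoherence analysis.  The printed
form sums over pairs; a mean reduction is available and recorded by
callers.  Pairs are labeled cliff iff ΔpKi ≥ 2 and non-cliff iff
ΔpKi ≤ 1 (both inclusive); values strictly between carry no label and
are excluded from training and evaluation, because only the two end
bands are defined.

## Online triplet mining

Mining is batch-all and anchor-centric: every ordered triple of
distinct in-batch indices with |y_A − y_P| ≤ cl and |y_A − y_N| > cu
is enumerated in lexicographic order (no subsampling), so the mined
count M and the violated count M′ are deterministic and reproducible —
a requirement for using M′ trajectories as a training diagnostic.
(A, P, N) and (P, A, N) are distinct triplets when both qualify.
Mining operates on ground-truth labels only; the latents enter only in
flagging which triplets are currently violated.  Cut-offs must satisfy
cl ≤ cu; when cl < cu every margin is strictly positive and bounded
below by cu − cl.  The implementation is vectorized over pairwise
label differences and is checked in the tests against an exhaustive
triple-loop reference for exact set-and-margin equality; the loss
computes each unique pair distance once and gathers, so cost scales
with batch² rather than with M.

## Encoders

Four message-passing backbones share one architecture: convolution
channels (64, 128, 256, 512) with batch normalization after each layer
(no dropout by default), ReLU activations, a global-max-pool (GMP)
readout selecting the per-channel maximum over a molecule's atoms, and
a pyramid dense head (256, 128, 32) ending in a linear output neuron.
The molecule latent f used by the TSM loss is the GMP output — its
width always equals the last convolution channel, never a head width,
and this extraction point is asserted structurally in the tests.

* **GCN**: mean aggregation over the neighborhood including the node
  itself; ignores bond features.
* **GIN**: sum aggregation with a trainable ε and a two-layer update
  network (hidden width = output width); bond features enter through a
  learned additive projection.
* **GAT**: 4 attention heads (head count is a package choice), scores
  from learned source/destination/edge projections with LeakyReLU(0.2),
  per-destination softmax, head outputs averaged.
* **PNA** (default): messages ReLU(W[x_src ‖ e]) aggregated with
  {mean, min, max, sum, std} and rescaled by the {identity,
  amplification, attenuation} degree scalers; the normalizer δ is the
  mean log-degree of the training data, frozen before training.

GAT and PNA receive self-loop edges with zero bond features so
single-atom molecules still aggregate; attenuation at degree zero is
defined as zero.  Activation, GAT head count and the GIN update width
are not dictated by the loss design; the defaults above are recorded
in `EncoderConfig`.

Molecules are featurized as heavy-atom graphs (implicit hydrogens,
largest fragment kept, SMILES canonicalized first so any dialect of
the same structure yields bit-identical arrays): 39 atom features
(15-element vocabulary + other, degree 0–5, formal charge −2…+2,
hybridization, aromaticity, ring membership, total H count 0–3) and
10 bond features (type, conjugation, ring membership, stereo), with
out-of-range ordinals clamped and unknown categories mapped to "other"
slots so the dimensionality never varies.  The exact column names are
exported as JSON (`write_feature_descriptor`) for provenance, and the
scheme is a named constant so it can be swapped wholesale.

The neural layer runs on a small in-package reverse-mode autodiff
engine over float64 NumPy arrays (`cliffaware.nn.tensor`): elementwise
ops, matmul, reductions, gathers with scatter-add adjoints, and
segment reductions for message passing and pooling.  Non-smooth points
use conventional subgradients (hinge and `sqrt` at 0 → 0; segment-max
ties route gradient to every attaining element, a measure-zero event
for learned features).  Model state snapshots include batch-norm
running statistics, so an early-stopping restore reproduces evaluation
outputs exactly.

## Training protocol

Each batch: forward → mine triplets on the batch labels → ACA loss →
Adam step (Adam is the package's optimizer choice; the reference
learning rate is 1e-4 with batch size 128 and up to 800 epochs).  The
last incomplete batch is kept — mining simply sees fewer candidates —
and batch size must be ≥ 3.  Per epoch the history records the
regression and contrastive terms, M and M′ on the training batches,
and RMSE plus M/M′ on the validation and test sets, the latter
computed on evaluation batches of the same batch size so counts are
comparable with the training curves.  Early stopping monitors the
validation ACA loss (or RMSE) with a default patience of 50 epochs and
restores the best epoch's parameters.  Seeds control parameter
initialization, fold assignment and batch shuffling; two runs with the
same seeds are bit-identical.

Cross-validation stratifies the continuous label by rank-binning into
10 quantile bins (configurable) and dealing each bin's shuffled
members cyclically across folds, so fold sizes differ by at most one
within every bin; n_folds = n degenerates to leave-one-out.

The hyperparameter search is T-shaped: with α at its 0.1 default,
phase 1 fixes cl = 0.1 and sweeps cu ∈ {0.5, 1.0, …, 4.0} (8
candidates); phase 2 fixes the best cu and sweeps cl over 8 equally
spaced values from 0.1 to that cu, endpoints included; phase 3 sweeps
α ∈ {0, 0.01, 0.05, 0.1, 0.2, 0.5, 1} (7 candidates).  Candidates are
scored by mean cross-validated validation RMSE by default, the scorer
is injectable for cheap surrogates, invalid candidates (cl > cu) are
skipped with a logged row, and the full 23-row table is returned for
audit.  Nested-CV prediction trains one sub-model per fold with early
stopping on its validation fold and averages the five sub-model
predictions on the held-out test set.

## Label Incoherence Index

For each embedded point, take the k nearest neighbors under cosine
distance (self excluded; ties broken deterministically by lower
index), average the absolute label differences, then average over
points.  Default k = 5 — a small neighborhood matching the metric's
local intent; k is configurable and must satisfy k < n.  The LII is
invariant to positive rescaling of embedding rows and to label shifts,
and is checked against an O(n²) reference implementation.  Zero-norm
rows are rejected (cosine undefined).

## Synthetic data

The generator emulates narrow-scaffold lead-optimization series: a
built-in library of aromatic cores is decorated with one or two
substituents from a fixed fragment library via explicit bond
attachment in RDKit, deduplicated by canonical SMILES.  Labels follow
a rule, not simulated physics: family base activity ~ U(5, 9) pChEMBL,
plus ±cliff_magnitude (default 2.0) for analogs carrying an
"activity-switching" substituent, plus N(0, noise_sd) (default 0.1).
Each substituent switches activity in a given family with probability
cliff_fraction (default 0.2); tying cliffs to substituents makes them
a *learnable* structure–activity relationship — randomly assigned
cliff labels would be irreducible noise that no model could predict,
which would make any train-vs-control comparison meaningless.  Every
(ordinary, cliff) pair within a family is recorded with its realized
label gap, so mined counts and MMP labels can be checked against
ground truth exactly.

What the generator does not emulate: realistic potency landscapes,
scaffold hops, assay artifacts, censored measurements, or activity
differences that depend on substitution position.  Tests passing on
this data show that the mining, losses, metrics and training machinery
behave as designed under controlled label structure — not that the
encoder generalizes on real SAR data.

The embedding fixture for metric tests generates
f = alignment·y·u + (1 − alignment)·noise with noise scaled to the
label spread; at alignment 1 in one dimension it reproduces the exact
zero-loss geometry of the TSM loss.  In two or more dimensions an
alignment-weighted constant anchor occupies the second coordinate so
the label also controls the vector's direction: a purely collinear
embedding carries no cosine neighborhood structure, and the anchor
makes the LII decrease monotonically with alignment, which is the
behavior the analyses rely on.

## The paired AC-awareness experiment

`run_ac_awareness_comparison` trains the same model with α = 1 and
α = 0 (cl = cu = 1) under identical conditions, paired over seeds, and
reads out (a) the training-set M′ trajectory and (b) the best
validation RMSE.  The fixed desk-scale conditions: the default
synthetic dataset (5 families × 40 analogs, 200 molecules), a 6:2:2
train/validation/test split, a GCN with channels (16, 32) and head
(16, 8), batch size 32, learning rate 2e-3, 100 epochs, best epoch by
validation RMSE.  Batch size and learning rate are sized so both arms
converge within the 100-epoch schedule at this dataset scale.  The
expected readout — reproduced by the acceptance tests and
`scripts/acceptance.py` — is a large relative M′ decay in the aware
arm (roughly half) against a flat control, and a lower mean validation
RMSE in the aware arm (one-sided paired t-test).

## Known limitations

* The AC-awareness RMSE benefit on the synthetic task lives in the
  semi-converged regime: with many more optimization steps both arms
  saturate the simple substituent rule and the gap closes or reverses.
  On the synthetic task the effect size is modest and a few seeds can
  favor the control arm individually.
* Whole-molecule encoding stands in for core/substituent
  decomposition in pair classification; pre-decomposed fragments can
  be supplied as additional molecules, but no decomposition algorithm
  is bundled.
* The engine is CPU/NumPy: fine at desk scale (hundreds of molecules,
  tens of channels), not intended for large-scale training.
* Censored potencies (">10000 nM"), replicate aggregation, 3D
  conformers and protonation states are out of scope.
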