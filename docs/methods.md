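# Methods

## Model and training procedure

`dbnexpr` classifies expression profiles x ∈ R^m (log2-scale intensities,
m genes) with multilayer logistic networks trained in two phases.

**Pretraining.** Each hidden layer is initialized by a binary-unit RBM with
energy E(v, h) = −aᵀv − bᵀh − vᵀWh. Training uses CD-k (default k = 1):
positive statistics ⟨v h⟩ come from a data mini-batch and its hidden
conditional probabilities; negative statistics from k alternating Gibbs
steps. Hidden states are sampled binary at every Gibbs step, while visible
reconstructions and the final hidden layer are kept as probabilities — the
usual variance-reduction choice for CD. The update applies learning rate,
momentum and an L2 weight-cost (weights only). Stacking is bottom-up:
RBM r > 1 trains on the hidden probabilities of RBM r − 1.

Because binary RBMs expect inputs in [0, 1], expression values are min-max
scaled per gene; the scaling is fit on training data only and stored with
every model container so held-out data are scaled identically.

**Fine-tuning.** The stack is unrolled into a^(l) = σ(w^(l)a^(l−1) + b^(l))
with a freshly initialized output layer (N(0, 0.01), zero biases). Reported
training error is E = (1/n) Σ‖o − t‖²; the optimized objective is
(1/2) Σ‖o − t‖², whose per-output derivative is exactly (a − t). (The two
differ by a constant factor that only rescales the gradient; using the
(a − t) convention keeps the backpropagation equations in their simplest
form and is absorbed by the learning rate.) Two optimizers:

- **Bprop**: mini-batch SGD,
  θ ← θ − η·g − λ·θ + ν·Δθ(t−1), with Δθ(t−1) the previous realized
  parameter change (classical momentum), λ applied to weights only, and a
  momentum schedule that switches from 0.5 to 0.9 after epoch 50.
- **Rprop (iRprop+)**: full-batch, sign-based per-parameter step sizes with
  weight backtracking; constants η⁺ = 1.2, η⁻ = 0.5, Δ₀ = 0.1,
  Δ_min = 1e−6, Δ_max = 50 (the standard values from the algorithm's
  literature). Only the iRprop+ variant is provided; the other resilient
  variants are rejected with a clear message. Sign-based updates degrade on
  mini-batches, hence one full-batch step per epoch.

**Weight-cost under Rprop.** A sign-based optimizer ignores gradient
magnitudes, so the −λθ term cannot be applied as a bare multiplicative
shrink: empirically that drives all weights to the step-size floor and
destroys the classifier. Instead λ enters through the penalized objective
E + (λ/2)‖w‖² (gradient g + λw, weights only; the backtracking comparison
uses the penalized error). This preserves the discriminative direction
while shrinking ‖w‖ — the behavior one actually observes when strong decay
*improves* shallow-network test accuracy. For Bprop the update keeps the
literal −λθ form.

**Other regularization.** Optional weight normalization rescales every
weight-matrix column to unit L2 norm after each epoch's updates (zero
columns are left untouched); it is idempotent. Early stopping is a fixed
epoch cutoff (the protocol that proved useful at ~90 epochs on real data);
an optional patience-based monitor stop exists but is off by default.

**Output encodings.** Binary tasks use either a single output node with
targets {0, 1} (prediction = rounded output) or two nodes with softened
targets {p, 1 − p}, default p = 0.9 (prediction = argmax, ties to the
lowest index). Three-class tasks extend the two-node scheme to softened
one-hot vectors with one node per class. Architecture strings like
"A-500-100-1" name the layers, "A" standing for the input dimension.

**Autoencoders** unfold the pretrained stack symmetrically; decoder
weights start as transposed encoder weights with the RBMs' visible biases
and are untied during fine-tuning (classic unfolding). Reconstruction
targets are the scaled inputs; the logistic output matches their [0, 1]
range. **Hybrid classifiers** feed a chosen representation — the last DBN
hidden layer by default, the code layer for autoencoders, chained RBM
hidden probabilities for raw stacks, or the identity (passthrough) — into
scikit-learn's LIBSVM-backed SVC (linear or RBF; defaults C = 1,
γ = 1/n_features, with a small grid-search helper). The passthrough
hybrid is provably identical to a plain SVM, which the tests exploit as a
reduction law.

## Evaluation protocol

Stratified k-fold cross-validation (each class dealt round-robin across
folds, so fold sizes differ by at most one and per-class proportions are
preserved to integer resolution). Per fold: optional undersampling of the
training portion to the smallest class size (test folds keep their natural
balance, since evaluation should reflect deployment), top-variance feature
selection fit on training folds only (a `selection_scope: global` switch
exists for comparison), min-max scaling fit on training folds, full
retraining of the learner, prediction on the untouched held-out fold.
Metrics: Acc, TPR, TNR, E from the contingency table; Acc + E = 1 exactly.
Undefined ratios (empty denominator) are reported as undefined, never 0.
Aggregates are the arithmetic mean over folds and the standard error
sd/√k. Three-class tasks report overall accuracy (one-vs-rest confusion
counts are available via `confusion` directly). All randomness fans out
from one seed through `numpy.random.SeedSequence`, making every report
bit-for-bit reproducible.

## Synthetic data

The generator emulates a log-scale microarray matrix: gene baselines
μ_g ~ N(8, 2) (log2 units), class-specific shifts of +δ on disjoint
differential gene sets, i.i.d. Gaussian noise N(0, σ). Defaults — two
classes of 100 samples, 2000 genes, 50 differential genes per class,
δ = 1.0, σ = 1.0 — describe a learnable but non-trivial design; imbalanced
presets (209/77 binary, 59/42/26 three-class) mirror typical clinical
cohort shapes. An optional shared-factor equicorrelation within the
differential blocks is off by default.

What the generator deliberately omits: probe effects, batch effects,
intensity-dependent variance, heavy-tailed noise and realistic gene–gene
correlation structure. Passing tests on these fixtures therefore
demonstrate correctness of the algorithms and protocol, not expected
accuracy on real cohorts.

## Problem sizes used by the test suite and acceptance script

Gradient checks use ≥ 20 random networks with layer sizes in {2..5} and
central finite differences (step 1e−5, relative tolerance 1e−6 against the
implemented batch objective, deviations measured relative to
max(1, |gradient|)). Exact RBM likelihood uses a 3-visible/2-hidden
machine, tractable by full 2⁵-state enumeration, with an independently
written brute-force enumeration cross-checking the package's own. The
expected first CD step at zero parameters is compared over 10 000 seeded
updates against the exhaustively enumerated expectation. Recovery runs use
the generator defaults (200 × 2000, 10-fold CV) with DBN A-50-10-1
(CD 10 epochs, iRprop+ 100 epochs), a linear SVM, and their hybrid; the
same runs with δ = 0 verify chance-level behavior. These sizes keep every
check at desk scale on one CPU.

On these conditions the fine-tuned DBN, the SVM and the DBN+SVM hybrid all
recover the signal, while the raw RBM-stack representation can collapse to
a near-constant map of the 2000-dimensional input (it is flagged by the
harness when it does) and the autoencoder hybrid lands in between —
consistent with the known observations that unsupervised pretraining is
fragile on full-dimensional expression input without feature selection and
that autoencoders want more data, whereas iRprop+ fine-tuning is largely
insensitive to pretraining quality.

## Numerical and design choices

- Logistic activation everywhere, including the output layer (the MSE +
  [0, 1]-target formulation assumes it); no softmax/cross-entropy.
- log transform is log2(v + 1), keeping zeros finite.
- Variance ties in feature selection break by ascending gene index;
  multi-node prediction ties break to the lowest index (reproducibility).
- Multiclass undersampling reduces every class to the global minimum
  count.
- RBM initialization: weights N(0, 0.01), zero biases. CD defaults:
  lr 0.1, batch 10, momentum 0.5 → 0.9 after 5 epochs, weight-cost 2e−4.
  Bprop defaults: η = 0.1, batch 10. All are config-exposed.
- Constant genes min-max scale to 0; test values outside the training
  range are clipped to [0, 1].
- Degenerate inputs fail loudly: empty datasets, single-class labels,
  k > n folds, non-palindromic autoencoders, inconsistent stacks and
  shape mismatches all raise with specific messages; a constant extracted
  representation warns and is flagged on the classifier.

## Known limitations

- No persistent CD, parallel tempering or Gaussian-visible RBMs; inputs
  are forced through per-gene min-max scaling instead of modelling
  continuous intensities directly.
- No conjugate-gradient fine-tuning and no dropout.
- No ROC/AUC or calibration; the report is the Acc/TPR/TNR/E table.
- The standard error is computed over folds of a single CV run; fold
  overlap makes it an optimistic estimate of between-study variability.
- Raw CEL preprocessing (RMA/mas5) and GEO retrieval are out of scope;
  the loaders expect preprocessed delimited text.
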