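# Methods

This note records what the package computes and why, in the package's own
terms. The pipeline classifies cancer cohorts into long-term survivors
(LTS, > 2 years) and non-long-term survivors (non-LTS, observed death at
or below 2 years) from multi-omics data, explains the classifier at the
pathway level, and screens the implicated pathways for survival-associated
genes.

## 1. Data preparation

Inputs are one numeric matrix per omics layer (samples x genes; TSV/CSV,
either orientation), a GMT file of pathway gene sets with an optional
exclusion list, and a clinical table with follow-up time and an event flag.

Cleaning per layer: duplicate gene columns are collapsed by mean; genes
with more than 20% missing values are dropped, then samples with more than
20% missing values; remaining missing cells are imputed with the gene's
median. Survival labels follow a three-way rule: time > 2y is LTS
(regardless of event), time <= 2y with an observed event is non-LTS, and
time <= 2y censored is *excluded* — too short a follow-up to know.
Harmonization intersects samples and genes across layers (sorted, so the
result is order-independent), drops excluded samples, and reports
per-layer counts when the intersection is empty.

## 2. Pathway-PC images

For every (survival class, omics layer, pathway) triple, the members of
that pathway in that layer for that class's samples form an isolated
matrix; with 2 classes, 3 layers and 146 pathways that is 876 matrices
(and 6 class-split matrices at the layer level). Each isolated matrix is
standardized (per-gene z-score) and decomposed by PCA; the top `n_pcs`
component scores become image cells. Component signs are fixed
(largest-|loading| entry positive) so embeddings are deterministic;
constant genes are dropped; rank-deficient fits are zero-padded.

A sample's image has one row per pathway and one column per
(omics layer, PC) pair in omics-major order — 146 x 6 at 2 PCs. Columns
are min-max scaled to [0, 1] using statistics of the fitting samples.

Two assembly modes:

- **paper-faithful** — each sample is embedded with its own class's PCA
  models, fitted on all samples of that class. This uses the label at
  embedding time, so classification results on such images are optimistic;
  the mode exists for faithfulness and for exploratory embedding.
- **fold-safe** — the PCA bank is fitted on the training fold only, and
  every sample is embedded under *both* classes' models (doubling the
  columns to 146 x 12), so no label enters a test image. Training images
  are additionally cross-fitted: the training fold is split per class into
  two halves and each half is embedded through a bank fitted on the other
  half. Without this, training projections are in-fit (systematically
  larger variance than out-of-fit test projections after normalization)
  and the classifier learns that artifact instead of the signal — in our
  experiments this pushed held-out AUC *below* chance. The half-fit PCA
  bases are then orthogonal-Procrustes-rotated onto the full-fold bank's
  bases (per pathway model, on their common genes): PCA fits on different
  subsets can disagree by component sign flips or PC swaps, which would
  put cross-fitted training columns and test columns in scrambled
  coordinates. In our benchmark this alignment raised a linear probe's
  pooled cross-validated AUC from 0.73 to 0.98 with no other change.

## 3. Classifier

A small CNN: convolution blocks (conv, batch-norm, ReLU, max-pool), a
flatten, one dense block with dropout, and a softmax over the two classes.
The default geometry is two *row-preserving* blocks — 1x3 kernels and
width-only pooling, filters (8, 16), dense width 32, dropout 0.5 — chosen
because pathway rows are independent signals in an arbitrary order:
kernels or pooling that span rows average unrelated pathways and bury
single-pathway effects (held-out AUC ~0.65 with a 4-block 3x3
architecture vs ~0.87 row-preserving on the same planted-signal
benchmark). Deeper 3x3 architectures remain expressible through
`CnnConfig`.

Training: Adam (lr 1e-3, optional decoupled weight decay on weight
matrices), 60 epochs, batch 4, a stratified 20% validation split, NaN
loss aborts. The small batch is deliberate: on ~10^2-sample cohorts the
gradient noise of 4-sample batches is a strong regularizer — in our
planted-signal benchmark the networks reach training accuracy 1.0 at any
batch size, but held-out AUC on the hardest folds rose from ~0.76
(batch 32) to ~0.95 (batch 4) with no other change. The weights kept are those of the
epoch with the best (validation AUC, validation accuracy) — AUC first
because it is the reported metric and has finer granularity than
accuracy on small validation splits. A trained model is a *seed
ensemble*: 4 members trained from independent initializations (seeds
offset deterministically), with predicted probabilities averaged.
Single runs on ~10^2-sample cohorts have large seed variance (held-out
AUC ranging 0.6–0.98 across seeds in our benchmark); the 4-member
average tracks the best members. All layers are implemented in NumPy
with explicit backward passes (verified against finite differences),
which also supplies the input gradients the attribution stage needs.

Evaluation is stratified k-fold (default 5) cross-validation in fold-safe
mode, reporting accuracy, precision, recall, F1, ROC AUC (Mann-Whitney
rank form, non-LTS positive) and the confusion matrix, per fold and pooled
over the folds' test predictions.

## 4. Gradient-SHAP attribution

The attribution of image cell i for class c is

    phi_i = E_{x'}[ (x_i - x'_i) * Integral_0^1 df_c/dx_i (x' + a(x - x')) da ]

estimated by Monte Carlo: baselines x' are training images plus Gaussian
noise (default SD 0.1 x mean per-cell training SD), the baseline pool is
cycled in permuted order and the path positions a are stratified — both
variance-reduction devices that leave the estimator unbiased. The
estimator satisfies the standard checks: zero attribution at a sole
baseline, the closed form w_i(x_i - x'_i) for linear models, and
completeness (sum of attributions ~= f_c(x) - E f_c(x')).

Each sample is attributed by the one fold model that never trained on it,
targeting its own class. Per-class global scores average |phi| over the
class's samples (signed means are also stored); the top-10 cells per class
roll up to (pathway, omics, PC) triples, and the classes' pathway sets are
compared for common and unique members.

## 5. Cox proportional-hazards gene selection

Within each implicated pathway, gene effects on survival are estimated by
a Cox model with Breslow tie handling, fitted by Newton's method with
step-halving on the partial likelihood (covariates z-scored by default;
gradient-norm tolerance 1e-8; non-convergence is flagged, never silently
accepted). Wald tests give z = beta/SE, hazard ratios e^beta with 95% CIs,
and p-values; genes with p < 0.01 are selected. Samples censored at or
below the threshold can be included (default) or excluded from the Cox
stage independently of their exclusion from classification. The default
mode fits one multivariate model per pathway; univariate per-gene fits are
available.

## 6. Synthetic cohorts and verification

The bundled generator plants known effects so every stage is testable:
pathway gene sets partition the gene universe; planted (pathway, layer,
delta) shifts move the non-LTS class's genes by delta noise-SDs; survival
times follow an exponential proportional-hazards model with chosen gene
coefficients, sampled within each class's time window so thresholding
reproduces the planted classes; extra short-censored samples exercise the
exclusion rule. Clean (unconditioned) survival data for Cox calibration
comes from `generate_survival_data`.

All randomness flows from one master seed through named per-stage
SHA-256-derived seeds, so runs are bit-reproducible and stages are
independently reproducible. Artifact directories record the configuration
and its hash.
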