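# Methods

This note documents the models, algorithms and numerical choices behind
`ftirdae`: a pipeline that learns a compressed, denoised representation of
blood-serum FTIR absorbance spectra with a fully convolutional denoising
autoencoder, and then treats the learned latent variables as candidate
disease markers.

## Spectra and manual preprocessing

A spectrum is a vector of absorbances on a wavenumber grid (cm^-1).  The
working range is 1000-3000 cm^-1; the default grid has 1037 evenly spaced
points (spacing ~1.9305 cm^-1), matching the network's input layer.
Manual preprocessing is deliberately minimal: truncation to that range
(inclusive bounds on both ends) followed by L2 normalization of each
spectrum.  Normalization removes overall intensity scale (path length,
sample volume), leaving relative band structure.

Serum barely absorbs between 1800 and 2300 cm^-1 (the *silent region*).
Any structure observed there — baseline offsets, interference fringes,
water-vapour lines — is instrument artefact, which makes the region a clean
sentinel for measurement drift.  `silent_mask` flags those grid points;
both bounds are inclusive.

## Synthetic cohorts

Real cohort data of this kind are access-restricted, so the package ships a
generator whose defaults emulate a serum case-control study:

* **Bands.** Each spectrum is a sum of 10 Gaussian absorption bands at
  serum-typical positions (1080-1740 cm^-1 fingerprint, 2850-2960 cm^-1
  CH-stretch; none inside 1800-2300 cm^-1, so the silent region is flat up
  to drift).  Amide I (1650 cm^-1) and amide II (1550 cm^-1) dominate.
* **Biological variation.** Per-sample log-normal multipliers on each band
  amplitude with coefficient of variation 0.15 — inter-subject variation
  dominates the fingerprint, as it must for raw-spectrum classification to
  be possible at all.
* **Drift and noise.** Additive baseline offset (sd 0.005), linear slope
  (sd 5e-6 per cm^-1), sinusoidal fringes (amplitude sd 0.004, period
  120 cm^-1, random phase) and white noise (sd 0.002).  These scales are
  small against the bands but dominate the near-zero silent region, which
  is exactly the phenomenology the autoencoder is meant to exploit.
* **Disease effect.** Cases carry a relative amplitude shift on the amide
  and lipid-ester bands proportional to a stage weight (I:0.25 … IV:1.0);
  the default effect size is 5% per unit weight.  Stage is recorded for
  roughly 45% of cases ("unknown" otherwise, mirroring incomplete staging),
  but the hidden severity still drives the spectrum and the surrogate
  biomarkers.
* **Covariates and biomarkers.** Age, sex and BMI are drawn with matched
  case/control moments (65 +/- 10 years, 46% female, 26 +/- 5 kg/m^2) and
  perturb selected bands weakly.  Four surrogate blood markers (CRP,
  CYFRA 21-1, leukocytes, hemoglobin) load linearly on disease severity
  with known signs and realistic missingness (30% for CYFRA 21-1).

What the generator does **not** emulate: Beer-Lambert/optical physics, Mie
scattering, water-vapour line structure, batch effects across instruments,
or correlated biomarker panels.  Tests passing on these cohorts show the
pipeline's statistical machinery works under the stated assumptions; they
are not evidence about any particular real cohort.

## Multivariate-Gaussian augmentation

The autoencoder is trained on synthetic spectra sampled from a multivariate
Gaussian fitted to the (preprocessed) training spectra of each fold: mean =
column means, covariance = sample covariance shrunk toward its diagonal,

    Sigma_hat = (1 - s) * S + s * diag(S).

Shrinkage is mandatory: with more grid points (1037) than training spectra
the sample covariance is singular.  The default intensity `s` is estimated
by a Ledoit-Wolf-style plug-in formula for the diagonal target,
`s* = sum_{i!=j} Var(S_ij) / sum_{i!=j} S_ij^2`, clipped to [0, 1].  The
5000-draw default matches the augmentation size of the full-scale training
regime; draws are L2-normalized before use.

## Autoencoder

Architecture (input length 1037, one channel):

| layer | filters | kernel | stride | activation | output | params |
|-------|---------|--------|--------|------------|--------|--------|
| conv    | 128 | 53 | 2 | ELU    | (493, 128) | 6 912   |
| conv    | 64  | 53 | 2 | ELU    | (221, 64)  | 434 240 |
| conv    | 32  | 53 | 2 | ELU    | (85, 32)   | 108 576 |
| conv    | 16  | 53 | 2 | ELU    | (17, 16)   | 27 152  |
| t-conv  | 32  | 53 | 2 | ELU    | (85, 32)   | 27 168  |
| t-conv  | 64  | 53 | 2 | ELU    | (221, 64)  | 108 608 |
| t-conv  | 128 | 53 | 2 | ELU    | (493, 128) | 434 304 |
| t-conv  | 1   | 53 | 2 | linear | (1037, 1)  | 6 785   |

All convolutions are 'valid' (no padding) with bias.  The bottleneck
flattens position-major to 272 latent variables.  The final layer is linear
because targets are signed normalized absorbances.  The layer stack is
implemented directly in NumPy (float32): strided per-tap GEMMs for the wide
layers, an explicit patch buffer for the narrow (1-channel) end layers, with
analytically derived backward passes (verified against finite differences)
and a standard ADAM optimizer.

### Loss

With silent-region point set S, fixed reference spectrum y~ on S, and
weight lambda,

    L = lambda * (1/n) sum_i sum_{j in S} (f_j(x_i) - y~_j)^2
      +          (1/n) sum_i sum_{j not in S} (f_j(x_i) - y_ij)^2.

The convention — average over spectra, sum over wavenumbers within each
region, lambda on the silent term — is fixed so that the default
lambda = 1000 is interpretable; any consistent alternative only rescales
lambda.  The silent region is mapped to a *fixed* target, forcing the
network to discard sample-specific drift; the rest must be reproduced.
y~ defaults to the silent-region column mean of the training spectra (a
repeatedly measured pooled-serum QC spectrum, when available, can be
supplied as an external reference instead).  `lambda_weight = 0` switches
to a plain-MSE ablation in which the silent region tracks the input.

### Training and the scaled-down regime

Full-scale defaults: ADAM (lr 0.001, eps 1e-7), batch 128, up to 50 epochs,
10% validation split, early stopping (patience 5, restore best weights).

Two optimization facts matter on a small step budget.  First, the
lambda = 1000 silent term dominates the gradient (and ADAM's second-moment
estimates) until the silent region is reproduced to high precision, so
fingerprint detail converges late.  Second, ADAM's early steps under this
loss are large and oscillatory at the conventional eps of 1e-7.
`TrainConfig.scaled_down()` therefore uses batch 8 (more optimizer steps
per epoch at identical arithmetic cost) and adam_epsilon 1e-4 (damped
early steps), keeping the single-phase objective.  An
optional two-phase schedule (`mse_pretrain_epochs`: plain-MSE epochs first,
then the full objective with reset moments at
`constrained_lr_factor * learning_rate`) trades silent-region flattening
for reconstruction fidelity on short budgets and is off by default.

On short budgets the two denoising outcomes converge at different speeds:
silent-region variance reduction is reached within a few hundred steps,
while *pair preservation* demands near-complete recovery of each sample's
deviation amplitude (an under-converged autoencoder shrinks deviations
toward the cohort mean, which scrambles nearest-neighbour pairs in the
crowded PC plane even when reconstructions correlate well with their
targets).  Calibration of the metric itself: an oracle denoiser that
returns the generator's true band component scores 0.99, and an isotropic
residual of 0.002 per point scores 0.92 — so high pair preservation is a
property of converged training (the full-scale regime), not of the
scaled-down runs.  The quick-run sizes used by the test-suite and the
acceptance script — cohorts of 100-300 samples, 300-1000 augmented
spectra, 6-15 epochs — are the package's own scaled-down study conditions;
the full-scale regime is the library default.

### Denoising diagnostics

* `silent_pc1_scores` — scores of the first principal component of the
  silent-region columns (centered, unscaled; sign fixed by positive loading
  sum).  Shrinking score variance after reconstruction indicates drift
  removal.
* `pair_preservation` — project originals and reconstructions into the
  first two principal components of the pooled set; the fraction of samples
  whose reconstruction is nearest its own original measures how much
  biological identity survives denoising.
* `spectral_comparison` — per-wavenumber paired Cohen's d (mean difference
  over sd of differences), paired t-test, and mean |residual|.

## Cross-validated classification workflow

Stratified, disjoint k-fold CV (default 10).  Per fold, using training data
only: fit the augmentation Gaussian, sample synthetic spectra, train a
fold-specific autoencoder, then evaluate up to three feature arms with a
logistic-regression classifier (features standardized with train-fold
moments; inverse-regularization chosen by inner 5-fold grid search over 7
log-spaced values, AUC criterion):

* *manual* — the preprocessed spectra;
* *reconstructed* — decoder output;
* *latent* — 272 encoder outputs, reduced by backward feature elimination.

Backward elimination greedily removes the feature whose removal least
degrades cross-validated AUC, stopping when the best removal would cost
more than a tolerance (default 0.005); it never empties the set, and ties
retain the lower index.  Because full backward elimination from 272
features costs O(p^2) classifier fits, the workflow optionally pre-screens
to the top-k latent features by |point-biserial correlation| with the
training labels (default k = 32) before eliminating; set
`pre_screen_k=None` for the exhaustive search.

Aggregation pools test scores across folds into one empirical ROC (the
per-fold AUC mean +/- sd is reported alongside; pooling can sit below
per-fold AUCs when fold score ranges interleave).  Paired two-sided t-tests
compare arms on fold-wise AUCs; zero-variance differences are flagged
degenerate with p = 1.  The test-fold hash never reaches any fitting stage;
audit hooks in `classification` expose this for verification.

## Latent analysis

Within one fold's model: point-biserial correlations (Pearson on 0/1
coding) of each latent variable with disease status and sex, Pearson with
age, all pairwise-complete on missing values; constant columns are flagged
with r = 0.  The *disentangled* reduction keeps features whose |r| crosses
a threshold (default 0.1) for exactly one of the three variables.  The
*single latent feature* (SLF) is the |disease correlation| argmax (ties to
the lowest index).  Latent columns are not comparable across folds — only
aggregate summaries (e.g. mean +/- sd of maximum |r|) are meaningful across
models.  The biomarker network computes pairwise-complete Pearson
correlations among {SLF, biomarkers}, drops markers with fewer than 3
observations, and emits edges with |r| >= 0.3 by default.

## ROC-GLM

The covariate-adjusted ROC model on the probit scale:

    Phi^-1(ROC(t | X)) = a + b*Phi^-1(t) + beta0*X + beta1*X*Phi^-1(t),

with t the false-positive rate.  The baseline h(t) = a + b*Phi^-1(t) is the
classical binormal curve (AUC = Phi(a / sqrt(1 + b^2))).  Estimation is the
standard semiparametric placement-value construction: each case score is
replaced by its placement value among the controls (survivor function, ties
one half — rank-based, hence invariant under monotone score transforms);
indicators U_ij = 1{PV_i <= t_j} on a default grid of 19 equally spaced t
in [0.05, 0.95] are regressed with a probit-link GLM on
{1, Phi^-1(t_j), X_i, X_i*Phi^-1(t_j)}.  Standard errors come from
bootstrap resampling cases and controls separately (default B = 1000; each
case keeps its covariates), and Wald z-tests use the bootstrap sd of the
tested contrast.  Stage enters as a categorical covariate with stage I as
reference; pairwise stage contrasts on intercept and slope terms are
provided.  Fits failing to converge in more than 20% of bootstrap draws
raise an error rather than reporting unstable intervals.

## Numerical conventions and degenerate inputs

* Region bounds (truncation, silent mask) are inclusive on both ends.
* l2_normalize errors on zero-norm rows, naming the sample.
* Zero-variance inputs: constant latent columns get r = 0 plus a flag;
  identical paired AUC vectors give p = 1 with a degeneracy flag; an
  all-zero covariance Gaussian yields its mean on every draw.
* Training requires unit-norm inputs (tolerance 1e-6 on row norms).
* Model persistence bundles weights, architecture, loss configuration and
  history in one `.npz`; reload reproduces encode/reconstruct outputs to
  float32 round-off.
* Bit-exact training reproducibility is promised only within one NumPy/BLAS
  build; all randomness flows from integer seeds kept below 2^31.

## Known limitations

* The synthetic generator's simplifications listed above; in particular
  additive drift is global, not band-local.
* The NumPy training loop is single-threaded BLAS-bound; full-scale
  training (5000 x 50 epochs) takes hours on one CPU core.
* Backward elimination with the default pre-screen is a heuristic; the
  exhaustive search changes selected sets on correlated latents.
* ROC-GLM assumes case covariates fully observed and conditions only on
  case covariates (control distribution enters through placement values).
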