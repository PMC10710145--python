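# Methods

## Pipeline overview

`mvfuse` predicts a continuous phenotype from several feature views by (1)
selecting genotype features with a covariate-adjusted score test, (2)
learning a shared latent representation with a multi-view variational
autoencoder fused by a product of experts, (3) regressing the phenotype on
the fused latents, and (4) ranking features by leave-one-out zero-fill
importance.  This note records the modelling assumptions, the defaults and
why, the numerical choices, and what the synthetic-data generator does and
does not emulate.

## Variant QC and association

Genotypes are minor-allele counts in {0,1,2} with an explicit missing state.
QC removes, in order: subjects with missing rate > 20%, then variants with
missing rate > 5%, Hardy–Weinberg exact-test p < 10⁻⁴, or MAF < 5%, with
variant statistics recomputed on the retained subjects.  Running the subject
filter first keeps excluded subjects from influencing variant statistics;
the filter is idempotent.

The HWE test is the conditional exact test: given the subject count and
minor-allele total, every attainable heterozygote count has a known
probability, and the p-value sums the probabilities of all counts no more
probable than the observed one.  Probabilities are computed with log-gamma
arithmetic; the test suite checks exact agreement with a rational-arithmetic
enumeration for every table with ≤ 30 subjects.

Population structure is captured by PCA on the mean-imputed genotype matrix
with each variant centered at 2p̂ and scaled by √(2p̂(1−p̂)) (standard
allele-frequency scaling).  PC signs are fixed by making each component's
largest-magnitude variant loading positive, so scores are deterministic.
Ten PCs join age, weight and height as covariates by default; both counts
are configurable.

The score test residualizes phenotype and (mean-imputed) genotype against
the covariates-plus-intercept design and forms T = U²/V with
U = Σ ỹᵢ g̃ᵢ and V = (1/N) Σ ỹᵢ² Σ g̃ᵢ².  T is quadratic in U, so the
p-value is taken from the upper tail of χ²(1) at T — equivalent to a
two-sided standard-normal test on U/√V.  Algebraically T = N·corr(ỹ,g̃)²,
which the tests verify to 1e-10.  Missing genotypes are mean-imputed
per variant before residualization (preserves the allele-frequency
expectation; the common GWAS default).  Selection keeps the K variants with
smallest p, ties broken by (chromosome, position) ascending; K defaults
to 256.

## The MVAE-PoE model

Each view m has an encoder MLP (1–3 hidden ReLU layers of 32–256 units)
with two linear heads: the posterior mean μₘ and the log-variance, which is
exponentiated so variances are positive by construction.  The log-variance
head is clamped to [−10, 10] before exponentiation for numerical stability.
The product of the M per-view Gaussians is Gaussian with precisions adding
and the mean precision-weighted; the leading normalization constant of the
product does not affect those parameters, so the closed form is used
directly.  No unit-Gaussian "prior expert" joins the product by default
(the fusion multiplies only the view posteriors); with one view the fusion
is the identity and the model is a standard VAE.

A sample z = μ_z + σ_z ⊙ ε (reparameterization trick) feeds per-view
decoder MLPs whose final activation is a logistic sigmoid, required for the
Bernoulli cross-entropy reconstruction term to be finite.  The loss is the
negative ELBO

    Σ_subjects Σ_views Σ_features −[x log x̂ + (1−x) log(1−x̂)]
      + Σ_subjects ½ Σ_d (μ_d² + σ_d² − log σ_d² − 1),

with reconstructions clipped to [1e−7, 1−1e−7] before the logs.  Because
the cross-entropy is only finite on [0,1], features are min–max scaled per
view using training-subject statistics only; constant features map to 0.5
and test values are clipped to [0,1].

The networks are plain dense MLPs implemented in numpy with analytically
derived gradients, including the backpropagation through the
precision-weighted fusion (∂μ_z/∂precₘ = σ_z²(μₘ − μ_z), ∂σ_z²/∂precₘ =
−σ_z⁴).  The test suite validates all gradients against central finite
differences at 1e−4 relative tolerance.  Weights are fan-in-scaled Gaussian
draws under the run seed; optimization is Adam (lr 1e−3, batch 64) with a
fixed epoch budget and optional early stopping on a 50-epoch
validation-loss plateau when a validation set is supplied.  Training is
bit-reproducible under the seed (initialization, batch order, noise draws).

## Prediction protocol

20% of subjects are randomly held out as the test set.  The regression head
is ordinary least squares with intercept on the fused posterior *means*
(no sampling), making predictions deterministic; when the latent design is
rank-deficient or underdetermined (D can reach 256) the head falls back to
ridge with penalty 1e−6 and logs a warning.  Metrics: MAE, RMSE,
R² = 1 − SS_res/SS_tot, and MAPE = mean(|y−ŷ|/y)·100 with the signed
denominator as defined — phenotypes here are positive, so this equals the
absolute-denominator convention in practice; if any y = 0 MAPE is reported
as undefined and the other metrics stand.

Hyperparameters (layers ∈ {1,2,3}, hidden units and latent dimension ∈
{32,48,64,128,256}) are grid-searched.  Selection uses the highest R² on a
validation split carved from the training data (20% of train), not the test
set: selecting on the test set would leak it into model choice, so reported
test metrics stay honest.  Failed grid points are recorded and skipped.

## Feature importance

Leave-one-out zero-fill: for each feature of each view, its scaled value is
set to 0 for all test subjects, latents are re-extracted, the phenotype
re-predicted, and the importance is the MAE increase over the intact
baseline.  Zero-filling happens in the scaled [0,1] space — 0 is the
training minimum — because the model only ever sees scaled inputs; the
choice of space is a genuine ambiguity and this one keeps the perturbation
well-defined for every feature.  Deltas are reported raw, ranked
descending, with a top-15 summary.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes:

- **Genotypes**: independent biallelic SNPs, each genotype the sum of two
  Bernoulli allele draws at a MAF uniform on a configured range, i.e. HWE
  within each (sub)population.  Optional two-subpopulation structure shifts
  allele frequencies by ±divergence/2 (clipped to (0.01, 0.99)) — the
  simplest controllable stand-in for ancestry, sufficient for PCA tests.
  Optional uniform missingness exercises the QC filters.
- **Covariates**: age/weight/height on adult-male cohort scales
  (age ≈ N(36.5, 8.4²) years, weight ≈ N(83, 16.7²) kg,
  height ≈ N(175, 6.9²) cm).
- **Phenotype**: linear in a sparse causal-SNP set, the covariates, and
  (by default) the shared latent factors, plus Gaussian noise.  Defaults
  put it on a fracture-load-like Newton scale (intercept 2320, residual SD
  300).  Letting the phenotype load on the latent factors makes the
  "views help prediction" property testable.
- **Views**: latent factors z ~ N(0, I_4) with per-view Gaussian loadings
  and noise, view widths defaulting to (196, 256).

All generators are bit-reproducible under one seed expanded into per-stage
seeds.  Not emulated: linkage disequilibrium, realistic MAF spectra,
imputation artifacts, nonlinear genotype–phenotype effects, and any
image-derived phenotype physics.  Passing tests therefore demonstrate that
the machinery is correct and calibrated under the assumed factor-model
structure, not that real cohort performance is reproduced.

## Problem sizes in the checks

The property checks use desk-scale sizes chosen to make the statistical
assertions sharp: null calibration at N = 500 with 10,000 variants
(binomial SE ≈ 0.002 on the 0.05 rate); causal recovery at N = 800 with
5 causal SNPs of effect 0.4 phenotype-SD per allele among 2,000 (single-test
noncentrality ≈ 30–50, power ≫ 99%); latent recovery and fusion benefit at
N = 800–1,000 with two 60–100-feature views, D_true = 4, view noise SD 0.3,
trained for 300 epochs.  One caveat found empirically and worth stating:
with very narrow views (≈ 20 features) the aggregate reconstruction gain
from encoding a factor can be comparable to its KL cost and the posterior
partially collapses; at the feature counts the method targets (hundreds per
view) the reconstruction term dominates and recovery is near-perfect.

## Known limitations

- Bernoulli cross-entropy on min–max-scaled continuous features is a
  pragmatic likelihood, not a calibrated density model; a Gaussian decoder
  would be the natural alternative.
- No relatedness or mixed-model correction in the association stage; no
  LD-aware selection (top-K by p-value can pick correlated variants).
- Grid search retrains one model per grid point sequentially; the full
  3×5×5 grid is expensive and is typically narrowed.
- The importance ranking is a perturbation measure tied to the trained
  model and scaling; it is not a significance test.
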