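# Methods

## The sequential model

The package models six prognostic tasks ordered by the natural history
of high-grade prostate cancer: lymph-node invasion (LNI) at surgery,
then biochemical recurrence (BCR-FS), metastasis (MFS), definitive
androgen-deprivation therapy (dADT-FS), castration resistance
(CRPC-FS) and cancer-specific death (PCSS).  Each task has its own
feed-forward model; task *i* consumes the standardized clinical
features, optional radiomic features, and a vector *a_i(t_p)* built
from the earlier tasks.  At `t_p = 0` the entries of *a_i* are the
upstream models' raw outputs (the pre-activation logit `q_j` for
classification, the Cox risk `g_j` for survival), so gradients flow
through the whole chain and the six losses — weighted binary
cross-entropy for LNI, negative partial log-likelihood (NPLL) per
survival task — are minimized jointly by full-batch Adam.  At
`t_p > 0` any outcome already known replaces the corresponding entry
with a finite stand-in for ±infinity: ±5 for a class label, +10 for an
observed event.  Survival functions are assembled per patient from the
Breslow cumulative-baseline-hazard estimate computed on the training
set after fitting, with pooled denominators at tied event times.

Assumptions inherited from the Cox formulation: proportional hazards
within each task, censoring non-informative given the features, and
risk scores identified only up to an additive constant (the NPLL is
shift-invariant; inference uses the raw risk).

### Training with outcome substitution

The ±C substitutions only help if the models know what those inputs
mean.  With training confined to `t_p = 0`, a linear task model's
predecessor channel is an exact linear function of the clinical
features, so its coefficient is unidentified — and substituting +10 at
inference probes precisely that unidentified direction; in our
simulations dynamic predictions then *degraded* (downstream
cumulative/dynamic AUC fell from ≈0.92 to ≈0.72 on average).  `fit`
therefore draws, for a configurable fraction of epochs (default one
half), a random positive prognosis time from {12, 24, 60} months and
substitutes the training patients' own known outcomes into the
predecessor inputs, exactly as at inference.  Gradients keep flowing
through the non-substituted entries.  This is the package's design
choice for a point the sequential-network formulation leaves open; it
makes the dynamic-prediction benefit systematic (20/20 seeds in the
acceptance experiment).

### Bayesian variant

Each weight of a Bayesian model carries a factorized Gaussian
posterior `q(θ) = N(μ, softplus(ρ))` trained by the reparametrization
trick with one standard-normal draw per weight per forward pass; the
objective adds `β · KL(q‖N(0,1)) / n_train` (β = 1 by default) to the
task losses.  Predictive mean and standard deviation come from K
stochastic passes (default 100).  Freezing every σ at zero (mean-mode
forward) reproduces the deterministic network exactly; the test suite
asserts this limit.  The softplus parametrization, the N(0,1) prior
and the 1/n KL scaling are package conventions chosen for positivity
and standard minibatch behaviour.

## Synthetic cohorts

No cohort of this kind can be redistributed, so the generator is
first-class, tested code and defines the study conditions:

* **Features.** age ~ N(66, 7²) years; PSA ~ logNormal(ln 15, 0.6²)
  ng/ml; (primary, secondary) Gleason drawn from the six high-grade
  pairs with global = primary + secondary ≥ 8 always; ordinal clinical
  stage 1–4.  Features are z-normalized internally.
* **Latent aggressiveness.** `z = w·x_std + 0.3·N(0,1)` with loadings
  w = (0.6, 0.9, 0.75, 0.6) on (age, PSA, global Gleason, stage).
  The global Gleason score is an exact sum of the primary and
  secondary scores, so per-feature hazard effects are identifiable
  only on this non-collinear subset; the generator reports it as
  `recovery_features` together with the marginal coefficients
  (latent coefficient × loadings) that a Cox-type fit estimates.
* **Outcomes.** LNI ~ Bernoulli(sigmoid(−1.2 + 1.5 z)) (prevalence
  ≈ 0.32).  Event times are built *cumulatively*: the BCR time and
  each subsequent inter-event gap follow Weibull
  proportional-hazards models with shape 1.2 and scales
  (36, 30, 40, 50, 60) months, each gap's log-hazard being
  `0.8·z + 0.8·e_prev` (the BCR stage omits the `e_prev` term), where
  `e_prev` indicates an early previous event.  Cumulative progression
  guarantees each patient's event times are ordered as the disease
  history dictates, which makes the uncensored median ordering robust
  to censoring selection — a marginal-scale design we tried first
  did not survive it.  Administrative censoring is uniform on
  [24, 120] months (median follow-up ≈ 6 years), one censoring time
  per patient across tasks.
* **What the generator does not emulate.** Measurement error and
  missing-not-at-random patterns in clinical variables, treatment
  effects on post-event hazards, competing mortality, and informative
  censoring.  Passing tests therefore demonstrate the machinery is
  correct under the stated generative model, not clinical
  performance on real cohorts.

Effect magnitudes were fixed once at values that make the identifiable
coefficients large relative to their sampling error at n = 2000
(roughly |β|/SE ≳ 10), since the recovery criterion presumes estimable
conditions; the remaining latent noise acts as a small frailty whose
attenuation of the marginal coefficients is a few per cent.

Missing-data handling mirrors standard practice: a round-robin
iterative imputer (10 sweeps, fixed column order) with a
random-forest regressor per incomplete column; ordinal columns are
snapped back onto their valid value sets and observed entries are
never altered.

## Phantoms and the imaging arm

Phantoms are ellipsoidal organs (default 32³ grid, 2 mm voxels) with
Gaussian CT/PET textures; PET uptake inside the organ increases by
`lesion_uptake × z`, so image intensity carries the prognostic signal.
Preprocessing resamples to an isotropic grid, crops a cube centred on
the mask centroid (128 mm at clinical scale, configurable for
phantoms), converts PET activity to SUV (body-weight formula with
decay correction; imputation defaults 75 kg, 420 MBq, 105 min, F-18
half-life 109.77 min), clips CT to [−200, 250] HU and PET to
[0, 25] SUV and maps both to [0, 1].  Augmentation applies Gaussian
noise (then re-clips), an axial flip and a small in-plane rotation,
each independently with probability ½, identically across CT, PET and
mask.

The segmentation network is a residual 3D U-Net with
strided-convolution downsampling and transposed-convolution
upsampling; every convolution is followed by instance normalization
and PReLU.  Instance norm is essential at this scale: without it the
stack saturates its sigmoid head and soft-Dice training stalls in the
empty-prediction basin.  The U-NEXtractor shares the encoder/decoder
and adds a radiomic branch: global-average-pooled encoder taps
(8+16+32 = 56 channels in the default scaled configuration) reduced by
a small MLP to 6 deep radiomic features (matching the number of
clinical features) and a linear prognostic head.  Default channels
(8, 16, 32) train on CPU in minutes; the clinical-scale configuration
is metadata, not a test path.  Imaging networks run in float32;
training uses Adam with learning rate 3·10⁻² (U-Net) chosen for the
soft-Dice loss's flat early landscape.

The handcrafted census is 200 features: 14 shape features from the
mask (mesh volume and surface by marching cubes, sphericity, PCA axis
lengths, maximum 3D and in-plane diameters) plus, per modality, 18
first-order, 24 co-occurrence (13 symmetric 3D directions, features
averaged over directions), 16 run-length (same directions), 16
size-zone (26-connected zones), 14 dependence and 5
neighbourhood-tone-difference features, following the IBSI
definitions; kurtosis is reported without the −3 excess correction.
Discretization uses fixed bin widths of 25 HU (CT) and 0.25 SUV (PET).
The 14 + 93×2 decomposition is the only standard family breakdown
consistent with a 200-feature total and is recorded here as a derived
reconstruction.  Feature selection fits a random-forest classifier
(default 10 000 trees) and keeps the top 6 features by Gini
importance.

## Risk stratification

Classification uses the fixed cutoff 0.5.  For survival tasks the
candidate percentiles span round(100·n0/(n0+n1))/100 ± 0.2 clipped to
[0.05, 0.95] in steps of 0.01 (n0 censored, n1 events; rounding is
half-away-from-zero), the threshold is the lower-interpolation
quantile of learning-set risks at each percentile, and the winner
minimizes the two-group log-rank p-value, ties broken toward the
smallest percentile.  Because the cutoff minimizes the learning-set
p-value, that p-value is anti-conservative; the library reports
learning-set and held-out p-values separately and the held-out one is
the honest test.  The hazard ratio is the O/E ratio estimate from the
log-rank table with a log-scale 95% CI from √(1/E1 + 1/E2);
Kaplan-Meier intervals use the log-hazard (exponential-Greenwood)
transformation.

## Experimental protocol

The holdout split takes floor(0.85·n) patients (295 → 250/45),
stratified on the LNI label and the BCR event indicator with
largest-remainder allocation so each stratum's proportion deviates by
at most one patient.  Stratified k-fold deals shuffled stratum members
in one continuing round-robin, giving fold sizes within one of each
other (250/5 → five folds of exactly 50); strata smaller than k —
which arise in small cohorts because LNI-positive patients almost
always recur — are pooled into the largest stratum first.
Hyperparameter search runs 25 trials, the first 5 uniform random and
the rest from a scrambled Sobol sequence (model-based refinement is
out of scope; the low-discrepancy default keeps the harness
deterministic).  Nested cross-validation fits exactly
k_outer · k_inner · budget = 5·5·25 = 625 instances per model design;
selection uses AUC for classification and concordance for survival,
averaged over tasks in multi-task runs.

## Metrics

AUC and balanced accuracy for classification; Harrell's concordance
(ties count ½), Uno's IPCW concordance with weights Ĝ(y)⁻² truncated
at the 80th percentile of observed times by default, and the IPCW
cumulative/dynamic AUC averaged over a default grid of event-time
deciles (extremes excluded) for survival; Dice similarity (1.0 for two
empty maps) for segmentation.  The censoring distribution Ĝ is
estimated on training outcomes.  The weighted estimators are backed by
scikit-survival; the test suite checks them against independent
double-loop pair enumerations to 10⁻¹⁰.

## Numerical conventions

Probabilities are clamped to [10⁻⁷, 1−10⁻⁷] before logarithms; the
Dice denominator carries a 10⁻⁵ smoothing term so empty/empty maps
score 0; NPLL risk sets use the closed comparison y_j ≥ y_i (censored
patients remain at risk through their censoring time); risks are
shifted by their maximum before exponentiation; the voxel rule assigns
p = 0.5 to background; boundary risk values go to the low-risk group.
Problem sizes in the test suite (n = 2000 for recovery, 20 seeds of
n = 1000 for the dynamic-benefit sign test, 30 training phantoms at
32³ for segmentation) were chosen as the smallest scales at which the
corresponding statistical claims are stable.

## Known limitations

Single-CPU numpy training limits the imaging arm to reduced
resolutions; the clinical-scale 128³/1 mm configuration is exposed but
untested.  The NPLL is full-batch (no within-batch risk-set
subsampling), so very large cohorts would need batching by risk-set
chunks.  Competing risks, time-varying covariates, Efron tie handling
and Bayesian imputation of missing clinical data are out of scope.
Threshold-search p-values are not corrected for the cutoff
optimization beyond the learning/held-out separation noted above.
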