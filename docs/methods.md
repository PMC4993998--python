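# Methods

`fcfmtex` asks a two-source prediction question: given a clinical/radiological
covariate vector x₁ and a label-free FCFM video x₂ of a solitary pulmonary
nodule, does p(y₁ | x₁, x₂) beat the published clinical calculator
p(y₁ | x₁)? This note records the models, the synthetic data they are tested
on, the numerical choices, and what the tests do and do not demonstrate.

## Video texture features

All three schemes reduce a video to one fixed-length vector by extracting a
per-frame representation over the manually annotated on-target segments only
and mean-pooling across frames, so no feature depends explicitly on the number
of frames.

**riu2 LBP (80-d).** At each pixel, the P neighbours at angles 2πp/P on a
radius-R circle are compared to the centre (neighbour ≥ centre → bit 1;
off-grid neighbours bilinearly interpolated). Patterns with ≤ 2 circular bit
transitions are binned by popcount, the rest pooled in one miscellaneous bin:
P + 2 bins per resolution, normalized per frame. Resolutions
(1,8), (2,16), (3,24), (4,24) concatenate to 10+18+26+26 = 80. Two deliberate
conventions: (i) pixels whose sampling circle crosses the *frame bounds* are
skipped, but pixels near the circular FOV boundary are not — they are a ~1%
minority and a per-radius FOV-erosion mask buys nothing measurable; (ii) the
comparison interpolates the neighbour−centre *difference* rather than the raw
neighbour value, which makes the ≥ tie-break exact in floating point (a
constant neighbourhood yields exactly the all-ones pattern).

**Bag of visual words (1024-d).** Dense-SIFT descriptors (4×4 spatial bins ×
8 orientation bins, rotation fixed at 0, L2-normalize / clip 0.2 /
re-normalize; "scale" = spatial bin side in pixels) are sampled at up to 8192
uniformly random (on-target frame, in-circle location, scale ∈ {2,4,6,8,10})
triples per video — dense extraction of full videos is memory-prohibitive.
Training-fold descriptors are pooled and clustered into k = 1024 visual words
(k-means++, one seeded run, ≤ 300 iterations, tol 1e-4); each video becomes a
nearest-centroid assignment histogram. Ties break to the lowest centroid
index. Fold discipline is structural: in cross-validation the codebook is a
function of training-fold videos only. k ∈ {512, 2048} are supported but
non-default (they perform worse in practice).

**Scattering transform (1401-d).** A two-layer Morlet wavelet-modulus cascade
(J = 7 dyadic dilations, L = 8 rotations in [0, π), kymatio-style filter
parameters σ = 0.8·2ʲ, ξ = 3π/4·2⁻ʲ, slant 4/L; Gaussian low-pass) applied to
the largest axis-aligned square inscribed in the FOV circle, resized to
128×128 and min-max normalized per frame (FCFM dynamic range varies wildly
between videos — normalization per video would leak cross-frame scale).
Second-order paths are restricted to increasing dilation j₂ > j₁; with
2J = log₂(pixels) every path retains a single coefficient, giving
1 + JL + L²J(J−1)/2 = 1401. Numerical realization: because pooling to one
retained sample of a unit-mass low-pass equals global averaging, each
coefficient is the spatial mean of the modulus along its path; second-layer
inputs are subsampled by max(2^j1, 2) via exact Fourier periodization (the
modulus is low-frequency-dominated, so the aliasing cost is negligible
against a ~5× runtime gain); the cascade runs in single precision. Histogram
equalization before the transform exists behind a flag, default off — it does
not help.

## Classifiers

All classifiers expose malignancy probabilities; the ~3:1 benign:malignant
imbalance is modest and no explicit correction is applied.

* **Lasso logistic GLM** — Bernoulli likelihood, logit link, L1 penalty;
  features standardized internally, intercept unpenalized. λ is selected by
  5-fold CV deviance over 100 candidates: λ = 0 plus 99 geometric points in
  [10⁻³ λ_max, λ_max], λ_max = max|X'(y−ȳ)|/n being the smallest λ that zeroes
  every coefficient (so at λ_max the model predicts exactly the class
  prevalence). The λ-grid search uses liblinear for speed (its 1:100
  intercept-penalty spread does not move the deviance argmin); the final model
  refits with saga, whose intercept is exactly unpenalized.
* **GP classifier** — probit likelihood, expectation propagation. Prior:
  constant mean m, isotropic squared-exponential kernel s·exp(−‖Δ‖²/2σ²).
  EP is implemented on the zero-mean part of the process (the constant mean
  enters the probit moment matching), with sequential site updates, a full
  Cholesky refresh per sweep, ≤ 15 sweeps, site precisions floored at 1e-10.
  Hyperparameters (m, log σ, log s) maximize the EP marginal likelihood by
  L-BFGS-B (numerical gradients, ≤ 30 iterations) from the initial guesses:
  mean of the ±1 outputs, median pairwise distance, 1. Probit rather than
  logistic likelihood because EP's moment matching is closed-form only for
  the probit; a Laplace-approximation GPC (scikit-learn) serves as an
  independent ranking cross-check in the tests.
* **Random forest** — 100 bootstrap trees, minimum 3 samples per leaf,
  ⌈√d⌉ candidate features per split, Gini criterion; the reported probability
  is the fraction of tree *votes*, not averaged leaf posteriors.
* **Plain logistic** — unpenalized ML, for the 12/13-feature clinical models
  (the 13th feature being a blinded expert's benign/malignant call).

## Risk calculators and fusion

Mayo (Swensen 1997) and Brock (McWilliams 2013; the full published variant
with spiculation, nodule-type and emphysema terms) are evaluated from
coefficient tables stored as data with source citations; a missing covariate
raises rather than imputes. Both models are validated against hand-computed
logistic values at 1e-6.

Fusion combines p(y₁|x₁) and p(y₁|x₂) per class and renormalizes:

* product-over-prior: score_k = p(y_k|x₁)p(y_k|x₂)/P(y_k) — the Bayes rule
  under class-conditional independence; priors default to training prevalence;
* α-mean: m_α = power mean of order (1−α)/2, the unique standard family
  matching all four special cases (arithmetic α=−1, geometric α=1, min α=∞,
  max α=−∞); candidate grid α ∈ {−∞, −4, −2, −1, 0, 1, 2, 4, ∞}.

Probabilities are clipped to [1e-6, 1−1e-6] before multiplicative forms.
The best rule is chosen by AUC on the evaluation split itself (not nested);
this mirrors a deliberately optimistic selection and is flagged in the
results summary. Ties prefer the product rule, then the smallest |α|.
Note the two rules are genuinely different even at uniform priors: the
normalized geometric mean √(p₁p₂)/(√(p₁p₂)+√(q₁q₂)) is not the normalized
product p₁p₂/(p₁p₂+q₁q₂) — e.g. p₁=p₂=0.8 gives 0.8 vs 16/17.

## Evaluation protocol

Patients are split into 5 stratified folds (the grouping unit is the patient,
so a video never straddles train/test; stratification keeps every fold
two-class at 3:1 imbalance). Out-of-fold probabilities are pooled and
summarized by the Mann–Whitney AUC (midranks for ties). Two calibration
devices: a Monte-Carlo null band — (0.05, 0.95) quantiles of AUC under
uniform random scores, 10,000 draws — and an exact one-sided binomial sign
test over per-split AUCs from 16 redrawn splits (seeds = base + repeat index;
ties dropped; p = P[Bin(n, ½) ≥ k]).

A caveat the tests quantify: pooled out-of-fold CV AUC has heavier tails than
the uniform-score null band, because each fold's classifier carries its own
small calibration offset and an offset shared by a fold's scores moves many
rank comparisons at once. The effect shrinks as per-video features get less
noisy (more frames averaged); with 20 frames per video the scattering+RF
null cohort lands inside the band in ~85% of seeds, with 6-frame videos only
~75%. The calibration test therefore keeps 20 frames per video.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, with
ground truth:

* **Frames** — bright curvilinear fibres over dark background inside a
  circular FOV: persistent random walks (von Mises turning angles with
  concentration = orientation coherence; step 1 px; length 0.4–1 × frame
  side; Poisson fibre count at `fibre_density` per 1000 px² of FOV),
  rasterized, Gaussian-blurred to `fibre_width`, plus additive Gaussian noise
  clipped at 0; quantized to uint16.
* **Class effect** — one scalar δ shifts (density, width, coherence) jointly
  by ±δ/2 of their between-video SD (baselines 1.2 / 2.2 px / 8.0; SDs
  0.25 / 0.35 / 1.6; within-class jitter 0.5 SD). One knob for power studies;
  δ = 0 makes classes exchangeable by construction.
* **Dynamic range** — per-video gain ~ U(0.5, 1.6) and offset ~ U(0, 0.12)
  applied after synthesis.
* **Clinical coupling** — 12 covariates from physiologic ranges (age
  N(67,9²) clipped to [35,90]; nodule size log-normal, median 12 mm, clipped
  to [4,30]; 80% smokers; etc.); labels Bernoulli(logistic(b₀ + c·η)) with η
  the standardized Mayo-style score and b₀ solved by root-finding so the
  expected prevalence is 25/91. `clinical_effect` c scales calculator signal;
  c = 0 decouples labels entirely.
* **Frame counts** — log-normal; defaults are the test scale (128 px frames,
  median 20 frames); `SyntheticConfig.paper_scale()` gives 500 px frames and
  median 159 with shape 0.6, matching on-target quartiles near 97/159/219.
  Videos get 1–2 on-target segments separated by an off-target noise frame.

What the generator does **not** emulate: breathing/fibre-motion artefacts,
bronchial (non-alveolar) structure, contrast-agent appearance, smoking-status
effects on autofluorescence, and any calibrated correspondence between δ and
real benign/malignant texture differences (no quantitative texture statistics
for the real classes are available). Passing tests therefore demonstrate that
the pipeline is correct and recovers/respects signal when it exists — not
that real FCFM texture carries (or lacks) signal.

## Problem sizes used by the heavy tests

Chosen as the package's own test scale: texture-effect recovery runs one
δ = 2 cohort at n = 100 videos × 20 frames × 128 px (scattering+RF above the
null band's 0.95 quantile); null calibration runs 20 seeds of δ = 0 cohorts
at n = 40 × 20 frames × 64 px (J = 6, preserving 2J = log₂N); the
no-imaging-signal fusion pattern runs one n = 91 cohort with LBP features,
two classifiers and both calculators, 16 CV splits each.

## Known limitations

* EP marginal-likelihood optimization uses numerical gradients; with ≤ 30
  L-BFGS-B iterations the hyperparameters are near- rather than fully
  converged (adequate at n ≲ 200; the analytic-gradient extension is the
  obvious upgrade).
* The scattering bank ignores boundary effects (circular convolution on the
  cropped square) and subsamples aggressively at the second layer; kymatio's
  oversampled pipeline would differ in the third digit of individual
  coefficients, not in downstream AUC.
* The sampled-descriptor BoW pipeline never builds the dense per-pixel
  descriptor field, so codebooks are sampling-noise-dependent at small caps.
* `choose_best_rule` selects on the evaluation split; its AUC is optimistic
  by construction and should be read against the sign test, not alone.
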