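# Methods

This note documents the models, numerical choices and assumptions behind
`xerpred`, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Endpoint and feature set

The endpoint is `XER_12`: RTOG salivary toxicity grade ≥ 2 twelve months
after radio(chemo)therapy, treated as the positive class throughout
(sensitivity = detection of toxicity). The predictor surface combines

* baseline perfusion heterogeneity of the combined parotids
  (`Ktrans_P10`, `ve_P25` — 10th/25th percentiles of voxel-wise Tofts
  parameters, both parotids pooled into one voxel sample per patient),
* planned dose metrics (`Dmean_Gy`, `V65_pct` for the combined parotids,
  `Dmean_SMG_Gy` for the submandibular glands),
* the in-treatment acute-symptom integral `XQ_Int_mid`.

## Diffusion fitting

Voxel signals follow the IVIM form
S(b) = S₀·[f·e^(−b·D*) + (1−f)·e^(−b·D_t)]. Both clinical coefficients are
mono-exponential fits by damped nonlinear least squares on the raw signal
(Levenberg–Marquardt, initialised from the log-linear OLS solution;
parameter/function tolerances 1e-12, ≤ 200 iterations): **ADC** on
b = 0, 500, 800 s/mm² and **D_t** on b = 300, 500, 800 s/mm², where the
pseudo-diffusion term is suppressed by at least e⁻³ for D* ≥ 0.01 mm²/s.
Raw-signal (rather than log-domain) fitting weights high-signal samples
appropriately under additive noise. Negative diffusion estimates are
clipped to zero and flagged instead of discarded, so per-gland voxel
accounting is preserved; ROI summaries take the median over converged
voxels only. Voxel-wise fitting with median aggregation is the default
(fitting ROI-mean signals is possible by passing an averaged signal).

## DCE pharmacokinetics

No T1 mapping is acquired, so signal is converted to a concentration
*proxy* by relative enhancement, C(t) = κ·(S−S_base)/S_base with κ = 1 and
S_base the mean of the three pre-bolus phases. Absolute K^trans values are
therefore convention-dependent; all recovery statements are round-trip
consistent under the same convention, which is also how the package is
validated.

The tracer model is the standard Tofts model (no plasma-volume term, since
only K^trans, K_ep, v_e are used downstream) driven by a population
bi-exponential plasma curve of Weinmann type (amplitudes 3.99 and
4.78 kg/L, decay rates 0.144 and 0.0111 min⁻¹, dose 0.1 mmol/kg), zero
before the bolus arrival. The convolution is evaluated by an exact
recurrence equivalent to trapezoidal quadrature on a 10×-refined uniform
grid (the refinement keeps the quadrature error of the sharp bolus onset
negligible; the fitted curve and the generated curve share the same
evaluator, so round trips are exact). The fit parameterises
(K^trans, δ = K_ep − K^trans) with bounds K^trans ∈ [0, 5] min⁻¹ and
δ ∈ [0, 50] min⁻¹, which enforces v_e = K^trans/K_ep ≤ 1 structurally; the
identity v_e·K_ep = K^trans then holds to machine precision on every fit.
Three multi-start initialisations guard against local minima, plus a
boundary candidate at K^trans = 0 so flat series fit exactly.

Bolus arrival is detected as one sample interval before the first sample
exceeding 10% of the concentration maximum (floored at 0); no single rule
is standard in the field, so the threshold is configurable. The
IAUGC is the trapezoidal integral over [arrival, arrival + 90 s] with
linear interpolation at window edges.

At realistic noise the (K^trans, K_ep) estimates are strongly ridge-
correlated; with the population AIF at κ = 1 the peak relative enhancement
is only ≈ 0.12, so noise levels should be read against the *enhancement*,
not the baseline signal. At an enhancement SNR near 20 the median
K^trans recovery error is a few percent (measured in the test suite);
at much lower SNR a systematic shrinkage along the ridge appears, as
expected for this estimator class.

## Histogram features

Percentiles use linear interpolation between order statistics; skewness is
Fisher–Pearson g1 = m₃/m₂^1.5 and kurtosis is excess g2 = m₄/m₂² − 3
(normal ⇒ 0). Energy Σp_k² and entropy −Σp_k·log₂p_k use 64 equal-width
bins spanning the observed [min, max]; the bin count is an assumption
(unstated in the source literature) and is configurable. Zero-variance
maps take the degenerate conventions skewness = kurtosis = 0, energy = 1,
entropy = 0.

## Dosimetry

Cumulative DVHs store "% volume receiving ≥ dose" at 0.1 Gy bins. D_mean
uses the differential-DVH midpoint rule, accurate to half a bin width
(worst case: all dose exactly on a bin edge). V_x interpolates the
cumulative curve linearly. Gland combination is the volume-weighted
average of the cumulative curves. Mid-treatment DVHs are interpolated (or
extrapolated) linearly per dose bin along the fraction-number axis — the
simplest faithful reading of re-planned DVH interpolation — with results
clipped to [0, 100] and monotonicity repaired by a running maximum from
the high-dose end (warned) when extrapolation breaks it. Submandibular
DVHs are handled identically to parotid ones under a structure tag.

## Questionnaire indicators

Weekly totals (8 items × 0–10) are fitted by OLS on {1, t, t²} with t in
weeks from the start of radiotherapy (missing weeks simply drop rows).
Mid-treatment is week 3: the 15th of 35 fractions at 5 per week; the
choice of weeks (not fractions) as the time axis only rescales the
integral by a constant shared by all patients. Gradients are the fitted
derivative at t = 1 and t = 4; the integral over [0, 3] is analytic and
floored at zero (flagged) in the rare case the fitted curve is net
negative.

## Modelling procedure

Per candidate feature subset: stratified 5-fold CV with a fixed seed.
Inside each fold, strictly train-only preprocessing: z-score statistics
fitted on the training rows (population SD; zero-variance features
dropped with a warning), then ADASYN oversampling of the minority class
on the standardised training rows, then a CART decision tree (Gini,
max_depth 4, min_samples_leaf 5 — defaults chosen as conventional
small-sample values, config-exposed). Test folds never see synthetic
points or training statistics; a dedicated test verifies that perturbing
a held-out row leaves its fold-mates' scores unchanged.

ADASYN generates G = (n_maj − n_min)·ratio synthetic points, allocated to
minority points by the fraction of majority samples among their k = 5
nearest neighbours (largest-remainder rounding so the count is exact) and
placed uniformly on segments to one of the k nearest *minority*
neighbours — every synthetic point is a convex combination of two real
minority points. If no minority point has majority neighbours the
allocation falls back to uniform with a warning.

Pooled test predictions across folds feed the metrics: AUC as the
normalised Mann–Whitney rank statistic (ties averaged) with a
bias-corrected-and-accelerated bootstrap CI (B = 2000, paired resampling,
seeded); proportion metrics at the 0.5 score threshold with Wilson CIs.
Models with pooled AUC ≤ 0.6 are screened out. Model pairs are compared
by the mid-p McNemar test on per-patient correct/incorrect pooled CV
predictions, with discordance defined as A-correct∧B-wrong vs
A-wrong∧B-correct; mid-p = 2·[P(X ≥ max(b,c)) − ½·P(X = max(b,c))] for
X ~ Bin(b+c, ½), capped at 1, p = 1 when b = c or b + c = 0.

Statistical wrappers use exact small-sample regimes (Mann–Whitney exact
enumeration for n ≤ 8 per group without ties; Wilcoxon exact for ≤ 25
nonzero untied differences) and asymptotic forms otherwise. The
univariate screen reports raw p-values without multiplicity correction, a
faithful reproduction of common practice rather than an endorsement.

## Synthetic cohort generator

The generator defines the study conditions; it emulates the statistical
structure the analysis assumes, not images. Defaults: 63 patients,
prevalence 1/3, 100 voxels per gland (two glands pooled), 7 weekly
questionnaire samples, additive Gaussian signal noise (DWI 2% of S₀,
DCE 1% of S₀ ≈ enhancement SNR 12, XQ SD 4 points). Voxel counts and SNR
are unreported in the source setting and are documented assumptions.

* **Feature marginals** are log-normal (positive, right-skewed — consistent
  with the skewness/kurtosis analysis the feature set supports), with
  medians and IQR-derived log-SDs set to the configured group statistics
  (defaults: grade < 2 vs grade 2 medians of K^trans-P10 0.28/0.21 min⁻¹,
  v_e-P25 0.15/0.13, D_mean 35.8/41.0 Gy, V65 6.5/10.1%, D_mean,SMG
  62.5/64.2 Gy, XQ_Int_mid 51.5/82.9). A Gaussian copula correlates the
  log-features (dose block r ≈ 0.4–0.7, the two perfusion summaries
  r = 0.6, symptom integral vs dose r ≈ 0.25–0.35) — without these
  correlations the requested simultaneous group separations would exceed
  what any single logistic mechanism can generate.
* **Labels** are Bernoulli(logistic(α + Σβ·z)) on the z-scored log
  features. β is solved in closed form (probit approximation of the
  logistic link, scale 1.7) from the requested group-median separations,
  so the generated group-conditional medians land on the configured
  targets; α is solved by root finding so the cohort's expected prevalence
  equals the configured value exactly. If a requested separation exceeds
  the mechanism's capacity the effect vector is scaled down with a
  warning. Because the solve is conditional-on-correlations, individual
  coefficients need not share the sign of their marginal separation.
* **Raw data** are synthesised per patient consistently with the latent
  features: log-normal voxel K^trans/v_e fields whose population
  P10/P25 equal the patient's latent values, IVIM decays
  (D_t median 1.0e-3 mm²/s, f ≈ 0.1, D* ≈ 0.05 mm²/s), Tofts dynamic
  series (60 phases, 5 s, bolus after 3 baseline phases), a two-component
  dose distribution (≥ 65 Gy boost with weight V65/100 plus a low-dose
  bath solved from D_mean; infeasible V65 draws are clamped with a
  warning), and a rising quadratic questionnaire trajectory (zero at
  week 0, vertex at week 6) whose analytic mid-course integral equals the
  latent `XQ_Int_mid`, split into integer item scores.

What the generator does **not** emulate: spatial anatomy and image-domain
effects (voxels are exchangeable), Rician noise (additive Gaussian is
indistinguishable at SNR ≥ 20; the noise type is where a Rician variant
would plug in), scanner drift/motion/registration error, questionnaire
item-level psychometrics, and any dose–image spatial coupling. Passing
tests therefore demonstrate correctness of the estimators and the
modelling harness under the assumed generative structure — not clinical
performance on real patients.

## Problem sizes and determinism

Monte-Carlo checks use sizes chosen for statistical resolution at desk
scale: 1000 voxels for diffusion bias, 1000 noiseless voxels for Tofts
recovery, 100 null-cohort replicates (n = 200) for the CV-AUC null, and a
300-patient cohort for the end-to-end discrimination check — the latter
because 5-fold CV AUC at the default 63 patients has a sampling SD of
several hundredths, too coarse to characterise the pipeline itself. All
randomness flows from explicit seeds; identical configurations reproduce
byte-identical cohorts and run manifests (SHA-256-verified).

## Known limitations

* Absolute pharmacokinetic values depend on the κ = 1 enhancement proxy
  and the population AIF; only round-trip and rank statements are
  meaningful.
* The DVH interpolation axis (linear per bin in fraction number) is one
  defensible reading; callers with accumulated-dose semantics should
  interpolate their own curves.
* The decision-tree hyperparameters and the 0.5 classification threshold
  are conventions, not tuned values; the catalog runner exposes both.
* BCa bootstrap CIs for the AUC can be undefined on resamples lacking a
  class; with n ≳ 100 and prevalence 1/3 this is negligible.
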