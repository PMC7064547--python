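# Methods

## The learning-curve model

Each Goalkeeper Game stage yields a sequence of binary outcomes
X_t ∈ {0, 1}, t = 1..T: whether the player predicted the penalty-kick
direction correctly among three options. gglearn models the trials as
conditionally independent Bernoulli draws with

    λ_t = (t − 1)·β − log(3γ − 1)
    P(X_t = 1) = γ · exp(λ_t) / (1 + exp(λ_t))

a generalization of logistic regression in the trial index with two
interpretable parameters per patient-stage:

* **γ** — the asymptotic success probability ("total learning"),
  constrained to (1/3, 1]: after many trials performance settles at γ,
  and it can never be below the three-option chance level.
* **β ≥ 0** — the per-trial learning rate: how fast the curve climbs
  from chance to γ. β = 0 leaves the curve flat at 1/3. A config switch
  (`allow_negative_beta`) admits "forgetting" curves for sensitivity
  analyses; the default excludes them because the asymptote
  interpretation of γ requires a non-decreasing curve.

The parameterization pins P(X_1 = 1) to exactly 1/3 for every valid
(β, γ): at the first trial the player has no information and three
options. The product-form likelihood (independence given parameters) is
the only reading consistent with the model statement; both the pin and
the normalization of the likelihood over all 2^T sequences are enforced
by tests.

## Posterior estimation

Each patient-stage is fitted independently (no hierarchical pooling).
Priors are weakly informative on the constrained domain:

* γ ~ Uniform(1/3, 1);
* β ~ Half-Normal(scale 2), truncated at β = 8 for quadrature
  (removing < 1e-4 of prior mass). The scale comfortably covers
  empirically observed learning rates (cohort means near 2).

The posterior is summarized by deterministic midpoint tensor-grid
quadrature, 240 × 240 nodes by default. For a two-parameter smooth
posterior this is accurate far below reporting precision (tests require
agreement within 0.01 with an independent 200 × 200 brute-force grid),
exactly reproducible without a sampler seed, and fast: all patients
sharing a stage length are fitted in a single matrix product, so a
74-patient cohort (222 fits) takes well under a second. Point estimates
are posterior means by default (marginal median and mode are
selectable); intervals are central credible intervals (90% default,
interpolated from the marginal grid CDF). For sensitivity analyses the
prior can be switched to an unconstrained Normal(0, 2) on β over
[−8, 8], admitting "forgetting" curves.

**Weak identification.** A 5-trial stage cannot pin down both
parameters. Rather than failing, the fitter flags a patient-stage when
its posterior interval is wider than half the prior's central interval
at the same level (for γ at 90%: wider than 0.30 of the 0.60 prior
interval). Degenerate sequences (e.g. all failures) produce wide,
flagged posteriors pulled toward the chance boundary.

The 9-variable feature vector per patient is (β̂₁..β̂₃, γ̂₁..γ̂₃,
t̄₁..t̄₃), where t̄_s is the plain arithmetic mean response time of
stage s in seconds — no outlier trimming, consistent with reported
response-time dispersions exceeding their means.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
with known ground truth. Defaults are the study conditions: 74
patients; 5 / 20 / 5 trials for the motor-baseline, learning and memory
stages.

* **Parameter populations.** Per stage, β is lognormal and γ is a
  shifted-scaled logit-normal on (1/3, 1); both are moment-calibrated
  (closed form for β; Gauss–Hermite + root finding for γ) so the
  population mean/sd of the *true* parameters equal the published
  cohort-level estimates: β means 1.74/1.76/2.00 (sd 0.53/0.38/0.37),
  γ means 0.68/0.64/0.78 (sd 0.16/0.14/0.18). Parameters are drawn
  independently across stages (a correlation structure is plausible in
  real patients but unreported; independence is the explicit default).
* **Response times.** Lognormal per trial with per-stage medians
  4.47/3.28/2.52 s and σ = 1, giving the heavy right tail (sd > mean)
  seen in real response-time summaries.
* **Clinical scores.** A latent trait z = Σ w_k·standardized(true
  feature k) + ε, ε ~ N(0,1). DGI (0–24) is z thresholded into 25
  ordered categories whose marginal is a discretized normal (mean 19,
  sd 3.5 — a realistic mildly left-concentrated distribution for an
  ambulatory Parkinson's cohort); this is exactly a proportional-odds
  construction, so the generator and the downstream ordinal analysis
  are coherent. MoCA shares a weak link with z and is truncated at
  ≥ 21, mirroring the study's no-dementia inclusion criterion.
* **Link calibration.** `calibrate_link` inverts
  corr(f_k, z) = w_k/sd(z) in closed form and rejects jointly
  infeasible targets (Σr² ≥ 1). The default targets are the
  moderately-to-strongly associated variables of the published
  association table: γ₃ 0.39 (dominant), γ₁ 0.24, t̄₁ −0.23, t̄₃
  −0.24, and MoCA–DGI 0.20.

What the generator does **not** emulate: within-patient cross-stage
parameter correlation, severity-stage (HY) progression effects,
demographic effects on learning (age/sex/HY are decorative columns
only), non-stationary response times, and any deviation from the
learning-curve model itself. Passing tests therefore demonstrate
internal consistency of the method chain under its own assumptions, not
validity on real patients.

Note one deliberate consequence of short stages: with 5 memory-stage
trials, β̂₃ and γ̂₃ are posteriorly correlated, so part of the true γ₃
signal surfaces in the β̂₃ column of the association table. This
attenuation/leakage is a property of the design (5 trials), not of the
estimator.

## Association analyses

* **Polyserial / polychoric correlations** are two-step ML under a
  latent bivariate normal: thresholds from each ordinal margin's
  cumulative proportions (hence invariance to monotone relabeling),
  then a bounded 1-D likelihood maximization over ρ. Discrete–discrete
  pairs (MoCA–DGI) use the polychoric estimator; continuous–discrete
  pairs (each game variable vs DGI) use the polyserial — the only
  assignment consistent with the estimators' definitions. Bivariate
  normal rectangle probabilities are computed from Owen's T function
  (machine precision, fully vectorized); empty cells need no merging.
  P-values are likelihood-ratio tests of ρ = 0 (the original analysis
  does not state its test; LR is the natural choice for an ML
  estimator). Boundary estimates (|ρ̂| ≥ ~0.99) are flagged.
* **Proportional odds.** Cumulative-logit ML via statsmodels
  `OrderedModel`, raw (per-unit) coefficients by default, Wald
  p-values, convergence flagged. With two response categories the fit
  reduces to ordinary logistic regression (tested to 1e-6).
* Complete-case analysis throughout; no multiple-testing correction is
  applied and raw p-values are reported, matching the unadjusted
  published tables.

## Classifier comparison

DGI is dichotomized at its sample median; "above" is read strictly, so
ties at the median join the lower class (rule logged, configurable by
relabeling). Two arms are evaluated with *identical* outer folds: the
nine game variables, and the single MoCA score.

* Elastic-net logistic regression (scikit-learn saga), per-fold
  standardization inside a pipeline; mixing parameter 0.5 by default.
* Repeated stratified k-fold CV: 10 folds × 10 repeats by default.
  Penalty strength is chosen by nested inner CV (5-fold, logarithmic
  grid 1e-2..1e2) on training folds only, minimizing log-loss. With a
  single predictor the penalty is inert and the search is skipped.
* Accuracy is the mean over repeats of pooled out-of-fold accuracy at
  threshold 0.5; the per-patient score is the repeat-averaged
  out-of-fold probability, from which ROC/AUC are computed.
* The binomial test against chance is exact and two-sided by default
  (one-sided available).  One caveat is inherent to a median split of a
  discrete score: ties at the median all fall to the lower class, so
  the labels are imbalanced (typically ~56/44 at n = 74 with the
  default DGI marginal) and the majority rate — not 50% — is the
  accuracy of an information-free classifier.  Null-calibration
  experiments therefore use balanced chance labels, for which "chance =
  50%" is well-posed; against imbalanced null labels the accuracy
  distribution centers at the majority rate and the coin-flip binomial
  test over-rejects.  Comparisons *between* arms are unaffected, since
  both arms face the same labels and folds.
* DeLong's test uses placement values and the structural-components
  covariance estimator; the one-sided alternative "game AUC greater"
  matches the scientific question. Zero-variance differences are
  flagged degenerate rather than producing a spurious p-value.

## Numerical choices and problem sizes

* Quadrature: midpoint rule; γ grid open at 1/3 (nodes at cell
  centers); likelihood clipped at 1e-300 before logs; interval
  endpoints interpolated and minimally widened if needed so that the
  interval always contains the point estimate.
* Correlation optimizer: bounded scalar minimization on
  [−0.9995, 0.9995], xatol 1e-7; cell probabilities clipped at 1e-300.
* Simulation-heavy tests and experiments use reduced but statistically
  adequate sizes chosen once: 120 × 120 quadrature grids for cohort
  batches (grid error ~1e-3, two orders below sampling noise); 5-fold ×
  1-repeat CV with a 5-point penalty grid for level (null) studies and
  10-fold × 3 repeats with the default grid for power (arm-contrast)
  studies; 200 replicate cohorts for null/positive-control studies, 100
  replicates for recovery, 500 for DeLong type-I error.  The inner
  penalty search fits a warm-started ascending-C path at a looser
  tolerance (1e-3) than the final per-fold fits (1e-4): the path only
  ranks penalties.
* Seed fan-out: the pipeline's global seed derives per-module seeds via
  `numpy.random.SeedSequence(seed, spawn_key=(i,))`, kept below 2^31;
  every output file carries a manifest line with the seed and a
  configuration hash, and the whole pipeline is byte-reproducible.

## Known limitations

* With 5-trial stages the per-stage estimates are strongly
  prior-influenced; population-level conclusions from stages 1 and 3
  lean on the generator's calibration, as they would on the prior in a
  real analysis.
* The polyserial estimator assumes the continuous margin is normal;
  true γ draws are logit-normal, so recovered correlations are
  attenuated by roughly 0.01–0.02 at the default settings.
* The exact CV scheme, priors and elastic-net mixing of the original
  analysis are not recoverable; defaults here are standard practice and
  all are exposed as configuration.
* The binomial test treats out-of-fold predictions as independent;
  with cross-validation this is approximate, and its level is verified
  empirically (≤ 7% at nominal 5%) rather than assumed.
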