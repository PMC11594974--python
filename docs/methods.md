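# Methods

## Model and estimation

`donorcalc` fits a Weibull accelerated failure time (AFT) model to
right-censored overall-survival data: given covariates $x$, survival time
$T$ is Weibull with scale $e^{\mu}$, $\mu = \beta \cdot x$, and shape $k$.
The log-likelihood sums $\log f$ over deaths and $\log S$ over censored
records,

$$\ell = \sum_{\text{events}} \big[\log k - k\mu_i + (k-1)\log t_i - (t_i e^{-\mu_i})^k\big] \; - \sum_{\text{censored}} (t_i e^{-\mu_i})^k .$$

Two equivalent shape conventions exist in the AFT literature: the Weibull
shape $k$ and the smallest-extreme-value scale $\sigma = 1/k$ of
$\log T$. The code treats $k$ as canonical; the summary table's `Shape` row
reports $k$, with its confidence interval formed on the $\log k$ scale and
exponentiated (hence asymmetric about the estimate).

Optimization is deterministic: BFGS with the analytic gradient in the
unconstrained parameterization $(\beta, \log k)$, started from the
closed-form intercept-only exponential fit (intercept = log(total follow-up
/ number of deaths), $k = 1$), then Newton steps with the analytic Hessian
until the gradient sup-norm is at most 1e-8. The reported covariance matrix
is the inverse observed information at the optimum, on the $(\beta, \log k)$
scale. Zero-day follow-up times (day-0 deaths exist in registry data, and
the likelihood is undefined at $t=0$) are shifted to 0.5 days with a logged
warning; the shift is configurable. A rank-deficient design aborts with the
collinear columns named; non-convergence is flagged on the result, never
silent.

## Default specification

Factors are dummy-coded against a reference level: diagnosis group
(reference 1, acute leukemias), donor type (reference HLA-identical
sibling), optionally comorbidity class (reference 0). Patient and donor age
enter in raw years, uncentered — the shipped coefficient set reproduces its
published worked example only with raw ages, which pins the convention.
Interactions are elementwise products. Without comorbidity the design has
15 columns; with it, 17. Disease status at transplant is carried in the
data model and can be added as a factor for sensitivity analyses, but is
excluded from the default specification.

The bundled reference coefficient set has no comorbidity rows, so
predictions from it treat comorbidity as the reference class; fitting on
cohort data includes comorbidity by default. Both specifications are
first-class (`default_spec(include_comorbidity=...)`).

## Prediction, intervals, hazard ratios

Survival at a horizon (default 730 days) is
$S(t) = \exp(-(t e^{-\mu})^k)$. The confidence interval is a delta-method
interval on the smallest-extreme-value linearized scale
$z(t) = k(\log t - \mu)$, whose gradient in $(\beta, \log k)$ is
$(-k x,\; z)$; the Wald interval on $z$ maps through the monotone
$S = \exp(-e^z)$, keeping endpoints inside $(0,1)$. The published source of
the reference model does not state its interval method; the delta method is
this package's documented choice. Hazard ratios between donor options for
the same patient use the Weibull PH–AFT identity
$\mathrm{HR}(a\,\text{vs}\,b) = \exp(-k(\mu_a - \mu_b))$, with a
delta-method CI on $\log \mathrm{HR}$ when a covariance matrix is
available. A coefficient-only model yields point estimates and hazard
ratios; interval fields are explicitly absent, never fabricated.

The comparison report ranks donors by predicted survival and groups donors
whose survival CIs mutually intersect ("comparable options"). Any
non-empty intersection counts as overlap; the rule is deliberately simple
and documented rather than a calibrated equivalence test.

## Validation

Harrell's concordance index is computed over usable pairs (the smaller
observed time must be a death); score ties count 1/2; the risk score is
$-\mu$. The Brier score at a horizon is inverse-probability-of-censoring
weighted: deaths before $t$ weighted by $1/G(T_i^-)$, subjects still under
observation by $1/G(t)$, censored-before-$t$ records dropped, with $G$ the
Kaplan–Meier estimate of the censoring distribution (left limits at event
times, per the standard IPCW construction). Cross-validation stratifies
folds on the death indicator (round-robin deal within each stratum after a
seeded shuffle), fits on $k-1$ folds, and scores held-out folds using the
training-set $G$; the concordance index is reported on pooled out-of-fold
risk scores.

## Distribution comparison

`compare_distributions` fits Weibull, exponential, log-normal and
log-logistic AFT models, computes Cox–Snell residuals (fitted cumulative
hazards, which are unit-exponential under a correct model, censoring
preserved), and scores each family with an Anderson–Darling-type statistic:
the AD-weighted squared distance between the Kaplan–Meier CDF of the
residuals and the unit-exponential CDF, accumulated over the exponential
measure between event residuals. This censoring-adjusted surrogate is this
package's own construction — commercial implementations of an "adjusted
Anderson–Darling" for censored regression are not publicly specified — and
it is used for ranking families, not as a calibrated test. AIC is reported
alongside.

## Synthetic cohorts

The generator emulates the structure of the modelled two-center cohort:

- donor-type mix SIB/MUD/HAPLO = 218/198/321; diagnosis groups
  306/114/317; comorbidity classes 423/256/58;
- patient age truncated-normal (mean 48, sd 13) on [21, 71];
- donor age per type: siblings ≈ patient age + N(0, 5) on [30, 57]; MUD a
  young-skewed Beta(2, 2.5) draw on [19, 48] independent of patient age;
  haploidentical donors a family-role mixture — offspring (patient age −
  generation gap, gap ≈ N(27.5, 3)), parent (patient age + gap), sibling —
  with the offspring weight growing with patient age, reproducing the
  observed bimodality (children donate to older patients, parents to
  younger ones), truncated to [19, 58];
- survival from the Weibull AFT truth model (default: the bundled
  reference coefficients) by inverse-CDF sampling;
- administrative censoring: uniform accrual over a window with a fixed
  analysis cutoff (censoring time = cutoff − accrual date). The default
  window/cutoff of 3150 days is an *effective* uniform-accrual window,
  shorter than the cohort's calendar span because real accrual was skewed
  toward recent years; it is calibrated so the default truth yields the
  observed ≈39.9% death fraction.

Sex, CMV serostatus, Karnofsky band and remission status are generated from
the cohort marginals for I/O realism but carry no survival effect under the
default truth. One seeded `numpy` generator drives everything; equal seeds
give byte-identical cohorts.

What the generator does not emulate: center effects, calendar-time trends
in practice (e.g. the growth of haploidentical transplantation),
covariate-dependent censoring, measurement error in diagnosis grouping, and
any GvHD/relapse processes. Passing tests on synthetic cohorts therefore
demonstrate the correctness and calibration of the machinery under the
model's own assumptions, not the clinical validity of the reference
coefficients.

## Problem sizes in the test suite

Parameter-recovery acceptance uses 500 replicate cohorts of n = 737 (at
this count the binomial standard error of an empirical coverage near 0.95
is about 0.01, small against the acceptance band [0.90, 0.98]); family
selection uses 50 seeds at n = 1500; oracle-equivalence checks use
hand-enumerable toys (≤ 25 records). Cross-validation sanity runs at the
study size n = 737 with 5 folds.

## Known limitations

- The reference coefficient set ships without covariance, so the default
  calculator cannot produce intervals; refitting on local data restores
  them.
- Wald inference throughout; no profile-likelihood or bootstrap intervals.
- No competing risks, frailty, time-varying covariates, or splines; ages
  are linear on the log-time scale.
- The concordance reported by cross-validation is the pooled out-of-fold
  variant; apparent (in-sample) concordance can be computed directly via
  `concordance_index` on fitted risk scores.
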