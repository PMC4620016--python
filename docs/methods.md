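# Methods

## Model

`hemolc` fits a finite-mixture joint model for a continuous marker and a
binary dropout outcome. The marker is the natural log of the cumulative RBC
units transfused by min(24 h, death); the outcome is death within 24 h. A
latent class label (K classes; K = 2 reads as severe hemorrhage, SH, vs
non-SH) ties together three submodels:

1. a multinomial-logit membership model on covariates `v` (class K is the
   reference; a single logistic regression when K = 2);
2. a class-specific Gaussian linear model for the marker on covariates
   `x_marker`, with one residual SD σ shared across classes — class-specific
   variances would make the mixture likelihood unbounded (a component can
   collapse onto a single point), so equal variance is a modelling
   assumption, not a convenience;
3. a class-specific logistic model for death on covariates `x_death`.

Marker and outcome are assumed conditionally independent given the class and
covariates ("local independence"). The three design matrices may differ;
`x_death` defaults to `x_marker`.

### Induced censoring

Death truncates transfusion, so for a patient who died the observed
cumulative amount understates the amount that would have been given. The
model assumes the observed amount is uniform on [0, true amount] on the
original (unit) scale; on the log scale the observed marker is the true
value plus log U, U ~ Uniform(0, 1). This yields a closed-form likelihood
factor for a censored record with class mean m = xᵀβₖ:

    ∫_y^∞ e^{−(u−y)} (1/σ) φ((u−m)/σ) du = exp(y − m + σ²/2) Φ((m − σ² − y)/σ),

i.e. an exponentially tilted Gaussian integral. The same tilt shows that,
conditionally on the observed value y, the uncensored marker is a
Normal(m − σ², σ²) truncated below at y, whose first two moments feed the
EM algorithm. The uniform-censoring assumption is untestable from the data;
it is the device that lets early deaths contribute information instead of
being discarded or treated as exact.

## Estimation

Maximum likelihood by EM, treating the class labels and the uncensored
markers of the dead as missing data.

- **E-step.** Posterior memberships by Bayes' rule over the K mixture
  components (censored marker branch for the dead), plus truncated-normal
  first and second moments for each censored record and class.
- **M-step.** α from a fractional-response multinomial logistic
  maximization (Newton–Raphson with step halving); each βₖ from weighted
  least squares with posterior weights and working response = observed
  marker (survivors) or conditional mean (dead); each γₖ from a posterior-
  weighted logistic regression of the death indicator; σ² from its closed
  form, using E[(z − xᵀβ)²] = E[z²] − 2E[z]xᵀβ + (xᵀβ)² for censored
  records.
- **Multi-start.** Each start draws per-patient soft labels from a
  symmetric Dirichlet, fits one weighted single-class model per component,
  and jitters the coefficients with N(0, 0.25) noise; data-informed starts
  of this kind converge far faster than random parameter draws. The default
  is 20 starts (the protocol appropriate for a one-shot data analysis);
  replicate-level simulation studies use 5 starts, tolerance 1e-6 and
  max_iter 500 (`study_config()`), because the benchmark scenarios are
  well separated and the lighter protocol reaches the same maximizer —
  spot checks against 20-start fits agree to the convergence tolerance.
- **Convergence.** Relative log-likelihood change below 1e-8 (default),
  max_iter 2000. The observed log-likelihood is monitored every iteration
  and is non-decreasing up to 1e-8 (an EM guarantee used as a self-test).
- **Label switching.** After fitting, classes are sorted by descending
  marker intercept β₀ₖ, so class 1 is always the high-transfusion (SH-like)
  class. This is a deterministic convention, not an inference.
- **Quasi-separation.** Any logistic subproblem whose coefficients exceed
  30 in absolute value (or whose Hessian is singular) is refit with a ridge
  penalty of 1e-4 and the fit is flagged. This arises naturally, e.g. when
  a class has (almost) no deaths.
- **Determinism.** A single integer seed spawns per-start substreams;
  identical seeds give bit-identical results.

Model size is counted as (K−1)·dim(v) + K·(dim(x_marker) + dim(x_death)) + 1
and BIC = −2·loglik + n_params·log n; the class count is chosen by argmin
BIC over a user-supplied range.

## Standard errors

The covariance of the estimates is the inverse of the empirical observed
information: the sum over patients of outer products of per-patient score
vectors. The per-patient scores are conditional expectations of the
complete-data scores given the observed data, which by Fisher's identity
equal the observed-data scores; the test suite verifies this against
central finite differences of the log-likelihood. σ enters the score vector
as log σ (the SD is positive, and the log scale makes its Wald interval
sensible); the SE of σ itself is available by the delta method. All
parameters — membership, marker, mortality, log σ — enter one joint
information matrix, so cross-parameter correlations propagate into the SEs.
A numerically singular information matrix falls back to a pseudo-inverse
with a warning and a flag. Wald z statistics use two-sided normal p-values.

## Classification

Patients are assigned the class with maximal posterior probability. For
K = 2 the SH posterior is additionally graded into seven bands
(0.80–1.00 "Group SH" down to 0.00–0.20 "Group non-SH"); intervals are
half-open [lower, upper) with the top band closed at 1.0 — the band table
does not dictate boundary ownership, so this is a package convention. A
posterior of exactly 0.5 sits in the "Uncertain" band and is hard-assigned
non-SH: when the evidence is exactly balanced the conservative action is
not to trigger a massive-transfusion response. The conventional MT rule
(observed units ≥ threshold, default 10, inclusive) and a 2×2
SH-vs-MT comparison (agreement, and sensitivity/specificity treating SH as
the reference) are provided for benchmarking.

## Synthetic benchmark design

`SimScenario` defaults encode the two-class study design used throughout
the tests and the acceptance script:

| quantity | value | meaning |
| --- | --- | --- |
| v | N(0, 1) | membership covariate |
| x | Bernoulli(0.5) | class-specific covariate |
| α | (0.5, 1) | class-1 share ≈ 60.2 % (by quadrature) |
| β⁽¹⁾ | (log 15, −1, 1) | SH class: ~15 units typical |
| β⁽²⁾ | (log 5, 1, −1) | non-SH class: ~5 units typical |
| γ⁽¹⁾ | (1, −1) | class-1 marginal mortality 61.6 % |
| γ⁽²⁾ | (−1, 1) | class-2 marginal mortality 38.4 % |
| σ | 0.5 / 1 / 2 | scenario noise levels |

Marker covariates are (1, v, x); mortality covariates are (1, x). The
dead have log U added to their log marker (the uniform-on-unit-scale
censoring above); survivors are observed exactly. Draws follow a fixed
per-patient order (v, x, class, w, ε, U) from per-patient substreams, so
enlarging n extends a dataset without reshuffling earlier patients.

What the generator emulates: the joint dependence of transfusion volume
and early death on a latent severity class, and the survivor bias of
volume-threshold rules. What it does not: real admission-vital covariate
structure (binary vitals and categorized blood-product ratios enter only
through the CSV ingestion layer), time-to-event detail (death is a 24-h
binary), within-class skewness or measurement clumping of unit counts.
Passing tests therefore certify the estimator and classifier under the
model's own assumptions, not clinical performance on real trauma data.

Under this design with n = 500: the MT rule agrees with the true class for
about 68.8 / 66.6 / 62.3 % of patients at σ = 0.5 / 1 / 2 (agreement decays
toward 50 % as noise blurs both classes across the 10-unit threshold),
while the fitted two-class posterior classifier is correct for about
91.8 / 87.9 / 80.6 % — close to the Bayes-optimal accuracies at the true
parameters (92.3 / 88.1 / 81.8 %), and uniformly ahead of the MT rule.

## Numerical choices

- All likelihoods are assembled in log space with per-patient log-sum-exp;
  the censored closed form uses the normal log-CDF so deep truncation
  (small σ, marker far above the class mean) underflows gracefully.
- Truncated-normal moments use the inverse Mills ratio computed as
  exp(logpdf − logsf), accurate arbitrarily deep into the tail; tiny
  negative variances from cancellation are clipped at zero and the mean is
  clipped at the truncation point.
- The closed-form integral and both moments are tested to 1e-8 relative
  against peak-rescaled high-precision quadrature over a grid spanning the
  working range.
- Weighted logistic/multinomial subproblems use Newton with step halving;
  ties between equal-likelihood EM starts (within 1e-10) resolve to the
  lowest start index.
- Degenerate inputs: empty datasets, non-finite values, died flags outside
  {0, 1}, σ ≤ 0, mismatched design dimensions and sub-unit RBC counts in
  study CSVs (inclusion criterion: at least 1 unit transfused) are rejected
  with explicit messages; simulated datasets may legitimately contain
  sub-unit observed amounts (censoring can push exp(y) below 1), so the
  ingestion threshold is relaxable.

## Study sizes

The replication harness defaults to 200 replicates for parameter-recovery
summaries (bias/SSE/ASE/MSE) and reports Monte-Carlo standard errors next
to every aggregate; a `--full` flag switches to the 1000-replicate
protocol. The acceptance script uses 100 replicates of n = 500 per σ for
the MT-agreement percentages and 50 replicates per σ for the fitted
classifier accuracy; at these sizes the pooled binomial Monte-Carlo SE is
0.2–0.3 percentage points, far below the differences of interest.

## Known limitations

- The uniform-censoring assumption is structural and untestable; violations
  bias β and σ for the dead-patient contribution.
- The mortality submodel is binary; with actual survival times a
  time-to-event submodel would use strictly more information and could
  relax local independence.
- The empirical (outer-product) information omits the Louis correction; at
  the MLE with a correctly specified model the two agree asymptotically,
  and the recovery study shows ASE/SSE ratios within 10 % for every
  parameter at n = 500, σ = 0.5. Under misspecification the outer-product
  form is not a sandwich estimator and its SEs are not robust.
- K > 2 is supported throughout the likelihood/EM/inference stack, but the
  seven-band posterior grading and the SH-vs-MT comparison are defined for
  K = 2.
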