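# Methods

This note documents the statistical model, the data-generating process
used for simulation, the numerical machinery, and the design choices
made where the design was genuinely open.  Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## Design and data

One record = one alcohol survey: 2 per day × 28 days = 56 signals over
4 weeks.  Day and week indices follow the survey schedule
(`day = ceil(signal/2)`, `week = ceil(day/7)`); the calendar weekday of
a record derives from the configurable `start_weekday` (default
Monday), and **social weekend** is Thursday–Saturday evaluated on the
record's calendar day.  Drinking is keyed to the reporting survey (the
morning survey covers the prior evening→morning window); treating the
report day as the drinking day is an approximation, noted here once
rather than warned about per record.

Intervention participants carry a week schedule: ABAB (weeks 1 and 3
active) or BABA.  Control participants have `week_type =
control_week` throughout — they are excluded from any model containing
the active-week contrast and are the reference population for the
pseudo-week null.

Randomization (`assign_design`) allocates conditions across the whole
sample by largest-remainder apportionment of the allocation proportions
followed by a seeded shuffle, and splits week orders as evenly as
possible *within* each intervention condition (an odd leftover drawn
from the same stream).

## The hurdle model

Answered surveys with a non-missing outcome enter one of two
independently-maximized sub-models:

- **Zero sub-model**: Bernoulli/logit on the indicator of *no alcohol*.
  The zero orientation matches the conventional reporting for this
  design: OR > 1 for the active-week term = more non-drinking
  occasions = the reminders reduced drinking frequency.  (A test pins
  this sign convention.)
- **Conditional sub-model**: zero-truncated negative binomial on
  drinks per occasion, log link, mean–dispersion parameterization
  (variance μ + μ²/k).  The truncated log-pmf is computed as
  `log NB(y) − log(1 − NB(0))` with the `log(1−p₀)` term evaluated via
  `expm1` so small means do not lose precision.

Fixed effects (defaults, reference levels in brackets): intercept,
active week [inactive], perspective-taking [mindfulness], signal count
1–56, number of answered surveys, social weekend [weekday], and the
condition × active-week interaction.  The **number of responses** is a
per-person total (a between-person compliance control, motivated by
the lower response rates observed on active weeks); a week-level count
is not used.  Both sub-models carry nested random intercepts — group,
and participant within group — interpreted from the conventional
"participant × group / participant" reporting of this design as two
variance components per sub-model, with no cross-sub-model correlation.

### Likelihood evaluation

For group *g* with participants *i* and observations *j*:

L_g = ∫ φ(u) Π_i [ ∫ φ(v) Π_j f(y_ij | x′β + σ_g u + σ_p v) dv ] du

Both one-dimensional integrals use **adaptive Gauss–Hermite
quadrature**: the inner (participant) integrand is recentred at its
conditional mode — found by Newton steps using the family's analytic
score and a finite-difference curvature — and rescaled by the local
curvature; the outer (group) integral does the same with
finite-difference derivatives of the inner result.  One quadrature
point per dimension reduces exactly to the (sequential) Laplace
approximation.  Validation: the evaluator matches dense grid
integration to ~1e-14 on small cases (see the likelihood tests), and
quadrature at 7 vs. 15 points moves estimates by < 1e-3 at the SDs
relevant here.

Numerical details that matter:

- The outer mode/curvature finite-difference step is 1e-2.  The
  curvature enters the objective through log τ, so a too-small step
  would inject noise into the marginal log-likelihood and corrupt the
  optimizer's finite-difference gradients; at 1e-2 the objective is
  reproducible to ~1e-7.
- Inner/outer modes are warm-started across objective evaluations.
- σ < 1e-8 is treated as exactly zero (point mass), so the
  no-random-effects model is nested without a boundary artefact and
  the σ = 0 reduction to independent logistic + truncated-NB fits is
  exact.
- Linear predictors are clipped at ±30 before exponentiation; a
  non-finite predictor raises a numerical error naming the parameters.

### Estimation

L-BFGS-B on (β, σ_p, σ_g[, log k]) with σ bounded below by 0, finite
difference gradients (step 1e-5), relative tolerance 1e-8, up to three
restarts from perturbed starts on non-convergence.  Internally the
non-binary covariate columns are standardized (the linear map is
inverted, and the covariance conjugated back, on exit) so that signal
count (1–56) and response totals (0–56) do not ill-condition the
search.  Starting values come from plain statsmodels GLM fits
(logistic; Poisson for the count part), σ = 0.3, log k = 0.

Standard errors are the inverse of a central finite-difference Hessian
(relative step 1e-3 — chosen above the objective's noise floor).  The
Hessian is symmetrized and its eigenvalues floored at a small positive
multiple of the largest before inversion: near a σ = 0 boundary or on a
flat small-sample likelihood this yields large, conservative variances
rather than spurious zeros.  Wald summaries use the fixed 1.96
multiplier; no profile likelihood.  The BH/FDR family defaults to the
two primary week-effect tests (frequency, amount) and is a
configuration list, never hard-coded; the adjustment itself delegates
to statsmodels' step-up implementation behind `bh_adjust`.

## Synthetic data generator

The generator is the analysis model run forwards, and its defaults
*are* the larger study's fitted values: zero sub-model ORs
(intercept 10.4, active week 1.39, perspective 1.06, signal count 1.00,
n-responses 1.02, social weekend 0.54), conditional ORs (1.79, 0.97,
0.54, 1.01, 0.99, 1.27), random-intercept SDs (zero: 0.447/0.282;
conditional: 1.371/0.859), and compliance 0.80 on active vs. 0.84 on
inactive weeks (controls use the single inactive rate, since the
compliance gap is only reported for intervention arms).  Two defaults
could not be read off a published table and were fixed once:

- **nb_dispersion k = 2.0** — no dispersion estimate is published;
  k = 2 gives per-occasion drink spreads in the range of the reported
  descriptive SDs (~1–2 drinks).
- **start_weekday = Monday** — never stated; configurable.

Sequence per dataset: (1) assignment; (2) random intercepts (drawn
independently per sub-model); (3) compliance pass — Bernoulli response
per survey at the week-type rate; (4) each participant's realized
`n_responses` becomes the covariate value used in both linear
predictors (mirroring its role as a per-person control in the model);
(5) zero draw from the inverse-logit predictor; (6) on drinking
occasions, a truncated-NB draw by rejection from the untruncated NB
(exact; zeros are redrawn), split into beer/wine/liquor by a fixed
multinomial (0.5/0.3/0.2) purely to populate the schema.

All randomness flows from one seed through named child streams
(assignment, effects, response, zero, counts, split), so a fixed seed
reproduces the dataset byte-for-byte and the zero-probability
coefficients share common random numbers with the response/zero draws
— raising a zero coefficient can only remove drinking occasions, a
property the tests exercise.

What the generator deliberately does *not* emulate: informative
missingness (compliance is independent of drinking — the motivating
studies do not report on this), reminder text content, baseline
drinking questionnaires, serial dependence beyond the fitted time
trend, and seasonal/semester effects.  Because the conditional
sub-model's random-intercept SD is large (1.371), the marginal drinks
distribution is heavy-tailed — single occasions of 40+ drinks occur in
large simulations, which is precisely why the winsorization operation
exists.  Passing tests therefore certify the estimator and inference
machinery under the model's own assumptions, not robustness to
violations of them.

## Winsorization

"Improbable" is a judgment call, so the pipeline never auto-flags:
either an explicit outlier value set is named (each member replaced by
the largest remaining total — the published worked example maps
{24, 36, 60} onto 16) or an explicit numeric threshold is given
(anything strictly above it replaced by the largest total not
exceeding it).  Winsorization caps totals only; it never changes the
drank flag or the occasion count, and it is idempotent.

## Change scores and the pseudo-week null

Δ = p(active) − p(inactive) per person, proportions of *answered*
surveys with a drinking occasion.  Two sign/numerator conventions
appear in descriptions of this analysis; the package defaults to
**active − inactive with an occasion numerator** (negative =
intervention-consistent, matching the figure-caption convention of the
motivating work) and exposes `sign_convention="methods"` and
`numerator="drinks"` flags for the alternates.

Controls get ABAB/BABA pseudo-labels — an even random split, odd
leftover by the seeded stream — independently re-drawn `n_iterations`
(default 100) times; iteration *i* uses a child seed derived from
(seed, i), so iterations are reproducible in any order.  A
participant's final score averages the iterations where it is defined
(≥ 1 answered survey under both labels); iterations where it is
undefined are skipped and counted, and a participant undefined
everywhere is excluded with a log entry.  For a participant with
identical weeks every labeling gives exactly 0; for full-compliance
participants the average converges to (Δ_ABAB + Δ_BABA)/2.

The comparison is a two-sided Mann–Whitney–Wilcoxon test: mid-ranks,
tie-corrected variance, **no continuity correction** (ambiguous under
the heavy ties produced by averaged scores), Z reported always, exact
enumeration p-values when both samples are small (n ≤ 25) and tie-free.
W is reported under both conventions (rank-sum of either group) plus
the U statistic, since published W values are ambiguous between them.
Effect size r = |Z|/√N with N defaulting to the full sample of the
comparison report (per-comparison n₁+n₂ available).  Shapiro–Wilk
p-values per group are reported as the gate that motivates the
nonparametric choice; the nonparametric test always runs regardless.

Calibration and power properties computed by the suite at the scales
stated there: under a no-effect simulation (225 participants, 2:1
intervention:control) the rejection rate at α = 0.05 over 400
replicates falls in the acceptance band [0.02, 0.09] — mildly
conservative, as expected when the control scores are variance-shrunk
by averaging; with a true active-week OR of 1.4, recovery over 20
seeds at 300 participants/10 groups is essentially unbiased with ≥ 90%
correct sign and ≥ 80% Wald coverage (the recovery harness uses the
Laplace approximation and fits only the zero sub-model, which is the
quantity under study — a deliberate speed/accuracy trade-off; the
Laplace-vs-AGQ difference is far below the sampling noise at these
sizes).

## Known limitations

- Random slopes, cross-sub-model random-effect correlation, and
  zero-inflation mixture (as opposed to hurdle) variants are out of
  scope; so are Bayesian estimation, model selection, and profile
  likelihood intervals.
- The nested AGQ is sequential (inner adapted given each outer node);
  with very large group-level SDs and tiny groups its accuracy decays
  gracefully toward Laplace rather than failing loudly.
- Wald inference on variance components near zero is unreliable (as
  always); the reported SDs are point estimates.
- The exact rank-sum path requires tie-free data; with ties the
  asymptotic tie-corrected approximation is used at any n.
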