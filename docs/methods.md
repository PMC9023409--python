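# Methods

This note documents the models and numerical choices behind `eq5dsim` in
the order the pipeline applies them.

## Synthetic cohort generator

Real longitudinal EQ-5D-5L microdata of the kind this framework targets are
not redistributable, so all experiments run on synthetic cohorts drawn from
a graded latent-Gaussian threshold model.  For subject *i*, timepoint *t*
and item *j*:

    eta_ijt = Σ_c  lambda_c · z_c(i)  +  delta_t  +  b_i  +  eps_ijt
    level_ijt = 1 + #{ k : eta_ijt > tau_k },   tau_1 < ... < tau_4

where `z_c` are the standardized covariate codes (age; gender; marital and
academic status as ordinal codes; self-rated health, SRH, 1–5), `lambda_c`
the latent loadings, `delta_t` the per-timepoint shift (negative =
improvement), `b_i ~ N(0, sigma_b²)` a shared subject intercept and
`eps ~ N(0, sigma_e²)` an item-level residual.  This is the most
parsimonious mechanism that produces ordinal items with within-subject
correlation, covariate-driven health and a time trend.  Covariates are
always complete; missingness is introduced only by the amputation module.

Defaults (GR-like preset): n=450 subjects, 2 timepoints, age ~ N(53.13,
10.43²), female share 0.667, 4-level marital and academic distributions and
a 5-level SRH distribution matching a published rehabilitation baseline
table; loadings age 0.10, academic −0.10, SRH 0.55; `delta = (0, −0.25)`;
`sigma_b = 0.8`, `sigma_e = 0.9`; thresholds (−0.35, 0.65, 1.55, 2.40).
With the default tariff this yields index means ≈ 0.72 at baseline and
≈ 0.78 at follow-up (improvement ≈ 0.056, the size seen in such cohorts).
The ABCD-like preset (n=2040, 3 timepoints, slight deterioration) mirrors a
chronic-disease cohort.  Moments are matched loosely to published
descriptive tables; the item-level joint distribution is illustrative — no
claim is made that the presets reproduce any real dataset's joint law, and
passing tests demonstrate properties of the machinery, not of real data.

One master seed drives everything; each stage (cohort, amputation, each
bootstrap) receives a deterministic substream, so runs are byte-identical
and stages can be reproduced in isolation.

## Value sets

A value set is additive: `index = full_health − Σ_j dec_j(level_j)`, with
per-dimension decrements nondecreasing in level.  Published tariffs are
external publications, so the package ships two clearly synthetic sets:

* `toy-linear` — decrement `0.05·(level−1)` in every dimension (range
  [0, 1]); convenient for hand-checked examples.
* `synthetic-5l` (default) — convex per-level decrements (0.04, 0.08,
  0.20, 0.33), mimicking the shape of published EQ-5D-5L tariffs in which
  severe levels cost far more than mild ones (worst state −0.65).  The
  convex shape matters: it is what lets small item-level imputation errors
  translate into asymmetric index errors.

A profile with any missing item scores NaN (the instrument's
non-scorability rule); this is a value, not an error, because the
complete-case and available-data approaches rely on it to drop rows.

## Amputation (MAR mechanism)

"Overall level" is the proportion of *subjects* receiving a missingness
pattern; under this denominator the schedule decomposition quoted in
percentage points is additive.  The GR schedule at level L splits L into:
baseline unit-nonresponse (UNR, all five items of a timepoint)
`min(5, L)`, item-nonresponse (INR, one item at follow-up, uniform over the
five items) `min(7.5, L − UNR_T0)`, and the remainder UNR at follow-up —
so UNR totals 57.5 points at the 65% level.  INR patterns blank a single
item at the follow-up wave (the wave where missingness grows).

Mechanics: every subject is assigned a candidate pattern by a seeded
multinomial over the pattern frequencies; a weighted sum score
`w · z(aux)` of the standardized auxiliaries is computed (defaults −1 age,
+0.5 gender, +0.5 marital, −0.5 academic, +1 SRH — signs chosen so that
younger, less educated and sicker subjects drop out more; magnitudes are
illustrative and configurable); within each pattern group subjects are
amputed Bernoulli with probability `expit(z_i + s)`, the shift `s` solved
by bisection so the mean probability equals the target (a right-tailed
logistic allocation: higher scores, higher dropout probability).  Equal
scores get identical probabilities; all-zero weights give the MCAR limit
with every probability exactly equal to the target.  Amputation only
deletes: observed cells are never altered, covariates are never touched.

## Multiple imputation (EMB)

Both MI flavours use EM-with-bootstrap under a joint multivariate-normal
working model on a long-format frame (one row per subject × timepoint):
for each of M imputations, resample the rows with replacement, estimate
(μ, Σ) on the resample by the EM algorithm for incomplete normal data
(pattern-wise E-step, moment M-step; tolerance 1e-6 on the maximum
parameter change, at most 500 iterations; the observed-data log-likelihood
is tracked and must be nondecreasing), then draw the *original* frame's
missing entries from the conditional normal under the bootstrap
parameters.  Near-singular observed blocks (the score is almost determined
by the items) get a jitter fallback in the solves and ridge-stabilized
conditional draws (ridge 1e-8).

The frame contains the outcomes, the complete predictors (age, a female
indicator, dummy-coded marital/academic with the modal level as reference,
SRH) and an orthogonal-polynomial basis of the time code, degree capped at
T−1 (with two waves: one linear column).

* **Item level**: the five items are outcomes; continuous imputations are
  rounded to the nearest integer (ties to even), clipped to [1, 5], and the
  index is recomputed with the value set.  Treating ordinal items as normal
  is a deliberate approximation — it is the standard joint-normal strategy,
  and its rounding errors interacting with a convex tariff are the
  suspected source of item-level score distortion.
* **Score level**: the index is the outcome, left continuous (no clipping
  to the tariff range by default); the items accompany it in the frame so
  partially observed rows contribute, but only the score is written back.

M defaults to 100; desk-scale runs use M=10.  When the input has no
missing outcome cells, MI returns M identical copies, which makes the MI
approaches reduce exactly to the available-data approach at zero
missingness.

## Mixed model and "predicted means"

All four approaches fit
`index ~ 1 + time (categorical, baseline ref) + age + female + academic + srh`
with a subject random intercept.  Marital status is deliberately excluded
from the fixed effects although it participates in amputation and MI — the
framework reproduces an analysis design with exactly this asymmetry.  With
one random intercept the marginal covariance per subject is
`sigma_e²(I + theta·J)`, `theta = sigma_b²/sigma_e²`, so the model is
estimated by profiled REML: closed-form GLS at fixed theta (rank-one
Woodbury per subject), then a bounded search over `log theta` in
[−12, 8] with tolerance 1e-8, plus an explicit check of the `theta = 0`
boundary.  ML is available by flag.  The fit agrees with
general-purpose mixed-model software to optimizer precision (asserted in
the test suite against an independent implementation).

A "predicted mean" at timepoint t is marginally standardized: the
fixed-effect prediction averaged over a reference sample of covariates
with time set to t; its SE is `sqrt(x̄' V(β) x̄)` (Rubin total variance for
the MI approaches, which therefore never undercuts the mean
within-imputation SE).  **By default each approach standardizes over its
own analysis sample** — the subjects contributing scored rows to that fit.
This choice is load-bearing: the simulated dropout depends only on
covariates that are also fixed effects, so standardizing every approach
over one common reference would mechanically equalize them all; what makes
complete-case analysis overestimate health in practice is precisely that
its surviving sample is healthier, and the own-sample reference lets that
selection pass through.  A `reference=` argument restores common-reference
standardization for sensitivity analyses.

The reported time slope is the coefficient of the last time dummy divided
by its time code (with two waves, the time coefficient itself).

## Evaluation

Truth is the available-data analysis of the pre-amputation (complete)
cohort — estimator and estimand on the same scale.  Per scenario the
pipeline reports, per approach and timepoint, the mean estimate, the mean
model SE, the empirical SD of estimates across replicates (both SE
flavours are emitted; the mean of model SEs is the headline), and the MSE
against truth, headlined at the follow-up wave.  MSE satisfies the
bias²+variance decomposition by construction.  The item-misspecification
table tabulates `true − imputed` over originally amputed cells across all
imputations and replicates, as percentages per item (rows sum to 100);
cells clipped at the scale boundary are included, since clipping is part
of the estimator.  Ordering flags record the qualitative pattern: complete
cases highest at follow-up, item-MI lowest, available-data ≈ score-MI
within 0.005 index points.

Each simulation replicate redraws a fresh cohort (the conservative reading
of "the complete simulation process was repeated"); a flag fixes the
cohort instead, isolating amputation/imputation noise.

## Problem sizes

Default experiment scale is 100 replicates × M=100 over eight levels; the
shipped desk-scale profile runs levels {10, 35, 65}% with 20 replicates and
M=10.  The test suite's end-to-end checks run n=450 with 50 replicates and
M=10 at those levels, and the calibration checks use 100 amputation
replicates per level.  These sizes
keep every Monte-Carlo standard error well below the tolerances they are
checked against.

## Known limitations

* Ordinal items are imputed under a normal working model with post-hoc
  rounding; an ordinal-probit imputation model is out of scope.
* At desk scale, the item-level-MI downward distortion at follow-up is
  real but small (a few thousandths of an index point) — of the same order
  as the linear mixed model's own approximation error on this nonlinear
  latent-threshold outcome — so "item-MI strictly lowest of all four
  approaches" is a near-tie with the available-data approach under the
  default synthetic tariff, and is flagged rather than guaranteed.
* Chained-equations (FCS) imputation, MNAR mechanisms, covariate
  missingness in the model, random slopes and statistical testing of
  between-approach differences are out of scope.
* The presets emulate published marginal summaries only; real cohorts'
  item-level joint distributions, floor/ceiling profiles and tariffs will
  shift all quantitative results.
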