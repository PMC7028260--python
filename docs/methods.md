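# Methods

This note documents the statistical model behind `hbmeta`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the known limits of reproducing the published summary
numbers from the printed study table.

## Data model

The unit of analysis is a *study record*: a cohort or cohort stratum with
an ordered set of HbA1c exposure categories, each carrying optional case
counts and a risk ratio with 95% CI against the study's own reference
category, plus an optional published per-1% RR.  Strata of one publication
(e.g. the diabetic and non-diabetic arms of one cohort) are separate
records and enter pools as independent units.  Category sets kept only for
the nonlinear model (a cohort's paroxysmal/nonparoxysmal AF splits, whose
per-1% effect already lives on the parent record) are flagged `auxiliary`
and never enter the linear pools.

All effect measures are treated generically as risk ratios and analysed as
natural logs; a 95% CI maps to a standard error via
`se = (ln hi − ln lo) / (2·1.959964)`.  The z-multiplier is kept at
1.959964 rather than 1.96 as a documented precision choice; asymmetric
printed CIs are handled by this symmetric-SE reading with no re-centering,
so published point estimates are never altered.

## Dose assignment

Each category needs one dose.  Closed intervals take their midpoint; an
open-ended interval is extended beyond its finite bound by half the width
of the nearest closed interval (configurable to a fixed width).  Wide
bands still take plain midpoints — no truncation.  A reference category
that is a bare control group with no numeric bounds keeps no dose: it
cannot contribute to dose-response fitting, and the record participates in
the linear analysis through its published per-1% effect instead.  This is
the one deliberate relaxation of the "every category is dosed" rule, and
it is forced by real tables.

## Per-study trend estimation

When a publication reports a per-1% RR, that value is used: it reflects
the study's own adjustment model and is strictly more faithful than
re-deriving a slope from collapsed categories.  Otherwise the slope comes
from generalized least squares over the category log RRs with a covariance
that accounts for the shared reference group.  The covariance uses
variances from the published CIs on the diagonal and the fitted-count
reference term `1/a₀ − 1/n₀` off the diagonal, with fitted cases obtained
by matching the category totals and reported RRs to the study's total
cases.  For risk ratios this margin-matching system is monotone in the
reference cell, so it is solved by a bracketed root solve (tolerance 1e-8)
rather than open-ended iteration.  When neither per-category counts nor
crude margins are available, the fit falls back to an independence
(diagonal) covariance and records that in the result.  With a single
non-reference category the estimator reduces exactly to `L₁/x₁` with
`se(L₁)/|x₁|`.

Pseudo-count re-referencing solves, per non-reference category, a closed
form for its effective cells given the reference cells, and finds the two
reference unknowns from the study's crude case and participant margins.
The margin equations can admit more than one positive root; the solver
multistarts over proportional splits and keeps the root with the largest
smallest cell, since degenerate roots (near-zero pseudo denominators)
would corrupt every downstream variance while fitting the constraints
equally well.

## Pooling

DerSimonian–Laird random effects throughout: fixed-effect weights give
Cochran's Q, the moment estimator `τ² = max(0, (Q − df)/(Σw − Σw²/Σw))`,
random-effects weights `1/(se² + τ²)`, and `I² = max(0, (Q − df)/Q)·100`.
DL (not REML or Paule–Mandel) is deliberate: the published numbers this
package reproduces were produced by mainstream inverse-variance
random-effects software, which implements DL.  I² bands follow the common
convention: below 50 low, 50–75 moderate, above 75 high.  The overall
two-sided p is a normal z-test on the pooled log RR.

Trim-and-fill uses the Duval–Tweedie R0 run estimator with fixed-effect
centering during trimming and a DL pool of the mirror-filled set.  `side`
names the funnel side where suppressed studies are presumed missing, the
convention of the major meta-analysis packages, against which the
implementation was cross-checked.  Note the R0 statistic is conservative
by construction (it counts a same-side run of extreme deviations minus
one): deleting m studies from a symmetric funnel is typically detected as
m − 1, and a uniformly spaced equal-variance funnel re-symmetrizes around
its shifted center and yields zero — both behaviours match the reference
implementation and are asserted in the tests.

## One-stage spline meta-regression

All non-reference category effects enter one weighted regression of log RR
on restricted-cubic-spline basis *differences* (basis at the category dose
minus basis at the study's reference dose), no intercept, weights
`1/se²`.  The reference category is the zero anchor, not a data row.
Default knots sit at the weighted 10/50/90th percentiles of observed doses
(three knots, two coefficients); knot count and placement are
configurable.  The coefficient covariance is a CR1 cluster sandwich
(clusters = studies, scale g/(g−1)), and the nonlinearity test is a Wald
statistic on the nonlinear coefficients referred to F(q, g−1) — the
standard small-sample treatment for cluster-robust inference, which keeps
the test's size near nominal with as few as six clusters (verified by
simulation in the acceptance suite: rejection rate under a linear truth
within [0.02, 0.09] at 400 replicates).

The predicted curve is `RR(d) = exp(b'(B(d) − B(ref)))` with delta-method
pointwise CIs; the anchor defaults to the lowest observed dose.  The
*significance threshold* is the smallest grid dose (step 0.01%) above the
anchor whose lower CI exceeds 1 and stays above 1 to the end of the span,
so isolated crossings do not count.

### What the threshold estimator is — and is not

The threshold is a property of the *evidence*, not of the underlying
curve: it marks where the data first demonstrate elevated risk.  Two
consequences, both measured by this package's simulations and worth
stating plainly:

1. A smooth spline cannot represent a flat-then-linear truth, so the
   fitted curve rises gradually from the anchor even when the true curve
   is exactly flat there.
2. The crossing dose therefore moves with the information level.  With
   very large per-category samples (5 000 per category) the pointwise CIs
   are so tight that the crossing happens far below a true 6.3% change
   point (median near 4.9% over 200 replicates); with sparse data
   (hundreds per category, like the real tables) it lands near or above
   the change point.  The threshold-recovery experiment in the acceptance
   suite runs at the high-information setting and documents this bias
   honestly rather than re-tuning the simulation to flatter the
   estimator.  Users should read reported thresholds as "elevated risk is
   demonstrable from here", not as change-point estimates.

The nonlinear analysis of the bundled data is restricted to cohorts
without known diabetes, whose category data are dose-resolved; the
diabetic records either lack dosed references (control-group reference) or
cover a disjoint exposure range, and a diabetes-only selection is refused.

## Synthetic data

The generator emulates the bundled table's structure: each study draws a
sub-range of the 4.5–10% HbA1c span, partitions it into 2–6 closed
categories, samples cases binomially at the category-midpoint risk
implied by the true curve (linear slope per 1%, or flat-to-linear with a
change point), and reports Wald-CI risk ratios against its reference
category.  Between-study heterogeneity is an additive normal shift on the
study's slope, matching the additive random-effects model being tested.
Binomial cumulative-incidence sampling (not person-time Poisson) matches
the cases/N reporting of the real tables.  A root seed spawns per-study
substreams, so adding a study never perturbs earlier ones.

Defaults: 10 studies, 4 categories, 2 000 participants per category,
baseline risk 0.05 at the low end of the span, slope ln(1.15)≈0.14 per 1%
— category standard errors of roughly 0.1–0.3 on the log scale, the range
the real studies print.  The simulation scenarios used by the acceptance
suite: CI coverage of a pooled linear slope at 10 studies × 3 000 per
category × 300 replicates; nonlinearity test size at 6 studies × 2 000 ×
400 replicates; threshold-shape power and recovery at 8 studies × 5 000 ×
200 replicates.

What the generator does **not** emulate: confounder adjustment (synthetic
RRs are crude), open-ended extreme categories, person-time follow-up,
selective publication, and correlated strata from one publication.
Passing simulations therefore validate the estimators' arithmetic and
calibration under the stated sampling model, not robustness to
adjustment-induced or selection-induced distortions in real tables.

## Reproduction limits on the bundled data

Direct DL pooling of the nine printed AF per-1% entries gives RR 1.21 with
I² 85, not the published 1.16 with I² 52.  The discrepancy is driven by
the acute-myocardial-infarction cohort's printed per-1% value (3.24,
2.41–4.35), which is plainly inconsistent with the published pooled
interval; the value that entered the original pooling software evidently
differed from the printed one and is not recoverable.  The package reports
its own computed pool and never substitutes a back-solved input.  All
other published pools reproduce within printed precision: POAF six-study
pool 1.01 (0.83–1.22), I² 79; adjusted-only 0.92, I² 74; diabetes/IGT
subgroup 1.13 (1.08–1.19), I² 0; no-known-diabetes subgroup 1.11
(1.05–1.18); AF without the AMI cohort 1.13 (1.09–1.16), I² 0.

Likewise, the published nonlinear curve's 6.3% significance threshold used
category-level inputs beyond those printed (not all cohorts print category
rows); on the printable subset the fitted curve rises and becomes
significant at ≈7.5%, and the published "P_nonlinear = 0.04" is treated as
qualitative.  The curve-shape test asserts the published 6–7% band and is
expected to fail on the printable subset; it is retained unweakened as an
explicit record of that gap.
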