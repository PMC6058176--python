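# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices and the known limitations of `radioimpact`.

## Setting

A pair-matched cluster randomised trial of a saturation radio campaign on
child health ran in 14 rural clusters (7 matched pairs) around community FM
stations, with monthly under-five primary-care consultation counts by
clinical diagnosis category available from routine facility reporting over
January 2011 – December 2014 and the campaign starting March 2012.  The
package links three stages: (1) preparation of the diagnosis counts,
(2) interrupted time-series (ITS) estimation of campaign-period utilisation
effects, and (3) a coverage–effectiveness ("lives saved") projection of the
child-mortality impact implied by those effects, with scenario algebra for
national and multi-country scale-up.  Because the underlying facility data
are not public, a first-class synthetic generator reproduces the design and
the assumed data-generating process, and every stage is tested against it.

## Diagnosis-count compression

Health workers record one or more diagnoses per consultation, so category
counts sum to more than the all-cause consultation total (the average
number of diagnoses per consultation drifts upward over the study window,
differently by arm).  For coverage modelling the categories must partition
consultations, so each cluster-month's counts are rescaled proportionally
to sum exactly to the all-cause total.  Integerisation uses
largest-remainder (Hamilton) apportionment with ties broken by fixed
category order, chosen so that compressed counts are exact integers (the
Poisson ITS stays well defined) and the apportionment is deterministic.
Records with consultations but no recorded diagnoses are retained with zero
category counts and surfaced in a data-quality report rather than dropped.
Both compressed and uncompressed counts are analysed, since either choice
is defensible; the pipeline reports both.

One consequence worth flagging: when the diagnoses-per-consultation drift
differs *by arm* (as it does, 1.51 → 2.29 in the intervention arm vs
1.23 → 2.17 in control), compression rescales the two arms differentially
over time, and that differential is partly absorbed by the period-by-arm
interactions — in the synthetic generator, compressed-count fits shift the
period rate ratios upward by roughly the change in the arms'
log-multiplicity gap (about +5 to +8 percentage points at the default
drift), while uncompressed fits recover the generating values.  For real
data the right variant depends on whether the extra diagnoses reflect
recording style (compression corrects them) or genuine case mix
(compression distorts them); the pipeline therefore fits both, and the
scenario feed uses the uncompressed effects as primary.

## Interrupted time-series model

For one diagnosis category, the count in cluster *i*, calendar month *t*:

    y_it | b_i ~ Poisson(mu_it)
    log mu_it = beta_0 + beta_t * t + gamma_{m(t)} + beta_a * A_i
                + beta_c * x_i + sum_p delta_p * A_i * P_p(t) + b_i
    b_i ~ N(0, sigma^2)

with a linear secular trend, eleven month-of-year contrasts (January
reference), an arm indicator A_i for systematic baseline differences, a
continuous cluster-level confounder score x_i, campaign-period-by-arm
interactions for the three campaign years, and a Gaussian cluster random
intercept.  No exposure offset is used because the routine reporting system
provides no reliable population denominators; the model describes raw
monthly counts.  `exp(delta_p)` is the period-*p* rate ratio: the
multiplicative change in consultations in the intervention arm relative to
the control-arm trajectory, displayed as a percentage change rounded half
away from zero.

Campaign years are 12-month blocks from March 2012, with the third year
truncated at December 2014; January–February 2012 (post-baseline-year but
pre-campaign) are assigned to baseline.  Period definitions are
configurable.

### Estimation

The marginal likelihood integrates the random intercept by adaptive
Gauss–Hermite quadrature with 9 nodes (configurable), centred and scaled at
each cluster's conditional mode.  Because the intercept is additive on the
log scale, each cluster's integrand reduces to three sufficient statistics
(count total, fitted-mean total, count-weighted linear predictor), so the
conditional mode is a one-dimensional Newton solve on cluster totals and
one likelihood evaluation costs O(n) plus O(G × nodes) regardless of
cluster sizes.  The gradient uses the Fisher identity (posterior
expectations of the complete-data score) and the Hessian the Louis identity
(posterior expectation of the complete-data Hessian plus the posterior
variance of the score), all from the same quadrature weights; the fit is a
damped Newton ascent with backtracking line search and Levenberg damping on
indefinite Hessians, falling back to L-BFGS-B if Newton stalls.
Convergence is declared when successive log-likelihoods change by less than
1e-8.  sigma is optimised as log sigma, bounded in [1e-4, 10]; data
generated without cluster heterogeneity drive the estimate to the lower
bound (variance ≈ 0) and the fixed effects then agree with a plain Poisson
GLM to ~1e-6, which the tests assert against an independent GLM fit.
Start values come from a plain Poisson IRLS; bootstrap refits warm-start at
the full-data optimum, which is what makes ~1000-replicate cluster
bootstraps affordable (a warm refit costs a few milliseconds).

Possible separation (a campaign period with zero counts in one arm) is
detected at design construction and reported as a warning, since the
corresponding interaction is then unstable; non-convergence is flagged on
the result, never silently returned.

### Uncertainty: BCa cluster bootstrap

Confidence intervals are bias-corrected and accelerated (BCa) bootstrap
intervals from B = 1000 replicates (configurable).  The resampling unit is
the cluster — the unit of randomisation and of dependence — drawn with
replacement within each arm so each replicate retains 7 intervention and 7
control clusters; matched-pair resampling is available as an option.
Re-drawn copies of a cluster are treated as distinct clusters in the refit.
The bias-correction constant is z0 = Phi^-1(#{theta* < theta_hat}/B), the
acceleration comes from a leave-one-cluster-out jackknife, and the interval
endpoints are linearly interpolated empirical quantiles at the BCa-adjusted
levels.  The two-sided p-value is the smallest nominal level at which the
interval excludes the null rate ratio, found by bisection (the interval is
monotone in the level); a Wald p-value from the observed-information
covariance is reported as a secondary quantity.  Replicate resampling is
driven by a single seeded generator, so runs are exactly reproducible, and
replicates whose refit fails are dropped and counted, with more than 5%
failures raising an error.

**Small-sample caveat.**  With only 7 clusters per arm, the cluster
bootstrap variance of a within-cluster contrast is systematically shrunk
(roughly the (G−1)/G factor familiar from resampling a mean of G units)
and the variance estimate itself is noisy (few effective degrees of
freedom).  In simulation under the null (all rate ratios 1, the default
generator design), 95% BCa intervals for a period rate ratio cover the
truth at roughly 80–85% rather than the nominal 95%.  This is an inherent
property of percentile-type cluster bootstraps at G = 7 per arm, not an
implementation artefact: the same machinery applied to smooth statistics
of more numerous clusters attains nominal coverage, the interval endpoints
match an independent implementation of the BCa formulas to 1e-10, and the
fitted effects themselves are unbiased.  Intervals at this design should
therefore be read as moderately anti-conservative.

## Synthetic-data generator

The generator draws exactly the process the ITS model assumes, plus the
multiple-diagnoses mechanism:

* one cluster pair at a time, a standard-normal confounder score and a
  N(0, cluster_sd²) intercept per cluster, fixed across months;
* category counts Poisson with the log-linear mean above — counts are
  Poisson *conditional* on the cluster intercept, hence marginally
  over-dispersed when cluster_sd > 0.  No negative-binomial option is
  provided: the generator deliberately mirrors the fitted model;
* the all-cause consultation total is the category-count sum divided by
  the arm's diagnoses-per-consultation multiplicity, interpolated linearly
  from its start value to its end value over the window (control
  1.23 → 2.17, intervention 1.51 → 2.29 by default), rounded to integer.

Defaults are the emulated trial: 7 pairs, 48 months from January 2011,
six diagnosis categories with shares malaria 0.55, pneumonia 0.18,
diarrhoea 0.03, URTI 0.10, malnutrition 0.05, other 0.09 (the targeted
shares follow the reported distribution of diagnoses; the remainder is
spread plausibly), baseline 800 all-cause consultations per cluster-month
(arm-specific baseline rates are not published; this is an illustrative
scale consistent with ~5–6 facilities per cluster), trend +0.005/month on
the log scale, a single-peak rainy-season profile (amplitude ±0.4),
arm offset −0.10, confounder coefficient 0.20, cluster SD 0.25, and the
trial's reported effect sizes as true rate ratios — malaria (1.56, 1.37,
1.35), pneumonia/LRTI (1.39, 1.25, 1.11), diarrhoea (1.73, 1.60, 2.07) —
with no effect on non-targeted categories.

What the generator does *not* emulate: individual children or facilities,
catchment/distance effects, reporting gaps and completeness changes (e.g.
the DHIS2 transition), effect heterogeneity across clusters, and secular
changes in diagnostic practice beyond the linear multiplicity drift.
Passing recovery tests therefore show the estimator is correct *for the
assumed process*; they cannot show robustness to misreporting or
model misspecification in real facility data.

## Deaths-averted engine

The engine is a deliberately small reconstruction of the Lives Saved Tool
(LiST) accounting identity, not a Spectrum reimplementation.  For an
intervention with effectiveness E and affected fraction AF acting on one
cause, a coverage change C0 → C1 averts the fraction

    phi = E·AF·(C1 − C0) / (1 − E·AF·C0)

of the cause's current deaths (equivalently the relative drop in residual
risk); several interventions on one cause combine as
phi_comb = 1 − Π(1 − phi_i).  Deaths in the absence of the intervention
come from an envelope D_y = U5MR_y × births_y / 1000 partitioned by cause
fractions, and percentage mortality reductions divide averted deaths by
D_y.  Only campaign-targeted interventions enter the engine, so the
published practice of subtracting lives saved through non-targeted
channels holds by construction.  The same algebra serves a maternal
envelope with ANC/delivery-linked causes.

Coverage paths come from the utilisation effects: baseline coverage C0 is
multiplied by (1 + r_y·q), where r_y is the relative increase in facility
attendance for the linked diagnosis group in campaign year y and q the
proportion of attenders who actually receive the effective treatment
(54.3% antimalarial among fever attenders, 34.5% ORS among diarrhoea
attenders; q = 1 where care-seeking is itself the coverage definition, as
for oral antibiotics for pneumonia, and for the directly-applied ANC and
facility-delivery effects).  The effects are applied *relatively* (they
are reported as percentage increases in attendance); an optional
rural/national multiplier on C0 (default 1) stands in for the published
but unquantified rural-adjustment step.  Coverage is capped at 1 with a
saturation warning; negative effects (the year-3 LRTI lower bound) push
coverage below baseline and produce negative contributions, as intended
for sensitivity runs.  Treatment parameters: ACT effectiveness 0.87 (a
deliberate down-weighting of the 99% default to allow for incorrect
antimalarials), oral antibiotics 0.70, ORS 0.93, affected fractions 1.0
for the three treatment interventions.  The ANC effect maps to a bundle of
three routine pregnancy interventions sharing one coverage path; their
cause links and effectiveness are config-supplied with small illustrative
defaults clearly labelled as such.

## Scenario algebra

On top of engine totals, in order: population scaling (either on envelope
live births, or post hoc on lives-saved totals — the latter is the default
and mirrors rescaling national projections to a trial-zone population
share); a penetration index multiplying lives saved by p_target/p_ref
under the assumption that people impacted are proportional to people
exposed (52% → 45.2% listenership gives the 13.1% national reduction); a
campaign-format discount of 0/10/20% representing a spots-only campaign;
and sensitivity bounds rerunning the entire engine with every utilisation
effect at its lower or upper 95% CI bound.  Percentage reductions under
discounting re-divide discounted lives by the unchanged envelope, so the
percentage scales by the same (1 − d).  All intermediate arithmetic is
double precision; lives saved are rounded to the nearest integer and
percentages to one decimal, half away from zero, exactly once at display.
Multi-year totals are computed from unrounded per-year values and rounded
once (summing independently rounded cells can differ by ±1; the published
tables show both conventions).

The shipped scenario files carry the printed inputs where the source
prints them (mortality rates, effectiveness, receipt proportions,
penetration, discounts, utilisation effects with CIs).  Live births are
back-derived from the printed per-year lives-saved/percentage algebra;
cause-of-death fractions, baseline coverages, ANC/delivery CI bounds and
all per-country scale-up inputs are illustrative stand-ins (the originals
live in unpublished supplementary files) and are labelled as such — the
five-country fixture is named `scaleup_countries_synthetic.yaml`.
Absolute lives-saved totals from these configs are therefore *not*
comparable to the published totals, which depend on an external national
base projection; the package's validation surface for the engine is its
algebraic identities plus the published scenario-algebra tables
(penetration, discount grids, deaths-weighted averages), which are
reproduced exactly from printed inputs.

## Problem sizes used in the test suite

Simulation-based checks use the emulated trial design (7 pairs × 48
months): 100 replicate datasets for effect recovery (assertion within 3
Monte-Carlo standard errors), 200 null replicates with B = 500 bootstrap
replicates for interval coverage, B = 999–2000 for the bootstrap formula
checks, and reduced designs (3 pairs, 30 months, B = 25) for end-to-end
determinism smoke runs.  These sizes give stable Monte-Carlo assertions
while keeping the default suite practical on one CPU.

## Known limitations

* Frequentist mixed-Poisson inference rests on a single scalar random
  intercept; random slopes (cluster-level effect heterogeneity) are not
  modelled, and real-data intervals would likely be wider than the
  generator suggests.
* The BCa cluster bootstrap is anti-conservative at 7 clusters per arm
  (see above).
* The engine omits Spectrum's demographic projection, nutrition and
  birth-outcome pathways, herd effects and cause-structure evolution;
  it is an accounting identity on a fixed envelope.
* The maternal pathway shares the child algebra and is provided, but no
  published maternal cause structure ships with the package.
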