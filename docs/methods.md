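# Methods

This note documents the models and procedures `gentbirth` implements,
the choices made where the design was genuinely open, and what the
synthetic experiments do and do not demonstrate.

## Problem setting

The package studies how neighborhood change relates to adverse birth
outcomes. Census tracts are the neighborhood unit and CBSA-style
regions the comparison benchmark. Each tract is classified over a
ten-year measurement period by two rule-based schemes, every birth is
linked to the tract-period exposure that was underway when the
pregnancy occurred, and tract-clustered mixed models estimate the
exposure–outcome associations. Because real birth registries of this
kind are access-restricted, the package ships a generator that
produces structurally faithful synthetic inputs with known truth;
all shipped experiments run on those.

## Exposure classification

### Regional benchmarks

For each region-period we compute the median tract household income
and median share of housing built in the prior two decades; the
benchmark *change* quantities (home value, rent in percent; bachelor's
share in percentage points); the regional median home value at period
start and end; the median low-income household share; and the 75th
percentile of tract home-value appreciation ("hot market" threshold).

The wording "the corresponding regional change" does not pin an
aggregation. The default computes the change between the medians of
tract start and end values (robust to outlier tracts); a
`mean_of_changes` mode averages per-tract changes instead. Percent
change is used for priced quantities and percentage-point change for
the education share so comparisons are scale-free across regions of
different price levels. No CPI adjustment is applied: tract and region
always compare same-period nominal values, so the comparison is
internally consistent. Benchmarks are computed over all tracts in the
region by default; an urban-only mode is provided.

### Freeman scheme

A tract is *eligible* when at least half its census blocks are urban
(unweighted block-count share) and its income and recent-construction
share are *at or below* the regional medians; eligibility comparators
are inclusive per the rule's phrasing, growth comparators strictly
exclusive — a tract exactly matching the regional change is *not*
gentrifying. An eligible tract is *gentrifying* when both home-value
growth and bachelor's-share growth strictly exceed the regional
change. Everything else is excluded (ineligible). Missing required
inputs yield UNCLASSIFIABLE, which is reported and propagates to the
cohort as missing exposure — never coerced into a referent group.

### Displacement & Gentrification typology

The nine categories are produced by a deterministic precedence table
over boolean clauses (low-income status, appreciation, rent growth,
education growth, end-of-period cost, low-income household loss,
spatial hot-market adjacency); the table is documented in
`classify.classify_dg_category` and every input combination yields
exactly one category. The exact numeric cutoffs of the published
typology live in external material; the implementation is a faithful
structural operationalization with every comparator margin exposed in
`ClassifierThresholds` (serialized with every output for provenance),
not a claim of bit-compatibility with any specific public release.
The in-migration clause of "Becoming exclusive" is deliberately
omitted, matching the analysis design this package follows. When rent
fields are absent the rent clause evaluates false (documented
degradation, not an error). The nine categories collapse 2/3/4 onto
displacement / gentrification / exclusive stages; the exclusive stage
is the referent.

The hot-market flag is true when any adjacent tract's appreciation
reaches the regional 75th percentile; without an adjacency list the
tract's own appreciation is used as a fallback.

## Cohort construction

Raw birth records pass a fixed-order exclusion cascade: unlinkable
tract; gestational age outside 22–45 completed weeks; maternal age
outside 10–60 years; birth weight outside 100–9000 g; plural birth;
missing exposure, outcome or covariate; race/ethnicity reported as
Other or mixed (too sparse for stratified models). A record violating
several rules is counted once at the first failing rule, so the
report reads as a CONSORT flow and input n always equals survivors
plus removals (asserted in code).

Outcomes: preterm is "after 24 and before 37 weeks", operationalized
on integer completed weeks as 25–36; very preterm 25–31. Week 24
exactly is neither by default — birth-certificate gestational age is
integer-valued and the phrase "after 24 weeks" is ambiguous at the
boundary, so a `ptb_lower_inclusive` switch is provided. SGA is
weight strictly below the sex-specific 10th percentile at the
gestational week; low birth weight strictly below 2500 g; both
boundaries exclusive so a weight exactly at the threshold is not
flagged. The z-score is (weight − mean)/SD at (sex, week); term
birth weight is defined for 37–44 weeks.

The growth reference is an input table. When none is supplied, an
empirical reference can be built from the cohort itself using the
type-1 (inverted-CDF) quantile for the 10th percentile; cells with
fewer than a configurable minimum of births borrow the pooled-sex
cell with a warning. The package also ships a synthetic normal-model
reference (`default_growth_reference`) consistent with the
generator's weight model; it is a package-built construction, not a
published standard.

Exposure linkage: births 2005–2011 link to the 2000–2010 period and
2012–2017 to 2007–2017, giving every birth a lag of at least five
years from the period start — the measured change should be underway
at delivery.

## Statistical models

Binary outcomes use a random-intercept logistic model,
logit P(y_ij=1) = x_ij'β + u_i with u_i ~ N(0, σ_u²) per tract. The
marginal likelihood integrates u out by Gauss–Hermite quadrature on
the standardized scale u = σ√2·z, which keeps nodes and weights
parameter-free and makes the analytic gradient exact for the
discretized likelihood. Estimation is maximum likelihood via
L-BFGS-B on (β, σ) with σ bounded at zero, warm-started from the
unclustered logistic fit; convergence tolerances are tight
(ftol 1e-13, gtol 1e-8) so algebraic identities such as the
referent-swap relation hold to ~1e-5 on the OR scale. The default 50
nodes are far more than needed at the cluster sizes fitted here; the
suite asserts that doubling the nodes moves estimates by less than
1e-3. Penalized quasi-likelihood is never used — its bias at modest
cluster sizes would fail the recovery checks. Standard errors come
from the observed information (central differences of the analytic
score); Wald 95% intervals are exponentiated to the OR scale,
matching the OR (95% CI) presentation convention. A σ estimate on
the boundary (zero) is reported as such, with its variance flagged
NaN rather than fabricated.

Continuous outcomes (birth-weight z-score, term weight) use a
random-intercept linear model estimated by profiled REML (ML
available): given the variance ratio λ = σ_u²/σ_e², the GLS solution
and residual variance are closed-form through per-cluster sums
(Woodbury identity), leaving a one-dimensional search over log λ with
an explicit comparison against the λ = 0 (OLS) boundary. The linear
fit is cross-checked in the tests against a brute-force
full-covariance GLS oracle and the OLS limit.

Adjustment sets: Model 1 adds maternal age (years, linear; a
categorical <20/20–34/≥35 switch exists for descriptive parity) and
payer at delivery (referent: private); Model 2 adds primiparity and
prenatal-care adequacy. Parity and care may be confounders or
mediators; they are fitted only as covariates — no mediation analysis.
No multiple-testing adjustment is applied; each outcome is reported
with its own unadjusted interval, as is conventional for this
presentation.

Stratified models are fitted per race/ethnicity level; small strata
are reported with their wide intervals rather than suppressed (a
minimum-size guard skips strata that cannot be fitted at all).
Effect modification is tested by a likelihood-ratio test comparing
the main-effects model with the model adding all exposure × race
products, on (levels−1)×(races−1) degrees of freedom; LR was chosen
over Wald as the better-calibrated nested-model test. Race levels
with an inestimable exposure cell (no events or no non-events) are
dropped from both nested fits with a warning, since their interaction
coefficients are not identified.

## Synthetic data generator

The generator defines the study conditions used throughout the test
suite and the acceptance script:

* **Geography.** 10 regions × 30 tracts (standard), ring adjacency.
  In each region half the tracts are scripted eligible (urban,
  low-income, low recent construction — disjoint value ranges around
  the regional medians) and half ineligible, with designated tracts
  realizing every typology category. Scripted clauses are set
  relative to the region's own provisional medians with 15–40 %
  margins, wide enough to dominate the small drift those overrides
  cause in the final medians; home values follow one smooth
  distribution across all tracts so the median-of-levels benchmark
  change tracks the regional drift. Designated displacement tracts
  sit on ring arcs with cold neighbors so their hot-market flag stays
  false. With the shipped seeds the intended labels are realized
  exactly; the self-consistency tests require ≥95 %.
* **Births.** ~150 per tract (Poisson), years uniform over 2005–2017.
  Outcomes follow the random-intercept logistic model with tract
  intercept SD 0.3 and exposure ORs near the modest magnitudes
  typical of neighborhood studies (0.94 ineligible, 1.09 gentrifying
  for preterm, against the eligible-not-gentrifying referent).
  Gestational age is drawn conditional on the preterm latent draw
  (~13 % of preterm mass before week 32) and weight through a latent
  growth percentile aligned with the reference, so re-deriving the
  flags reproduces the latent draws; percentile margins around 0.10
  absorb gram rounding. The race mix (28 % White, 51.5 % Hispanic,
  14.8 % API, 5.4 % Black, 0.3 % AIAN), payer mix, parity and care
  rates mirror a large diverse state registry. Implausible values
  and missingness are injected at small configurable rates (~3 %
  total) to exercise the cascade.
* **Truth.** Intended labels, true log-ORs, σ_u, per-tract
  intercepts and per-birth latent predictors are serialized so any
  estimate can be scored without re-deriving the generating model.

What passing on synthetic data shows — and does not. The experiments
demonstrate that the classifiers implement their rules exactly, the
cascade accounts for every record, and the estimator is calibrated
(recovery within ±0.04 on the log-odds at 300×150; CI coverage and
type-I error at nominal level on 200 null replicates of 250 tracts ×
40 births, a cluster-rich regime chosen because the Wald test is
asymptotic in the number of clusters and the emulated registry has
thousands of tracts). They do not validate the substantive exposure
model against real neighborhoods: the generator has no spatially
realistic geography, no migration dynamics, no correlation between
covariates and tract trajectories beyond what is scripted, and its
growth reference is synthetic.

## Numerical and degenerate-input policy

Percent changes with a zero or missing start value are flagged
missing, never infinite. Empty regions raise, never return silent
zeros. A constant-weight reference cell (SD 0) raises. A constant
continuous outcome yields a flagged degenerate result with zero
effects. Non-convergence is flagged on the result object; there is
no silent fallback to an unclustered fit. Ties: growth comparisons
are strict, eligibility comparisons inclusive (see above). All
randomness flows through `numpy.random.default_rng` (PCG64) seeded
from config; identical seed and config reproduce inputs byte-for-byte
and estimates exactly.

## Problem sizes used in the shipped experiments

Classifier oracle checks use 1,000–1,500 randomized tracts; the
standard synthetic study is 10×30 tracts with ~45,000 births;
parameter recovery uses 20 replicates of 300 tracts × 150 births;
null calibration uses 200 replicates of 250 tracts × 40 births. These
sizes make the full suite run in a few minutes on one core while
keeping Monte Carlo error well inside the asserted bands.

## Known limitations

* The typology thresholds are structural defaults, not the published
  cutoffs; analyses comparing against a specific public release
  should load that release's thresholds into `ClassifierThresholds`.
* The urban share is an unweighted block-count share; block-population
  weighting is not implemented.
* Kotelchuck-index computation is out of scope: care adequacy is
  consumed as a binary input.
* Only a single (tract) random intercept is supported — no crossed or
  spatially correlated random effects, and no Bayesian estimation.
* Address geocoding and acquisition of real census extracts are out
  of scope; inputs are the documented CSV schemas.
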