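# Methods

## The scientific question

Brazil's Dietary Guidelines (*Guia Alimentar para a População Brasileira*)
formulate ten qualitative "steps" toward an adequate and healthy diet. For
adolescents, the national school health survey (PeNSE 2019) carries 22
dietary-practice markers that map onto four of those steps: basing the diet
on unprocessed/minimally processed food (daily beans, fruit, vegetables),
avoiding ultra-processed food (weekly soda and sweets frequency plus 13
previous-day ultra-processed items), eating regularly and attentively and
with others (breakfast, family meals, screen-free eating), and preferring
places that serve fresh meals (fast-food venue frequency). This package
implements the full analysis of *multiple* adherence: build a 0-10 score
from ten binary components, estimate its design-based distribution, and
model which sociodemographic and behavioral factors are associated with
meeting all ten practices at once.

## The adherence score

Each of ten components awards one point when a threshold predicate on the
relevant marker holds (see `data/scoring_rules.yaml`, the single canonical
encoding). Two variants of the same components are computed:

* **ideal** (more restricted): daily beans/fruit/vegetables/breakfast/family
  meals; zero days of soda, sweets, screen-eating and fast-food venues; zero
  previous-day ultra-processed items;
* **possible** (less restricted): the same daily staples, with soda, sweets,
  screen-eating and fast-food tolerated up to 2 days/week and up to 3
  previous-day ultra-processed items (the survey's lower quartile).

The previous-day ultra-processed sum counts "yes" flags over the 13 items;
a missing flag invalidates the sum, because the sum — not the item — is the
scoring input. The screen-eating item's ordered categories are stored as
days/week 0-7 ("never" = 0), which turns both variants into pure threshold
predicates. The possible-variant ultra-processed cutoff is fixed at 3 items
rather than recomputed from the loaded data, for reproducibility of the
published rule; `ScoringModel.with_upf_threshold` supports sensitivity runs.

Missing handling mirrors the survey's absent(99) convention: any missing
component invalidates the whole score (no partial scoring). The dichotomous
study outcome, **greater adherence**, is a possible-variant total of exactly
10; totals 0-9 ("some adherence") form the reference, acknowledging that a
score of, say, 8 still reflects several incorporated healthy practices.
Records flagged absent are *kept in the data with their design row*; all
estimation treats validity as a domain indicator so design variances remain
correct. Covariate missingness never invalidates a record; regressions drop
such records per analysis (complete case). The published analysis does not
state whether covariate-missing categories were modeled; per-analysis
complete case is our documented choice.

## Design-based estimation

The survey is a stratified two-stage cluster sample (strata = region x
school size, schools as first-stage units, classes/students within). Point
estimates are weighted (Horvitz-Thompson ratio) proportions. Variances use
first-order Taylor linearization with the usual with-replacement
approximation at the first stage: linearized values are totaled per PSU and
the stratified between-PSU variance `sum_h n_h/(n_h-1) sum_c (Z_hc-Zbar_h)^2`
is accumulated. Out-of-domain units carry zero linearized values but keep
their PSUs in the computation. No finite-population correction and no
replicate weights are used (the public design variables do not support
them).

Confidence intervals for proportions are logit-scale t intervals with
design degrees of freedom `PSUs - strata`, the convention of the survey
software named by the source analysis; a Wald interval is available by
configuration, since the original publication names neither the transform
nor the df convention. Degenerate estimates (0 or 1, where the linearized
SE collapses to zero) are reported with a one-sided interval built from the
nearest representable proportion `1/(2n)` and flagged — a zero prevalence
then prints as "0.0 (0.0; 0.1)" in percent, as rare outcomes do in the
published tables. Strata with a single PSU raise an error by default, with
explicit `certainty` (contribute zero) and `collapse` (pool singletons)
policies; silent fixes corrupt variance.

Report percentages are rounded half-up to one decimal, matching the printed
tables; 0.25 rounds to 0.3, where float rounding would give 0.2.

## Prevalence-ratio modeling and selection

Associations are estimated as prevalence ratios from a log-link Poisson
working model for the binary outcome — the standard direct-PR approach in
cross-sectional data. Points come from the weighted pseudo-maximum-
likelihood fit (statsmodels GLM, sampling weights as variance weights); the
covariance is the design-based sandwich `B G B` with `B` the inverse
expected information and `G` the stratified between-PSU covariance of the
weighted score vectors. Excluded records contribute zero scores while the
full design keeps its PSU structure (subpopulation estimation), and PSU
counts per stratum always refer to the full design.

Per-variable tests are joint Wald tests on the variable's dummy block,
referred to `F(k, d-k+1)` after the `(d-k+1)/(dk)` adjustment with
`d = PSUs - strata` — the survey-software convention; a chi-square
reference is selectable. Category CIs are t-based at `d` df. Selection
follows the published procedure: every covariate is fitted alone, those
with joint p < 0.20 enter the multivariate model, and backward elimination
repeatedly removes the largest-p variable at or above 0.05 (whole dummy
blocks, one variable per step, refitting each step). The complete-case
sample is fixed once at the screen-to-multivariate transition so nested
models are compared on identical records; recomputing it per step would let
the estimation sample drift during selection. Reference categories follow
the published table: urban, South region, capital, private school, "no" for
the behavioral items, very unhappy with body, very bad self-rated health.
(The source's Results text instead describes the North as the region
reference while its table marks the South row "Ref", and the North row's
printed CI crosses 1 with p<0.05; we reproduce the table convention and
note the internal inconsistency rather than reconciling it. The published
territory bivariate CI "1.54 (1.15; 1.06)" is an apparent typo and is not
used as a reference value.)

## The synthetic survey and what it does (not) show

`simulate.generate` draws a survey with the full design structure: 10
strata (5 regions x 2 school-size classes), 4,000 schools by default with
20-30 or 45-55 sampled students each (~150,000 students, mirroring the real
survey's ~37.5 students per school), classes within schools, and student
weights equal to a region-level base rate (population share x 15,192,972 /
sampled students) times lognormal noise (sd 0.35, mean 1). Region shares
follow the published descriptives (Southeast 40.2%); the remaining
covariate marginals are survey-plausible values fixed once and documented
in `simulate.py`.

The outcome model is a single latent adherence propensity
`eta_i = alpha + sum delta[v, x_iv] + eps_i`, `eps_i ~ N(0, 0.7)`; given
`eta_i` the ten components are independent Bernoulli draws with probability
`sigmoid(eta_i + offset_c)`. This is the simplest structure consistent with
the observed score distribution; it makes no claim about the survey's true
inter-item correlations. The latent sd 0.7 was chosen because, with the
intercept calibrated to a 0.4% full-adherence prevalence, it reproduces the
published possible-variant score distribution closely (mode at 4, ~1% at
score 0); larger sds over-disperse the score, smaller ones cannot reach a
0.4% product event. Marker values are drawn as a two-point mixture around
the possible-variant threshold (adherent draws uniform on the adherent
side, non-adherent uniform on the other side), so ideal-variant adherence
arises as the sub-event of hitting the stricter cutoff — making full ideal
adherence ~300x rarer than full possible adherence, which prints as 0.0%.

Calibration solves the intercept by bracketed root finding so the probe-
sample full-adherence prevalence hits the target (default 0.4%), and each
covariate effect as a latent shift whose *realized* counterfactual
prevalence ratio matches the requested value; the two are iterated four
times because effects move the overall prevalence and vice versa. The probe
is 50,000 draws with a 10% relative tolerance. The default effect map is
the published final-model adjusted PR set (rural 1.91, region block,
out-of-capital 1.33, body-satisfaction block, self-rated-health block);
variables the published final model excluded (sex, race, maternal
education, school administration, laxatives, the two formulas) are
generated null. Marker missingness is MCAR at 0.00176 per field, which
makes ~3.8% of records absent — the published exclusion fraction — so the
default run's retention prints 96.2%.

What passing tests on this generator do **not** show: real PeNSE weights
include nonresponse and post-stratification adjustments we do not emulate;
real markers are correlated beyond a single factor; real covariates are
mutually correlated (urbanity, region, school type) while ours are
independent given region; and marker missingness in the field is unlikely
to be MCAR. Parameter-recovery results therefore validate the estimators
under the design structure, not the substantive findings.

A note on instability that the synthetic runs reproduce faithfully: with a
0.4% outcome and a 2%-share reference category (very bad self-rated
health), the reference cell contains only a handful of cases, so the
health-block PRs are extremely noisy — exactly why the published health
estimates carry intervals like 1.20-31.12 and why single-run recovered
values for that block can sit far from the generating truth while their
CIs remain honest.

## Numerical and scaling choices

* GLM fits use tolerance 1e-10 so the one-covariate PR matches the direct
  weighted prevalence ratio to 1e-8 (an exact identity of the saturated
  model).
* Monte Carlo test conditions (chosen once): parameter recovery uses 200
  replicate surveys of ~90,000 students (2,400 schools) with a single
  injected rural effect PR 1.9 at 0.4% prevalence; screen calibration uses
  1,000 label permutations on one ~20,000-student survey; CI coverage uses
  1,000 replicates of an 8-strata x 4-PSU x 30-student design with logit-
  normal PSU effects. All seeds are fixed in the tests.
* The acceptance script (`scripts/acceptance.py`) runs the default
  ~150,000-student configuration end to end, including the dictionary-
  driven raw-coding round trip.
* Deterministic output: one seeded generator; the probe (calibration) and
  data streams are separate children of the config seed, so calibration can
  be cached across replicate draws without touching the data stream.

## Known limitations

* No imputation, no interaction terms, no continuous covariates, no
  log-binomial fallback, no replicate-weight variance — all out of scope of
  the source analysis.
* Only the 2019 marker set is supported; the dictionary abstraction is the
  intended extension point for other editions. Input is delimited text plus
  a YAML dictionary; fixed-width/statistical-package readers would slot in
  behind the same dictionary but are not implemented.
* The real-data reproduction (`guia reproduce`) requires the user to
  download the public microdata and write the raw-column dictionary; the
  package ships the published reference values and the comparison logic,
  not the data.
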