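# guia-adherence

Design-based analysis of how many Brazilian school adolescents adhere to
*multiple* recommendations of the national Dietary Guidelines at once, and
of the factors associated with full adherence — built for epidemiologists
working with PeNSE-style school-survey microdata (stratified two-stage
cluster samples with unequal weights).

## What it computes

1. **Adherence score (0-10).** Ten binary components built from 22
   dietary-practice markers (weekly beans/fruit/vegetables/soda/sweets/
   breakfast/family-meal/fast-food frequencies, screen-eating, and 13
   previous-day ultra-processed items summed into one component), in two
   threshold variants: *ideal* (daily staples, zero ultra-processed
   exposure) and *possible* (exposure tolerated up to 2 days/week, at most
   3 previous-day items). Records missing any scoring input are flagged
   absent(99) and kept in the design as out-of-domain units.
2. **Score distribution.** Weighted prevalence of each level 0-10 with 95%
   CIs from stratified Taylor linearization over school PSUs
   (logit-t intervals, design df = PSUs − strata).
3. **Associated factors.** Prevalence ratios for the dichotomous outcome
   (*greater adherence* = possible-variant score 10) from survey-weighted
   Poisson regression with a design-based sandwich covariance, a p<0.20
   bivariate screen and backward elimination to p<0.05.
4. **Synthetic survey.** A generator that emulates the full design
   (region x school-size strata, schools as clusters, unequal weights,
   calibrated 0.4% full-adherence prevalence, injectable covariate effects
   with known truth), so every stage is testable without downloading data.

For a binary outcome \(y\) with weights \(w\), the prevalence ratio for
category \(c\) vs its reference is \(e^{\beta_c}\) from the working model
\(\log E[y_i] = x_i^\top \beta\), fitted by weighted pseudo-ML; variances
linearize the weighted score over PSUs within strata, the same estimator
used for all prevalences.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (about two minutes end to end):

```bash
python analysis/01_simulate.py     # ~150k students, 4,000 schools
python analysis/02_score.py
python analysis/03_prevalence.py
python analysis/04_associations.py
```

`02_score.py` prints the exclusion accounting:

```
initial n=149,579; valid n=143,923 (96.2% retained, 5,656 absent)
```

`03_prevalence.py` prints the design summary and the headline prevalences:

```
design: 10 strata, 4,000 schools, df=3,990, weighted total 15,158,484
ideal: full adherence 0.0% (0.0; 0.0)
possible: full adherence 0.4% (0.3; 0.4)
```

i.e. essentially no adolescent meets all ten practices at the ideal
thresholds, and 0.4% (95%CI 0.3; 0.4) meet them at the possible
thresholds — the outcome modeled in step 4. `04_associations.py` then
prints the screen (here sex, race, area, region, territory, body
satisfaction and self-rated health pass at p<0.20), the backward-
elimination trace, and the adjusted PRs next to the generating truth, e.g.

```
area[rural]: 2.12 (1.76; 2.57)  truth 1.91
territory[out_of_capital]: 1.28 (1.05; 1.56)  truth 1.33
body_satisfaction[very_happy]: 2.24 (1.46; 3.44)  truth 2.72
```

Rare reference categories (very bad self-rated health, ~6 outcome cases)
give very wide, unstable PRs in any single run — the same instability the
original survey analysis reports for that block.

Tables land in `results/` (`02_exclusion_report.csv`,
`03_prevalence_table.csv`, `04_association_table.csv`,
`04_selection_trace.json`); bulky microdata go to `scratch/`. The same
pipeline runs from the command line (`guia simulate`, `guia run`,
`guia score`, `guia reproduce`) or the library API (see
`guia_adherence.pipeline.run`).

To rerun the published analysis on the real microdata, download the public
PeNSE 2019 student file from IBGE, write a dictionary YAML mapping its raw
columns to the canonical variables (`guia_adherence.simulate.make_dictionary`
shows the layout), and call `guia reproduce --in <csv> --dictionary <yaml>`;
the result is compared side by side with the published reference values
shipped in `data/published_values.yaml`.

## Layout

```
src/guia_adherence/   microdata.py   dictionary-driven loading + absent(99) rule
                      scoring.py     component rules, both variants, outcome
                      survey.py      weighted proportions, Taylor variance, CIs
                      association.py Poisson PRs, screen, backward elimination
                      simulate.py    synthetic survey + worked 50-record fixture
                      pipeline.py    end-to-end runs, manifest, reproduction
                      cli.py         `guia` command
analysis/             numbered narrative drivers (synthetic study)
tests/                unit, property and acceptance suites
docs/methods.md       model, assumptions, calibration and design choices
```
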