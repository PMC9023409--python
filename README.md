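# eq5dsim

Simulation framework for comparing missing-data strategies in longitudinal
EQ-5D-5L analyses.

## The problem

The EQ-5D-5L is a five-item health-related quality-of-life questionnaire
(mobility, self-care, usual activities, pain/discomfort, anxiety/depression;
five severity levels per item, hence 5⁵ = 3125 health states).  A profile is
converted into a single utility index by a value set — a constant minus one
decrement per dimension whose level exceeds 1 — and the index cannot be
computed when *any* item is missing.  In longitudinal studies, dropout is
usually health-related, so complete-case analyses are biased, and it is not
obvious whether multiple imputation (MI) should be done at the *item* level
(impute the five responses, then rescore) or the *score* level (impute the
index directly), or whether a mixed model on all available data suffices.

`eq5dsim` implements the full simulation machinery for studying this
question when the original patient-level cohorts cannot be redistributed:

1. **synthetic cohorts** — a graded latent-Gaussian threshold model produces
   complete 2–3-wave panels of ordinal items with covariates (age, gender,
   marital status, academic status, self-rated health), a subject random
   intercept and a configurable time trend (presets: an improving
   rehabilitation-like cohort, n=450, and a slowly deteriorating
   chronic-disease-like cohort, n=2040);
2. **scoring** — additive value sets, the non-scorability rule, and loaders
   for user-supplied tariffs (two synthetic tariffs ship with the package);
3. **amputation** — multivariate MAR amputation: per-subject missingness
   patterns (unit vs. item non-response), weighted sum scores of the
   auxiliary covariates, and a right-tailed logistic allocation calibrated
   to overall levels of 5–65% of subjects;
4. **imputation** — MI by EM-with-bootstrap (EMB) under a joint
   multivariate-normal working model with an orthogonal-polynomial time
   basis, at item level (rounded/clipped, rescored) and score level;
5. **modelling** — a random-intercept linear mixed model
   `index ~ time + age + gender + academic + srh + (1 | subject)` fitted by
   profiled REML, with marginally standardized predicted means per
   timepoint;
6. **pooling** — Rubin's rules (Q̄, W, B, T = W + (1+1/M)B, df);
7. **evaluation & pipeline** — bias/SE/MSE surfaces against the
   complete-data truth, item-misspecification tables, qualitative ordering
   flags, and a seeded, fully deterministic factorial driver with a CLI.

## Worked example

Generate a complete cohort, ampute 65% of subjects with health-weighted MAR
dropout, and compare the four analysis approaches:

```python
import eq5dsim as e

vs = e.synthetic_5l_value_set()
cohort = e.score_dataset(e.generate_cohort(e.gr_like(seed=1)), vs)
truth, beta_true = e.truth_reference(cohort, vs)          # complete-data truth
amputed = e.ampute(cohort, e.build_gr_schedule(65), seed=2)

e.run_approach_1_cc(amputed, vs)                          # complete cases
e.run_approach_2_available(amputed, vs)                   # all available data
e.run_approach_3_mi_score(amputed, vs, M=10, seed=3)      # MI of scores
e.run_approach_4_mi_item(amputed, vs, M=10, seed=3)       # MI of items
```

Output (predicted mean index per timepoint, model/Rubin SEs, time slope):

```
truth:     T0=0.7190             T1=0.7847             beta_time=0.0658
       cc: T0=0.7222 (SE 0.0177) T1=0.7952 (SE 0.0177) beta_time=0.0730
available: T0=0.7172 (SE 0.0115) T1=0.7901 (SE 0.0151) beta_time=0.0729
 mi_score: T0=0.7165 (SE 0.0114) T1=0.7837 (SE 0.0166) beta_time=0.0672
  mi_item: T0=0.7169 (SE 0.0105) T1=0.7833 (SE 0.0160) beta_time=0.0664
```

The complete-case estimate sits above the truth at both waves — dropout was
weighted toward poor self-rated health, so the surviving complete cases are
healthier than the cohort — while the available-data mixed model and both
MI approaches stay close to the truth.  Averaged over replicates (see the
pipeline below), complete cases are the highest at every missingness level
with an MSE that grows with the missingness proportion, and the
available-data and score-MI trajectories agree to a few thousandths of an
index point.

The same experiment, as a factorial over levels × replicates, from the
shell:

```bash
eq5dsim run --config examples/gr_like.yaml
eq5dsim simulate-cohort --preset gr --n 450 --seed 1 --out cohort.csv
eq5dsim ampute --data cohort.csv --level 65 --seed 2 --out amputed.csv
eq5dsim fit --data amputed.csv
```

`run` writes `scenario_summary.csv` (per approach × timepoint: mean
estimate, mean SE, empirical SD, MSE vs. truth, mean time slope),
`results_raw.csv`, `orderings.csv`, `misspecification.csv` (percentage of
item-MI imputations at each difference true − imputed, per item) and a
`manifest.json` recording the configuration and master seed.

## Documentation

`docs/methods.md` describes the generator, the amputation mechanism, the
EMB imputation model, the mixed model and the evaluation conventions,
including all tunable parameters and known limitations.
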