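# bsisurv

Survival analysis of **regional Bone Scan Index (BSI)** measurements in
advanced prostate cancer.

The BSI quantifies skeletal metastatic burden on a bone scan as the
percentage of total skeletal mass occupied by metastatic hotspots: each
hotspot contributes `(hotspot area / region area) × region mass fraction`,
summed per anatomical region (twelve regions) and over regions into the
total BSI. Total BSI is an established prognostic biomarker; the question
this package is built around is whether the *regional* breakdown — where
the metastases sit — adds prognostic value beyond the total, and whether
any such value is linear or hides in non-linear interactions.

It is aimed at biostatisticians and nuclear-medicine researchers who want a
tested, reusable pipeline for that comparison:

* **Models** — Cox proportional hazards (Newton–Raphson, Breslow ties,
  written here and cross-checked against lifelines) and ensembles of small
  neural networks (15 members × 3 tanh hidden units) trained by bagging to
  directly maximize Harrell's concordance index
  C = (concordant + ½·tied) / usable pairs.
* **Evaluation** — repeated event-stratified k-fold cross-validation
  (default 20×3) on shared, hashed fold partitions; univariate region scan;
  coupled backward-elimination / forward-addition region ranking; a
  non-linearity screen placing each region by univariate linear performance
  versus multivariate knockout importance.
* **Descriptives** — positive-subset Pearson correlations with p-values,
  reference-style summary tables, Kaplan–Meier 5-year survival by
  metastatic-burden group with log-rank tests (via lifelines).
* **Synthetic cohorts** — a calibrated generator (zero-inflated log-normal
  regional burdens coupled by a Gaussian copula, independent age, Weibull
  proportional-hazards survival with censoring tuned to a target fraction,
  Poisson lesion counts) standing in for unavailable patient data, with
  known ground truth for recovery tests. See `docs/methods.md` for the
  model and every default.

## Worked example

```python
import bsisurv as bs

# a calibrated synthetic cohort of 1,013 patients
cohort = bs.generate_cohort(bs.default_config(n=1013, seed=1))

summary = bs.cohort_summary(cohort)
print(f"censored: {summary.attrs['censored_fraction']:.1%}, "
      f"mean follow-up: {summary.attrs['mean_followup_years']:.2f} y")

flags = bs.flag_strong_pairs(bs.pairwise_correlations(cohort))
print(f"{flags['n_flagged']} region pairs with |rho|>=0.7 (p<0.05); "
      f"least correlated: {flags['least_correlated']}")

# does any single region rival the total burden?
scan = bs.univariate_region_scan(cohort, repeats=5, folds=3, seed=0)
best = max((r for r in scan if r != "total_bsi"), key=lambda r: scan[r].median)
print(f"age + total BSI : C = {scan['total_bsi'].median:.3f}")
print(f"age + {best:9s}: C = {scan[best].median:.3f}")
```

prints

```
censored: 32.1%, mean follow-up: 2.59 y
10 region pairs with |rho|>=0.7 (p<0.05); least correlated: Skull
age + total BSI : C = 0.692
age + Pelvis   : C = 0.685
```

Read: about a third of patients are censored; the regional burdens are
strongly cross-correlated (ten strong pairs among the axial cluster);
the best single region ranks patients essentially as well as the total
burden, and (running `backward_elimination` / `forward_addition`, or the
`rank` CLI command) no multivariate combination of regions does better than
age + total BSI on this additive cohort — while the `screen` command shows
an empty upper-left quadrant, i.e. no region is more important to a
non-linear model than its linear performance warrants.

The same pipeline is scriptable from the shell:

```bash
bsisurv simulate --n 1013 --seed 1 --out cohort.csv
bsisurv describe cohort.csv
bsisurv scan cohort.csv --repeats 5 --seed 0
bsisurv rank cohort.csv --repeats 5 --seed 0
bsisurv screen cohort.csv --repeats 10 --seed 0
```

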