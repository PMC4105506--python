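# Methods

`bsisurv` analyses the prognostic value of *regional* Bone Scan Index (BSI)
measurements for overall survival in advanced prostate cancer. The BSI is
the percentage of total skeletal mass occupied by metastatic hotspots on a
bone scan; it is computed per anatomical region (twelve regions: cervical,
thoracic and lumbar spine, clavicle, ribs, femur, humerus, pelvis, sacrum,
scapula, skull, sternum) and summed into the total BSI. The scientific
question the pipeline addresses is whether knowing *where* the burden sits
improves survival prediction over knowing only *how much* there is.

## Models and performance measure

**Concordance index.** All models are scored by Harrell's C: the fraction
of usable patient pairs in which the patient with the higher predicted risk
died first. A pair (i, j) is usable when `t_i < t_j` and patient *i*'s
death was observed; pairs with exactly tied observed times are excluded,
and tied risk scores count 1/2. This strict-tie convention is fixed so
results are reproducible bit for bit; generated survival times are
continuous, so time ties essentially never occur in simulation.

**Cox proportional hazards** is the linear reference. The Breslow partial
likelihood is maximized by Newton–Raphson with step-halving (convergence:
max |gradient| < 1e-7, at most 100 iterations; singular information
matrices fall back to a small ridge and are flagged). Breslow rather than
Efron tie handling was chosen because ties are rare in continuous simulated
data — with no ties the two coincide, which is also how the implementation
is cross-checked against lifelines. Covariates are standardized to zero
mean and unit sample standard deviation (n−1 denominator, recorded in the
stored normalization parameters); standardization is always fitted on
training rows only and re-applied to validation rows. Survival time is
never transformed for Cox, since risk-set ordering is invariant to monotone
transforms.

**ANN ensembles** are the non-linear comparator: 15 members per ensemble,
each a one-hidden-layer perceptron with 3 tanh units and a linear output
producing a scalar prognostic index (its only contract is the ordering of
patients). Each member trains on a bootstrap bag of the training set and
maximizes the C-index on its bag directly. Because the exact C-index is
piecewise constant in the weights, the default optimizer performs Adam
ascent on a smoothed surrogate — the mean over usable pairs of
`sigmoid((s_i − s_j)/τ)` with τ = 0.1 — while the exact bag C-index,
evaluated every 10 iterations, selects which iterate is kept. Usable pairs
are capped at 10,000 per bag (seeded subsample) to bound the per-iteration
cost. Weights initialize uniform(−0.5, 0.5); the default budget is 500
iterations with learning rate 0.05. A seeded evolution-strategy backend
(Gaussian perturbations, exact-C selection) is available as an alternative;
both backends are interchangeable behind the same configuration. The
ensemble index is the mean of member outputs.

**Knockout importance.** The multivariate importance of a covariate to a
trained ensemble is the drop in validation C when that input column is
replaced by its training mean (zero after standardization), with no
retraining.

## Evaluation harness

Repeated stratified k-fold cross-validation, default 20×3 (most analyses
here use a scaled-down 5×3; see *Problem sizes*). Fold partitions are
stratified by event status, drawn from a seeded, model-independent fold
stream, and hashed: every model compared at a given point sees identical
partitions, so comparisons are paired. The selection criterion throughout
is the **median** validation C-index (means and SDs are recorded too).

**Univariate region scan** — thirteen Cox models (each region + age, plus
age + total BSI) on a shared fold stream.

**Backward elimination / forward addition** — starting from all twelve
regions + age, every candidate one-region-removed model is re-fitted and
cross-validated; the region whose removal costs least (by median C) is
dropped, ties broken by the fixed canonical region order. The complementary
forward models (age + regions in removal order) audit whether removals were
forced by correlation overlap rather than uselessness: with strong
inter-region correlation the forward curve reaches the backward plateau
quickly. For ANN-based elimination the within-step ranking uses knockout
importance on a single ensemble without retraining, and the chosen reduced
model is then re-fitted for the step's reported performance; Cox refits
everywhere (the standard reading of creating a new model per step).

**Non-linearity screen** — per repeat (default 10; no cross-validation
here, a fresh 2/3-1/3 train/evaluation split instead), each region is
placed by (a) the held-out C of a Cox model on that region + age and (b)
its knockout drop in an ANN ensemble trained on all regions + age. Means
and SDs over repeats are reported. Quadrant boundaries default to the
midpoint of each axis's observed range — the halves of the plot — and are
always recorded; boundary points classify as lower/left. (Per-axis medians
were rejected as the default: they force six of twelve regions above the
importance boundary even when every knockout drop is noise around zero, so
an empty upper-left would be structurally impossible.) A region in the
upper-left —
individually weak but multivariately relied upon — is the signature of a
non-linear interaction. The univariate axis is Cox-based (the linear
benchmark is what "univariately weak" should mean here).

## Synthetic cohorts

No patient-level data ship with the package; the generator reproduces the
statistical structure such a cohort exhibits, with known ground truth:

* **Regional BSI marginals** are zero-inflated log-normals. From a
  per-region summary (mean, median, SD, % zeros) the positive part is
  solved by moment matching: positive mean = mean/(1−z), positive second
  moment = (sd²+mean²)/(1−z), mapped to log-normal (μ, σ). The shipped
  reference summary describes a 1,013-patient hospital cohort (e.g. ribs:
  mean 0.30, SD 0.56, 52% zeros; pelvis: mean 0.78, SD 1.23, 41% zeros).
* **Dependence** comes from a single Gaussian copula draw per patient: the
  lowest `zero_fraction` quantiles of each latent coordinate map to zero,
  the rest through the positive-part quantile function, so zero patterns
  and positive values are correlated by one mechanism. The default latent
  correlation is 0.9 within the axial cluster that carries most burden
  (thoracic + lumbar spine, pelvis, ribs, scapula) and 0.3 elsewhere,
  projected to the nearest PSD correlation matrix. Zero-inflation
  attenuates dependence: latent 0.9 yields positive-subset Pearson ≈ 0.8,
  so the ten cluster pairs are flagged at the conventional |ρ| ≥ 0.7
  threshold, the sacrum is the least-correlated region, and a cluster
  region the most — the qualitative pattern such cohorts show. (A latent
  0.75, the first value tried, attenuates to ≈ 0.55 and produces no strong
  pairs at all, which is why the default is higher.)
* **Age** is truncated-normal (mean 77.02, SD 9.13, bounds 40–100), drawn
  independently of all BSI values.
* **Survival** follows a Weibull proportional-hazards law, shape 1.2,
  scale 3.0 years. The default log-hazard is 0.04 per year of age plus
  0.35 per total-BSI percent, covariates centred at their configuration
  means so the baseline stays on a sensible time scale. These defaults were
  fixed once so that a Cox model on age + total BSI cross-validates at
  C ≈ 0.70 and the mean observed follow-up is ≈ 2.3–2.5 years at the
  censoring target — the operating point of the motivating study. The true
  region-level dependence in any real cohort is unknown; total-burden-only
  hazard is this package's modelling choice and also the null scenario the
  headline analysis needs.
* **Censoring** is administrative-uniform on (0, W], with W tuned by
  bisection on the realized sample so the censored fraction hits the
  target (default 32%). Real cohorts censor by staggered accrual; a uniform
  window reproduces the fraction and roughly the follow-up scale, not the
  accrual process.
* **Lesion counts** are Poisson with rate 2.5 per total-BSI percent (zero
  burden ⇒ zero lesions) — a coarse device so that lesion-count survival
  groups (none / any / ≤5 / >5) order as clinical series report; the
  absolute 5-year rates of such series are properties of their cohorts and
  are not calibration targets.
* **Optional interaction**: a multiplicative term `strength · z_a · z_b`
  on the in-sample standardized columns of two regions. Note a caveat
  discovered during validation: with zero-inflated margins the standardized
  product is *not* exactly univariately null — the point mass at zero makes
  the conditional hazard asymmetric, so a linear model can pick up part of
  the signal. The shipped positive-control configurations are designed
  around this: `interaction_only_config` (hazard = age + interaction only)
  is where the ensemble's direct C-advantage over Cox is measured, and
  `screen_control_config` (main effects on the ten other regions, the
  interacting pair decorrelated from the rest of the skeleton) is where the
  pair lands in the screen's upper-left quadrant. `sparse_signal_config`
  (three informative regions on a flat copula, per-SD effect 0.4) is the
  ground-truth scenario for ranking tests.

Everything is deterministic given the config seed; member training, fold
streams and screen splits all derive from seeded generators.

## What the simulations do and do not show

Passing tests show the machinery is sound: the C-index matches brute-force
enumeration exactly; Cox recovers known log hazard ratios with honest
standard errors; the generator hits its marginal and censoring targets; on
additive cohorts the ensemble matches Cox and no regional subset beats age
+ total BSI; with a planted interaction the ensemble wins and the screen
flags the pair; with planted sparse signal the elimination keeps the
informative regions longest. They do **not** show that any particular real
cohort's numbers are recovered — headline statistics of a specific patient
population (C ≈ 0.704, 5-year rates, the exact correlation table) are
properties of that population, and the synthetic cohort reproduces their
qualitative pattern, not their values.

## Problem sizes and numerical choices

Analyses in the shipped tests and in `scripts/acceptance.py` use 5×3
repeated CV (vs the 20×3 default), ANN budgets of 200–500 iterations, and
cohorts of n = 1,000–1,013 (n = 100,000 for marginal calibration checks) —
sizes chosen so the full suite runs on a laptop-class single core in
minutes while leaving the Monte-Carlo noise well below the effect sizes
being asserted. Degenerate inputs are handled explicitly: constant
covariate columns are centred and flagged rather than divided by zero;
all-censored bags are redrawn (bounded retries); folds without usable pairs
void and redraw the repeat with a note; an undefined C-index raises rather
than returning a number.

## Known limitations

* The ensemble optimizer is a smoothed-surrogate gradient method, not the
  population-based search used in earlier work on direct C-index
  optimization; it is validated by its behavior (matching Cox on linear
  data, beating it on interaction data), not by matching any specific prior
  optimizer.
* Pairwise-deletion correlation matrices (positive-subset computation) need
  not be positive semidefinite; only symmetry and range are guaranteed.
* The generator does not model accrual, treatment, PSA/Gleason/stage, or
  bone-scan image artefacts; lesion counts are a Poisson device, not an
  image-derived quantity.
* Group definitions for the survival table (lesions = 0 vs > 0, cutoff 5)
  are configurable because clinical series are inconsistent about whether
  "no metastases" means zero burden or zero detected lesions.
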