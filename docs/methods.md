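# Methods

This note documents the models, defaults and numerical choices behind
`icufluid`, and what the synthetic-data experiments do and do not establish.

## The synthetic cohort generator

The generator stands in for access-restricted ICU databases. It emulates the
*structure* of a critically ill heart-failure cohort, not the marginal
distribution of any real variable.

**Latent phenotypes.** Each patient draws one of four phenotypes A–D with
prevalences 0.3249 / 0.1831 / 0.2796 / 0.2124 (the published phenotype sizes
1949 / 1098 / 1677 / 1274 over 5998 stays). Baseline features are ten
numerics (Normal per phenotype) and eleven binaries (Bernoulli per
phenotype). Where the published baseline table prints per-phenotype values
(age, weight, SOFA, Charlson index, and all binary percentages) the generator
uses them as means/probabilities. The remaining lab/vital means (BUN,
creatinine, DBP, hematocrit, anion gap, heart rate) were chosen once as
clinically coherent profiles — A: respiratory failure/shock/inflammation
(tachycardic, hypotensive); B: younger, heavier, mild; C: elderly,
comorbid, haemodynamically quiet; D: renal dysfunction and metabolic
acidosis — separated enough that the four-group structure is genuinely
recoverable, which is the premise of the recovery experiments.

**Longitudinal process.** With aₜ = Aₜ/1000 (daily net fluid balance in
litres) and L the scalar severity composite (initialised at baseline SOFA):

    Lₜ = α₀ + α₁·Lₜ₋₁ + α₂·aₜ₋₁ + ε_L,   ε_L ~ N(0, σ_L²)
    Aₜ = β₀ + β_L·Lₜ + ε_A,              ε_A ~ N(0, σ_A²)
    hₜ = logit⁻¹(θ₀ + θ_L·Lₜ + θ_A·aₜ + θ_{A²}·aₜ² + θ_t·t)

Defaults: α = (0.6, 0.85, 0.4), σ_L = 1; β = (−100 mL, 150 mL per severity
unit), σ_A = 1200 mL; per-day discharge (censoring) probability 0.08. β_L > 0
makes fluid confounded by severity; α₂ > 0 gives fluid an additional causal
pathway through future severity. θ_{A²} > 0 makes the daily-balance effect
U-shaped, so an optimal *range* exists: the hazard is minimised at
a\* = −θ_A/(2·θ_{A²}) litres. The default phenotypes place a\* at −250 mL
(A), −500 mL (C) and −1250 mL (D), the centres of clinically recommended
ranges; B has no fluid effect. Hazard intercepts were calibrated once by
bisection against the generator's own oracle so that 7-day mortality under
no censoring matches the published in-hospital mortality fractions
(10.06 / 6.74 / 12.70 / 19.62 %); daily hazards then order D > C > A > B.

**Oracle.** `true_counterfactual_risk` simulates the generative law itself
with the daily balance clamped and discharge disabled, so the estimand — 7-day
mortality under a range strategy with no censoring — is known to Monte-Carlo
precision √(0.25/n_mc). Every g-formula validation compares against it.

What the generator does *not* emulate: skewed/heavy-tailed labs, informative
censoring, measurement error, missingness mechanisms other than MCAR,
cross-database shift. Passing tests therefore show the estimation chain is
correct *when its assumptions hold*, not that the assumptions hold in any
real ICU.

## Preprocessing

Features with missing fraction strictly above 0.30 are dropped ("more than",
so a column at exactly the threshold survives). Imputation is single
median/mode (ties to the lexicographically smallest level) — the simplest
defensible default, recorded per column in the `PreprocessReport`.
Min–max scaling to [0,1] is the clustering default so numeric features
contribute comparably to the mixed distance; z-scoring is provided, and the
fitted parameters replay onto held-out data. Correlation pruning uses
Spearman's ρ (robust to skewed labs): offending pairs are visited in
descending |ρ| and the member with the larger mean absolute correlation to
all other numerics is dropped (tie → the later column), threshold 0.8.

For the profile panel, per-feature group means are centred on the
*unweighted* mean of group means and divided by the largest absolute
deviation, mapping every feature onto [−1, 1] with identical groups at 0 and
two groups always at ±1.

## K-prototypes

Alternating minimisation with numeric prototypes = cluster means and
categorical prototypes = cluster modes (ties → lexicographically smallest
level); empty clusters are reseeded from the point farthest from its current
prototype; best of `n_init = 10` seeded restarts (ties → the earlier
restart) with `max_iter = 100`. γ = "auto" is Huang's heuristic, 0.5 × mean
numeric column sd. On toy tables (n ≤ 8) best-of-60-restarts reproduces the
global optimum found by exhaustive enumeration of all assignments; with
γ = 0 and no categoricals the procedure coincides with k-means.

`select_k` reports the cost elbow and the mean silhouette for every k and
returns the silhouette argmax. The silhouette is computed on the **square
root** of the mixed dissimilarity: the silhouette statistic expects a
distance, and feeding it the squared form inflates apparent separation (a
single Gaussian blob scores ≈ 0.36 on the squared form but ≈ 0.23 on the
root form, matching the usual "no structure" reading). Diagnostics carry a
"no strong cluster structure" flag when no k reaches silhouette 0.25 — note
that realistic EHR-like cohorts, including the default generator, sit below
this bar even when the clustering is recoverable; the flag marks weak
geometric separation, not failure. Cluster stability is quantified as the
adjusted Rand index between assignments before and after correlation pruning.

## Group comparison conventions

Numeric: median (Q1, Q3) per group with the Kruskal–Wallis test. Categorical:
count (percent) with the chi-square test on the full level × group table, no
continuity correction. Percentages are 100·count/group-size rounded
**half-up** to two decimals, so published-style cells (including ".48")
reproduce exactly from counts. Survival curves are product-limit estimates
(lifelines) truncated at each horizon with the multivariate log-rank test;
event times are day-of-event + 1, administrative end-of-window counts as
censoring.

## Parametric g-formula

**Models** (all pooled over person-days; censored patients contribute their
observed days, censoring assumed non-informative given modelled history):

* each time-varying covariate: OLS on (lagged covariates, lagged fluid in
  litres, optional baseline features, day), fit over days t ≥ 1; the day −1
  lag comes from a designated baseline feature (SOFA by default), so the same
  fitted equation rolls the simulation forward from day 0;
* daily fluid balance: OLS on (current covariates, baseline features, day),
  Gaussian residual;
* death hazard: pooled logistic on (current covariates, a, a², baseline
  features, day). The quadratic term is essential — a purely linear effect
  cannot produce a range-shaped optimum. Collinear columns are dropped
  greedily before fitting; non-convergence or zero events raises an error
  naming the model; fewer than 30 events warns.

**Simulation.** Each replicate draws a baseline row with replacement, rolls
covariates and fluid forward with Gaussian residuals, clamps the fluid into
the intervention range, and accumulates expected hazard:
r_t = 1 − E[Π_{s≤t}(1 − h_s)]. No death events are sampled — this is
unbiased for the same estimand with visibly lower Monte-Carlo variance. The
reported `mc_se` is the replicate standard error of the survival product.

**Common random numbers.** `intervention_grid` simulates every cell with the
same seed, so contrasts between strategies are far more precise than the
per-cell `mc_se` suggests; comparisons of a spread against "3 pooled MC SEs"
are therefore conservative. Range interventions are truncations of the
natural draw, preserving within-range variability; degenerate cells
(lower = upper) are fixed-dose strategies. When localising an optimal
*range*, the argmin is taken over non-degenerate cells: a fixed dose 250 mL
off the optimum ties with the optimal 500 mL range within oracle precision,
so including the diagonal makes the question ill-posed at that grid step.

**Uncertainty.** Percentile 95% bootstrap with patient-level resampling
(default 500 replicates; the design matrices are built once, so a refit only
gathers rows). Replicates that fail to refit are skipped with a warning;
more than 20% failures aborts. The interval is clipped to bracket the
full-data point estimate.

**Problem sizes used in validation** (chosen to make each check sharp on one
core): consistency and optimum-localisation at n = 5000 patients,
n_mc = 20 000, oracle at 200 000 — estimator–oracle gaps come out ≈ 0.006,
well under the 0.02 band. Null-effect flatness at n = 40 000 so that hazard
coefficient noise (the only source of spread once the generative fluid effect
is zero *through both pathways*, hazard and severity feedback) is small
against the Monte-Carlo yardstick. Bootstrap coverage at n = 600,
n_boot = 200, n_mc = 600 over 50 outer replications, for the one-sided
restrictive strategy (daily balance ≤ 0 mL): long-run coverage of the 95%
interval measures ≈ 96% there and ≈ 98% for the natural course. Tight
two-sided clamps run a little lower (≈ 93–94%): their risk depends on the
fitted quadratic coefficient nonlinearly enough that the percentile interval
inherits some skew — a known small-sample property of percentile bootstraps,
not specific to this implementation.

## JMIM and the classifier

Mutual information is the plug-in estimate in bits; continuous features are
discretised at their quantiles (5 bins by default; ties collapse bins, values
equal to an edge fall below it). JMIM greedily selects
argmax_c min_{s∈selected} I(X_c, X_s; Y), seeded with argmax I(X; Y), ties to
the earlier column. A feature's raw score is the criterion value at its
selection and importances are normalised by the largest raw score, so a fixed
threshold (default 0.8) yields a deterministic subset. Note a structural
property of the criterion: I(X_c, X_s; Y) ≥ I(X_s; Y), so once a very strong
feature is selected, every later candidate inherits at least that feature's
information — with near-deterministic features the normalised scores
saturate. On the default cohort the 0.8 cutoff keeps fewer variables than a
real EHR cohort would; the distilled-classifier demonstrations therefore use
the nine top-ranked features (the published classifier's size). The
classifier is XGBoost (200 trees, depth 4) on a stratified 70/30 split with
one-vs-rest AUC per phenotype; net benefit follows the standard
decision-curve definition with treat-all/treat-none references.

## Determinism

Every stochastic routine takes an explicit seed; the pipeline derives one
seed per stage from the master seed by hashing the stage name, so stages can
be re-run in isolation and whole runs are byte-identical. Mode/assignment
ties, restart ties and collinearity drops are all resolved by fixed rules.

## Known limitations

Single imputation understates uncertainty; the g-formula's covariate and
treatment models are linear-Gaussian (adequate for the generator's law,
optimistic for real labs); discharge is independent censoring, not a
competing risk; the silhouette criterion for k can prefer coarse splits when
one group is much more distinct than the rest; JMIM importances are
comparable only within one dataset.
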