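# icufluid

Phenotyping of critically ill heart-failure patients and counterfactual
evaluation of daily fluid-balance strategies.

Heart failure in the ICU is heterogeneous: the same diagnosis covers young
patients with isolated pump failure, elderly multimorbid patients, patients in
shock on a ventilator, and patients dominated by renal and metabolic
derangement. Those groups plausibly need *different* daily fluid management —
a net balance that helps one may harm another. `icufluid` implements the full
analysis chain for this question on mixed-type electronic-health-record
tables:

1. **Unsupervised phenotyping** — from-scratch K-prototypes clustering for
   mixed numeric/categorical data. The dissimilarity between a record *x* and
   a cluster prototype *(μ, m)* is Huang's

   d(x, (μ, m)) = Σⱼ (xⱼ − μⱼ)² + γ · Σⱼ 1[xⱼ ≠ mⱼ],

   with γ weighting categorical mismatches (default ½·mean numeric sd). The
   number of clusters is chosen by the mean silhouette on this dissimilarity,
   with the elbow curve and a cluster-stability ARI check exposed alongside.
2. **Phenotype profiling** — baseline-characteristics tables (median (Q1,Q3)
   with Kruskal–Wallis, n (%) with chi-square, percentages rounded half-up),
   comorbidity co-occurrence matrices for chord diagrams, and Kaplan–Meier /
   log-rank survival contrasts.
3. **Parametric g-formula** — for the first 7 ICU days, fit pooled models for
   the time-varying severity covariate Lₜ, the daily net fluid balance Aₜ and
   the discrete-time death hazard
   hₜ = logit⁻¹(θ₀ + θ_L Lₜ + θ_A aₜ + θ_{A²} aₜ² + θ_t t)  (aₜ = Aₜ/1000 mL),
   then Monte-Carlo simulate the cumulative mortality risk
   r_T = 1 − E[Π (1 − hₜ)] under *range interventions* that clamp each day's
   natural balance into [lower, upper] mL. Percentile bootstrap CIs, a
   natural-course diagnostic and per-phenotype strategy grids are included.
4. **Phenotype distillation** — JMIM (joint mutual information maximisation)
   feature ranking, an XGBoost phenotype classifier with one-vs-rest AUC, and
   decision-curve net benefit NB(p_t) = TP/N − FP/N · p_t/(1−p_t).

The real cohorts behind such studies (MIMIC, eICU) are access-restricted, so
the package ships a **synthetic cohort generator** with four latent
phenotypes (prevalences and feature profiles echoing a published 5998-stay
cohort), a confounded fluid process, and a U-shaped fluid–mortality hazard —
plus an exact oracle for true counterfactual risks, so the whole estimation
chain is validated against a known ground truth.

## Worked example

```python
from icufluid import (default_phenotypes, default_trajectory, default_units,
                      generate_cohort, impute, scale_numeric, select_k,
                      fit_kprototypes, adjusted_rand_index)

baseline, persondays = generate_cohort(
    default_phenotypes(), default_trajectory(), n=2000, seed=2,
    units=default_units())
complete, _ = impute(baseline)
scaled, _ = scale_numeric(complete, "minmax01")
k, diag = select_k(scaled, (2, 8), seed=2)
model, labels = fit_kprototypes(scaled, k=k, seed=2)
truth = baseline.df.set_index("patient_id")["true_phenotype"]
print(k, adjusted_rand_index(labels, truth))
```

prints `4 0.844...`: the silhouette picks four clusters and the recovered
partition agrees with the latent phenotypes at ARI ≈ 0.84 (1.0 would be a
perfect relabelling). Running `examples/04_fluid_strategies.py` then shows
the causal half of the pipeline on a cohort whose hazard is minimised at
−750 mL/day:

```
natural-course diagnostic: max |simulated - observed| = 0.0042
risk under selected strategies (estimate vs generative-oracle truth):
        natural course: 0.3386 (truth 0.3338)
      [-1000, -500] mL: 0.1441 (truth 0.1465)
        [500, 1500] mL: 0.2937 (truth 0.2891)
best range strategy: [-1000, -500] mL with risk 0.1446
```

i.e. the g-formula estimate tracks the true counterfactual risk to a few
parts in a thousand, and the risk-minimising range strategy brackets the true
optimum. The `examples/` directory holds one short script per capability
(simulation, clustering, profiling, fluid strategies, classifier
distillation); each prints the numbers it computes and a line on what they
mean. A thin CLI mirrors the stages
(`icufluid simulate|preprocess|cluster|profile|gformula|select-features|classify|run-all`).

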