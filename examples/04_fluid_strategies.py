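"""Estimate in-hospital mortality under daily fluid-balance range strategies
with the parametric g-formula, and check it against the generative oracle.

A strategy clamps each day's natural net fluid balance into [lower, upper]
mL.  The g-formula fits pooled models for severity, fluid and the daily death
hazard, then Monte-Carlo simulates 7-day mortality under each clamp.
"""

from icufluid import (
    InterventionSpec,
    NATURAL_COURSE,
    PhenotypeSpec,
    HazardCoefs,
    TrajectorySpec,
    bootstrap_ci,
    fit_gformula,
    generate_cohort,
    intervention_grid,
    natural_course_check,
    simulate_risk,
    true_counterfactual_risk,
)

# One-phenotype cohort whose hazard is U-shaped in daily fluid with the
# minimum at -750 mL/day.
specs = [
    PhenotypeSpec(
        label="hf",
        prevalence=1.0,
        numeric_means={"sofa": 5.0},
        numeric_sds={"sofa": 1.5},
        categorical_probs={},
        hazard_coefs=HazardCoefs(-4.8, theta_covar=0.25, theta_fluid=0.6, theta_fluid2=0.4),
    )
]
traj = TrajectorySpec(covar_ar=(0.6, 0.85, 0.0, 1.0), treat_model=(-1400.0, 150.0, 1200.0))

baseline, persondays = generate_cohort(specs, traj, n=5000, seed=4)
fit = fit_gformula(baseline, persondays)
print(f"fitted on {len(persondays.df)} person-days, {fit.n_events} deaths")

sim, obs, gap = natural_course_check(fit, persondays, n_mc=20000, seed=5)
print(f"natural-course diagnostic: max |simulated - observed| = {gap:.4f}")

print("\nrisk under selected strategies (estimate vs generative-oracle truth):")
for iv in (NATURAL_COURSE, InterventionSpec(-1000, -500), InterventionSpec(500, 1500)):
    est = simulate_risk(fit, iv, n_mc=20000, seed=6)
    oracle = true_counterfactual_risk(specs, traj, iv, n_mc=200000, seed=7)
    print(f"  {iv.label:>20}: {est.point:.4f} (truth {oracle:.4f})")

bounds = [-3000.0, -2000.0, -1000.0, -500.0, 0.0, 1000.0]
grid = intervention_grid(fit, bounds, bounds, n_mc=20000, seed=8)
ranges = grid[grid["lower"] < grid["upper"]]
best = ranges.loc[ranges["risk"].idxmin()]
print(f"\nbest range strategy: {best['label']} with risk {best['risk']:.4f}")
print("(the hazard's true optimum is -750 mL/day, inside the chosen range)")

est = bootstrap_ci(baseline, persondays, InterventionSpec(-1000, -500),
                   n_boot=100, n_mc=2000, seed=9)
print(
    f"\nbootstrap 95% CI for the [-1000, -500] mL strategy: "
    f"{est.point:.4f} ({est.ci_lower:.4f}, {est.ci_upper:.4f})"
)
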