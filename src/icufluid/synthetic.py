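"""Synthetic ICU heart-failure cohorts with latent phenotypes.

The real cohorts behind this kind of study (MIMIC, eICU) are access
restricted, so the package ships a generator that emulates their structure:

* four latent phenotypes with distinct mixed-feature profiles and prevalences,
* a confounded daily net-fluid-balance process over the first ICU days
  (sicker patients accumulate more fluid, and severity drives mortality), and
* a discrete-time mortality hazard with a U-shaped dependence on the daily
  fluid balance, so that an optimal balance *range* exists per phenotype.

Because the data-generating process is known exactly, the module also provides
an oracle, :func:`true_counterfactual_risk`, that computes the true
counterfactual mortality risk under any clamp intervention by brute-force
simulation — the yardstick against which the g-formula estimator is validated.

Generative model
----------------
Patient ``i`` draws a phenotype ``z`` from the prevalence vector, baseline
numeric features from per-phenotype normals and binary features from
per-phenotype Bernoullis.  With ``a_t = A_t / 1000`` (fluid in litres) the
daily process for ``t = 0..T-1`` is::

    L_t = alpha0 + alpha1 * L_{t-1} + alpha2 * a_{t-1} + eps_L   (severity)
    A_t = beta0  + betaL  * L_t     + eps_A                      (fluid, mL)
    h_t = logistic(th0 + thL*L_t + thA*a_t + thA2*a_t^2 + tht*t) (hazard)

with ``L_{-1}`` the baseline severity feature (SOFA) and ``A_{-1} = 0``.
Death on day ``t`` occurs with probability ``h_t``; survivors may be
discharged (censored) with a fixed per-day probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .interventions import InterventionSpec, NATURAL_COURSE
from .schema import (
    ID_COL,
    PHENOTYPE_COL,
    BaselineTable,
    FeatureSchema,
    PersonDayTable,
    ValidationError,
)

BINARY_LEVELS = ("no", "yes")


@dataclass(frozen=True)
class HazardCoefs:
    """Discrete-time logistic hazard coefficients for one phenotype.

    ``theta_fluid`` and ``theta_fluid2`` act on the daily balance in litres
    (mL / 1000); ``theta_fluid2 > 0`` gives a U-shaped dose-response with
    minimum at ``-theta_fluid / (2 * theta_fluid2)`` litres.
    """

    intercept: float
    theta_covar: float = 0.0
    theta_fluid: float = 0.0
    theta_fluid2: float = 0.0
    theta_day: float = 0.0

    def logit(self, L: np.ndarray, fluid_l: np.ndarray, day: float) -> np.ndarray:
        return (
            self.intercept
            + self.theta_covar * L
            + self.theta_fluid * fluid_l
            + self.theta_fluid2 * fluid_l**2
            + self.theta_day * day
        )


@dataclass(frozen=True)
class PhenotypeSpec:
    """Generator parameters for one latent phenotype."""

    label: str
    prevalence: float
    numeric_means: dict[str, float]
    numeric_sds: dict[str, float]
    categorical_probs: dict[str, float]
    hazard_coefs: HazardCoefs

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence <= 1.0:
            raise ValidationError(f"prevalence must be in (0,1], got {self.prevalence}")
        if set(self.numeric_means) != set(self.numeric_sds):
            raise ValidationError("numeric_means and numeric_sds must list the same features")
        bad_sd = {f: s for f, s in self.numeric_sds.items() if not s > 0}
        if bad_sd:
            raise ValidationError(f"numeric sds must be > 0: {bad_sd}")
        bad_p = {f: p for f, p in self.categorical_probs.items() if not 0.0 <= p <= 1.0}
        if bad_p:
            raise ValidationError(f"categorical probabilities must be in [0,1]: {bad_p}")


@dataclass(frozen=True)
class TrajectorySpec:
    """Shared longitudinal process parameters.

    ``covar_ar = (alpha0, alpha1, alpha2, sigma_L)`` drives the severity
    autoregression (``alpha2`` per litre of previous-day fluid);
    ``treat_model = (beta0 mL, betaL mL per severity unit, sigma_A mL)``
    drives the confounded fluid draw.
    """

    horizon_days: int = 7
    covar_ar: tuple[float, float, float, float] = (0.6, 0.85, 0.4, 1.0)
    treat_model: tuple[float, float, float] = (-100.0, 150.0, 1200.0)
    discharge_prob: float = 0.08
    severity_feature: str = "sofa"

    def __post_init__(self) -> None:
        if self.horizon_days < 1:
            raise ValidationError("horizon_days must be >= 1")
        if not self.covar_ar[3] > 0:
            raise ValidationError("sigma_L must be > 0")
        if not self.treat_model[2] > 0:
            raise ValidationError("sigma_A must be > 0")
        if not abs(self.covar_ar[1]) < 1:
            raise ValidationError("|alpha1| must be < 1")
        if not 0.0 <= self.discharge_prob < 1.0:
            raise ValidationError("discharge_prob must be in [0,1)")


def _check_specs(specs: list[PhenotypeSpec]) -> None:
    if not specs:
        raise ValidationError("at least one PhenotypeSpec required")
    total = sum(s.prevalence for s in specs)
    if abs(total - 1.0) > 1e-12:
        raise ValidationError(f"prevalences must sum to 1, got {total!r}")
    ref = specs[0]
    for s in specs[1:]:
        if set(s.numeric_means) != set(ref.numeric_means) or set(s.categorical_probs) != set(
            ref.categorical_probs
        ):
            raise ValidationError("all phenotypes must share the same feature set")


def _schema_for(specs: list[PhenotypeSpec], units: dict[str, str] | None = None) -> FeatureSchema:
    units = units or {}
    ref = specs[0]
    return FeatureSchema(
        numeric={f: units.get(f, "") for f in ref.numeric_means},
        categorical={f: BINARY_LEVELS for f in ref.categorical_probs},
    )


def generate_cohort(
    specs: list[PhenotypeSpec],
    traj: TrajectorySpec,
    n: int,
    seed: int,
    units: dict[str, str] | None = None,
) -> tuple[BaselineTable, PersonDayTable]:
    """Draw a cohort of ``n`` patients and their day-level trajectories.

    Returns the baseline table (with a ``true_phenotype`` column recording the
    latent label) and the person-day table.  Identical arguments yield
    bit-identical output.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    _check_specs(specs)
    if traj.severity_feature not in specs[0].numeric_means:
        raise ValidationError(
            f"severity feature {traj.severity_feature!r} not among numeric features"
        )
    rng = np.random.default_rng(seed)
    baseline, z = _draw_baseline(specs, n, rng, units)
    rows = _simulate_process(
        specs,
        traj,
        z,
        baseline.df[traj.severity_feature].to_numpy(float),
        rng,
        intervention=NATURAL_COURSE,
        discharge=True,
    )
    return baseline, PersonDayTable(rows)


def _draw_baseline(
    specs: list[PhenotypeSpec],
    n: int,
    rng: np.random.Generator,
    units: dict[str, str] | None = None,
) -> tuple[BaselineTable, np.ndarray]:
    prev = np.array([s.prevalence for s in specs])
    z = rng.choice(len(specs), size=n, p=prev / prev.sum())
    data: dict[str, object] = {ID_COL: [f"p{i:06d}" for i in range(n)]}
    ref = specs[0]
    for f in ref.numeric_means:
        means = np.array([s.numeric_means[f] for s in specs])[z]
        sds = np.array([s.numeric_sds[f] for s in specs])[z]
        data[f] = rng.normal(means, sds)
    for f in ref.categorical_probs:
        p = np.array([s.categorical_probs[f] for s in specs])[z]
        data[f] = np.where(rng.random(n) < p, "yes", "no")
    data[PHENOTYPE_COL] = np.array([s.label for s in specs])[z]
    df = pd.DataFrame(data)
    return BaselineTable(df, _schema_for(specs, units)), z


def _simulate_process(
    specs: list[PhenotypeSpec],
    traj: TrajectorySpec,
    z: np.ndarray,
    severity0: np.ndarray,
    rng: np.random.Generator,
    intervention: InterventionSpec,
    discharge: bool,
    collect_rows: bool = True,
) -> pd.DataFrame | np.ndarray:
    """Vectorised day loop shared by the generator and the oracle.

    Returns the person-day DataFrame when ``collect_rows`` else the boolean
    death-by-horizon indicator per patient.  Random draws are taken for every
    patient every day regardless of survival, so the stream is identical
    across interventions with the same seed (common random numbers).
    """
    n = len(z)
    alpha0, alpha1, alpha2, sigma_L = traj.covar_ar
    beta0, betaL, sigma_A = traj.treat_model
    th = [s.hazard_coefs for s in specs]
    intercept = np.array([c.intercept for c in th])[z]
    theta_covar = np.array([c.theta_covar for c in th])[z]
    theta_fluid = np.array([c.theta_fluid for c in th])[z]
    theta_fluid2 = np.array([c.theta_fluid2 for c in th])[z]
    theta_day = np.array([c.theta_day for c in th])[z]

    L_prev = severity0.astype(float)
    a_prev = np.zeros(n)  # litres
    alive = np.ones(n, dtype=bool)
    dead = np.zeros(n, dtype=bool)
    out: dict[str, list[np.ndarray]] = {k: [] for k in ("idx", "day", "fluid", "sev", "died", "cens")}

    for t in range(traj.horizon_days):
        L = alpha0 + alpha1 * L_prev + alpha2 * a_prev + rng.normal(0.0, sigma_L, n)
        A_nat = beta0 + betaL * L + rng.normal(0.0, sigma_A, n)
        A = intervention.apply(A_nat)
        a = A / 1000.0
        h = expit(intercept + theta_covar * L + theta_fluid * a + theta_fluid2 * a**2 + theta_day * t)
        u_death = rng.random(n)
        u_disc = rng.random(n)
        dies_now = alive & (u_death < h)
        if discharge:
            cens_now = alive & ~dies_now & (u_disc < traj.discharge_prob)
        else:
            cens_now = np.zeros(n, dtype=bool)
        if collect_rows:
            idx = np.flatnonzero(alive)
            out["idx"].append(idx)
            out["day"].append(np.full(idx.size, t))
            out["fluid"].append(A[idx])
            out["sev"].append(L[idx])
            out["died"].append(dies_now[idx].astype(int))
            out["cens"].append(cens_now[idx].astype(int))
        dead |= dies_now
        alive &= ~(dies_now | cens_now)
        L_prev, a_prev = L, a

    if not collect_rows:
        return dead
    idx = np.concatenate(out["idx"])
    df = pd.DataFrame(
        {
            ID_COL: np.array([f"p{i:06d}" for i in idx]),
            "day": np.concatenate(out["day"]).astype(int),
            "fluid_balance": np.concatenate(out["fluid"]),
            "severity": np.concatenate(out["sev"]),
            "died": np.concatenate(out["died"]),
            "censored": np.concatenate(out["cens"]),
        }
    )
    return df.sort_values([ID_COL, "day"], kind="stable").reset_index(drop=True)


def true_counterfactual_risk(
    specs: list[PhenotypeSpec],
    traj: TrajectorySpec,
    intervention: InterventionSpec,
    n_mc: int,
    seed: int,
) -> float:
    """Oracle: true risk of death by the end of the horizon under a clamp.

    Simulates the generative process itself with the daily balance clamped
    into the intervention range and discharge disabled (the estimand is
    horizon mortality under no censoring).  Monte-Carlo standard error is at
    most ``sqrt(0.25 / n_mc)``.
    """
    if n_mc < 1:
        raise ValidationError("n_mc must be >= 1")
    _check_specs(specs)
    rng = np.random.default_rng(seed)
    sev_feature = traj.severity_feature
    prev = np.array([s.prevalence for s in specs])
    z = rng.choice(len(specs), size=n_mc, p=prev / prev.sum())
    means = np.array([s.numeric_means[sev_feature] for s in specs])[z]
    sds = np.array([s.numeric_sds[sev_feature] for s in specs])[z]
    severity0 = rng.normal(means, sds)
    dead = _simulate_process(
        specs, traj, z, severity0, rng, intervention, discharge=False, collect_rows=False
    )
    return float(np.mean(dead))


def inject_missingness(
    table: BaselineTable, rates: dict[str, float], seed: int
) -> BaselineTable:
    """Return a copy with cells of the listed features set missing at random.

    Each cell of feature ``f`` is independently blanked with probability
    ``rates[f]``; patient ids are never blanked.
    """
    for f, r in rates.items():
        if not 0.0 <= r <= 1.0:
            raise ValidationError(f"missingness rate for {f!r} must be in [0,1], got {r}")
        if f not in table.features:
            raise ValidationError(f"unknown feature {f!r}")
    rng = np.random.default_rng(seed)
    df = table.df.copy()
    for f, r in rates.items():
        mask = rng.random(len(df)) < r
        if table.schema.is_numeric(f):
            df.loc[mask, f] = np.nan
        else:
            df[f] = df[f].astype(object)
            df.loc[mask, f] = pd.NA
    return table.with_df(df)


# ---------------------------------------------------------------------------
# Default study conditions: a four-phenotype heart-failure ICU cohort.
#
# Prevalences follow the published phenotype sizes (1949/1098/1677/1274 of
# 5998).  Numeric means use the published per-phenotype medians where printed
# (age, weight, SOFA, Charlson) and clinically coherent values elsewhere
# (phenotype A: respiratory failure/shock/inflammation; B: younger, heavier,
# mild; C: elderly with comorbidities; D: renal dysfunction and metabolic
# derangement).  Binary prevalences follow the published percentages.  Hazard
# intercepts are calibrated so 7-day in-hospital mortality lands near the
# published fractions (10.1 / 6.7 / 12.7 / 19.6 %), and the fluid terms place
# each phenotype's optimal daily balance at the centre of its recommended
# range: A -250 mL, B no effect, C -500 mL, D -1250 mL.
# ---------------------------------------------------------------------------

_NUMERIC_UNITS = {
    "age": "years",
    "weight": "kg",
    "sofa": "score",
    "charlson": "score",
    "bun": "mg/dL",
    "creatinine": "mg/dL",
    "dbp": "mmHg",
    "hematocrit": "%",
    "anion_gap": "mEq/L",
    "heart_rate": "bpm",
}

_DEFAULTS = {
    # label: (prevalence, means, sds, binary yes-probs, hazard)
    "A": (
        1949 / 5998,
        dict(age=73.4, weight=79.5, sofa=6.0, charlson=6.0, bun=28.0, creatinine=1.3,
             dbp=50.0, hematocrit=33.0, anion_gap=16.0, heart_rate=102.0),
        dict(age=7.0, weight=14.0, sofa=1.6, charlson=1.5, bun=9.0, creatinine=0.4,
             dbp=8.0, hematocrit=3.5, anion_gap=2.5, heart_rate=11.0),
        dict(female=0.5526, mi=0.3207, hypertension=0.6311, af=0.4649,
             pulmonary_disease=0.3438, renal_disease=0.1339, diabetes=0.3207,
             sepsis=0.1036, vasoactive_drugs=0.7635, mechanical_ventilation=0.8281,
             crrt=0.0118),
        HazardCoefs(-7.349, theta_covar=0.25, theta_fluid=0.15, theta_fluid2=0.30,
                    theta_day=-0.05),
    ),
    "B": (
        1098 / 5998,
        dict(age=57.5, weight=94.8, sofa=4.0, charlson=4.0, bun=18.0, creatinine=1.0,
             dbp=70.0, hematocrit=40.0, anion_gap=12.0, heart_rate=86.0),
        dict(age=6.5, weight=16.0, sofa=1.6, charlson=1.4, bun=7.0, creatinine=0.35,
             dbp=8.0, hematocrit=3.5, anion_gap=2.2, heart_rate=10.0),
        dict(female=0.3097, mi=0.2942, hypertension=0.5756, af=0.3042,
             pulmonary_disease=0.3352, renal_disease=0.1138, diabetes=0.3370,
             sepsis=0.0911, vasoactive_drugs=0.3124, mechanical_ventilation=0.3670,
             crrt=0.0100),
        HazardCoefs(-5.711, theta_covar=0.25, theta_day=-0.05),
    ),
    "C": (
        1677 / 5998,
        dict(age=79.7, weight=76.8, sofa=3.0, charlson=7.0, bun=26.0, creatinine=1.2,
             dbp=62.0, hematocrit=36.0, anion_gap=13.0, heart_rate=78.0),
        dict(age=5.5, weight=13.0, sofa=1.3, charlson=1.5, bun=8.5, creatinine=0.38,
             dbp=8.0, hematocrit=3.5, anion_gap=2.2, heart_rate=10.0),
        dict(female=0.4562, mi=0.3620, hypertension=0.7150, af=0.6184,
             pulmonary_disease=0.4192, renal_disease=0.2504, diabetes=0.3327,
             sepsis=0.0674, vasoactive_drugs=0.1282, mechanical_ventilation=0.1944,
             crrt=0.0048),
        HazardCoefs(-6.400, theta_covar=0.25, theta_fluid=0.30, theta_fluid2=0.30,
                    theta_day=-0.05),
    ),
    "D": (
        1274 / 5998,
        dict(age=75.7, weight=83.2, sofa=7.0, charlson=8.0, bun=60.0, creatinine=3.0,
             dbp=54.0, hematocrit=28.0, anion_gap=20.0, heart_rate=92.0),
        dict(age=7.0, weight=15.0, sofa=1.8, charlson=1.8, bun=14.0, creatinine=0.9,
             dbp=8.0, hematocrit=3.5, anion_gap=3.0, heart_rate=11.0),
        dict(female=0.3273, mi=0.4074, hypertension=0.8312, af=0.5863,
             pulmonary_disease=0.3721, renal_disease=0.8234, diabetes=0.6625,
             sepsis=0.1860, vasoactive_drugs=0.5008, mechanical_ventilation=0.3752,
             crrt=0.1256),
        HazardCoefs(-9.709, theta_covar=0.25, theta_fluid=1.00, theta_fluid2=0.40,
                    theta_day=-0.05),
    ),
}


def default_phenotypes() -> list[PhenotypeSpec]:
    """The four default heart-failure phenotypes (A–D)."""
    return [
        PhenotypeSpec(label, prev, means, sds, probs, hz)
        for label, (prev, means, sds, probs, hz) in _DEFAULTS.items()
    ]


def default_trajectory(**overrides) -> TrajectorySpec:
    """The default 7-day confounded fluid/severity/mortality process."""
    return TrajectorySpec(**overrides)


def default_units() -> dict[str, str]:
    return dict(_NUMERIC_UNITS)
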