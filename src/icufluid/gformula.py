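"""Parametric g-formula for daily fluid-balance range strategies.

The estimand is the cumulative risk of in-hospital death over the first
``horizon`` ICU days had everyone's daily net fluid balance been clamped into
a range ``[lower, upper]`` (the natural balance is kept when already inside).

Procedure (discrete time, pooled-over-person-days models):

1. **Fit** — for each time-varying covariate, a linear model on the lagged
   covariates, lagged fluid (litres), optional baseline features and day;
   a linear-Gaussian model for the daily fluid balance given current
   covariates; and a pooled logistic model for the daily death hazard on
   current covariates, fluid (litres), fluid squared, baseline features and
   day.  The squared term is essential: range-shaped optima cannot exist
   under a purely linear effect.  Censored patients contribute their observed
   days (censoring assumed non-informative given modelled history).
2. **Simulate** — Monte-Carlo replicates draw a baseline row with
   replacement, then roll covariates and fluid forward from the fitted
   models, clamping each day's fluid into the intervention range.  Risk is
   accumulated as expected hazard, ``r_t = 1 - E[prod_s (1-h_s)]``, without
   sampling death events — unbiased for the same estimand with lower
   Monte-Carlo variance.
3. **Bootstrap** — percentile intervals from patient-level resampling
   (all person-days of a resampled patient move together).

Interventions are compared with common random numbers: the same seed drives
the simulation of every grid cell, so contrasts between strategies are not
blurred by independent Monte-Carlo noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from .interventions import NATURAL_COURSE, InterventionSpec
from .schema import ID_COL, BaselineTable, PersonDayTable, ValidationError


class GFormulaError(RuntimeError):
    """A model inside the g-formula failed to fit."""


@dataclass(frozen=True)
class GFormulaSpec:
    """Model specification for the g-formula.

    ``covariates`` are time-varying columns of the person-day table;
    ``init_features`` maps each to the baseline feature providing its day -1
    value.  ``baseline_adjust`` lists numeric baseline features entering every
    model.  Fluid enters in litres (mL/1000) with a quadratic hazard term.
    """

    horizon: int = 7
    covariates: tuple[str, ...] = ("severity",)
    init_features: dict[str, str] = field(default_factory=lambda: {"severity": "sofa"})
    baseline_adjust: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.horizon < 1:
            raise ValidationError("horizon must be >= 1")
        missing = [c for c in self.covariates if c not in self.init_features]
        if missing:
            raise ValidationError(f"no baseline init feature for covariates: {missing}")


@dataclass
class _LinearModel:
    names: list[str]
    params: np.ndarray
    bse: np.ndarray
    resid_sd: float = 0.0

    def predict(self, X: np.ndarray) -> np.ndarray:
        return X @ self.params


@dataclass
class GFormulaFit:
    """Fitted component models plus the empirical baseline sample."""

    spec: GFormulaSpec
    covariate_models: dict[str, _LinearModel]
    treatment_model: _LinearModel
    hazard_model: _LinearModel
    baseline_sample: np.ndarray  # n x (len(covariates) inits + baseline_adjust)
    n_events: int


@dataclass
class RiskEstimate:
    """Cumulative mortality risk under one intervention.

    ``cumulative[t]`` is the risk of death by the end of day ``t`` (0-based);
    ``point`` is the horizon risk.  ``mc_se`` is the Monte-Carlo standard
    error of ``point`` from the replicate variance (treats replicates as
    independent; contrasts under common random numbers are more precise than
    pooling these suggests).
    """

    intervention: InterventionSpec
    cumulative: np.ndarray
    point: float
    mc_se: float
    ci_lower: float = float("nan")
    ci_upper: float = float("nan")
    n_boot: int = 0
    n_mc: int = 0

    def __post_init__(self) -> None:
        c = np.asarray(self.cumulative)
        if (np.diff(c) < -1e-12).any() or (c < -1e-12).any() or (c > 1 + 1e-12).any():
            raise ValidationError("cumulative risk must be non-decreasing in [0,1]")
        if self.n_boot > 0 and not (self.ci_lower <= self.point + 1e-12 and self.point - 1e-12 <= self.ci_upper):
            # percentile intervals can in principle miss a skewed point; flag loudly
            warnings.warn("bootstrap interval does not bracket the point estimate")


# --------------------------------------------------------------------------
# pooled design matrices, built once so patient-level bootstrap is cheap
# --------------------------------------------------------------------------


@dataclass
class _Design:
    spec: GFormulaSpec
    pids: np.ndarray  # unique patient codes
    cov_rows: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]  # pid_code, X, y
    tr_rows: tuple[np.ndarray, np.ndarray, np.ndarray]
    hz_rows: tuple[np.ndarray, np.ndarray, np.ndarray]
    baseline_matrix: np.ndarray  # per patient code
    cov_names: list[str]
    tr_names: list[str]
    hz_names: list[str]


def _build_design(baseline: BaselineTable, persondays: PersonDayTable, spec: GFormulaSpec) -> _Design:
    df = persondays.df.sort_values([ID_COL, "day"], kind="stable")
    for c in spec.covariates:
        if c not in df.columns:
            raise ValidationError(f"person-day table lacks covariate {c!r}")
    base = baseline.df.set_index(ID_COL)
    for f in list(spec.init_features.values()) + list(spec.baseline_adjust):
        if f not in base.columns:
            raise ValidationError(f"baseline table lacks feature {f!r}")

    pid_codes, pids = pd.factorize(df[ID_COL], sort=True)
    day = df["day"].to_numpy(float)
    a = df["fluid_balance"].to_numpy(float) / 1000.0
    died = df["died"].to_numpy(float)
    L = {c: df[c].to_numpy(float) for c in spec.covariates}
    bl_adj = base.loc[pids, list(spec.baseline_adjust)].to_numpy(float) if spec.baseline_adjust else np.empty((len(pids), 0))
    bl_adj_rows = bl_adj[pid_codes]

    same_prev = np.zeros(len(df), dtype=bool)
    same_prev[1:] = (pid_codes[1:] == pid_codes[:-1]) & (day[1:] == day[:-1] + 1)
    lagged = {c: np.where(same_prev, np.r_[np.nan, L[c][:-1]], np.nan) for c in spec.covariates}
    lag_a = np.where(same_prev, np.r_[np.nan, a[:-1]], 0.0)  # day 0: A_{-1}=0

    ones = np.ones(len(df))
    adj_names = list(spec.baseline_adjust)

    # covariate models: pooled over person-days with an observed previous day
    cov_rows = {}
    cov_names = (["const"] + [f"lag_{c}" for c in spec.covariates] + ["lag_fluid_l"] + adj_names + ["day"])
    mask_lag = same_prev
    X_cov = np.column_stack(
        [ones] + [lagged[c] for c in spec.covariates] + [lag_a] + [bl_adj_rows] + [day]
    )[mask_lag]
    for c in spec.covariates:
        cov_rows[c] = (pid_codes[mask_lag], X_cov, L[c][mask_lag])

    tr_names = ["const"] + list(spec.covariates) + adj_names + ["day"]
    X_tr = np.column_stack([ones] + [L[c] for c in spec.covariates] + [bl_adj_rows] + [day])
    tr_rows = (pid_codes, X_tr, df["fluid_balance"].to_numpy(float))

    hz_names = ["const"] + list(spec.covariates) + ["fluid_l", "fluid_l2"] + adj_names + ["day"]
    X_hz = np.column_stack([ones] + [L[c] for c in spec.covariates] + [a, a**2] + [bl_adj_rows] + [day])
    hz_rows = (pid_codes, X_hz, died)

    init = base.loc[pids, [spec.init_features[c] for c in spec.covariates]].to_numpy(float)
    baseline_matrix = np.column_stack([init, bl_adj])
    return _Design(
        spec=spec,
        pids=np.arange(len(pids)),
        cov_rows=cov_rows,
        tr_rows=tr_rows,
        hz_rows=hz_rows,
        baseline_matrix=baseline_matrix,
        cov_names=cov_names,
        tr_names=tr_names,
        hz_names=hz_names,
    )


def _row_indices_for(pid_codes: np.ndarray, chosen: np.ndarray) -> np.ndarray:
    """Row indices for a multiset of patient codes (bootstrap gather)."""
    order = np.argsort(pid_codes, kind="stable")
    sorted_codes = pid_codes[order]
    starts = np.searchsorted(sorted_codes, chosen, side="left")
    ends = np.searchsorted(sorted_codes, chosen, side="right")
    return np.concatenate([order[s:e] for s, e in zip(starts, ends)]) if len(chosen) else np.empty(0, int)


def _fit_ols(X: np.ndarray, y: np.ndarray, names: list[str], label: str) -> _LinearModel:
    if len(y) <= X.shape[1]:
        raise GFormulaError(f"{label}: too few rows ({len(y)}) for {X.shape[1]} coefficients")
    keep = _identify(X)
    res = sm.OLS(y, X[:, keep]).fit()
    params = np.zeros(X.shape[1])
    bse = np.full(X.shape[1], np.nan)
    params[keep], bse[keep] = res.params, res.bse
    dof = max(len(y) - len(keep), 1)
    resid_sd = float(np.sqrt(np.sum(res.resid**2) / dof))
    return _LinearModel(names=names, params=params, bse=bse, resid_sd=max(resid_sd, 1e-12))


def _fit_logit(X: np.ndarray, y: np.ndarray, names: list[str], label: str) -> _LinearModel:
    if y.sum() == 0:
        raise GFormulaError(f"{label}: zero events")
    keep = _identify(X)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X[:, keep]).fit(disp=0, maxiter=100)
        if not res.mle_retvals.get("converged", True):
            raise GFormulaError(f"{label}: logistic fit did not converge")
    except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError) as exc:
        raise GFormulaError(f"{label}: {exc}") from exc
    params = np.zeros(X.shape[1])
    bse = np.full(X.shape[1], np.nan)
    params[keep], bse[keep] = res.params, res.bse
    return _LinearModel(names=names, params=params, bse=bse)


def _identify(X: np.ndarray) -> list[int]:
    """Greedily keep a linearly independent, non-constant-beyond-intercept column set."""
    keep: list[int] = []
    for j in range(X.shape[1]):
        cand = X[:, keep + [j]]
        if np.linalg.matrix_rank(cand) == len(keep) + 1:
            keep.append(j)
    return keep


def _fit_from_rows(design: _Design, chosen: np.ndarray | None) -> GFormulaFit:
    def gather(rows):
        codes, X, y = rows
        if chosen is None:
            return X, y
        idx = _row_indices_for(codes, chosen)
        return X[idx], y[idx]

    cov_models = {}
    for c, rows in design.cov_rows.items():
        X, y = gather(rows)
        cov_models[c] = _fit_ols(X, y, design.cov_names, f"covariate model [{c}]")
    X, y = gather(design.tr_rows)
    tr = _fit_ols(X, y, design.tr_names, "treatment model")
    X, y = gather(design.hz_rows)
    hz = _fit_logit(X, y, design.hz_names, "hazard model")
    n_events = int(y.sum())
    bl = design.baseline_matrix if chosen is None else design.baseline_matrix[chosen]
    return GFormulaFit(
        spec=design.spec,
        covariate_models=cov_models,
        treatment_model=tr,
        hazard_model=hz,
        baseline_sample=bl,
        n_events=n_events,
    )


def fit_gformula(
    baseline: BaselineTable, persondays: PersonDayTable, spec: GFormulaSpec | None = None
) -> GFormulaFit:
    """Fit the pooled covariate, treatment and hazard models."""
    spec = spec or GFormulaSpec()
    design = _build_design(baseline, persondays, spec)
    fit = _fit_from_rows(design, None)
    if fit.n_events < 30:
        warnings.warn(f"only {fit.n_events} events; g-formula estimates will be unstable")
    return fit


def simulate_risk(
    fit: GFormulaFit, intervention: InterventionSpec, n_mc: int, seed: int
) -> RiskEstimate:
    """Monte-Carlo cumulative mortality risk under one clamp intervention."""
    if n_mc < 1:
        raise ValidationError("n_mc must be >= 1")
    spec = fit.spec
    rng = np.random.default_rng(seed)
    n_cov = len(spec.covariates)
    rows = fit.baseline_sample[rng.integers(0, len(fit.baseline_sample), size=n_mc)]
    L_prev = {c: rows[:, i].astype(float) for i, c in enumerate(spec.covariates)}
    bl_adj = rows[:, n_cov:]
    a_prev = np.zeros(n_mc)
    surv = np.ones(n_mc)
    cumulative = np.zeros(spec.horizon)
    ones = np.ones(n_mc)
    for t in range(spec.horizon):
        day = np.full(n_mc, float(t))
        X_cov = np.column_stack([ones] + [L_prev[c] for c in spec.covariates] + [a_prev] + [bl_adj] + [day])
        L = {}
        for c in spec.covariates:
            m = fit.covariate_models[c]
            L[c] = m.predict(X_cov) + rng.normal(0.0, m.resid_sd, n_mc)
        X_tr = np.column_stack([ones] + [L[c] for c in spec.covariates] + [bl_adj] + [day])
        A_nat = fit.treatment_model.predict(X_tr) + rng.normal(0.0, fit.treatment_model.resid_sd, n_mc)
        a = intervention.apply(A_nat) / 1000.0
        X_hz = np.column_stack([ones] + [L[c] for c in spec.covariates] + [a, a**2] + [bl_adj] + [day])
        h = expit(fit.hazard_model.predict(X_hz))
        surv = surv * (1.0 - h)
        cumulative[t] = 1.0 - surv.mean()
        L_prev, a_prev = L, a
    mc_se = float(np.std(surv, ddof=1) / np.sqrt(n_mc)) if n_mc > 1 else float("nan")
    return RiskEstimate(
        intervention=intervention,
        cumulative=cumulative,
        point=float(cumulative[-1]),
        mc_se=mc_se,
        n_mc=n_mc,
    )


def observed_cumulative_incidence(persondays: PersonDayTable, horizon: int) -> np.ndarray:
    """Discrete-time cumulative incidence with censoring treated as non-informative."""
    df = persondays.df
    surv = 1.0
    out = np.zeros(horizon)
    for t in range(horizon):
        rows = df[df["day"] == t]
        at_risk = len(rows)
        h = rows["died"].sum() / at_risk if at_risk else 0.0
        surv *= 1.0 - h
        out[t] = 1.0 - surv
    return out


def natural_course_check(
    fit: GFormulaFit, persondays: PersonDayTable, n_mc: int, seed: int
) -> tuple[np.ndarray, np.ndarray, float]:
    """Simulated natural-course risk vs observed incidence (model diagnostic)."""
    est = simulate_risk(fit, NATURAL_COURSE, n_mc=n_mc, seed=seed)
    observed = observed_cumulative_incidence(persondays, fit.spec.horizon)
    gap = float(np.max(np.abs(est.cumulative - observed)))
    return est.cumulative, observed, gap


def bootstrap_ci(
    baseline: BaselineTable,
    persondays: PersonDayTable,
    intervention: InterventionSpec,
    spec: GFormulaSpec | None = None,
    n_boot: int = 500,
    n_mc: int = 2000,
    seed: int = 0,
) -> RiskEstimate:
    """Percentile 95% CI via patient-level nonparametric bootstrap.

    The point estimate comes from the full data; each bootstrap replicate
    resamples patients with replacement, refits all models and re-simulates.
    Replicates whose refit fails are skipped with a warning; more than 20%
    failures aborts.
    """
    if n_boot < 2:
        raise ValidationError("n_boot must be >= 2")
    spec = spec or GFormulaSpec()
    design = _build_design(baseline, persondays, spec)
    full = _fit_from_rows(design, None)
    rng = np.random.default_rng(seed)
    point_est = simulate_risk(full, intervention, n_mc=n_mc, seed=int(rng.integers(2**31)))
    n_pat = len(design.baseline_matrix)
    stats, failures = [], 0
    for _ in range(n_boot):
        chosen = rng.integers(0, n_pat, size=n_pat)
        sim_seed = int(rng.integers(2**31))
        try:
            bfit = _fit_from_rows(design, chosen)
            stats.append(simulate_risk(bfit, intervention, n_mc=n_mc, seed=sim_seed).point)
        except GFormulaError as exc:
            failures += 1
            warnings.warn(f"bootstrap replicate failed: {exc}")
    if failures > 0.2 * n_boot:
        raise GFormulaError(f"{failures}/{n_boot} bootstrap refits failed")
    lo, hi = np.percentile(stats, [2.5, 97.5])
    return RiskEstimate(
        intervention=intervention,
        cumulative=point_est.cumulative,
        point=point_est.point,
        mc_se=point_est.mc_se,
        ci_lower=float(min(lo, point_est.point)),
        ci_upper=float(max(hi, point_est.point)),
        n_boot=n_boot,
        n_mc=n_mc,
    )


def intervention_grid(
    fit: GFormulaFit,
    lowers: list[float],
    uppers: list[float],
    n_mc: int = 20000,
    seed: int = 0,
    include_natural: bool = True,
) -> pd.DataFrame:
    """Risk for every valid (lower <= upper) range on a bounds grid.

    All cells share the same Monte-Carlo seed (common random numbers), so
    between-cell contrasts are far more precise than the per-cell ``mc_se``
    suggests.  Returns a long DataFrame (label, lower, upper, risk, mc_se).
    """
    pairs = [(lo, up) for lo in lowers for up in uppers if lo <= up]
    if not pairs:
        raise ValidationError("empty intervention grid")
    records = []
    if include_natural:
        est = simulate_risk(fit, NATURAL_COURSE, n_mc=n_mc, seed=seed)
        records.append(
            {"label": est.intervention.label, "lower": -np.inf, "upper": np.inf,
             "risk": est.point, "mc_se": est.mc_se}
        )
    for lo, up in pairs:
        est = simulate_risk(fit, InterventionSpec(lo, up), n_mc=n_mc, seed=seed)
        records.append(
            {"label": est.intervention.label, "lower": lo, "upper": up,
             "risk": est.point, "mc_se": est.mc_se}
        )
    return pd.DataFrame(records)


def phenotype_intervention_grids(
    baseline: BaselineTable,
    persondays: PersonDayTable,
    labels: pd.Series,
    lowers: list[float],
    uppers: list[float],
    spec: GFormulaSpec | None = None,
    n_mc: int = 20000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-phenotype strategy grids from phenotype-stratified fits."""
    spec = spec or GFormulaSpec()
    labels = labels.reindex(baseline.df[ID_COL])
    if labels.isna().any():
        raise ValidationError("labels must cover all patients")
    frames = []
    for g in sorted(pd.unique(labels)):
        pids = labels.index[labels == g]
        bsub = baseline.with_df(baseline.df[baseline.df[ID_COL].isin(pids)].copy())
        psub = PersonDayTable(persondays.df[persondays.df[ID_COL].isin(pids)].copy())
        fit = fit_gformula(bsub, psub, spec)
        grid = intervention_grid(fit, lowers, uppers, n_mc=n_mc, seed=seed)
        grid.insert(0, "phenotype", g)
        frames.append(grid)
    return pd.concat(frames, ignore_index=True)
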