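"""Phenotype characterisation: group-comparison tables, comorbidity
co-occurrence, and survival contrasts.

The group summary mirrors the conventional baseline-characteristics table of
a phenotyping study: continuous variables as median (Q1, Q3) compared with
the Kruskal-Wallis test, categorical variables as n (%) compared with the
chi-square test (no continuity correction), percentages rounded half-up to
two decimals.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .schema import ID_COL, BaselineTable, PersonDayTable, ValidationError, time_to_event


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (so 0.475 -> 0.48, not banker's 0.47...)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent_cell(count: int, group_n: int) -> float:
    """The n (%) percentage cell: 100*count/group_n, half-up to 2 decimals."""
    if group_n <= 0:
        raise ValidationError("empty group")
    return round_half_up(100.0 * count / group_n, 2)


@dataclass
class GroupSummary:
    """A baseline-characteristics comparison across phenotype groups."""

    group_sizes: pd.Series
    numeric: pd.DataFrame  # rows: feature; cols: MultiIndex (group, median/q1/q3)
    categorical: pd.DataFrame  # rows: (feature, level); cols: MultiIndex (group, count/percent)
    tests: pd.DataFrame  # rows: feature; cols: test, pvalue

    def render(self) -> pd.DataFrame:
        """Printable table: 'median (q1, q3)' / 'n (pct)' strings per group."""
        rows = {}
        for f in self.numeric.index:
            rows[f] = {
                g: f"{self.numeric.loc[f, (g, 'median')]:.2f} "
                f"({self.numeric.loc[f, (g, 'q1')]:.2f},{self.numeric.loc[f, (g, 'q3')]:.2f})"
                for g in self.group_sizes.index
            }
        for f, lv in self.categorical.index:
            rows[f"{f}={lv}"] = {
                g: f"{int(self.categorical.loc[(f, lv), (g, 'count')])} "
                f"({self.categorical.loc[(f, lv), (g, 'percent')]:.2f})"
                for g in self.group_sizes.index
            }
        return pd.DataFrame(rows).T


def summarize_groups(table: BaselineTable, labels: pd.Series) -> GroupSummary:
    """Table-1-style description of the phenotype groups.

    ``labels`` maps patient_id to a group label and must cover every patient.
    """
    labels = labels.reindex(table.df[ID_COL])
    if labels.isna().any():
        raise ValidationError("labels must cover all patients")
    lab = labels.to_numpy()
    groups = sorted(pd.unique(lab))
    sizes = pd.Series({g: int((lab == g).sum()) for g in groups}, name="n")
    if (sizes == 0).any():
        raise ValidationError("empty group")

    num_cols = pd.MultiIndex.from_product([groups, ["median", "q1", "q3"]])
    numeric = pd.DataFrame(index=list(table.schema.numeric), columns=num_cols, dtype=float)
    tests_rows = []
    for f in table.schema.numeric:
        x = table.df[f].astype(float).to_numpy()
        samples = [x[lab == g] for g in groups]
        for g, s in zip(groups, samples):
            numeric.loc[f, (g, "median")] = np.median(s)
            numeric.loc[f, (g, "q1")] = np.quantile(s, 0.25)
            numeric.loc[f, (g, "q3")] = np.quantile(s, 0.75)
        try:
            p = stats.kruskal(*samples).pvalue if len(groups) > 1 else np.nan
        except ValueError:  # all values identical
            p = np.nan
        tests_rows.append({"feature": f, "test": "kruskal-wallis", "pvalue": p})

    cat_index, cat_rows = [], []
    for f in table.schema.categorical:
        col = table.df[f].astype(str).to_numpy()
        levels = sorted(pd.unique(col))
        observed = np.array(
            [[(col[lab == g] == lv).sum() for g in groups] for lv in levels], dtype=float
        )
        for lv, row in zip(levels, observed):
            cat_index.append((f, lv))
            cells = {}
            for g, cnt in zip(groups, row):
                cells[(g, "count")] = cnt
                cells[(g, "percent")] = percent_cell(int(cnt), int(sizes[g]))
            cat_rows.append(cells)
        if len(levels) > 1 and len(groups) > 1 and observed.sum() > 0:
            p = stats.chi2_contingency(observed, correction=False).pvalue
        else:
            p = np.nan
        tests_rows.append({"feature": f, "test": "chi-square", "pvalue": p})

    categorical = pd.DataFrame(
        cat_rows, index=pd.MultiIndex.from_tuples(cat_index, names=["feature", "level"])
    )
    if len(categorical.columns):
        categorical.columns = pd.MultiIndex.from_tuples(categorical.columns)
    tests = pd.DataFrame(tests_rows).set_index("feature")
    return GroupSummary(group_sizes=sizes, numeric=numeric, categorical=categorical, tests=tests)


def comorbidity_cooccurrence(
    table: BaselineTable, labels: pd.Series, comorbidity_features: list[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Within-phenotype prevalence of each comorbidity, plus chord weights.

    Returns ``(prevalence, weights)``: both phenotype x comorbidity; weights
    are the prevalence rows normalised to sum to 1 (the arc widths of a chord
    diagram).  All listed features must be binary with a "yes" level.
    """
    labels = labels.reindex(table.df[ID_COL])
    if labels.isna().any():
        raise ValidationError("labels must cover all patients")
    for f in comorbidity_features:
        if f not in table.schema.categorical:
            raise ValidationError(f"{f!r} is not a categorical feature")
        lv = set(map(str, pd.unique(table.df[f].astype(str))))
        if not lv <= {"yes", "no"}:
            raise ValidationError(f"{f!r} is not binary yes/no (levels {sorted(lv)})")
    lab = labels.to_numpy()
    groups = sorted(pd.unique(lab))
    prev = pd.DataFrame(index=groups, columns=comorbidity_features, dtype=float)
    for g in groups:
        sub = table.df.loc[lab == g, comorbidity_features]
        prev.loc[g] = (sub.astype(str) == "yes").mean()
    row_sums = prev.sum(axis=1)
    weights = prev.div(row_sums.where(row_sums > 0, 1.0), axis=0)
    return prev, weights


@dataclass
class SurvivalContrast:
    """Per-phenotype product-limit curves at one horizon plus the log-rank test."""

    horizon: int
    curves: dict[object, pd.DataFrame]  # label -> (time, survival)
    logrank_p: float
    undefined: bool = False  # no events anywhere: test not meaningful


def survival_contrast(
    persondays: PersonDayTable | None,
    labels: pd.Series,
    horizons: list[int],
    tte: pd.DataFrame | None = None,
) -> dict[int, SurvivalContrast]:
    """Kaplan-Meier curves per phenotype, truncated at each horizon.

    Times come from the person-day table (death/censoring day + 1) unless an
    explicit time-to-event frame (patient_id, time, event) is supplied — the
    latter supports horizons beyond the daily observation window.
    """
    if tte is None:
        if persondays is None:
            raise ValidationError("need persondays or an explicit time-to-event table")
        tte = time_to_event(persondays)
    tte = tte.set_index(ID_COL) if ID_COL in tte.columns else tte
    lab = labels.reindex(tte.index)
    if lab.isna().any():
        raise ValidationError("labels must cover all patients with event times")
    out = {}
    for horizon in horizons:
        t = np.minimum(tte["time"].to_numpy(float), horizon)
        e = np.where(tte["time"].to_numpy(float) <= horizon, tte["event"].to_numpy(int), 0)
        curves = {}
        for g in sorted(pd.unique(lab)):
            m = (lab == g).to_numpy()
            km = KaplanMeierFitter().fit(t[m], e[m])
            sf = km.survival_function_.reset_index()
            sf.columns = ["time", "survival"]
            curves[g] = sf
        undefined = e.sum() == 0
        if undefined or len(curves) < 2:
            p = float("nan")
        else:
            p = float(multivariate_logrank_test(t, lab.to_numpy(), e).p_value)
        out[horizon] = SurvivalContrast(horizon=horizon, curves=curves, logrank_p=p, undefined=undefined)
    return out
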