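"""Variable-level cleaning feeding the mixed-data clusterer.

Order of play, mirroring the study workflow: drop features with excessive
missingness, impute the remainder (median / mode), scale numeric features so
they contribute comparably to the mixed distance, and optionally prune highly
correlated numeric features before re-clustering as a stability check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schema import BaselineTable, ValidationError


@dataclass
class PreprocessReport:
    """What a preprocessing step did, for transparency and reuse.

    ``scaling_params`` maps feature -> (min, max) under ``minmax01`` or
    (mean, sd) under ``zscore``; they allow the identical affine transform to
    be applied to held-out data.
    """

    dropped_missing: list[tuple[str, float]] = field(default_factory=list)
    dropped_correlated: list[tuple[str, str, float]] = field(default_factory=list)
    imputation_values: dict[str, object] = field(default_factory=dict)
    scaling_params: dict[str, tuple[float, float]] = field(default_factory=dict)
    scaling_mode: str | None = None


def filter_missing(table: BaselineTable, threshold: float = 0.30) -> tuple[BaselineTable, PreprocessReport]:
    """Drop every feature whose missing fraction strictly exceeds ``threshold``.

    A feature with missing fraction exactly at the threshold is retained
    (the rule is "more than", not "at least").  Patient rows are untouched.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValidationError("threshold must be in [0,1]")
    if table.n == 0:
        raise ValidationError("empty table")
    frac = table.missing_fraction()
    report = PreprocessReport(
        dropped_missing=[(f, float(frac[f])) for f in table.features if frac[f] > threshold]
    )
    dropped = {f for f, _ in report.dropped_missing}
    keep = [f for f in table.features if f not in dropped]
    extra = [c for c in table.df.columns if c not in table.features]
    out = table.with_df(table.df[extra + keep].copy(), table.schema.subset(keep))
    return out, report


def impute(table: BaselineTable) -> tuple[BaselineTable, PreprocessReport]:
    """Fill numeric missing with the column median, categorical with the mode.

    Mode ties break to the lexicographically smallest level.  A column with no
    observed value cannot be imputed and raises an error naming it.
    """
    df = table.df.copy()
    report = PreprocessReport()
    for f in table.features:
        col = df[f]
        if not col.isna().any():
            continue
        observed = col.dropna()
        if observed.empty:
            raise ValidationError(f"feature {f!r} has no observed values to impute from")
        if table.schema.is_numeric(f):
            value: object = float(observed.astype(float).median())
        else:
            counts = observed.value_counts()
            top = counts[counts == counts.max()]
            value = sorted(top.index)[0]
        df[f] = col.fillna(value)
        report.imputation_values[f] = value
    return table.with_df(df), report


def scale_numeric(
    table: BaselineTable, mode: str = "minmax01"
) -> tuple[BaselineTable, PreprocessReport]:
    """Scale numeric columns (``minmax01`` onto [0,1], or ``zscore``).

    Categorical columns are untouched.  The fitted parameters are recorded so
    the same transform can be replayed on held-out data via
    :func:`apply_scaling`.  ``zscore`` uses the n-1 denominator and refuses
    constant columns; a constant column under ``minmax01`` maps to 0.
    """
    if mode not in ("minmax01", "zscore"):
        raise ValidationError(f"unknown scaling mode {mode!r}")
    df = table.df.copy()
    report = PreprocessReport(scaling_mode=mode)
    for f in table.schema.numeric:
        x = df[f].astype(float)
        if mode == "minmax01":
            lo, hi = float(x.min()), float(x.max())
            report.scaling_params[f] = (lo, hi)
            df[f] = (x - lo) / (hi - lo) if hi > lo else 0.0 * x
        else:
            mu, sd = float(x.mean()), float(x.std(ddof=1))
            if not sd > 0:
                raise ValidationError(f"constant column {f!r} cannot be z-scored")
            report.scaling_params[f] = (mu, sd)
            df[f] = (x - mu) / sd
    return table.with_df(df), report


def apply_scaling(table: BaselineTable, report: PreprocessReport) -> BaselineTable:
    """Replay stored scaling parameters on a new (held-out) table."""
    if report.scaling_mode is None:
        raise ValidationError("report carries no scaling parameters")
    df = table.df.copy()
    for f, (p1, p2) in report.scaling_params.items():
        if f not in df.columns:
            continue
        x = df[f].astype(float)
        if report.scaling_mode == "minmax01":
            df[f] = (x - p1) / (p2 - p1) if p2 > p1 else 0.0 * x
        else:
            df[f] = (x - p1) / p2
    return table.with_df(df)


def prune_correlated(
    table: BaselineTable, corr_threshold: float = 0.8
) -> tuple[BaselineTable, PreprocessReport]:
    """Drop numeric features until no pair has |Spearman rho| above threshold.

    Pairs are visited in descending |rho|; when both members of an offending
    pair still survive, the member with the larger mean absolute correlation
    to all other numeric features is dropped (tie -> the later column).
    Categorical features are never touched.
    """
    if not 0.0 < corr_threshold <= 1.0:
        raise ValidationError("corr_threshold must be in (0,1]")
    numeric = list(table.schema.numeric)
    report = PreprocessReport()
    if len(numeric) < 2:
        return table.copy(), report
    X = table.numeric_frame()
    rho = X.corr(method="spearman").to_numpy()
    np.fill_diagonal(rho, 0.0)
    mean_abs = np.nanmean(np.abs(rho), axis=1)
    p = len(numeric)
    pairs = [
        (abs(rho[i, j]), i, j)
        for i in range(p)
        for j in range(i + 1, p)
        if abs(rho[i, j]) > corr_threshold
    ]
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    alive = np.ones(p, dtype=bool)
    for r, i, j in pairs:
        if not (alive[i] and alive[j]):
            continue
        # drop the feature more entangled with everything else
        if mean_abs[i] > mean_abs[j]:
            drop, keep = i, j
        elif mean_abs[j] > mean_abs[i]:
            drop, keep = j, i
        else:
            drop, keep = j, i  # tie -> later column order
        alive[drop] = False
        report.dropped_correlated.append((numeric[drop], numeric[keep], float(rho[i, j])))
    keep_feats = [f for f, a in zip(numeric, alive) if a] + list(table.schema.categorical)
    cols = [c for c in table.df.columns if c not in table.features or c in keep_feats]
    return table.with_df(table.df[cols].copy(), table.schema.subset(keep_feats)), report


def scale_group_means(table: BaselineTable, labels: pd.Series | np.ndarray) -> pd.DataFrame:
    """Per-feature group means rescaled to [-1, 1] for profile plots.

    For each numeric feature, the vector of per-group means is centred on the
    (unweighted) mean of group means and divided by its largest absolute
    deviation, so the most extreme group sits at +/-1 and identical groups at
    0.  Rows are groups, columns numeric features.
    """
    labels = np.asarray(labels)
    if len(labels) != table.n:
        raise ValidationError("labels must cover all patients")
    groups = np.unique(labels)
    X = table.numeric_frame()
    out = pd.DataFrame(index=groups, columns=list(table.schema.numeric), dtype=float)
    for g in groups:
        sub = X[labels == g]
        if sub.empty:
            raise ValidationError(f"empty group {g!r}")
        out.loc[g] = sub.mean()
    centered = out - out.mean(axis=0)
    span = centered.abs().max(axis=0)
    span = span.replace(0.0, 1.0)  # all-equal groups -> zeros, not NaN
    return centered / span
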