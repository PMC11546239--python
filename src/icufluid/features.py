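"""Distilling phenotypes into a compact classifier.

Feature selection uses Joint Mutual Information Maximisation (JMIM): greedily
pick the feature whose *worst-case* joint information with an already-selected
feature about the outcome is largest,

    pick  argmax_c  min_{s in selected}  I(X_c, X_s ; Y),

starting from the feature with the largest marginal I(X;Y).  Each feature's
raw score is the criterion value at its selection, and the reported importance
is the raw score divided by the largest one, so the top feature scores exactly
1 and a fixed importance threshold (default 0.8) yields a deterministic
subset.  Continuous features are discretised by quantile binning before any
information estimate.

The classifier itself is deliberately plumbing: a gradient-boosted tree model
on the selected features, reported as per-phenotype one-vs-rest AUC, plus
decision-curve net benefit for clinical usefulness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import LabelEncoder

from .schema import ID_COL, BaselineTable, ValidationError


def _codes(x) -> np.ndarray:
    codes, _ = pd.factorize(np.asarray(x))
    if (codes < 0).any():
        raise ValidationError("missing values in a discrete vector")
    return codes


def mutual_information(x, y) -> float:
    """Plug-in mutual information I(X;Y) in bits from empirical frequencies."""
    x, y = np.asarray(x), np.asarray(y)
    if len(x) != len(y):
        raise ValidationError(f"length mismatch: {len(x)} vs {len(y)}")
    if len(x) == 0:
        raise ValidationError("empty vectors")
    xc, yc = _codes(x), _codes(y)
    joint = np.zeros((xc.max() + 1, yc.max() + 1))
    np.add.at(joint, (xc, yc), 1.0)
    joint /= joint.sum()
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log2(joint[nz] / (px @ py)[nz])))


def joint_mutual_information(x1, x2, y) -> float:
    """I((X1, X2); Y): the pair treated as one variable on the product alphabet."""
    x1, x2 = np.asarray(x1), np.asarray(x2)
    if len(x1) != len(x2):
        raise ValidationError(f"length mismatch: {len(x1)} vs {len(x2)}")
    c1, c2 = _codes(x1), _codes(x2)
    pair = c1 * (c2.max() + 1) + c2
    return mutual_information(pair, y)


def quantile_discretize(x: np.ndarray, bins: int = 5) -> np.ndarray:
    """Bin a continuous vector at its quantiles (ties collapse bins)."""
    edges = np.unique(np.quantile(x, np.linspace(0, 1, bins + 1)[1:-1]))
    return np.searchsorted(edges, x, side="left")


def discretize_table(table: BaselineTable, bins: int = 5) -> pd.DataFrame:
    """Discretise every feature: numeric by quantile bins, categorical by level codes."""
    out = {}
    for f in table.schema.numeric:
        out[f] = quantile_discretize(table.df[f].to_numpy(float), bins)
    for f in table.schema.categorical:
        out[f] = _codes(table.df[f].astype(str))
    return pd.DataFrame(out, index=table.df.index)


@dataclass(frozen=True)
class FeatureScore:
    feature: str
    raw_jmim: float  # criterion value (bits) at selection
    importance: float  # raw / max raw, top feature exactly 1
    rank: int  # 1-based selection order


def jmim_rank(features: pd.DataFrame, y, m: int | None = None) -> list[FeatureScore]:
    """Greedy JMIM ranking of discretised features against a discrete outcome.

    ``m`` limits how many features are selected (default: all).  Ties break to
    the earlier column.  The first feature's raw score is its marginal I(X;Y).
    """
    cols = list(features.columns)
    if m is None:
        m = len(cols)
    if m < 1:
        raise ValidationError("m must be >= 1")
    if m > len(cols):
        raise ValidationError(f"m={m} exceeds {len(cols)} features")
    y = np.asarray(y)
    X = {c: features[c].to_numpy() for c in cols}

    marginal = {c: mutual_information(X[c], y) for c in cols}
    first = max(cols, key=lambda c: (marginal[c], -cols.index(c)))
    selected = [first]
    raw = {first: marginal[first]}
    joint_cache: dict[tuple[str, str], float] = {}

    def joint(c: str, s: str) -> float:
        key = (c, s)
        if key not in joint_cache:
            joint_cache[key] = joint_mutual_information(X[c], X[s], y)
        return joint_cache[key]

    while len(selected) < m:
        best, best_val = None, -np.inf
        for c in cols:
            if c in selected:
                continue
            val = min(joint(c, s) for s in selected)
            if val > best_val + 1e-12:
                best, best_val = c, val
        selected.append(best)
        raw[best] = best_val
    top = max(raw.values())
    scale = top if top > 0 else 1.0
    return [
        FeatureScore(feature=c, raw_jmim=raw[c], importance=raw[c] / scale, rank=i + 1)
        for i, c in enumerate(selected)
    ]


def scores_frame(scores: list[FeatureScore]) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in scores])


def select_by_importance(scores: list[FeatureScore], threshold: float = 0.8) -> list[str]:
    """Features whose normalised importance strictly exceeds the threshold."""
    return [s.feature for s in scores if s.importance > threshold]


@dataclass(frozen=True)
class SplitSpec:
    test_size: float = 0.3
    stratify: bool = True


def _design_matrix(table: BaselineTable, features: list[str]) -> np.ndarray:
    cols = []
    for f in features:
        if table.schema.is_numeric(f):
            cols.append(table.df[f].to_numpy(float))
        else:
            cols.append(_codes(table.df[f].astype(str)).astype(float))
    return np.column_stack(cols)


def train_phenotype_classifier(
    table: BaselineTable,
    labels: pd.Series,
    selected_features: list[str],
    split_spec: SplitSpec | None = None,
    seed: int = 0,
    **xgb_params,
):
    """Gradient-boosted phenotype classifier on the selected features.

    Returns ``(model, per-class one-vs-rest AUC dict, (min, max) AUC range)``
    computed on a stratified held-out split.
    """
    from xgboost import XGBClassifier

    split_spec = split_spec or SplitSpec()
    labels = labels.reindex(table.df[ID_COL])
    if labels.isna().any():
        raise ValidationError("labels must cover all patients")
    enc = LabelEncoder()
    y = enc.fit_transform(labels.to_numpy())
    if len(enc.classes_) < 2:
        raise ValidationError("need at least 2 classes")
    X = _design_matrix(table, selected_features)
    X_tr, X_te, y_tr, y_te = train_test_split(
        X,
        y,
        test_size=split_spec.test_size,
        random_state=seed,
        stratify=y if split_spec.stratify else None,
    )
    if len(np.unique(y_tr)) < len(enc.classes_):
        raise ValidationError("a class is absent from the training split")
    params = dict(
        n_estimators=200, max_depth=4, learning_rate=0.1, subsample=0.9,
        eval_metric="mlogloss", random_state=seed, n_jobs=1,
    )
    params.update(xgb_params)
    model = XGBClassifier(**params)
    model.fit(X_tr, y_tr)
    prob = model.predict_proba(X_te)
    auc = {}
    for i, cls in enumerate(enc.classes_):
        auc[cls] = float(roc_auc_score((y_te == i).astype(int), prob[:, i]))
    values = list(auc.values())
    return model, auc, (min(values), max(values))


def net_benefit(
    predicted_prob: np.ndarray, truth: np.ndarray, thresholds: list[float]
) -> pd.DataFrame:
    """Decision-curve net benefit of a binary risk model.

    At threshold ``p_t`` patients with predicted probability >= ``p_t`` are
    treated: NB = TP/N - FP/N * p_t/(1-p_t).  Also returns the treat-all and
    treat-none reference policies.
    """
    p = np.asarray(predicted_prob, float)
    y = np.asarray(truth, int)
    if len(y) == 0:
        raise ValidationError("empty truth vector")
    if len(p) != len(y):
        raise ValidationError("length mismatch")
    for t in thresholds:
        if not 0.0 < t < 1.0:
            raise ValidationError(f"threshold {t} outside (0,1)")
    n = len(y)
    pi = y.mean()
    rows = []
    for t in thresholds:
        odds = t / (1.0 - t)
        treat = p >= t
        tp = int((treat & (y == 1)).sum())
        fp = int((treat & (y == 0)).sum())
        rows.append(
            {
                "threshold": t,
                "net_benefit": tp / n - fp / n * odds,
                "treat_all": pi - (1.0 - pi) * odds,
                "treat_none": 0.0,
            }
        )
    return pd.DataFrame(rows)
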