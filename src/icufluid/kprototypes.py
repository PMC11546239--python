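"""K-prototypes clustering for mixed numeric + categorical data.

Dissimilarity between a record ``x`` and a prototype ``(mu, m)`` is Huang's
mixed distance::

    d(x, proto) = sum_numeric (x_j - mu_j)^2  +  gamma * sum_categorical 1[x_j != m_j]

minimised by alternating assignment and prototype updates (numeric prototype =
cluster mean, categorical prototype = cluster mode).  ``gamma`` trades off a
categorical mismatch against squared numeric distance; the ``auto`` default is
Huang's heuristic, half the mean numeric column standard deviation.

Determinism matters for reproducible phenotyping, so mode ties break to the
lexicographically smallest level, empty clusters are reseeded from the point
farthest from its current prototype, and the best of ``n_init`` seeded
restarts is returned (ties to the earlier restart).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.metrics import adjusted_rand_score, silhouette_score

from .preprocess import prune_correlated
from .schema import ID_COL, BaselineTable, FeatureSchema, ValidationError


@dataclass
class ClusterModel:
    """A fitted K-prototypes model."""

    k: int
    numeric_prototypes: np.ndarray  # k x p_num, scaled units
    categorical_modes: np.ndarray  # k x p_cat, level strings
    gamma: float
    feature_schema: FeatureSchema
    total_cost: float
    n_iter: int
    seed: int

    def assign(self, table: BaselineTable) -> pd.Series:
        """Assign (possibly new) complete records to the nearest prototype."""
        for f, declared in self.feature_schema.categorical.items():
            extra = set(map(str, pd.unique(table.df[f].astype(str)))) - set(map(str, declared))
            if extra:
                raise ValidationError(f"unknown levels for {f!r}: {sorted(extra)}")
        Xn, Xc, _ = _encode(table, self.feature_schema)
        modes = _encode_modes(self.categorical_modes, self.feature_schema)
        d = _distances(Xn, Xc, self.numeric_prototypes, modes, self.gamma)
        return pd.Series(d.argmin(axis=1), index=table.df[ID_COL], name="phenotype")


def mixed_distance(x: dict, prototype: dict, gamma: float, schema: FeatureSchema) -> float:
    """Huang dissimilarity between one record and one prototype."""
    missing = set(schema.features) - set(x) | set(schema.features) - set(prototype)
    if missing:
        raise ValidationError(f"record/prototype missing features: {sorted(missing)}")
    d = sum((float(x[f]) - float(prototype[f])) ** 2 for f in schema.numeric)
    d += gamma * sum(x[f] != prototype[f] for f in schema.categorical)
    return float(d)


def _encode(table: BaselineTable, schema: FeatureSchema) -> tuple[np.ndarray, np.ndarray, list[list[str]]]:
    """Split a complete table into a float matrix and integer level codes.

    Codes index each feature's sorted level list, so smaller code ==
    lexicographically smaller level (used for deterministic mode ties).
    """
    if not table.df[schema.features].notna().all().all():
        raise ValidationError("table must be complete (impute first)")
    Xn = table.df[list(schema.numeric)].to_numpy(float) if schema.numeric else np.empty((table.n, 0))
    levels: list[list[str]] = []
    cols = []
    for f, declared in schema.categorical.items():
        observed = set(map(str, pd.unique(table.df[f].astype(str))))
        lv = sorted(set(map(str, declared)) | observed)
        levels.append(lv)
        lookup = {v: i for i, v in enumerate(lv)}
        cols.append(table.df[f].astype(str).map(lookup).to_numpy(np.int64))
    Xc = np.column_stack(cols) if cols else np.empty((table.n, 0), dtype=np.int64)
    return Xn, Xc, levels


def _encode_modes(modes: np.ndarray, schema: FeatureSchema) -> np.ndarray:
    out = np.zeros(modes.shape, dtype=np.int64)
    for j, f in enumerate(schema.categorical):
        lv = {str(v): i for i, v in enumerate(sorted(schema.categorical[f]))}
        for c in range(modes.shape[0]):
            val = str(modes[c, j])
            out[c, j] = lv.get(val, -1)
    return out


def _distances(Xn, Xc, protos_n, protos_c, gamma) -> np.ndarray:
    d = cdist(Xn, protos_n, "sqeuclidean") if Xn.shape[1] else np.zeros((len(Xn), len(protos_n)))
    if Xc.shape[1]:
        d = d + gamma * (Xc[:, None, :] != protos_c[None, :, :]).sum(axis=2)
    return d


def _update_prototypes(Xn, Xc, assign, k, levels):
    protos_n = np.zeros((k, Xn.shape[1]))
    protos_c = np.zeros((k, Xc.shape[1]), dtype=np.int64)
    for c in range(k):
        members = assign == c
        if Xn.shape[1]:
            protos_n[c] = Xn[members].mean(axis=0)
        for j in range(Xc.shape[1]):
            counts = np.bincount(Xc[members, j], minlength=len(levels[j]))
            protos_c[c, j] = int(counts.argmax())  # argmax takes first max: smallest code
    return protos_n, protos_c


def resolve_gamma(table: BaselineTable, gamma: float | str = "auto") -> float:
    """``auto`` -> 0.5 x mean numeric column sd (Huang's heuristic)."""
    if gamma == "auto":
        if not table.schema.numeric:
            return 1.0
        sds = table.numeric_frame().std(ddof=0)
        return float(0.5 * sds.mean())
    g = float(gamma)
    if g < 0:
        raise ValidationError("gamma must be >= 0")
    return g


def fit_kprototypes(
    table: BaselineTable,
    k: int,
    gamma: float | str = "auto",
    n_init: int = 10,
    max_iter: int = 100,
    seed: int = 0,
) -> tuple[ClusterModel, pd.Series]:
    """Fit K-prototypes on a complete, scaled baseline table.

    Returns the best model over ``n_init`` restarts and the assignment as a
    Series mapping patient_id to a cluster label in ``0..k-1``.  Cost is
    non-increasing within every restart; a fixed seed gives bit-identical
    results.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    if k > table.n:
        raise ValidationError(f"k={k} exceeds n={table.n}")
    g = resolve_gamma(table, gamma)
    Xn, Xc, levels = _encode(table, table.schema)
    rng = np.random.default_rng(seed)
    best = None
    for restart in range(n_init):
        init_idx = rng.choice(table.n, size=k, replace=False)
        protos_n, protos_c = Xn[init_idx].copy(), Xc[init_idx].copy()
        assign = np.full(table.n, -1)
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            d = _distances(Xn, Xc, protos_n, protos_c, g)
            new_assign = d.argmin(axis=1)
            # empty-cluster repair: reseed from the farthest points (distinct
            # point per empty cluster)
            empty = [c for c in range(k) if not (new_assign == c).any()]
            if empty:
                own = d[np.arange(table.n), new_assign]
                farthest = iter(np.argsort(-own))
                for c in empty:
                    new_assign[next(farthest)] = c
            if np.array_equal(new_assign, assign):
                break
            assign = new_assign
            protos_n, protos_c = _update_prototypes(Xn, Xc, assign, k, levels)
        d = _distances(Xn, Xc, protos_n, protos_c, g)
        cost = float(d[np.arange(table.n), assign].sum())
        if best is None or cost < best[0] - 1e-12:
            best = (cost, assign.copy(), protos_n.copy(), protos_c.copy(), n_iter)
    cost, assign, protos_n, protos_c, n_iter = best
    modes = np.array(
        [[levels[j][protos_c[c, j]] for j in range(Xc.shape[1])] for c in range(k)],
        dtype=object,
    ).reshape(k, Xc.shape[1])
    model = ClusterModel(
        k=k,
        numeric_prototypes=protos_n,
        categorical_modes=modes,
        gamma=g,
        feature_schema=table.schema,
        total_cost=cost,
        n_iter=n_iter,
        seed=seed,
    )
    labels = pd.Series(assign, index=table.df[ID_COL], name="phenotype")
    return model, labels


def mixed_distance_matrix(table: BaselineTable, gamma: float) -> np.ndarray:
    """Full pairwise mixed-dissimilarity matrix (for silhouettes)."""
    Xn, Xc, _ = _encode(table, table.schema)
    D = cdist(Xn, Xn, "sqeuclidean") if Xn.shape[1] else np.zeros((table.n, table.n))
    for j in range(Xc.shape[1]):
        D += gamma * (Xc[:, j][:, None] != Xc[:, j][None, :])
    return D


def select_k(
    table: BaselineTable,
    k_range: range | tuple[int, int] = (2, 8),
    gamma: float | str = "auto",
    n_init: int = 10,
    seed: int = 0,
    weak_silhouette: float = 0.25,
) -> tuple[int, pd.DataFrame]:
    """Fit every k in range; report cost (elbow) and mean mixed silhouette.

    The silhouette is computed on the square root of the mixed dissimilarity
    (the silhouette expects a distance; feeding it the squared form inflates
    apparent separation).  The chosen k maximises the silhouette; all
    diagnostics are returned so a clinically motivated override remains
    possible.  If no k reaches ``weak_silhouette`` the diagnostics carry a
    "no strong cluster structure" flag.
    """
    ks = list(k_range) if isinstance(k_range, range) else list(range(k_range[0], k_range[1] + 1))
    if not ks or min(ks) < 2 or max(ks) > table.n - 1:
        raise ValidationError(f"degenerate k_range {ks!r} for n={table.n}")
    g = resolve_gamma(table, gamma)
    D = np.sqrt(mixed_distance_matrix(table, g))
    rows = []
    for k in ks:
        model, labels = fit_kprototypes(table, k=k, gamma=g, n_init=n_init, seed=seed)
        sil = float(silhouette_score(D, labels.to_numpy(), metric="precomputed"))
        rows.append({"k": k, "total_cost": model.total_cost, "silhouette": sil})
    diag = pd.DataFrame(rows)
    diag["flag"] = (
        "no strong cluster structure" if diag["silhouette"].max() < weak_silhouette else ""
    )
    chosen = int(diag.loc[diag["silhouette"].idxmax(), "k"])
    return chosen, diag


def adjusted_rand_index(a: pd.Series, b: pd.Series) -> float:
    """Chance-corrected agreement between two labelings of the same patients."""
    if set(a.index) != set(b.index):
        raise ValidationError("assignments cover different patient sets")
    b = b.reindex(a.index)
    return float(adjusted_rand_score(a.to_numpy(), b.to_numpy()))


def stability_check(
    table: BaselineTable,
    corr_threshold: float = 0.8,
    k: int = 4,
    gamma: float | str = "auto",
    n_init: int = 10,
    seed: int = 0,
) -> tuple[float, pd.Series, pd.Series]:
    """Re-cluster after correlation pruning and report the ARI to the original.

    High ARI means the phenotypes do not hinge on redundant collinear
    features.
    """
    _, labels_full = fit_kprototypes(table, k=k, gamma=gamma, n_init=n_init, seed=seed)
    pruned, _ = prune_correlated(table, corr_threshold)
    _, labels_pruned = fit_kprototypes(pruned, k=k, gamma=gamma, n_init=n_init, seed=seed)
    return adjusted_rand_index(labels_full, labels_pruned), labels_full, labels_pruned
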