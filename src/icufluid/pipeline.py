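"""End-to-end pipeline: simulate -> preprocess -> cluster -> profile ->
g-formula -> feature selection -> classifier.

Every stage draws its randomness from a seed derived from the master seed by
stage name (see :func:`icufluid.io.stage_seed`), so a stage can be re-run in
isolation and the whole run is byte-reproducible.  Every artifact directory
carries a manifest with the config hash and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import features as fs
from . import gformula as gf
from . import io as iomod
from . import kprototypes as kp
from . import preprocess as pp
from . import profile as prof
from . import synthetic as syn
from .schema import ValidationError

log = logging.getLogger("icufluid")


@dataclass
class PipelineConfig:
    """Tunable knobs of the full pipeline, with study defaults."""

    seed: int = 0
    out_dir: str = "icufluid_out"
    # simulate (set n_patients=0 to skip and read baseline/persondays paths)
    n_patients: int = 2000
    baseline_path: str | None = None
    schema_path: str | None = None
    persondays_path: str | None = None
    # preprocess
    missing_threshold: float = 0.30
    corr_threshold: float = 0.8
    scaling: str = "minmax01"
    # cluster
    k: int | str = "auto"
    k_range: tuple[int, int] = (2, 8)
    gamma: float | str = "auto"
    n_init: int = 10
    # g-formula
    horizon: int = 7
    n_mc: int = 5000
    n_boot: int = 0
    grid_lowers: tuple[float, ...] = (-3000, -2500, -2000, -1500, -1000, -500, 0, 500, 1000, 1500)
    grid_uppers: tuple[float, ...] = (-3000, -2500, -2000, -1500, -1000, -500, 0, 500, 1000, 1500)
    # feature selection / classifier
    jmim_bins: int = 5
    importance_threshold: float = 0.8
    test_size: float = 0.3

    def validate(self) -> None:
        if not 0 <= self.missing_threshold <= 1:
            raise ValidationError("missing_threshold must be in [0,1]")
        if not 0 < self.corr_threshold <= 1:
            raise ValidationError("corr_threshold must be in (0,1]")
        if self.horizon < 1:
            raise ValidationError("horizon must be >= 1")
        if not 0 < self.importance_threshold <= 1:
            raise ValidationError("importance_threshold must be in (0,1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("k_range", "grid_lowers", "grid_uppers"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage; returns the artifact directory.

    Writes: baseline/persondays/schema CSVs (when simulating), assignment
    CSV, group-summary CSV, risk-grid CSV, feature-score CSV, AUC CSV and a
    manifest JSON with the config hash.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = iomod.config_hash(dataclasses.asdict(config))
    log.info("pipeline start: config hash %s, seed %d", chash, config.seed)

    # --- simulate or load -------------------------------------------------
    if config.n_patients and config.baseline_path is None:
        seed = iomod.stage_seed(config.seed, "simulate")
        log.info("simulate: n=%d (seed %d)", config.n_patients, seed)
        baseline, persondays = syn.generate_cohort(
            syn.default_phenotypes(),
            syn.default_trajectory(horizon_days=config.horizon),
            n=config.n_patients,
            seed=seed,
            units=syn.default_units(),
        )
        iomod.write_baseline(baseline, out / "baseline.csv", out / "schema.csv")
        iomod.write_persondays(persondays, out / "persondays.csv")
    else:
        if not (config.baseline_path and config.schema_path and config.persondays_path):
            raise ValidationError("need baseline_path, schema_path and persondays_path")
        baseline = iomod.read_baseline(config.baseline_path, config.schema_path)
        persondays = iomod.read_persondays(config.persondays_path)

    # --- preprocess -------------------------------------------------------
    filtered, rep_missing = pp.filter_missing(baseline, config.missing_threshold)
    imputed, rep_impute = pp.impute(filtered)
    scaled, rep_scale = pp.scale_numeric(imputed, config.scaling)
    log.info(
        "preprocess: dropped %d features for missingness; scaling=%s (defaults: median/mode imputation)",
        len(rep_missing.dropped_missing), config.scaling,
    )

    # --- cluster ----------------------------------------------------------
    seed = iomod.stage_seed(config.seed, "cluster")
    if config.k == "auto":
        k, diagnostics = kp.select_k(
            scaled, config.k_range, gamma=config.gamma, n_init=config.n_init, seed=seed
        )
        diagnostics.to_csv(out / "k_diagnostics.csv", index=False)
        log.info("select_k: chose k=%d by mixed silhouette", k)
    else:
        k = int(config.k)
    model, labels = kp.fit_kprototypes(
        scaled, k=k, gamma=config.gamma, n_init=config.n_init, seed=seed
    )
    letters = [chr(ord("A") + i) for i in range(k)]
    named = labels.map(lambda c: letters[c])
    iomod.write_labels(named, out / "assignment.csv")
    log.info("cluster: k=%d gamma=%.4f cost=%.2f", model.k, model.gamma, model.total_cost)

    # --- profile ----------------------------------------------------------
    summary = prof.summarize_groups(imputed, named)
    summary.render().to_csv(out / "group_summary.csv")
    summary.tests.to_csv(out / "group_tests.csv")
    comorbs = [f for f in imputed.schema.categorical if f not in ("female",)]
    prev, weights = prof.comorbidity_cooccurrence(imputed, named, comorbs)
    prev.to_csv(out / "comorbidity_prevalence.csv")
    contrasts = prof.survival_contrast(persondays, named, horizons=[config.horizon])
    logrank_p = contrasts[config.horizon].logrank_p
    log.info("profile: log-rank p=%.3g at %d days", logrank_p, config.horizon)

    # --- g-formula --------------------------------------------------------
    seed = iomod.stage_seed(config.seed, "gformula")
    gspec = gf.GFormulaSpec(horizon=config.horizon)
    grid = gf.phenotype_intervention_grids(
        baseline, persondays, named,
        lowers=list(config.grid_lowers), uppers=list(config.grid_uppers),
        spec=gspec, n_mc=config.n_mc, seed=seed,
    )
    natural = grid[~np.isfinite(grid["lower"])].set_index("phenotype")["risk"]
    grid["risk_vs_natural"] = grid["risk"] - grid["phenotype"].map(natural)
    grid.to_csv(out / "risk_grid.csv", index=False)
    best = grid[np.isfinite(grid["lower"])].loc[
        grid[np.isfinite(grid["lower"])].groupby("phenotype")["risk"].idxmin()
    ]
    log.info("gformula: per-phenotype argmin ranges\n%s",
             best[["phenotype", "lower", "upper", "risk"]].to_string(index=False))

    # --- feature selection + classifier -----------------------------------
    seed = iomod.stage_seed(config.seed, "classify")
    disc = fs.discretize_table(imputed, bins=config.jmim_bins)
    scores = fs.jmim_rank(disc, named.to_numpy())
    fs.scores_frame(scores).to_csv(out / "feature_scores.csv", index=False)
    selected = fs.select_by_importance(scores, config.importance_threshold)
    if len(selected) < 9:  # distilled model keeps at least nine variables
        selected = [s.feature for s in scores[:9]]
    log.info("jmim: %d features kept (importance threshold %.2f): %s",
             len(selected), config.importance_threshold, selected)
    _, auc, auc_range = fs.train_phenotype_classifier(
        imputed, named, selected, fs.SplitSpec(test_size=config.test_size), seed=seed
    )
    pd.Series(auc, name="auc").rename_axis("phenotype").reset_index().to_csv(
        out / "classifier_auc.csv", index=False
    )
    log.info("classifier: per-class AUC %.3f-%.3f", *auc_range)

    manifest = {
        "config_hash": chash,
        "seed": config.seed,
        "k": int(model.k),
        "gamma": float(model.gamma),
        "logrank_p": float(logrank_p),
        "auc_range": [float(a) for a in auc_range],
        "selected_features": selected,
        "defaults": {
            "imputation": "median/mode",
            "scaling": config.scaling,
            "gamma_rule": "0.5 x mean numeric sd" if config.gamma == "auto" else config.gamma,
            "intervention": "clamp (truncation) of natural fluid draw",
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    log.info("pipeline done: artifacts in %s", out)
    return out
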