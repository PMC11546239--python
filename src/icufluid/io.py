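"""Schema-aware CSV readers/writers and seeded stage RNG derivation.

Tables travel as plain CSV with a sidecar schema file (columns: ``feature``,
``kind`` numeric|categorical, ``units``, ``levels`` pipe-separated) so every
artifact stays inspectable with ordinary tools.  Missing cells are empty
strings on disk.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

from .schema import (
    ID_COL,
    PHENOTYPE_COL,
    BaselineTable,
    FeatureSchema,
    PersonDayTable,
    ValidationError,
)


def stage_seed(master_seed: int, stage: str) -> int:
    """A reproducible per-stage seed derived from the master seed by name.

    Stages can therefore be re-run in isolation with the same stream.
    Always below 2**31.
    """
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def config_hash(payload: object) -> str:
    return hashlib.sha256(repr(payload).encode()).hexdigest()[:12]


def write_schema(schema: FeatureSchema, path: str | Path) -> None:
    rows = [
        {"feature": f, "kind": "numeric", "units": u, "levels": ""}
        for f, u in schema.numeric.items()
    ] + [
        {"feature": f, "kind": "categorical", "units": "", "levels": "|".join(lv)}
        for f, lv in schema.categorical.items()
    ]
    pd.DataFrame(rows, columns=["feature", "kind", "units", "levels"]).to_csv(path, index=False)


def read_schema(path: str | Path) -> FeatureSchema:
    df = pd.read_csv(path, dtype=str).fillna("")
    numeric, categorical = {}, {}
    for _, row in df.iterrows():
        if row["kind"] == "numeric":
            numeric[row["feature"]] = row["units"]
        elif row["kind"] == "categorical":
            categorical[row["feature"]] = tuple(v for v in row["levels"].split("|") if v)
        else:
            raise ValidationError(f"unknown kind {row['kind']!r} for feature {row['feature']!r}")
    return FeatureSchema(numeric=numeric, categorical=categorical)


def write_baseline(table: BaselineTable, path: str | Path, schema_path: str | Path) -> None:
    write_schema(table.schema, schema_path)
    table.df.to_csv(path, index=False)


def read_baseline(path: str | Path, schema_path: str | Path) -> BaselineTable:
    """Load a baseline table, enforcing the sidecar schema.

    Undeclared columns, unparseable numerics and unknown categorical levels
    are all rejected with the offending column (and row) named.
    """
    schema = read_schema(schema_path)
    df = pd.read_csv(path, dtype=str)
    if ID_COL not in df.columns:
        raise ValidationError(f"{path}: no {ID_COL!r} column")
    declared = set(schema.features) | {ID_COL, PHENOTYPE_COL}
    undeclared = [c for c in df.columns if c not in declared]
    if undeclared:
        raise ValidationError(f"{path}: columns not declared in schema: {undeclared}")
    missing_cols = [f for f in schema.features if f not in df.columns]
    if missing_cols:
        raise ValidationError(f"{path}: schema features absent: {missing_cols}")
    for f in schema.numeric:
        parsed = pd.to_numeric(df[f], errors="coerce")
        bad = parsed.isna() & df[f].notna() & (df[f].str.strip() != "")
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValidationError(f"{path}: unparseable numeric in column {f!r}, row {row}")
        df[f] = parsed
    for f, levels in schema.categorical.items():
        col = df[f].astype(object)
        col = col.where(pd.notna(col) & (col.astype(str).str.strip() != ""), pd.NA)
        observed = set(col.dropna().astype(str))
        unknown = observed - set(levels) if levels else set()
        if unknown:
            raise ValidationError(f"{path}: unknown levels in column {f!r}: {sorted(unknown)}")
        df[f] = col
    return BaselineTable(df=df, schema=schema)


def write_persondays(table: PersonDayTable, path: str | Path) -> None:
    table.df.to_csv(path, index=False)


def read_persondays(path: str | Path) -> PersonDayTable:
    df = pd.read_csv(path)
    df[ID_COL] = df[ID_COL].astype(str)
    return PersonDayTable(df=df)


def write_labels(labels: pd.Series, path: str | Path) -> None:
    labels.rename("phenotype").rename_axis(ID_COL).reset_index().to_csv(path, index=False)


def read_labels(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, dtype={ID_COL: str})
    return df.set_index(ID_COL)["phenotype"]
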