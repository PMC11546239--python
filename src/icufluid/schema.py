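"""Typed tabular containers shared by every pipeline stage.

A cohort is carried as two tables:

* :class:`BaselineTable` — one row per ICU stay, mixed numeric (labs, vitals,
  severity scores, age, weight) and categorical (comorbidities, interventions,
  demographics) columns, with a :class:`FeatureSchema` declaring the kind of
  every feature.  Missing values are explicit (``NaN`` / ``pd.NA``).
* :class:`PersonDayTable` — one row per patient per ICU day, holding the daily
  net fluid balance (mL), the time-varying covariates and the death/censoring
  indicators for a discrete-time survival analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ID_COL = "patient_id"
PHENOTYPE_COL = "true_phenotype"

#: reserved columns of a person-day table; everything else is a covariate
PERSONDAY_FIXED = (ID_COL, "day", "fluid_balance", "died", "censored")


class ValidationError(ValueError):
    """Raised when a table or specification violates its invariants."""


@dataclass(frozen=True)
class FeatureSchema:
    """Declares every feature of a baseline table as numeric or categorical.

    Parameters
    ----------
    numeric
        Ordered mapping ``feature -> units`` (units are informational only).
    categorical
        Ordered mapping ``feature -> tuple of allowed levels``.
    """

    numeric: dict[str, str] = field(default_factory=dict)
    categorical: dict[str, tuple[str, ...]] = field(default_factory=dict)

    @property
    def features(self) -> list[str]:
        return list(self.numeric) + list(self.categorical)

    def is_numeric(self, feature: str) -> bool:
        return feature in self.numeric

    def subset(self, keep: list[str]) -> "FeatureSchema":
        return FeatureSchema(
            numeric={f: u for f, u in self.numeric.items() if f in keep},
            categorical={f: lv for f, lv in self.categorical.items() if f in keep},
        )

    def __post_init__(self) -> None:
        overlap = set(self.numeric) & set(self.categorical)
        if overlap:
            raise ValidationError(f"features declared both numeric and categorical: {sorted(overlap)}")


@dataclass
class BaselineTable:
    """Per-patient mixed-type feature matrix with explicit missingness."""

    df: pd.DataFrame
    schema: FeatureSchema

    def __post_init__(self) -> None:
        if ID_COL not in self.df.columns:
            raise ValidationError(f"baseline table must have a {ID_COL!r} column")
        if self.df[ID_COL].duplicated().any():
            raise ValidationError("patient_id values must be unique")
        declared = set(self.schema.features) | {ID_COL, PHENOTYPE_COL}
        undeclared = [c for c in self.df.columns if c not in declared]
        if undeclared:
            raise ValidationError(f"columns not declared in schema: {undeclared}")
        missing = [f for f in self.schema.features if f not in self.df.columns]
        if missing:
            raise ValidationError(f"schema features absent from table: {missing}")

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def features(self) -> list[str]:
        return self.schema.features

    def numeric_frame(self) -> pd.DataFrame:
        return self.df[list(self.schema.numeric)].astype(float)

    def categorical_frame(self) -> pd.DataFrame:
        return self.df[list(self.schema.categorical)]

    def missing_fraction(self) -> pd.Series:
        """Fraction of missing cells per feature column."""
        return self.df[self.features].isna().mean()

    def is_complete(self) -> bool:
        return not self.df[self.features].isna().any().any()

    def with_df(self, df: pd.DataFrame, schema: FeatureSchema | None = None) -> "BaselineTable":
        return BaselineTable(df=df, schema=schema if schema is not None else self.schema)

    def copy(self) -> "BaselineTable":
        return BaselineTable(df=self.df.copy(), schema=self.schema)


@dataclass
class PersonDayTable:
    """Longitudinal day-level records: one row per (patient, ICU day).

    Rows run from day 0 contiguously until the first absorbing event (death or
    censoring); ``died`` and ``censored`` are mutually exclusive per row and no
    rows may follow either.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        for col in PERSONDAY_FIXED:
            if col not in self.df.columns:
                raise ValidationError(f"person-day table missing column {col!r}")
        self.validate()

    @property
    def covariate_columns(self) -> list[str]:
        return [c for c in self.df.columns if c not in PERSONDAY_FIXED]

    def validate(self) -> None:
        df = self.df
        if ((df["died"] == 1) & (df["censored"] == 1)).any():
            raise ValidationError("died and censored both set on the same person-day")
        if df.duplicated([ID_COL, "day"]).any():
            raise ValidationError("duplicate (patient_id, day) rows")
        for pid, g in df.groupby(ID_COL, sort=False):
            days = g["day"].to_numpy()
            order = np.argsort(days)
            if not np.array_equal(days[order], np.arange(len(days))):
                raise ValidationError(f"days for patient {pid!r} not contiguous from 0")
            absorbing = (g["died"].to_numpy() + g["censored"].to_numpy())[order]
            if absorbing[:-1].any():
                raise ValidationError(f"rows after an absorbing event for patient {pid!r}")

    def copy(self) -> "PersonDayTable":
        return PersonDayTable(df=self.df.copy())


def time_to_event(persondays: PersonDayTable) -> pd.DataFrame:
    """Collapse person-days to one row per patient: (time, event).

    ``time`` is 1-based (death or censoring on day ``t`` gives time ``t+1``,
    i.e. the number of days survived into); administrative end of the window
    counts as censoring at the last observed day.
    """
    last = (
        persondays.df.sort_values([ID_COL, "day"])
        .groupby(ID_COL, sort=False)
        .tail(1)
        .reset_index(drop=True)
    )
    return pd.DataFrame(
        {
            ID_COL: last[ID_COL],
            "time": last["day"].astype(int) + 1,
            "event": last["died"].astype(int),
        }
    )
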