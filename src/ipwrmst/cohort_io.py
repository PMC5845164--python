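"""Cohort data model: subject-level time-to-event tables with a binary exposure.

A cohort is one row per subject carrying an exposure indicator X in {0, 1},
an observed follow-up time ``min(T, C)``, an integer event-type code J
(0 = censored, 1..m = event types), baseline covariates Z, and an optional
stratum label (e.g. calendar era of enrollment).  Event semantics — which
code is the event of interest and which codes form the composite competing
event — live in :class:`EventCoding` so the same table can be analysed under
different outcome definitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "CohortTable",
    "EventCoding",
    "SchemaError",
    "ValidationError",
    "read_cohort",
    "write_cohort",
    "complete_case_filter",
]


class SchemaError(ValueError):
    """A required column is absent or the column mapping is inconsistent."""


class ValidationError(ValueError):
    """Row-level contents violate the cohort invariants."""


@dataclass(frozen=True)
class EventCoding:
    """Roles of the integer event codes.

    Parameters
    ----------
    event_of_interest
        Code j of the event whose cumulative incidence is the target
        (e.g. treatment initiation).
    competing_codes
        Codes collapsed into one composite competing event (e.g. death
        together with loss to clinic).  May be empty when no competing
        risks are in play.
    censor_code
        Code meaning right-censored; 0 by convention.
    """

    event_of_interest: int = 1
    competing_codes: frozenset[int] = frozenset()
    censor_code: int = 0

    def __post_init__(self):
        competing = frozenset(int(c) for c in self.competing_codes)
        object.__setattr__(self, "competing_codes", competing)
        if self.event_of_interest in competing:
            raise ValueError("event_of_interest cannot be a competing code")
        if self.censor_code == self.event_of_interest or self.censor_code in competing:
            raise ValueError("censor_code must be distinct from event codes")

    @property
    def event_codes(self) -> frozenset[int]:
        """All non-censoring codes."""
        return frozenset({self.event_of_interest}) | self.competing_codes


@dataclass
class CohortTable:
    """Validated subject-level cohort.

    ``data`` holds the canonical columns ``subject_id``, ``exposure``,
    ``time``, ``event_type``, the named covariates, and optionally ``era``.
    ``time_unit`` is carried verbatim into outputs; the estimators are
    unit-agnostic.
    """

    data: pd.DataFrame
    covariate_names: list[str] = field(default_factory=list)
    time_unit: str = "years"
    era_column: str | None = None

    REQUIRED = ("subject_id", "exposure", "time", "event_type")

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        df = self.data
        for col in self.REQUIRED:
            if col not in df.columns:
                raise SchemaError(f"missing required column {col!r}")
        for col in self.covariate_names:
            if col not in df.columns:
                raise SchemaError(f"missing covariate column {col!r}")
        if self.era_column is not None and self.era_column not in df.columns:
            raise SchemaError(f"missing era column {self.era_column!r}")
        for col in ("exposure", "time", "event_type"):
            if df[col].isna().any():
                rows = df.index[df[col].isna()].tolist()[:10]
                raise ValidationError(f"missing values in {col!r} at rows {rows}")
        bad_t = df.index[np.asarray(df["time"], dtype=float) < 0].tolist()
        if bad_t:
            raise ValidationError(f"negative time at rows {bad_t[:10]}")
        ev = np.asarray(df["event_type"])
        if not np.array_equal(ev, ev.astype(int)):
            raise ValidationError("event_type must be integer-coded")
        if (np.asarray(ev, dtype=int) < 0).any():
            bad = df.index[np.asarray(ev, dtype=int) < 0].tolist()
            raise ValidationError(f"negative event code at rows {bad[:10]}")
        x = np.asarray(df["exposure"])
        if not set(np.unique(x)) <= {0, 1}:
            raise ValidationError("exposure must be coded 0/1")
        if len(np.unique(x)) < 2:
            raise ValidationError("both exposure levels required")

    # -- convenience accessors used throughout the estimators -------------
    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def exposure(self) -> np.ndarray:
        return np.asarray(self.data["exposure"], dtype=int)

    @property
    def time(self) -> np.ndarray:
        return np.asarray(self.data["time"], dtype=float)

    @property
    def event_type(self) -> np.ndarray:
        return np.asarray(self.data["event_type"], dtype=int)

    def subset(self, mask: np.ndarray) -> "CohortTable":
        """Row subset (keeps covariate metadata); exposure levels re-checked lazily."""
        sub = self.data.loc[np.asarray(mask)].reset_index(drop=True)
        out = object.__new__(CohortTable)
        out.data = sub
        out.covariate_names = list(self.covariate_names)
        out.time_unit = self.time_unit
        out.era_column = self.era_column
        return out

    def resample(self, rng: np.random.Generator) -> "CohortTable":
        """Nonparametric bootstrap resample: n subjects drawn with replacement."""
        idx = rng.integers(0, self.n, size=self.n)
        out = object.__new__(CohortTable)
        out.data = self.data.iloc[idx].reset_index(drop=True)
        out.covariate_names = list(self.covariate_names)
        out.time_unit = self.time_unit
        out.era_column = self.era_column
        return out


def read_cohort(
    path,
    schema: dict[str, str] | None = None,
    covariates: list[str] | None = None,
    era: str | None = None,
    sep: str = ",",
    time_unit: str = "years",
) -> CohortTable:
    """Read a delimited cohort table and validate it.

    Parameters
    ----------
    path
        CSV/TSV file with a header row.
    schema
        Mapping from canonical names (``subject_id``, ``exposure``, ``time``,
        ``event_type``) to the column names in the file.  Identity if omitted.
    covariates
        Covariate column names (file names, before renaming).
    era
        Optional stratum column.
    """
    df = pd.read_csv(path, sep=sep)
    schema = dict(schema or {})
    rename = {v: k for k, v in schema.items()}
    for canon in CohortTable.REQUIRED:
        src = schema.get(canon, canon)
        if src not in df.columns:
            raise SchemaError(f"column {src!r} (for {canon!r}) not found in {path}")
    df = df.rename(columns=rename)
    cov = list(covariates or [])
    return CohortTable(df, covariate_names=cov, time_unit=time_unit, era_column=era)


def write_cohort(cohort: CohortTable, path, sep: str = ",") -> None:
    """Write the canonical table back to delimited text (round-trips with read_cohort)."""
    cohort.data.to_csv(path, sep=sep, index=False)


def complete_case_filter(
    cohort: CohortTable, covariate_names: list[str] | None = None
) -> tuple[CohortTable, int]:
    """Drop subjects with missing values in the named covariates.

    Returns the filtered cohort and the number of excluded rows.  Mirrors
    complete-case handling: no imputation, exclusion before any estimation.
    """
    names = list(covariate_names if covariate_names is not None else cohort.covariate_names)
    for c in names:
        if c not in cohort.data.columns:
            raise SchemaError(f"missing covariate column {c!r}")
    if not names:
        return cohort, 0
    keep = ~cohort.data[names].isna().any(axis=1)
    excluded = int((~keep).sum())
    if excluded == cohort.n:
        raise ValidationError("all rows have missing covariates; nothing left to analyse")
    if excluded == 0:
        return cohort, 0
    return cohort.subset(keep.to_numpy()), excluded
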