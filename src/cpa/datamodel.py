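"""Core domain containers shared by every pipeline stage.

A *clinotype* is an objectively measured piece of clinical information —
chiefly a numerical laboratory test result.  Each measured value arrives
with its own (low, high) reference range: ranges are attached per record,
not per clinotype, because they depend on the individual (e.g. Hematocrit
is 35–45% for women and 40–50% for men).

The central container is :class:`ClinotypeMatrix`: a patient × clinotype
grid of float values where ``NaN`` marks a missing measurement, together
with per-cell reference-range grids aligned to the same axes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

SEXES = ("female", "male")

#: Adult age strata used for the demographic mix; pediatric (<18) patients
#: are filtered out during preprocessing.
AGE_GROUPS = ("pediatric", "young", "middle", "old")

ANNOTATION_LABELS = ("low", "normal", "high")


@dataclass(frozen=True)
class ClinotypeResult:
    """One raw laboratory record (long-format row)."""

    patient_id: str
    clinotype: str
    value: float
    date: pd.Timestamp
    ref_low: float
    ref_high: float

    def __post_init__(self) -> None:
        if not self.ref_low < self.ref_high:
            raise ValueError(
                f"reference range must satisfy low < high, got "
                f"({self.ref_low}, {self.ref_high}) for {self.clinotype}"
            )
        if self.value is not None and not np.isfinite(self.value):
            raise ValueError(f"non-finite value for {self.clinotype}")


@dataclass(frozen=True)
class DiagnosisRecord:
    """A single ICD-10 coded diagnosis event."""

    patient_id: str
    icd10_code: str
    date: pd.Timestamp

    def __post_init__(self) -> None:
        if not self.icd10_code:
            raise ValueError("empty ICD-10 code")


@dataclass(frozen=True)
class Geneset:
    """A named set of gene symbols (one GMT line)."""

    name: str
    description: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"geneset {self.name!r} has no genes")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"geneset {self.name!r} has duplicate genes")


@dataclass(frozen=True)
class AssociationRecord:
    """An association between a clinotype and a phenotype or another clinotype.

    ``kind`` is "phenotype" for disease associations (``partner`` is an
    ICD-10 prefix, ``effect`` a mean difference in normalized units,
    ``p_value`` from a two-sample t-test) and "clinotype" for
    clinotype–clinotype associations mined from imputation models
    (``effect`` is the averaged regression coefficient; ``stability`` is
    the sign-consistency fraction across resampling repetitions).
    """

    clinotype: str
    partner: str
    kind: str
    effect: float
    p_value: float = float("nan")
    significant: bool = False
    stability: float = float("nan")


class ClinotypeMatrix:
    """Patient × clinotype value grid with per-cell reference ranges.

    Parameters
    ----------
    values
        Float DataFrame, rows = patients, columns = clinotypes.  ``NaN``
        marks a missing measurement.
    ref_low, ref_high
        DataFrames aligned to ``values`` carrying the per-record reference
        range; must be present wherever a value is observed.
    first_date
        Optional per-patient Series with the earliest record date, used by
        the temporal train/test split.
    imputed
        Optional boolean DataFrame flagging cells filled by a model rather
        than observed.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        ref_low: pd.DataFrame,
        ref_high: pd.DataFrame,
        first_date: pd.Series | None = None,
        imputed: pd.DataFrame | None = None,
        meta: dict | None = None,
    ) -> None:
        values = values.astype(float)
        values.index.name = "patient_id"
        values.columns.name = "clinotype"
        if not values.index.is_unique or not values.columns.is_unique:
            raise ValueError("patient ids and clinotype names must be unique")
        ref_low = ref_low.reindex(index=values.index, columns=values.columns).astype(float)
        ref_high = ref_high.reindex(index=values.index, columns=values.columns).astype(float)

        observed = values.notna()
        if imputed is not None:
            measured = observed & ~imputed.reindex(
                index=values.index, columns=values.columns
            ).fillna(False).astype(bool)
        else:
            measured = observed
        if bool((measured & (ref_low.isna() | ref_high.isna())).any().any()):
            raise ValueError("every measured cell must carry a reference range")
        both = ref_low.notna() & ref_high.notna()
        if bool((both & ~(ref_low < ref_high)).any().any()):
            raise ValueError("reference ranges must satisfy low < high")

        if first_date is not None:
            first_date = pd.Series(pd.to_datetime(first_date)).reindex(values.index)
        if imputed is None:
            imputed = pd.DataFrame(False, index=values.index, columns=values.columns)
        else:
            imputed = imputed.reindex(index=values.index, columns=values.columns).fillna(False)

        self.values = values
        self.ref_low = ref_low
        self.ref_high = ref_high
        self.first_date = first_date
        self.imputed = imputed.astype(bool)
        self.meta = dict(meta or {})

    # -- basic introspection -------------------------------------------------
    @property
    def patients(self) -> pd.Index:
        return self.values.index

    @property
    def clinotypes(self) -> pd.Index:
        return self.values.columns

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean DataFrame, True where the value is observed."""
        return self.values.notna()

    @property
    def n_patients(self) -> int:
        return self.values.shape[0]

    @property
    def n_clinotypes(self) -> int:
        return self.values.shape[1]

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().sum().sum())

    def copy(self) -> "ClinotypeMatrix":
        return ClinotypeMatrix(
            self.values.copy(),
            self.ref_low.copy(),
            self.ref_high.copy(),
            None if self.first_date is None else self.first_date.copy(),
            self.imputed.copy(),
            dict(self.meta),
        )

    def subset_patients(self, patient_ids: Iterable) -> "ClinotypeMatrix":
        idx = pd.Index(patient_ids)
        missing = idx.difference(self.patients)
        if len(missing):
            raise KeyError(f"unknown patients: {list(missing)[:5]}")
        return ClinotypeMatrix(
            self.values.loc[idx],
            self.ref_low.loc[idx],
            self.ref_high.loc[idx],
            None if self.first_date is None else self.first_date.loc[idx],
            self.imputed.loc[idx],
            dict(self.meta),
        )

    def subset_clinotypes(self, names: Iterable[str]) -> "ClinotypeMatrix":
        cols = pd.Index(names)
        missing = cols.difference(self.clinotypes)
        if len(missing):
            raise KeyError(f"unknown clinotypes: {list(missing)[:5]}")
        return ClinotypeMatrix(
            self.values[cols],
            self.ref_low[cols],
            self.ref_high[cols],
            self.first_date,
            self.imputed[cols],
            dict(self.meta),
        )

    def equals(self, other: "ClinotypeMatrix") -> bool:
        return (
            self.values.equals(other.values)
            and self.ref_low.equals(other.ref_low)
            and self.ref_high.equals(other.ref_high)
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ClinotypeMatrix({self.n_patients} patients × "
            f"{self.n_clinotypes} clinotypes, {self.n_missing} missing)"
        )


def make_patients_frame(
    patient_ids: Iterable,
    sex: Iterable[str],
    birth_year: Iterable[int],
    age_group: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Assemble the patient metadata table (index = patient_id)."""
    df = pd.DataFrame(
        {"sex": list(sex), "birth_year": list(birth_year)},
        index=pd.Index(patient_ids, name="patient_id"),
    )
    bad = set(df["sex"]) - set(SEXES)
    if bad:
        raise ValueError(f"unknown sex labels: {sorted(bad)}")
    if age_group is not None:
        df["age_group"] = list(age_group)
    return df


def age_group_of(age: float) -> str:
    """Map an age in years to the demographic stratum."""
    if age < 18:
        return "pediatric"
    if age < 40:
        return "young"
    if age < 60:
        return "middle"
    return "old"


def assign_age_groups(patients: pd.DataFrame, reference_date: pd.Timestamp | pd.Series) -> pd.Series:
    """Age stratum at the (per-patient or global) reference date."""
    ref_year = (
        reference_date.dt.year
        if isinstance(reference_date, pd.Series)
        else pd.Series(pd.Timestamp(reference_date).year, index=patients.index)
    )
    age = ref_year.reindex(patients.index) - patients["birth_year"]
    return age.map(age_group_of)
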