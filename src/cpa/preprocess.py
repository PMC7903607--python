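"""The P0 → P1 → P2 preprocessing cascade.

P0 is the raw matrix; P1 results from filtering rare clinotypes and
uninformative/pediatric patients; P2 is P1 z-score normalized with
statistics computed on the training split only.  The temporal split into
Pr (training) and Pt (test) is patient-level, keyed on each patient's
earliest record date relative to a cutoff date.

Reference ranges are transformed with the same per-clinotype affine map
as the values, so the high/normal/low annotation of any cell is invariant
under normalization.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import ClinotypeMatrix, assign_age_groups

logger = logging.getLogger(__name__)


class EmptyResultError(ValueError):
    """Filtering or splitting produced an empty data subset."""


@dataclass(frozen=True)
class FilterConfig:
    """Rarity and patient filters for P0 → P1.

    A clinotype is dropped when observed by fewer than
    ``max(min_patients_per_clinotype, ceil(min_fraction * n_patients))``
    patients (strictly fewer: a clinotype observed by exactly the bound is
    retained).
    """

    min_patients_per_clinotype: int = 1000
    min_fraction: float = 0.01
    drop_pediatric: bool = True
    numeric_only: bool = True

    def threshold(self, n_patients: int) -> int:
        return max(self.min_patients_per_clinotype, math.ceil(self.min_fraction * n_patients))


@dataclass
class FilterReport:
    threshold: int
    clinotypes_in: int
    clinotypes_dropped_empty: list[str] = field(default_factory=list)
    clinotypes_dropped_rare: list[str] = field(default_factory=list)
    patients_in: int = 0
    patients_dropped_pediatric: int = 0
    patients_dropped_no_values: int = 0

    @property
    def clinotypes_retained(self) -> int:
        return (
            self.clinotypes_in
            - len(self.clinotypes_dropped_empty)
            - len(self.clinotypes_dropped_rare)
        )


def filter_dataset(
    matrix: ClinotypeMatrix,
    patients: pd.DataFrame | None = None,
    config: FilterConfig = FilterConfig(),
) -> tuple[ClinotypeMatrix, pd.DataFrame | None, FilterReport]:
    """Apply the P0 → P1 filters; idempotent.

    Drops: all-missing (non-numeric) clinotypes, clinotypes observed by
    fewer patients than the rarity bound, pediatric patients (age < 18 at
    earliest record, when birth years are known), and patients left with
    no observed values.
    """
    report = FilterReport(
        threshold=config.threshold(matrix.n_patients),
        clinotypes_in=matrix.n_clinotypes,
        patients_in=matrix.n_patients,
    )

    values = matrix.values
    keep_cols = []
    for clin in matrix.clinotypes:
        n_obs = int(values[clin].notna().sum())
        if config.numeric_only and n_obs == 0:
            report.clinotypes_dropped_empty.append(clin)
        elif n_obs < report.threshold:
            report.clinotypes_dropped_rare.append(clin)
        else:
            keep_cols.append(clin)
    if not keep_cols:
        raise EmptyResultError("all clinotypes were filtered out")

    keep_idx = matrix.patients
    if config.drop_pediatric and patients is not None and "birth_year" in patients:
        ref = (
            matrix.first_date
            if matrix.first_date is not None
            else pd.Series(pd.Timestamp.now(), index=matrix.patients)
        )
        groups = assign_age_groups(patients.loc[keep_idx], ref)
        pediatric = groups[groups == "pediatric"].index
        report.patients_dropped_pediatric = len(pediatric)
        keep_idx = keep_idx.difference(pediatric, sort=False)

    sub = values.loc[keep_idx, keep_cols]
    has_values = sub.notna().any(axis=1)
    report.patients_dropped_no_values = int((~has_values).sum())
    keep_idx = sub.index[has_values]
    if len(keep_idx) == 0:
        raise EmptyResultError("all patients were filtered out")

    out = matrix.subset_patients(keep_idx).subset_clinotypes(keep_cols)
    out_patients = None if patients is None else patients.loc[keep_idx]
    return out, out_patients, report


@dataclass
class SplitResult:
    train: ClinotypeMatrix  # Pr
    test: ClinotypeMatrix  # Pt
    cutoff_date: pd.Timestamp
    ratio: float  # |Pr| / |Pt|


def temporal_split(matrix: ClinotypeMatrix, cutoff_date) -> SplitResult:
    """Patient-level temporal split at ``cutoff_date``.

    A patient joins the training side (Pr) when their earliest record
    date is on or before the cutoff; otherwise the test side (Pt).  All
    of a patient's records travel together, so no patient appears in
    both subsets.
    """
    if matrix.first_date is None or matrix.first_date.isna().any():
        raise ValueError("every patient needs a record date for the temporal split")
    cutoff = pd.Timestamp(cutoff_date)
    in_train = matrix.first_date <= cutoff
    train_ids = matrix.patients[in_train]
    test_ids = matrix.patients[~in_train]
    if len(train_ids) == 0:
        raise EmptyResultError("temporal split produced an empty training set (Pr)")
    if len(test_ids) == 0:
        raise EmptyResultError("temporal split produced an empty test set (Pt)")
    return SplitResult(
        train=matrix.subset_patients(train_ids),
        test=matrix.subset_patients(test_ids),
        cutoff_date=cutoff,
        ratio=len(train_ids) / len(test_ids),
    )


@dataclass
class NormalizationParams:
    """Per-clinotype mean and sample (n−1) standard deviation from Pr only."""

    mean: pd.Series
    std: pd.Series
    excluded: list[str] = field(default_factory=list)  # zero-variance or <2 values


def fit_normalization(train: ClinotypeMatrix) -> NormalizationParams:
    values = train.values
    mean = values.mean(skipna=True)
    std = values.std(ddof=1, skipna=True)
    counts = values.notna().sum()
    excluded = sorted(
        set(std.index[(counts < 2) | std.isna() | (std <= 0)])
    )
    if excluded:
        logger.warning("zero-variance clinotypes excluded from modeling: %s", excluded)
    keep = [c for c in values.columns if c not in excluded]
    return NormalizationParams(mean=mean[keep], std=std[keep], excluded=excluded)


def apply_normalization(matrix: ClinotypeMatrix, params: NormalizationParams) -> ClinotypeMatrix:
    """z-score values *and both range endpoints* with the training statistics."""
    missing = matrix.clinotypes.difference(params.mean.index)
    if len(missing):
        raise KeyError(f"no normalization parameters for clinotypes: {list(missing)}")
    mu = params.mean[matrix.clinotypes]
    sd = params.std[matrix.clinotypes]
    return ClinotypeMatrix(
        (matrix.values - mu) / sd,
        (matrix.ref_low - mu) / sd,
        (matrix.ref_high - mu) / sd,
        matrix.first_date,
        matrix.imputed,
        dict(matrix.meta, normalized=True),
    )


def annotate_value(value: float, ref_low: float, ref_high: float) -> str | None:
    """3-class label for a single measurement; ``None`` when unobserved.

    Values equal to an endpoint are labeled normal (inclusive bounds).
    """
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    if not ref_low < ref_high:
        raise ValueError(f"invalid reference range ({ref_low}, {ref_high})")
    if value < ref_low:
        return "low"
    if value > ref_high:
        return "high"
    return "normal"


def annotate(matrix: ClinotypeMatrix) -> pd.DataFrame:
    """Label every ranged, observed cell as low/normal/high (NaN otherwise).

    Cells without a recorded reference range (possible for imputed
    values) stay unlabeled.
    """
    values = matrix.values
    labels = pd.DataFrame(np.nan, index=values.index, columns=values.columns, dtype=object)
    low = values < matrix.ref_low
    high = values > matrix.ref_high
    observed = values.notna() & matrix.ref_low.notna() & matrix.ref_high.notna()
    labels = labels.mask(observed, "normal")
    labels = labels.mask(observed & low, "low")
    labels = labels.mask(observed & high, "high")
    return labels
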