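"""Clinotype–phenotype association discovery and its classifier validation.

Associations are screened with a two-sample Student t-test per clinotype
between a disease cohort (patients carrying an ICD-10 code prefix) and a
healthy control cohort (patients with <5% abnormal observed values and
no diagnostic history).  Clinotypes with p < α (default 0.05, raw) are
flagged significant; Benjamini–Hochberg correction is available behind a
flag.

Validation trains two disease-vs-control classifiers on the training
split: ASS uses only the significantly associated clinotypes, NON only
the complement.  If the associations are real, ASS should dominate NON
on the held-out test split (AUC/ACC/PPV).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from statsmodels.stats.multitest import multipletests

from .datamodel import AssociationRecord, ClinotypeMatrix, DiagnosisRecord
from .preprocess import annotate

logger = logging.getLogger(__name__)


class EmptyCohortError(ValueError):
    pass


@dataclass(frozen=True)
class CohortSpec:
    """A named patient set; ``disease_code`` is "control" for the control set."""

    disease_code: str
    patient_ids: tuple


def select_control(
    matrix: ClinotypeMatrix,
    diagnoses: Sequence[DiagnosisRecord],
    max_abnormal_fraction: float = 0.05,
) -> CohortSpec:
    """Healthy controls: <5% abnormal observed cells and no diagnosis history.

    The abnormal fraction is computed over observed (non-missing) cells
    only; the threshold is strict (exactly 5% is excluded).
    """
    labels = annotate(matrix)
    abnormal = labels.isin(["high", "low"]).sum(axis=1)
    observed = matrix.mask.sum(axis=1)
    frac = abnormal / observed.replace(0, np.nan)
    diagnosed = {r.patient_id for r in diagnoses}
    keep = [
        pid
        for pid in matrix.patients
        if pd.notna(frac.loc[pid])
        and frac.loc[pid] < max_abnormal_fraction
        and pid not in diagnosed
    ]
    if not keep:
        raise EmptyCohortError("control selection produced an empty cohort")
    return CohortSpec("control", tuple(keep))


def select_disease_cohort(
    diagnoses: Sequence[DiagnosisRecord], icd10_prefix: str
) -> CohortSpec:
    """Patients with ≥1 diagnosis code matching the prefix (case-insensitive)."""
    prefix = icd10_prefix.strip().upper()
    ids = sorted({r.patient_id for r in diagnoses if r.icd10_code.upper().startswith(prefix)})
    if not ids:
        raise EmptyCohortError(f"no patients match ICD-10 prefix {icd10_prefix!r}")
    return CohortSpec(prefix, tuple(ids))


def clinotype_phenotype_ttest(
    disease: CohortSpec,
    control: CohortSpec,
    matrix: ClinotypeMatrix,
    welch: bool = False,
) -> list[AssociationRecord]:
    """Two-sided two-sample t-test per clinotype (pooled variance by default).

    The effect is the disease-minus-control mean difference in normalized
    units.  Clinotypes with fewer than 2 observed values in either cohort
    are skipped with a warning.  Records are sorted by ascending p-value;
    significance flags are left to :func:`significant_associations`.
    """
    if set(disease.patient_ids) & set(control.patient_ids):
        raise ValueError("disease and control cohorts must be disjoint")
    d_ids = [p for p in disease.patient_ids if p in matrix.patients]
    c_ids = [p for p in control.patient_ids if p in matrix.patients]
    records: list[AssociationRecord] = []
    for clin in matrix.clinotypes:
        dv = matrix.values.loc[d_ids, clin].dropna()
        cv = matrix.values.loc[c_ids, clin].dropna()
        if len(dv) < 2 or len(cv) < 2:
            logger.warning(
                "clinotype %r skipped: <2 observed values in a cohort", clin
            )
            continue
        res = stats.ttest_ind(dv, cv, equal_var=not welch)
        records.append(
            AssociationRecord(
                clinotype=clin,
                partner=disease.disease_code,
                kind="phenotype",
                effect=float(dv.mean() - cv.mean()),
                p_value=float(res.pvalue),
            )
        )
    return sorted(records, key=lambda r: r.p_value)


def significant_associations(
    records: Sequence[AssociationRecord],
    alpha: float = 0.05,
    correction: str = "none",
) -> list[AssociationRecord]:
    """Flag records significant at α (strict ``p < α``).

    ``correction="none"`` applies the raw threshold; ``"bh"`` flags by
    Benjamini–Hochberg step-up instead.
    """
    if not records:
        return []
    pvals = np.array([r.p_value for r in records])
    if correction == "none":
        flags = pvals < alpha
    elif correction == "bh":
        flags = multipletests(pvals, alpha=alpha, method="fdr_bh")[0]
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return [
        AssociationRecord(
            r.clinotype, r.partner, r.kind, r.effect, r.p_value, bool(f), r.stability
        )
        for r, f in zip(records, flags)
    ]


@dataclass
class ValidationReport:
    disease: str
    model_type: str  # "ASS" | "NON"
    AUC: float
    ACC: float
    PPV: float | None
    n_features: int
    n_test: int


ClassifierFactory = Callable[[int], object]


def _default_classifier(seed: int):
    return RandomForestClassifier(n_estimators=100, random_state=seed)


def validate_ass_non(
    train: ClinotypeMatrix,
    test: ClinotypeMatrix,
    disease: CohortSpec,
    control: CohortSpec,
    associations: Sequence[AssociationRecord],
    classifier_factory: ClassifierFactory | None = None,
    seed: int = 0,
) -> tuple[ValidationReport, ValidationReport]:
    """Train ASS (associated features) and NON (complement) classifiers.

    Both are fit on training-split patients of the two cohorts and scored
    on the held-out test split with AUC, ACC and PPV.  The two feature
    sets partition the clinotype set; an empty set on either side is an
    error.  Feature matrices must be complete (imputed beforehand).
    """
    factory = classifier_factory or _default_classifier
    sig = [r.clinotype for r in associations if r.significant]
    feats_ass = [c for c in train.clinotypes if c in set(sig)]
    feats_non = [c for c in train.clinotypes if c not in set(sig)]
    if not feats_ass:
        raise ValueError("ASS feature set is empty (no significant associations)")
    if not feats_non:
        raise ValueError("NON feature set is empty (every clinotype is associated)")
    assert not (set(feats_ass) & set(feats_non))

    cohort = {pid: 1 for pid in disease.patient_ids}
    cohort.update({pid: 0 for pid in control.patient_ids})
    tr_ids = [p for p in train.patients if p in cohort]
    te_ids = [p for p in test.patients if p in cohort]
    if not tr_ids or not te_ids:
        raise EmptyCohortError("cohorts do not overlap both data splits")
    y_tr = np.array([cohort[p] for p in tr_ids])
    y_te = np.array([cohort[p] for p in te_ids])

    reports = []
    for model_type, feats in (("ASS", feats_ass), ("NON", feats_non)):
        X_tr = train.values.loc[tr_ids, feats].to_numpy()
        X_te = test.values.loc[te_ids, feats].to_numpy()
        if np.isnan(X_tr).any() or np.isnan(X_te).any():
            raise ValueError("feature matrices contain missing values; impute first")
        clf = factory(seed)
        clf.fit(X_tr, y_tr)
        score = clf.predict_proba(X_te)[:, 1]
        pred = (score >= 0.5).astype(int)
        tp = int(((pred == 1) & (y_te == 1)).sum())
        fp = int(((pred == 1) & (y_te == 0)).sum())
        reports.append(
            ValidationReport(
                disease=disease.disease_code,
                model_type=model_type,
                AUC=float(roc_auc_score(y_te, score)),
                ACC=float((pred == y_te).mean()),
                PPV=tp / (tp + fp) if (tp + fp) else None,
                n_features=len(feats),
                n_test=len(te_ids),
            )
        )
    return reports[0], reports[1]


def associations_to_frame(records: Sequence[AssociationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "clinotype": [r.clinotype for r in records],
            "partner": [r.partner for r in records],
            "kind": [r.kind for r in records],
            "effect": [r.effect for r in records],
            "p_value": [r.p_value for r in records],
            "significant": [r.significant for r in records],
            "stability": [r.stability for r in records],
        }
    )
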