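"""Resampling-averaged missing-value models and their 3-class evaluation.

For each target clinotype, an ε-insensitive linear SVR is trained on the
training split's observed values, using every other clinotype as a
predictor (predictor gaps are mean-substituted with 0 on the normalized
scale).  Because "normal" dominates lab data, each repetition first
draws a balanced 1:1:1 under-resample across the high/normal/low classes
(m per class, m = smallest class count); coefficients and predictions
are averaged over the repetitions.

Evaluation annotates both the true and the predicted value against the
(normalized) reference range and maps the 9 outcomes to a confusion
count with "abnormal" as the positive class:

    true \\ predicted   high    normal  low
    high               TP      FN      FP
    normal             FP      TN      FP
    low                FP      FN      TP

Note the asymmetry: a high↔low swap is a false positive even though both
labels are abnormal.  ACC = (TP+TN)/total, PPV = TP/(TP+FP),
NPV = TN/(TN+FN); undefined ratios (zero denominator) are reported as
None, never 0.  Under uniform-random truth and prediction all 9 cells
are equiprobable, giving expected ACC = PPV = NPV = 1/3.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import AssociationRecord, ClinotypeMatrix
from .preprocess import annotate
from .svlr import SVLRConfig, fit_svlr

logger = logging.getLogger(__name__)

#: (true, predicted) -> confusion cell, abnormal = positive.
CONFUSION_MAP: dict[tuple[str, str], str] = {
    ("high", "high"): "TP",
    ("high", "normal"): "FN",
    ("high", "low"): "FP",
    ("normal", "high"): "FP",
    ("normal", "normal"): "TN",
    ("normal", "low"): "FP",
    ("low", "high"): "FP",
    ("low", "normal"): "FN",
    ("low", "low"): "TP",
}


class ImbalanceError(ValueError):
    """A required annotation class is absent from the training labels."""


def balanced_resample(labels: Sequence[str], seed: int) -> np.ndarray:
    """Indices of a balanced 1:1:1 under-resample across the three classes.

    Draws ``m = min class count`` indices per class without replacement;
    deterministic for a fixed seed.  Raises :class:`ImbalanceError`
    naming the missing class when any class is absent.
    """
    labels = np.asarray(labels, dtype=object)
    classes = ("high", "normal", "low")
    index_by_class = {c: np.flatnonzero(labels == c) for c in classes}
    for c, idx in index_by_class.items():
        if idx.size == 0:
            raise ImbalanceError(f"class {c!r} absent from training labels")
    return _resample(index_by_class, seed)


def _resample(index_by_class: dict[str, np.ndarray], seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    m = min(idx.size for idx in index_by_class.values())
    parts = [
        rng.choice(idx, size=m, replace=False) for _, idx in sorted(index_by_class.items())
    ]
    return np.sort(np.concatenate(parts))


@dataclass
class ImputationModel:
    """Averaged linear model predicting one clinotype from all others."""

    target: str
    predictors: list[str]
    w: pd.Series  # averaged coefficients, indexed by predictor name
    b: float
    archive: list[tuple[np.ndarray, float]]  # per-repetition (w, b)
    config: SVLRConfig
    downgraded: bool = False  # balanced over <3 classes
    diagnostics: dict = field(default_factory=dict)

    def predict(self, X: pd.DataFrame) -> pd.Series:
        """ŷ = wᵀx + b with missing predictors mean-substituted (0)."""
        Xf = X[self.predictors].fillna(0.0)
        return Xf @ self.w + self.b

    def to_dict(self) -> dict:
        return {
            "target": self.target,
            "b": self.b,
            "w": {k: float(v) for k, v in self.w.items()},
            "config": {
                "C": self.config.C,
                "epsilon": self.config.epsilon,
                "n_repetitions": self.config.n_repetitions,
                "seed": self.config.seed,
            },
            "downgraded": self.downgraded,
            "n_archived": len(self.archive),
        }


def fit_imputation_model(
    train: ClinotypeMatrix,
    target: str,
    config: SVLRConfig = SVLRConfig(),
    allow_downgrade: bool = True,
) -> ImputationModel:
    """Fit the resampling-averaged SVLR for one target clinotype.

    Repetition ``r`` uses seed ``config.seed + r``; the archive holds all
    per-repetition (w, b) pairs and the reported model is their
    arithmetic mean.  If a class is missing from the training labels and
    ``allow_downgrade`` is set, resampling balances over the available
    classes with a logged downgrade instead of refusing.
    """
    if target not in train.clinotypes:
        raise KeyError(f"unknown target clinotype {target!r}")
    labels = annotate(train)[target]
    observed = train.values[target].notna()
    rows = train.patients[observed]
    if len(rows) < 2:
        raise ValueError(f"target {target!r} has fewer than 2 observed training values")

    y = train.values.loc[rows, target].to_numpy()
    predictors = [c for c in train.clinotypes if c != target]
    X = train.values.loc[rows, predictors].fillna(0.0).to_numpy()
    row_labels = labels.loc[rows].to_numpy(dtype=object)

    index_by_class = {
        c: np.flatnonzero(row_labels == c) for c in ("high", "normal", "low")
    }
    missing_classes = [c for c, idx in index_by_class.items() if idx.size == 0]
    downgraded = False
    if missing_classes:
        if not allow_downgrade or len(missing_classes) > 2:
            raise ImbalanceError(
                f"class {missing_classes[0]!r} absent from training labels for {target!r}"
            )
        downgraded = True
        logger.warning(
            "target %r lacks class(es) %s; balancing over remaining classes",
            target,
            missing_classes,
        )
        index_by_class = {c: idx for c, idx in index_by_class.items() if idx.size > 0}

    archive: list[tuple[np.ndarray, float]] = []
    for r in range(config.n_repetitions):
        sel = _resample(index_by_class, config.seed + r)
        sol = fit_svlr(X[sel], y[sel], C=config.C, epsilon=config.epsilon, tol=config.tol)
        archive.append((sol.w, sol.b))

    w_mean = np.mean([w for w, _ in archive], axis=0)
    b_mean = float(np.mean([b for _, b in archive]))
    return ImputationModel(
        target=target,
        predictors=predictors,
        w=pd.Series(w_mean, index=predictors),
        b=b_mean,
        archive=archive,
        config=config,
        downgraded=downgraded,
        diagnostics={"n_train": len(rows), "resample_size": len(sel)},
    )


def fit_all_models(
    train: ClinotypeMatrix,
    targets: Sequence[str] | None = None,
    config: SVLRConfig = SVLRConfig(),
) -> dict[str, ImputationModel]:
    """Fit imputation models for the requested targets (default: all)."""
    targets = list(train.clinotypes) if targets is None else list(targets)
    return {t: fit_imputation_model(train, t, config) for t in targets}


def impute_missing(
    matrix: ClinotypeMatrix, models: Mapping[str, ImputationModel]
) -> ClinotypeMatrix:
    """Fill every missing cell with its model's averaged prediction.

    Observed cells are untouched; filled cells are flagged in
    ``result.imputed``.  A cell whose predictors are all missing is
    filled with 0 (the normalized mean) and flagged degenerate in
    ``result.meta["degenerate_cells"]``.
    """
    missing_cols = [c for c in matrix.clinotypes if matrix.values[c].isna().any()]
    absent = [c for c in missing_cols if c not in models]
    if absent:
        raise KeyError(f"no imputation model for clinotypes with missing cells: {absent}")

    out_values = matrix.values.copy()
    imputed = matrix.imputed.copy()
    degenerate: list[tuple[str, str]] = []
    for target in missing_cols:
        model = models[target]
        rows = matrix.patients[matrix.values[target].isna()]
        X = matrix.values.loc[rows, model.predictors]
        all_missing = X.isna().all(axis=1)
        preds = model.predict(X)
        preds[all_missing] = 0.0
        degenerate.extend((pid, target) for pid in rows[all_missing])
        out_values.loc[rows, target] = preds
        imputed.loc[rows, target] = True
    return ClinotypeMatrix(
        out_values,
        matrix.ref_low,
        matrix.ref_high,
        matrix.first_date,
        imputed,
        dict(matrix.meta, degenerate_cells=degenerate),
    )


@dataclass
class ConfusionSummary:
    """3-class confusion counts and the derived ACC/PPV/NPV metrics."""

    TP: int = 0
    TN: int = 0
    FP: int = 0
    FN: int = 0

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    @property
    def ACC(self) -> float | None:
        return (self.TP + self.TN) / self.total if self.total else None

    @property
    def PPV(self) -> float | None:
        denom = self.TP + self.FP
        return self.TP / denom if denom else None

    @property
    def NPV(self) -> float | None:
        denom = self.TN + self.FN
        return self.TN / denom if denom else None

    @classmethod
    def from_labels(cls, true_labels, predicted_labels) -> "ConfusionSummary":
        """Count confusion cells over paired label sequences.

        Pairs with a missing label on either side are ignored.
        """
        summary = cls()
        for t, p in zip(np.asarray(true_labels, dtype=object), np.asarray(predicted_labels, dtype=object)):
            if t is None or p is None or (isinstance(t, float)) or (isinstance(p, float)):
                continue
            cell = CONFUSION_MAP[(t, p)]
            setattr(summary, cell, getattr(summary, cell) + 1)
        return summary


@dataclass
class WeightedSummary:
    """Across-clinotype weighted averages, weights = evaluated-cell counts."""

    ACC: float | None
    PPV: float | None
    NPV: float | None
    n_cells: int


def _weighted(metrics: list[tuple[float | None, int]]) -> float | None:
    pairs = [(m, n) for m, n in metrics if m is not None and n > 0]
    if not pairs:
        return None
    total = sum(n for _, n in pairs)
    return sum(m * n for m, n in pairs) / total


def evaluate_imputation(
    test: ClinotypeMatrix, models: Mapping[str, ImputationModel]
) -> tuple[dict[str, ConfusionSummary], WeightedSummary]:
    """Score each model on the observed test cells of its target.

    Every observed test cell is predicted from the patient's other
    clinotypes, both the prediction and the truth are annotated via the
    cell's (normalized) reference range, and the pair is mapped to
    TP/TN/FP/FN.  Returns per-clinotype summaries plus the weighted
    average; clinotypes with no evaluable cells are omitted from the
    weighted average with a warning.
    """
    true_labels = annotate(test)
    per_clinotype: dict[str, ConfusionSummary] = {}
    for target, model in models.items():
        observed = test.values[target].notna()
        rows = test.patients[observed]
        if len(rows) == 0:
            logger.warning("clinotype %r has no evaluable test cells; omitted", target)
            continue
        preds = model.predict(test.values.loc[rows, model.predictors])
        pred_labels = [
            _label(p, test.ref_low.loc[pid, target], test.ref_high.loc[pid, target])
            for pid, p in preds.items()
        ]
        summary = ConfusionSummary.from_labels(
            true_labels.loc[rows, target].tolist(), pred_labels
        )
        per_clinotype[target] = summary

    weighted = WeightedSummary(
        ACC=_weighted([(s.ACC, s.total) for s in per_clinotype.values()]),
        PPV=_weighted([(s.PPV, s.total) for s in per_clinotype.values()]),
        NPV=_weighted([(s.NPV, s.total) for s in per_clinotype.values()]),
        n_cells=sum(s.total for s in per_clinotype.values()),
    )
    return per_clinotype, weighted


def _label(value: float, low: float, high: float) -> str:
    if value < low:
        return "low"
    if value > high:
        return "high"
    return "normal"


def extract_clinotype_associations(
    models: Mapping[str, ImputationModel],
    stability_threshold: float = 0.95,
    effect_floor: float = 0.1,
) -> list[AssociationRecord]:
    """Mine clinotype–clinotype associations from the model archives.

    For each (target, predictor) pair the effect is the averaged
    coefficient; the pair is flagged significant when the coefficient
    keeps one sign in at least ``stability_threshold`` of the
    repetitions *and* |averaged coefficient| exceeds ``effect_floor``
    (normalized units).  Symmetric duplicates are merged keeping the
    larger |effect|.
    """
    best: dict[frozenset, AssociationRecord] = {}
    for target, model in models.items():
        W = np.array([w for w, _ in model.archive])  # (reps, d)
        mean_w = W.mean(axis=0)
        pos = (W > 0).mean(axis=0)
        neg = (W < 0).mean(axis=0)
        stability = np.maximum(pos, neg)
        for k, predictor in enumerate(model.predictors):
            significant = bool(
                stability[k] >= stability_threshold and abs(mean_w[k]) > effect_floor
            )
            rec = AssociationRecord(
                clinotype=target,
                partner=predictor,
                kind="clinotype",
                effect=float(mean_w[k]),
                significant=significant,
                stability=float(stability[k]),
            )
            key = frozenset((target, predictor))
            prev = best.get(key)
            if prev is None or abs(rec.effect) > abs(prev.effect):
                best[key] = rec
    return sorted(best.values(), key=lambda r: -abs(r.effect))
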