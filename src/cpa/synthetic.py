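"""Synthetic EHR cohort generator with known ground truth.

Emulates the structure of a health-checkup lab-test dataset: a patient ×
clinotype matrix with sex-specific reference ranges, latent linear
dependencies among clinotypes, configurable missingness (MCAR or
MAR-by-clinotype), disease labels that shift selected clinotypes, and
planted cluster structure.  Every stochastic choice flows from a single
integer seed, so the full output tuple is reproducible bit-for-bit.

Clinotype values are built on a standardized latent scale ``z`` and then
mapped to a raw scale ``value = mu + sigma * z`` with per-clinotype,
per-sex location/scale and reference ranges.  Disease and cluster
effects are additive mean shifts on the ``z`` scale, i.e. expressed in
standard-deviation units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import ClinotypeMatrix, DiagnosisRecord, make_patients_frame

#: Demographic mix over the six adult strata, as cohort proportions:
#: (young M, young F, middle M, middle F, old M, old F).
DEFAULT_DEMOGRAPHIC_MIX = {
    ("young", "male"): 0.2133,
    ("young", "female"): 0.1841,
    ("middle", "male"): 0.2736,
    ("middle", "female"): 0.2066,
    ("old", "male"): 0.0761,
    ("old", "female"): 0.0463,
}

_AGE_BANDS = {"young": (18, 39), "middle": (40, 59), "old": (60, 85)}

#: Per-clinotype raw-scale parameters: sex -> (mu, sigma, ref_low, ref_high).
#: Named panel entries use plausible adult values; reference ranges sit at
#: mu ± 1.5 sigma.  Hematocrit carries the sex-specific 35–45 (F) /
#: 40–50 (M) ranges.
DEFAULT_PANEL: dict[str, dict[str, tuple[float, float, float, float]]] = {
    "Hematocrit": {
        "female": (40.0, 10 / 3, 35.0, 45.0),
        "male": (45.0, 10 / 3, 40.0, 50.0),
    },
    "Hemoglobin": {"female": (13.5, 1.0, 12.0, 15.0), "male": (15.0, 1.0, 13.5, 16.5)},
    "Glucose": {"female": (5.2, 0.6, 4.3, 6.1), "male": (5.2, 0.6, 4.3, 6.1)},
    "Blood Platelet": {"female": (250.0, 50.0, 175.0, 325.0), "male": (250.0, 50.0, 175.0, 325.0)},
    "White Blood Cell": {"female": (6.5, 1.2, 4.7, 8.3), "male": (6.5, 1.2, 4.7, 8.3)},
    "ALT": {"female": (22.0, 8.0, 10.0, 34.0), "male": (28.0, 8.0, 16.0, 40.0)},
    "AST": {"female": (24.0, 7.0, 13.5, 34.5), "male": (26.0, 7.0, 15.5, 36.5)},
    "Cholesterol": {"female": (4.9, 0.8, 3.7, 6.1), "male": (4.9, 0.8, 3.7, 6.1)},
    "Triglycerides": {"female": (1.3, 0.5, 0.55, 2.05), "male": (1.5, 0.5, 0.75, 2.25)},
    "Creatinine": {"female": (65.0, 12.0, 47.0, 83.0), "male": (80.0, 12.0, 62.0, 98.0)},
    "Urea": {"female": (5.0, 1.2, 3.2, 6.8), "male": (5.4, 1.2, 3.6, 7.2)},
    "Albumin": {"female": (44.0, 3.0, 39.5, 48.5), "male": (44.0, 3.0, 39.5, 48.5)},
}

#: Raw-scale parameters for clinotypes not in the named panel.
GENERIC_PANEL_ENTRY = {"female": (100.0, 10.0, 85.0, 115.0), "male": (100.0, 10.0, 85.0, 115.0)}

DEFAULT_CLINOTYPES = tuple(DEFAULT_PANEL)


@dataclass(frozen=True)
class LatentModel:
    """Linear-Gaussian structural model over clinotypes on the z scale.

    ``coefficients[target][predictor]`` gives the linear weight of an
    earlier clinotype (in panel order) on a later one, so generation is a
    single forward pass and, with ``noise_sd == 0`` and no effects, every
    clinotype equals its linear prediction exactly.  ``quadratic`` adds an
    optional ``coef * predictor**2`` term to exercise nonlinear failure
    modes of a linear imputer.
    """

    coefficients: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    intercepts: Mapping[str, float] = field(default_factory=dict)
    noise_sd: Mapping[str, float] | float = 1.0
    quadratic: Mapping[str, Mapping[str, float]] = field(default_factory=dict)

    def sd_of(self, clinotype: str) -> float:
        if isinstance(self.noise_sd, Mapping):
            return float(self.noise_sd.get(clinotype, 1.0))
        return float(self.noise_sd)


@dataclass(frozen=True)
class DiseaseSpec:
    """A disease with an ICD-10 code, prevalence, and additive clinotype shifts
    (in sd units of the affected clinotypes)."""

    code: str
    prevalence: float
    effects: Mapping[str, float]

    def __post_init__(self) -> None:
        if not 0 < self.prevalence < 1:
            raise ValueError(f"prevalence must be in (0,1), got {self.prevalence}")


@dataclass(frozen=True)
class ClusterSpec:
    """A mixture component: sampling weight and per-clinotype mean shift (sd units)."""

    weight: float
    shifts: Mapping[str, float]


@dataclass(frozen=True)
class GeneratorConfig:
    n_patients: int = 2000
    clinotypes: Sequence[str] = DEFAULT_CLINOTYPES
    demographic_mix: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_DEMOGRAPHIC_MIX)
    )
    latent: LatentModel = field(default_factory=LatentModel)
    missing_rate: float = 0.0
    missing_mechanism: str = "mcar"  # "mcar" | "mar"
    mar_driver: str | None = None
    mar_target: str | None = None
    mar_tercile_weights: tuple[float, float, float] = (0.5, 1.0, 1.5)
    diseases: Sequence[DiseaseSpec] = ()
    clusters: Sequence[ClusterSpec] = ()
    study_start: str = "2010-07-01"
    study_end: str = "2014-06-30"
    seed: int = 0
    panel: Mapping[str, Mapping[str, tuple[float, float, float, float]]] | None = None

    def __post_init__(self) -> None:
        total = sum(self.demographic_mix.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"demographic proportions must sum to 1, got {total}")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.missing_mechanism not in ("mcar", "mar"):
            raise ValueError(f"unknown missing mechanism {self.missing_mechanism!r}")
        if self.clusters and abs(sum(c.weight for c in self.clusters) - 1.0) > 1e-6:
            raise ValueError("cluster weights must sum to 1")
        for d in self.diseases:
            for eff in d.effects.values():
                if not np.isfinite(eff):
                    raise ValueError(f"non-finite effect size for disease {d.code}")


@dataclass
class GroundTruth:
    """Everything the generator knows that downstream stages must recover."""

    latent: LatentModel
    disease_effects: dict[str, dict[str, float]]
    cluster_labels: pd.Series | None
    masked_values: pd.DataFrame  # NaN except at cells removed by missingness
    z_values: pd.DataFrame  # standardized values before raw-scale mapping


def _panel_entry(panel, clinotype: str) -> dict:
    return panel.get(clinotype, GENERIC_PANEL_ENTRY)


def assign_reference_ranges(
    patients: pd.DataFrame,
    clinotypes: Sequence[str],
    config: GeneratorConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell (low, high) reference ranges from the per-sex panel table."""
    panel = (config.panel if config and config.panel else DEFAULT_PANEL)
    low = pd.DataFrame(index=patients.index, columns=list(clinotypes), dtype=float)
    high = pd.DataFrame(index=patients.index, columns=list(clinotypes), dtype=float)
    for clin in clinotypes:
        entry = _panel_entry(panel, clin)
        for sex in ("female", "male"):
            _, _, lo, hi = entry[sex]
            sel = patients["sex"] == sex
            low.loc[sel, clin] = lo
            high.loc[sel, clin] = hi
    return low, high


def inject_missingness(
    matrix: ClinotypeMatrix,
    rate: float,
    mechanism: str = "mcar",
    seed: int = 0,
    driver: str | None = None,
    target: str | None = None,
    tercile_weights: tuple[float, float, float] = (0.5, 1.0, 1.5),
    columns: Sequence[str] | None = None,
) -> tuple[ClinotypeMatrix, pd.DataFrame]:
    """Remove exactly ``round(rate × eligible cells)`` values.

    MCAR removes uniformly.  MAR-by-clinotype upweights cells of
    ``target`` according to the tercile of the same patient's ``driver``
    value, with the configured tercile weights (low/mid/high tercile).
    ``columns`` optionally restricts eligibility to a clinotype subset
    (useful for recovery experiments that must keep predictors intact).
    Returns the masked matrix and a same-shape DataFrame holding the
    removed true values (NaN elsewhere).
    """
    if not 0 <= rate < 1:
        raise ValueError("missing rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    values = matrix.values.copy()
    observed = values.notna()
    if columns is not None:
        eligible = pd.DataFrame(False, index=values.index, columns=values.columns)
        eligible[list(columns)] = True
        observed = observed & eligible
    observed = observed.to_numpy()
    flat_obs = np.flatnonzero(observed.ravel())
    n_remove = int(round(rate * flat_obs.size))
    removed = pd.DataFrame(np.nan, index=values.index, columns=values.columns)
    if n_remove == 0:
        return matrix.copy(), removed

    if mechanism == "mcar":
        weights = np.ones(flat_obs.size)
    elif mechanism == "mar":
        if driver is None or target is None:
            raise ValueError("MAR mechanism needs driver and target clinotypes")
        w = pd.DataFrame(1.0, index=values.index, columns=values.columns)
        drv = values[driver]
        terciles = drv.rank(pct=True, method="average")
        lo, mid, hi = tercile_weights
        tw = np.where(terciles <= 1 / 3, lo, np.where(terciles <= 2 / 3, mid, hi))
        w[target] = tw
        w = w.where(pd.notna(drv), 1.0, axis=0)
        weights = w.to_numpy().ravel()[flat_obs]
    else:
        raise ValueError(f"unknown missing mechanism {mechanism!r}")

    p = weights / weights.sum()
    chosen = rng.choice(flat_obs, size=n_remove, replace=False, p=p)
    arr = values.to_numpy()
    rows, cols = np.unravel_index(chosen, arr.shape)
    removed_arr = removed.to_numpy()
    removed_arr[rows, cols] = arr[rows, cols]
    arr[rows, cols] = np.nan
    out = ClinotypeMatrix(
        pd.DataFrame(arr, index=values.index, columns=values.columns),
        matrix.ref_low,
        matrix.ref_high,
        matrix.first_date,
        meta=dict(matrix.meta),
    )
    return out, pd.DataFrame(removed_arr, index=values.index, columns=values.columns)


def _sample_demographics(config: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    strata = list(config.demographic_mix)
    probs = np.array([config.demographic_mix[s] for s in strata], dtype=float)
    probs = probs / probs.sum()
    draws = rng.choice(len(strata), size=config.n_patients, p=probs)
    ids = [f"P{i:06d}" for i in range(config.n_patients)]
    sexes, groups, ages = [], [], []
    for d in draws:
        group, sex = strata[d]
        lo, hi = _AGE_BANDS[group]
        sexes.append(sex)
        groups.append(group)
        ages.append(int(rng.integers(lo, hi + 1)))
    start = pd.Timestamp(config.study_start)
    end = pd.Timestamp(config.study_end)
    span_days = (end - start).days
    offsets = rng.integers(0, span_days + 1, size=config.n_patients)
    visit = start + pd.to_timedelta(offsets, unit="D")
    birth_year = visit.year - np.array(ages)
    patients = make_patients_frame(ids, sexes, birth_year, groups)
    patients["visit_date"] = visit
    return patients


def generate_cohort(
    config: GeneratorConfig,
) -> tuple[ClinotypeMatrix, pd.DataFrame, list[DiagnosisRecord], GroundTruth]:
    """Generate (matrix, patients, diagnoses, ground truth) for one cohort.

    Order of construction: demographics → latent z values (forward pass
    through the structural model) → cluster shifts → disease shifts →
    raw-scale mapping with per-sex ranges → missingness last.
    """
    rng = np.random.default_rng(config.seed)
    patients = _sample_demographics(config, rng)
    clins = list(config.clinotypes)
    n = config.n_patients
    latent = config.latent

    z = pd.DataFrame(0.0, index=patients.index, columns=clins)
    for clin in clins:
        base = np.full(n, float(latent.intercepts.get(clin, 0.0)))
        for pred, coef in latent.coefficients.get(clin, {}).items():
            if clins.index(pred) >= clins.index(clin):
                raise ValueError(
                    f"latent model must be a forward DAG: {pred!r} does not precede {clin!r}"
                )
            base += coef * z[pred].to_numpy()
        for pred, coef in latent.quadratic.get(clin, {}).items():
            base += coef * z[pred].to_numpy() ** 2
        sd = latent.sd_of(clin)
        noise = rng.standard_normal(n) * sd if sd > 0 else 0.0
        z[clin] = base + noise

    cluster_labels = None
    if config.clusters:
        weights = np.array([c.weight for c in config.clusters], dtype=float)
        labels = rng.choice(len(config.clusters), size=n, p=weights / weights.sum())
        cluster_labels = pd.Series(labels + 1, index=patients.index, name="cluster")
        for idx, spec in enumerate(config.clusters):
            sel = labels == idx
            for clin, shift in spec.shifts.items():
                z.loc[sel, clin] += shift

    diagnoses: list[DiagnosisRecord] = []
    disease_effects: dict[str, dict[str, float]] = {}
    for disease in config.diseases:
        affected = rng.random(n) < disease.prevalence
        disease_effects[disease.code] = dict(disease.effects)
        for clin, shift in disease.effects.items():
            z.loc[affected, clin] += shift
        for pid, visit in zip(patients.index[affected], patients.loc[affected, "visit_date"]):
            diagnoses.append(DiagnosisRecord(pid, disease.code, visit))

    panel = config.panel or DEFAULT_PANEL
    values = pd.DataFrame(index=patients.index, columns=clins, dtype=float)
    for clin in clins:
        entry = _panel_entry(panel, clin)
        for sex in ("female", "male"):
            mu, sigma, _, _ = entry[sex]
            sel = (patients["sex"] == sex).to_numpy()
            values.loc[sel, clin] = mu + sigma * z.loc[sel, clin]
    ref_low, ref_high = assign_reference_ranges(patients, clins, config)

    matrix = ClinotypeMatrix(
        values,
        ref_low,
        ref_high,
        first_date=patients["visit_date"],
        meta={"generator_seed": config.seed},
    )

    if config.missing_rate > 0:
        matrix, removed = inject_missingness(
            matrix,
            config.missing_rate,
            config.missing_mechanism,
            seed=config.seed + 1,
            driver=config.mar_driver,
            target=config.mar_target,
            tercile_weights=config.mar_tercile_weights,
        )
    else:
        removed = pd.DataFrame(np.nan, index=values.index, columns=values.columns)

    truth = GroundTruth(
        latent=latent,
        disease_effects=disease_effects,
        cluster_labels=cluster_labels,
        masked_values=removed,
        z_values=z,
    )
    return matrix, patients, diagnoses, truth
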