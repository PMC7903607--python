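"""End-to-end orchestration: P0 → P1 → Pr/Pt → P2 → impute → analyses.

A single :class:`PipelineConfig` (loadable from YAML) drives the run;
every stage's output is persisted as delimited text/JSON under the
output directory and summarized in a :class:`RunManifest`.  One base
seed fans out to the stages via fixed offsets, so reruns with the same
config and inputs are bit-identical (modulo timestamps).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .associate import (
    associations_to_frame,
    clinotype_phenotype_ttest,
    select_control,
    select_disease_cohort,
    significant_associations,
    validate_ass_non,
)
from .datamodel import ClinotypeMatrix
from .genelink import NameNormalizationConfig, map_to_genesets
from .impute import (
    SVLRConfig,
    evaluate_imputation,
    extract_clinotype_associations,
    fit_all_models,
    impute_missing,
)
from .io import (
    read_diagnoses,
    read_gmt,
    read_lab_table,
    read_patients,
    write_diagnoses,
    write_gmt,
    write_lab_table,
    write_patients,
)
from .preprocess import (
    FilterConfig,
    apply_normalization,
    filter_dataset,
    fit_normalization,
    temporal_split,
)
from .stratify import anova_annotate, enrichment_table, pairwise_distances, select_k
from .synthetic import DiseaseSpec, GeneratorConfig, LatentModel, generate_cohort

logger = logging.getLogger(__name__)

_SEED_OFFSETS = {"simulate": 0, "impute": 101, "associate": 202, "stratify": 303}


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    lab_table: str = "lab_table.csv"
    patients_table: str = "patients.csv"
    diagnoses_table: str = "diagnoses.csv"
    gmt_file: str | None = None
    output_dir: str = "output"
    cutoff_date: str = "2013-06-30"
    filter: FilterConfig = field(default_factory=FilterConfig)
    svlr: SVLRConfig = field(default_factory=SVLRConfig)
    alpha: float = 0.05
    correction: str = "none"
    diseases: list[str] = field(default_factory=list)  # ICD-10 prefixes to screen
    cluster_method: str = "dapwc"
    k_range: tuple[int, int] = (2, 6)
    stages: tuple[str, ...] = ("preprocess", "impute", "associate", "stratify", "genelink")
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "filter" in raw:
            raw["filter"] = FilterConfig(**raw["filter"])
        if "svlr" in raw:
            raw["svlr"] = SVLRConfig(**raw["svlr"])
        if "k_range" in raw:
            raw["k_range"] = tuple(raw["k_range"])
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["filter"] = dataclasses.asdict(self.filter)
        data["svlr"] = dataclasses.asdict(self.svlr)
        data["k_range"] = list(self.k_range)
        data["stages"] = list(self.stages)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass
class RunManifest:
    config: dict
    version: str
    stages: dict = field(default_factory=dict)

    def record(self, stage: str, **info) -> None:
        self.stages[stage] = {"status": "completed", **info}

    def save(self, path: str | Path) -> None:
        payload = {
            "version": self.version,
            "config": self.config,
            "stages": self.stages,
            "timestamp": pd.Timestamp.now().isoformat(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=str)


def run_pipeline(config: PipelineConfig, workdir: str | Path = ".") -> RunManifest:
    """Execute the configured stages in pipeline order.

    Any stage error halts the run; the partial manifest (with the failed
    stage named) is saved before the error is re-raised as
    :class:`StageError`.
    """
    workdir = Path(workdir)
    outdir = workdir / config.output_dir
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config={**dataclasses.asdict(config)}, version=__version__
    )
    stage = "load"
    try:
        p0 = read_lab_table(workdir / config.lab_table)
        patients = read_patients(workdir / config.patients_table)
        diagnoses_path = workdir / config.diagnoses_table
        needs_dx = "associate" in config.stages or "stratify" in config.stages
        if needs_dx and not diagnoses_path.exists():
            raise FileNotFoundError(
                f"diagnosis table {diagnoses_path} required by the associate/stratify stages"
            )
        diagnoses = read_diagnoses(diagnoses_path) if diagnoses_path.exists() else []
        manifest.record(
            stage,
            patients=p0.n_patients,
            clinotypes=p0.n_clinotypes,
            diagnoses=len(diagnoses),
        )

        stage = "preprocess"
        p1, patients1, report = filter_dataset(p0, patients, config.filter)
        split = temporal_split(p1, config.cutoff_date)
        params = fit_normalization(split.train)
        keep = [c for c in p1.clinotypes if c not in params.excluded]
        pr = apply_normalization(split.train.subset_clinotypes(keep), params)
        pt = apply_normalization(split.test.subset_clinotypes(keep), params)
        norm = {
            "mean": {k: float(v) for k, v in params.mean.items()},
            "std": {k: float(v) for k, v in params.std.items()},
            "excluded": params.excluded,
        }
        (outdir / "normalization.json").write_text(json.dumps(norm, indent=2))
        manifest.record(
            stage,
            threshold=report.threshold,
            clinotypes_retained=report.clinotypes_retained,
            train_patients=pr.n_patients,
            test_patients=pt.n_patients,
            split_ratio=round(split.ratio, 3),
        )

        pr_complete, pt_complete = pr, pt
        models = {}
        if "impute" in config.stages:
            stage = "impute"
            svlr = dataclasses.replace(config.svlr, seed=config.seed + _SEED_OFFSETS["impute"])
            models = fit_all_models(pr, config=svlr)
            pr_complete = impute_missing(pr, models)
            pt_complete = impute_missing(pt, models)
            per_clin, weighted = evaluate_imputation(pt, models)
            rows = [
                {
                    "clinotype": t,
                    "TP": s.TP,
                    "TN": s.TN,
                    "FP": s.FP,
                    "FN": s.FN,
                    "ACC": s.ACC,
                    "PPV": s.PPV,
                    "NPV": s.NPV,
                }
                for t, s in per_clin.items()
            ]
            pd.DataFrame(rows).to_csv(outdir / "imputation_metrics.csv", index=False)
            (outdir / "imputation_models.json").write_text(
                json.dumps({t: m.to_dict() for t, m in models.items()}, indent=2)
            )
            write_lab_table(pr_complete, outdir / "pr_imputed.csv")
            write_lab_table(pt_complete, outdir / "pt_imputed.csv")
            cc = extract_clinotype_associations(models)
            associations_to_frame(cc).to_csv(outdir / "clinotype_associations.csv", index=False)
            manifest.record(
                stage,
                models=len(models),
                weighted_ACC=weighted.ACC,
                weighted_PPV=weighted.PPV,
                weighted_NPV=weighted.NPV,
                clinotype_associations=sum(r.significant for r in cc),
            )

        if "associate" in config.stages:
            stage = "associate"
            # controls come from the whole normalized cohort so that both
            # splits contribute to classifier validation
            p2_all = ClinotypeMatrix(
                pd.concat([pr.values, pt.values]),
                pd.concat([pr.ref_low, pt.ref_low]),
                pd.concat([pr.ref_high, pt.ref_high]),
            )
            control = select_control(p2_all, diagnoses)
            all_records = []
            n_validated = 0
            for code in config.diseases:
                cohort = select_disease_cohort(diagnoses, code)
                disease_ids = set(cohort.patient_ids)
                control_ids = tuple(
                    p for p in control.patient_ids if p not in disease_ids
                )
                ctl = dataclasses.replace(control, patient_ids=control_ids)
                records = clinotype_phenotype_ttest(cohort, ctl, pr)
                records = significant_associations(records, config.alpha, config.correction)
                all_records.extend(records)
                if models and any(r.significant for r in records) and not all(
                    r.significant for r in records
                ):
                    ass, non = validate_ass_non(
                        pr_complete,
                        pt_complete,
                        cohort,
                        ctl,
                        records,
                        seed=config.seed + _SEED_OFFSETS["associate"],
                    )
                    n_validated += 1
                    manifest.stages.setdefault("validation", {})[code] = {
                        "ASS_AUC": ass.AUC,
                        "NON_AUC": non.AUC,
                        "ASS_PPV": ass.PPV,
                        "NON_PPV": non.PPV,
                    }
            associations_to_frame(all_records).to_csv(
                outdir / "phenotype_associations.csv", index=False
            )
            manifest.record(
                stage,
                control_size=len(control.patient_ids),
                associations=sum(r.significant for r in all_records),
                diseases_validated=n_validated,
            )

        if "stratify" in config.stages:
            stage = "stratify"
            D = pairwise_distances(pt_complete if pt_complete.n_missing == 0 else pr_complete)
            best, table = select_k(
                D,
                range(config.k_range[0], config.k_range[1] + 1),
                method=config.cluster_method,
                seed=config.seed + _SEED_OFFSETS["stratify"],
            )
            best.labels.to_csv(outdir / "clusters.csv")
            table.to_csv(outdir / "silhouette_by_k.csv", index=False)
            anova = anova_annotate(
                pt_complete if pt_complete.n_missing == 0 else pr_complete, best, config.alpha
            )
            anova.to_csv(outdir / "cluster_anova.csv")
            if config.diseases and diagnoses:
                enr = enrichment_table(best, diagnoses, config.diseases, config.alpha)
                enr.to_csv(outdir / "cluster_enrichment.csv", index=False)
            manifest.record(
                stage,
                k=best.k,
                silhouette=best.silhouette_score,
                significant_clinotypes=int(anova["significant"].sum()),
            )

        if "genelink" in config.stages and config.gmt_file:
            stage = "genelink"
            genesets = read_gmt(workdir / config.gmt_file)
            result = map_to_genesets(list(p1.clinotypes), genesets, NameNormalizationConfig())
            result.to_frame().to_csv(outdir / "gene_links.csv", index=False)
            (outdir / "unmatched_terms.txt").write_text("\n".join(result.unmatched))
            manifest.record(
                stage,
                links=len(result.links),
                unique_pairs=len(result.unique_pairs()),
                unmatched=len(result.unmatched),
            )
    except Exception as exc:  # noqa: BLE001 - halt with stage context
        manifest.stages[stage] = {"status": "failed", "error": str(exc)}
        manifest.save(outdir / "manifest.json")
        raise StageError(stage, exc) from exc

    manifest.save(outdir / "manifest.json")
    return manifest


DEMO_GMT = [
    ("BASOPHIL_ACTIVATION", "demo", ("CCR3", "IL3RA", "ENPP3")),
    ("GLUCOSE_METABOLISM", "demo", ("GCK", "G6PC", "INS", "SLC2A2")),
    ("TRIGLYCERIDE_LIPASE_ACTIVITY", "demo", ("LPL", "LIPC", "PNPLA2")),
    ("HEMOGLOBIN_COMPLEX", "demo", ("HBA1", "HBA2", "HBB")),
    ("CHOLESTEROL_HOMEOSTASIS", "demo", ("LDLR", "HMGCR", "APOB", "PCSK9")),
]


def make_demo(
    target_dir: str | Path, seed: int = 7, n_patients: int = 500, force: bool = False
) -> PipelineConfig:
    """Write a self-contained synthetic workspace exercising every stage.

    Refuses to overwrite a non-empty directory unless ``force`` is set.
    """
    target = Path(target_dir)
    target.mkdir(parents=True, exist_ok=True)
    if any(target.iterdir()) and not force:
        raise FileExistsError(f"{target} is not empty; use force=True to overwrite")

    latent = LatentModel(
        coefficients={
            "Hemoglobin": {"Hematocrit": 0.8},
            "AST": {"ALT": 0.6},
            "Triglycerides": {"Cholesterol": 0.5},
        },
        noise_sd={"Hemoglobin": 0.6, "AST": 0.8, "Triglycerides": 0.85},
    )
    gen = GeneratorConfig(
        n_patients=n_patients,
        latent=latent,
        missing_rate=0.1,
        diseases=[
            DiseaseSpec("E11", 0.12, {"Glucose": 1.5, "Triglycerides": 0.8}),
            DiseaseSpec("I25", 0.08, {"Cholesterol": 1.0}),
        ],
        seed=seed,
    )
    matrix, patients, diagnoses, _ = generate_cohort(gen)
    write_lab_table(matrix, target / "lab_table.csv")
    write_patients(patients, target / "patients.csv")
    write_diagnoses(diagnoses, target / "diagnoses.csv")
    from .datamodel import Geneset

    write_gmt([Geneset(*g) for g in DEMO_GMT], target / "genesets.gmt")

    config = PipelineConfig(
        gmt_file="genesets.gmt",
        filter=FilterConfig(min_patients_per_clinotype=10, min_fraction=0.01),
        svlr=SVLRConfig(n_repetitions=10, seed=seed),
        diseases=["E11", "I25"],
        k_range=(2, 4),
        seed=seed,
    )
    config.to_yaml(target / "config.yaml")
    return config
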