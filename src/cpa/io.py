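"""Readers and writers for the delimited-text interchange formats.

Lab tables, patient metadata and diagnosis tables are UTF-8 delimited
text (comma or tab, autodetected); genesets use the standard GMT format
(name, description, then tab-separated gene symbols).  All readers
canonicalize row/column order by sorting, so output is independent of
input row order.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import ClinotypeMatrix, DiagnosisRecord, Geneset, make_patients_frame

logger = logging.getLogger(__name__)

LAB_COLUMNS = ("patient_id", "clinotype", "value", "date", "ref_low", "ref_high")
DIAGNOSIS_COLUMNS = ("patient_id", "icd10", "date")
PATIENT_COLUMNS = ("patient_id", "sex", "birth_year")


class SchemaError(ValueError):
    """A mandatory column is missing from an input table."""


def _read_delimited(path: str | Path) -> pd.DataFrame:
    # sep=None sniffs comma vs tab via csv.Sniffer
    return pd.read_csv(path, sep=None, engine="python", dtype=str, skipinitialspace=True)


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")


def read_lab_table(path: str | Path, dialect: str | None = None) -> ClinotypeMatrix:
    """Read a long-format lab-result table into a :class:`ClinotypeMatrix`.

    Duplicate (patient, clinotype) measurements are collapsed by keeping
    the most recent dated record.  Rows with an unparseable numeric value
    are skipped with a warning; the count is available under
    ``matrix.meta["skipped_rows"]``.  Each patient's earliest record date
    (over all parseable rows) is kept for the temporal split.
    """
    df = _read_delimited(path) if dialect is None else pd.read_csv(path, sep=dialect, dtype=str)
    _require_columns(df, LAB_COLUMNS, path)

    df = df.copy()
    for col in ("value", "ref_low", "ref_high"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["date"] = pd.to_datetime(df["date"], errors="coerce")

    bad = df["value"].isna() | df["ref_low"].isna() | df["ref_high"].isna() | df["date"].isna()
    n_skipped = int(bad.sum())
    if n_skipped:
        logger.warning("%s: skipped %d row(s) with unparseable fields", path, n_skipped)
    kept = df.loc[~bad]

    first_date = kept.groupby("patient_id")["date"].min()

    # keep the latest dated record per (patient, clinotype); stable sort makes
    # ties deterministic (last occurrence in file order wins)
    kept = kept.sort_values("date", kind="stable")
    kept = kept.drop_duplicates(subset=["patient_id", "clinotype"], keep="last")

    values = kept.pivot(index="patient_id", columns="clinotype", values="value").sort_index()
    values = values[sorted(values.columns)]
    ref_low = kept.pivot(index="patient_id", columns="clinotype", values="ref_low")
    ref_high = kept.pivot(index="patient_id", columns="clinotype", values="ref_high")

    return ClinotypeMatrix(
        values,
        ref_low.reindex(index=values.index, columns=values.columns),
        ref_high.reindex(index=values.index, columns=values.columns),
        first_date=first_date.reindex(values.index),
        meta={"skipped_rows": n_skipped, "source": str(path)},
    )


def write_lab_table(matrix: ClinotypeMatrix, path: str | Path) -> None:
    """Write a matrix back to long format (observed cells only).

    Values are written with full float precision so that write→read
    round-trips exactly.
    """
    rows = []
    default_date = pd.Timestamp("2000-01-01")
    for pid in matrix.patients:
        date = (
            matrix.first_date.loc[pid]
            if matrix.first_date is not None and pd.notna(matrix.first_date.loc[pid])
            else default_date
        )
        row_vals = matrix.values.loc[pid]
        for clin in matrix.clinotypes:
            v = row_vals[clin]
            if pd.isna(v):
                continue
            rows.append(
                (
                    pid,
                    clin,
                    np.format_float_positional(v, trim="0"),
                    pd.Timestamp(date).date().isoformat(),
                    np.format_float_positional(matrix.ref_low.loc[pid, clin], trim="0"),
                    np.format_float_positional(matrix.ref_high.loc[pid, clin], trim="0"),
                )
            )
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(LAB_COLUMNS)
        writer.writerows(rows)


def read_patients(path: str | Path) -> pd.DataFrame:
    """Read the patient metadata table (patient_id, sex, birth_year)."""
    df = _read_delimited(path)
    _require_columns(df, PATIENT_COLUMNS, path)
    return make_patients_frame(
        df["patient_id"],
        df["sex"].str.strip().str.lower(),
        pd.to_numeric(df["birth_year"]).astype(int),
    ).sort_index()


def write_patients(patients: pd.DataFrame, path: str | Path) -> None:
    out = patients.reset_index()[["patient_id", "sex", "birth_year"]]
    out.to_csv(path, index=False)


def read_diagnoses(path: str | Path) -> list[DiagnosisRecord]:
    """Read diagnosis records; codes are uppercased and whitespace-trimmed.

    Rows with an empty code are rejected with a warning.
    """
    df = _read_delimited(path)
    if df.empty and df.columns.size == 0:
        return []
    _require_columns(df, DIAGNOSIS_COLUMNS, path)
    records: list[DiagnosisRecord] = []
    n_rejected = 0
    for _, row in df.iterrows():
        code = ("" if pd.isna(row["icd10"]) else str(row["icd10"])).strip().upper()
        if not code:
            n_rejected += 1
            continue
        records.append(
            DiagnosisRecord(str(row["patient_id"]), code, pd.to_datetime(row["date"]))
        )
    if n_rejected:
        logger.warning("%s: rejected %d diagnosis row(s) with empty code", path, n_rejected)
    return records


def write_diagnoses(records: Sequence[DiagnosisRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(DIAGNOSIS_COLUMNS)
        for rec in records:
            writer.writerow((rec.patient_id, rec.icd10_code, pd.Timestamp(rec.date).date().isoformat()))


def diagnoses_to_frame(records: Sequence[DiagnosisRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "icd10": [r.icd10_code for r in records],
            "date": [r.date for r in records],
        }
    )


def read_gmt(path: str | Path) -> list[Geneset]:
    """Read a GMT geneset file (one set per line, ≥3 tab-separated fields).

    Duplicate genes within a line are deduplicated preserving first
    occurrence; lines with fewer than three fields are rejected with a
    warning.
    """
    genesets: list[Geneset] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                logger.warning("%s:%d: GMT line has <3 fields, rejected", path, lineno)
                continue
            name, description, *genes = fields
            unique = tuple(dict.fromkeys(g.strip() for g in genes if g.strip()))
            if not unique:
                logger.warning("%s:%d: GMT line has no genes, rejected", path, lineno)
                continue
            genesets.append(Geneset(name, description, unique))
    return genesets


def write_gmt(genesets: Sequence[Geneset], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in genesets:
            fh.write("\t".join((gs.name, gs.description, *gs.genes)) + "\n")
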