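"""Tabular and config I/O: subject TSV, study-count TSV, panel YAML,
model JSON.

All tabular files are tab-delimited UTF-8 with a header row.  Missing
genotypes are written as ``NA`` and parsed from ``NA``, ``.`` or empty
fields.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .grs import SnpSpec
from .meta import StudyCounts
from .models import FittedModel

SUBJECT_COLUMNS = ["id", "status", "age", "sex", "smoking", "drinking", "family_history"]
_MISSING = {"NA", "", "."}
_STATUS = {"case": 1, "control": 0, "1": 1, "0": 0}


def read_subject_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a per-subject genotype+covariate TSV.

    Dosage columns (everything after the fixed covariates) must contain
    0/1/2 or a missing marker; violations are reported with their line
    number.  Duplicate subject ids are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = [c for c in SUBJECT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing required columns {missing_cols}")
    dup = df["id"][df["id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicate subject id(s): {', '.join(dup.unique()[:5])}")

    out = pd.DataFrame({"id": df["id"]})
    try:
        out["status"] = df["status"].str.lower().map(_STATUS)
    except KeyError:
        pass
    if out["status"].isna().any():
        line = int(out["status"].isna().idxmax()) + 2  # header is line 1
        raise ValueError(f"{path}: line {line}: status must be case/control/1/0")
    out["status"] = out["status"].astype(int)
    out["age"] = pd.to_numeric(df["age"])
    out["sex"] = df["sex"].str.lower()
    for col in ("smoking", "drinking", "family_history"):
        out[col] = pd.to_numeric(df[col]).astype(int)
        if not set(out[col].unique()) <= {0, 1}:
            raise ValueError(f"{path}: {col} must be 0/1")

    snp_cols = [c for c in df.columns if c not in SUBJECT_COLUMNS]
    for col in snp_cols:
        raw = df[col].str.strip()
        vals = np.where(raw.isin(_MISSING), "nan", raw)
        parsed = pd.to_numeric(pd.Series(vals), errors="coerce")
        bad = (~raw.isin(_MISSING)) & (~parsed.isin([0, 1, 2]))
        if bad.any():
            line = int(bad.idxmax()) + 2
            raise ValueError(
                f"{path}: line {line}: dosage {raw[bad.idxmax()]!r} in column {col} "
                "is not 0, 1, 2 or missing"
            )
        out[col] = parsed
    return out


def write_subject_table(subjects: pd.DataFrame, path: str | Path) -> None:
    df = subjects.copy()
    df["status"] = df["status"].map({1: "case", 0: "control"})
    snp_cols = [c for c in df.columns if c not in SUBJECT_COLUMNS]
    for col in snp_cols:
        df[col] = df[col].map(lambda v: "NA" if pd.isna(v) else str(int(v)))
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")


def read_study_table(path: str | Path) -> dict[str, list[StudyCounts]]:
    """Read a per-study genotype-count TSV, long format.

    Columns: study_id, case_AA, case_AB, case_BB, ctrl_AA, ctrl_AB,
    ctrl_BB, optionally rsid for a multi-SNP file.  Returns studies
    grouped by rsid (single-SNP files group under "").
    """
    df = pd.read_csv(path, sep="\t")
    needed = ["study_id", "case_AA", "case_AB", "case_BB", "ctrl_AA", "ctrl_AB", "ctrl_BB"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    out: dict[str, list[StudyCounts]] = {}
    for _, row in df.iterrows():
        key = str(row["rsid"]) if "rsid" in df.columns else ""
        out.setdefault(key, []).append(
            StudyCounts(
                study_id=str(row["study_id"]),
                case_counts=(int(row["case_AA"]), int(row["case_AB"]), int(row["case_BB"])),
                control_counts=(int(row["ctrl_AA"]), int(row["ctrl_AB"]), int(row["ctrl_BB"])),
            )
        )
    return out


def write_study_table(studies: list[StudyCounts], path: str | Path, rsid: str | None = None) -> None:
    rows = []
    for s in studies:
        row = {
            "study_id": s.study_id,
            "case_AA": s.case_counts[0],
            "case_AB": s.case_counts[1],
            "case_BB": s.case_counts[2],
            "ctrl_AA": s.control_counts[0],
            "ctrl_AB": s.control_counts[1],
            "ctrl_BB": s.control_counts[2],
        }
        if rsid is not None:
            row = {"rsid": rsid, **row}
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_panel(path: str | Path) -> list[SnpSpec]:
    """Read a SNP-panel config (YAML or JSON list of SNP entries)."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if isinstance(data, dict) and "snps" in data:
        data = data["snps"]
    return [
        SnpSpec(
            rsid=str(e["rsid"]),
            risk_allele=str(e.get("risk_allele", "B")),
            p=float(e["p"]),
            or_allele=float(e["or"]),
            genetic_model=str(e.get("genetic_model", "allelic")),
        )
        for e in data
    ]


def write_panel(panel: list[SnpSpec], path: str | Path) -> None:
    data = {
        "snps": [
            {
                "rsid": s.rsid,
                "risk_allele": s.risk_allele,
                "p": s.p,
                "or": s.or_allele,
                "genetic_model": s.genetic_model,
            }
            for s in panel
        ]
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def write_model(model: FittedModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(dataclasses.asdict(model), indent=2) + "\n")


def read_model(path: str | Path) -> FittedModel:
    data = json.loads(Path(path).read_text())
    return FittedModel(
        name=data["name"],
        terms=tuple(data["terms"]),
        coefficients=dict(data["coefficients"]),
        log_likelihood=data.get("log_likelihood"),
        n=data.get("n"),
    )
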