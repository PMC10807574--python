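"""Readers and writers for the plain-text formats used by the pipeline.

Expression matrices are TSV with genes as rows (first column the gene id,
remaining columns sample/cell ids); clinical tables are TSV keyed by
sample_id; gene sets use the GMT dialect (set name, description, then gene
ids, tab-separated).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from .datatypes import InputError, SurvivalRecord, check_expression_matrix, records_to_frame


def read_expression_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return check_expression_matrix(df)


def write_expression_tsv(expr: pd.DataFrame, path) -> None:
    expr = check_expression_matrix(expr)
    expr.to_csv(path, sep="\t", index_label="gene_id")


CLINICAL_COLUMNS = ("sample_id", "cohort", "os_time", "os_event", "surgery_only")


def write_clinical_tsv(records: Sequence[SurvivalRecord], path,
                       subtype_truth: dict[str, str] | None = None) -> None:
    df = records_to_frame(records).rename(columns={"time": "os_time", "event": "os_event"})
    if subtype_truth is not None:
        df["subtype_truth"] = [subtype_truth.get(s) for s in df.index]
    df.to_csv(path, sep="\t", index_label="sample_id")


def read_clinical_tsv(path) -> list[SurvivalRecord]:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    for col in ("os_time", "os_event"):
        if col not in df.columns:
            raise InputError(f"clinical table missing required column {col!r}")
    base = {"os_time", "os_event", "cohort", "surgery_only", "subtype_truth"}
    out = []
    for sid, row in df.iterrows():
        cov = {}
        for c in df.columns:
            if c in base or pd.isna(row[c]):
                continue
            try:
                cov[c] = float(row[c])
            except (TypeError, ValueError):
                continue
        out.append(SurvivalRecord(
            sample_id=str(sid), time=float(row["os_time"]),
            event=int(row["os_event"]), covariates=cov,
            cohort=str(row["cohort"]) if "cohort" in df.columns and pd.notna(row["cohort"]) else None,
            surgery_only=bool(row["surgery_only"]) if "surgery_only" in df.columns else False))
    return out


def read_gmt(path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    if not sets:
        raise InputError(f"no gene sets found in {path}")
    return sets


def write_gmt(sets: dict[str, Sequence[str]], path, description: str = "stemreo") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *map(str, genes)]) + "\n")


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(o):
    import numpy as np
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.bool_,)):
        return bool(o)
    if isinstance(o, (np.ndarray,)):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
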