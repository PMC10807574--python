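"""Core domain types shared across the pipeline.

Expression matrices are plain :class:`pandas.DataFrame` objects with gene
identifiers on the index and sample (or cell) identifiers on the columns;
all functions in this package treat gene/sample ids as opaque strings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class ConfigError(ValueError):
    """An invalid configuration value; the message names the field."""


class InputError(ValueError):
    """Invalid or degenerate input data."""


@dataclass(frozen=True, order=True)
class DirectedGenePair:
    """An ordered gene pair whose pattern E(gene_high) > E(gene_low) votes high risk."""

    gene_high: str
    gene_low: str

    def __post_init__(self) -> None:
        if self.gene_high == self.gene_low:
            raise InputError(f"gene pair must contain two distinct genes, got {self.gene_high!r} twice")

    @property
    def canonical(self) -> tuple[str, str]:
        """The pair's identity irrespective of direction (lexicographic order)."""
        a, b = sorted((self.gene_high, self.gene_low))
        return a, b

    @property
    def key(self) -> tuple[str, str, bool]:
        """Canonical genes plus whether the lexicographically smaller gene is the high one."""
        a, b = self.canonical
        return a, b, self.gene_high == a

    def vote(self, sample: Mapping[str, float]) -> bool | None:
        """High-risk vote of this pair in one sample; ``None`` if unusable (missing or tied)."""
        try:
            hi, lo = sample[self.gene_high], sample[self.gene_low]
        except KeyError:
            return None
        if not np.isfinite(hi) or not np.isfinite(lo) or hi == lo:
            return None
        return bool(hi > lo)


@dataclass
class StemnessProfile:
    """Per-cell stemness scores (CytoTRACE-like, in [0, 1]) and malignancy labels."""

    stemness: pd.Series
    malignant: pd.Series

    def __post_init__(self) -> None:
        self.stemness = pd.Series(self.stemness, dtype=float)
        self.malignant = pd.Series(self.malignant).astype(bool)
        if not self.stemness.index.equals(self.malignant.index):
            raise InputError("stemness and malignant series must share the same cell index")
        vals = self.stemness.to_numpy()
        if not np.all(np.isfinite(vals)) or vals.min() < 0 or vals.max() > 1:
            raise InputError("stemness scores must be finite and within [0, 1]")

    @property
    def cell_ids(self) -> pd.Index:
        return self.stemness.index

    @property
    def malignant_cells(self) -> pd.Index:
        return self.stemness.index[self.malignant.to_numpy()]

    @property
    def normal_cells(self) -> pd.Index:
        return self.stemness.index[~self.malignant.to_numpy()]


@dataclass
class SurvivalRecord:
    """One sample's follow-up: time on study, event indicator, and covariates."""

    sample_id: str
    time: float
    event: int
    covariates: dict[str, float] = field(default_factory=dict)
    cohort: str | None = None
    surgery_only: bool = False

    def __post_init__(self) -> None:
        if not self.time > 0:
            raise InputError(f"survival time must be positive, got {self.time} for {self.sample_id}")
        if self.event not in (0, 1):
            raise InputError(f"event must be 0 or 1, got {self.event} for {self.sample_id}")


def records_to_frame(records: Sequence[SurvivalRecord]) -> pd.DataFrame:
    """Tabulate survival records (index = sample id)."""
    rows = {}
    for r in records:
        rows[r.sample_id] = {"time": r.time, "event": r.event, "cohort": r.cohort,
                             "surgery_only": r.surgery_only, **r.covariates}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "sample_id"
    return df


def frame_to_records(df: pd.DataFrame) -> list[SurvivalRecord]:
    """Inverse of :func:`records_to_frame`; extra columns become covariates."""
    base = {"time", "event", "cohort", "surgery_only"}
    out = []
    for sid, row in df.iterrows():
        cov = {c: float(row[c]) for c in df.columns if c not in base and pd.notna(row[c])}
        out.append(SurvivalRecord(
            sample_id=str(sid), time=float(row["time"]), event=int(row["event"]),
            covariates=cov, cohort=row.get("cohort"),
            surgery_only=bool(row.get("surgery_only", False))))
    return out


@dataclass
class SubtypeAssignment:
    """Median-split subtype labels for one cohort."""

    labels: pd.Series  # 'high' / 'low' per sample
    threshold: float
    cohort: str

    @property
    def high_samples(self) -> pd.Index:
        return self.labels.index[self.labels == "high"]

    @property
    def low_samples(self) -> pd.Index:
        return self.labels.index[self.labels == "low"]


@dataclass
class StablePairSet:
    """Gene pairs with a significantly stable REO direction within one group.

    ``table`` columns: gene_a, gene_b (canonical, gene_a < gene_b), direction
    ('a_gt_b' or 'a_lt_b', the majority pattern), k (effective sample count,
    ties excluded), s (samples showing the majority pattern), p_value, fdr.
    Only pairs passing the FDR threshold are retained.
    """

    subtype: str
    table: pd.DataFrame
    n_tested: int
    fdr_threshold: float

    def __len__(self) -> int:
        return len(self.table)

    def directions(self) -> dict[tuple[str, str], str]:
        return dict(zip(zip(self.table["gene_a"], self.table["gene_b"]),
                        self.table["direction"]))


@dataclass
class GeneSelectionResult:
    """Stemness signature-gene selection: G1 ∩ G2 with per-gene statistics."""

    g1: set[str]
    g2: set[str]
    signature_genes: list[str]
    stats: pd.DataFrame

    def __post_init__(self) -> None:
        assert set(self.signature_genes) <= self.g1 and set(self.signature_genes) <= self.g2


@dataclass
class CoxFit:
    """Summary of a Cox proportional-hazards fit."""

    coef: pd.Series
    hazard_ratio: pd.Series
    se: pd.Series
    p_value: pd.Series
    n_events: int
    converged: bool
    message: str = ""


@dataclass
class VoteResult:
    """Half-voting outcome for a single sample."""

    sample_id: str
    votes_high: int
    votes_total: int
    label: str | None  # 'high' / 'low' / None (unclassifiable)

    @property
    def vote_fraction(self) -> float:
        return self.votes_high / self.votes_total if self.votes_total else float("nan")

    @property
    def classifiable(self) -> bool:
        return self.label is not None


VOTE_RULE = "high if votes_high >= votes_total / 2"


@dataclass
class Signature:
    """An ordered gene-pair signature with the half-voting decision rule."""

    pairs: list[DirectedGenePair]
    c_index_train: float
    c_index_path: list[float] = field(default_factory=list)
    vote_rule: str = VOTE_RULE
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.pairs:
            raise InputError("a signature must contain at least one gene pair")
        seen = set()
        for p in self.pairs:
            if p.canonical in seen:
                raise InputError(f"duplicate gene pair in signature: {p.canonical}")
            seen.add(p.canonical)

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def genes(self) -> list[str]:
        out: set[str] = set()
        for p in self.pairs:
            out.update((p.gene_high, p.gene_low))
        return sorted(out)

    def to_dict(self) -> dict:
        return {
            "pairs": [[p.gene_high, p.gene_low] for p in self.pairs],
            "vote_rule": self.vote_rule,
            "c_index_train": self.c_index_train,
            "c_index_path": list(self.c_index_path),
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Signature":
        return cls(
            pairs=[DirectedGenePair(h, l) for h, l in d["pairs"]],
            c_index_train=float(d["c_index_train"]),
            c_index_path=[float(x) for x in d.get("c_index_path", [])],
            vote_rule=d.get("vote_rule", VOTE_RULE),
            provenance=d.get("provenance", {}),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "Signature":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame({"gene_high": [p.gene_high for p in self.pairs],
                             "gene_low": [p.gene_low for p in self.pairs]})


def check_expression_matrix(expr: pd.DataFrame) -> pd.DataFrame:
    """Validate a gene × sample matrix: unique ids, numeric values."""
    if expr.index.has_duplicates:
        raise InputError("expression matrix has duplicate gene identifiers")
    if expr.columns.has_duplicates:
        raise InputError("expression matrix has duplicate sample identifiers")
    try:
        expr = expr.astype(float)
    except (TypeError, ValueError) as exc:
        raise InputError(f"expression matrix is not numeric: {exc}") from exc
    return expr
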