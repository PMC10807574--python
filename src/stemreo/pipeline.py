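"""End-to-end orchestration: stemness genes → subtypes → reversal pairs →
candidate screen → forward search → evaluation.

The in-memory entry point is :func:`build_signature_from_cohorts`, used by
the tests and by downstream scripts; :func:`run_pipeline` is the file-based
wrapper driven by a :class:`PipelineConfig`, writing every intermediate
table plus a manifest of per-stage counts, thresholds, seed and file hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    ConfigError,
    DirectedGenePair,
    InputError,
    Signature,
    SurvivalRecord,
)
from . import io as sio
from .stemness_genes import derive_signature_genes
from .enrichment_subtyping import SsgseaParams, median_split, ssgsea_score
from .reo_core import find_stable_pairs, intersect_cohort_reversals, reversal_pairs
from .signature_builder import (
    CandidateTable,
    evaluate_signature,
    filter_prognostic_pairs,
    forward_search,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Declarative configuration of a full run."""

    # inputs
    single_cell_expr: str | None = None
    cell_metadata: str | None = None      # TSV: cell_id, stemness, malignant
    bulk_expr: list[str] = field(default_factory=list)
    clinical: str | None = None
    gene_set_gmt: str | None = None       # alternative to deriving from single-cell
    out_dir: str = "stemreo_out"
    # thresholds
    r_threshold: float = 0.2
    lfc_threshold: float = 0.25
    stemness_fdr: float = 0.05
    tau: float = 0.25
    top_fraction: float = 0.05
    stable_fdr: float = 0.05
    cox_fdr: float = 0.05
    surgery_only: bool = True
    seed: int = 0
    # stage toggles
    run_stemness: bool = True
    run_evaluation: bool = True
    write_stable_pairs: bool = False  # per-subtype tables can be very large

    def validate(self) -> None:
        for name in ("stemness_fdr", "stable_fdr", "cox_fdr", "top_fraction"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ConfigError(f"{name} must lie in (0, 1], got {v!r}")
        if not (-1 <= self.r_threshold <= 1):
            raise ConfigError(f"r_threshold must lie in [-1, 1], got {self.r_threshold!r}")
        if self.tau < 0:
            raise ConfigError(f"tau must be nonnegative, got {self.tau!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


@dataclass
class PipelineResult:
    """All intermediate and final products of a signature build."""

    gene_set: list[str]
    scores: list[pd.Series]
    subtypes: list  # SubtypeAssignment per cohort
    stable_counts: list[dict[str, int]]
    stable_sets: list[dict[str, object]]  # per cohort: subtype -> StablePairSet
    reversals: list[list[DirectedGenePair]]
    consistent_pairs: list[DirectedGenePair]
    concordance: float
    concordance_p: float
    candidates: CandidateTable
    signature: Signature | None
    training_report: object | None
    counts: dict[str, object] = field(default_factory=dict)


def build_signature_from_cohorts(exprs: Sequence[pd.DataFrame],
                                 records: Sequence[Sequence[SurvivalRecord]],
                                 gene_set: Sequence[str],
                                 ssgsea_params: SsgseaParams | None = None,
                                 stable_fdr: float = 0.05,
                                 cox_fdr: float = 0.05,
                                 surgery_only: bool = True,
                                 provenance: dict | None = None) -> PipelineResult:
    """Derive a gene-pair signature from one or more training cohorts.

    Each cohort is subtyped at the median single-sample enrichment score of
    ``gene_set``; stable pairs are found separately within each subtype and
    reversal pairs per cohort; reversals are intersected across cohorts
    keeping orientation-consistent pairs, which are screened by univariate
    Cox on the pooled (surgery-only) samples and combined by forward search.
    """
    if len(exprs) != len(records) or not exprs:
        raise InputError("need one record list per cohort expression matrix")
    ssgsea_params = ssgsea_params or SsgseaParams()

    scores, subtypes, stable_counts, stable_sets, reversals = [], [], [], [], []
    for i, expr in enumerate(exprs):
        cohort = records[i][0].cohort if records[i] else f"cohort{i + 1}"
        sc = ssgsea_score(expr, gene_set, ssgsea_params)
        assign = median_split(sc, cohort=str(cohort))
        hi = find_stable_pairs(expr, samples=list(assign.high_samples),
                               fdr_threshold=stable_fdr, subtype="high")
        lo = find_stable_pairs(expr, samples=list(assign.low_samples),
                               fdr_threshold=stable_fdr, subtype="low")
        rev = reversal_pairs(hi, lo)
        log.info("cohort %s: %d stable (high), %d stable (low), %d reversal pairs",
                 cohort, len(hi), len(lo), len(rev))
        scores.append(sc)
        subtypes.append(assign)
        stable_counts.append({"high": len(hi), "low": len(lo)})
        stable_sets.append({"high": hi, "low": lo})
        reversals.append(rev)

    if len(reversals) == 1:
        consistent, concordance, conc_p = list(reversals[0]), 1.0, 1.0
    else:
        consistent, concordance, conc_p = intersect_cohort_reversals(
            reversals[0], reversals[1])
        for extra in reversals[2:]:
            consistent, _, _ = intersect_cohort_reversals(consistent, extra)
    log.info("cross-cohort: %d orientation-consistent reversal pairs "
             "(concordance %.4f)", len(consistent), concordance)

    pooled = [r for cohort_recs in records for r in cohort_recs]
    candidates = filter_prognostic_pairs(consistent, list(exprs), pooled,
                                         fdr_threshold=cox_fdr,
                                         surgery_only=surgery_only)
    signature = None
    training_report = None
    if len(candidates):
        signature = forward_search(candidates, list(exprs), pooled,
                                   surgery_only=surgery_only,
                                   provenance=provenance or {})
        training_report = evaluate_signature(signature, list(exprs), pooled)

    counts = {
        "n_genes": int(exprs[0].shape[0]),
        "gene_set_size": len(set(gene_set) & set(exprs[0].index)),
        "stable_pairs": stable_counts,
        "reversal_pairs": [len(r) for r in reversals],
        "shared_consistent_pairs": len(consistent),
        "concordance": concordance,
        "concordance_p": conc_p,
        "candidates": len(candidates),
        "signature_pairs": len(signature) if signature else 0,
        "training_c_index": signature.c_index_train if signature else None,
    }
    return PipelineResult(
        gene_set=sorted(set(gene_set)), scores=scores, subtypes=subtypes,
        stable_counts=stable_counts, stable_sets=stable_sets, reversals=reversals,
        consistent_pairs=consistent, concordance=concordance,
        concordance_p=conc_p, candidates=candidates, signature=signature,
        training_report=training_report, counts=counts)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """File-based pipeline run; returns (and writes) the manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": {}}

    # stage 1: stemness gene set
    if config.run_stemness and config.single_cell_expr:
        sc_expr = sio.read_expression_tsv(config.single_cell_expr)
        meta = pd.read_csv(config.cell_metadata, sep="\t", index_col=0)
        from .datatypes import StemnessProfile
        profile = StemnessProfile(stemness=meta["stemness"].astype(float),
                                  malignant=meta["malignant"].astype(bool))
        sel = derive_signature_genes(sc_expr, profile,
                                     r_threshold=config.r_threshold,
                                     lfc_threshold=config.lfc_threshold,
                                     fdr_threshold=config.stemness_fdr)
        gene_set = sel.signature_genes
        sel.stats.to_csv(out / "gene_stats.tsv", sep="\t")
        sio.write_gmt({"stemness_signature": gene_set}, out / "signature_genes.gmt")
        manifest["stages"]["stemness_genes"] = {
            "g1": len(sel.g1), "g2": len(sel.g2), "signature_genes": len(gene_set)}
    elif config.gene_set_gmt:
        sets = sio.read_gmt(config.gene_set_gmt)
        gene_set = next(iter(sets.values()))
        manifest["stages"]["stemness_genes"] = {"from_gmt": len(gene_set)}
    else:
        raise ConfigError("either single_cell_expr (+cell_metadata) or "
                          "gene_set_gmt must be provided")
    if not gene_set:
        raise InputError("empty stemness gene set; cannot continue")

    # stage 2..6: bulk cohorts → signature
    if not config.bulk_expr or not config.clinical:
        raise ConfigError("bulk_expr and clinical are required")
    exprs = [sio.read_expression_tsv(p) for p in config.bulk_expr]
    all_records = sio.read_clinical_tsv(config.clinical)
    by_cohort: dict[str, list[SurvivalRecord]] = {}
    for r in all_records:
        by_cohort.setdefault(r.cohort or "cohort", []).append(r)
    records = []
    for expr in exprs:
        cols = set(expr.columns)
        match = [rs for rs in by_cohort.values()
                 if any(r.sample_id in cols for r in rs)]
        if not match:
            raise InputError("no clinical records match a bulk expression matrix")
        records.append([r for rs in match for r in rs if r.sample_id in cols])

    result = build_signature_from_cohorts(
        exprs, records, gene_set,
        ssgsea_params=SsgseaParams(tau=config.tau),
        stable_fdr=config.stable_fdr, cox_fdr=config.cox_fdr,
        surgery_only=config.surgery_only,
        provenance={"seed": config.seed, "stable_fdr": config.stable_fdr,
                    "cox_fdr": config.cox_fdr})

    for i, (sc, assign) in enumerate(zip(result.scores, result.subtypes)):
        df = pd.DataFrame({"ssgsea": sc, "subtype": assign.labels})
        df.to_csv(out / f"subtypes_cohort{i + 1}.tsv", sep="\t",
                  index_label="sample_id")
    if config.write_stable_pairs:
        for i, sets in enumerate(result.stable_sets):
            for subtype, sp in sets.items():
                sp.table.to_csv(out / f"stable_pairs_cohort{i + 1}_{subtype}.tsv",
                                sep="\t", index=False)
    pd.DataFrame([(p.gene_high, p.gene_low) for p in result.consistent_pairs],
                 columns=["gene_high", "gene_low"]).to_csv(
        out / "reversal_pairs.tsv", sep="\t", index=False)
    result.candidates.table.to_csv(out / "candidate_pairs.tsv", sep="\t", index=False)
    if result.signature is not None:
        result.signature.to_json(out / "signature.json")
        result.signature.to_table().to_csv(out / "signature_pairs.tsv",
                                           sep="\t", index=False)
        if config.run_evaluation and result.training_report is not None:
            result.training_report.labels.to_csv(out / "training_labels.tsv", sep="\t")
    manifest["stages"]["signature"] = result.counts

    manifest["files"] = {p.name: _sha256(p) for p in sorted(out.glob("*"))
                         if p.is_file() and p.name != "manifest.json"}
    sio.write_json(manifest, out / "manifest.json")
    return manifest
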