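"""Single-sample gene-set enrichment (ssGSEA) and median-split subtyping.

Each bulk sample is scored for the stemness gene set with a single-sample
enrichment statistic computed from that sample's gene ranks alone, then
each cohort is split at its median score into high- and low-risk subtypes.
Because the score depends only on within-sample ranks, it is invariant to
any strictly increasing per-sample transform of the expression values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .datatypes import InputError, SubtypeAssignment, check_expression_matrix
from .stemness_genes import _ordered_positions


@dataclass
class SsgseaParams:
    """Weighting of the single-sample enrichment walk.

    tau is the exponent on the rank magnitude for in-set genes (0 gives an
    unweighted Kolmogorov–Smirnov-like walk); rank_mode chooses whether the
    magnitude is the raw descending rank (n..1) or that rank divided by n.
    The choice of rank_mode rescales scores identically within a sample set
    and never changes their ordering.
    """

    tau: float = 0.25
    rank_mode: str = "raw_rank"

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise InputError(f"tau must be nonnegative, got {self.tau}")
        if self.rank_mode not in ("raw_rank", "normalized_rank"):
            raise InputError(f"unknown rank_mode {self.rank_mode!r}")


def ssgsea_score(expr: pd.DataFrame, gene_set: Iterable[str],
                 params: SsgseaParams | None = None) -> pd.Series:
    """Per-sample enrichment score of ``gene_set``.

    For each sample the genes are ranked by decreasing expression (ties
    broken by gene id). Walking down the ranked list, an in-set empirical
    CDF weighted by rank-magnitude**tau and an unweighted out-of-set CDF
    are accumulated; the score is the sum over all positions of their
    difference.
    """
    params = params or SsgseaParams()
    expr = check_expression_matrix(expr)
    gene_set = set(gene_set)
    present = gene_set & set(expr.index)
    if not present:
        raise InputError("gene set has no overlap with the expression matrix genes")
    n_genes = expr.shape[0]
    m = len(present)
    if m == n_genes:
        raise InputError("gene set covers every gene; enrichment is undefined")
    if n_genes - m < 2:
        raise InputError("need at least 2 genes outside the gene set")

    order, sorted_index = _ordered_positions(expr)
    in_set = np.asarray(sorted_index.isin(present))
    hits = in_set[order]                                 # (n_genes, n_samples)

    magnitude = np.arange(n_genes, 0, -1, dtype=float)     # rank magnitude, top first
    if params.rank_mode == "normalized_rank":
        magnitude = magnitude / n_genes
    w = magnitude ** params.tau

    w_in = np.where(hits, w[:, None], 0.0)
    cdf_in = np.cumsum(w_in, axis=0) / w_in.sum(axis=0, keepdims=True)
    cdf_out = np.cumsum(~hits, axis=0) / float(n_genes - m)
    es = (cdf_in - cdf_out).sum(axis=0)
    return pd.Series(es, index=expr.columns, name="ssgsea")


def median_split(scores: pd.Series, cohort: str = "cohort") -> SubtypeAssignment:
    """Split samples at the cohort-median score: strictly above -> high.

    Samples tied with the median are assigned to the low group, keeping the
    rule deterministic.
    """
    scores = pd.Series(scores, dtype=float)
    if len(scores) < 2:
        raise InputError("median split requires at least 2 samples")
    vals = scores.to_numpy()
    if np.allclose(vals, vals[0], rtol=0.0, atol=0.0):
        raise InputError(f"all enrichment scores identical in cohort {cohort!r}; "
                         "cannot split at the median")
    thr = float(np.median(vals))
    labels = pd.Series(np.where(vals > thr, "high", "low"), index=scores.index)
    return SubtypeAssignment(labels=labels, threshold=thr, cohort=cohort)
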