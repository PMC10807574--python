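"""Selection of stemness-related signature genes from single-cell data.

Two gene lists are derived and intersected: G1, genes whose expression
correlates positively with a per-cell stemness score across malignant
cells (Pearson R > 0.2, BH-FDR < 0.05 by default), and G2, genes
upregulated in malignant versus non-malignant cells (Wilcoxon rank-sum,
log2 fold change > 0.25 on pseudocount-1 means, BH-FDR < 0.05). Cells are
also scored for any gene set with an AUCell-style area under the recovery
curve within the top-ranked fraction of genes.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import GeneSelectionResult, InputError, StemnessProfile, check_expression_matrix

log = logging.getLogger(__name__)


def _bh(pvals: np.ndarray) -> np.ndarray:
    if len(pvals) == 0:
        return pvals
    return multipletests(pvals, method="fdr_bh")[1]


def correlate_with_stemness(expr: pd.DataFrame, profile: StemnessProfile,
                            r_threshold: float = 0.2,
                            fdr_threshold: float = 0.05) -> tuple[set[str], pd.DataFrame]:
    """Genes positively correlated with stemness across malignant cells (G1).

    Returns the selected gene set and a per-gene table (r, p, fdr,
    testable). Zero-variance genes are recorded as untestable and excluded
    from the FDR family rather than raising.
    """
    expr = check_expression_matrix(expr)
    cells = profile.malignant_cells
    missing = cells.difference(expr.columns)
    if len(missing):
        raise InputError(f"cells missing from expression matrix: {list(missing)[:5]}")
    if len(cells) < 3:
        raise InputError("correlation requires at least 3 malignant cells")

    x = profile.stemness.loc[cells].to_numpy(float)
    mat = expr[cells].to_numpy(float)
    n = len(cells)
    xc = x - x.mean()
    sx = xc.std()
    gc = mat - mat.mean(axis=1, keepdims=True)
    sg = gc.std(axis=1)
    testable = (sg > 0) & (sx > 0)

    r = np.full(mat.shape[0], np.nan)
    p = np.full(mat.shape[0], np.nan)
    if testable.any() and sx > 0:
        r_t = (gc[testable] @ xc) / (n * sg[testable] * sx)
        r_t = np.clip(r_t, -1.0, 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = r_t * np.sqrt((n - 2) / np.maximum(1.0 - r_t ** 2, 1e-300))
        p_t = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
        r[testable], p[testable] = r_t, p_t

    fdr = np.full(mat.shape[0], np.nan)
    fdr[testable] = _bh(p[testable])
    stats_df = pd.DataFrame({"r": r, "p": p, "fdr": fdr, "testable": testable},
                            index=expr.index)
    sel = stats_df.index[(testable) & (r > r_threshold) & (fdr < fdr_threshold)]
    return set(sel), stats_df


def malignant_upregulated(expr: pd.DataFrame, profile: StemnessProfile,
                          lfc_threshold: float = 0.25,
                          fdr_threshold: float = 0.05) -> tuple[set[str], pd.DataFrame]:
    """Genes upregulated in malignant cells (G2).

    Two-sided Wilcoxon rank-sum per gene; log2 fold change computed as
    log2((mean_malignant + 1) / (mean_non_malignant + 1)) on linear values.
    """
    expr = check_expression_matrix(expr)
    mal, non = profile.malignant_cells, profile.normal_cells
    if len(mal) < 2 or len(non) < 2:
        raise InputError("differential expression requires >=2 cells per group")
    missing = mal.union(non).difference(expr.columns)
    if len(missing):
        raise InputError(f"cells missing from expression matrix: {list(missing)[:5]}")

    xm = expr[mal].to_numpy(float)
    xn = expr[non].to_numpy(float)
    res = stats.mannwhitneyu(xm, xn, axis=1, alternative="two-sided")
    p = np.asarray(res.pvalue, dtype=float)
    # fully tied genes yield NaN p; they carry no signal
    p = np.where(np.isnan(p), 1.0, p)
    lfc = np.log2((xm.mean(axis=1) + 1.0) / (xn.mean(axis=1) + 1.0))
    fdr = _bh(p)
    stats_df = pd.DataFrame({"log2fc": lfc, "p": p, "fdr": fdr}, index=expr.index)
    sel = stats_df.index[(lfc > lfc_threshold) & (fdr < fdr_threshold)]
    return set(sel), stats_df


def select_signature_genes(g1: Iterable[str], g2: Iterable[str]) -> list[str]:
    """The stemness signature genes: G1 ∩ G2, sorted for determinism."""
    out = sorted(set(g1) & set(g2))
    if not out:
        log.warning("G1 and G2 are disjoint: empty signature gene set")
    return out


def derive_signature_genes(expr: pd.DataFrame, profile: StemnessProfile,
                           r_threshold: float = 0.2, lfc_threshold: float = 0.25,
                           fdr_threshold: float = 0.05) -> GeneSelectionResult:
    """Run both selections and intersect them."""
    g1, corr_stats = correlate_with_stemness(expr, profile, r_threshold, fdr_threshold)
    g2, de_stats = malignant_upregulated(expr, profile, lfc_threshold, fdr_threshold)
    sig = select_signature_genes(g1, g2)
    stats_df = corr_stats.join(de_stats, lsuffix="_corr", rsuffix="_de")
    stats_df["in_g1"] = stats_df.index.isin(g1)
    stats_df["in_g2"] = stats_df.index.isin(g2)
    stats_df["selected"] = stats_df.index.isin(sig)
    return GeneSelectionResult(g1=g1, g2=g2, signature_genes=sig, stats=stats_df)


def _ordered_positions(expr: pd.DataFrame) -> np.ndarray:
    """Per column, row indices ordered by decreasing value, ties by gene id.

    Returns an (n_genes, n_columns) array of row indices into the
    alphabetically sorted gene index.
    """
    srt = expr.sort_index(axis=0)
    vals = srt.to_numpy(float)
    # stable sort on -value: equal values keep alphabetical gene order
    order = np.argsort(-vals, axis=0, kind="stable")
    return order, srt.index


def aucell_score(expr: pd.DataFrame, gene_set: Iterable[str],
                 top_fraction: float = 0.05) -> pd.Series:
    """AUCell-style per-cell gene-set activity.

    For each cell, genes are ranked by decreasing expression (ties broken
    by gene id); the score is the area under the step recovery curve of
    gene-set members within the top ``ceil(top_fraction * n_genes)`` ranks,
    normalised by the maximal achievable area, so scores lie in [0, 1].
    """
    expr = check_expression_matrix(expr)
    if not (0 < top_fraction <= 1):
        raise InputError(f"top_fraction must lie in (0, 1], got {top_fraction}")
    gene_set = set(gene_set)
    present = sorted(gene_set & set(expr.index))
    if not present:
        raise InputError("gene set has no overlap with the expression matrix genes")

    order, sorted_index = _ordered_positions(expr)
    in_set = np.asarray(sorted_index.isin(present))
    n_genes, n_cells = order.shape
    thr = int(np.ceil(top_fraction * n_genes))
    m_eff = min(len(present), thr)

    hits = in_set[order[:thr, :]]                    # (thr, n_cells)
    cum = np.cumsum(hits, axis=0)
    auc = cum.sum(axis=0).astype(float)
    max_auc = float(np.minimum(np.arange(1, thr + 1), m_eff).sum())
    return pd.Series(auc / max_auc, index=expr.columns, name="aucell")
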