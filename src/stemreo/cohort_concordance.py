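"""Cross-cohort concordance of high- vs low-risk differential expression.

A reproducibility check on the subtype labels: genes differentially
expressed between the high- and low-risk groups are detected per cohort
(Wilcoxon rank-sum, BH-FDR), and the direction agreement of the genes
shared between two cohorts' lists is tested against chance with an exact
one-sided binomial test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import InputError, SubtypeAssignment, check_expression_matrix


@dataclass
class DegList:
    """Significant genes with their direction in the high-risk group."""

    cohort: str
    table: pd.DataFrame  # index gene, columns: direction ('up'/'down'), fdr
    fdr_threshold: float

    def __len__(self) -> int:
        return len(self.table)

    def directions(self) -> dict[str, str]:
        return dict(self.table["direction"])


def deg_between_groups(expr: pd.DataFrame, labels: SubtypeAssignment,
                       fdr_threshold: float = 0.05) -> DegList:
    """Differentially expressed genes between high- and low-risk samples."""
    expr = check_expression_matrix(expr)
    hi = [s for s in labels.high_samples if s in expr.columns]
    lo = [s for s in labels.low_samples if s in expr.columns]
    if len(hi) < 2 or len(lo) < 2:
        raise InputError("both groups need at least 2 samples for DE")
    xh = expr[hi].to_numpy(float)
    xl = expr[lo].to_numpy(float)
    res = stats.mannwhitneyu(xh, xl, axis=1, alternative="two-sided")
    p = np.where(np.isnan(res.pvalue), 1.0, np.asarray(res.pvalue, float))
    fdr = multipletests(p, method="fdr_bh")[1]
    direction = np.where(xh.mean(axis=1) >= xl.mean(axis=1), "up", "down")
    keep = fdr < fdr_threshold
    table = pd.DataFrame({"direction": direction[keep], "fdr": fdr[keep]},
                         index=expr.index[keep]).sort_index()
    return DegList(cohort=labels.cohort, table=table, fdr_threshold=fdr_threshold)


def concordance_score(a: DegList, b: DegList) -> tuple[int, float, float]:
    """Direction agreement of the genes shared between two DEG lists.

    Returns (shared gene count, fraction with the same direction, one-sided
    exact binomial p-value of the concordant count against 0.5). With no
    shared genes: (0, NaN, 1.0).
    """
    da, db = a.directions(), b.directions()
    shared = sorted(set(da) & set(db))
    if not shared:
        return 0, float("nan"), 1.0
    conc = sum(da[g] == db[g] for g in shared)
    score = conc / len(shared)
    p = float(stats.binomtest(conc, len(shared), 0.5, alternative="greater").pvalue)
    return len(shared), score, p
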