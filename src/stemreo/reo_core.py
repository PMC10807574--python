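"""Within-sample relative expression orderings (REOs) and stable/reversal pairs.

The REO of a gene pair (i, j) in a sample is the order relation between
their expression values (Ei > Ej or Ei < Ej). A pair is *stable* within a
group of samples when one direction occurs more often than expected by
chance under a cumulative binomial model with per-sample success
probability 0.5; a *reversal* pair is stable in both risk subtypes with
opposite directions, and its direction observed in a new sample votes for
that sample's subtype. Every quantity computed here depends only on
within-sample orderings, so all outputs are invariant under any strictly
increasing per-sample transform of the expression matrix — the property
that makes REO signatures robust to batch effects.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import DirectedGenePair, InputError, StablePairSet, check_expression_matrix


def binomial_reo_p(k: int, s: int, pe: float = 0.5) -> float:
    """Upper-tail probability P(X >= s) for X ~ Binomial(k, pe).

    This is the stable-REO p-value: the chance that at least s of k samples
    would show the majority direction if directions were coin flips.
    ``s = 0`` returns 1.
    """
    if k < 1:
        raise InputError(f"k must be >= 1, got {k}")
    if not (0 <= s <= k):
        raise InputError(f"s must lie in [0, k], got s={s}, k={k}")
    if not (0 < pe < 1):
        raise InputError(f"Pe must lie in (0, 1), got {pe}")
    if s == 0:
        return 1.0
    return float(stats.binom.sf(s - 1, k, pe))


def _canonical_direction(gene_a: str, gene_b: str, a_gt_b: bool) -> str:
    return "a_gt_b" if a_gt_b else "a_lt_b"


def find_stable_pairs(expr: pd.DataFrame,
                      samples: Sequence[str] | None = None,
                      fdr_threshold: float = 0.05,
                      candidate_pairs: Sequence[tuple[str, str]] | None = None,
                      subtype: str = "") -> StablePairSet:
    """Identify gene pairs with a stable REO direction across ``samples``.

    For each pair the majority direction is counted over samples (a sample
    with exactly tied values contributes to neither direction and reduces
    that pair's effective k); the binomial upper tail gives the p-value and
    Benjamini–Hochberg adjustment is applied across all tested pairs. Pairs
    with FDR below the threshold are retained together with their majority
    direction. Pairs are stored canonically with gene_a < gene_b.
    """
    expr = check_expression_matrix(expr)
    if samples is not None:
        samples = list(samples)
        if len(samples) == 0:
            raise InputError("empty sample subset")
        missing = set(samples) - set(expr.columns)
        if missing:
            raise InputError(f"samples missing from expression matrix: {sorted(missing)[:5]}")
        expr = expr[samples]
    if expr.shape[1] < 2:
        raise InputError("stable-pair detection requires at least 2 samples")
    if expr.shape[0] < 2:
        raise InputError("stable-pair detection requires at least 2 genes")

    expr = expr.sort_index(axis=0)
    x = expr.to_numpy(float)
    genes = expr.index.to_numpy()
    n_genes = x.shape[0]

    if candidate_pairs is not None:
        pos = {g: i for i, g in enumerate(genes)}
        ia, ib = [], []
        for g1, g2 in candidate_pairs:
            if g1 == g2:
                raise InputError(f"gene paired with itself: {g1!r}")
            if g1 not in pos or g2 not in pos:
                continue
            a, b = sorted((g1, g2))
            ia.append(pos[a])
            ib.append(pos[b])
        ia = np.asarray(ia, dtype=np.int64)
        ib = np.asarray(ib, dtype=np.int64)
        gt = (x[ia] > x[ib]).sum(axis=1)
        lt = (x[ia] < x[ib]).sum(axis=1)
        idx_a, idx_b = ia, ib
    else:
        gt_parts, lt_parts, a_parts, b_parts = [], [], [], []
        for i in range(n_genes - 1):
            rest = x[i + 1:]
            gt_parts.append((x[i] > rest).sum(axis=1))
            lt_parts.append((x[i] < rest).sum(axis=1))
            a_parts.append(np.full(n_genes - i - 1, i, dtype=np.int64))
            b_parts.append(np.arange(i + 1, n_genes, dtype=np.int64))
        gt = np.concatenate(gt_parts) if gt_parts else np.empty(0, dtype=np.int64)
        lt = np.concatenate(lt_parts) if lt_parts else np.empty(0, dtype=np.int64)
        idx_a = np.concatenate(a_parts) if a_parts else np.empty(0, dtype=np.int64)
        idx_b = np.concatenate(b_parts) if b_parts else np.empty(0, dtype=np.int64)

    k_eff = gt + lt
    s = np.maximum(gt, lt)
    testable = k_eff > 0
    n_tested = int(testable.sum())

    pvals = np.ones(len(k_eff))
    kt, st = k_eff[testable], s[testable]
    pvals[testable] = stats.binom.sf(st - 1, kt, 0.5)

    fdr = np.ones(len(k_eff))
    if n_tested:
        fdr[testable] = multipletests(pvals[testable], method="fdr_bh")[1]

    keep = testable & (fdr < fdr_threshold)
    table = pd.DataFrame({
        "gene_a": genes[idx_a[keep]],
        "gene_b": genes[idx_b[keep]],
        "direction": np.where(gt[keep] >= lt[keep], "a_gt_b", "a_lt_b"),
        "k": k_eff[keep].astype(int),
        "s": s[keep].astype(int),
        "p_value": pvals[keep],
        "fdr": fdr[keep],
    })
    table = table.sort_values(["gene_a", "gene_b"], kind="stable").reset_index(drop=True)
    return StablePairSet(subtype=subtype, table=table, n_tested=n_tested,
                         fdr_threshold=fdr_threshold)


def reversal_pairs(stable_high: StablePairSet,
                   stable_low: StablePairSet) -> list[DirectedGenePair]:
    """Pairs stable in both subtypes with opposite directions.

    Each reversal is oriented by the high-risk subtype's pattern: the gene
    with the larger expression in high-risk samples becomes ``gene_high``,
    so observing gene_high > gene_low in a new sample votes high risk.
    """
    hi = stable_high.table[["gene_a", "gene_b", "direction"]]
    lo = stable_low.table[["gene_a", "gene_b", "direction"]]
    merged = hi.merge(lo, on=["gene_a", "gene_b"], suffixes=("_high", "_low"))
    rev = merged[merged["direction_high"] != merged["direction_low"]]
    out = []
    for row in rev.itertuples(index=False):
        if row.direction_high == "a_gt_b":
            out.append(DirectedGenePair(gene_high=row.gene_a, gene_low=row.gene_b))
        else:
            out.append(DirectedGenePair(gene_high=row.gene_b, gene_low=row.gene_a))
    return sorted(out)


def intersect_cohort_reversals(reversals_a: Sequence[DirectedGenePair],
                               reversals_b: Sequence[DirectedGenePair]
                               ) -> tuple[list[DirectedGenePair], float, float]:
    """Cross-cohort agreement of reversal pairs.

    Returns (orientation-consistent shared pairs, concordance = fraction of
    shared pairs with identical orientation, two-sided exact binomial p of
    the concordant count against 0.5). With no shared pairs the concordance
    is NaN and p is 1.
    """
    map_a = {p.canonical: p for p in reversals_a}
    map_b = {p.canonical: p for p in reversals_b}
    shared = sorted(set(map_a) & set(map_b))
    if not shared:
        return [], float("nan"), 1.0
    consistent = [map_a[c] for c in shared if map_a[c] == map_b[c]]
    n_conc = len(consistent)
    concordance = n_conc / len(shared)
    binom_p = float(stats.binomtest(n_conc, len(shared), 0.5,
                                    alternative="two-sided").pvalue)
    return sorted(consistent), concordance, binom_p
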