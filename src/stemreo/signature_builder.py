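"""Building, applying and evaluating the gene-pair voting signature.

Candidate reversal pairs are screened for prognostic value (univariate Cox
on the binary within-sample vote, BH-FDR), ranked by Harrell's C-index,
and combined by a greedy forward search that accepts a pair only when it
strictly improves the training C-index of the half-voting classifier.
Classification of a sample uses nothing but that sample's own expression
vector — the property that makes the signature individualized and immune
to cohort composition and to any within-sample monotone distortion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .datatypes import (
    DirectedGenePair,
    InputError,
    Signature,
    SurvivalRecord,
    VoteResult,
    check_expression_matrix,
)
from . import survival_stats as ss

log = logging.getLogger(__name__)


def vote_matrix(exprs: pd.DataFrame | Sequence[pd.DataFrame],
                pairs: Sequence[DirectedGenePair]) -> pd.DataFrame:
    """Binary high-risk votes, one row per pair, one column per sample.

    1.0 where E(gene_high) > E(gene_low), 0.0 where lower; NaN where either
    gene is missing from that matrix or the two values are exactly tied.
    Votes from several matrices (cohorts/platforms) are concatenated; votes
    are within-sample quantities, so matrices never need to be comparable.
    """
    if isinstance(exprs, pd.DataFrame):
        exprs = [exprs]
    if not pairs:
        raise InputError("no gene pairs supplied")
    cols = []
    for expr in exprs:
        expr = check_expression_matrix(expr)
        block = np.full((len(pairs), expr.shape[1]), np.nan)
        index = expr.index
        for i, p in enumerate(pairs):
            if p.gene_high in index and p.gene_low in index:
                hi = expr.loc[p.gene_high].to_numpy(float)
                lo = expr.loc[p.gene_low].to_numpy(float)
                with np.errstate(invalid="ignore"):
                    v = np.where(hi > lo, 1.0, np.where(hi < lo, 0.0, np.nan))
                block[i] = v
        cols.append(pd.DataFrame(block, columns=expr.columns))
    out = pd.concat(cols, axis=1)
    out.index = pd.RangeIndex(len(pairs))
    if out.columns.has_duplicates:
        raise InputError("duplicate sample identifiers across matrices")
    return out


def half_vote_labels(votes: pd.DataFrame) -> pd.Series:
    """Half-voting rule on a vote matrix: high iff votes_high >= usable/2.

    Samples with zero usable pairs get NaN (unclassifiable).
    """
    v = votes.to_numpy(float)
    usable = np.isfinite(v).sum(axis=0)
    high = np.nansum(v, axis=0)
    with np.errstate(invalid="ignore"):
        lab = np.where(usable == 0, np.nan, (2 * high >= usable).astype(float))
    return pd.Series(lab, index=votes.columns, name="label")


@dataclass
class CandidateTable:
    """Prognosis-screened reversal pairs, ranked for the forward search.

    ``table`` columns: gene_high, gene_low, coef, hr, p, fdr, c_index;
    sorted by descending C-index, ties broken by smaller Cox p then
    lexicographic pair id. ``status`` distinguishes an empty result
    ('no_candidates') from a populated one ('ok').
    """

    table: pd.DataFrame
    n_input: int
    n_tested: int
    status: str = "ok"

    @property
    def pairs(self) -> list[DirectedGenePair]:
        return [DirectedGenePair(h, l)
                for h, l in zip(self.table["gene_high"], self.table["gene_low"])]

    def __len__(self) -> int:
        return len(self.table)


def filter_prognostic_pairs(pairs: Sequence[DirectedGenePair],
                            exprs: pd.DataFrame | Sequence[pd.DataFrame],
                            records: Sequence[SurvivalRecord],
                            fdr_threshold: float = 0.05,
                            surgery_only: bool = True) -> CandidateTable:
    """Screen reversal pairs for association with overall survival.

    Restricts to surgery-only samples when flagged, fits a univariate Cox
    model on each pair's binary vote, BH-adjusts across pairs, keeps pairs
    with FDR below the threshold, and ranks them by per-pair C-index
    (descending; ties by smaller Cox p, then pair id).
    """
    if not pairs:
        return CandidateTable(table=_empty_candidates(), n_input=0, n_tested=0,
                              status="no_candidates")
    recs = list(records)
    if surgery_only:
        recs = [r for r in recs if r.surgery_only]
        if not recs:
            raise InputError("no surgery-only samples available")
    votes = vote_matrix(exprs, pairs)
    sample_ids = [r.sample_id for r in recs]
    missing = set(sample_ids) - set(votes.columns)
    if missing:
        raise InputError(f"records without expression data: {sorted(missing)[:5]}")
    v = votes[sample_ids].to_numpy(float)
    times = np.array([r.time for r in recs])
    events = np.array([r.event for r in recs])

    # pairs with any unusable vote are re-fitted on their complete samples
    complete = np.isfinite(v).all(axis=1)
    coef = np.full(len(pairs), np.nan)
    pval = np.full(len(pairs), np.nan)
    if complete.any():
        fit = ss.batch_binary_cox(times, events, v[complete])
        coef[complete] = fit["coef"].to_numpy()
        pval[complete] = fit["p"].to_numpy()
    for i in np.where(~complete)[0]:
        ok = np.isfinite(v[i])
        if ok.sum() < 2 or events[ok].sum() == 0 or len(np.unique(v[i, ok])) < 2:
            continue
        fit = ss.batch_binary_cox(times[ok], events[ok], v[i:i + 1, ok])
        coef[i], pval[i] = fit.loc[0, "coef"], fit.loc[0, "p"]

    tested = np.isfinite(pval)
    n_tested = int(tested.sum())
    fdr = np.full(len(pairs), np.nan)
    if n_tested:
        fdr[tested] = multipletests(pval[tested], method="fdr_bh")[1]
    keep = tested & (fdr < fdr_threshold)
    log.info("prognostic screen: %d pairs in, %d tested, %d pass FDR<%g",
             len(pairs), n_tested, int(keep.sum()), fdr_threshold)
    if not keep.any():
        return CandidateTable(table=_empty_candidates(), n_input=len(pairs),
                              n_tested=n_tested, status="no_candidates")

    keep_idx = np.where(keep)[0]
    cis = np.full(len(pairs), np.nan)
    fast = keep_idx[complete[keep_idx]]
    if len(fast):
        try:
            cis[fast] = ss.batch_binary_c_index(times, events, v[fast])
            slow = keep_idx[~complete[keep_idx]]
        except InputError:  # tied times: generic path for everything
            slow = keep_idx
    else:
        slow = keep_idx[~complete[keep_idx]]
    for i in slow:
        ok = np.isfinite(v[i])
        cis[i] = ss.c_index([recs[j] for j in np.where(ok)[0]], v[i, ok])

    rows = []
    for i in keep_idx:
        p = pairs[i]
        rows.append((p.gene_high, p.gene_low, coef[i], float(np.exp(coef[i])),
                     pval[i], fdr[i], cis[i]))
    table = pd.DataFrame(rows, columns=["gene_high", "gene_low", "coef", "hr",
                                        "p", "fdr", "c_index"])
    table = table.sort_values(by=["c_index", "p", "gene_high", "gene_low"],
                              ascending=[False, True, True, True],
                              kind="stable").reset_index(drop=True)
    return CandidateTable(table=table, n_input=len(pairs), n_tested=n_tested)


def _empty_candidates() -> pd.DataFrame:
    return pd.DataFrame(columns=["gene_high", "gene_low", "coef", "hr", "p",
                                 "fdr", "c_index"])


def forward_search(candidates: CandidateTable | Sequence[DirectedGenePair],
                   exprs: pd.DataFrame | Sequence[pd.DataFrame],
                   records: Sequence[SurvivalRecord],
                   surgery_only: bool = True,
                   use_vote_fraction: bool = False,
                   tol: float = 1e-9,
                   provenance: dict | None = None) -> Signature:
    """Greedy forward selection of gene pairs maximizing the training C-index.

    Starting from the top-ranked pair, candidates are traversed in rank
    order; each is kept only if adding it strictly increases (by more than
    ``tol``) the C-index of the half-voting classifier on the training
    samples. By default the C-index is computed on the binary high/low
    label; ``use_vote_fraction`` switches to the continuous vote fraction.
    """
    pairs = candidates.pairs if isinstance(candidates, CandidateTable) else list(candidates)
    if not pairs:
        raise InputError("forward search requires at least one candidate pair")
    recs = list(records)
    if surgery_only:
        recs = [r for r in recs if r.surgery_only]
    if not recs:
        raise InputError("no training samples after filtering")
    votes = vote_matrix(exprs, pairs)
    sample_ids = [r.sample_id for r in recs]
    v = votes[sample_ids]
    va = v.to_numpy(float)
    times = np.array([r.time for r in recs])
    events = np.array([r.event for r in recs])

    def score(idx: list[int]) -> float:
        sub = v.iloc[idx]
        if use_vote_fraction:
            arr = sub.to_numpy(float)
            usable = np.isfinite(arr).sum(axis=0)
            risk = np.where(usable == 0, np.nan, np.nansum(arr, axis=0) / np.maximum(usable, 1))
        else:
            risk = half_vote_labels(sub).to_numpy()
        return ss.c_index(recs, risk)

    fast = (not use_vote_fraction and np.isfinite(va).all()
            and len(np.unique(times)) == len(times))
    selected = [0]
    best = score(selected)
    path = [best]
    if fast:
        # pass-based greedy: trial labels for every remaining candidate are
        # scored in one vectorized sweep; semantics identical to the
        # one-at-a-time traversal in rank order
        sum_votes = va[0].copy()
        j = 1
        while j < len(pairs):
            cand = np.arange(j, len(pairs))
            lab = (2.0 * (sum_votes[None, :] + va[cand])
                   >= (len(selected) + 1)).astype(float)
            cs = ss.batch_binary_c_index(times, events, lab)
            better = np.where(cs > best + tol)[0]
            if len(better) == 0:
                break
            take = int(cand[better[0]])
            selected.append(take)
            sum_votes += va[take]
            best = float(cs[better[0]])
            path.append(best)
            j = take + 1
    else:
        for j in range(1, len(pairs)):
            trial = score(selected + [j])
            if trial > best + tol:
                selected.append(j)
                best = trial
                path.append(best)
    log.info("forward search: %d candidates -> %d selected, C-index %.4f",
             len(pairs), len(selected), best)
    return Signature(pairs=[pairs[i] for i in selected], c_index_train=best,
                     c_index_path=path, provenance=provenance or {})


def classify(sample: pd.Series, signature: Signature,
             sample_id: str | None = None) -> VoteResult:
    """Half-voting classification of one sample from its own expression only.

    Pairs with a missing gene or exactly tied values are skipped (reducing
    the usable total); a sample with zero usable pairs is unclassifiable
    (label None), which is distinct from low risk.
    """
    sid = sample_id if sample_id is not None else str(sample.name)
    votes = [p.vote(sample) for p in signature.pairs]
    usable = [x for x in votes if x is not None]
    votes_high = sum(usable)
    total = len(usable)
    if total == 0:
        return VoteResult(sample_id=sid, votes_high=0, votes_total=0, label=None)
    label = "high" if 2 * votes_high >= total else "low"
    return VoteResult(sample_id=sid, votes_high=votes_high, votes_total=total,
                      label=label)


def classify_matrix(expr: pd.DataFrame, signature: Signature) -> pd.DataFrame:
    """Classify every column of a matrix, one sample at a time."""
    expr = check_expression_matrix(expr)
    rows = []
    for col in expr.columns:
        r = classify(expr[col], signature, sample_id=str(col))
        rows.append((r.sample_id, r.votes_high, r.votes_total, r.vote_fraction,
                     r.label))
    return pd.DataFrame(rows, columns=["sample_id", "votes_high", "votes_total",
                                       "vote_fraction", "label"]).set_index("sample_id")


@dataclass
class SignatureReport:
    """Evaluation of a signature on one dataset."""

    labels: pd.DataFrame
    n_high: int
    n_low: int
    n_unclassifiable: int
    c_index: float
    logrank_statistic: float
    logrank_p: float
    km: "ss.KmResult"
    cox_univariate: "ss.CoxFit | None"
    cox_multivariate: "ss.CoxFit | None"


def evaluate_signature(signature: Signature, expr: pd.DataFrame | Sequence[pd.DataFrame],
                       records: Sequence[SurvivalRecord],
                       adjust_covariates: Sequence[str] = ()) -> SignatureReport:
    """Classify each sample individually and report survival separation.

    Reports Kaplan–Meier curves and the log-rank test between predicted
    groups, the C-index of the binary label, and uni-/multivariate Cox fits
    of the label (the latter adjusted for ``adjust_covariates`` when
    available in the records).
    """
    if isinstance(expr, pd.DataFrame):
        exprs = [expr]
    else:
        exprs = list(expr)
    labels = pd.concat([classify_matrix(e, signature) for e in exprs])
    recs = [r for r in records if r.sample_id in labels.index]
    if not recs:
        raise InputError("no records match the classified samples")
    lab = labels.loc[[r.sample_id for r in recs], "label"]
    ok = lab.notna().to_numpy()
    recs_ok = [r for r, o in zip(recs, ok) if o]
    lab_ok = lab[ok]
    risk = (lab_ok == "high").astype(float).to_numpy()

    km = ss.km_curve(recs_ok, lab_ok) if lab_ok.nunique() > 1 else None
    ci = ss.c_index(recs_ok, risk)

    aug = [SurvivalRecord(sample_id=r.sample_id, time=r.time, event=r.event,
                          covariates={**r.covariates, "signature_high": float(v)},
                          cohort=r.cohort, surgery_only=r.surgery_only)
           for r, v in zip(recs_ok, risk)]
    cox_uni = cox_multi = None
    if lab_ok.nunique() > 1:
        cox_uni = ss.cox_fit(aug, ["signature_high"])
        extra = [c for c in adjust_covariates
                 if all(c in r.covariates for r in recs_ok)]
        if extra:
            cox_multi = ss.cox_fit(aug, ["signature_high", *extra])
    return SignatureReport(
        labels=labels,
        n_high=int((labels["label"] == "high").sum()),
        n_low=int((labels["label"] == "low").sum()),
        n_unclassifiable=int(labels["label"].isna().sum()),
        c_index=ci,
        logrank_statistic=km.statistic if km else float("nan"),
        logrank_p=km.p_value if km else float("nan"),
        km=km,
        cox_univariate=cox_uni,
        cox_multivariate=cox_multi)
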