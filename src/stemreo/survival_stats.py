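"""Survival analysis: Kaplan–Meier, log-rank, Cox PH, Harrell's C-index.

General model fitting is delegated to lifelines (Efron handling of tied
event times). A vectorized Newton solver for the special case of a single
binary covariate is provided for screening thousands of candidate gene
pairs at once; it maximizes the same Efron partial likelihood and is
cross-checked against lifelines in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test, multivariate_logrank_test
from lifelines.utils import concordance_index

from .datatypes import CoxFit, InputError, SurvivalRecord, records_to_frame


@dataclass
class KmResult:
    """Kaplan–Meier curves per group plus the log-rank test."""

    curves: dict[str, pd.DataFrame]   # columns: time, survival
    statistic: float
    p_value: float
    group_sizes: dict[str, int]


def _records_arrays(records: Sequence[SurvivalRecord]) -> tuple[np.ndarray, np.ndarray]:
    t = np.array([r.time for r in records], dtype=float)
    e = np.array([r.event for r in records], dtype=int)
    return t, e


def km_curve(records: Sequence[SurvivalRecord],
             group: Sequence[str] | pd.Series) -> KmResult:
    """Product-limit survival estimate per group and the log-rank test.

    With exactly two groups the classical 1-df two-sample log-rank test is
    reported; with more, the k-sample generalization.
    """
    if len(records) == 0:
        raise InputError("no survival records")
    t, e = _records_arrays(records)
    g = np.asarray(pd.Series(list(group)).astype(str))
    if len(g) != len(records):
        raise InputError("group labels must align with records")
    if e.sum() == 0:
        raise InputError("log-rank requires at least one observed event")
    labels = sorted(set(g))
    if any((g == lab).sum() == 0 for lab in labels):
        raise InputError("every group must contain at least one sample")

    curves = {}
    for lab in labels:
        m = g == lab
        kmf = KaplanMeierFitter()
        kmf.fit(t[m], e[m], label=lab)
        sf = kmf.survival_function_
        curves[lab] = pd.DataFrame({"time": sf.index.to_numpy(),
                                    "survival": sf[lab].to_numpy()})
    if len(labels) == 1:
        stat, p = 0.0, 1.0
    elif len(labels) == 2:
        m = g == labels[0]
        res = logrank_test(t[m], t[~m], e[m], e[~m])
        stat, p = float(res.test_statistic), float(res.p_value)
    else:
        res = multivariate_logrank_test(t, g, e)
        stat, p = float(res.test_statistic), float(res.p_value)
    return KmResult(curves=curves, statistic=stat, p_value=p,
                    group_sizes={lab: int((g == lab).sum()) for lab in labels})


def cox_fit(records: Sequence[SurvivalRecord],
            covariate_names: Sequence[str]) -> CoxFit:
    """Cox proportional-hazards fit by partial likelihood (Efron ties).

    Non-convergence (e.g. complete separation) yields a flagged fit with
    ``converged=False`` and the diagnostic message, never a silent result.
    """
    if not covariate_names:
        raise InputError("at least one covariate is required")
    df = records_to_frame(records)
    missing = [c for c in covariate_names if c not in df.columns]
    if missing:
        raise InputError(f"covariates absent from records: {missing}")
    sub = df[["time", "event", *covariate_names]].dropna()
    if sub["event"].sum() == 0:
        raise InputError("Cox fit requires at least one observed event")
    for c in covariate_names:
        if sub[c].nunique() < 2:
            raise InputError(f"covariate {c!r} is constant")

    cph = CoxPHFitter()
    converged, msg = True, ""
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            cph.fit(sub, duration_col="time", event_col="event")
        conv_warnings = [str(w.message) for w in caught
                         if "converg" in str(w.message).lower()]
        if conv_warnings:
            converged, msg = False, "; ".join(conv_warnings)
    except ConvergenceError as exc:
        nan = pd.Series(np.nan, index=list(covariate_names))
        return CoxFit(coef=nan, hazard_ratio=nan, se=nan, p_value=nan,
                      n_events=int(sub["event"].sum()),
                      converged=False, message=str(exc))
    summ = cph.summary
    return CoxFit(coef=summ["coef"], hazard_ratio=summ["exp(coef)"],
                  se=summ["se(coef)"], p_value=summ["p"],
                  n_events=int(sub["event"].sum()), converged=converged, message=msg)


def c_index(records: Sequence[SurvivalRecord],
            risk_score: Sequence[float]) -> float:
    """Harrell's concordance index of a risk score.

    Over all comparable pairs (the sample with the shorter time had an
    event), the fraction in which the higher risk score belongs to the
    shorter survival; tied scores count 0.5. Samples with a missing risk
    score are dropped.
    """
    t, e = _records_arrays(records)
    r = np.asarray(list(risk_score), dtype=float)
    if len(r) != len(t):
        raise InputError("risk scores must align with records")
    ok = np.isfinite(r)
    t, e, r = t[ok], e[ok], r[ok]
    try:
        # lifelines scores concordance of predicted *survival*; negate risk
        return float(concordance_index(t, -r, e))
    except ZeroDivisionError as exc:
        raise InputError("no comparable pairs for the C-index") from exc


def batch_binary_c_index(times: np.ndarray, events: np.ndarray,
                         risk: np.ndarray) -> np.ndarray:
    """Harrell's C for many binary risk vectors at once.

    ``risk`` is (n_scores, n_samples) with values in {0, 1}. Valid only for
    untied event times (the generic :func:`c_index` handles ties); raises
    otherwise. Agrees exactly with :func:`c_index` on such data.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    risk = np.atleast_2d(np.asarray(risk, float))
    if len(np.unique(times)) != len(times):
        raise InputError("batch_binary_c_index requires untied times")
    order = np.argsort(times, kind="stable")
    e_s = events[order]
    x = risk[:, order]

    # suffix counts of x==1 / x==0 among strictly-later samples
    later1 = np.concatenate([np.cumsum(x[:, ::-1], axis=1)[:, ::-1][:, 1:],
                             np.zeros((x.shape[0], 1))], axis=1)
    n_later = np.arange(len(times) - 1, -1, -1, dtype=float)[None, :]
    later0 = n_later - later1

    ev = (e_s == 1)[None, :]
    conc = np.where(ev & (x == 1), later0, 0.0).sum(axis=1)
    ties = np.where(ev, np.where(x == 1, later1, later0), 0.0).sum(axis=1)
    comparable = (ev * n_later).sum(axis=1)
    if np.any(comparable == 0):
        raise InputError("no comparable pairs for the C-index")
    return (conc + 0.5 * ties) / comparable


# ---------------------------------------------------------------------------
# batch univariate Cox for binary covariates (candidate-pair screening)

def batch_binary_cox(times: np.ndarray, events: np.ndarray, x: np.ndarray,
                     max_iter: int = 25, tol: float = 1e-9
                     ) -> pd.DataFrame:
    """Univariate Cox fits for many binary covariates simultaneously.

    ``x`` is (n_covariates, n_samples) with values in {0, 1}. Each row is
    fitted as its own univariate Cox model by Newton iteration on the Efron
    partial likelihood (identical to the per-covariate lifelines fit).
    Returns a DataFrame with coef, se, p (Wald), converged per covariate;
    degenerate covariates (constant) yield NaN coefficients.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    x = np.atleast_2d(np.asarray(x, float))
    n_cov, n = x.shape
    if len(times) != n or len(events) != n:
        raise InputError("times/events must align with covariate columns")

    order = np.argsort(times, kind="stable")
    t_s, e_s = times[order], events[order]
    xs = x[:, order]

    # risk set counts of x=1 members at each position (suffix sums)
    rev_c1 = np.cumsum(xs[:, ::-1], axis=1)[:, ::-1]          # (P, n) sum_{j>=i} x_j
    rev_n = np.arange(n, 0, -1, dtype=float)                  # |risk set| at position i

    # group tied event times
    ev_idx = np.where(e_s == 1)[0]
    if len(ev_idx) == 0:
        raise InputError("no observed events")
    ev_t = t_s[ev_idx]
    # first position of each tied-event-time block
    starts = np.where(np.r_[True, ev_t[1:] != ev_t[:-1]])[0]
    blocks = np.split(ev_idx, starts[1:])

    # anchor each block at the leftmost sample sharing its time, so censored
    # samples tied with an event time stay in the risk set
    g_first = np.searchsorted(t_s, t_s[[b[0] for b in blocks]], side="left")
    d = np.array([len(b) for b in blocks], dtype=float)       # ties per block
    d1 = np.stack([xs[:, b].sum(axis=1) for b in blocks], axis=1)  # (P, B) events w/ x=1
    n1 = rev_c1[:, g_first]                                   # (P, B) risk-set x=1 count
    n_tot = rev_n[g_first]                                    # (B,)
    maxd = int(d.max())
    l_over_d = (np.arange(maxd)[None, :] / d[:, None])        # (B, maxd)
    valid_l = np.arange(maxd)[None, :] < d[:, None]           # (B, maxd)

    beta = np.zeros(n_cov)
    variable = (x.min(axis=1) == 0) & (x.max(axis=1) == 1)
    converged = np.zeros(n_cov, dtype=bool)
    active = variable.copy()

    for _ in range(max_iter):
        if not active.any():
            break
        th = np.exp(beta[active])[:, None]                    # (P', 1)
        n1a, d1a = n1[active], d1[active]
        s0 = (n_tot[None, :] - n1a) + th * n1a                # Σ θ^x over risk set
        s1 = th * n1a
        s0d = (d[None, :] - d1a) + th * d1a                   # over the tied event set
        s1d = th * d1a
        # Efron: for l = 0..d-1 subtract (l/d) * event-set sums
        S0 = s0[:, :, None] - l_over_d[None, :, :] * s0d[:, :, None]
        S1 = s1[:, :, None] - l_over_d[None, :, :] * s1d[:, :, None]
        S2 = S1  # x in {0,1} -> x^2 = x
        S0safe = np.where(valid_l[None], S0, 1.0)
        ratio1 = np.where(valid_l[None], S1 / S0safe, 0.0)
        ratio2 = np.where(valid_l[None], S2 / S0safe - (S1 / S0safe) ** 2, 0.0)
        U = d1a.sum(axis=1) - ratio1.sum(axis=(1, 2))
        I = ratio2.sum(axis=(1, 2))
        step = np.where(I > 0, U / np.maximum(I, 1e-300), 0.0)
        step = np.clip(step, -5.0, 5.0)
        beta[active] += step
        done = np.abs(step) < tol
        idx_active = np.where(active)[0]
        converged[idx_active[done]] = True
        active[idx_active[done]] = False

    # final information for SE at the fitted beta
    th = np.exp(beta)[:, None]
    s0 = (n_tot[None, :] - n1) + th * n1
    s1 = th * n1
    s0d = (d[None, :] - d1) + th * d1
    s1d = th * d1
    S0 = s0[:, :, None] - l_over_d[None, :, :] * s0d[:, :, None]
    S1 = s1[:, :, None] - l_over_d[None, :, :] * s1d[:, :, None]
    S0safe = np.where(valid_l[None], S0, 1.0)
    ratio2 = np.where(valid_l[None], S1 / S0safe - (S1 / S0safe) ** 2, 0.0)
    info = ratio2.sum(axis=(1, 2))
    se = np.where(info > 0, 1.0 / np.sqrt(np.maximum(info, 1e-300)), np.nan)
    z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))

    out = pd.DataFrame({"coef": beta, "se": se, "p": p, "converged": converged})
    out.loc[~variable, ["coef", "se", "p"]] = np.nan
    out.loc[~variable, "converged"] = False
    return out
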