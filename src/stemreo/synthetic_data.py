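"""Synthetic single-cell and bulk cohorts with known planted structure.

Every downstream stage of the pipeline is exercised against data produced
here, where the ground truth — which genes track stemness, which gene pairs
reverse their within-sample ordering between risk subtypes, and which
subtype each sample belongs to — is known exactly.

Expression is generated on a log2-like scale (per-gene baseline plus
planted effects plus Gaussian noise), floored at zero, then exponentiated
for output, so values resemble linear-scale microarray/RNA-seq intensities.
Within-sample orderings are identical on either scale. Two kinds of batch
distortion are available: a strictly increasing per-sample map
``x -> a * x**b + c`` (REO-preserving — the regime the signature is designed
to survive) and per-cohort per-gene offsets (REO-perturbing across cohorts).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    ConfigError,
    DirectedGenePair,
    StemnessProfile,
    SurvivalRecord,
)

BATCH_MODES = ("monotone_per_sample", "genewise_shift", "both", "none")


@dataclass
class SyntheticConfig:
    """Parameters of the generative model.

    Defaults correspond to the simulation conditions used throughout the
    package's validation runs: two cohorts of 150 samples over 1000 genes
    with 60 planted reversal pairs at a log2 gap of three noise SDs, a
    hazard ratio of 2.5 between subtypes, and REO-preserving per-sample
    batch distortion.
    """

    n_genes: int = 1000
    n_cells: int = 500
    frac_malignant: float = 0.5
    n_stem_genes: int = 50
    stem_effect: float = 2.0
    malignant_shift: float = 1.0
    n_cohorts: int = 2
    n_samples_per_cohort: int = 150
    n_planted_pairs: int = 60
    delta: float = 1.5
    sigma: float = 0.5
    subtype_prevalence: float = 0.5
    hazard_ratio: float = 2.5
    baseline_scale: float = 60.0
    censor_max: float = 120.0
    batch_mode: str = "monotone_per_sample"
    genewise_shift_sd: float = 0.5
    frac_surgery_only: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        counts = ("n_genes", "n_cells", "n_stem_genes", "n_cohorts",
                  "n_samples_per_cohort", "n_planted_pairs")
        for name in counts:
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ConfigError(f"{name} must be a nonnegative integer, got {v!r}")
        if self.n_genes < 1 or self.n_cells < 0:
            raise ConfigError("n_genes must be >= 1")
        for name in ("frac_malignant", "subtype_prevalence", "frac_surgery_only"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ConfigError(f"{name} must lie in (0, 1), got {v!r}")
        for name in ("delta", "sigma", "hazard_ratio", "baseline_scale", "censor_max"):
            v = getattr(self, name)
            if not v > 0:
                raise ConfigError(f"{name} must be positive, got {v!r}")
        for name in ("stem_effect", "malignant_shift", "genewise_shift_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be nonnegative")
        if self.n_stem_genes > self.n_genes:
            raise ConfigError("n_stem_genes must not exceed n_genes")
        if self.n_stem_genes + 2 * self.n_planted_pairs > self.n_genes:
            raise ConfigError(
                "n_stem_genes + 2*n_planted_pairs exceeds n_genes: planted pair "
                "genes and stem genes are disjoint")
        if self.batch_mode not in BATCH_MODES:
            raise ConfigError(f"batch_mode must be one of {BATCH_MODES}, got {self.batch_mode!r}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticTruth:
    """Ground truth planted by the generators."""

    stem_gene_ids: list[str]
    planted_pairs: list[DirectedGenePair]
    sample_subtype: dict[str, str] = field(default_factory=dict)
    cell_stemness: dict[str, float] = field(default_factory=dict)
    cell_malignant: dict[str, bool] = field(default_factory=dict)
    # population-level structure, reused when drawing further cohorts
    gene_baselines: dict[str, float] = field(default_factory=dict)
    pair_centers: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "stem_gene_ids": self.stem_gene_ids,
            "planted_pairs": [[p.gene_high, p.gene_low] for p in self.planted_pairs],
            "sample_subtype": self.sample_subtype,
            "cell_stemness": self.cell_stemness,
            "cell_malignant": self.cell_malignant,
            "gene_baselines": self.gene_baselines,
            "pair_centers": self.pair_centers,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticTruth":
        return cls(
            stem_gene_ids=list(d["stem_gene_ids"]),
            planted_pairs=[DirectedGenePair(h, l) for h, l in d["planted_pairs"]],
            sample_subtype=dict(d.get("sample_subtype", {})),
            cell_stemness={k: float(v) for k, v in d.get("cell_stemness", {}).items()},
            cell_malignant={k: bool(v) for k, v in d.get("cell_malignant", {}).items()},
            gene_baselines={k: float(v) for k, v in d.get("gene_baselines", {}).items()},
            pair_centers=[float(v) for v in d.get("pair_centers", [])],
        )


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def _plant_structure(config: SyntheticConfig, rng: np.random.Generator
                     ) -> tuple[list[str], list[str], list[DirectedGenePair]]:
    """Choose disjoint stem genes and planted-pair genes."""
    genes = _gene_ids(config.n_genes)
    perm = rng.permutation(config.n_genes)
    stem = sorted(genes[i] for i in perm[: config.n_stem_genes])
    pair_idx = perm[config.n_stem_genes: config.n_stem_genes + 2 * config.n_planted_pairs]
    pairs = []
    for j in range(config.n_planted_pairs):
        a, b = genes[pair_idx[2 * j]], genes[pair_idx[2 * j + 1]]
        pairs.append(DirectedGenePair(gene_high=a, gene_low=b))
    return genes, stem, pairs


def _jitter(rng: np.random.Generator, shape) -> np.ndarray:
    # tie-breaking jitter, far below any planted effect
    return rng.uniform(0.0, 1e-9, size=shape)


def monotone_distort(values: np.ndarray, a: float, b: float, c: float) -> np.ndarray:
    """Strictly increasing map x -> a*x**b + c on nonnegative values (a, b > 0, c >= 0)."""
    if a <= 0 or b <= 0 or c < 0:
        raise ConfigError("monotone_distort requires a, b > 0 and c >= 0")
    return a * np.power(values, b) + c


def simulate_single_cell(config: SyntheticConfig
                         ) -> tuple[pd.DataFrame, StemnessProfile, SyntheticTruth]:
    """Generate a gene × cell matrix with a planted stemness programme.

    Stem genes increase linearly (on the log2 scale, slope ``stem_effect``)
    with a latent per-cell stemness score and are additionally shifted up by
    ``malignant_shift`` in malignant cells; all other genes are independent
    of both. Malignant cells draw stemness from a right-skewed Beta(4, 2),
    non-malignant cells from Beta(2, 4).
    """
    config.validate()
    if config.n_cells < 4:
        raise ConfigError("n_cells must be at least 4 (>=2 cells per group)")
    ss = np.random.SeedSequence(config.seed)
    r_struct, r_cells, r_noise = (np.random.default_rng(s) for s in ss.spawn(3))

    genes, stem_genes, planted_pairs = _plant_structure(config, r_struct)
    n_mal = int(round(config.frac_malignant * config.n_cells))
    n_mal = min(max(n_mal, 2), config.n_cells - 2)
    malignant = np.zeros(config.n_cells, dtype=bool)
    malignant[r_cells.permutation(config.n_cells)[:n_mal]] = True
    stemness = np.where(malignant,
                        r_cells.beta(4.0, 2.0, size=config.n_cells),
                        r_cells.beta(2.0, 4.0, size=config.n_cells))

    cells = [f"cell{i:05d}" for i in range(1, config.n_cells + 1)]
    base = r_struct.uniform(3.0, 8.0, size=config.n_genes)
    log_expr = base[:, None] + r_noise.normal(0.0, config.sigma,
                                              size=(config.n_genes, config.n_cells))
    stem_mask = np.isin(genes, stem_genes)
    log_expr[stem_mask] += config.stem_effect * stemness[None, :]
    log_expr[stem_mask] += config.malignant_shift * malignant[None, :].astype(float)
    log_expr = np.maximum(log_expr, 0.0) + _jitter(r_noise, log_expr.shape)

    expr = pd.DataFrame(np.exp2(log_expr), index=pd.Index(genes, name="gene_id"),
                        columns=pd.Index(cells, name="cell_id"))
    profile = StemnessProfile(
        stemness=pd.Series(stemness, index=expr.columns),
        malignant=pd.Series(malignant, index=expr.columns))
    truth = SyntheticTruth(
        stem_gene_ids=stem_genes,
        planted_pairs=planted_pairs,
        cell_stemness=dict(zip(cells, map(float, stemness))),
        cell_malignant=dict(zip(cells, map(bool, malignant))))
    return expr, profile, truth


def simulate_bulk_cohorts(config: SyntheticConfig, truth: SyntheticTruth | None = None
                          ) -> tuple[list[pd.DataFrame], list[list[SurvivalRecord]], SyntheticTruth]:
    """Generate bulk cohorts with planted subtypes, reversal pairs and survival.

    Each sample is 'high' risk with probability ``subtype_prevalence``. For a
    planted pair (a, b), the mean log2 expression of a exceeds b's by
    ``delta`` in high-risk samples and b exceeds a by ``delta`` in low-risk
    samples (both genes share a fixed per-pair baseline center). Stem genes
    are shifted up by ``delta`` in high-risk samples, so the single-sample
    enrichment of the stem gene set tracks the subtype. Survival is
    exponential with hazard multiplied by ``hazard_ratio`` for high-risk
    samples, censored uniformly on (0, censor_max). Per-gene baseline means
    are population-level structure shared by every cohort; cohort-specific
    distortion comes only from ``batch_mode`` (per-sample monotone maps
    and/or per-cohort gene-wise offsets).

    Pass ``truth`` from a previous call to reuse the planted structure and
    baselines (e.g. to draw an independent held-out cohort from the same
    population).
    """
    config.validate()
    if config.n_cohorts < 1 or config.n_samples_per_cohort < 2:
        raise ConfigError("need n_cohorts >= 1 and n_samples_per_cohort >= 2")
    ss = np.random.SeedSequence(config.seed)
    r_struct, r_assign, r_noise, r_surv, r_batch = (
        np.random.default_rng(s) for s in ss.spawn(5))

    genes = _gene_ids(config.n_genes)
    if truth is None:
        genes, stem_genes, planted_pairs = _plant_structure(config, r_struct)
        base = r_struct.uniform(3.0, 8.0, size=config.n_genes)
        centers = r_struct.uniform(3.0, 8.0, size=len(planted_pairs))
    else:
        stem_genes = list(truth.stem_gene_ids)
        planted_pairs = list(truth.planted_pairs)
        known = set(stem_genes) | {g for p in planted_pairs for g in (p.gene_high, p.gene_low)}
        if not known <= set(genes):
            raise ConfigError("supplied truth references genes outside the configured universe")
        if len(truth.gene_baselines) != len(genes) or len(truth.pair_centers) != len(planted_pairs):
            raise ConfigError("supplied truth lacks baselines/centers for this gene universe")
        base = np.array([truth.gene_baselines[g] for g in genes])
        centers = np.asarray(truth.pair_centers, dtype=float)

    gene_pos = {g: i for i, g in enumerate(genes)}
    stem_idx = np.array([gene_pos[g] for g in stem_genes], dtype=int)
    hi_idx = np.array([gene_pos[p.gene_high] for p in planted_pairs], dtype=int)
    lo_idx = np.array([gene_pos[p.gene_low] for p in planted_pairs], dtype=int)

    exprs: list[pd.DataFrame] = []
    all_records: list[list[SurvivalRecord]] = []
    sample_subtype: dict[str, str] = {}
    lam0 = 1.0 / config.baseline_scale

    for c in range(config.n_cohorts):
        cohort = f"cohort{c + 1}"
        n = config.n_samples_per_cohort
        # seed in the id keeps samples from independent draws distinct
        samples = [f"{cohort}_r{config.seed}_S{i:04d}" for i in range(1, n + 1)]
        high = r_assign.random(n) < config.subtype_prevalence

        log_expr = base[:, None] + r_noise.normal(0.0, config.sigma,
                                                  size=(config.n_genes, n))
        # planted reversal pairs: both members share a center, split by ±delta/2,
        # sign flipped between subtypes
        if len(planted_pairs):
            sign = np.where(high, 1.0, -1.0)  # per sample
            half = config.delta / 2.0
            log_expr[hi_idx] = centers[:, None] + sign[None, :] * half + \
                r_noise.normal(0.0, config.sigma, size=(len(planted_pairs), n))
            log_expr[lo_idx] = centers[:, None] - sign[None, :] * half + \
                r_noise.normal(0.0, config.sigma, size=(len(planted_pairs), n))
        if len(stem_idx):
            log_expr[stem_idx[:, None], np.where(high)[0][None, :]] += config.delta

        if config.batch_mode in ("genewise_shift", "both"):
            log_expr += r_batch.normal(0.0, config.genewise_shift_sd,
                                       size=(config.n_genes, 1))
        log_expr = np.maximum(log_expr, 0.0) + _jitter(r_noise, log_expr.shape)
        values = np.exp2(log_expr)

        if config.batch_mode in ("monotone_per_sample", "both"):
            a = r_batch.uniform(0.5, 2.0, size=n)
            b = r_batch.uniform(0.8, 1.25, size=n)
            cc = r_batch.uniform(0.0, 1.0, size=n)
            values = a[None, :] * np.power(values, b[None, :]) + cc[None, :]

        expr = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"),
                            columns=pd.Index(samples, name="sample_id"))
        exprs.append(expr)

        lam = lam0 * np.where(high, config.hazard_ratio, 1.0)
        t_event = r_surv.exponential(1.0 / lam)
        t_cens = r_surv.uniform(0.0, config.censor_max, size=n)
        time = np.maximum(np.minimum(t_event, t_cens), 1e-6)
        event = (t_event <= t_cens).astype(int)
        surgery = r_surv.random(n) < config.frac_surgery_only

        records = [SurvivalRecord(sample_id=s, time=float(t), event=int(e),
                                  cohort=cohort, surgery_only=bool(so))
                   for s, t, e, so in zip(samples, time, event, surgery)]
        all_records.append(records)
        sample_subtype.update(zip(samples, np.where(high, "high", "low")))

    out_truth = SyntheticTruth(
        stem_gene_ids=stem_genes, planted_pairs=planted_pairs,
        sample_subtype=sample_subtype,
        cell_stemness=truth.cell_stemness if truth else {},
        cell_malignant=truth.cell_malignant if truth else {},
        gene_baselines=dict(zip(genes, map(float, base))),
        pair_centers=[float(c) for c in centers])
    return exprs, all_records, out_truth
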