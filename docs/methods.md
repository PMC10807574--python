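# Methods

`stemreo` builds individualized prognostic classifiers for bulk tumour
transcriptomes from the within-sample *relative expression ordering* (REO)
of gene pairs. Because a sample's classification depends only on which of
two genes is expressed higher *within that sample*, the classifier is
invariant to any strictly increasing per-sample transform of the data —
the regime covering most scaling, normalization and monotone batch
distortions — and can be applied to one patient at a time, with no cohort
context and no dataset-specific threshold.

## Pipeline model

1. **Stemness signature genes (single-cell).** Given a per-cell stemness
   score in [0, 1] (a CytoTRACE-style differentiation-potential estimate,
   supplied or synthetic) and malignancy labels, two gene lists are
   intersected: G1, genes with Pearson *r* > 0.2 (BH-FDR < 0.05) against
   the stemness score across malignant cells; and G2, genes upregulated in
   malignant vs non-malignant cells (two-sided Wilcoxon rank-sum,
   BH-FDR < 0.05, log2 fold change > 0.25 computed on pseudocount-1 group
   means). The correlation is restricted to malignant cells because the
   stemness gradient of interest is the one inside the malignant
   compartment; the DE comparison group is configurable.
2. **Single-sample enrichment and subtyping (bulk).** Each bulk sample is
   scored for the signature gene set with an ssGSEA statistic: genes are
   ranked by decreasing expression (ties broken by gene id), and the score
   is the summed difference between a rank-magnitude^tau-weighted in-set
   CDF and an unweighted out-of-set CDF (tau = 0.25 by default; tau = 0
   gives the unweighted Kolmogorov–Smirnov-like walk). Scores are *not*
   range-normalized across samples: only the within-cohort ordering is
   consumed by the median split, and omitting the normalization removes a
   cross-sample coupling. Each cohort is split at its median score;
   strictly-above-median samples are the high-risk subtype, ties go low
   (a fixed rule chosen for determinism).
3. **Stable and reversal gene pairs.** Within each subtype, a pair (i, j)
   is *stable* when one direction (Ei > Ej or Ei < Ej) recurs across
   samples more often than coin flips would allow: with k usable samples
   and s showing the majority direction, the p-value is the upper binomial
   tail P(X ≥ s), X ~ Binomial(k, 0.5), BH-adjusted across all tested
   pairs (FDR < 5%). Samples where the two values are exactly tied count
   for neither direction and reduce k for that pair. A *reversal* pair is
   stable in both subtypes with opposite directions; it is oriented so
   that observing E(gene_high) > E(gene_low) votes "high risk". Reversal
   pairs are detected per training cohort and intersected across cohorts,
   keeping only orientation-consistent pairs (agreement is reported with
   an exact two-sided binomial test against 0.5).
4. **Prognostic screening and forward search.** Each consistent reversal
   pair's binary vote is screened by univariate Cox regression on the
   pooled training samples (restricted to surgery-only cases by default,
   so treatment does not confound the association), BH-adjusted, and
   survivors are ranked by Harrell's C-index (descending; ties broken by
   smaller Cox p, then pair id). A single-pass greedy forward search
   walks the ranking, keeping a pair only when it strictly increases
   (> 1e-9) the training C-index of the half-voting classifier. No
   backward elimination and no re-ranking between acceptances.
5. **Half-voting classification.** A sample is labeled high risk iff at
   least half of the usable signature pairs vote high
   (votes_high ≥ votes_total/2, so an exact tie goes high). Pairs with a
   missing gene or tied values are skipped, reducing votes_total; a
   sample with zero usable pairs is *unclassifiable*, which is distinct
   from low risk. Evaluation reports Kaplan–Meier curves, the log-rank
   test between predicted groups, the C-index of the binary label, and
   uni-/multivariate Cox fits.

The evolving signature's C-index is computed on the binary high/low label
(classification precedes measurement); a continuous vote-fraction variant
is available via `use_vote_fraction=True`.

## Survival machinery

Kaplan–Meier estimation, the log-rank test, multi-covariate Cox fitting
(Efron handling of tied event times) and Harrell's C (tied scores count
0.5) are delegated to lifelines. Screening thousands of candidate pairs
needs thousands of univariate fits, so `batch_binary_cox` implements a
vectorized Newton solver for the special case of one binary covariate,
maximizing the same Efron partial likelihood; it agrees with lifelines to
its convergence tolerance and with direct numerical maximization of the
partial likelihood to ~1e-8. Likewise `batch_binary_c_index` evaluates
Harrell's C for many binary risk vectors at once (untied event times
only; the generic path handles ties). Non-convergent or separated Cox
fits are returned flagged, never silently.

## Synthetic data model

The generator plants known structure so every stage can be scored against
ground truth:

- **Single cell.** Malignant cells draw stemness from Beta(4, 2),
  non-malignant from Beta(2, 4). Stem genes' log2 expression rises
  linearly in stemness (slope `stem_effect`, default 2.0) plus a
  malignant offset (`malignant_shift`, default 1.0); all other genes are
  independent of both. Gaussian noise (sd `sigma`, default 0.5) on the
  log2 scale, floored at 0, exponentiated for output.
- **Bulk cohorts.** Per-gene baseline means ~ U(3, 8) on the log2 scale
  are population structure shared by all cohorts (and stored in the truth
  object so held-out cohorts can be drawn from the same population). Each
  sample is high-risk with probability `subtype_prevalence` (0.5). Each
  planted reversal pair (a, b) shares a center; a sits `delta`/2 above
  and b `delta`/2 below in high-risk samples, flipped in low-risk, so the
  expected log2 gap is ±`delta` (default 1.5 = 3 sigma). Stem genes gain
  `delta` in high-risk samples, which is what lets the ssGSEA median
  split recover the subtype. Survival is exponential with scale
  `baseline_scale` (60, months-like) and hazard multiplied by
  `hazard_ratio` (2.5) for high-risk samples; censoring is U(0, 120); a
  surgery-only flag is Bernoulli(0.7). Ties are broken by a seeded
  jitter ≤ 1e-9.
- **Batch distortion.** `monotone_per_sample` applies x → a·x^b + c
  (a ~ U(0.5, 2), b ~ U(0.8, 1.25), c ~ U(0, 1), drawn per sample) to the
  linear-scale values — strictly increasing, hence REO-preserving: this
  is the regime the signature is provably robust to. `genewise_shift`
  adds per-cohort per-gene N(0, 0.5) offsets on the log scale, which
  *does* perturb within-sample orderings across cohorts. `both` and
  `none` combine/disable these.

What the generator does **not** emulate: count-based noise (negative
binomial, dropout), correlated gene programs beyond the planted ones,
copy number or mutations, non-proportional hazards, or informative
censoring. Passing tests therefore demonstrate correctness of the
machinery and recoverability of planted rank structure — not performance
on real tumour data.

## Reference study conditions

Validation runs use: 2 training cohorts × 150 samples, 1000 genes, 50
stem genes, 60 planted reversal pairs, delta = 3 sigma, HR = 2.5,
monotone per-sample distortion; held-out cohorts of 200 samples drawn
from the same population under fresh distortions; 500 cells for the
single-cell stage. Smaller instances (50–200 genes) are used where a
property is exact and size-independent. Calibration checks use
`hazard_ratio=1` with `delta` → 0 so subtype labels carry no survival
signal.

## Numerical choices and edge cases

- BH (Benjamini–Hochberg) is the FDR procedure for every family of tests.
- Zero-variance genes are recorded as untestable in the correlation
  screen, not errors; fully tied genes get p = 1 in rank-sum scans.
- Pairs are stored canonically (gene_a < gene_b lexicographically), so
  results are independent of input gene order.
- Degenerate inputs fail loudly: all-identical enrichment scores, empty
  gene-set overlap, groups below minimum size, constant Cox covariates,
  no comparable C-index pairs.
- Determinism: every stochastic component is driven by
  `numpy.random.SeedSequence(seed)` children; identical config + seed
  reproduces outputs byte-for-byte (the pipeline manifest records file
  hashes to make this checkable).

## Known limitations

- The strict-improvement greedy can stop after very few pairs when the
  candidate ranking's top entries quickly saturate the binary-label
  C-index (which moves in coarse steps). Small signatures (2–4 pairs)
  separate held-out survival less reliably than larger ones; signature
  size varies noticeably across simulation seeds.
- With ~5% of genes tied to the subtype, candidate reversal-pair lists
  are large (tens of thousands) and their C-index ranking is subject to
  winner's curse; the planted pairs are recovered, but rarely top-ranked.
- The binomial stability test treats pairs independently; no attempt is
  made to model correlation between overlapping pairs in the BH family.
- `ssgsea_score` omits GSVA-style cross-sample range normalization by
  design (see above); scores are comparable within, not across, cohorts.
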