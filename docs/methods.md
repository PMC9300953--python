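# Methods

`sighub` implements a seed-gene-guided procedure for discovering a
"signaling hub" transcriptional signature in a bulk-tumor expression cohort
with overall-survival follow-up, and for testing that signature as a
univariate Cox proportional-hazards risk score in independent cohorts.
This note records the model, the numerical choices, and what the synthetic
cohorts do and do not establish.

## The discovery cascade

Given a genes × samples expression matrix X (RSEM-like, non-negative), a
clinical table (overall survival in months, event indicator), a signaling
annotation (gene → categories such as GPCR, RTK, STK, PTP), and a seed gene
*s*:

1. **Stratification.** Samples are split 50:50 at the median of the seed
   gene's expression. Ties at the median are assigned to the low half first,
   in sample order, until the low half reaches ⌈n/2⌉; the rule is
   deterministic and keeps the split as balanced as ties permit.
2. **Within-stratum coexpression.** For every other gene g, Spearman's
   ρ(g, s) is computed separately in the low and high strata. Spearman's ρ
   is the Pearson correlation of midranked data; genes constant within a
   stratum have undefined correlation, are dropped from that stratum's
   ranking, and are logged (this is why the two strata can rank slightly
   different gene counts).
3. **Quartiling.** Each stratum's ranking (ρ descending, ties broken by
   gene symbol) is cut into quartiles. The top quartile (labelled 4) takes
   ⌈G/4⌉ genes; the remainder splits evenly with lower quartiles absorbing
   leftovers, so a 20,096-gene ranking yields a 5,024-gene top quartile.
4. **Signaling intersection.** The high-stratum top quartile is intersected
   with the annotation (any category, or a caller-supplied subset).
   `category_enrichment` reports, per category, (members in the top
   quartile)/(category size/4): 1.0 is the base rate, above 1.0 flags
   preferential coexpression.
5. **Contrast filter.** Keep genes with ρ_high ≥ 0.2 (configurable) and
   ρ_high > ρ_low — correlated with the seed specifically where the seed is
   high.
6. **Survival filter.** Each surviving candidate is median-split on its own
   expression over the whole cohort; the halves are compared with the
   two-group log-rank test. A gene is retained iff p < α (default 0.05,
   raw; Benjamini–Hochberg-adjusted p is reported side by side and can be
   targeted instead) **and** the high-expression half fares worse.
7. **Optional substrate expansion.** Kinases among the retained partners
   pull in their known substrates (kinase → substrate map), restricted to
   the top quartile; expanded genes must independently re-pass the contrast
   and survival filters.

The seed plus the survivors form the `HubSignature`. Every stage's
input/output count is recorded in a provenance funnel (total → top quartile
→ signaling → contrast → survival), mirroring how such screens are
narrated, so a real-data run can be audited stage by stage.

**Direction rule.** "High expression fares worse" is read from the
Kaplan–Meier curves: the package integrates the survival difference of the
two halves up to the last common event time (a restricted-mean comparison)
and takes its sign, falling back to the sign of observed-minus-expected
events in the high half on an exact tie. Evaluating the curves at the
single terminal event time instead is dominated by small-at-risk tail noise
and mislabels a substantial fraction of genuinely hazardous genes at
realistic censoring; the integrated comparison answers the same question
("which curve lies lower") stably.

## Survival and test kernels

All statistical kernels are implemented in-package from their definitions
(scipy supplies only distribution functions and root finding); lifelines,
scipy and statsmodels are used purely as independent cross-checks in the
test suite.

* **Kaplan–Meier**: product-limit estimator over distinct event times.
* **Log-rank**: Mantel–Cox chi-square on 1 df from per-event-time 2×2
  hypergeometric tables; the observed/expected/variance decomposition is
  exposed so callers can read effect direction.
* **Cox PH (univariate)**: Newton–Raphson maximization of the partial
  likelihood with the Efron correction for tied event times (survival
  exports at month resolution tie heavily; Efron is markedly better than
  Breslow there) and step-halving so the log partial likelihood never
  decreases. Non-convergence is reported as a flag, never an exception.
  Wald p-values and 95% CIs (z = 1.959964). The score test at β = 0 equals
  the log-rank statistic exactly for a binary covariate without ties —
  checked to 1e-8.
* **Welch t, one-way ANOVA, Holm and Benjamini–Hochberg adjustment.**
  Multi-group expression comparisons report the omnibus ANOVA followed by
  pairwise Welch tests with Holm adjustment. This replaces the
  studentized-range (Tukey HSD) post-hoc: the omnibus F is faithful, and
  pairwise-Welch+Holm is a conservative, dependency-free post-hoc that
  avoids re-implementing a special-function distribution peripheral to the
  pipeline's claims.

## Risk scoring and validation

The hub signature's risk score for a sample is the mean over signature
genes (seed included by default) of the per-gene z-score of log2(x+1)
expression, with z-scores computed within the cohort being scored. This
makes the score invariant to per-gene affine rescaling and comparable
across cohorts with different normalizations; mean raw expression is
available as an option. Missing genes are reported, never imputed; genes
constant in the cohort are excluded from the mean and logged. Validation
fits the univariate Cox model on the continuous score and, for display,
compares the median-split high/low-risk halves by Kaplan–Meier and
log-rank (median, not optimized, cutoff — optimizing the cutoff would
inflate the apparent effect). Cross-cohort coexpression summaries
(Spearman of each signature gene vs the seed over all samples, no
stratification) stack into the heatmap-style matrix used to compare
cohorts.

## Microenvironment readouts

Signature genes are correlated (Spearman, all samples) against a
user-supplied marker panel (e.g. GFAP astrocytes, MBP oligodendrocytes,
TMEM119 microglia, PECAM1 endothelium, PTPRC leukocytes, ITGAM
macrophages); seed-vs-marker correlations are contrasted between the
low/high seed strata. Immune/stromal infiltration is proxied by a
rank-based single-sample enrichment score of user-supplied gene sets (GMT):
per sample, genes are midranked by expression and the score is the summed
difference of the rank^0.25-weighted cumulative distributions of in-set vs
out-of-set genes, each normalized by its *expected* total weight and
divided by the gene count. Normalizing by expected rather than realized
group weight makes a randomly placed set score exactly zero in expectation
(the realized-weight ratio estimator carries an O(1/|set|) bias);
the statistic remains maximal when the set occupies the top ranks and is
invariant to any strictly monotone per-sample transform. The published
immune/stromal scoring this emulates ships trained gene sets; those sets
are data, not method — here they are user inputs, and the score scale is
this package's own. "Combined" is the immune + stromal sum.

## Synthetic cohorts

`synthetic.generate_cohort` plants exactly the structure the cascade
assumes, providing ground truth for every stage:

* A standard-normal seed latent per sample; the cohort's high half is its
  upper median split.
* Partner genes share a Gaussian factor with the seed with
  stratum-specific loading λ: g = λ·s + √(1−λ²)·ε. λ is calibrated
  numerically so the *within-stratum* Spearman hits the target (ρ_high
  default 0.45, ρ_low 0.05): because the seed is median-truncated inside a
  stratum, the closed-form Gaussian Pearson↔Spearman map
  (ρ_P = 2 sin(πρ_S/6)) is biased there, so the loading is found by
  bracketed root-finding against a deterministic 20,000-point quasi-sample
  (half-normal quantile grid for the seed, fixed-seed noise). Calibration
  accuracy is ~±0.01 and is verified by Monte-Carlo tests.
* Expression is 2^(base + scale·latent) with per-gene base ~ U(3, 9) and
  scale ~ U(0.8, 1.5): non-negative, RSEM-like magnitudes, and monotone per
  gene, so all rank statistics survive the map.
* Survival is Weibull proportional hazards (scale 60 months, shape 1.2)
  with log-hazard β per SD of the mean partner latent (β has no empirical
  reference value; the package default is 0.5 and the end-to-end
  recovery scenarios use 0.8 explicitly). Censoring is uniform on [0, c]
  with c solved numerically so the realized censoring fraction matches the
  target (default 0.3).
* The annotation tags every partner plus 20% of background genes with
  random categories from the controlled vocabulary; partner gene symbols
  are fixed (first n background symbols), so independently seeded cohorts
  share the planted hub — the design needed for independent-cohort
  validation. Companion generators plant mutation tables (group-dependent
  alteration rates) and dependency screens (exact planted T-statistics on
  Gaussian background).

What the generator does **not** emulate: negative-binomial count noise and
library-size effects, batch effects, copy-number structure, correlated
background genes, informative censoring, and real gene identities (symbols
are synthetic). Passing tests therefore demonstrate that the pipeline
recovers the structure it is designed to detect under its own model — at
cohort scale (510 samples, 5,000 genes, a 30-gene hub) it recovers ≥27/30
planted partners with ≤10 false positives and the null pipeline returns
essentially empty signatures — not that any particular real-data signature
is correct.

## Problem sizes and numerical choices

Simulation-based checks run at deliberately chosen sizes: log-rank type-I
calibration at 2×100 samples over 2,000 replicates; Cox recovery of
β = 0.5 over 100 cohorts of n = 1,000; end-to-end recovery at one 510 ×
5,000 cohort; the null pipeline at 20 replicates; independent-cohort
validation at 50 replicates with a 120-gene background (the signature only
needs its own genes plus background for ranking). Newton–Raphson uses
tolerance 1e-9 on the step with a 50-iteration cap and 30 halvings;
correlations are clipped to [−1, 1] against rounding; the Cox covariate is
centered for conditioning (β is translation-invariant). Quartile and
median-split tie rules are exact and documented above so every pipeline
output is bit-reproducible given inputs.

## Known limitations

* Only univariate Cox: no multivariate adjustment (grade, IDH status),
  stratification, time-varying covariates, or proportionality diagnostics.
* Spearman p-values are not computed; gene selection uses ρ magnitude and
  quartile rank, with significance entering only through the survival
  filter.
* The log-rank screen across ~10³ candidates defaults to raw p < 0.05
  (matching how single-gene survival portals are typically used);
  BH-adjusted selection is available via `p_adjust="bh"`.
* The 0.2 contrast floor is a convention, exposed as a parameter.
* Whether a real cohort's risk-score aggregation should include the seed
  gene, or use raw-mean instead of z-score aggregation, is surfaced as
  options rather than fixed.
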