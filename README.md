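# sighub

Seed-gene-guided discovery of **signaling-hub transcriptional signatures**
in bulk tumor cohorts, and their validation as survival risk scores.

Motivation: a single effector gene (for example a RhoGEF highly expressed
in glioma) whose expression correlates with shorter overall survival may
mark an entire signaling program — receptors, kinases, phosphatases,
adaptors — co-expressed with it specifically in the high-expression
patients. `sighub` packages that idea as a reproducible pipeline for
computational-biology users: given a genes × samples expression matrix, a
clinical table, and a signaling-protein annotation, it

1. splits the cohort 50:50 at the median of the seed gene's expression;
2. ranks every gene by within-stratum Spearman correlation with the seed
   and keeps the top quartile (⌈G/4⌉ genes) of the high stratum;
3. intersects with the signaling annotation;
4. applies a contrast filter (ρ_high ≥ 0.2 and ρ_high > ρ_low);
5. keeps only genes whose whole-cohort median-split log-rank test shows
   significantly worse survival in the high-expression half;
6. optionally expands through kinase → substrate edges (re-filtered); and
7. scores the resulting signature per sample as the mean of per-gene
   z-scores of log2(x+1) expression and tests it by univariate Cox
   proportional hazards, h(t|x) = h₀(t)·exp(βx), with Kaplan–Meier display
   of the median-split risk halves.

The statistical kernels (Spearman with midranks, Welch t, one-way ANOVA,
Holm/BH adjustment, Kaplan–Meier, log-rank, Cox partial likelihood with
Efron ties) are implemented in-package and cross-checked against
scipy/statsmodels/lifelines in the test suite. A synthetic-cohort module
generates cohorts with a *planted* hub (stratum-dependent coexpression,
Weibull hazard driven by the hub, calibrated censoring) so every stage is
testable against known ground truth. Auxiliary modules cover
microenvironment readouts (marker correlations, rank-based single-sample
immune/stromal enrichment) and genomic context (dependency-screen
essentiality filters at T ≤ −0.5 and T < −3, mutation-frequency contrasts).

See `docs/methods.md` for the model, parameter defaults, and limitations.

## Worked example

```bash
sighub fixture --out-dir demo --preset planted_hub --rng-seed 1
sighub -v discover --expr demo/expression.tsv --clinical demo/clinical.tsv \
    --annotation demo/annotation.tsv --seed GSEED --out demo/sig.tsv
sighub validate --expr demo/expression.tsv --clinical demo/clinical.tsv \
    --signature demo/sig.tsv --out demo/val
```

The fixture plants a 12-gene hub in a 200-sample, 400-gene cohort.
`discover` prints the gene-count funnel:

```
genes_total=400 -> genes_ranked_high=400 -> genes_ranked_low=400 ->
top_quartile_high=100 -> signaling_in_top_quartile=30 ->
after_contrast_filter=15 -> substrate_candidates=0 -> after_survival_filter=10
```

reading: of 400 ranked genes, 100 form the high-stratum top quartile, 30 of
those are annotated as signaling, 15 survive the contrast filter and 10 the
survival filter — those 10 (here, all true planted partners) plus the seed
are the signature. `validate` then prints the risk-score test:

```
HR=7.304 (95% CI 5.088-10.484), Cox p=4.18e-27, log-rank p=8.24e-17
```

i.e. one standard deviation of the signature score multiplies the hazard
about 7-fold in this synthetic cohort (the planted log-hazard is strong by
design), and the median-split high-risk half dies significantly earlier.

The same objects are available as a library, including scikit-learn-style
estimators:

```python
from sighub import HubSignatureDiscovery, SignatureRiskScorer

est = HubSignatureDiscovery(seed_gene="GSEED", annotation=annotation)
est.fit(expression.T, clinical)        # X: samples x genes
scores = SignatureRiskScorer(est.signature_).fit(expression.T) \
    .score_samples(expression.T)
```

A full multi-stage run (discovery → validation → microenvironment →
context) is driven by a YAML config via `sighub run-all --config run.yaml`,
which writes a manifest with input checksums and per-stage counts.

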