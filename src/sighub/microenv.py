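"""Tumor-microenvironment readouts for a hub signature.

Correlation of signature genes with cell-type marker genes (astrocyte,
oligodendrocyte, microglia, endothelial, leukocyte, macrophage, ... panels
are user-supplied), stratum contrasts of seed-marker correlation, and a
rank-based single-sample enrichment score for user-supplied immune/stromal
gene sets (an ESTIMATE-style infiltration proxy).

The enrichment score for one sample ranks all genes by expression (midranks
for ties) and sums, over the ranking from the top down, the difference
between the weighted cumulative distribution of in-set genes and that of
out-of-set genes, both weighted by rank^exponent (default 0.25), each
normalized by its expected total weight, and the sum divided by the number
of genes.  Weighting both distributions and normalizing by expected rather
than realized group weight keeps the score centered exactly at zero for
randomly placed sets; being purely rank-based it is invariant to any
strictly monotone transform of a sample's expression.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import CoverageError, ParameterError
from .stats import TestResult, midranks, spearman_matrix_vs_vector, welch_t

logger = logging.getLogger(__name__)

__all__ = [
    "marker_correlation_matrix",
    "group_marker_contrast",
    "ssgsea_score",
    "estimate_like_scores",
    "score_group_comparison",
]

#: marker -> cell type, after the glioma panel used throughout the analyses
DEFAULT_MARKER_PANEL = {
    "GFAP": "astrocyte",
    "MBP": "oligodendrocyte",
    "TMEM119": "microglia",
    "ALDH1A1": "cancer stem cell",
    "PECAM1": "endothelial",
    "PTPRC": "leukocyte",
    "ITGAM": "macrophage",
    "CSPG4": "pericyte",
    "EPCAM": "epithelial",
}


def marker_correlation_matrix(expression: pd.DataFrame, genes,
                              panel: dict) -> pd.DataFrame:
    """Spearman rho of each gene against each present marker (all samples)."""
    if expression.shape[1] < 3:
        raise ParameterError("need at least 3 samples")
    markers = [m for m in panel if m in expression.index]
    absent = [m for m in panel if m not in expression.index]
    if absent:
        logger.info("markers absent from matrix: %s", absent)
    if not markers:
        raise CoverageError("no marker gene present in the matrix")
    genes = [g for g in genes if g in expression.index]
    mat = expression.loc[genes].to_numpy(dtype=float)
    out = pd.DataFrame(index=genes, columns=markers, dtype=float)
    for m in markers:
        out[m] = spearman_matrix_vs_vector(
            mat, expression.loc[m].to_numpy(dtype=float))
    return out


def group_marker_contrast(expression: pd.DataFrame, low_ids, high_ids,
                          seed_gene: str, panel: dict) -> pd.DataFrame:
    """Seed-vs-marker Spearman within each stratum.

    Markers constant in a stratum get NaN for that stratum (flagged in the
    log) rather than an error.
    """
    if len(low_ids) < 3 or len(high_ids) < 3:
        raise ParameterError("each stratum needs at least 3 samples")
    if seed_gene not in expression.index:
        raise KeyError(f"seed gene {seed_gene!r} absent from matrix")
    markers = [m for m in panel if m in expression.index]
    if not markers:
        raise CoverageError("no marker gene present in the matrix")
    rows = {}
    for name, ids in (("rho_low", list(low_ids)), ("rho_high", list(high_ids))):
        seed_vec = expression.loc[seed_gene, ids].to_numpy(dtype=float)
        rho = spearman_matrix_vs_vector(
            expression.loc[markers, ids].to_numpy(dtype=float), seed_vec)
        rows[name] = rho
    out = pd.DataFrame(rows, index=markers)
    out["cell_type"] = [panel[m] for m in markers]
    n_flagged = int(out[["rho_low", "rho_high"]].isna().sum().sum())
    if n_flagged:
        logger.info("group_marker_contrast: %d undefined stratum "
                    "correlation(s)", n_flagged)
    return out


def ssgsea_score(expression: pd.DataFrame, gene_set,
                 weight_exponent: float = 0.25) -> pd.Series:
    """Single-sample rank-based enrichment score of one gene set.

    Per sample: genes are midranked by expression; walking the ranking from
    the highest-expressed gene down, the score is the mean difference
    between the rank^exponent-weighted cumulative distributions of in-set
    and out-of-set genes, each normalized by its expected total weight so
    that a randomly placed set scores exactly zero in expectation.
    Positive = the set sits high in this sample's expression ranking.
    """
    set_genes = [g for g in dict.fromkeys(gene_set) if g in expression.index]
    if not set_genes:
        raise CoverageError("no gene-set member present in the matrix")
    if len(set_genes) == expression.shape[0]:
        raise ParameterError("gene set covers the whole matrix; "
                             "enrichment undefined")
    in_set = expression.index.isin(set_genes)
    values = expression.to_numpy(dtype=float)
    n_genes, n_samples = values.shape
    scores = np.empty(n_samples)
    for j in range(n_samples):
        r = midranks(values[:, j])
        order = np.argsort(-r, kind="mergesort")   # top-expressed first
        w = np.abs(r[order]) ** weight_exponent
        mask = in_set[order]
        w_in = np.where(mask, w, 0.0)
        w_out = np.where(mask, 0.0, w)
        # normalize by the expected group weight (set size / universe share
        # of the total weight): keeps the null mean exactly zero, unlike
        # normalizing by the realized in-set weight (a ratio estimator with
        # an O(1/|set|) bias)
        m = int(mask.sum())
        w_total = w.sum()
        p_in = np.cumsum(w_in) / (w_total * m / n_genes)
        p_out = np.cumsum(w_out) / (w_total * (n_genes - m) / n_genes)
        scores[j] = (p_in - p_out).sum() / n_genes
    return pd.Series(scores, index=expression.columns, name="enrichment")


def estimate_like_scores(expression: pd.DataFrame, gene_sets: dict,
                         weight_exponent: float = 0.25) -> pd.DataFrame:
    """Per-sample enrichment for each named set; adds immune+stromal sum
    as ``combined`` when both sets are supplied (additive convention)."""
    out = pd.DataFrame(index=expression.columns)
    for name, genes in gene_sets.items():
        out[name] = ssgsea_score(expression, genes, weight_exponent)
    if {"immune", "stromal"} <= set(out.columns):
        out["combined"] = out["immune"] + out["stromal"]
    return out


def score_group_comparison(scores: pd.Series, low_ids, high_ids) -> TestResult:
    """Welch t test of per-sample scores between seed-expression strata.

    ``extra['direction']`` reports which stratum has the larger mean.
    """
    lo = scores.loc[list(low_ids)].to_numpy(dtype=float)
    hi = scores.loc[list(high_ids)].to_numpy(dtype=float)
    res = welch_t(hi, lo)
    extra = dict(res.extra or {})
    extra["mean_high"] = extra.pop("mean_a")
    extra["mean_low"] = extra.pop("mean_b")
    extra["direction"] = ("higher_in_high" if extra["mean_high"] > extra["mean_low"]
                          else "higher_in_low" if extra["mean_high"] < extra["mean_low"]
                          else "equal")
    return TestResult(statistic=res.statistic, df=res.df,
                      p_value=res.p_value, extra=extra)
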