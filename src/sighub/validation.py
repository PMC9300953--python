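"""Score cohorts with a hub signature and test the score as a risk factor.

The reference risk score is the per-sample mean of per-gene z-scores of
log2(x+1) expression over the signature genes (seed included by default).
Z-scoring within the scored cohort makes the score robust to cohorts with
different normalizations; mean raw expression is available as an option.
Validation fits a univariate Cox proportional-hazards model on the
continuous score and, for display, compares the median-split high- vs
low-risk halves by Kaplan-Meier / log-rank.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import CoverageError, DegenerateInputError, ParameterError
from .io import log2_transform
from .stats import TestResult, spearman_matrix_vs_vector
from .survival import CoxFit, KMCurve, cox_univariate, km_estimate, \
    logrank_test, median_split

logger = logging.getLogger(__name__)

__all__ = [
    "RiskScoreResult",
    "SignatureRiskScorer",
    "signature_score",
    "cox_risk_validation",
    "validate_signature",
    "cross_dataset_coexpression",
]


@dataclass
class RiskScoreResult:
    """Cox fit plus KM display artifacts for one scored cohort."""

    scores: pd.Series
    cox: CoxFit
    km_low: KMCurve
    km_high: KMCurve
    logrank: TestResult
    n_genes_used: int
    genes_missing: list
    genes_constant: list


def _signature_genes(signature, include_seed: bool) -> list[str]:
    # accept a HubSignature or a plain list of gene symbols
    if hasattr(signature, "genes"):
        genes = list(signature.genes)
        if include_seed:
            genes = [signature.seed_gene] + genes
    else:
        genes = list(signature)
    return genes


def signature_score(expression: pd.DataFrame, signature,
                    include_seed: bool = True, method: str = "zscore"):
    """Per-sample signature score.

    ``method='zscore'`` (reference): mean over present signature genes of
    the per-gene z-score of log2(x+1) expression; ``method='mean'``: mean
    raw expression.  Missing genes are reported, never imputed; genes
    constant across samples are excluded from the mean and logged.

    Returns (scores Series, info dict).
    """
    if method not in ("zscore", "mean"):
        raise ParameterError("method must be 'zscore' or 'mean'")
    genes = _signature_genes(signature, include_seed)
    if not genes:
        raise CoverageError("signature has no genes")
    present = [g for g in genes if g in expression.index]
    missing = [g for g in genes if g not in expression.index]
    if not present:
        raise CoverageError("no signature gene present in the matrix")
    sub = expression.loc[present].astype(float)
    constant = list(sub.index[sub.nunique(axis=1) <= 1])
    usable = [g for g in present if g not in constant]
    if not usable:
        raise CoverageError("all present signature genes are constant")
    if constant:
        logger.info("signature_score: %d constant gene(s) excluded: %s",
                    len(constant), constant[:5])
    sub = sub.loc[usable]
    if method == "zscore":
        logx = log2_transform(sub)
        z = logx.sub(logx.mean(axis=1), axis=0).div(logx.std(axis=1, ddof=1),
                                                    axis=0)
        scores = z.mean(axis=0)
    else:
        scores = sub.mean(axis=0)
    scores.name = "risk_score"
    info = {"genes_used": usable, "genes_missing": missing,
            "genes_constant": constant}
    return scores, info


def cox_risk_validation(scores: pd.Series, clinical: pd.DataFrame,
                        info: dict | None = None) -> RiskScoreResult:
    """Cox fit on the continuous score + KM/log-rank for its median split."""
    clin = clinical.set_index("sample_id")
    shared = [s for s in scores.index if s in clin.index]
    if len(shared) < 4:
        raise ParameterError("fewer than 4 samples shared with clinical")
    x = scores.loc[shared].to_numpy(dtype=float)
    times = clin.loc[shared, "os_months"].to_numpy(dtype=float)
    events = clin.loc[shared, "os_event"].to_numpy(dtype=int)
    if np.all(x == x[0]):
        raise DegenerateInputError("constant risk score")
    cox = cox_univariate(times, events, x)
    labels = median_split(x)
    lo, hi = labels == "low", labels == "high"
    lr = logrank_test((times[lo], events[lo]), (times[hi], events[hi]))
    info = info or {}
    return RiskScoreResult(
        scores=pd.Series(x, index=shared, name="risk_score"),
        cox=cox,
        km_low=km_estimate(times[lo], events[lo]),
        km_high=km_estimate(times[hi], events[hi]),
        logrank=lr,
        n_genes_used=len(info.get("genes_used", [])),
        genes_missing=list(info.get("genes_missing", [])),
        genes_constant=list(info.get("genes_constant", [])),
    )


def validate_signature(expression: pd.DataFrame, clinical: pd.DataFrame,
                       signature, include_seed: bool = True,
                       method: str = "zscore") -> RiskScoreResult:
    """Convenience: score a cohort then run the Cox/KM validation."""
    scores, info = signature_score(expression, signature,
                                   include_seed=include_seed, method=method)
    return cox_risk_validation(scores, clinical, info)


def cross_dataset_coexpression(expression: pd.DataFrame, signature,
                               seed_gene: str | None = None) -> pd.Series:
    """Spearman of each signature gene vs the seed over ALL samples.

    No stratification; genes absent from the cohort get NaN (flagged in the
    log).  One such Series per cohort stacks into the cross-cohort heatmap
    matrix.
    """
    seed = seed_gene or getattr(signature, "seed_gene", None)
    if seed is None:
        raise ParameterError("seed gene not given and not on the signature")
    if seed not in expression.index:
        raise KeyError(f"seed gene {seed!r} absent from matrix")
    genes = _signature_genes(signature, include_seed=False)
    present = [g for g in genes if g in expression.index]
    missing = [g for g in genes if g not in expression.index]
    if missing:
        logger.info("cross_dataset_coexpression: %d signature gene(s) "
                    "missing: %s", len(missing), missing[:5])
    out = pd.Series(np.nan, index=genes, name="rho", dtype=float)
    if present:
        rho = spearman_matrix_vs_vector(
            expression.loc[present].to_numpy(dtype=float),
            expression.loc[seed].to_numpy(dtype=float))
        out.loc[present] = rho
    return out


class SignatureRiskScorer(BaseEstimator, TransformerMixin):
    """Transformer mapping a samples x genes matrix to a risk-score column.

    The score z-standardizes each signature gene within the cohort being
    scored (per-cohort standardization is intrinsic to the score
    definition, so ``transform`` uses the statistics of the matrix it is
    given, and ``fit`` only validates coverage).

    Parameters
    ----------
    signature : HubSignature or list of gene symbols
    include_seed : include the seed gene in the mean (HubSignature input)
    method : 'zscore' (reference) or 'mean' (raw expression)
    """

    def __init__(self, signature=None, include_seed: bool = True,
                 method: str = "zscore"):
        self.signature = signature
        self.include_seed = include_seed
        self.method = method

    def fit(self, X: pd.DataFrame, y=None):
        if self.signature is None:
            raise ParameterError("signature is required")
        genes = _signature_genes(self.signature, self.include_seed)
        self.genes_ = genes
        self.genes_missing_ = [g for g in genes if g not in X.columns]
        if len(self.genes_missing_) == len(genes):
            raise CoverageError("no signature gene present in the matrix")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        from sklearn.utils.validation import check_is_fitted
        check_is_fitted(self, "genes_")
        scores, _ = signature_score(X.T, self.signature,
                                    include_seed=self.include_seed,
                                    method=self.method)
        return scores.to_numpy(dtype=float).reshape(-1, 1)

    def score_samples(self, X: pd.DataFrame) -> pd.Series:
        """Named per-sample scores (Series indexed by sample ID)."""
        return pd.Series(self.transform(X).ravel(), index=X.index,
                         name="risk_score")
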