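"""Seed-gene-guided signaling-hub signature discovery.

The selection cascade, run on one discovery cohort:

1. split samples 50:50 at the median of the seed gene's expression;
2. rank every other gene by its Spearman correlation with the seed inside
   each stratum and assign quartiles (quartile 4 = most positively
   correlated, ceil(G/4) genes);
3. intersect the high-stratum top quartile with a signaling annotation;
4. contrast filter: keep genes with rho_high >= 0.2 (configurable) and
   rho_high > rho_low;
5. survival filter: keep genes whose whole-cohort median-split log-rank is
   significant with the high-expression half faring worse;
6. optionally expand through kinase -> substrate edges, with expanded
   genes re-passing filters 4-5.

The seed gene plus the survivors form the hub signature.  Every stage
records its input/output counts in a provenance funnel so a run on real
data can be compared against the published narrative numbers
(whole transcriptome -> top quartile -> signaling -> contrast -> survival).

``HubSignatureDiscovery`` wraps the cascade as a scikit-learn style
estimator (``fit(X, y)`` with X = samples x genes); the module functions
below are the underlying pipeline stages and keep the genes x samples
orientation used by the file formats.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .errors import (CoverageError, DegenerateInputError, FormatError,
                     ParameterError)
from .stats import bh_adjust, spearman_matrix_vs_vector
from .survival import km_estimate, logrank_test, median_split
from .synthetic import KINASE_CATEGORIES

logger = logging.getLogger(__name__)

__all__ = [
    "HubSignature",
    "HubSignatureDiscovery",
    "stratify_by_seed",
    "coexpression_list",
    "assign_quartiles",
    "top_quartile",
    "coexpression_table",
    "signaling_intersect",
    "category_enrichment",
    "contrast_filter",
    "survival_filter",
    "expand_phosphosubstrates",
    "build_hub_signature",
]


@dataclass
class HubSignature:
    """A discovered signature: the seed plus every filtered-in partner.

    ``partners`` carries one row per partner with the statistics that
    justified inclusion; ``provenance`` records the parameters and the
    gene-count funnel of every stage.
    """

    seed_gene: str
    partners: pd.DataFrame        # gene, rho_high, rho_low, logrank_p, ...
    provenance: dict = field(default_factory=dict)

    @property
    def genes(self) -> list[str]:
        return list(self.partners["gene"])

    def __len__(self) -> int:
        return len(self.partners)

    def to_tsv(self, path) -> None:
        header = pd.DataFrame({"gene": [self.seed_gene], "role": ["seed"]})
        body = self.partners.copy()
        body.insert(1, "role", "partner")
        pd.concat([header, body], ignore_index=True).to_csv(
            path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "HubSignature":
        df = pd.read_csv(path, sep="\t", dtype={"gene": str})
        seed_rows = df[df["role"] == "seed"]
        if len(seed_rows) != 1:
            raise FormatError(f"{path}: signature needs exactly one seed row")
        partners = df[df["role"] == "partner"].drop(columns=["role"])
        return cls(seed_gene=str(seed_rows["gene"].iloc[0]),
                   partners=partners.reset_index(drop=True))


def stratify_by_seed(expression: pd.DataFrame, seed_gene: str,
                     percentile: float = 50.0):
    """Split samples at the given percentile of seed-gene expression.

    Returns (low_ids, high_ids) as lists in the matrix's sample order.
    The split is exhaustive and disjoint; with percentile=50 it follows
    the median-split tie rule (ties fill the low group first).
    """
    if seed_gene not in expression.index:
        raise KeyError(f"seed gene {seed_gene!r} absent from matrix")
    if expression.shape[1] < 4:
        raise ParameterError("need at least 4 samples to stratify")
    values = expression.loc[seed_gene].to_numpy(dtype=float)
    if percentile == 50.0:
        labels = median_split(values)
    else:
        if np.all(values == values[0]):
            raise DegenerateInputError("seed gene constant across samples")
        n = values.size
        k = math.ceil(n * percentile / 100.0)
        order = np.argsort(values, kind="mergesort")
        labels = np.full(n, "high", dtype="<U4")
        labels[order[:k]] = "low"
    cols = np.asarray(expression.columns)
    return list(cols[labels == "low"]), list(cols[labels == "high"])


def coexpression_list(expression: pd.DataFrame, seed_gene: str,
                      sample_ids=None) -> pd.Series:
    """Spearman rho of every non-seed gene against the seed in one stratum.

    Genes with undefined correlation (constant within the stratum) get NaN
    and are excluded from quartiling downstream.
    """
    if seed_gene not in expression.index:
        raise KeyError(f"seed gene {seed_gene!r} absent from matrix")
    sub = expression if sample_ids is None else expression[list(sample_ids)]
    if sub.shape[1] < 3:
        raise ParameterError("stratum needs at least 3 samples")
    others = sub.drop(index=seed_gene)
    rho = spearman_matrix_vs_vector(
        others.to_numpy(dtype=float),
        sub.loc[seed_gene].to_numpy(dtype=float))
    n_dropped = int(np.isnan(rho).sum())
    if n_dropped:
        logger.info("coexpression: %d gene(s) constant in stratum, dropped "
                    "from ranking", n_dropped)
    return pd.Series(rho, index=others.index, name="rho")


def assign_quartiles(rho: pd.Series) -> pd.Series:
    """Quartile labels 4..1 from the highest positive rho downward.

    Sorting is by rho descending with ties broken by gene symbol (stable).
    The top quartile takes ceil(G/4) genes; the remainder is split evenly
    with earlier (lower-numbered) quartiles absorbing leftovers.  NaN rho
    values are excluded (label 0 = unranked).
    """
    valid = rho.dropna()
    if valid.empty:
        raise ParameterError("no ranked genes to quartile")
    order = valid.reset_index()
    order.columns = ["gene", "rho"]
    order = order.sort_values(["rho", "gene"],
                              ascending=[False, True], kind="mergesort")
    g = len(order)
    q4 = math.ceil(g / 4)
    rest = g - q4
    base, extra = divmod(rest, 3)
    sizes = {4: q4, 3: base, 2: base + (1 if extra >= 2 else 0),
             1: base + (1 if extra >= 1 else 0)}
    labels = np.concatenate([np.full(sizes[q], q, dtype=int)
                             for q in (4, 3, 2, 1)])
    out = pd.Series(0, index=rho.index, dtype=int, name="quartile")
    out.loc[order["gene"].to_numpy()] = labels
    return out


def top_quartile(rho: pd.Series) -> set:
    """Genes in quartile 4 (highest positive correlation with the seed)."""
    q = assign_quartiles(rho)
    return set(q.index[q == 4])


def coexpression_table(expression: pd.DataFrame, seed_gene: str,
                       low_ids, high_ids) -> pd.DataFrame:
    """Per-gene within-stratum correlations and quartiles, both strata."""
    rho_low = coexpression_list(expression, seed_gene, low_ids)
    rho_high = coexpression_list(expression, seed_gene, high_ids)
    table = pd.DataFrame({"rho_low": rho_low, "rho_high": rho_high})
    table["quartile_low"] = assign_quartiles(rho_low)
    table["quartile_high"] = assign_quartiles(rho_high)
    return table


def signaling_intersect(genes, annotation: dict, categories=None) -> set:
    """Genes carrying at least one (matching) annotation category."""
    genes = set(genes)
    if categories is None:
        return {g for g in genes if annotation.get(g)}
    wanted = set(categories)
    return {g for g in genes if annotation.get(g) and
            (set(annotation[g]) & wanted)}


def category_enrichment(top_set, annotation: dict, category: str,
                        genes_in_matrix) -> float:
    """Normalized top-quartile representation of one signaling category.

    metric = (category members in the top quartile) / (category size / 4);
    1.0 means the category is represented exactly at the quartile's base
    rate, > 1.0 flags preferential coexpression with the seed.
    """
    present = [g for g in genes_in_matrix
               if category in annotation.get(g, ())]
    if not present:
        raise ParameterError(
            f"category {category!r} has no members in the matrix")
    in_top = sum(1 for g in present if g in set(top_set))
    return in_top / (len(present) / 4.0)


def contrast_filter(coexpr: pd.DataFrame, min_rho_high: float = 0.2) -> set:
    """Keep genes correlated with the seed preferentially in the high stratum.

    Conditions: rho_high >= min_rho_high, rho_high > rho_low, and membership
    in the high-stratum top quartile.
    """
    ok = ((coexpr["rho_high"] >= min_rho_high)
          & (coexpr["rho_high"] > coexpr["rho_low"])
          & (coexpr["quartile_high"] == 4))
    return set(coexpr.index[ok.fillna(False)])


def _km_direction(times_low, events_low, times_high, events_high,
                  o_minus_e_high: float) -> str:
    """Which half fares worse: the KM curve that lies lower over the common
    follow-up window.

    "Lower" is decided by the integrated survival difference (restricted
    mean survival) up to the last common event time rather than the single
    terminal point, which is dominated by small-at-risk noise; an exact tie
    falls back to the sign of observed-minus-expected events in the high
    group.
    """
    km_low = km_estimate(times_low, events_low)
    km_high = km_estimate(times_high, events_high)
    t_star = min(times_low.max(), times_high.max())
    grid = np.unique(np.concatenate([[0.0], km_low.times, km_high.times,
                                     [t_star]]))
    grid = grid[grid <= t_star]
    if grid.size > 1:
        widths = np.diff(grid)
        s_low = np.array([km_low.survival_at(t) for t in grid[:-1]])
        s_high = np.array([km_high.survival_at(t) for t in grid[:-1]])
        area = float(((s_low - s_high) * widths).sum())
        if area > 0:
            return "worse_when_high"
        if area < 0:
            return "better_when_high"
    return ("worse_when_high" if o_minus_e_high > 0 else "better_when_high")


def survival_filter(expression: pd.DataFrame, clinical: pd.DataFrame,
                    genes, alpha: float = 0.05,
                    min_clinical_coverage: float = 0.9,
                    p_adjust: str = "raw"):
    """Per-gene whole-cohort median-split log-rank screen.

    Each candidate is dichotomized at its own median over the full cohort;
    the two halves are compared by the log-rank test and the direction read
    from the Kaplan-Meier curves.  A gene is retained iff its (raw or BH,
    per ``p_adjust``) p-value is below ``alpha`` and high expression tracks
    worse survival.

    Returns (per_gene DataFrame, retained set).
    """
    if p_adjust not in ("raw", "bh"):
        raise ParameterError("p_adjust must be 'raw' or 'bh'")
    clin = clinical.set_index("sample_id")
    shared = [s for s in expression.columns if s in clin.index]
    coverage = len(shared) / expression.shape[1]
    if coverage < min_clinical_coverage:
        raise CoverageError(
            f"clinical covers {coverage:.1%} of expression samples "
            f"(< {min_clinical_coverage:.0%})")
    times = clin.loc[shared, "os_months"].to_numpy(dtype=float)
    events = clin.loc[shared, "os_event"].to_numpy(dtype=int)
    if events.sum() == 0:
        raise DegenerateInputError("all samples censored")
    records = []
    for gene in genes:
        if gene not in expression.index:
            continue
        values = expression.loc[gene, shared].to_numpy(dtype=float)
        try:
            labels = median_split(values)
        except DegenerateInputError:
            records.append((gene, np.nan, np.nan, "undefined"))
            continue
        lo, hi = labels == "low", labels == "high"
        res = logrank_test((times[lo], events[lo]), (times[hi], events[hi]))
        # O-E of the high group is the negative of the A(=low)-group excess
        direction = _km_direction(times[lo], events[lo],
                                  times[hi], events[hi],
                                  -res.extra["o_minus_e_a"])
        records.append((gene, res.statistic, res.p_value, direction))
    per_gene = pd.DataFrame(records,
                            columns=["gene", "logrank_chi2", "logrank_p",
                                     "direction"]).set_index("gene")
    valid = per_gene["logrank_p"].notna()
    per_gene["logrank_p_bh"] = np.nan
    if valid.any():
        per_gene.loc[valid, "logrank_p_bh"] = bh_adjust(
            per_gene.loc[valid, "logrank_p"].to_numpy())
    p_col = "logrank_p" if p_adjust == "raw" else "logrank_p_bh"
    keep = valid & (per_gene[p_col] < alpha) & (
        per_gene["direction"] == "worse_when_high")
    return per_gene, set(per_gene.index[keep])


def expand_phosphosubstrates(kinases, ks_map: dict, top_set) -> dict:
    """Substrates of the given kinases that sit in the top quartile.

    Returns substrate -> set of upstream kinases (a substrate hit by
    several retained kinases is listed once with all of them recorded).
    """
    top = set(top_set)
    out: dict[str, set] = {}
    for kin in kinases:
        for sub in ks_map.get(kin, ()):
            if sub in top:
                out.setdefault(sub, set()).add(kin)
    return out


def build_hub_signature(expression: pd.DataFrame, clinical: pd.DataFrame,
                        annotation: dict, seed_gene: str, *,
                        percentile: float = 50.0,
                        min_rho_high: float = 0.2,
                        alpha: float = 0.05,
                        categories=None,
                        ks_map: dict | None = None,
                        kinase_categories=KINASE_CATEGORIES,
                        min_clinical_coverage: float = 0.9,
                        p_adjust: str = "raw") -> HubSignature:
    """Run the full selection cascade and assemble the hub signature.

    An empty result is returned as an empty signature with a structured
    warning, never an exception.
    """
    low_ids, high_ids = stratify_by_seed(expression, seed_gene, percentile)
    coexpr = coexpression_table(expression, seed_gene, low_ids, high_ids)
    top_high = set(coexpr.index[coexpr["quartile_high"] == 4])
    signaling = signaling_intersect(top_high, annotation, categories)
    contrast = contrast_filter(coexpr, min_rho_high) & signaling
    per_gene, survivors = survival_filter(
        expression, clinical, sorted(contrast), alpha=alpha,
        min_clinical_coverage=min_clinical_coverage, p_adjust=p_adjust)

    origin = {g: "coexpression" for g in survivors}
    n_substrate_candidates = 0
    if ks_map:
        kinases = {g for g in survivors
                   if set(annotation.get(g, ())) & set(kinase_categories)}
        sub_map = expand_phosphosubstrates(kinases, ks_map, top_high)
        extra = (set(sub_map) - survivors - {seed_gene})
        # expanded genes must independently re-pass both filters
        extra &= contrast_filter(coexpr, min_rho_high)
        n_substrate_candidates = len(extra)
        if extra:
            per_sub, kept_sub = survival_filter(
                expression, clinical, sorted(extra), alpha=alpha,
                min_clinical_coverage=min_clinical_coverage,
                p_adjust=p_adjust)
            per_gene = pd.concat([per_gene, per_sub])
            for g in kept_sub:
                origin[g] = "substrate:" + ";".join(sorted(sub_map[g]))
            survivors |= kept_sub

    survivors.discard(seed_gene)
    rows = []
    for g in sorted(survivors):
        rows.append({
            "gene": g,
            "rho_high": float(coexpr.loc[g, "rho_high"]),
            "rho_low": float(coexpr.loc[g, "rho_low"]),
            "logrank_p": float(per_gene.loc[g, "logrank_p"]),
            "logrank_p_bh": float(per_gene.loc[g, "logrank_p_bh"]),
            "direction": per_gene.loc[g, "direction"],
            "origin": origin[g],
        })
    partners = pd.DataFrame(
        rows, columns=["gene", "rho_high", "rho_low", "logrank_p",
                       "logrank_p_bh", "direction", "origin"])
    funnel = {
        "genes_total": int(expression.shape[0] - 1),
        "genes_ranked_high": int(coexpr["rho_high"].notna().sum()),
        "genes_ranked_low": int(coexpr["rho_low"].notna().sum()),
        "top_quartile_high": len(top_high),
        "signaling_in_top_quartile": len(signaling),
        "after_contrast_filter": len(contrast),
        "substrate_candidates": n_substrate_candidates,
        "after_survival_filter": len(partners),
    }
    logger.info("discovery funnel: %s", funnel)
    provenance = {
        "seed_gene": seed_gene,
        "percentile": percentile,
        "min_rho_high": min_rho_high,
        "alpha": alpha,
        "p_adjust": p_adjust,
        "categories": sorted(categories) if categories else None,
        "n_samples": int(expression.shape[1]),
        "n_low": len(low_ids),
        "n_high": len(high_ids),
        "funnel": funnel,
        "empty": partners.empty,
    }
    if partners.empty:
        warnings.warn("hub discovery produced an empty signature; "
                      "see provenance funnel", stacklevel=2)
    return HubSignature(seed_gene=seed_gene, partners=partners,
                        provenance=provenance)


class HubSignatureDiscovery(BaseEstimator):
    """Scikit-learn style wrapper around the discovery cascade.

    Parameters mirror :func:`build_hub_signature`; the signaling annotation
    and optional kinase-substrate map are constructor resources because they
    are fixed reference data, not per-cohort measurements.

    ``fit(X, y)`` expects X as a samples x genes DataFrame (sklearn
    orientation; transposed internally) and y as a clinical DataFrame with
    ``sample_id``, ``os_months`` and ``os_event`` columns.

    Attributes
    ----------
    signature_ : HubSignature
    coexpression_ : DataFrame of per-gene rho/quartile statistics
    funnel_ : dict of per-stage gene counts
    """

    def __init__(self, seed_gene: str = "GSEED", annotation: dict | None = None,
                 percentile: float = 50.0, min_rho_high: float = 0.2,
                 alpha: float = 0.05, categories=None,
                 ks_map: dict | None = None,
                 min_clinical_coverage: float = 0.9, p_adjust: str = "raw"):
        self.seed_gene = seed_gene
        self.annotation = annotation
        self.percentile = percentile
        self.min_rho_high = min_rho_high
        self.alpha = alpha
        self.categories = categories
        self.ks_map = ks_map
        self.min_clinical_coverage = min_clinical_coverage
        self.p_adjust = p_adjust

    def fit(self, X: pd.DataFrame, y: pd.DataFrame):
        if self.annotation is None:
            raise ParameterError("annotation is required to fit")
        expression = X.T
        self.signature_ = build_hub_signature(
            expression, y, self.annotation, self.seed_gene,
            percentile=self.percentile, min_rho_high=self.min_rho_high,
            alpha=self.alpha, categories=self.categories, ks_map=self.ks_map,
            min_clinical_coverage=self.min_clinical_coverage,
            p_adjust=self.p_adjust)
        low_ids, high_ids = stratify_by_seed(expression, self.seed_gene,
                                             self.percentile)
        self.coexpression_ = coexpression_table(expression, self.seed_gene,
                                                low_ids, high_ids)
        self.funnel_ = self.signature_.provenance["funnel"]
        self.n_features_in_ = X.shape[1]
        return self

    def get_support(self) -> list[str]:
        """Partner genes selected by the fitted cascade."""
        from sklearn.utils.validation import check_is_fitted
        check_is_fitted(self, "signature_")
        return self.signature_.genes
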