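"""Auxiliary genomic-context screens around the hub signature.

Dependency-screen filtering for essential signaling genes (a cell line is
"dependent" on a gene when the perturbation T-statistic is -0.5 or more
negative; "coessential signaling" genes fall strictly below -3), and
mutation-status association with seed-gene expression (alteration
frequencies by seed stratum; Welch t / one-way ANOVA of expression across
WT/MT/AMP/DEL groups).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, ParameterError
from .stats import TestResult, one_way_anova, pairwise_welch_holm, welch_t

__all__ = [
    "filter_dependent_lines",
    "coessential_signaling",
    "mutation_frequency_by_group",
    "expression_by_mutation",
]


def filter_dependent_lines(dependencies: pd.DataFrame, gene: str,
                           threshold: float = -0.5) -> list[str]:
    """Cell lines whose T-statistic for ``gene`` is <= threshold
    (threshold included: '-0.5 or more negative')."""
    sub = dependencies[dependencies["gene"] == gene]
    if sub.empty:
        raise KeyError(f"gene {gene!r} absent from dependency table")
    hits = sub[sub["t_statistic"] <= threshold]
    return sorted(hits["cell_line"].unique())


def coessential_signaling(dependencies: pd.DataFrame, annotation: dict,
                          threshold: float = -3.0) -> pd.DataFrame:
    """Signaling genes with any T-statistic strictly below the threshold.

    Returns one row per qualifying (gene, cell line) observation, sorted by
    T ascending (most essential first).
    """
    is_sig = dependencies["gene"].map(lambda g: bool(annotation.get(g)))
    hits = dependencies[(dependencies["t_statistic"] < threshold) & is_sig]
    hits = hits.sort_values(["t_statistic", "gene", "cell_line"],
                            kind="mergesort").reset_index(drop=True)
    hits = hits.assign(is_signaling=True)
    return hits


def mutation_frequency_by_group(mutations: pd.DataFrame, low_ids, high_ids,
                                genes) -> pd.DataFrame:
    """Percent of samples altered (status != WT) per gene and seed stratum.

    Flags genes whose alteration frequency is higher in the high-seed group.
    """
    low, high = set(low_ids), set(high_ids)
    if not low or not high:
        raise ParameterError("both groups must be non-empty")
    if low & high:
        raise ParameterError("groups must be disjoint")
    altered = mutations[mutations["status"] != "WT"]
    rows = []
    for gene in genes:
        sub = altered[altered["gene"] == gene]
        alt_samples = set(sub["sample_id"])
        f_low = 100.0 * len(alt_samples & low) / len(low)
        f_high = 100.0 * len(alt_samples & high) / len(high)
        rows.append({"gene": gene, "freq_low": f_low, "freq_high": f_high,
                     "higher_in_high": f_high > f_low})
    return pd.DataFrame(rows)


def expression_by_mutation(expression: pd.DataFrame, mutations: pd.DataFrame,
                           query_gene: str, target_gene: str) -> TestResult:
    """Compare ``target_gene`` expression across mutation-status groups of
    ``query_gene``.

    Two groups: Welch t test.  Three or more: ordinary one-way ANOVA with
    pairwise Welch + Holm post-hoc in ``extra['pairwise']``.  Group means
    and sizes are always reported in ``extra['groups']``.
    """
    if target_gene not in expression.index:
        raise KeyError(f"target gene {target_gene!r} absent from matrix")
    sub = mutations[mutations["gene"] == query_gene]
    if sub.empty:
        raise KeyError(f"query gene {query_gene!r} absent from mutations")
    status = sub.set_index("sample_id")["status"]
    shared = [s for s in expression.columns if s in status.index]
    values = expression.loc[target_gene, shared].astype(float)
    groups = {st: values[status.loc[shared] == st].to_numpy()
              for st in status.loc[shared].unique()}
    groups = {st: v for st, v in groups.items() if v.size >= 2}
    if len(groups) < 2:
        raise DegenerateInputError(
            "need at least 2 mutation-status groups with n >= 2")
    summary = {st: {"mean": float(v.mean()), "n": int(v.size)}
               for st, v in groups.items()}
    if len(groups) == 2:
        (sa, va), (sb, vb) = sorted(groups.items())
        res = welch_t(va, vb)
        extra = dict(res.extra or {})
        extra.update({"test": "welch_t", "groups": summary,
                      "order": (sa, sb)})
        return TestResult(statistic=res.statistic, df=res.df,
                          p_value=res.p_value, extra=extra)
    ordered = [groups[st] for st in sorted(groups)]
    res = one_way_anova(ordered)
    pairwise = pairwise_welch_holm(groups)
    return TestResult(statistic=res.statistic, df=res.df, p_value=res.p_value,
                      extra={"test": "anova", "groups": summary,
                             "pairwise": pairwise})
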