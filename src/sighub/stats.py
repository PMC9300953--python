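"""Elementary statistics implemented in-package.

Spearman rank correlation (midranks for ties), Welch's unequal-variance t
test, ordinary one-way ANOVA, and Holm / Benjamini-Hochberg multiplicity
adjustment.  These four kernels are used by every downstream stage of the
pipeline, so they are written here once, from their definitions; the only
external calls are to scipy's distribution functions (Student t, F) for
p-values.  Tukey's studentized-range post-hoc is deliberately not
implemented: multi-group expression comparisons use the omnibus ANOVA
followed by pairwise Welch tests with Holm adjustment (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

from .errors import DegenerateInputError, ParameterError

__all__ = [
    "TestResult",
    "midranks",
    "spearman_rho",
    "spearman_matrix_vs_vector",
    "welch_t",
    "one_way_anova",
    "pairwise_welch_holm",
    "holm_adjust",
    "bh_adjust",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a hypothesis test.

    ``df`` is a float for single-df tests and a ``(df1, df2)`` tuple for F
    tests.  ``extra`` carries test-specific payload (group means, pairwise
    tables) without widening the core contract.
    """

    statistic: float
    df: float | tuple[float, float]
    p_value: float
    extra: dict | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ParameterError(f"p-value outside [0,1]: {self.p_value}")


def midranks(values) -> np.ndarray:
    """Average ranks (1-based) with midranks assigned to ties.

    Ties receive the mean of the rank positions they occupy, so the rank
    vector always sums to n(n+1)/2.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise ParameterError("midranks expects a 1-D vector")
    n = v.size
    order = np.argsort(v, kind="mergesort")
    sv = v[order]
    new_group = np.empty(n, dtype=bool)
    new_group[0] = True
    np.not_equal(sv[1:], sv[:-1], out=new_group[1:])
    group = np.cumsum(new_group) - 1
    counts = np.bincount(group)
    # average of the 1-based positions each tie group occupies
    avg = np.cumsum(counts) - (counts - 1) / 2.0
    ranks = np.empty(n, dtype=float)
    ranks[order] = avg[group]
    return ranks


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    dx = x - x.mean()
    dy = y - y.mean()
    denom = np.sqrt((dx * dx).sum() * (dy * dy).sum())
    if denom == 0.0:
        raise DegenerateInputError("correlation undefined for a constant vector")
    return float(np.clip((dx * dy).sum() / denom, -1.0, 1.0))


def spearman_rho(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of midranked data.

    Raises
    ------
    ParameterError
        if the vectors differ in length or have fewer than 3 elements.
    DegenerateInputError
        if either vector is constant (correlation undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise ParameterError("need at least 3 paired observations")
    return _pearson(midranks(x), midranks(y))


def spearman_matrix_vs_vector(matrix, vector) -> np.ndarray:
    """Spearman rho of every row of ``matrix`` against ``vector``.

    Rows that are constant get NaN (undefined correlation) rather than an
    exception; callers drop and log them.  This is the bulk path used for
    genome-wide coexpression rankings.
    """
    m = np.asarray(matrix, dtype=float)
    v = np.asarray(vector, dtype=float)
    if m.ndim != 2 or v.ndim != 1 or m.shape[1] != v.shape[0]:
        raise ParameterError("matrix columns must match vector length")
    if m.shape[1] < 3:
        raise ParameterError("need at least 3 samples")
    rv = midranks(v)
    drv = rv - rv.mean()
    denom_v = np.sqrt((drv * drv).sum())
    if denom_v == 0.0:
        raise DegenerateInputError("reference vector is constant")
    out = np.empty(m.shape[0], dtype=float)
    for i in range(m.shape[0]):
        row = m[i]
        if row[0] == row[-1] and np.all(row == row[0]):
            out[i] = np.nan
            continue
        rr = midranks(row)
        drr = rr - rr.mean()
        denom_r = np.sqrt((drr * drr).sum())
        if denom_r == 0.0:
            out[i] = np.nan
        else:
            out[i] = np.clip((drr * drv).sum() / (denom_r * denom_v), -1.0, 1.0)
    return out


def welch_t(a, b) -> TestResult:
    """Unpaired two-sample t test with Welch's unequal-variance correction.

    Two-sided p-value from the Student t distribution with
    Welch-Satterthwaite degrees of freedom.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ParameterError("each group needs at least 2 observations")
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        raise DegenerateInputError("zero variance in both groups")
    sa, sb = va / a.size, vb / b.size
    se = np.sqrt(sa + sb)
    t = (a.mean() - b.mean()) / se
    df = (sa + sb) ** 2 / (
        (sa**2 / (a.size - 1)) + (sb**2 / (b.size - 1))
    )
    p = 2.0 * float(_sps.t.sf(abs(t), df))
    return TestResult(
        statistic=float(t),
        df=float(df),
        p_value=min(p, 1.0),
        extra={"mean_a": float(a.mean()), "mean_b": float(b.mean()),
               "n_a": int(a.size), "n_b": int(b.size)},
    )


def one_way_anova(groups) -> TestResult:
    """Ordinary (equal-variance) one-way ANOVA F test.

    F = MS_between / MS_within on (k-1, N-k) degrees of freedom.  If every
    observation is identical the statistic is defined as 0 with p = 1.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ParameterError("ANOVA needs at least 2 groups")
    for g in gs:
        if g.size < 2:
            raise ParameterError("each group needs at least 2 observations")
    all_obs = np.concatenate(gs)
    grand = all_obs.mean()
    k = len(gs)
    n_tot = all_obs.size
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in gs)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in gs)
    df1, df2 = k - 1, n_tot - k
    if ssb == 0.0:
        return TestResult(statistic=0.0, df=(float(df1), float(df2)), p_value=1.0)
    if ssw == 0.0:
        return TestResult(statistic=float("inf"), df=(float(df1), float(df2)),
                          p_value=0.0)
    f = (ssb / df1) / (ssw / df2)
    p = float(_sps.f.sf(f, df1, df2))
    return TestResult(statistic=float(f), df=(float(df1), float(df2)), p_value=p)


def holm_adjust(p) -> np.ndarray:
    """Holm step-down adjusted p-values, order-preserving with the input."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ParameterError("p-values must lie in [0,1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    # step-down: running maximum of (n-i)*p_(i) from the smallest p upward
    adj_sorted = np.maximum.accumulate(np.minimum((n - np.arange(n)) * p[order], 1.0))
    out = np.empty(n, dtype=float)
    out[order] = adj_sorted
    return out


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving with the input."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ParameterError("p-values must lie in [0,1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / (np.arange(n) + 1.0)
    q_sorted = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
    out = np.empty(n, dtype=float)
    out[order] = q_sorted
    return out


def pairwise_welch_holm(groups: dict) -> list[dict]:
    """All pairwise Welch t tests between named groups, Holm-adjusted.

    Returns a list of records ``{pair, statistic, df, p_raw, p_holm}`` in a
    deterministic (sorted-name) pair order.
    """
    names = sorted(groups)
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    results = [welch_t(groups[a], groups[b]) for a, b in pairs]
    p_adj = holm_adjust([r.p_value for r in results]) if pairs else np.array([])
    return [
        {"pair": pair, "statistic": r.statistic, "df": r.df,
         "p_raw": r.p_value, "p_holm": float(q)}
        for pair, r, q in zip(pairs, results, p_adj)
    ]
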