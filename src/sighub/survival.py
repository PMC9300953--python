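"""Survival-analysis kernels: Kaplan-Meier, log-rank, median split, Cox PH.

All four are implemented from their definitions.  The Cox model is the
univariate proportional-hazards partial likelihood with the Efron correction
for tied event times, maximized by Newton-Raphson with step-halving; the
Efron correction is preferred over Breslow because survival exports at month
resolution produce many ties.  Confidence intervals are Wald at 95%
(z = 1.959964); all p-values are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _sps

from .errors import DegenerateInputError, ParameterError
from .stats import TestResult

__all__ = [
    "KMCurve",
    "CoxFit",
    "km_estimate",
    "logrank_test",
    "median_split",
    "cox_univariate",
    "cox_score_test",
]

_Z95 = 1.959964


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival curve over the distinct event times."""

    times: np.ndarray          # distinct event times, increasing
    survival: np.ndarray       # S(t) just after each event time
    at_risk: np.ndarray        # n_i at each event time
    n_events: np.ndarray       # d_i at each event time

    def survival_at(self, t: float) -> float:
        """Step-function evaluation S(t); S = 1 before the first event."""
        idx = np.searchsorted(self.times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival[idx - 1])


@dataclass(frozen=True)
class CoxFit:
    """Univariate Cox proportional-hazards fit (per-unit covariate)."""

    beta: float
    se: float
    hr: float
    ci95: tuple[float, float]
    p_value: float
    n: int
    n_events: int
    log_likelihood: float
    converged: bool
    iterations: int


def _check_surv(times, events):
    t = np.asarray(times, dtype=float)
    e = np.asarray(events)
    if t.ndim != 1 or t.shape != e.shape:
        raise ParameterError("times and events must be equal-length 1-D vectors")
    if t.size == 0:
        raise ParameterError("empty survival input")
    if np.any(t < 0):
        raise ParameterError("negative survival times")
    if not np.all(np.isin(e, (0, 1))):
        raise ParameterError("event flags must be 0 or 1")
    return t, e.astype(int)


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    S(t) = prod over event times t_i <= t of (1 - d_i / n_i), where n_i
    counts subjects still at risk (observed time >= t_i).
    """
    t, e = _check_surv(times, events)
    ev_times = np.unique(t[e == 1])
    if ev_times.size == 0:
        return KMCurve(times=np.array([]), survival=np.array([]),
                       at_risk=np.array([], dtype=int),
                       n_events=np.array([], dtype=int))
    sorted_t = np.sort(t)
    at_risk = t.size - np.searchsorted(sorted_t, ev_times, side="left")
    d = np.array([(t[e == 1] == et).sum() for et in ev_times])
    surv = np.cumprod(1.0 - d / at_risk)
    return KMCurve(times=ev_times, survival=surv,
                   at_risk=at_risk.astype(int), n_events=d.astype(int))


def logrank_test(group_a, group_b) -> TestResult:
    """Two-group log-rank test (Mantel-Cox, chi-square on 1 df).

    Each group is a ``(times, events)`` pair.  At every pooled distinct
    event time a 2x2 table contributes observed-minus-expected events in
    group A and the hypergeometric variance; the statistic is
    (O_A - E_A)^2 / V.  ``extra`` reports O, E and V so callers can read the
    direction of the effect from sign(O_A - E_A).
    """
    ta, ea = _check_surv(*group_a)
    tb, eb = _check_surv(*group_b)
    t = np.concatenate([ta, tb])
    e = np.concatenate([ea, eb])
    in_a = np.concatenate([np.ones(ta.size, bool), np.zeros(tb.size, bool)])
    if e.sum() == 0:
        raise DegenerateInputError("no events in the pooled data")
    ev_times = np.unique(t[e == 1])
    sa = np.sort(ta)
    sb = np.sort(tb)
    n1 = ta.size - np.searchsorted(sa, ev_times, side="left")   # at risk, A
    n2 = tb.size - np.searchsorted(sb, ev_times, side="left")   # at risk, B
    n = n1 + n2
    te_a = ta[ea == 1]
    te_all = t[e == 1]
    d1 = np.array([(te_a == et).sum() for et in ev_times], dtype=float)
    d = np.array([(te_all == et).sum() for et in ev_times], dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        expected = d * n1 / n
        var = np.where(n > 1, d * (n1 / n) * (n2 / n) * (n - d) / (n - 1), 0.0)
    o_minus_e = float((d1 - expected).sum())
    v = float(var.sum())
    if v == 0.0:
        # identical degenerate groups: no information, no difference
        return TestResult(statistic=0.0, df=1.0, p_value=1.0,
                          extra={"observed_a": float(d1.sum()),
                                 "expected_a": float(expected.sum()),
                                 "o_minus_e_a": o_minus_e, "variance": v})
    chi2 = o_minus_e**2 / v
    p = float(_sps.chi2.sf(chi2, 1))
    return TestResult(statistic=float(chi2), df=1.0, p_value=p,
                      extra={"observed_a": float(d1.sum()),
                             "expected_a": float(expected.sum()),
                             "o_minus_e_a": o_minus_e, "variance": v})


def median_split(values) -> np.ndarray:
    """Label each sample ``low`` or ``high`` relative to the median.

    Values strictly above the median are high, strictly below are low;
    values equal to the median are assigned to low first (in input order)
    until the low group reaches ceil(n/2), then to high.  This keeps the
    split as close to 50:50 as ties permit and is deterministic.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ParameterError("median_split needs a 1-D vector with n >= 2")
    if np.all(v == v[0]):
        raise DegenerateInputError("all values identical; split undefined")
    med = float(np.median(v))
    labels = np.full(v.size, "high", dtype="<U4")
    labels[v < med] = "low"
    n_low_target = v.size - v.size // 2   # ceil(n/2)
    tie_idx = np.flatnonzero(v == med)
    n_low = int((v < med).sum())
    for i in tie_idx:
        if n_low < n_low_target:
            labels[i] = "low"
            n_low += 1
        else:
            labels[i] = "high"
    return labels


def _efron_terms(beta: float, t, e, x):
    """Log partial likelihood, score and information under Efron ties."""
    order = np.argsort(t, kind="mergesort")
    ts, es, xs = t[order], e[order], x[order]
    w = np.exp(xs * beta)
    # suffix sums: risk set at time t = subjects with observed time >= t
    s0 = np.concatenate([np.cumsum((w)[::-1])[::-1], [0.0]])
    s1 = np.concatenate([np.cumsum((xs * w)[::-1])[::-1], [0.0]])
    s2 = np.concatenate([np.cumsum((xs * xs * w)[::-1])[::-1], [0.0]])
    ll = 0.0
    score = 0.0
    info = 0.0
    ev_pos = np.flatnonzero(es == 1)
    i = 0
    while i < ev_pos.size:
        j = i
        tt = ts[ev_pos[i]]
        while j < ev_pos.size and ts[ev_pos[j]] == tt:
            j += 1
        dset = ev_pos[i:j]
        d = dset.size
        start = np.searchsorted(ts, tt, side="left")
        wd = w[dset]
        xd = xs[dset]
        s0d, s1d, s2d = wd.sum(), (xd * wd).sum(), (xd * xd * wd).sum()
        ll += float((xd * beta).sum())
        score += float(xd.sum())
        for el in range(d):
            f = el / d
            phi0 = s0[start] - f * s0d
            phi1 = s1[start] - f * s1d
            phi2 = s2[start] - f * s2d
            ll -= np.log(phi0)
            score -= phi1 / phi0
            info += phi2 / phi0 - (phi1 / phi0) ** 2
        i = j
    return ll, score, info


def cox_univariate(times, events, covariate, *, max_iter: int = 50,
                   tol: float = 1e-9, min_events: int = 5) -> CoxFit:
    """Fit hazard(t | x) = h0(t) * exp(beta * x) by partial likelihood.

    Newton-Raphson with step-halving (the log partial likelihood never
    decreases across accepted steps).  Non-convergence sets
    ``converged=False`` instead of raising.
    """
    t, e = _check_surv(times, events)
    x = np.asarray(covariate, dtype=float)
    if x.shape != t.shape:
        raise ParameterError("covariate length must match times")
    if np.all(x == x[0]):
        raise DegenerateInputError("constant covariate")
    n_events = int(e.sum())
    if n_events < min_events:
        raise DegenerateInputError(
            f"only {n_events} events; need at least {min_events}")
    x_center = x - x.mean()           # improves conditioning; beta unchanged
    beta = 0.0
    ll, score, info = _efron_terms(beta, t, e, x_center)
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        if info <= 0:
            break
        step = score / info
        # step-halving: accept only non-decreasing log-likelihood
        factor = 1.0
        for _ in range(30):
            new_beta = beta + factor * step
            new_ll, new_score, new_info = _efron_terms(new_beta, t, e, x_center)
            if new_ll >= ll - 1e-12:
                break
            factor *= 0.5
        delta = new_beta - beta
        beta, ll, score, info = new_beta, new_ll, new_score, new_info
        if abs(delta) < tol and abs(score) < 1e-6 * max(1.0, abs(info)):
            converged = True
            break
    se = float(1.0 / np.sqrt(info)) if info > 0 else float("inf")
    hr = float(np.exp(beta))
    ci = (float(np.exp(beta - _Z95 * se)), float(np.exp(beta + _Z95 * se)))
    z = beta / se if se > 0 and np.isfinite(se) else 0.0
    p = 2.0 * float(_sps.norm.sf(abs(z)))
    return CoxFit(beta=float(beta), se=se, hr=hr, ci95=ci,
                  p_value=min(p, 1.0), n=int(t.size), n_events=n_events,
                  log_likelihood=float(ll), converged=converged,
                  iterations=iterations)


def cox_score_test(times, events, covariate) -> TestResult:
    """Score (Rao) test of beta = 0 in the univariate Cox model.

    For a binary covariate without tied event times this statistic equals
    the log-rank chi-square exactly.
    """
    t, e = _check_surv(times, events)
    x = np.asarray(covariate, dtype=float)
    if np.all(x == x[0]):
        raise DegenerateInputError("constant covariate")
    _, score, info = _efron_terms(0.0, t, e, x - x.mean())
    if info <= 0:
        raise DegenerateInputError("zero information at beta=0")
    chi2 = score**2 / info
    return TestResult(statistic=float(chi2), df=1.0,
                      p_value=float(_sps.chi2.sf(chi2, 1)),
                      extra={"score": float(score), "information": float(info)})
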