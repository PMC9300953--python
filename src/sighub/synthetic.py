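"""Synthetic survival cohorts with a planted signaling hub.

The generator emulates the statistical structure the discovery pipeline
assumes in a real bulk-RNA cohort:

* a seed gene whose expression stratifies the cohort at its median;
* a planted set of partner genes whose rank correlation with the seed is
  stronger in the high-seed half (``rho_high``) than in the low half
  (``rho_low``), induced through a shared Gaussian factor with
  stratum-specific loading;
* overall-survival times from a Weibull proportional-hazards model whose
  log-hazard is ``beta`` per standard deviation of the mean partner signal;
* independent uniform right-censoring calibrated to a target fraction;
* a signaling annotation covering every partner plus a background fraction,
  and optional mutation / dependency-screen tables.

Expression values are produced by exponentiating the Gaussian latents to an
RSEM-like non-negative scale; because the map is monotone per gene, all
rank-based targets survive it.  The factor loading that achieves a given
within-stratum Spearman target is found numerically: the seed is median-
truncated inside a stratum, so the closed-form Gaussian Pearson-Spearman
map is only used to bracket the search.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import ParameterError
from .stats import midranks

__all__ = [
    "CohortParams",
    "CohortTruth",
    "generate_cohort",
    "generate_mutation_table",
    "generate_dependency_table",
    "CATEGORY_VOCABULARY",
]

CATEGORY_VOCABULARY = frozenset({
    "GPCR", "RTK", "STK", "DK", "TyrK", "PPP", "PTP", "DSP",
    "agonist", "adaptor", "GEF", "GAP",
})
# kinase-like categories used when expanding phospho-substrates
KINASE_CATEGORIES = frozenset({"STK", "DK", "TyrK", "RTK"})

MUTATION_STATUSES = ("WT", "MT", "AMP", "DEL")


@dataclass(frozen=True)
class CohortParams:
    """Ground-truth parameters for one synthetic cohort.

    Defaults mirror a TCGA-LGG-sized discovery cohort: 510 samples, a
    5,000-gene background, a 30-gene planted hub, within-stratum Spearman
    targets 0.45 (high) / 0.05 (low), and ~20% of background genes tagged
    as signaling (the ratio of signaling transcripts to the top-quartile
    size reported for genome-wide screens).  ``beta`` is the log hazard per
    SD of the mean partner signal; there is no empirical reference value
    for it, so it is an explicit, configurable choice.
    """

    n_samples: int = 510
    n_genes: int = 5000
    n_partners: int = 30
    rho_high: float = 0.45
    rho_low: float = 0.05
    beta: float = 0.5
    baseline_scale: float = 60.0      # Weibull scale, months
    weibull_shape: float = 1.2
    censor_frac: float = 0.3
    frac_signaling: float = 0.2
    rng_seed: int = 0
    seed_gene: str = "GSEED"

    def __post_init__(self) -> None:
        if self.n_samples < 4 or self.n_genes < 1:
            raise ParameterError("need n_samples >= 4 and n_genes >= 1")
        if not (0 <= self.n_partners < self.n_genes):
            raise ParameterError("require 0 <= n_partners < n_genes")
        for name in ("rho_high", "rho_low", "censor_frac", "frac_signaling"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ParameterError(f"{name} must lie in [0, 1): got {v}")
        if self.n_partners > 0 and self.rho_high <= self.rho_low:
            raise ParameterError("rho_high must exceed rho_low for a "
                                 "discoverable planted hub")
        if self.baseline_scale <= 0 or self.weibull_shape <= 0:
            raise ParameterError("baseline_scale and weibull_shape must be > 0")


@dataclass(frozen=True)
class CohortTruth:
    """What was planted: the answer key for downstream recovery tests."""

    seed_gene: str
    partner_genes: frozenset
    latent_risk: pd.Series        # beta * standardized partner signal
    high_samples: frozenset       # samples in the upper seed-latent half


def _gene_symbols(n_genes: int) -> list[str]:
    return [f"G{i:06d}" for i in range(1, n_genes + 1)]


def _sample_ids(n: int) -> list[str]:
    return [f"S{i:04d}" for i in range(1, n + 1)]


@lru_cache(maxsize=64)
def _calibrate_loading(rho_target: float) -> float:
    """Factor loading whose within-half-stratum Spearman hits the target.

    Uses a deterministic quasi-sample: the seed latent is an equal-mass
    quantile grid of the upper-half truncated normal, the gene noise a
    fixed-seed Gaussian draw.  Monotone in the loading, so a bracketed
    root-find suffices.  By symmetry the same loading works for the lower
    half.
    """
    if rho_target == 0.0:
        return 0.0
    m = 20000
    from scipy.stats import norm
    probs = 0.5 + (np.arange(m) + 0.5) / (2 * m)
    s = norm.ppf(probs)                       # upper-half truncated normal
    eps = np.random.default_rng(20220707).standard_normal(m)
    rs = midranks(s)
    drs = rs - rs.mean()
    denom_s = np.sqrt((drs * drs).sum())

    def stratum_spearman(lam: float) -> float:
        g = lam * s + np.sqrt(1.0 - lam * lam) * eps
        rg = midranks(g)
        drg = rg - rg.mean()
        return float((drg * drs).sum() /
                     (np.sqrt((drg * drg).sum()) * denom_s))

    f = lambda lam: stratum_spearman(lam) - rho_target
    lo, hi = 1e-6, 1.0 - 1e-9
    if f(hi) < 0:           # unreachable target; saturate
        return hi
    return float(brentq(f, lo, hi, xtol=1e-4))


def _calibrate_censor_bound(event_times: np.ndarray, censor_frac: float) -> float:
    """Upper bound c of Uniform(0, c) censoring achieving the target fraction.

    P(censored) = E[min(T/c, 1)] is continuous and decreasing in c; solve on
    the realized event-time sample.
    """
    def frac(c: float) -> float:
        return float(np.minimum(event_times / c, 1.0).mean())

    lo = max(event_times.min() * 1e-6, 1e-9)
    hi = event_times.max() * 2.0
    while frac(hi) > censor_frac:
        hi *= 4.0
        if hi > event_times.max() * 1e9:       # pragma: no cover
            break
    return float(brentq(lambda c: frac(c) - censor_frac, lo, hi, xtol=1e-10))


def generate_cohort(params: CohortParams):
    """Generate one cohort: expression, clinical, annotation and truth.

    Returns
    -------
    (expression, clinical, annotation, truth)
        ``expression``: genes x samples DataFrame of non-negative values;
        ``clinical``: DataFrame with ``sample_id``, ``os_months``,
        ``os_event``; ``annotation``: dict gene -> frozenset of categories;
        ``truth``: :class:`CohortTruth`.

    Partner genes are always the first ``n_partners`` background symbols,
    so two cohorts generated with the same structural parameters but
    different seeds share the planted hub — the design needed for
    independent-cohort validation.
    """
    p = params
    rng = np.random.default_rng(p.rng_seed)
    samples = _sample_ids(p.n_samples)
    genes = _gene_symbols(p.n_genes)
    partners = genes[: p.n_partners]

    s = rng.standard_normal(p.n_samples)                 # seed latent
    med = np.median(s)
    high = s > med
    if high.sum() != p.n_samples // 2:                   # tie safety net
        order = np.argsort(s, kind="mergesort")
        high = np.zeros(p.n_samples, dtype=bool)
        high[order[p.n_samples - p.n_samples // 2:]] = True

    lam_high = _calibrate_loading(p.rho_high)
    lam_low = _calibrate_loading(p.rho_low)
    lam = np.where(high, lam_high, lam_low)

    latents = rng.standard_normal((p.n_genes, p.n_samples))
    if p.n_partners:
        noise = latents[: p.n_partners]
        latents[: p.n_partners] = (lam * s +
                                   np.sqrt(1.0 - lam * lam) * noise)

    base = rng.uniform(3.0, 9.0, size=p.n_genes)
    scale = rng.uniform(0.8, 1.5, size=p.n_genes)
    expr_values = np.exp2(base[:, None] + scale[:, None] * latents)
    seed_row = np.exp2(rng.uniform(3.0, 9.0) + s)        # monotone in s
    expression = pd.DataFrame(
        np.vstack([seed_row, expr_values]),
        index=[p.seed_gene] + genes, columns=samples,
    )

    if p.n_partners:
        raw = latents[: p.n_partners].mean(axis=0)
        z = (raw - raw.mean()) / raw.std()
    else:
        z = np.zeros(p.n_samples)
    log_hazard = p.beta * z
    u = rng.exponential(1.0, p.n_samples)
    t_event = p.baseline_scale * (u * np.exp(-log_hazard)) ** (1.0 / p.weibull_shape)
    if p.censor_frac > 0:
        c = _calibrate_censor_bound(t_event, p.censor_frac)
        censor = rng.uniform(0.0, c, p.n_samples)
        os_months = np.minimum(t_event, censor)
        os_event = (t_event <= censor).astype(int)
    else:
        os_months = t_event
        os_event = np.ones(p.n_samples, dtype=int)
    clinical = pd.DataFrame({
        "sample_id": samples,
        "os_months": os_months,
        "os_event": os_event,
    })

    vocab = sorted(CATEGORY_VOCABULARY)
    annotation: dict[str, frozenset] = {}
    for g in partners:
        annotation[g] = frozenset({vocab[rng.integers(len(vocab))]})
    background = genes[p.n_partners:]
    n_bg_signaling = int(round(p.frac_signaling * len(background)))
    if n_bg_signaling:
        chosen = rng.choice(len(background), size=n_bg_signaling, replace=False)
        for i in np.sort(chosen):
            annotation[background[i]] = frozenset(
                {vocab[rng.integers(len(vocab))]})

    truth = CohortTruth(
        seed_gene=p.seed_gene,
        partner_genes=frozenset(partners),
        latent_risk=pd.Series(log_hazard, index=samples, name="latent_risk"),
        high_samples=frozenset(np.asarray(samples)[high]),
    )
    return expression, clinical, annotation, truth


def generate_mutation_table(n_samples: int, genes, alt_freq_low: float,
                            alt_freq_high: float, high_ids, rng_seed: int
                            ) -> pd.DataFrame:
    """Per-(sample, gene) mutation statuses with group-dependent rates.

    Samples in ``high_ids`` are altered with probability ``alt_freq_high``,
    others with ``alt_freq_low``; altered statuses are drawn uniformly from
    MT/AMP/DEL.
    """
    for name, v in (("alt_freq_low", alt_freq_low),
                    ("alt_freq_high", alt_freq_high)):
        if not (0.0 <= v <= 1.0):
            raise ParameterError(f"{name} must lie in [0,1]: got {v}")
    samples = _sample_ids(n_samples)
    high_ids = set(high_ids)
    unknown = high_ids - set(samples)
    if unknown:
        raise ParameterError(f"high_ids not in sample universe: {sorted(unknown)[:5]}")
    rng = np.random.default_rng(rng_seed)
    records = []
    alt_choices = [st for st in MUTATION_STATUSES if st != "WT"]
    for g in genes:
        for sid in samples:
            p_alt = alt_freq_high if sid in high_ids else alt_freq_low
            if rng.random() < p_alt:
                status = alt_choices[rng.integers(len(alt_choices))]
            else:
                status = "WT"
            records.append((sid, g, status))
    return pd.DataFrame(records, columns=["sample_id", "gene", "status"])


def generate_dependency_table(cell_lines, genes, essential_pairs: dict,
                              background_sd: float, rng_seed: int
                              ) -> pd.DataFrame:
    """Dense gene x cell-line dependency screen with planted essentials.

    ``essential_pairs`` maps ``(gene, cell_line)`` to the exact T-statistic
    to plant; every other cell is Gaussian noise with SD ``background_sd``.
    """
    cell_lines = list(cell_lines)
    genes = list(genes)
    line_set, gene_set = set(cell_lines), set(genes)
    for (g, cl) in essential_pairs:
        if g not in gene_set:
            raise KeyError(f"unknown gene in essential_pairs: {g}")
        if cl not in line_set:
            raise KeyError(f"unknown cell line in essential_pairs: {cl}")
    rng = np.random.default_rng(rng_seed)
    t = rng.normal(0.0, background_sd, size=(len(genes), len(cell_lines)))
    records = []
    for i, g in enumerate(genes):
        for j, cl in enumerate(cell_lines):
            val = essential_pairs.get((g, cl), t[i, j])
            records.append((cl, g, float(val), "crispr"))
    return pd.DataFrame(records,
                        columns=["cell_line", "gene", "t_statistic",
                                 "perturbation"])
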