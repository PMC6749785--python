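"""Default-prior (JZS) Bayes-factor t tests, evidence labels, and bootstrap CIs.

The group analysis compares per-participant wiggle thresholds between
conditions (paired) and against the baseline amplitude 1.0 (one sample). Both
reduce to a one-sample problem on differences ``d_i`` with t statistic
``t = mean(d) / (sd(d)/sqrt(n))``. The Bayes factor BF10 compares

    H0: standardised effect delta = 0
    H1: delta ~ Cauchy(0, r)        (the JZS default prior, r = sqrt(2)/2)

via the marginal likelihood of ``t`` under each hypothesis: the sampling
density of ``t`` given ``delta`` is noncentral t with ``n - 1`` degrees of
freedom and noncentrality ``delta * sqrt(n)``, so

    BF10 = integral nct(t; n-1, delta*sqrt(n)) Cauchy(delta; 0, r) d delta
           / t_pdf(t; n-1),

evaluated by adaptive quadrature. A one-sided variant (effect constrained
positive, folded half-Cauchy prior) is available for the against-baseline
tests. Evidence strength is classified on the conventional Bayes-factor
ladder (anecdotal / moderate / strong / very strong / extreme), mirrored for
evidence favouring H0.

Group summaries use percentile bootstrap CIs resampling participants with
replacement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, stats

__all__ = [
    "BayesResult",
    "GroupSummary",
    "DegenerateDataError",
    "DEFAULT_PRIOR_SCALE",
    "jzs_bf_from_t",
    "jzs_bf_paired",
    "jzs_bf_one_sample",
    "classify_evidence",
    "bootstrap_group_ci",
]

DEFAULT_PRIOR_SCALE = float(np.sqrt(2.0) / 2.0)


class DegenerateDataError(ValueError):
    """Zero-variance differences: the t statistic is undefined."""


@dataclass(frozen=True)
class BayesResult:
    bf10: float
    t_stat: float
    n: int
    prior_scale: float
    evidence_label: str
    direction: str = "two-sided"
    mean_diff: float = float("nan")


def jzs_bf_from_t(
    t: float,
    n: int,
    prior_scale: float = DEFAULT_PRIOR_SCALE,
    one_sided: bool = False,
) -> float:
    """JZS Bayes factor BF10 from a one-sample/paired t statistic.

    ``one_sided=True`` constrains H1 to positive effects (half-Cauchy prior);
    evidence then increases for positive ``t`` and collapses for negative.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if prior_scale <= 0:
        raise ValueError("prior scale must be positive")
    nu = n - 1
    root_n = np.sqrt(n)

    def integrand(delta: float) -> float:
        return stats.nct.pdf(t, nu, delta * root_n) * stats.cauchy.pdf(
            delta, 0.0, prior_scale
        )

    if one_sided:
        m1, _ = integrate.quad(
            lambda d: 2.0 * integrand(d), 0.0, np.inf, epsabs=0, epsrel=1e-10, limit=200
        )
    else:
        lo, _ = integrate.quad(integrand, -np.inf, 0.0, epsabs=0, epsrel=1e-10, limit=200)
        hi, _ = integrate.quad(integrand, 0.0, np.inf, epsabs=0, epsrel=1e-10, limit=200)
        m1 = lo + hi
    m0 = stats.t.pdf(t, nu)
    return float(m1 / m0)


def _one_sample_result(
    d: np.ndarray, prior_scale: float, one_sided: bool, direction: str
) -> BayesResult:
    d = np.asarray(d, dtype=np.float64)
    n = d.size
    if n < 3:
        raise ValueError("need n >= 3 paired observations")
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateDataError("differences have zero variance")
    t = float(d.mean() / (sd / np.sqrt(n)))
    bf = jzs_bf_from_t(t, n, prior_scale, one_sided=one_sided)
    return BayesResult(
        bf10=bf,
        t_stat=t,
        n=n,
        prior_scale=prior_scale,
        evidence_label=classify_evidence(bf),
        direction=direction,
        mean_diff=float(d.mean()),
    )


def jzs_bf_paired(
    x: np.ndarray, y: np.ndarray, prior_scale: float = DEFAULT_PRIOR_SCALE
) -> BayesResult:
    """Paired (within-participant) JZS Bayes-factor t test on ``x - y``."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    return _one_sample_result(x - y, prior_scale, False, "two-sided")


def jzs_bf_one_sample(
    x: np.ndarray,
    mu0: float = 1.0,
    prior_scale: float = DEFAULT_PRIOR_SCALE,
    one_sided: bool = False,
) -> BayesResult:
    """One-sample JZS Bayes-factor t test of ``x`` against ``mu0``.

    With ``one_sided=True`` the alternative is "greater than ``mu0``".
    """
    d = np.asarray(x, dtype=np.float64) - mu0
    return _one_sample_result(
        d, prior_scale, one_sided, "one-sided" if one_sided else "two-sided"
    )


_BANDS = [
    (3.0, "anecdotal"),
    (10.0, "moderate"),
    (30.0, "strong"),
    (100.0, "very strong"),
    (np.inf, "extreme"),
]


def classify_evidence(bf10: float) -> str:
    """Evidence-strength label for a Bayes factor.

    BF10 in (1, 3] is anecdotal, (3, 10] moderate, (10, 30] strong, (30, 100]
    very strong and above 100 extreme evidence for H1; reciprocal bands give
    the same ladder for H0. Exactly 1 is no evidence either way.
    """
    if not (bf10 > 0) or not np.isfinite(bf10):
        raise ValueError("Bayes factor must be positive and finite")
    if bf10 == 1.0:
        return "no evidence"
    favours = "H1" if bf10 > 1 else "H0"
    mag = bf10 if bf10 > 1 else 1.0 / bf10
    for bound, name in _BANDS:
        if mag <= bound:
            return f"{name} evidence for {favours}"
    raise AssertionError("unreachable")


@dataclass(frozen=True)
class GroupSummary:
    """Per-condition mean thresholds with bootstrap percentile CIs."""

    table: pd.DataFrame  # index: condition; columns: mean, ci_lo, ci_hi
    n_participants: int
    n_resamples: int
    ci_level: float


def bootstrap_group_ci(
    thresholds: pd.DataFrame,
    n_resamples: int = 10_000,
    seed: int | np.random.Generator = 0,
    ci_level: float = 0.95,
) -> GroupSummary:
    """Bootstrap CIs on the condition means of a participant x condition table.

    Resamples participants (rows) with replacement; each condition column's CI
    is the percentile interval of the resampled means.
    """
    if thresholds.shape[0] < 5:
        raise ValueError("need at least 5 participants")
    if n_resamples < 1000:
        raise ValueError("need at least 1000 resamples")
    rng = np.random.default_rng(seed)
    vals = thresholds.to_numpy(dtype=np.float64)
    n = vals.shape[0]
    idx = rng.integers(0, n, size=(n_resamples, n))
    boot_means = vals[idx].mean(axis=1)  # (n_resamples, n_conditions)
    alpha = (1.0 - ci_level) / 2.0
    lo, hi = np.quantile(boot_means, [alpha, 1.0 - alpha], axis=0)
    table = pd.DataFrame(
        {"mean": vals.mean(axis=0), "ci_lo": lo, "ci_hi": hi},
        index=thresholds.columns,
    )
    return GroupSummary(
        table=table,
        n_participants=n,
        n_resamples=n_resamples,
        ci_level=ci_level,
    )
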