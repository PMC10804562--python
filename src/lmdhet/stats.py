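"""Shared statistical primitives.

Small wrappers with pinned semantics used across the heterogeneity and
differential modules: raw MAD (no consistency constant), a Mann-Whitney U
that is exact for small groups, BH adjustment, and the empirical-Bayes
variance squeezing (moment matching of log sample variances against a
scaled inverse-chi-square prior via digamma/trigamma inversion).
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
from scipy import special, stats

__all__ = [
    "mad",
    "mann_whitney_u",
    "bh_adjust",
    "trigamma_inverse",
    "squeeze_variances",
    "SqueezeResult",
]


def mad(x, axis=None):
    """Raw median absolute deviation: median(|x - median(x)|).

    No 1.4826 normal-consistency scaling — thresholds like "MAD > 1" are
    applied to the raw value.
    """
    x = np.asarray(x, dtype=float)
    med = np.nanmedian(x, axis=axis, keepdims=True)
    return np.nanmedian(np.abs(x - med), axis=axis)


class MWUResult(NamedTuple):
    statistic: float  # U for the first sample
    pvalue: float
    method: str


def mann_whitney_u(x, y, exact_max: int = 8) -> MWUResult:
    """Two-sided Mann-Whitney U test.

    Exact null distribution when both groups have <= ``exact_max``
    observations and the pooled values contain no ties; otherwise normal
    approximation with tie correction (and continuity correction).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(x) <= exact_max and len(y) <= exact_max and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return MWUResult(float(res.statistic), float(res.pvalue), method)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    return stats.false_discovery_control(p, method="bh")


def trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        raise ValueError("trigamma_inverse requires x > 0")
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(100):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


class SqueezeResult(NamedTuple):
    s2_post: np.ndarray  # posterior (squeezed) variances
    d0: float            # prior degrees of freedom (may be inf)
    s0_2: float          # prior variance


def squeeze_variances(s2, df, d0: float | None = None,
                      s0_2: float | None = None) -> SqueezeResult:
    """Shrink per-feature sample variances toward an estimated prior.

    The prior (d0, s0^2) is fitted by matching the mean and variance of
    z = log(s2) to the theoretical moments of log of a scaled F / scaled
    inverse-chi-square variate: E[z] and Var[z] involve digamma/trigamma
    at df/2 and d0/2, so d0 is found by trigamma inversion. Posterior
    variance is the weighted combination (d0*s0^2 + df*s2) / (d0 + df).

    ``d0``/``s0_2`` may be forced (d0=0 -> no shrinkage, classical
    variances; d0=inf -> full shrinkage to s0^2).
    """
    s2 = np.asarray(s2, dtype=float)
    df = float(df)
    if np.any(~np.isfinite(s2)) or np.any(s2 < 0):
        raise ValueError("sample variances must be finite and non-negative")
    if d0 is None:
        positive = s2[s2 > 0]
        if positive.size < 2:
            raise ValueError("need >= 2 positive variances to fit the prior")
        z = np.log(positive)
        e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
        e_mean = float(np.mean(e))
        e_var = float(np.var(e, ddof=1))
        excess = e_var - float(special.polygamma(1, df / 2.0))
        if excess > 0:
            d0 = 2.0 * trigamma_inverse(excess)
            if s0_2 is None:
                s0_2 = float(np.exp(
                    e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
        else:
            d0 = np.inf
            if s0_2 is None:
                s0_2 = float(np.exp(e_mean))
    elif s0_2 is None:
        if np.isinf(d0):
            s0_2 = float(np.exp(np.mean(np.log(s2[s2 > 0]))))
        elif d0 == 0:
            s0_2 = float(np.median(s2))
        else:
            raise ValueError("s0_2 must be given when forcing a finite d0 > 0")

    if d0 == 0:
        s2_post = s2.copy()
    elif np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
    else:
        s2_post = (d0 * s0_2 + df * s2) / (d0 + df)
    return SqueezeResult(s2_post, float(d0), float(s0_2))
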