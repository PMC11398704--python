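"""Model-comparison criteria and distance-based goodness-of-fit tests.

The information criteria are all monotone transforms of -2*loglik at fixed
(k, n); the distance statistics (Kolmogorov-Smirnov, Cramer-von Mises,
Anderson-Darling) are computed on the probability-integral transform of
the ordered sample under the fitted CDF.

p-values use the asymptotic case-0 null distributions, i.e. they treat the
fitted parameters as known.  With estimated parameters this convention is
anti-conservative (a Lilliefors-type bootstrap would be smaller); it is
nonetheless the convention the reported reference values follow, and the
report object says so explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import special, stats

from .distribution import MKTLParams, cdf
from .estimation import UnitSample, log_likelihood, _as_sample

__all__ = [
    "GofReport",
    "information_criteria",
    "ks_test",
    "cvm_test",
    "ad_test",
    "gof_report",
]


@dataclass(frozen=True)
class GofReport:
    """Information criteria and distance statistics for one fitted model.

    ``neg2loglik`` is -2 times the maximized log-likelihood; all criteria
    are built on it.  p-values are asymptotic, parameters-treated-as-known.
    """

    neg2loglik: float
    aic: float
    bic: float
    caic: float
    hqic: float
    ks_stat: float
    ks_p: float
    w_stat: float
    w_p: float
    a_stat: float
    a_p: float
    k: int
    n: int


def information_criteria(neg2loglik: float, k: int, n: int) -> tuple[float, float, float, float]:
    """(AIC, BIC, CAIC, HQIC) from -2*loglik, parameter count k, sample size n.

    AIC  = -2l + 2k
    BIC  = -2l + k log n
    CAIC = AIC + 2k(k+1)/(n-k-1)     (small-sample corrected AIC)
    HQIC = -2l + 2k log(log n)
    """
    if n <= k + 1:
        raise ValueError("CAIC requires n > k + 1")
    aic = neg2loglik + 2.0 * k
    bic = neg2loglik + k * math.log(n)
    caic = aic + 2.0 * k * (k + 1.0) / (n - k - 1.0)
    hqic = neg2loglik + 2.0 * k * math.log(math.log(n))
    return aic, bic, caic, hqic


def _pit(data, p: MKTLParams) -> np.ndarray:
    data = _as_sample(data)
    return cdf(data.values, p)


def ks_test(data, p: MKTLParams) -> tuple[float, float]:
    """One-sample Kolmogorov-Smirnov statistic and asymptotic p-value.

    D = max_i max(i/n - F(x_(i)), F(x_(i)) - (i-1)/n); the p-value is the
    Kolmogorov series 2 sum_{k>=1} (-1)^(k-1) exp(-2 k^2 n D^2).
    """
    f = _pit(data, p)
    n = f.size
    i = np.arange(1, n + 1)
    d = max(np.max(i / n - f), np.max(f - (i - 1) / n))
    return float(d), float(special.kolmogorov(math.sqrt(n) * d))


def cvm_test(data, p: MKTLParams) -> tuple[float, float]:
    """Cramer-von Mises statistic W = 1/(12n) + sum (F_(i) - (2i-1)/(2n))^2
    with its asymptotic null p-value."""
    f = _pit(data, p)
    n = f.size
    i = np.arange(1, n + 1)
    w = 1.0 / (12.0 * n) + float(np.sum((f - (2 * i - 1) / (2.0 * n)) ** 2))
    # asymptotic null distribution of W via the uniform one-sample test on
    # the PIT values (identical statistic)
    p_val = float(stats.cramervonmises(f, "uniform").pvalue)
    return w, min(max(p_val, 0.0), 1.0)


def _ad_sf(z: float) -> float:
    """Asymptotic survival function of the Anderson-Darling statistic
    (fully specified null), Marsaglia & Marsaglia's series approximation."""
    if z <= 0.0:
        return 1.0
    if z < 2.0:
        c = (
            2.00012
            + (0.247105 - (0.0649821 - (0.0347962 - (0.011672 - 0.00168691 * z) * z) * z) * z) * z
        )
        return 1.0 - z**-0.5 * math.exp(-1.2337141 / z) * c
    g = math.exp(
        1.0776 - (2.30695 - (0.43424 - (0.082433 - (0.008056 - 0.0003146 * z) * z) * z) * z) * z
    )
    return 1.0 - math.exp(-g)


def ad_test(data, p: MKTLParams) -> tuple[float, float]:
    """Anderson-Darling statistic
    A = -n - (1/n) sum (2i-1)[log F(x_(i)) + log(1 - F(x_(n+1-i)))]
    with its asymptotic case-0 p-value.

    A is infinite when any PIT value hits 0 or 1 exactly; reported as inf
    with p-value 0 in that case.
    """
    f = _pit(data, p)
    n = f.size
    if np.any(f <= 0.0) or np.any(f >= 1.0):
        return math.inf, 0.0
    i = np.arange(1, n + 1)
    a = -n - float(np.mean((2 * i - 1) * (np.log(f) + np.log1p(-f[::-1]))))
    return a, _ad_sf(a)


def gof_report(data, p: MKTLParams, k: int = 2) -> GofReport:
    """Full goodness-of-fit report for an MKTL fit (k fitted parameters)."""
    data = _as_sample(data)
    n2l = -2.0 * log_likelihood(p, data)
    aic, bic, caic, hqic = information_criteria(n2l, k, data.n)
    d, ks_p = ks_test(data, p)
    w, w_p = cvm_test(data, p)
    a, a_p = ad_test(data, p)
    return GofReport(
        neg2loglik=n2l, aic=aic, bic=bic, caic=caic, hqic=hqic,
        ks_stat=d, ks_p=ks_p, w_stat=w, w_p=w_p, a_stat=a, a_p=a_p,
        k=k, n=data.n,
    )
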