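"""Parameter estimation for the MKTL distribution.

Twelve estimators, each defined as an objective over the ordered sample:

======  ======================================================================
MLE     maximum likelihood (negative log-likelihood minimized)
ADE     Anderson-Darling minimum distance
CME     Cramer-von Mises minimum distance
MPS     maximum product of spacings (mean log-spacing, maximized)
LSE     ordinary least squares on F(x_(i)) vs plotting positions i/(n+1)
RADE    right-tail Anderson-Darling
WLSE    weighted least squares (variance-weighted plotting positions)
LADE    left-tail Anderson-Darling
MSALD   minimum spacing absolute-log distance
ADLTS   left-tail Anderson-Darling of second order
PE      percentile estimator (least squares on quantiles)
MSSL    minimum spacing square-log distance
======  ======================================================================

All objectives are optimized by derivative-free search on log-parameters
(positivity enforced by construction) from a fixed multi-start grid, so
fitting is deterministic.  MPS is a maximization (the mean log-spacing is
bounded above); every other objective is minimized.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize
from statsmodels.tools.numdiff import approx_hess3

from .distribution import MKTLParams, cdf, logpdf, quantile

__all__ = [
    "METHODS",
    "UnitSample",
    "FitResult",
    "neg_log_likelihood",
    "log_likelihood",
    "score",
    "spacings",
    "objective",
    "fit",
    "fit_all",
]

METHODS: tuple[str, ...] = (
    "MLE", "ADE", "CME", "MPS", "LSE", "RADE",
    "WLSE", "LADE", "MSALD", "ADLTS", "PE", "MSSL",
)

#: fixed multi-start grid over (eta, beta); deterministic, no RNG
START_GRID: tuple[float, ...] = (0.25, 0.5, 1.0, 2.0, 4.0)

_LOG_FLOOR = 1e-300  # floor inside logs of spacings (ties give zero spacings)


@dataclass(frozen=True)
class UnitSample:
    """An ordered univariate sample on the open unit interval."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.sort(np.asarray(self.values, dtype=float))
        if v.ndim != 1 or v.size < 1:
            raise ValueError("sample must be a one-dimensional, non-empty array")
        if np.any(~np.isfinite(v)) or v[0] <= 0.0 or v[-1] >= 1.0:
            raise ValueError("all sample values must lie strictly inside (0, 1)")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class FitResult:
    """Outcome of one estimation method on one sample.

    ``loglik`` is always the MKTL log-likelihood at the returned estimate
    (whatever the objective was); ``neg2loglik`` is -2*loglik, the quantity
    information criteria are built on.  Standard errors are reported for
    MLE only (inverse observed information).
    """

    method: str
    params: MKTLParams
    loglik: float
    objective_value: float
    converged: bool
    n: int
    se: tuple[float, float] | None = None
    n_restarts_used: int = 1

    @property
    def neg2loglik(self) -> float:
        return -2.0 * self.loglik


def _as_sample(data) -> UnitSample:
    return data if isinstance(data, UnitSample) else UnitSample(np.asarray(data))


def log_likelihood(p: MKTLParams, data) -> float:
    """MKTL log-likelihood: sum of log densities over the sample."""
    data = _as_sample(data)
    return float(np.sum(logpdf(data.values, p)))


def neg_log_likelihood(p: MKTLParams, data) -> float:
    return -log_likelihood(p, data)


def score(p: MKTLParams, data) -> tuple[float, float]:
    """Analytic score (d l/d eta, d l/d beta) of the log-likelihood.

    Used as a stationarity check on returned MLEs, not by the optimizer.
    """
    data = _as_sample(data)
    x = data.values
    eta, beta = p.eta, p.beta
    n = data.n
    a = np.log(x) + np.log1p(1.0 - x)          # log G
    u = np.exp(eta * a)                        # G^eta in (0,1)
    t = (1.0 - u) / u
    d_eta = (
        n / eta
        + beta * np.sum(a)
        + (beta + 1.0) * np.sum(a * u / (1.0 - u))
        - beta * np.sum(a * t ** (-beta - 1.0) / u)
    )
    d_beta = (
        n / beta
        + eta * np.sum(a)
        - np.sum(np.log1p(-u))
        + np.sum(t ** (-beta) * np.log(t))
    )
    return float(d_eta), float(d_beta)


def _safe_cdf(x: np.ndarray, p: MKTLParams) -> np.ndarray | None:
    with np.errstate(all="ignore"):
        f = cdf(x, p)
    if np.any(~np.isfinite(f)):
        return None
    return f


def spacings(p: MKTLParams, data) -> np.ndarray:
    """The n+1 CDF spacings  F(x_(i)) - F(x_(i-1))  with F(x_(0)) = 0 and
    F(x_(n+1)) = 1.  Non-negative; they telescope to 1.  Tied observations
    legitimately produce zero spacings."""
    data = _as_sample(data)
    f = cdf(data.values, p)
    return np.diff(np.concatenate(([0.0], f, [1.0])))


def objective(method: str, p: MKTLParams, data, *, printed_form: bool = False) -> float:
    """Evaluate one estimation objective at (eta, beta) on the ordered sample.

    Returns +inf when the proposal is numerically invalid so optimizers can
    recover.  ``printed_form`` switches RADE to the variant with the
    log-survival term at the direct (unreversed) index.
    """
    method = method.upper()
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    data = _as_sample(data)
    x = data.values
    n = data.n
    i = np.arange(1, n + 1, dtype=float)

    if method == "MLE":
        with np.errstate(all="ignore"):
            val = neg_log_likelihood(p, data)
        return val if np.isfinite(val) else np.inf

    if method == "PE":
        with np.errstate(all="ignore"):
            q = quantile(i / (n + 1.0), p)
        if np.any(~np.isfinite(q)):
            return np.inf
        return float(np.sum((x - q) ** 2))

    f = _safe_cdf(x, p)
    if f is None:
        return np.inf

    if method in ("MPS", "MSALD", "MSSL"):
        lam = np.diff(np.concatenate(([0.0], f, [1.0])))
        log_lam = np.log(np.maximum(lam, _LOG_FLOOR))
        ref = -math.log(n + 1.0)
        if method == "MPS":
            return float(np.mean(log_lam))          # maximized
        if method == "MSALD":
            return float(np.sum(np.abs(log_lam - ref)))
        return float(np.sum((log_lam - ref) ** 2))  # MSSL

    with np.errstate(divide="ignore", invalid="ignore"):
        log_f = np.log(f)
        log_s = np.log1p(-f)
        inv_f = 1.0 / f

    if method == "ADE":
        # printed index log S(x_(n-i-1)) runs out of range; standard pairing
        val = -n - np.mean((2.0 * i - 1.0) * (log_f + log_s[::-1]))
    elif method == "CME":
        val = 1.0 / (12.0 * n) + np.sum((f - (2.0 * i - 1.0) / (2.0 * n)) ** 2)
    elif method == "LSE":
        val = np.sum((f - i / (n + 1.0)) ** 2)
    elif method == "WLSE":
        w = (n + 1.0) ** 2 * (n + 2.0) / (i * (n - i + 1.0))
        val = np.sum(w * (f - i / (n + 1.0)) ** 2)
    elif method == "RADE":
        ls = log_s if printed_form else log_s[::-1]
        val = n / 2.0 - 2.0 * np.sum(f) - np.mean((2.0 * i - 1.0) * ls)
    elif method == "LADE":
        val = -1.5 * n + 2.0 * np.sum(f) - np.mean((2.0 * i - 1.0) * log_f)
    elif method == "ADLTS":
        # second term 1/F per the objective's own derivative (F^2 denominator)
        with np.errstate(invalid="ignore"):
            val = 2.0 * np.sum(log_f) + np.mean((2.0 * i - 1.0) * inv_f)
    else:  # pragma: no cover
        raise AssertionError(method)
    return float(val) if np.isfinite(val) else np.inf


def _mle_standard_errors(p: MKTLParams, data: UnitSample) -> tuple[float, float] | None:
    """SEs from the inverse of the numerically differenced observed information."""

    def nll(theta):
        e, b = theta
        if e <= 0 or b <= 0:
            return np.inf
        return neg_log_likelihood(MKTLParams(e, b), data)

    try:
        hess = approx_hess3(np.array(p.as_tuple()), nll)
        cov = np.linalg.inv(hess)
        d = np.diag(cov)
        if np.any(d <= 0):
            return None
        return (math.sqrt(d[0]), math.sqrt(d[1]))
    except (np.linalg.LinAlgError, FloatingPointError):
        return None


def fit(
    data,
    method: str = "MLE",
    *,
    starts: Sequence[tuple[float, float]] | None = None,
    compute_se: bool | None = None,
    printed_form: bool = False,
    xatol: float = 1e-8,
    fatol: float = 1e-10,
    maxiter: int = 4000,
) -> FitResult:
    """Fit the MKTL distribution to a unit-interval sample by one method.

    Parameters
    ----------
    data : UnitSample or array_like
        Values strictly in (0, 1); at least 3 observations.
    method : str
        One of :data:`METHODS`.
    starts : sequence of (eta, beta), optional
        Starting points for the local searches.  Default is the fixed 5x5
        grid ``START_GRID x START_GRID``; the best objective value wins
        (ties broken by grid order), so the fit is deterministic.
    compute_se : bool, optional
        Report observed-information standard errors.  Defaults to True for
        MLE, False otherwise (non-MLE methods report estimates only).

    Notes
    -----
    Degenerate data (all values equal) is rejected.  Non-convergence of
    every local search is flagged on the result; the best point found is
    still returned.
    """
    method = method.upper()
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    data = _as_sample(data)
    if data.n < 3:
        raise ValueError("fitting requires at least 3 observations")
    if data.values[0] == data.values[-1]:
        raise ValueError("degenerate sample: all values identical")
    sign = -1.0 if method == "MPS" else 1.0

    def wrapped(z):
        # large finite sentinel (not inf) so the simplex arithmetic stays clean
        try:
            e, b = math.exp(z[0]), math.exp(z[1])
            val = objective(method, MKTLParams(e, b), data, printed_form=printed_form)
        except (OverflowError, ValueError):
            return 1e300
        return sign * val if np.isfinite(val) else 1e300

    if starts is None:
        starts = [(e, b) for e in START_GRID for b in START_GRID]
    best = None
    any_converged = False
    for e0, b0 in starts:
        res = optimize.minimize(
            wrapped,
            np.log([e0, b0]),
            method="Nelder-Mead",
            options={"xatol": xatol, "fatol": fatol, "maxiter": maxiter, "maxfev": maxiter},
        )
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    params = MKTLParams(*np.exp(best.x))
    if compute_se is None:
        compute_se = method == "MLE"
    se = _mle_standard_errors(params, data) if compute_se else None
    return FitResult(
        method=method,
        params=params,
        loglik=log_likelihood(params, data),
        objective_value=sign * float(best.fun),
        converged=bool(any_converged and np.isfinite(best.fun)),
        n=data.n,
        se=se,
        n_restarts_used=len(starts),
    )


def fit_all(data, methods: Sequence[str] = METHODS, **kwargs) -> dict[str, FitResult]:
    """Fit with several methods; returns a dict keyed by method name."""
    return {m: fit(data, m, **kwargs) for m in methods}
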