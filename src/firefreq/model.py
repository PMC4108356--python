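"""Discrete lognormal fire-interval model.

The fire interval T (whole years between consecutive fires at a point) is
modelled by discretizing a lognormal distribution at integer cut-points:

    f(t) = Phi((ln t - mu)/sigma) - Phi((ln(t-1) - mu)/sigma),   t = 1, 2, ...
    A(t) = 1 - Phi((ln t - mu)/sigma)                            (survival)
    lambda(t) = f(t) / A(t-1)                                    (hazard of burning)

where Phi is the standard normal CDF.  A(t) is the probability that a
vegetation patch stays unburned for more than t years since its last fire;
lambda(t) is the conditional probability of burning in year t given survival
to the start of year t.  Parameters are estimated by maximum likelihood from
a censored sample of interval observations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.stats import norm

__all__ = [
    "CensorStatus",
    "DiscreteLognormalParams",
    "IntervalObservation",
    "FitResult",
    "interval_pmf",
    "survival",
    "hazard",
    "derived_descriptors",
    "log_likelihood",
    "fit_mle",
]


class CensorStatus(str, Enum):
    """Censoring status of a fire-interval observation."""

    COMPLETE = "complete"
    RIGHT_CENSORED = "right_censored"
    LEFT_CENSORED = "left_censored"


@dataclass(frozen=True)
class DiscreteLognormalParams:
    """Parameters (mu, sigma) of the discrete lognormal interval model.

    mu and sigma are on the log-year scale; sigma must be strictly positive.
    """

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.mu):
            raise ValueError(f"mu must be finite, got {self.mu}")
        if not (math.isfinite(self.sigma) and self.sigma > 0):
            raise ValueError(f"sigma must be finite and > 0, got {self.sigma}")


@dataclass(frozen=True)
class IntervalObservation:
    """One fire-interval observation with censoring status and class label.

    ``length`` is in whole years.  Complete intervals have length >= 1.
    Censored observations may have length 0, in which case they carry no
    likelihood information (survival beyond 0 years is certain).
    """

    length: int
    status: CensorStatus
    class_label: str = ""

    def __post_init__(self) -> None:
        if self.length != int(self.length) or self.length < 0:
            raise ValueError(f"length must be a nonnegative integer, got {self.length}")
        if self.status == CensorStatus.COMPLETE.value and self.length < 1:
            raise ValueError("complete observations must have length >= 1")


@dataclass
class FitResult:
    """Maximum-likelihood fit with derived fire-regime descriptors."""

    params: DiscreteLognormalParams
    log_likelihood: float
    n_complete: int
    n_right: int
    n_left: int
    median: int
    mode: int
    turning_point: int
    converged: bool
    degenerate: bool = False
    message: str = ""


def _zvals(t: np.ndarray, params: DiscreteLognormalParams) -> np.ndarray:
    # (ln t - mu)/sigma with ln 0 -> -inf
    with np.errstate(divide="ignore"):
        return (np.log(t) - params.mu) / params.sigma


def interval_pmf(t, params: DiscreteLognormalParams):
    """P(T = t): probability the time between consecutive fires equals t years.

    Vectorized over t; each t must be an integer >= 1.
    """
    t = np.asarray(t)
    if np.any(t < 1) or np.any(t != np.floor(t)):
        raise ValueError("interval_pmf requires integer t >= 1")
    t = t.astype(float)
    upper = norm.cdf(_zvals(t, params))
    lower = np.where(t > 1, norm.cdf(_zvals(np.maximum(t - 1, 1e-300), params)), 0.0)
    out = upper - lower
    return out if out.ndim else float(out)


def survival(t, params: DiscreteLognormalParams):
    """A(t) = P(T > t): probability of surviving fire longer than t years.

    A(0) = 1.  Vectorized over integer t >= 0; non-increasing in t.
    """
    t = np.asarray(t)
    if np.any(t < 0) or np.any(t != np.floor(t)):
        raise ValueError("survival requires integer t >= 0")
    t = t.astype(float)
    out = np.where(t == 0, 1.0, norm.sf(_zvals(np.maximum(t, 1e-300), params)))
    return out if out.ndim else float(out)


def hazard(t, params: DiscreteLognormalParams):
    """lambda(t) = f(t)/A(t-1): conditional probability of burning in year t.

    The denominator is P(T >= t) = A(t-1), the probability of entering year t
    unburned.  Raises if the denominator underflows to 0 (support horizon
    exceeded) rather than returning 0/0.
    """
    t = np.asarray(t)
    if np.any(t < 1) or np.any(t != np.floor(t)):
        raise ValueError("hazard requires integer t >= 1")
    denom = np.asarray(survival(t - 1, params))
    if np.any(denom <= 0.0):
        raise FloatingPointError(
            "survival(t-1) underflowed to 0: hazard undefined beyond the support horizon"
        )
    out = np.asarray(interval_pmf(t, params)) / denom
    return out if out.ndim else float(out)


def derived_descriptors(params: DiscreteLognormalParams, t_max: int = 100) -> tuple[int, int, int]:
    """Median, mode and hazard turning point of the interval distribution.

    median  -- smallest integer >= exp(mu)
    mode    -- smallest integer >  exp(mu - sigma^2)
    turning point -- fuel age at which the hazard attains its maximum over
                     {1..t_max}; ties broken toward the smallest age.  A
                     turning point of 1 means the hazard only decreases.
    """
    if t_max < 1:
        raise ValueError("t_max must be >= 1")
    median = max(1, math.ceil(math.exp(params.mu)))
    mode = max(1, math.floor(math.exp(params.mu - params.sigma**2)) + 1)
    ts = np.arange(1, t_max + 1)
    haz = np.asarray(hazard(ts, params))
    turning_point = int(ts[np.argmax(haz)])
    return median, mode, turning_point


def expected_interval(params: DiscreteLognormalParams) -> float:
    """Mean fire interval E[T] = sum_t t*f(t) = sum_{a>=0} A(a) (tail sum)."""
    log_horizon = params.mu + 8.0 * params.sigma
    if log_horizon > math.log(5e6):
        # far-tail params: continuous lognormal mean plus half-step
        # discretization offset (error < 1 year, negligible on this scale)
        mean_log = params.mu + params.sigma**2 / 2.0
        return math.exp(min(mean_log, 700.0)) + 0.5
    ages = np.arange(0, int(math.exp(log_horizon)) + 2)
    return float(np.sum(survival(ages, params)))


def _sample_arrays(sample: Sequence[IntervalObservation]):
    lengths = np.array([obs.length for obs in sample], dtype=int)
    status = np.array([obs.status.value for obs in sample])
    return lengths, status


def log_likelihood(
    sample: Sequence[IntervalObservation],
    params: DiscreteLognormalParams,
    stationary: bool = False,
    record_years: int | None = None,
) -> float:
    """Censored-data log-likelihood of the discrete lognormal model.

    Default contributions: complete interval t -> ln f(t); right-censored
    open interval of length t -> ln A(t) (the next fire is known not to have
    come within t years); left-censored observed length l -> ln A(l-1) (the
    interval is known to be at least l years).  Censored observations of
    length 0 contribute exactly 0.

    With ``stationary=True`` the boundary observations of a record window
    cut from a long-running (stationary) fire regime are given their exact
    renewal-theory terms instead.  The first observed fire time is a forward
    recurrence time V, whose pmf is A(v-1)/E[T]; a left-censored observation
    of length l therefore contributes ln A(l-1) - ln E[T].  The interval in
    progress at the start of the window is a length-biased draw (inspection
    paradox), so the plain left-censored term overweights long intervals and
    biases the fit upward; the 1/E[T] factor removes that bias.  If
    ``record_years`` is given, right-censored observations of that length
    are recognized as never-burned points and contribute
    ln P(V > N) = ln(sum_{a>=N} A(a)) - ln E[T].
    """
    if len(sample) == 0:
        raise ValueError("log_likelihood requires a non-empty sample")
    lengths, status = _sample_arrays(sample)
    ll = 0.0
    informative = False

    comp = lengths[status == CensorStatus.COMPLETE.value]
    if comp.size:
        p = np.asarray(interval_pmf(comp, params), dtype=float).reshape(-1)
        with np.errstate(divide="ignore"):
            ll += float(np.sum(np.log(p)))
        informative = True

    right = lengths[status == CensorStatus.RIGHT_CENSORED.value]
    n_never = 0
    if stationary and record_years is not None:
        never = right >= record_years
        n_never = int(never.sum())
        right = right[~never]
    right = right[right > 0]
    if right.size:
        s = np.asarray(survival(right, params), dtype=float).reshape(-1)
        with np.errstate(divide="ignore"):
            ll += float(np.sum(np.log(s)))
        informative = True

    left = lengths[status == CensorStatus.LEFT_CENSORED.value]
    n_left_stat = 0
    if stationary:
        n_left_stat = int(np.sum(left >= 1))
    left = left[left > 1]  # l = 1 gives A(0) = 1, contribution 0
    if left.size:
        s = np.asarray(survival(left - 1, params), dtype=float).reshape(-1)
        with np.errstate(divide="ignore"):
            ll += float(np.sum(np.log(s)))
        informative = True

    if stationary and (n_left_stat or n_never):
        et = expected_interval(params)
        ll -= (n_left_stat + n_never) * math.log(et)
        if n_never:
            # P(V > N): mass of the forward recurrence time beyond the record
            n = record_years
            log_h = min(params.mu + 8.0 * params.sigma, math.log(5e6))
            horizon = int(min(5e6, max(n + 1, math.exp(log_h)) + 2))
            tail = float(np.sum(survival(np.arange(n, horizon), params)))
            with np.errstate(divide="ignore"):
                ll += n_never * math.log(max(tail, 1e-300))
        informative = True

    if not informative:
        raise ValueError("sample contains no informative observations (all censored with length 0)")
    return ll


_SIGMA_FLOOR = 1e-3


def fit_mle(
    sample: Sequence[IntervalObservation],
    t_max: int = 100,
    stationary: bool = True,
    record_years: int | None = None,
) -> FitResult:
    """Fit (mu, sigma) by maximizing the censored-data log-likelihood.

    Optimizes over (mu, ln sigma) with a bounded quasi-Newton method
    (L-BFGS-B); the log parameterization keeps sigma > 0 without an active
    boundary.  Starting values are the mean and standard deviation of the log
    complete intervals (sigma floored at 0.1).  Deterministic given the
    sample.  Samples with fewer than 2 complete observations, or with zero
    variance in log intervals, are flagged degenerate.

    By default the stationary-renewal boundary terms are used for
    left-censored (and, when ``record_years`` is given, never-burned)
    observations — see :func:`log_likelihood`; without the correction the
    length-biased interval straddling the record start drags the estimates
    upward.  Pass ``stationary=False`` for the plain censored-data
    likelihood.
    """
    if len(sample) == 0:
        raise ValueError("fit_mle requires a non-empty sample")
    lengths, status = _sample_arrays(sample)
    comp = lengths[status == CensorStatus.COMPLETE.value]
    n_complete = int(comp.size)
    n_right = int(np.sum(status == CensorStatus.RIGHT_CENSORED.value))
    n_left = int(np.sum(status == CensorStatus.LEFT_CENSORED.value))

    def _result(params, ll, converged, degenerate, message):
        median, mode, tp = derived_descriptors(params, t_max=t_max)
        return FitResult(
            params=params,
            log_likelihood=ll,
            n_complete=n_complete,
            n_right=n_right,
            n_left=n_left,
            median=median,
            mode=mode,
            turning_point=tp,
            converged=converged,
            degenerate=degenerate,
            message=message,
        )

    if n_complete < 2:
        raise ValueError(
            f"fit_mle needs >= 2 complete observations to identify (mu, sigma); got {n_complete}"
        )

    logs = np.log(comp.astype(float))
    mu0 = float(np.mean(logs))
    sd0 = float(np.std(logs, ddof=1)) if n_complete > 1 else 0.0
    degenerate_start = sd0 < 1e-12
    sigma0 = max(sd0, 0.1)

    def nll(theta):
        mu, log_sigma = theta
        if abs(mu) > 20 or abs(log_sigma) > 10:
            return 1e12
        p = DiscreteLognormalParams(mu, math.exp(log_sigma))
        try:
            return -log_likelihood(sample, p, stationary=stationary, record_years=record_years)
        except (ValueError, FloatingPointError):
            return 1e12

    res = minimize(
        nll,
        x0=np.array([mu0, math.log(sigma0)]),
        method="L-BFGS-B",
        bounds=[(-10.0, 10.0), (math.log(_SIGMA_FLOOR), 5.0)],
    )
    mu_hat, log_sigma_hat = res.x
    sigma_hat = math.exp(float(log_sigma_hat))
    params = DiscreteLognormalParams(float(mu_hat), sigma_hat)
    at_floor = sigma_hat <= _SIGMA_FLOOR * (1 + 1e-6)
    degenerate = degenerate_start or at_floor
    message = res.message if isinstance(res.message, str) else str(res.message)
    if degenerate:
        message = (message + "; sigma at lower bound (zero-variance sample)").strip("; ")
    return _result(params, -float(res.fun), bool(res.success), degenerate, message)
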