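"""Poisson and double-Poisson (hypoexponential) waiting-time models.

Permeation events through a wide, highly conductive channel arrive nearly
independently, so inter-event waiting times are to first order exponential
with a single rate λ (a homogeneous Poisson process). Observed waiting
times, however, show a refractory-like deficit of very short intervals:
an ion that has just entered the pore mouth transiently repels the next
one. That delay is modelled as a second exponential stage chained in front
of the conduction stage, giving a hypoexponential ("double-Poisson")
waiting-time density with rates λ_lag and λ_cond. The mean inter-event time
is then 1/λ_lag + 1/λ_cond and the expected event count over a window T is
T divided by that mean.

Estimators provided:

* count rate λ = N/Δt;
* the order-statistic quantile regression t_(i) ~ −ln(1 − i/N) through the
  origin, whose slope is 1/λ;
* maximum likelihood (and binned least squares) for the hypoexponential
  pair;
* log-normal maximum likelihood for event durations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "PoissonModel",
    "DoublePoissonModel",
    "DurationFit",
    "poisson_pdf",
    "poisson_cdf",
    "rate_from_counts",
    "fit_poisson_quantile",
    "dp_pdf",
    "dp_cdf",
    "fit_double_poisson",
    "predicted_events",
    "fit_durations",
]

# Relative rate separation below which the Erlang-2 limit is used.
_EQUAL_RATE_RTOL = 1e-9


@dataclass
class PoissonModel:
    """Single-rate exponential waiting-time model; lam in events/ns."""

    lam: float
    source: str = "count_rate"  # or "quantile_fit"
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.degenerate and self.lam <= 0:
            raise ValueError("rate must be positive")

    @property
    def mean_waiting_time(self) -> float:
        return 1.0 / self.lam


@dataclass
class DoublePoissonModel:
    """Hypoexponential waiting-time model: lag stage + conduction stage.

    By convention lam_lag >= lam_cond (the lag is the faster stage, i.e.
    the shorter mean delay). Rates in events/ns.
    """

    lam_lag: float
    lam_cond: float
    log_likelihood: float | None = None
    n: int | None = None
    near_degenerate: bool = False
    converged: bool = True
    method: str = "analytic"

    def __post_init__(self) -> None:
        if self.lam_lag <= 0 or self.lam_cond <= 0:
            raise ValueError("both rates must be positive")

    @property
    def mean_waiting_time(self) -> float:
        return 1.0 / self.lam_lag + 1.0 / self.lam_cond

    def pdf(self, t):
        return dp_pdf(self, t)

    def cdf(self, t):
        return dp_cdf(self, t)


@dataclass
class DurationFit:
    """Log-normal fit to event durations: mu, sigma of log-duration (ns)."""

    mu: float
    sigma: float
    n: int
    degenerate: bool = False

    @property
    def implied_mean(self) -> float:
        return float(np.exp(self.mu + self.sigma**2 / 2.0))


def _check_t(t):
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("waiting time must be nonnegative")
    return t


def poisson_pdf(model: PoissonModel, t):
    """f(t) = λ e^(−λt) for t ≥ 0."""
    t = _check_t(t)
    return model.lam * np.exp(-model.lam * t)


def poisson_cdf(model: PoissonModel, t):
    """F(t) = 1 − e^(−λt) for t ≥ 0."""
    t = _check_t(t)
    return -np.expm1(-model.lam * t)


def rate_from_counts(event_count: int, dt: float) -> PoissonModel:
    """Count-rate estimator λ = N/Δt (events/ns)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    if event_count == 0:
        warnings.warn("zero events: degenerate Poisson model (lam=0)", stacklevel=2)
        return PoissonModel(lam=0.0, source="count_rate", degenerate=True)
    return PoissonModel(lam=event_count / dt, source="count_rate")


def fit_poisson_quantile(waiting_times) -> PoissonModel:
    """Order-statistic regression estimator of the Poisson rate.

    Sorted waiting times t_(i) are regressed (through the origin, the
    shortest possible waiting time) on x_i = −ln(1 − i/N) for i = 1..N−1;
    the slope is the mean waiting time 1/λ. The i = N point is dropped
    (x_N diverges).
    """
    w = np.sort(np.asarray(waiting_times, dtype=float))
    n = len(w)
    if n < 3:
        raise ValueError("need at least 3 waiting times")
    i = np.arange(1, n)
    x = -np.log1p(-i / n)
    y = w[:-1]
    slope = float(np.dot(x, y) / np.dot(x, x))
    if slope <= 0:
        raise ValueError("degenerate waiting-time sample (non-positive slope)")
    return PoissonModel(lam=1.0 / slope, source="quantile_fit")


def _dp_rates(model: DoublePoissonModel) -> tuple[float, float]:
    return float(model.lam_lag), float(model.lam_cond)


def dp_pdf(model: DoublePoissonModel, t):
    """Hypoexponential density, order-symmetric in the two rates.

    f(t) = λ1 λ2 (e^(−λ2 t) − e^(−λ1 t)) / (λ1 − λ2), continuous at
    λ1 = λ2 where it equals the Erlang-2 density λ² t e^(−λt).
    """
    t = _check_t(t)
    l1, l2 = _dp_rates(model)
    if abs(l1 - l2) <= _EQUAL_RATE_RTOL * max(l1, l2):
        lam = 0.5 * (l1 + l2)
        return lam**2 * t * np.exp(-lam * t)
    return l1 * l2 / (l1 - l2) * (np.exp(-l2 * t) - np.exp(-l1 * t))


def dp_cdf(model: DoublePoissonModel, t):
    """Hypoexponential CDF, continuous in the equal-rate (Erlang-2) limit."""
    t = _check_t(t)
    l1, l2 = _dp_rates(model)
    if abs(l1 - l2) <= _EQUAL_RATE_RTOL * max(l1, l2):
        lam = 0.5 * (l1 + l2)
        return 1.0 - np.exp(-lam * t) * (1.0 + lam * t)
    return 1.0 - (l1 * np.exp(-l2 * t) - l2 * np.exp(-l1 * t)) / (l1 - l2)


def _dp_logpdf(t, l1, l2):
    # stable log-density: log(l1 l2) - l2 t + log((1 - e^{-(l1-l2) t})/(l1-l2))
    # written for l1 > l2; symmetric wrapper below.
    if l1 < l2:
        l1, l2 = l2, l1
    d = l1 - l2
    if d <= _EQUAL_RATE_RTOL * l1:
        lam = 0.5 * (l1 + l2)
        with np.errstate(divide="ignore"):
            return 2 * np.log(lam) + np.log(t) - lam * t
    with np.errstate(divide="ignore"):
        return np.log(l1) + np.log(l2) - l2 * t + np.log(-np.expm1(-d * t)) - np.log(d)


def _moment_init(w: np.ndarray) -> tuple[float, float, bool]:
    """Initial (λ1, λ2) from mean/variance matching; degeneracy flag.

    For a hypoexponential, mean = a + b and var = a² + b² with a, b the
    stage means; var ≥ mean² has no two-stage solution (sample looks like
    a single exponential or is over-dispersed).
    """
    m = float(np.mean(w))
    v = float(np.var(w, ddof=1))
    if v >= m * m:
        # indistinguishable from single exponential: lag stage pushed fast
        return 50.0 / m, 1.0 / m, True
    ab = (m * m - v) / 2.0
    disc = m * m - 4.0 * ab
    if disc < 0:
        # var < mean²/2: under-dispersed beyond Erlang-2; start at equal rates
        a = b = m / 2.0
    else:
        a = (m + np.sqrt(disc)) / 2.0
        b = m - a
    return 1.0 / min(a, b), 1.0 / max(a, b), False


def fit_double_poisson(waiting_times, method: str = "mle", bins: int = 30) -> DoublePoissonModel:
    """Fit (λ_lag, λ_cond) to a waiting-time sample.

    method="mle" (default) maximizes the hypoexponential likelihood,
    initialized from moment matching; method="lsq" least-squares fits the
    density to a binned empirical histogram. Rates are returned with
    λ_lag ≥ λ_cond. A sample whose variance is at least its squared mean is
    flagged near-degenerate (a single exponential explains it).
    """
    w = np.asarray(waiting_times, dtype=float)
    w = w[w > 0]
    if len(w) < 10:
        raise ValueError("need at least 10 positive waiting times")
    l1_0, l2_0, near_deg = _moment_init(w)
    if near_deg:
        warnings.warn(
            "sample variance >= mean^2: double-Poisson fit is near-degenerate "
            "(indistinguishable from a single exponential)",
            stacklevel=2,
        )

    if method == "mle":
        def nll(theta):
            l1, l2 = np.exp(theta)
            return -float(np.sum(_dp_logpdf(w, l1, l2)))

        res = optimize.minimize(
            nll, np.log([l1_0, l2_0]), method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000},
        )
        l1, l2 = np.exp(res.x)
        loglik = -float(res.fun)
        converged = bool(res.success)
        if not converged:
            warnings.warn(f"double-Poisson MLE did not converge: {res.message}", stacklevel=2)
    elif method == "lsq":
        dens, edges = np.histogram(w, bins=bins, density=True)
        mids = 0.5 * (edges[:-1] + edges[1:])

        def resid(theta):
            l1, l2 = np.exp(theta)
            return dp_pdf(DoublePoissonModel(max(l1, l2), min(l1, l2)), mids) - dens

        res = optimize.least_squares(resid, np.log([l1_0, l2_0]))
        l1, l2 = np.exp(res.x)
        loglik = float(np.sum(_dp_logpdf(w, l1, l2)))
        converged = bool(res.success)
    else:
        raise ValueError(f"unknown method {method!r}")

    lam_lag, lam_cond = max(l1, l2), min(l1, l2)
    if not near_deg and lam_lag / lam_cond > 50.0:
        # the lag stage fitted away: one exponential explains the sample
        near_deg = True
        warnings.warn(
            "fitted lag rate dwarfs the conduction rate: near-degenerate fit "
            "(indistinguishable from a single exponential)",
            stacklevel=2,
        )
    return DoublePoissonModel(
        lam_lag=float(lam_lag),
        lam_cond=float(lam_cond),
        log_likelihood=loglik,
        n=len(w),
        near_degenerate=near_deg,
        converged=converged,
        method=method,
    )


def predicted_events(model, T: float) -> float:
    """Expected event count over a window of length T (ns).

    λT for a Poisson model; T / (1/λ_lag + 1/λ_cond) for the double-Poisson
    model (window divided by the mean inter-event time).
    """
    if T <= 0:
        raise ValueError("T must be positive")
    if isinstance(model, DoublePoissonModel):
        return T / model.mean_waiting_time
    return model.lam * T


def fit_durations(durations) -> DurationFit:
    """Log-normal MLE on event durations (ns): μ, σ of log-duration."""
    d = np.asarray(durations, dtype=float)
    if len(d) < 5:
        raise ValueError("need at least 5 durations")
    if np.any(d <= 0):
        raise ValueError("durations must be positive")
    logs = np.log(d)
    mu = float(np.mean(logs))
    sigma = float(np.std(logs, ddof=0))  # MLE uses the biased sd
    degenerate = sigma < 1e-12
    if degenerate:
        warnings.warn("all durations equal: sigma -> 0, fit degenerate", stacklevel=2)
        sigma = max(sigma, 1e-300)
    return DurationFit(mu=mu, sigma=sigma, n=len(d), degenerate=degenerate)


def lognormal_params_for_mean(mean: float, sigma: float) -> tuple[float, float]:
    """(μ, σ) of a log-normal with the given arithmetic mean and log-sd."""
    if mean <= 0 or sigma <= 0:
        raise ValueError("mean and sigma must be positive")
    return float(np.log(mean) - sigma**2 / 2.0), float(sigma)


def sample_waiting_times(model, n: int, seed) -> np.ndarray:
    """Draw n i.i.d. waiting times (ns) from a Poisson or double-Poisson model.

    Double-Poisson draws are the sum of two independent exponentials with
    rates λ_lag and λ_cond. ``seed`` may be an int or a numpy Generator.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if isinstance(model, DoublePoissonModel):
        return rng.exponential(1.0 / model.lam_lag, n) + rng.exponential(1.0 / model.lam_cond, n)
    if model.lam <= 0:
        raise ValueError("rate must be positive")
    return rng.exponential(1.0 / model.lam, n)
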