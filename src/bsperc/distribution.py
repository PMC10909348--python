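"""Two-parameter Birnbaum-Saunders (fatigue-life) distribution.

The Birnbaum-Saunders distribution BS(α, β) is a positive, right-skewed
distribution with shape parameter α > 0 and scale parameter β > 0.  It arises
as the first-passage time of cumulative damage past a threshold and is a
standard model for failure times and for ambient pollutant concentrations.
Its defining property is that

    Z = (√(X/β) − √(β/X)) / α

is standard normal, so the p-th percentile has the closed form

    θ_p = (β/4) (α z_p + √(α² z_p² + 4))²,   z_p = Φ⁻¹(p),

and in particular the median equals β for every α.

This module provides the density, distribution function, percentile
(quantile) function, random generation, the sufficient summaries used by the
generalized pivotal quantities, and maximum-likelihood fitting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.special import ndtr, ndtri

__all__ = [
    "BSParams",
    "PercentileSpec",
    "SampleStats",
    "MLEResult",
    "EstimationError",
    "bs_pdf",
    "bs_logpdf",
    "bs_cdf",
    "bs_percentile",
    "bs_from_normal",
    "bs_rvs",
    "bs_loglik",
    "sufficient_stats",
    "bs_mle",
]

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


class EstimationError(RuntimeError):
    """Raised when an iterative fit fails to converge."""


@dataclass(frozen=True)
class BSParams:
    """Shape/scale pair (α, β) of a Birnbaum-Saunders distribution."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.alpha) and self.alpha > 0):
            raise ValueError(f"shape alpha must be a positive real, got {self.alpha!r}")
        if not (np.isfinite(self.beta) and self.beta > 0):
            raise ValueError(f"scale beta must be a positive real, got {self.beta!r}")


@dataclass(frozen=True)
class PercentileSpec:
    """A percentile level p ∈ (0, 1) and its standard-normal quantile z_p."""

    p: float

    def __post_init__(self) -> None:
        if not (0.0 < self.p < 1.0):
            raise ValueError(f"percentile level p must lie in (0, 1), got {self.p!r}")

    @property
    def z_p(self) -> float:
        return float(ndtri(self.p))


@dataclass(frozen=True)
class SampleStats:
    """Sufficient summaries of a positive sample on the √x and 1/√x scales.

    I and J are the sample means of √x_i and 1/√x_i; K and L the corresponding
    sums of squared deviations; S1 = Σ x_i and S2 = Σ 1/x_i.  These feed the
    generalized pivotal quantities for (β, α).
    """

    n: int
    I: float
    J: float
    K: float
    L: float
    S1: float
    S2: float


@dataclass(frozen=True)
class MLEResult:
    """Maximum-likelihood fit: parameter estimates plus fit diagnostics."""

    params: BSParams
    loglik: float
    converged: bool
    n_widenings: int = 0


def _as_sample(x, min_n: int = 1) -> np.ndarray:
    """Validate and return a 1-D array of strictly positive finite reals."""
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size < min_n:
        raise ValueError(f"sample must contain at least {min_n} values, got {arr.size}")
    bad = np.flatnonzero(~(np.isfinite(arr) & (arr > 0)))
    if bad.size:
        i = int(bad[0])
        raise ValueError(
            f"sample values must be positive finite reals; offending index {i} "
            f"(value {arr[i]!r})"
        )
    return arr


def _as_positive(x, name: str = "x") -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if np.any(~(np.isfinite(arr) & (arr > 0))):
        raise ValueError(f"{name} must be strictly positive and finite")
    return arr


def bs_logpdf(x, params: BSParams):
    """Log-density of BS(α, β), finite for every x > 0."""
    x = _as_positive(x)
    a, b = params.alpha, params.beta
    r = b / x
    # log((β/x)^{1/2} + (β/x)^{3/2}) = ½log(β/x) + log1p(β/x)
    out = (
        -math.log(2.0 * a * b)
        - _LOG_SQRT_2PI
        + 0.5 * np.log(r)
        + np.log1p(r)
        - (1.0 / r + r - 2.0) / (2.0 * a * a)
    )
    return out if out.ndim else float(out)


def bs_pdf(x, params: BSParams):
    """Density of BS(α, β); zero mass at and below the origin is enforced."""
    out = np.exp(bs_logpdf(x, params))
    return out if np.ndim(out) else float(out)


def bs_cdf(x, params: BSParams):
    """Distribution function Φ((√(x/β) − √(β/x)) / α)."""
    x = _as_positive(x)
    a, b = params.alpha, params.beta
    s = np.sqrt(x / b)
    out = ndtr((s - 1.0 / s) / a)
    return out if out.ndim else float(out)


def bs_percentile(params: BSParams, spec: PercentileSpec | float):
    """Closed-form p-th percentile θ_p = (β/4)(α z_p + √(α² z_p² + 4))²."""
    if not isinstance(spec, PercentileSpec):
        spec = PercentileSpec(float(spec))
    a, b = params.alpha, params.beta
    az = a * spec.z_p
    return float(b / 4.0 * (az + math.sqrt(az * az + 4.0)) ** 2)


def bs_from_normal(z, params: BSParams):
    """Map standard-normal variates through X = β(1 + α²Z²/2 + αZ√(α²Z²/4 + 1)).

    The inverse of Z = (√(X/β) − √(β/X))/α; Z = 0 maps to the median β.
    """
    z = np.asarray(z, dtype=float)
    az = params.alpha * z
    out = params.beta * (1.0 + az * az / 2.0 + az * np.sqrt(az * az / 4.0 + 1.0))
    return out if out.ndim else float(out)


def bs_rvs(params: BSParams, n: int, rng) -> np.ndarray:
    """Draw n variates by transforming standard normals through ``bs_from_normal``."""
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(rng)
    return bs_from_normal(rng.standard_normal(n), params)


def bs_loglik(sample, params: BSParams) -> float:
    """Total log-likelihood of a sample under BS(α, β)."""
    x = _as_sample(sample)
    return float(np.sum(bs_logpdf(x, params)))


def sufficient_stats(sample) -> SampleStats:
    """Compute the sufficient summaries (n, I, J, K, L, S1, S2)."""
    x = _as_sample(sample, min_n=2)
    sqrt_x = np.sqrt(x)
    inv_sqrt_x = 1.0 / sqrt_x
    i_bar = float(sqrt_x.mean())
    j_bar = float(inv_sqrt_x.mean())
    return SampleStats(
        n=int(x.size),
        I=i_bar,
        J=j_bar,
        K=float(np.sum((sqrt_x - i_bar) ** 2)),
        L=float(np.sum((inv_sqrt_x - j_bar) ** 2)),
        S1=float(x.sum()),
        S2=float(np.sum(1.0 / x)),
    )


def _profile_alpha_sq(beta: float, s: float, m2: float) -> float:
    """α̂²(β) = S1/(nβ) + β S2/n − 2, with s = mean(x) and m2 = mean(1/x)."""
    return s / beta + beta * m2 - 2.0


def bs_mle(sample, *, max_widenings: int = 8, xatol: float = 1e-12) -> MLEResult:
    """Maximum-likelihood fit of BS(α, β).

    The shape is profiled out in closed form, α̂²(β) = mean(x)/β + β·mean(1/x) − 2,
    and the resulting one-dimensional profile log-likelihood is maximized over
    log β by bounded Brent search.  The initial bracket [min x, max x] is widened
    geometrically if the optimum pins to an endpoint.  A constant sample is
    rejected: it drives α̂ to zero and degenerates every downstream pivotal
    quantity.
    """
    x = _as_sample(sample, min_n=2)
    if np.ptp(x) == 0.0:
        raise ValueError("sample is constant; the Birnbaum-Saunders MLE is degenerate")
    n = x.size
    s = float(x.mean())
    m2 = float(np.mean(1.0 / x))
    log_x = np.log(x)

    def neg_profile(log_beta: float) -> float:
        beta = math.exp(log_beta)
        a2 = _profile_alpha_sq(beta, s, m2)
        if a2 <= 0.0:  # only possible through rounding; AM-GM gives a2 >= 0
            return np.inf
        # profile log-lik up to an additive constant in the data
        term = 0.5 * (n * log_beta - log_x.sum()) + np.sum(np.log1p(beta / x))
        return -(-0.5 * n * math.log(a2) - n * log_beta + float(term))

    lo, hi = math.log(x.min()), math.log(x.max())
    widenings = 0
    while True:
        res = optimize.minimize_scalar(
            neg_profile, bounds=(lo, hi), method="bounded", options={"xatol": xatol}
        )
        edge = min(res.x - lo, hi - res.x) < 1e-6
        if res.success and not edge:
            break
        widenings += 1
        if widenings > max_widenings:
            raise EstimationError(
                f"profile-likelihood maximization did not converge inside "
                f"[{math.exp(lo):g}, {math.exp(hi):g}] after {max_widenings} widenings"
            )
        span = hi - lo
        lo -= 0.5 * span
        hi += 0.5 * span

    beta_hat = math.exp(res.x)
    alpha_hat = math.sqrt(_profile_alpha_sq(beta_hat, s, m2))
    params = BSParams(alpha=alpha_hat, beta=beta_hat)
    return MLEResult(
        params=params,
        loglik=bs_loglik(x, params),
        converged=True,
        n_widenings=widenings,
    )
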