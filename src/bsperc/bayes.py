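"""Bayesian inference for a Birnbaum-Saunders percentile.

Priors are inverse gamma on the scale β ~ IG(a1, b1) and on the squared shape
α² ~ IG(a2, b2), near-flat by default (all hyperparameters 1e-4).  Under
these priors the marginal posterior kernel of β is

    p(β|x) ∝ β^{−(n+a1+1)} exp(−b1/β) Π_i ((β/x_i)^{1/2} + (β/x_i)^{3/2})
             × (Σ_i (x_i/β + β/x_i − 2)/2 + b2)^{−((n+1)/2 + a2)},

and α² | β, x is exactly inverse gamma with shape n/2 + a2 and scale
Σ_i (x_i/β + β/x_i − 2)/2 + b2.

β is sampled by the generalized ratio-of-uniforms rejection method: with
bounds a(r) = sup p^{1/(r+1)} and b⁺(r) = sup β p^{r/(r+1)} (b⁻(r) = 0 for
this kernel), a pair (u, v) uniform on [0, a(r)] × [0, b⁺(r)] yields the
candidate ρ = v/uʳ, accepted when u ≤ p(ρ|x)^{1/(r+1)}.  Accepted candidates
are exact draws from the normalized posterior — this is rejection sampling,
not a Markov chain.  All kernel work is done in the log domain with the
kernel rescaled by its maximum, which leaves the accepted distribution
unchanged and avoids the underflow that the raw kernel suffers at n in the
hundreds.

Percentile draws θ_k follow by applying the percentile formula to each
(α_k, β_k) pair; equal-tailed and highest-posterior-density (HPD) credible
intervals are read off the θ draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .distribution import PercentileSpec, _as_sample
from .intervals import Interval

__all__ = [
    "Hyperparams",
    "RoUBounds",
    "PosteriorDraws",
    "log_marginal_beta",
    "rou_bounds",
    "rou_sample_beta",
    "sample_alpha_given_beta",
    "posterior_sample",
    "posterior_theta",
    "credible_interval",
    "hpd_interval",
    "bayes_interval",
]


@dataclass(frozen=True)
class Hyperparams:
    """Inverse-gamma prior hyperparameters and ratio-of-uniforms constant r."""

    a1: float = 1e-4
    b1: float = 1e-4
    a2: float = 1e-4
    b2: float = 1e-4
    r: float = 2.0

    def __post_init__(self) -> None:
        for name in ("a1", "b1", "a2", "b2"):
            if not getattr(self, name) > 0:
                raise ValueError(f"hyperparameter {name} must be positive")
        if self.r < 0:
            raise ValueError("ratio-of-uniforms constant r must be nonnegative")


@dataclass(frozen=True)
class RoUBounds:
    """Bounding rectangle [0, a_r] × [b_minus, b_plus] for the (u, v) pairs.

    ``log_shift`` is the additive constant subtracted from the log kernel
    before the suprema were taken (the kernel's log-maximum by default);
    acceptance tests must use the same shift.  ``beta_mode`` locates the
    kernel maximum.
    """

    a_r: float
    b_plus: float
    b_minus: float
    log_shift: float
    beta_mode: float


@dataclass(frozen=True)
class PosteriorDraws:
    """Paired posterior draws of (β, α) and the sampler's acceptance rate."""

    beta: np.ndarray
    alpha: np.ndarray
    acceptance_rate: float


def log_marginal_beta(beta, sample, hyper: Hyperparams = Hyperparams()):
    """Log of the unnormalized marginal posterior kernel of β.

    Vectorized over ``beta``; finite for every β > 0.
    """
    x = _as_sample(sample)
    b = np.asarray(beta, dtype=float)
    if np.any(b <= 0):
        raise ValueError("beta must be strictly positive")
    scalar = b.ndim == 0
    b = np.atleast_1d(b)
    n = x.size

    col = b[:, None]
    # Σ_i log((β/x_i)^{1/2} + (β/x_i)^{3/2}) = Σ_i [½ log(β/x_i) + log1p(β/x_i)]
    prod_term = 0.5 * (n * np.log(b) - np.sum(np.log(x))) + np.log1p(col / x).sum(axis=1)
    # Σ_i (x_i/β + β/x_i − 2) in closed form from the sample sums
    s1, s2 = float(x.sum()), float(np.sum(1.0 / x))
    quad = s1 / b + b * s2 - 2.0 * n
    out = (
        -(n + hyper.a1 + 1.0) * np.log(b)
        - hyper.b1 / b
        + prod_term
        - ((n + 1.0) / 2.0 + hyper.a2) * np.log(quad / 2.0 + hyper.b2)
    )
    return float(out[0]) if scalar else out


def _maximize_over_log_beta(objective, x: np.ndarray) -> tuple[float, float]:
    """Multistart bounded maximization over log β; returns (log β*, value)."""
    starts = np.log(np.quantile(x, [0.1, 0.5, 0.9]))
    span = max(np.log(x.max()) - np.log(x.min()), 1.0)
    lo, hi = np.log(x.min()) - span, np.log(x.max()) + span
    best = (None, -np.inf)
    for s in starts:
        res = optimize.minimize_scalar(
            lambda t: -objective(t),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-10},
        )
        if not res.success:
            continue
        if -res.fun > best[1]:
            best = (float(res.x), float(-res.fun))
    if best[0] is None:
        raise RuntimeError("ratio-of-uniforms bound search failed to converge")
    return best


def rou_bounds(sample, hyper: Hyperparams = Hyperparams(), log_shift=None) -> RoUBounds:
    """Bounding rectangle for the generalized ratio-of-uniforms sampler.

    With the kernel rescaled to q(β) = p(β|x) / exp(log_shift) and the default
    shift equal to the kernel's log-maximum, a(r) = sup q^{1/(r+1)} = 1 and
    b⁺(r) = sup β q^{r/(r+1)} is found by a second one-dimensional
    maximization.  b⁻(r) = 0 always: the kernel decays fast enough at the
    origin that β p^{r/(r+1)} → 0.
    """
    x = _as_sample(sample)
    r = hyper.r
    if r <= 0.0:
        # with r = 0 the exponent r/(r+1) vanishes and sup β·q^0 = ∞
        raise ValueError("r must be positive for b⁺(r) to be finite")

    def logp(t):
        return float(log_marginal_beta(np.exp(t), x, hyper))

    log_beta_mode, log_pmax = _maximize_over_log_beta(logp, x)
    shift = log_pmax if log_shift is None else float(log_shift)
    a_r = np.exp((log_pmax - shift) / (r + 1.0))

    def b_obj(t):
        return t + (r / (r + 1.0)) * (logp(t) - shift)

    _, log_bplus = _maximize_over_log_beta(b_obj, x)
    return RoUBounds(
        a_r=float(a_r),
        b_plus=float(np.exp(log_bplus)),
        b_minus=0.0,
        log_shift=shift,
        beta_mode=float(np.exp(log_beta_mode)),
    )


def rou_sample_beta(
    sample,
    hyper: Hyperparams = Hyperparams(),
    size: int = 1000,
    rng=None,
    bounds: RoUBounds | None = None,
) -> tuple[np.ndarray, float]:
    """Exact posterior draws of β by ratio-of-uniforms rejection.

    Returns ``(draws, acceptance_rate)``.  Fresh (u, v) pairs are generated
    for every attempt; rejected pairs are never reused.
    """
    if size < 1:
        raise ValueError("size must be at least 1")
    x = _as_sample(sample)
    rng = np.random.default_rng(rng)
    if bounds is None:
        bounds = rou_bounds(x, hyper)
    r = hyper.r

    out = np.empty(size)
    accepted = 0
    attempts = 0
    probe = 0
    while accepted < size:
        batch = max(2 * (size - accepted), 256)
        u = rng.uniform(0.0, bounds.a_r, size=batch)
        v = rng.uniform(0.0, bounds.b_plus, size=batch)
        attempts += batch
        ok = u > 0.0  # guard the measure-zero u = 0 edge before forming v/u^r
        rho = np.empty(batch)
        rho[ok] = v[ok] / u[ok] ** r
        ok &= rho > 0.0
        if ok.any():
            logq = log_marginal_beta(rho[ok], x, hyper) - bounds.log_shift
            acc = np.log(u[ok]) <= logq / (r + 1.0)
            good = rho[ok][acc]
            take = min(good.size, size - accepted)
            out[accepted : accepted + take] = good[:take]
            accepted += take
        probe += batch
        if probe >= 1_000_000 and accepted / attempts < 1e-6:
            raise RuntimeError(
                "ratio-of-uniforms acceptance rate below 1e-6; check the bounds"
            )
    return out, accepted / attempts


def sample_alpha_given_beta(
    beta_draw, sample, hyper: Hyperparams = Hyperparams(), rng=None
) -> np.ndarray:
    """Draw α | β, x: α² is inverse gamma, conjugate given β.

    Shape n/2 + a2, scale Σ(x_i/β + β/x_i − 2)/2 + b2; α is its square root.
    Vectorized over ``beta_draw``.
    """
    x = _as_sample(sample)
    b = np.atleast_1d(np.asarray(beta_draw, dtype=float))
    if np.any(b <= 0):
        raise ValueError("beta draws must be strictly positive")
    rng = np.random.default_rng(rng)
    n = x.size
    s1, s2 = float(x.sum()), float(np.sum(1.0 / x))
    scale = (s1 / b + b * s2 - 2.0 * n) / 2.0 + hyper.b2
    shape = n / 2.0 + hyper.a2
    # InverseGamma(shape, scale) = scale / Gamma(shape, 1)
    alpha_sq = scale / rng.gamma(shape, size=b.size)
    out = np.sqrt(alpha_sq)
    return out if np.ndim(beta_draw) else float(out[0])


def posterior_sample(
    sample,
    hyper: Hyperparams = Hyperparams(),
    size: int = 1000,
    rng=None,
) -> PosteriorDraws:
    """Joint posterior draws of (β, α): ratio-of-uniforms for β, conjugate α²|β."""
    rng = np.random.default_rng(rng)
    beta, rate = rou_sample_beta(sample, hyper, size=size, rng=rng)
    alpha = sample_alpha_given_beta(beta, sample, hyper, rng=rng)
    return PosteriorDraws(beta=beta, alpha=np.asarray(alpha), acceptance_rate=rate)


def posterior_theta(draws: PosteriorDraws, spec: PercentileSpec | float) -> np.ndarray:
    """Induced posterior draws of the percentile θ_p from the (α, β) pairs."""
    if not isinstance(spec, PercentileSpec):
        spec = PercentileSpec(float(spec))
    az = draws.alpha * spec.z_p
    return draws.beta / 4.0 * (az + np.sqrt(az * az + 4.0)) ** 2


def credible_interval(theta_draws, level: float = 0.95) -> Interval:
    """Equal-tailed credible interval: γ/2 and 1−γ/2 empirical quantiles."""
    theta = np.asarray(theta_draws, dtype=float)
    if theta.size < 100:
        raise ValueError("at least 100 draws are required")
    lower, upper = np.quantile(theta, [(1 - level) / 2.0, 1 - (1 - level) / 2.0])
    return Interval(
        lower=float(lower), upper=float(upper), level=level, method="bayes",
        diagnostics={"draws": int(theta.size)},
    )


def hpd_interval(theta_draws, level: float = 0.95) -> Interval:
    """Highest-posterior-density interval by the sorted-window method.

    Among all contiguous windows of ⌈level·M⌉ sorted draws, returns the one of
    minimal length; ties resolve to the smallest lower endpoint.  Exact for
    unimodal posteriors up to Monte Carlo error.
    """
    theta = np.sort(np.asarray(theta_draws, dtype=float))
    m = theta.size
    if m < 100:
        raise ValueError("at least 100 draws are required")
    if not (0.0 < level < 1.0):
        raise ValueError(f"level must lie in (0, 1), got {level!r}")
    window = int(np.ceil(level * m))
    widths = theta[window - 1 :] - theta[: m - window + 1]
    j = int(np.argmin(widths))  # first minimum = smallest lower endpoint
    return Interval(
        lower=float(theta[j]),
        upper=float(theta[j + window - 1]),
        level=level,
        method="hpd",
        diagnostics={"draws": int(m)},
    )


def bayes_interval(
    sample,
    spec: PercentileSpec | float = 0.5,
    level: float = 0.95,
    draws: int = 1000,
    hyper: Hyperparams = Hyperparams(),
    rng=None,
    hpd: bool = False,
) -> Interval:
    """Credible interval for the p-th percentile (equal-tailed or HPD)."""
    if not isinstance(spec, PercentileSpec):
        spec = PercentileSpec(float(spec))
    post = posterior_sample(sample, hyper, size=draws, rng=rng)
    theta = posterior_theta(post, spec)
    ci = hpd_interval(theta, level) if hpd else credible_interval(theta, level)
    diag = dict(ci.diagnostics, acceptance_rate=post.acceptance_rate)
    return Interval(
        lower=ci.lower, upper=ci.upper, level=level, method=ci.method,
        p=spec.p, diagnostics=diag,
    )
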