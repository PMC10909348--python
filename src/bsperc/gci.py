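"""Generalized confidence interval (GCI) for a Birnbaum-Saunders percentile.

The construction rests on generalized pivotal quantities (GPQs).  Given the
observed sufficient summaries (I, J, K, L, S1, S2) of a sample of size n, a
Student-t(n−1) draw T yields a pivotal quantity R_β as a root of the quadratic

    A β² − 2B β + C = 0,
    A = (n−1)J² − L T²/n,
    B = (n−1)IJ − (1 − IJ) T²,
    C = (n−1)I² − K T²/n,

taking the larger root when T ≤ 0 and the smaller when T > 0.  A χ²(n) draw V
then gives R_α = √((S2 R_β² − 2n R_β + S1)/(R_β V)), and substituting
(R_α, R_β) into the percentile formula gives R_θ.  The empirical γ/2 and
1−γ/2 quantiles of M simulated R_θ values form the 100(1−γ)% interval.

Draws whose quadratic has complex roots or whose selected root is not
positive are invalid and are resimulated; the resimulation count is reported.
"""

from __future__ import annotations

import numpy as np

from .distribution import PercentileSpec, SampleStats, sufficient_stats
from .intervals import Interval

__all__ = ["SamplingError", "gpq_beta", "gpq_alpha", "gpq_theta", "gci_interval"]


class SamplingError(RuntimeError):
    """Raised when the resimulation budget for invalid GPQ draws is exhausted."""


def gpq_beta(stats: SampleStats, t_draw):
    """Pivotal quantity R_β for the scale parameter.

    Vectorized over ``t_draw``.  Returns ``(r_beta, valid)`` where ``valid``
    flags draws with real roots and a positive selected root; invalid entries
    of ``r_beta`` are NaN and must be resimulated by the caller.
    """
    t = np.asarray(t_draw, dtype=float)
    n, I, J, K, L = stats.n, stats.I, stats.J, stats.K, stats.L
    t2 = t * t
    A = (n - 1) * J * J - L * t2 / n
    B = (n - 1) * I * J - (1.0 - I * J) * t2
    C = (n - 1) * I * I - K * t2 / n

    disc = B * B - A * C
    real = disc >= 0.0
    sq = np.sqrt(np.where(real, disc, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        root_lo = np.where(A != 0.0, (B - sq) / A, np.nan)
        root_hi = np.where(A != 0.0, (B + sq) / A, np.nan)
        # A ≈ 0 collapses the quadratic to the linear root C/(2B)
        linear = np.where(B != 0.0, C / (2.0 * B), np.nan)
    root_lo = np.where(A == 0.0, linear, root_lo)
    root_hi = np.where(A == 0.0, linear, root_hi)

    r_beta = np.where(t <= 0.0, np.maximum(root_lo, root_hi), np.minimum(root_lo, root_hi))
    valid = real & np.isfinite(r_beta) & (r_beta > 0.0)
    r_beta = np.where(valid, r_beta, np.nan)
    if t.ndim == 0:
        return float(r_beta), bool(valid)
    return r_beta, valid


def gpq_alpha(stats: SampleStats, r_beta, v_draw):
    """Pivotal quantity R_α for the shape parameter, given R_β and V ~ χ²(n).

    The radicand S2 R_β² − 2n R_β + S1 is nonnegative for every R_β > 0 by the
    AM-GM inequality applied termwise; tiny negative values from rounding are
    clipped to zero, and structurally negative radicands (impossible for valid
    inputs) are flagged invalid.
    """
    rb = np.asarray(r_beta, dtype=float)
    v = np.asarray(v_draw, dtype=float)
    radicand = stats.S2 * rb * rb - 2.0 * stats.n * rb + stats.S1
    tol = -1e-9 * (stats.S1 + stats.S2 * rb * rb)
    valid = (radicand >= tol) & (rb > 0.0) & (v > 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r_alpha = np.sqrt(np.maximum(radicand, 0.0) / (rb * v))
    r_alpha = np.where(valid, r_alpha, np.nan)
    if rb.ndim == 0 and v.ndim == 0:
        return float(r_alpha), bool(valid)
    return r_alpha, valid


def gpq_theta(r_beta, r_alpha, spec: PercentileSpec):
    """Pivotal quantity R_θ: the percentile formula evaluated at (R_α, R_β)."""
    rb = np.asarray(r_beta, dtype=float)
    ra = np.asarray(r_alpha, dtype=float)
    az = ra * spec.z_p
    out = rb / 4.0 * (az + np.sqrt(az * az + 4.0)) ** 2
    return float(out) if out.ndim == 0 else out


def gci_interval(
    sample,
    spec: PercentileSpec | float = 0.5,
    level: float = 0.95,
    draws: int = 5000,
    rng=None,
) -> Interval:
    """Generalized confidence interval for the p-th percentile.

    Simulates ``draws`` valid (T, V) GPQ pairs, resimulating any pair whose
    R_β is invalid, and returns the empirical γ/2 and 1−γ/2 quantiles of R_θ
    (linear interpolation between order statistics).
    """
    if not isinstance(spec, PercentileSpec):
        spec = PercentileSpec(float(spec))
    if draws < 100:
        raise ValueError("draws must be at least 100")
    if not (0.0 < level < 1.0):
        raise ValueError(f"confidence level must lie in (0, 1), got {level!r}")
    rng = np.random.default_rng(rng)
    stats = sufficient_stats(sample)
    n = stats.n

    r_theta = np.empty(draws)
    accepted = 0
    attempts = 0
    budget = 100 * draws
    while accepted < draws:
        batch = min(draws - accepted + 64, budget - attempts)
        if batch <= 0:
            raise SamplingError(
                f"GPQ resimulation budget exhausted after {attempts} attempts "
                f"({accepted}/{draws} valid draws)"
            )
        t = rng.standard_t(df=n - 1, size=batch)
        attempts += batch
        rb, ok = gpq_beta(stats, t)
        rb = rb[ok]
        if rb.size == 0:
            continue
        v = rng.chisquare(df=n, size=rb.size)
        ra, ok2 = gpq_alpha(stats, rb, v)
        rb, ra = rb[ok2], ra[ok2]
        take = min(rb.size, draws - accepted)
        r_theta[accepted : accepted + take] = gpq_theta(rb[:take], ra[:take], spec)
        accepted += take

    lower, upper = np.quantile(r_theta, [(1 - level) / 2.0, 1 - (1 - level) / 2.0])
    return Interval(
        lower=float(lower),
        upper=float(upper),
        level=level,
        method="gci",
        p=spec.p,
        diagnostics={"draws": draws, "resimulated": attempts - draws},
    )
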