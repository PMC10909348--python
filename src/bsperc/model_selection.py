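"""Maximum-likelihood fits of seven candidate families and AIC ranking.

For a positive, right-skewed series (e.g. pollutant concentrations) the
candidate families are normal, log-normal, Weibull, gamma, exponential,
Cauchy and Birnbaum-Saunders.  Each is fit by maximum likelihood — closed
form where one exists (normal, log-normal with the n-divisor variance,
exponential), numerical otherwise — and ranked by AIC = 2k − 2 log L, with
k = 1 for the exponential and k = 2 for every other family.

Parameterizations: Weibull (shape, scale), gamma (shape, rate), Cauchy
(location, scale), log-normal (meanlog, sdlog).  AIC is invariant to the
chart, but the optimizers need one pinned down.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .distribution import _as_sample, bs_mle

__all__ = ["FAMILIES", "ModelFit", "FitError", "fit_candidate", "aic_table"]

FAMILIES = (
    "normal",
    "log-normal",
    "weibull",
    "gamma",
    "exponential",
    "cauchy",
    "birnbaum-saunders",
)


class FitError(RuntimeError):
    """Raised when a family's MLE optimizer fails."""


@dataclass(frozen=True)
class ModelFit:
    family: str
    k: int
    loglik: float
    aic: float
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        expected = 2.0 * self.k - 2.0 * self.loglik
        if not math.isclose(self.aic, expected, rel_tol=0, abs_tol=1e-8):
            raise ValueError(f"aic {self.aic} inconsistent with 2k − 2 loglik {expected}")


def _make_fit(family: str, k: int, loglik: float, params: dict) -> ModelFit:
    return ModelFit(family=family, k=k, loglik=float(loglik),
                    aic=float(2 * k - 2 * loglik), params=params)


def _fit_normal(x: np.ndarray) -> ModelFit:
    mu = float(x.mean())
    var = float(x.var())  # MLE divisor n
    n = x.size
    loglik = -0.5 * n * (math.log(2 * math.pi * var) + 1.0)
    return _make_fit("normal", 2, loglik, {"mean": mu, "sd": math.sqrt(var)})


def _fit_lognormal(x: np.ndarray) -> ModelFit:
    lx = np.log(x)
    mu = float(lx.mean())
    var = float(lx.var())
    n = x.size
    loglik = -0.5 * n * (math.log(2 * math.pi * var) + 1.0) - float(lx.sum())
    return _make_fit("log-normal", 2, loglik, {"meanlog": mu, "sdlog": math.sqrt(var)})


def _fit_exponential(x: np.ndarray) -> ModelFit:
    rate = 1.0 / float(x.mean())
    n = x.size
    loglik = n * math.log(rate) - n  # rate·Σx = n at the MLE
    return _make_fit("exponential", 1, loglik, {"rate": rate})


def _fit_weibull(x: np.ndarray) -> ModelFit:
    shape, _, scale = sps.weibull_min.fit(x, floc=0)
    loglik = float(sps.weibull_min.logpdf(x, shape, scale=scale).sum())
    return _make_fit("weibull", 2, loglik, {"shape": shape, "scale": scale})


def _fit_gamma(x: np.ndarray) -> ModelFit:
    shape, _, scale = sps.gamma.fit(x, floc=0)
    loglik = float(sps.gamma.logpdf(x, shape, scale=scale).sum())
    return _make_fit("gamma", 2, loglik, {"shape": shape, "rate": 1.0 / scale})


def _fit_cauchy(x: np.ndarray) -> ModelFit:
    loc, scale = sps.cauchy.fit(x)
    loglik = float(sps.cauchy.logpdf(x, loc=loc, scale=scale).sum())
    return _make_fit("cauchy", 2, loglik, {"location": loc, "scale": scale})


def _fit_bs(x: np.ndarray) -> ModelFit:
    res = bs_mle(x)
    return _make_fit(
        "birnbaum-saunders", 2, res.loglik,
        {"alpha": res.params.alpha, "beta": res.params.beta},
    )


_FITTERS = {
    "normal": _fit_normal,
    "log-normal": _fit_lognormal,
    "weibull": _fit_weibull,
    "gamma": _fit_gamma,
    "exponential": _fit_exponential,
    "cauchy": _fit_cauchy,
    "birnbaum-saunders": _fit_bs,
}


def fit_candidate(sample, family: str) -> ModelFit:
    """Fit one candidate family by maximum likelihood and compute its AIC."""
    if family not in _FITTERS:
        raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")
    x = _as_sample(sample, min_n=2)
    try:
        return _FITTERS[family](x)
    except (ValueError, RuntimeError) as exc:
        raise FitError(f"maximum-likelihood fit failed for family {family!r}: {exc}") from exc


def aic_table(sample) -> list[ModelFit]:
    """Fit all seven families and return them sorted by ascending AIC.

    A family whose optimizer fails is recorded as missing (skipped) rather
    than aborting the comparison.
    """
    fits = []
    for family in FAMILIES:
        try:
            fits.append(fit_candidate(sample, family))
        except FitError:
            continue
    fits.sort(key=lambda f: f.aic)
    return fits
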