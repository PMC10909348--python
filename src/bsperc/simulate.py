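"""Monte-Carlo evaluation of the four interval methods.

For each replicate a BS(α, β) sample of size n is drawn, every requested
interval method is run on the *same* sample (paired design, which removes
between-method sampling noise from the comparison), and the coverage
indicator and interval length are recorded against the true percentile
θ_p(α, β).  A cell reports, per method, the coverage probability (mean
indicator), the average length, and the binomial Monte-Carlo standard error
√(cov(1−cov)/reps).

Replicate k derives its generators from child k of the master seed's
SeedSequence, so results are reproducible and cells are independent of the
method subset requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bayes import Hyperparams, credible_interval, hpd_interval, posterior_sample, posterior_theta
from .bootstrap import bootstrap_interval
from .distribution import BSParams, PercentileSpec, bs_percentile, bs_rvs
from .gci import gci_interval

__all__ = ["ALL_METHODS", "SimConfig", "MethodResult", "SimResult", "run_cell", "run_grid"]

ALL_METHODS = ("gci", "bootstrap", "bayes", "hpd")
_MAX_REDRAWS = 20


@dataclass(frozen=True)
class SimConfig:
    """One simulation cell: true parameters, sizes and per-method draw counts."""

    n: int
    alpha: float
    beta: float = 1.0
    p: float = 0.5
    level: float = 0.95
    reps: int = 5000
    m_gci: int = 5000
    b_boot: int = 500
    m_bayes: int = 1000
    hyper: Hyperparams = field(default_factory=Hyperparams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reps < 1:
            raise ValueError("reps must be at least 1")
        if self.n < 2:
            raise ValueError("n must be at least 2")


@dataclass(frozen=True)
class MethodResult:
    method: str
    coverage: float
    avg_length: float
    mc_stderr: float
    reps: int


@dataclass(frozen=True)
class SimResult:
    config: SimConfig
    theta_true: float
    methods: dict  # method name -> MethodResult


def _replicate_intervals(sample, config: SimConfig, methods, rng) -> dict:
    spec = PercentileSpec(config.p)
    out = {}
    if "gci" in methods:
        out["gci"] = gci_interval(sample, spec, config.level, config.m_gci, rng)
    if "bootstrap" in methods:
        out["bootstrap"] = bootstrap_interval(sample, spec, config.level, config.b_boot, rng)
    if "bayes" in methods or "hpd" in methods:
        # one posterior sample serves both credible constructions
        post = posterior_sample(sample, config.hyper, size=config.m_bayes, rng=rng)
        theta = posterior_theta(post, spec)
        if "bayes" in methods:
            out["bayes"] = credible_interval(theta, config.level)
        if "hpd" in methods:
            out["hpd"] = hpd_interval(theta, config.level)
    return out


def run_cell(config: SimConfig, methods=ALL_METHODS) -> SimResult:
    """Run one (n, p, α, β) cell: per-method coverage and average length."""
    methods = tuple(methods)
    unknown = set(methods) - set(ALL_METHODS)
    if unknown:
        raise ValueError(f"unknown methods {sorted(unknown)}; choose from {ALL_METHODS}")
    params = BSParams(config.alpha, config.beta)
    theta_true = bs_percentile(params, config.p)

    covered = {m: np.zeros(config.reps, dtype=bool) for m in methods}
    lengths = {m: np.zeros(config.reps) for m in methods}
    children = np.random.SeedSequence(config.seed).spawn(config.reps)
    for k, child in enumerate(children):
        for attempt in range(_MAX_REDRAWS + 1):
            rng = np.random.default_rng(child if attempt == 0 else child.spawn(1)[0])
            sample = bs_rvs(params, config.n, rng)
            try:
                ivs = _replicate_intervals(sample, config, methods, rng)
            except (ValueError, RuntimeError):
                continue
            break
        else:
            raise RuntimeError(f"replicate {k} failed after {_MAX_REDRAWS} redraws")
        for m, iv in ivs.items():
            covered[m][k] = iv.contains(theta_true)
            lengths[m][k] = iv.length

    results = {}
    for m in methods:
        cov = float(covered[m].mean())
        results[m] = MethodResult(
            method=m,
            coverage=cov,
            avg_length=float(lengths[m].mean()),
            mc_stderr=float(np.sqrt(cov * (1.0 - cov) / config.reps)),
            reps=config.reps,
        )
    return SimResult(config=config, theta_true=theta_true, methods=results)


def run_grid(
    n_values,
    alpha_values,
    p: float = 0.5,
    beta: float = 1.0,
    methods=ALL_METHODS,
    seed: int = 0,
    **config_kwargs,
) -> pd.DataFrame:
    """Full coverage/length grid over n × α at fixed (p, β).

    Returns a tidy DataFrame with one row per cell and per-method coverage
    and average-length columns.  Each cell gets its own child seed of the
    master seed, so the grid is deterministic and cells are independent.
    """
    n_values = list(n_values)
    alpha_values = list(alpha_values)
    if not n_values or not alpha_values:
        raise ValueError("n_values and alpha_values must be nonempty")
    cells = [(n, a) for n in n_values for a in alpha_values]
    cell_seeds = np.random.SeedSequence(seed).spawn(len(cells))
    rows = []
    for (n, a), cell_seed in zip(cells, cell_seeds):
        config = SimConfig(
            n=n, alpha=a, beta=beta, p=p,
            seed=int(cell_seed.generate_state(1)[0] % (2**31)),
            **config_kwargs,
        )
        result = run_cell(config, methods)
        row = {"n": n, "p": p, "alpha": a, "beta": beta,
               "theta_true": result.theta_true, "reps": config.reps, "seed": config.seed}
        for m, mr in result.methods.items():
            row[f"coverage_{m}"] = mr.coverage
            row[f"avg_length_{m}"] = mr.avg_length
            row[f"mc_stderr_{m}"] = mr.mc_stderr
        rows.append(row)
    return pd.DataFrame(rows)
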