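"""CSV report writers for intervals, simulation grids and AIC tables."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .intervals import Interval
from .model_selection import ModelFit

__all__ = ["intervals_frame", "aic_frame", "write_csv"]


def intervals_frame(intervals: list[Interval], seed=None) -> pd.DataFrame:
    """One row per interval: method, endpoints, length, level, p, seed, diagnostics."""
    rows = []
    for iv in intervals:
        row = {
            "method": iv.method,
            "lower": iv.lower,
            "upper": iv.upper,
            "length": iv.length,
            "level": iv.level,
            "p": iv.p,
            "seed": seed,
        }
        for key, value in iv.diagnostics.items():
            row[key] = value
        rows.append(row)
    return pd.DataFrame(rows)


def aic_frame(fits: list[ModelFit]) -> pd.DataFrame:
    """Ranked AIC table; the minimum-AIC family is flagged ``best``."""
    frame = pd.DataFrame(
        [{"family": f.family, "k": f.k, "loglik": f.loglik, "aic": f.aic} for f in fits]
    )
    frame["best"] = frame["aic"] == frame["aic"].min()
    return frame


def write_csv(frame: pd.DataFrame, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)
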