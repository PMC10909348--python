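"""Sample readers and the bundled PM2.5 fixture series.

The package ships the daily PM2.5 concentration series (µg/m³, 181 daily
values each, 2023-01-01 to 2023-06-30, Thai Pollution Control Department)
for the Mae Hong Son and Lampang provinces as plain one-column CSV files.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np

__all__ = ["FIXTURES", "load_series"]

FIXTURES = ("maehongson", "lampang")


class ParseError(ValueError):
    """A non-numeric or nonpositive token in an input series, with its line."""


def _parse_text(text: str, source: str) -> np.ndarray:
    values = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        for token in stripped.replace(",", " ").split():
            try:
                value = float(token)
            except ValueError:
                raise ParseError(
                    f"{source}: line {lineno}: non-numeric token {token!r}"
                ) from None
            if not value > 0:
                raise ParseError(
                    f"{source}: line {lineno}: values must be positive, got {value}"
                )
            values.append(value)
    if not values:
        raise ParseError(f"{source}: no values found")
    return np.asarray(values, dtype=float)


def load_series(path_or_name) -> np.ndarray:
    """Load a positive univariate series from a file or a bundled fixture.

    Accepts a path to a one-column CSV / whitespace-delimited text file
    (blank lines ignored), or one of the fixture names ``"maehongson"`` /
    ``"lampang"``.
    """
    name = str(path_or_name)
    if name in FIXTURES:
        text = resources.files("bsperc.data").joinpath(f"{name}.csv").read_text()
        return _parse_text(text, name)
    path = Path(path_or_name)
    if not path.exists():
        raise FileNotFoundError(
            f"{path}: no such file, and not a fixture name (choose from {FIXTURES})"
        )
    return _parse_text(path.read_text(), str(path))
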