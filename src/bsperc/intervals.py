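"""Generic interval result shared by all four construction methods."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class Interval:
    """A two-sided interval estimate for a distribution percentile.

    ``diagnostics`` carries method-specific counters (resimulations, dropped
    replicates, acceptance rates, draw counts) so that stochastic results are
    auditable.
    """

    lower: float
    upper: float
    level: float
    method: str
    p: float = 0.5
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 < self.level < 1.0):
            raise ValueError(f"confidence level must lie in (0, 1), got {self.level!r}")
        if self.lower > self.upper:
            raise ValueError(f"interval endpoints out of order: {self.lower} > {self.upper}")

    @property
    def length(self) -> float:
        return self.upper - self.lower

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper
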