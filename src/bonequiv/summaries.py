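"""Per-bone summary statistics and the report number-formatting convention.

Summary tables describe the *spread of a population* of signed surface
distances (per-vertex within a bone, or per-subject means at group level),
so the standard deviation uses divisor ``n`` and the interval is the normal
population-spread interval ``mean ± 1.96·std`` — not a standard-error
confidence interval.  Inferential statistics (the TOST layer) use the
``n−1`` sample standard deviation instead; see :mod:`bonequiv.stats`.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal

import numpy as np

from .errors import DegenerateSampleError

__all__ = ["BoneSummary", "format_mm", "summarize_values"]


def format_mm(value: float) -> str:
    """Format a millimetre quantity for report tables.

    Two decimal places by default, extended while the magnitude is below
    what two (three) decimals can resolve, so sub-0.01 mm means such as
    0.006 or 0.003 remain visible instead of rounding to "0.01"/"0.00".
    Ties round half-to-even on the decimal value (means of exact-decimal
    inputs often land exactly on a rounding boundary, e.g. -0.065).
    """
    if abs(value) >= 0.0095:
        quantum = "0.01"
    elif abs(value) >= 0.00095:
        quantum = "0.001"
    else:
        quantum = "0.0001"
    return str(Decimal(repr(float(value))).quantize(Decimal(quantum), rounding=ROUND_HALF_EVEN))


@dataclass(frozen=True)
class BoneSummary:
    """Mean/std and population-spread interval of signed distances (mm)."""

    bone: str
    n: int
    mean: float
    std: float  # population std, divisor n
    lower: float  # mean - 1.96 std
    upper: float  # mean + 1.96 std

    def __post_init__(self) -> None:
        if self.std < 0:
            raise ValueError("std must be >= 0")
        if not (self.lower <= self.mean <= self.upper):
            raise ValueError("interval must bracket the mean")

    def formatted(self) -> dict[str, str]:
        """Row rendered with the report formatting convention."""
        return {
            "bone": self.bone,
            "n": str(self.n),
            "mean": format_mm(self.mean),
            "std": format_mm(self.std),
            "upper": format_mm(self.upper),
            "lower": format_mm(self.lower),
        }


def summarize_values(values: np.ndarray, bone: str = "") -> BoneSummary:
    """Summarize a vector of signed distances (or of per-subject means)."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise DegenerateSampleError(f"need >=2 values, got {values.size}")
    mean = float(values.mean())
    std = float(values.std(ddof=0))
    return BoneSummary(
        bone=bone,
        n=int(values.size),
        mean=mean,
        std=std,
        lower=mean - 1.96 * std,
        upper=mean + 1.96 * std,
    )
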