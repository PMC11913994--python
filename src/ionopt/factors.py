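"""Instrument factors and coded/natural unit conversion.

A :class:`Factor` is one tunable instrument parameter (interface voltage,
interface temperature, CID gas pressure, ...) with a linear mapping between
*coded* units (design space, -1 at ``low``, +1 at ``high``) and *natural*
units (what the instrument accepts).  Natural settings are quantised to the
instrument's setting granularity (``rounding_step``, round-half-to-even) and
clipped to hard feasibility bounds where the hardware imposes them (e.g. the
interface heater cannot exceed 400 °C).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import yaml

from .errors import InvalidValueError

__all__ = [
    "Factor",
    "round_to_step",
    "code_level",
    "decode_level",
    "screening_factors",
    "ccd_factors",
    "ce_factors",
    "load_factors",
    "dump_factors",
]


def round_to_step(value: float, step: float) -> float:
    """Round ``value`` to the nearest multiple of ``step`` (half-to-even).

    The result is cleaned to the decimal precision of ``step`` so that e.g.
    ``round_to_step(3.175, 0.1) == 3.2`` rather than ``3.2000000000000002``.
    """
    if step <= 0:
        raise InvalidValueError("rounding step must be positive")
    n = float(np.round(value / step))
    # number of decimals needed to represent the step exactly enough
    decimals = max(0, -int(math.floor(math.log10(step))) + 2)
    return round(n * step, decimals)


@dataclass(frozen=True)
class Factor:
    """One tunable instrument parameter with its coded-unit frame."""

    name: str
    unit: str
    low: float
    high: float
    rounding_step: float = 1.0
    hard_min: Optional[float] = None
    hard_max: Optional[float] = None

    def __post_init__(self):
        if not (np.isfinite(self.low) and np.isfinite(self.high)):
            raise InvalidValueError(f"{self.name}: non-finite level range")
        if not self.low < self.high:
            raise InvalidValueError(f"{self.name}: low must be < high")
        if self.rounding_step <= 0:
            raise InvalidValueError(f"{self.name}: rounding_step must be > 0")
        if (
            self.hard_min is not None
            and self.hard_max is not None
            and self.hard_min >= self.hard_max
        ):
            raise InvalidValueError(f"{self.name}: hard_min must be < hard_max")

    @property
    def center(self) -> float:
        return 0.5 * (self.low + self.high)

    @property
    def half_range(self) -> float:
        return 0.5 * (self.high - self.low)

    def code(self, natural: float) -> float:
        """Map a natural-unit value into coded units (low -> -1, high -> +1)."""
        if not np.all(np.isfinite(natural)):
            raise InvalidValueError(f"{self.name}: non-finite natural value")
        return (natural - self.center) / self.half_range

    def decode(self, coded: float, clip: bool = True) -> float:
        """Map a coded level to a settable natural value.

        Clips to hard bounds (if any) first, then rounds to
        ``rounding_step``.  Axial (star) points may legitimately lie outside
        ``[low, high]``; they are only constrained by the hard bounds.
        """
        if not np.isfinite(coded):
            raise InvalidValueError(f"{self.name}: non-finite coded value")
        raw = self.center + coded * self.half_range
        if clip:
            raw = self.clip(raw)
        return round_to_step(raw, self.rounding_step)

    def clip(self, natural: float) -> float:
        if self.hard_min is not None:
            natural = max(natural, self.hard_min)
        if self.hard_max is not None:
            natural = min(natural, self.hard_max)
        return natural

    def would_clip(self, coded: float) -> bool:
        raw = self.center + coded * self.half_range
        return self.clip(raw) != raw


def code_level(factor: Factor, natural: float) -> float:
    return factor.code(natural)


def decode_level(factor: Factor, coded: float) -> float:
    return factor.decode(coded)


# ---------------------------------------------------------------------------
# Default factor frames.
#
# The screening frame covers all seven ESI-source / collision-cell parameters
# at the two-level ranges used to screen for active factors; the optimization
# frame covers the three factors retained for response-surface work, at
# narrower ranges.  Nebulizing gas is fixed at 3 L/min and is not a factor.
# ---------------------------------------------------------------------------


def screening_factors() -> list[Factor]:
    """Seven-factor frame for the two-level screening design."""
    return [
        Factor("IntV", "kV", 2.0, 4.0, 0.1),
        Factor("IntT", "degC", 200.0, 400.0, 1.0, hard_max=400.0),
        Factor("HG", "L/min", 5.0, 10.0, 0.5),
        Factor("DG", "L/min", 5.0, 10.0, 0.5),
        Factor("HB", "degC", 300.0, 500.0, 1.0),
        Factor("DL", "degC", 200.0, 300.0, 1.0),
        Factor("CID", "kPa", 140.0, 270.0, 5.0),
    ]


def ccd_factors() -> list[Factor]:
    """Three-factor frame for the central composite optimization design.

    The interface heater has a hard 400 °C ceiling, so the +alpha star point
    for IntT clips to 400 °C.
    """
    return [
        Factor("CID", "kPa", 140.0, 250.0, 5.0),
        Factor("IntT", "degC", 300.0, 400.0, 1.0, hard_max=400.0),
        Factor("IntV", "kV", 2.0, 3.0, 0.1),
    ]


def ce_factors() -> list[Factor]:
    """Collision-energy x CID frame for the multilevel D-optimal design."""
    return [
        Factor("CE", "eV", 12.0, 28.0, 1.0),
        Factor("CID", "kPa", 190.0, 250.0, 5.0),
    ]


# ---------------------------------------------------------------------------
# YAML round-trip
# ---------------------------------------------------------------------------


def load_factors(path) -> list[Factor]:
    """Read a factor list from a YAML (or JSON) file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if isinstance(raw, dict):
        raw = raw.get("factors", raw)
    factors = []
    for item in raw:
        factors.append(
            Factor(
                name=item["name"],
                unit=item.get("unit", ""),
                low=float(item["low"]),
                high=float(item["high"]),
                rounding_step=float(item.get("rounding_step", 1.0)),
                hard_min=item.get("hard_min"),
                hard_max=item.get("hard_max"),
            )
        )
    return factors


def dump_factors(factors: Sequence[Factor], path) -> None:
    payload = [
        {
            "name": f.name,
            "unit": f.unit,
            "low": f.low,
            "high": f.high,
            "rounding_step": f.rounding_step,
            **({"hard_min": f.hard_min} if f.hard_min is not None else {}),
            **({"hard_max": f.hard_max} if f.hard_max is not None else {}),
        }
        for f in factors
    ]
    with open(path, "w") as fh:
        yaml.safe_dump({"factors": payload}, fh, sort_keys=False)
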