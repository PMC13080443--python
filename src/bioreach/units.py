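"""Units, quantities and the reporting rounding rule.

The engine deals with a small closed set of units that occur in seed-system
and food-balance accounting.  Two deliberate restrictions:

* mass units (kg, MT) and count units (bundles — cassava planting stems)
  never inter-convert.  Cassava seed arithmetic stays in bundles throughout;
  nothing in the calculation ever needs a bundle mass because yield is
  expressed per hectare.
* only explicitly declared pairs convert (kg <-> MT by 1000; annual kg per
  person <-> daily g per person by 1000/365; percent <-> fraction).

All intermediate arithmetic is done in full floating precision; rounding
happens once, at reporting time, half-up (`round_half_up`), which is the
convention the bundled worked examples follow.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from .errors import UnitError

#: The closed unit vocabulary.
UNITS = frozenset(
    {
        "kg",
        "MT",
        "bundles",
        "ha",
        "kg_per_ha",
        "bundles_per_ha",
        "MT_per_ha",
        "kg_per_person_year",
        "g_per_person_day",
        "persons",
        "households",
        "fraction",
        "percent",
    }
)

#: Declared compatible conversions: (from, to) -> multiplicative factor.
_CONVERSIONS: dict[tuple[str, str], float] = {
    ("kg", "MT"): 1e-3,
    ("MT", "kg"): 1e3,
    ("kg_per_person_year", "g_per_person_day"): 1000.0 / 365.0,
    ("g_per_person_day", "kg_per_person_year"): 365.0 / 1000.0,
    ("percent", "fraction"): 0.01,
    ("fraction", "percent"): 100.0,
}

#: Seed-rate units and the unit their numerator is expressed in.
RATE_NUMERATOR: dict[str, str] = {
    "kg_per_ha": "kg",
    "bundles_per_ha": "bundles",
    "MT_per_ha": "MT",
}


def convert(value: float, from_unit: str, to_unit: str) -> float:
    """Convert ``value`` between two declared-compatible units.

    Raises :class:`UnitError` for unknown units or undeclared pairs
    (notably any mass <-> bundles attempt).
    """
    for u in (from_unit, to_unit):
        if u not in UNITS:
            raise UnitError(f"unknown unit {u!r}")
    if from_unit == to_unit:
        return value
    try:
        return value * _CONVERSIONS[(from_unit, to_unit)]
    except KeyError:
        raise UnitError(f"no declared conversion from {from_unit!r} to {to_unit!r}") from None


@dataclass(frozen=True)
class Quantity:
    """A non-negative value with a unit from the closed vocabulary."""

    value: float
    unit: str

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise UnitError(f"unknown unit {self.unit!r}")
        if not (self.value >= 0):  # also rejects NaN
            raise ValueError(f"quantity must be non-negative, got {self.value!r} {self.unit}")

    def to(self, unit: str) -> "Quantity":
        return Quantity(convert(self.value, self.unit, unit), unit)

    def in_unit(self, unit: str) -> float:
        """The bare value expressed in ``unit``."""
        return convert(self.value, self.unit, unit)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.value:g} {self.unit}"


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (0.5 -> 1), the convention used for all
    reported counts and tonnages.  Python's builtin ``round`` is banker's
    rounding, which disagrees on exact halves."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
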