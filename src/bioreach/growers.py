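"""Household growing model.

Estimates the number of farming households cultivating the biofortified
variety (the "3B" input of the main pipeline) from seed distribution data.
Two steps:

1. :func:`households_from_packs` converts per-year seed-channel records
   (agro-dealer sales, community multipliers, public distribution,
   farmer-to-farmer transfers) into newly *acquiring* households.  Where the
   number of seed packs sold per pack size is recorded, one pack is counted
   as one household; otherwise the channel quantity is divided by a
   configured typical purchase size.

2. :func:`project_growers` accumulates acquirers over years with
   farmer-to-farmer diffusion (rate ``d`` per year) and attrition (rate
   ``a`` per year), using the recursion

       H_t = H_{t-1} * (1 + d) * (1 - a) + A_t,   H_{first} = A_{first}

   i.e. last year's growers first recruit neighbours, a fraction then stops
   growing, and this year's new acquirers are added.  Applying diffusion
   before attrition within a year is a modelling choice; both rates are
   survey-derived inputs, not constants of this package.

With d = 0 and a = 0 the series is the cumulative sum of acquirers; with
a = 1 it collapses to the new acquirers of each year.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .errors import ConfigurationError
from .units import Quantity

#: Recognised seed acquisition channels.
CHANNELS = frozenset(
    {"agro_dealer", "community_multiplier", "public_distribution", "farmer_to_farmer"}
)

#: Tolerance for pack-count totals exceeding the recorded channel quantity.
PACK_TOTAL_TOLERANCE = 0.01


@dataclass(frozen=True)
class SeedChannelRecord:
    """Seed moved through one channel in one year.

    ``pack_counts`` maps pack size (kg or bundles per pack) to the number of
    packs sold; when present its mass total must not exceed ``quantity``
    by more than 1%.
    """

    year: int
    channel: str
    quantity: Quantity
    pack_counts: Optional[Mapping[float, int]] = None

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ConfigurationError(
                f"unknown seed channel {self.channel!r}; expected one of {sorted(CHANNELS)}"
            )
        if self.pack_counts:
            total = sum(size * n for size, n in self.pack_counts.items())
            if total > self.quantity.value * (1.0 + PACK_TOTAL_TOLERANCE):
                raise ConfigurationError(
                    f"pack counts for {self.channel!r} in {self.year} multiply out to "
                    f"{total:g}, exceeding the recorded channel quantity "
                    f"{self.quantity.value:g} {self.quantity.unit} by more than 1%"
                )


@dataclass
class GrowerSeries:
    """Year-indexed farming-household counts with the rates that produced them."""

    households: dict[int, float] = field(default_factory=dict)
    diffusion_rate: float = 0.0
    attrition_rate: float = 0.0

    def at(self, year: int) -> float:
        """Households in ``year``; falls back to the latest modelled year at
        or before ``year``."""
        if year in self.households:
            return self.households[year]
        earlier = [y for y in self.households if y <= year]
        if not earlier:
            raise ConfigurationError(
                f"grower series covers {sorted(self.households)} but year {year} was requested"
            )
        return self.households[max(earlier)]


def households_from_packs(
    records: Sequence[SeedChannelRecord],
    typical_purchase: Optional[Quantity] = None,
) -> dict[int, float]:
    """Newly acquiring households per year from seed-channel records.

    One pack = one household where pack counts exist; otherwise channel
    quantity / typical purchase size.  An empty record list yields an empty
    mapping with a warning (zero households everywhere).
    """
    if not records:
        warnings.warn("no seed-channel records supplied; acquiring households is zero")
        return {}
    acquirers: dict[int, float] = {}
    for rec in records:
        if rec.pack_counts:
            n = float(sum(rec.pack_counts.values()))
        else:
            if typical_purchase is None:
                raise ConfigurationError(
                    f"record for {rec.channel!r} in {rec.year} has no pack counts and "
                    "no typical purchase size was configured"
                )
            per_hh = rec.quantity.in_unit(typical_purchase.unit)
            if typical_purchase.value <= 0:
                raise ConfigurationError("typical purchase size must be positive")
            n = per_hh / typical_purchase.value
        acquirers[rec.year] = acquirers.get(rec.year, 0.0) + n
    return acquirers


def project_growers(
    acquirers_by_year: Mapping[int, float],
    diffusion_rate: float = 0.0,
    attrition_rate: float = 0.0,
    through_year: Optional[int] = None,
) -> GrowerSeries:
    """Project the grower-household series from annual acquirers.

    ``through_year`` extends the projection past the last acquisition year
    (diffusion and attrition keep acting with zero new acquirers)."""
    if diffusion_rate < 0:
        raise ConfigurationError(f"diffusion rate must be >= 0, got {diffusion_rate}")
    if not (0.0 <= attrition_rate <= 1.0):
        raise ConfigurationError(f"attrition rate must be in [0, 1], got {attrition_rate}")
    series = GrowerSeries(diffusion_rate=diffusion_rate, attrition_rate=attrition_rate)
    if not acquirers_by_year:
        return series
    last = max(acquirers_by_year)
    if through_year is not None:
        last = max(last, through_year)
    years = range(min(acquirers_by_year), last + 1)
    h = 0.0
    for i, year in enumerate(years):
        a_t = float(acquirers_by_year.get(year, 0.0))
        if i == 0:
            h = a_t
        else:
            h = h * (1.0 + diffusion_rate) * (1.0 - attrition_rate) + a_t
        series.households[year] = h
    return series
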