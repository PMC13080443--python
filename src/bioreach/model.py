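"""The five-phase reach/coverage calculation engine.

Estimates how many people eat a biofortified staple crop in a year (reach)
and what share of the national population that is (coverage), from seed
production, area, yield and food-balance inputs:

* phase 1 — seed availability: total biofortified seed planted, commercial
  plus farm-saved.  Farm-saved seed (FSS) is back-calculated: total seed
  used is area harvested x seed rate (1D = 1B x 1C); the FSS ratio is the
  excess of seed used over commercially produced seed, relative to seed
  produced (1F = (1D - 1E) / 1E); the same ratio is assumed to apply to the
  biofortified variety (1G = 1A x 1F, 1H = 1A + 1G).
* phase 2 — production: area planted with the biofortified crop
  (2B = 1H / seed rate), harvest (2D = 2B x yield), and the edible supply
  after deducting next-season seed, animal feed and post-harvest losses
  (2H = 2D x (1 - 2E - 2F - 2G)).
* phase 3 — on-farm consumption: farming population (3D = households x
  household size) and the tonnage they retain (3E = 3D x annual per-capita
  on-farm intake / 1000).
* phase 4 — off-farm consumption: marketed surplus (4A = 2H - 3E) and, for
  each replacement scenario r, the population it can supply at an intake of
  r x the national per-capita supply (4C = 4A x 1000 / (r x 4B)).
* phase 5 — reach (5A = 3D + 4C) and coverage (5C = 100 x 5A / national
  population).

Quantities flow through in full floating precision; rounding is applied only
when reporting (see :meth:`PipelineResult.rounded`).  Physically impossible
intermediates are clamped to zero with a recorded warning instead of raising:
a negative raw FSS ratio (commercial seed exceeds total seed use) and on-farm
consumption exceeding the edible supply both occur in plausible real
configurations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

from .config import CountryCropConfig, Scenario, validate_config
from .errors import BioreachError, ConfigValidationError, ConfigurationError, UnitError
from .growers import project_growers
from .units import RATE_NUMERATOR, Quantity, convert, round_half_up

__all__ = [
    "SeedParams",
    "SeedAvailability",
    "ProductionParams",
    "SupplyChain",
    "OnFarmParams",
    "FarmingPopulation",
    "ScenarioSpec",
    "ScenarioResult",
    "PipelineResult",
    "estimate_seed_availability",
    "estimate_production",
    "adjust_yield",
    "estimate_onfarm",
    "estimate_offfarm",
    "estimate_reach_coverage",
    "run_pipeline",
    "alternative_seed_ratio_method",
    "intake_plausibility",
    "overlap_adjusted_reach",
    "DEFAULT_DAILY_INTAKE_BOUNDS",
]


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SeedParams:
    """Phase-1 inputs: commercial biofortified seed (1A), area harvested (1B),
    seed rate (1C) and total seed produced (1E)."""

    bf_seed_produced: Quantity
    total_area_harvested: Quantity
    seed_rate: Quantity
    total_seed_produced: Quantity


@dataclass(frozen=True)
class SeedAvailability:
    """Phase-1 outputs; ``clamped`` records a negative raw FSS ratio."""

    total_seed_used: Quantity  # 1D, in the unit of 1E
    fss_ratio: float  # 1F
    bf_fss: Quantity  # 1G
    total_bf_seed_used: Quantity  # 1H
    clamped: bool = False


@dataclass(frozen=True)
class ProductionParams:
    """Phase-2 inputs: seed rate (2A, equals 1C), yield (2C) and the three
    harvest deduction fractions (2E farm-saved seed, 2F feed, 2G losses)."""

    seed_rate: Quantity
    yield_per_ha: Quantity
    fss_frac: float
    feed_frac: float
    phl_frac: float

    def __post_init__(self) -> None:
        for name, f in (("2E", self.fss_frac), ("2F", self.feed_frac), ("2G", self.phl_frac)):
            if not (0.0 <= f < 1.0):
                raise ConfigurationError(f"{name}: deduction fraction {f!r} outside [0, 1)")
        if self.fss_frac + self.feed_frac + self.phl_frac >= 1.0:
            raise ConfigurationError(
                "deduction fractions sum to "
                f"{self.fss_frac + self.feed_frac + self.phl_frac:.4f} >= 1"
            )


@dataclass
class SupplyChain:
    """Phase 2-4 tonnages.  ``onfarm_quantity`` and ``offfarm_quantity`` are
    filled by phases 3/4; before rounding they sum to ``edible_supply``
    (unless on-farm demand was clamped)."""

    area_planted: Quantity  # 2B
    harvest: Quantity  # 2D
    edible_supply: Quantity  # 2H
    onfarm_quantity: Optional[Quantity] = None  # 3E
    offfarm_quantity: Optional[Quantity] = None  # 4A


@dataclass(frozen=True)
class OnFarmParams:
    households: float  # 3B
    household_size: float  # 3C
    intake_onfarm: Quantity  # 3A, kg/person/year

    def __post_init__(self) -> None:
        if self.households < 0:
            raise ConfigurationError(f"3B: households must be >= 0, got {self.households!r}")
        if not (self.household_size > 0):
            raise ConfigurationError(f"3C: household size must be > 0, got {self.household_size!r}")
        if not (self.intake_onfarm.value > 0):
            raise ConfigurationError("3A: on-farm intake must be > 0")


@dataclass(frozen=True)
class FarmingPopulation:
    persons: float  # 3D


@dataclass(frozen=True)
class ScenarioSpec:
    """An off-farm consumption scenario: consumers obtain
    ``replacement_fraction`` of their annual crop intake from the
    biofortified variety."""

    label: str
    replacement_fraction: float
    intake_national: Quantity  # 4B basis, kg/person/year

    def __post_init__(self) -> None:
        if not (0.0 < self.replacement_fraction <= 1.0):
            raise ConfigurationError(
                f"replacement fraction must be in (0, 1], got {self.replacement_fraction!r}"
            )


@dataclass
class ScenarioResult:
    """Off-farm and overall results for one scenario.  ``reach`` and
    ``coverage_pct`` are filled by phase 5."""

    label: str
    replacement_fraction: float
    intake_bf_offfarm: Quantity  # 4B.x
    offfarm_population: float  # 4C.x
    reach: Optional[float] = None  # 5A.x
    coverage_pct: Optional[float] = None  # 5C.x
    plausibility_flags: list[str] = field(default_factory=list)


# --------------------------------------------------------------------------
# phase operations
# --------------------------------------------------------------------------


def estimate_seed_availability(p: SeedParams) -> SeedAvailability:
    """Phase 1: back-calculate farm-saved seed and total biofortified seed use.

    1D = 1B x 1C (expressed in the unit of 1E); 1F = max(0, (1D - 1E) / 1E);
    1G = 1A x 1F; 1H = 1A + 1G.  A negative raw ratio (more commercial seed
    than total seed use) clamps to zero and sets ``clamped``.
    """
    rate = p.seed_rate
    if rate.unit not in RATE_NUMERATOR:
        raise UnitError(f"1C: {rate.unit!r} is not a per-hectare seed rate unit")
    num_unit = RATE_NUMERATOR[rate.unit]
    stock_unit = p.total_seed_produced.unit
    area_ha = p.total_area_harvested.in_unit("ha")
    total_used = convert(area_ha * rate.value, num_unit, stock_unit)  # 1D
    produced = p.total_seed_produced.value  # 1E
    if produced <= 0:
        raise ConfigurationError("1E: total seed produced must be positive (FSS ratio undefined)")
    bf = p.bf_seed_produced.in_unit(stock_unit)  # 1A
    raw = (total_used - produced) / produced
    fss_ratio = max(0.0, raw)  # 1F
    bf_fss = bf * fss_ratio  # 1G
    return SeedAvailability(
        total_seed_used=Quantity(total_used, stock_unit),
        fss_ratio=fss_ratio,
        bf_fss=Quantity(bf_fss, stock_unit),
        total_bf_seed_used=Quantity(bf + bf_fss, stock_unit),
        clamped=raw < 0,
    )


def estimate_production(seed: SeedAvailability, p: ProductionParams) -> SupplyChain:
    """Phase 2: area planted, harvest, and edible supply.

    2B = 1H / 2A, 2D = 2B x 2C, 2H = 2D x (1 - 2E - 2F - 2G), full precision
    carried throughout.
    """
    rate = p.seed_rate
    if rate.unit not in RATE_NUMERATOR:
        raise UnitError(f"2A: {rate.unit!r} is not a per-hectare seed rate unit")
    num_unit = RATE_NUMERATOR[rate.unit]
    seed_in_rate_unit = seed.total_bf_seed_used.in_unit(num_unit)
    if rate.value <= 0:
        raise ConfigurationError("2A: seed rate must be positive")
    area = seed_in_rate_unit / rate.value  # 2B, ha
    harvest = area * p.yield_per_ha.in_unit("MT_per_ha")  # 2D, MT
    keep = 1.0 - p.fss_frac - p.feed_frac - p.phl_frac
    return SupplyChain(
        area_planted=Quantity(area, "ha"),
        harvest=Quantity(harvest, "MT"),
        edible_supply=Quantity(harvest * keep, "MT"),
    )


def adjust_yield(base_yield: float, ref_yield_prev: float, ref_yield_curr: float) -> float:
    """Scale a survey yield (MT/ha) to another year by the ratio of reference
    (e.g. national statistical) yields for the two years.

    Used when no farmer survey exists for the target year: the most recent
    survey yield is carried forward with the year-over-year change observed
    in the reference series.
    """
    for name, y in (
        ("base yield", base_yield),
        ("reference yield (previous)", ref_yield_prev),
        ("reference yield (current)", ref_yield_curr),
    ):
        if not (y > 0):
            raise ConfigurationError(f"{name} must be positive, got {y!r}")
    return base_yield * (ref_yield_curr / ref_yield_prev)


def estimate_onfarm(p: OnFarmParams) -> tuple[FarmingPopulation, Quantity]:
    """Phase 3: farming population (3D = 3B x 3C) and the tonnage consumed
    on-farm (3E = 3D x 3A / 1000, kg -> MT)."""
    persons = p.households * p.household_size
    onfarm_mt = persons * p.intake_onfarm.in_unit("kg_per_person_year") / 1000.0
    return FarmingPopulation(persons=persons), Quantity(onfarm_mt, "MT")


def estimate_offfarm(supply: SupplyChain, scenario: ScenarioSpec) -> ScenarioResult:
    """Phase 4: marketed surplus and the population it can supply.

    4A = 2H - 3E (clamped at zero with a flag when on-farm consumption
    exceeds the edible supply); 4B = r x national intake; 4C = 4A x 1000 / 4B.
    """
    if supply.onfarm_quantity is None:
        raise ConfigurationError("phase 3 on-farm quantity missing from supply chain")
    flags: list[str] = []
    raw = supply.edible_supply.in_unit("MT") - supply.onfarm_quantity.in_unit("MT")
    if raw < 0:
        flags.append(
            "on-farm consumption exceeds edible supply; off-farm quantity clamped to 0 "
            f"(deficit {-raw:.1f} MT)"
        )
        raw = 0.0
    supply.offfarm_quantity = Quantity(raw, "MT")
    intake = scenario.replacement_fraction * scenario.intake_national.in_unit(
        "kg_per_person_year"
    )
    if intake <= 0:
        raise ConfigurationError("4B: scenario intake must be positive")
    population = raw * 1000.0 / intake
    return ScenarioResult(
        label=scenario.label,
        replacement_fraction=scenario.replacement_fraction,
        intake_bf_offfarm=Quantity(intake, "kg_per_person_year"),
        offfarm_population=population,
        plausibility_flags=flags,
    )


def estimate_reach_coverage(
    farm: FarmingPopulation, s: ScenarioResult, national_population: float
) -> ScenarioResult:
    """Phase 5: reach (5A = 3D + 4C) and coverage (5C = 100 x 5A / 5B),
    flagging reach above the national population instead of raising."""
    if not (national_population > 0):
        raise ConfigurationError(f"5B: national population must be > 0, got {national_population!r}")
    s.reach = farm.persons + s.offfarm_population
    s.coverage_pct = 100.0 * s.reach / national_population
    if s.reach > national_population:
        s.plausibility_flags.append(
            f"reach {s.reach:,.0f} exceeds national population "
            f"{national_population:,.0f} (coverage {s.coverage_pct:.1f}%)"
        )
    return s


# --------------------------------------------------------------------------
# the composed pipeline
# --------------------------------------------------------------------------

#: Decimal places used when reporting each parameter (default: integer).
REPORT_DECIMALS = {"1F": 1, "2C": 1, "3C": 1, "2E": 3, "2F": 3, "2G": 3}

_PHASES = {
    "1": "phase 1 (seed availability)",
    "2": "phase 2 (production)",
    "3": "phase 3 (on-farm consumption)",
    "4": "phase 4 (off-farm consumption)",
    "5": "phase 5 (reach and coverage)",
}


@dataclass
class PipelineResult:
    """Full-precision values for every parameter ID, plus per-scenario
    results and any plausibility warnings raised along the way."""

    metadata: dict
    values: dict[str, float]
    units: dict[str, str]
    scenarios: list[ScenarioResult]
    flags: list[str] = field(default_factory=list)

    def rounded(self) -> dict[str, float]:
        """Values rounded per the reporting policy: half-up to integers for
        counts, tonnages and percents; one decimal for ratios, yields and
        household size."""
        return {
            pid: round_half_up(v, REPORT_DECIMALS.get(pid.split(".")[0], 0))
            for pid, v in self.values.items()
        }

    def to_dict(self) -> dict:
        return {
            "metadata": dict(self.metadata),
            "values": dict(self.values),
            "units": dict(self.units),
            "flags": list(self.flags),
            "scenarios": [
                {
                    "label": s.label,
                    "replacement_fraction": s.replacement_fraction,
                    "intake_bf_offfarm": s.intake_bf_offfarm.value,
                    "offfarm_population": s.offfarm_population,
                    "reach": s.reach,
                    "coverage_pct": s.coverage_pct,
                    "plausibility_flags": list(s.plausibility_flags),
                }
                for s in self.scenarios
            ],
        }


def _resolve_households(cfg: CountryCropConfig) -> float:
    if "3B" in cfg.parameters:
        return cfg.effective("3B")
    series = project_growers(
        cfg.grower_model.acquirers_by_year,
        cfg.grower_model.diffusion_rate,
        cfg.grower_model.attrition_rate,
        through_year=cfg.metadata.year,
    )
    return series.at(cfg.metadata.year)


def run_pipeline(cfg: CountryCropConfig) -> PipelineResult:
    """Run phases 1-5 for one country-crop-year configuration.

    Returns every parameter keyed by its ID ("1A" ... "5C.<i>"), with
    scenario-dependent parameters suffixed by the 1-based scenario index in
    the order the config lists them.  Identical to composing the phase
    operations by hand; phase errors are re-raised with the phase named.
    """
    violations = validate_config(cfg)
    if violations:
        raise ConfigValidationError(violations)

    values: dict[str, float] = {}
    units: dict[str, str] = {}
    flags: list[str] = []

    def put(pid: str, value: float, unit: str) -> None:
        values[pid] = float(value)
        units[pid] = unit

    seed_unit = cfg.unit("1E")
    put("1A", cfg.parameters["1A"].effective, cfg.unit("1A"))
    put("1B", cfg.effective("1B"), "ha")
    put("1C", cfg.effective("1C"), cfg.unit("1C"))
    put("1E", cfg.effective("1E"), seed_unit)

    try:
        avail = estimate_seed_availability(
            SeedParams(
                bf_seed_produced=Quantity(cfg.effective("1A"), cfg.unit("1A")),
                total_area_harvested=Quantity(cfg.effective("1B"), "ha"),
                seed_rate=Quantity(cfg.effective("1C"), cfg.unit("1C")),
                total_seed_produced=Quantity(cfg.effective("1E"), seed_unit),
            )
        )
    except BioreachError as e:
        raise type(e)(f"{_PHASES['1']}: {e}") from e
    put("1D", avail.total_seed_used.value, seed_unit)
    put("1F", avail.fss_ratio, "fraction")
    put("1G", avail.bf_fss.value, seed_unit)
    put("1H", avail.total_bf_seed_used.value, seed_unit)
    if avail.clamped:
        flags.append(
            "commercial seed production exceeds estimated total seed use; "
            "farm-saved seed clamped to 0"
        )

    try:
        supply = estimate_production(
            avail,
            ProductionParams(
                seed_rate=Quantity(cfg.effective("1C"), cfg.unit("1C")),
                yield_per_ha=Quantity(cfg.effective("2C"), "MT_per_ha"),
                fss_frac=cfg.fraction("2E"),
                feed_frac=cfg.fraction("2F"),
                phl_frac=cfg.fraction("2G"),
            ),
        )
    except BioreachError as e:
        raise type(e)(f"{_PHASES['2']}: {e}") from e
    put("2A", cfg.effective("1C"), cfg.unit("1C"))
    put("2B", supply.area_planted.value, "ha")
    put("2C", cfg.effective("2C"), "MT_per_ha")
    put("2D", supply.harvest.value, "MT")
    for pid in ("2E", "2F", "2G"):
        put(pid, cfg.fraction(pid), "fraction")
    put("2H", supply.edible_supply.value, "MT")

    try:
        households = _resolve_households(cfg)
        farm, onfarm_qty = estimate_onfarm(
            OnFarmParams(
                households=households,
                household_size=cfg.effective("3C"),
                intake_onfarm=Quantity(cfg.effective("3A"), "kg_per_person_year"),
            )
        )
    except BioreachError as e:
        raise type(e)(f"{_PHASES['3']}: {e}") from e
    supply.onfarm_quantity = onfarm_qty
    put("3A", cfg.effective("3A"), "kg_per_person_year")
    put("3B", households, "households")
    put("3C", cfg.effective("3C"), "persons")
    put("3D", farm.persons, "persons")
    put("3E", onfarm_qty.value, "MT")

    national_intake = Quantity(cfg.effective("4B"), "kg_per_person_year")
    national_population = cfg.effective("5B")
    put("5B", national_population, "persons")

    scenario_results: list[ScenarioResult] = []
    for i, sc in enumerate(cfg.scenarios, start=1):
        try:
            res = estimate_offfarm(
                supply,
                ScenarioSpec(
                    label=sc.label,
                    replacement_fraction=sc.replacement_fraction,
                    intake_national=national_intake,
                ),
            )
        except BioreachError as e:
            raise type(e)(f"{_PHASES['4']}: {e}") from e
        try:
            res = estimate_reach_coverage(farm, res, national_population)
        except BioreachError as e:
            raise type(e)(f"{_PHASES['5']}: {e}") from e
        put(f"4B.{i}", res.intake_bf_offfarm.value, "kg_per_person_year")
        put(f"4C.{i}", res.offfarm_population, "persons")
        put(f"5A.{i}", res.reach, "persons")
        put(f"5C.{i}", res.coverage_pct, "percent")
        scenario_results.append(res)
        flags.extend(f"[{sc.label}] {f}" for f in res.plausibility_flags)
    # 4A is scenario-independent (set by the first estimate_offfarm call).
    put("4A", supply.offfarm_quantity.value, "MT")

    return PipelineResult(
        metadata=cfg.metadata.model_dump(),
        values=values,
        units=units,
        scenarios=scenario_results,
        flags=flags,
    )


# --------------------------------------------------------------------------
# auxiliary computations
# --------------------------------------------------------------------------


def alternative_seed_ratio_method(result: PipelineResult) -> ScenarioResult:
    """Off-farm reach under a full-mixing assumption.

    Instead of positing a replacement fraction, the share of biofortified
    seed in total seed use (s = 1H / 1D) is taken as the biofortified share
    of everyone's crop intake: off-farm intake = s x national per-capita
    intake, off-farm population = 4A x 1000 / intake, reach and coverage as
    in phase 5.  Because full mixing dilutes the per-capita biofortified
    intake, this method yields much larger populations and can produce a
    reach above the national population, which is flagged (never raised) —
    the signal that the mixing assumption is implausible for that crop.
    """
    v = result.values
    if not (v["1D"] > 0):
        raise ConfigurationError("1D: total seed used must be positive")
    s = v["1H"] / v["1D"]
    # national intake basis = scenario intake / replacement fraction
    first = result.scenarios[0]
    intake_national = first.intake_bf_offfarm.value / first.replacement_fraction
    intake = s * intake_national
    flags: list[str] = []
    if intake <= 0:
        flags.append("biofortified seed share is zero; off-farm population set to 0")
        population = 0.0
    else:
        population = v["4A"] * 1000.0 / intake
    res = ScenarioResult(
        label="seed-ratio (full mixing)",
        replacement_fraction=s,
        intake_bf_offfarm=Quantity(intake, "kg_per_person_year"),
        offfarm_population=population,
        plausibility_flags=flags,
    )
    return estimate_reach_coverage(FarmingPopulation(v["3D"]), res, v["5B"])


#: Default plausible range for a daily staple intake, g/person/day.
DEFAULT_DAILY_INTAKE_BOUNDS = (100.0, 600.0)


class IntakeCheck(NamedTuple):
    daily_g: float
    flagged: bool


def intake_plausibility(
    intake_annual_kg: float,
    bounds: tuple[float, float] = DEFAULT_DAILY_INTAKE_BOUNDS,
) -> IntakeCheck:
    """Convert an annual per-capita intake (kg/person/y) to g/person/day and
    flag values outside ``bounds``.

    Survey-derived staple intakes above ~600 g/day are generally considered
    implausible for an individual mean and signal a data problem.
    """
    if intake_annual_kg < 0:
        raise ConfigurationError(f"intake must be >= 0, got {intake_annual_kg!r}")
    daily = intake_annual_kg * 1000.0 / 365.0
    lo, hi = bounds
    return IntakeCheck(daily_g=daily, flagged=not (lo <= daily <= hi))


def overlap_adjusted_reach(reaches: Sequence[float], overlap_fraction: float) -> float:
    """Combined reach of several crops when a fraction of people consume more
    than one of them: sum(reaches) x (1 - overlap_fraction)."""
    if not reaches:
        raise ConfigurationError("at least one reach value is required")
    if not (0.0 <= overlap_fraction < 1.0):
        raise ConfigurationError(
            f"overlap fraction must be in [0, 1), got {overlap_fraction!r}"
        )
    return sum(reaches) * (1.0 - overlap_fraction)
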