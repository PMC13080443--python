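"""Phase operations against worked-example cells and hand-computed oracles."""

import pytest

from bioreach import (
    ConfigurationError,
    FarmingPopulation,
    OnFarmParams,
    ProductionParams,
    Quantity,
    ScenarioResult,
    ScenarioSpec,
    SeedParams,
    SupplyChain,
    UnitError,
    adjust_yield,
    alternative_seed_ratio_method,
    estimate_offfarm,
    estimate_onfarm,
    estimate_production,
    estimate_reach_coverage,
    estimate_seed_availability,
    intake_plausibility,
    overlap_adjusted_reach,
    round_half_up,
)


def seed_params(bf=1.0, area=1.0, rate=1.0, produced=1.0, unit="MT", rate_unit="kg_per_ha"):
    return SeedParams(
        bf_seed_produced=Quantity(bf, unit),
        total_area_harvested=Quantity(area, "ha"),
        seed_rate=Quantity(rate, rate_unit),
        total_seed_produced=Quantity(produced, unit),
    )


class TestSeedAvailability:
    def test_total_seed_used_from_area_and_rate(self):
        """11.64 Mha at 30 kg/ha is 349,249 MT of seed (rice example)."""
        avail = estimate_seed_availability(
            seed_params(bf=7_244, area=11_641_645, rate=30, produced=146_708)
        )
        assert round_half_up(avail.total_seed_used.value) == 349_249
        assert avail.total_seed_used.unit == "MT"

    def test_fss_ratio_and_total_bf_seed(self):
        """Maize example: ratio (114,000-60,000)/60,000 = 0.9 exactly,
        total biofortified seed 13,282 x 1.9 = 25,236 (rounded)."""
        avail = estimate_seed_availability(
            seed_params(bf=13_282, area=5_700_000, rate=20, produced=60_000)
        )
        assert avail.fss_ratio == pytest.approx(0.9, abs=1e-12)
        assert round_half_up(avail.total_bf_seed_used.value) == 25_236
        assert not avail.clamped

    def test_no_farm_saved_seed_when_use_equals_production(self):
        avail = estimate_seed_availability(seed_params(bf=5, area=1000, rate=10, produced=10))
        assert avail.fss_ratio == 0.0
        assert avail.total_bf_seed_used.value == 5.0
        assert not avail.clamped

    def test_negative_raw_ratio_clamps_and_flags(self):
        """More commercial seed than total use: ratio clamps to 0, flagged."""
        avail = estimate_seed_availability(seed_params(bf=5, area=1000, rate=10, produced=20))
        assert avail.fss_ratio == 0.0
        assert avail.clamped
        assert avail.total_bf_seed_used.value == 5.0

    def test_bundles_stay_bundles(self):
        avail = estimate_seed_availability(
            seed_params(bf=100, area=50, rate=60, produced=2000, unit="bundles",
                        rate_unit="bundles_per_ha")
        )
        assert avail.total_seed_used == Quantity(3000, "bundles")

    def test_zero_seed_production_is_an_error(self):
        with pytest.raises(ConfigurationError):
            estimate_seed_availability(seed_params(produced=0.0))

    def test_incompatible_seed_units_refused(self):
        with pytest.raises(UnitError):
            estimate_seed_availability(
                seed_params(unit="bundles", rate_unit="kg_per_ha")
            )


class TestProduction:
    def test_area_planted_from_seed_and_rate(self):
        """Wheat example: 380,440 MT of seed at 120 kg/ha plants ~3.17 Mha."""
        avail = estimate_seed_availability(
            seed_params(bf=179_486, area=9_032_688, rate=120, produced=511_379)
        )
        supply = estimate_production(
            avail,
            ProductionParams(
                seed_rate=Quantity(120, "kg_per_ha"),
                yield_per_ha=Quantity(3.5, "MT_per_ha"),
                fss_frac=0.04, feed_frac=0.02, phl_frac=0.04,
            ),
        )
        assert supply.area_planted.value == pytest.approx(3_170_332, abs=2)
        assert supply.harvest.value == pytest.approx(11_096_161, rel=1e-5)

    def test_zero_deductions_leave_harvest_edible(self):
        avail = estimate_seed_availability(seed_params(bf=10, area=1000, rate=10, produced=5))
        supply = estimate_production(
            avail,
            ProductionParams(
                seed_rate=Quantity(10, "kg_per_ha"),
                yield_per_ha=Quantity(2.0, "MT_per_ha"),
                fss_frac=0.0, feed_frac=0.0, phl_frac=0.0,
            ),
        )
        assert supply.edible_supply.value == supply.harvest.value

    def test_deductions_summing_to_one_rejected(self):
        with pytest.raises(ConfigurationError):
            ProductionParams(
                seed_rate=Quantity(10, "kg_per_ha"),
                yield_per_ha=Quantity(2.0, "MT_per_ha"),
                fss_frac=0.5, feed_frac=0.3, phl_frac=0.2,
            )


class TestYieldAdjustment:
    def test_reference_series_scaling(self):
        """Carrying an 8.2 MT/ha survey yield forward by a 6.0145->6.3459
        reference change gives 8.65 MT/ha."""
        assert round_half_up(adjust_yield(8.2, 6.0145, 6.3459), 2) == 8.65

    def test_equal_references_leave_yield_unchanged(self):
        assert adjust_yield(4.2, 3.0, 3.0) == 4.2

    def test_direct_arithmetic(self):
        assert adjust_yield(10.0, 5.0, 6.0) == pytest.approx(12.0)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ConfigurationError):
            adjust_yield(8.2, 0.0, 6.3)


class TestOnFarm:
    def test_farming_population(self):
        """Rice example: 2,552,319 households x 2.8 persons = 7,146,493."""
        farm, _ = estimate_onfarm(
            OnFarmParams(households=2_552_319, household_size=2.8,
                         intake_onfarm=Quantity(187, "kg_per_person_year"))
        )
        assert round_half_up(farm.persons) == 7_146_493

    def test_onfarm_tonnage(self):
        """Cassava example: 12.53 M people at 89 kg/y eat ~1.11 M MT."""
        _, qty = estimate_onfarm(
            OnFarmParams(households=2_236_726, household_size=5.6,
                         intake_onfarm=Quantity(89, "kg_per_person_year"))
        )
        assert round_half_up(qty.value) == 1_114_784
        assert qty.unit == "MT"

    def test_zero_households(self):
        farm, qty = estimate_onfarm(
            OnFarmParams(households=0, household_size=4.0,
                         intake_onfarm=Quantity(100, "kg_per_person_year"))
        )
        assert farm.persons == 0.0 and qty.value == 0.0


def make_supply(edible, onfarm):
    return SupplyChain(
        area_planted=Quantity(1.0, "ha"),
        harvest=Quantity(edible, "MT"),
        edible_supply=Quantity(edible, "MT"),
        onfarm_quantity=Quantity(onfarm, "MT"),
    )


class TestOffFarm:
    def test_marketed_surplus(self):
        """Wheat example: 9,980,420 - 2,125,839 = 7,854,581 MT to market."""
        res = estimate_offfarm(
            make_supply(9_980_420, 2_125_839),
            ScenarioSpec("full replacement", 1.0, Quantity(103, "kg_per_person_year")),
        )
        assert res.plausibility_flags == []

    def test_onfarm_consuming_everything_clamps(self):
        supply = make_supply(100.0, 100.0)
        res = estimate_offfarm(
            supply, ScenarioSpec("full replacement", 1.0, Quantity(50, "kg_per_person_year"))
        )
        assert supply.offfarm_quantity.value == 0.0
        assert res.offfarm_population == 0.0

    def test_onfarm_exceeding_supply_flags(self):
        res = estimate_offfarm(
            make_supply(100.0, 150.0),
            ScenarioSpec("full replacement", 1.0, Quantity(50, "kg_per_person_year")),
        )
        assert res.offfarm_population == 0.0
        assert any("clamped" in f for f in res.plausibility_flags)

    def test_half_replacement_population(self):
        """1,000 MT at half of a 50 kg/y intake feeds 40,000 people."""
        res = estimate_offfarm(
            make_supply(1_000.0, 0.0),
            ScenarioSpec("half replacement", 0.5, Quantity(50, "kg_per_person_year")),
        )
        assert res.intake_bf_offfarm.value == pytest.approx(25.0)
        assert res.offfarm_population == pytest.approx(40_000.0)


class TestReachCoverage:
    def test_reach_is_farm_plus_market(self):
        s = ScenarioResult("full replacement", 1.0,
                           Quantity(100, "kg_per_person_year"), offfarm_population=30_000.0)
        s = estimate_reach_coverage(FarmingPopulation(70_000.0), s, 1_000_000.0)
        assert s.reach == 100_000.0
        assert s.coverage_pct == pytest.approx(10.0)
        assert s.plausibility_flags == []

    def test_zero_offfarm_reach_equals_farming_population(self):
        s = ScenarioResult("full replacement", 1.0,
                           Quantity(100, "kg_per_person_year"), offfarm_population=0.0)
        s = estimate_reach_coverage(FarmingPopulation(5_000.0), s, 50_000.0)
        assert s.reach == 5_000.0

    def test_reach_above_population_flags_never_raises(self):
        s = ScenarioResult("full replacement", 1.0,
                           Quantity(100, "kg_per_person_year"), offfarm_population=2_000_000.0)
        s = estimate_reach_coverage(FarmingPopulation(0.0), s, 1_000_000.0)
        assert s.coverage_pct > 100.0
        assert any("exceeds national population" in f for f in s.plausibility_flags)


class TestAlternativeSeedRatioMethod:
    def test_unit_seed_share_reduces_to_full_replacement(self, results):
        """When all seed is biofortified (s = 1) the full-mixing estimate
        coincides with the full-replacement scenario."""
        res = results["pakistan_zinc_wheat_2023"]
        import copy

        forced = copy.deepcopy(res)
        forced.values["1H"] = forced.values["1D"]
        alt = alternative_seed_ratio_method(forced)
        assert alt.offfarm_population == pytest.approx(
            res.scenarios[0].offfarm_population, rel=1e-12
        )
        assert alt.reach == pytest.approx(res.scenarios[0].reach, rel=1e-12)


class TestAuxiliary:
    @pytest.mark.parametrize(
        "annual,expected_daily,expected_flag",
        [
            (259.0, 710, True),   # implausibly high survey intake
            (103.0, 282, False),  # within plausible staple range
            (0.0, 0, True),
        ],
    )
    def test_intake_plausibility(self, annual, expected_daily, expected_flag):
        daily, flagged = intake_plausibility(annual)
        assert round_half_up(daily) == expected_daily
        assert flagged is expected_flag

    def test_intake_custom_bounds(self):
        assert intake_plausibility(259.0, bounds=(100.0, 800.0)).flagged is False

    @pytest.mark.parametrize(
        "reaches,overlap,expected",
        [
            ([17.9e6, 12.5e6], 0.25, 22.8e6),
            ([5.0, 7.0], 0.0, 12.0),
            ([10.0, 10.0], 0.5, 10.0),
        ],
    )
    def test_overlap_adjusted_reach(self, reaches, overlap, expected):
        assert overlap_adjusted_reach(reaches, overlap) == pytest.approx(expected)

    def test_overlap_bounds(self):
        with pytest.raises(ConfigurationError):
            overlap_adjusted_reach([1.0], 1.0)
        with pytest.raises(ConfigurationError):
            overlap_adjusted_reach([], 0.2)
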