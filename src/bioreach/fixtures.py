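"""Bundled worked-example configurations and randomized valid configs.

Four country-crop-year parameter sets ship with the package (zinc rice in
Bangladesh, zinc wheat in Pakistan, vitamin A maize and cassava in Nigeria,
all for 2023).  They are the engine's golden inputs: every published input
cell is stored as printed, with precise overrides where the published
arithmetic used unrounded source values.

:func:`random_config` draws a structurally valid configuration whose
parameter ranges bracket the bundled ones by roughly an order of magnitude
in either direction; it is the input generator for property tests.
"""

from __future__ import annotations

import random
from importlib import resources

import yaml

from .config import CountryCropConfig, config_from_dict

FIXTURE_NAMES = (
    "bangladesh_zinc_rice_2023",
    "pakistan_zinc_wheat_2023",
    "nigeria_vita_maize_2023",
    "nigeria_vita_cassava_2023",
)


def load_fixture(name: str) -> CountryCropConfig:
    """Load one bundled configuration by name."""
    if name not in FIXTURE_NAMES:
        raise KeyError(
            f"unknown fixture {name!r}; valid names: {', '.join(FIXTURE_NAMES)}"
        )
    text = (resources.files("bioreach") / "data" / f"{name}.yaml").read_text()
    return config_from_dict(yaml.safe_load(text))


def load_catalog() -> dict[str, CountryCropConfig]:
    """All bundled configurations, keyed by name."""
    return {name: load_fixture(name) for name in FIXTURE_NAMES}


def random_config(seed: int) -> CountryCropConfig:
    """A deterministic, schema-valid random configuration.

    Construction guarantees the engine's preconditions: positive rates and
    stocks, deductions summing below 0.9, and a farming population whose
    on-farm demand stays within the edible supply (so the mass balance is
    exercised without clamping).
    """
    rng = random.Random(seed)
    bundles = rng.random() < 0.25
    if bundles:
        rate, rate_unit, stock_unit = rng.uniform(6.0, 600.0), "bundles_per_ha", "bundles"
        to_stock = 1.0
    else:
        rate, rate_unit, stock_unit = rng.uniform(3.0, 600.0), "kg_per_ha", "MT"
        to_stock = 1e-3
    area = rng.uniform(1e5, 5e7)  # ha
    total_used = area * rate * to_stock  # 1D in stock unit
    fss_ratio = rng.uniform(0.0, 6.0)
    produced = total_used / (1.0 + fss_ratio)  # 1E so that 1F = fss_ratio
    bf_seed = produced * rng.uniform(1e-3, 0.5)  # 1A
    yield_mt = rng.uniform(0.8, 15.0)
    while True:
        fracs = [rng.uniform(0.0, 0.4) for _ in range(3)]
        if sum(fracs) < 0.9:
            break
    household_size = rng.uniform(2.0, 12.0)
    intake_onfarm = rng.uniform(20.0, 300.0)
    intake_national = rng.uniform(30.0, 300.0)

    # straight-line supply arithmetic to place the farming population safely
    total_bf = bf_seed * (1.0 + fss_ratio)
    area_bf = total_bf / to_stock / rate
    edible = area_bf * yield_mt * (1.0 - sum(fracs))
    farm_pop = rng.uniform(0.05, 0.9) * edible * 1000.0 / intake_onfarm
    households = farm_pop / household_size
    population = max(farm_pop * rng.uniform(1.5, 50.0), 1e6)

    params = {
        "1A": {"value": bf_seed, "unit": stock_unit},
        "1B": {"value": area, "unit": "ha"},
        "1C": {"value": rate, "unit": rate_unit},
        "1E": {"value": produced, "unit": stock_unit},
        "2C": {"value": yield_mt, "unit": "MT_per_ha"},
        "2E": {"value": fracs[0], "unit": "fraction"},
        "2F": {"value": fracs[1], "unit": "fraction"},
        "2G": {"value": fracs[2], "unit": "fraction"},
        "3A": {"value": intake_onfarm, "unit": "kg_per_person_year"},
        "3B": {"value": households, "unit": "households"},
        "3C": {"value": household_size, "unit": "persons"},
        "4B": {"value": intake_national, "unit": "kg_per_person_year"},
        "5B": {"value": population, "unit": "persons"},
    }
    return config_from_dict(
        {
            "metadata": {
                "country": f"Synthetica-{seed}",
                "crop": "bundleroot" if bundles else "grain",
                "nutrient": "zinc",
                "year": 2023,
            },
            "parameters": params,
            "scenarios": [
                {"label": "full replacement", "replacement_fraction": 1.0},
                {"label": "half replacement", "replacement_fraction": 0.5},
            ],
        }
    )
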