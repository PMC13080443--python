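"""Shared fixtures: the published golden table and an independent
worksheet-style recomputation used as the engine's oracle."""

from __future__ import annotations

import pytest
from hypothesis import settings as hypothesis_settings

from bioreach import load_catalog

# Deterministic property tests, no on-disk example database.
hypothesis_settings.register_profile("bioreach", database=None, derandomize=True)
hypothesis_settings.load_profile("bioreach")

# ---------------------------------------------------------------------------
# The published worked-example table (one column per country-crop, 2023).
# Input rows are the values stored in the bundled fixture configs; computed
# rows are the published results the engine must reproduce.
# ---------------------------------------------------------------------------

INPUT_IDS = ("1A", "1B", "1C", "1E", "2C", "2E", "2F", "2G", "3A", "3B", "3C", "4B", "5B")

PRINTED = {
    "bangladesh_zinc_rice_2023": {
        "1A": 7_244, "1B": 11_641_645, "1C": 30, "1D": 349_249, "1E": 146_708,
        "1F": 1.4, "1G": 10_001, "1H": 17_245,
        "2B": 574_829, "2C": 5.6, "2D": 3_219_045,
        "2E": 2, "2F": 13, "2G": 4, "2H": 2_640_819,
        "3A": 187, "3B": 2_552_319, "3C": 2.8, "3D": 7_146_493, "3E": 1_336_394,
        "4A": 1_304_425, "4B.1": 247, "4B.2": 123,
        "4C.1": 5_283_212, "4C.2": 10_566_423,
        "5A.1": 12_429_705, "5A.2": 17_712_916, "5B": 171_466_990,
        "5C.1": 7, "5C.2": 10,
        "4B": 247,
    },
    "pakistan_zinc_wheat_2023": {
        "1A": 179_486, "1B": 9_032_688, "1C": 120, "1D": 1_083_923, "1E": 511_379,
        "1F": 1.1, "1G": 200_954, "1H": 380_440,
        "2B": 3_170_332, "2C": 3.5, "2D": 11_096_161,
        "2E": 4, "2F": 2, "2G": 4, "2H": 9_980_420,
        "3A": 103, "3B": 3_276_066, "3C": 6.3, "3D": 20_639_216, "3E": 2_125_839,
        "4A": 7_854_581, "4B.1": 103, "4B.2": 52,
        "4C.1": 76_258_065, "4C.2": 152_516_129,
        "5A.1": 96_897_280, "5A.2": 173_155_345, "5B": 247_504_495,
        "5C.1": 39, "5C.2": 70,
        "4B": 103,
    },
    "nigeria_vita_maize_2023": {
        "1A": 13_282, "1B": 5_700_000, "1C": 20, "1D": 114_000, "1E": 60_000,
        "1F": 0.9, "1G": 11_954, "1H": 25_236,
        "2B": 1_261_790, "2C": 1.5, "2D": 1_892_685,
        "2E": 1, "2F": 36, "2G": 5, "2H": 1_095_556,
        "3A": 20, "3B": 1_962_832, "3C": 9.1, "3D": 17_861_771, "3E": 357_235,
        "4A": 738_321, "4B.1": 31, "4B.2": 15,
        "4C.1": 23_893_871, "4C.2": 47_787_742,
        "5A.1": 41_755_642, "5A.2": 65_649_513, "5B": 227_882_945,
        "5C.1": 18, "5C.2": 29,
        "4B": 31,
    },
    "nigeria_vita_cassava_2023": {
        "1A": 4_845_831, "1B": 9_878_773, "1C": 60, "1D": 592_726_380, "1E": 79_820_000,
        "1F": 6.4, "1G": 31_138_282, "1H": 35_984_113,
        "2B": 599_735, "2C": 8.7, "2D": 5_188_801,
        "2E": 0, "2F": 20, "2G": 18, "2H": 3_196_561,
        "3A": 89, "3B": 2_236_726, "3C": 5.6, "3D": 12_525_666, "3E": 1_114_784,
        "4A": 2_081_777, "4B.1": 162, "4B.2": 81,
        "4C.1": 12_882_281, "4C.2": 25_764_563,
        "5A.1": 25_407_947, "5A.2": 38_290_228, "5B": 227_882_945,
        "5C.1": 11, "5C.2": 17,
        "4B": 162,
    },
}

# Note: the published cassava FSS ratio row prints "6.0" although the working
# value implied by the same column's own 1D/1E cells is ~6.43; the rendered
# ratio is therefore excluded from golden comparisons (its downstream cells
# 1G/1H are compared instead, and match).


@pytest.fixture(scope="session")
def catalog():
    return load_catalog()


@pytest.fixture(scope="session")
def results(catalog):
    from bioreach import run_pipeline

    return {name: run_pipeline(cfg) for name, cfg in catalog.items()}


# ---------------------------------------------------------------------------
# Independent oracle: a straight-line worksheet recomputation that shares no
# code with the engine (plain arithmetic on the raw parameter values).
# ---------------------------------------------------------------------------


def worksheet_recompute(cfg) -> dict[str, float]:
    def val(pid):
        p = cfg.parameters[pid]
        return p.value if p.value_precise is None else p.value_precise

    def frac(pid):
        p = cfg.parameters[pid]
        v = p.value if p.value_precise is None else p.value_precise
        return v / 100.0 if p.unit == "percent" else v

    mass_rate = cfg.parameters["1C"].unit == "kg_per_ha"
    to_stock = 1e-3 if mass_rate else 1.0  # kg -> MT for mass crops
    out = {}
    out["1D"] = val("1B") * val("1C") * to_stock
    out["1F"] = max(0.0, (out["1D"] - val("1E")) / val("1E"))
    out["1G"] = val("1A") * out["1F"]
    out["1H"] = val("1A") + out["1G"]
    out["2B"] = out["1H"] / to_stock / val("1C")
    out["2D"] = out["2B"] * val("2C")
    out["2H"] = out["2D"] * (1.0 - frac("2E") - frac("2F") - frac("2G"))
    out["3D"] = val("3B") * val("3C")
    out["3E"] = out["3D"] * val("3A") / 1000.0
    out["4A"] = max(0.0, out["2H"] - out["3E"])
    for i, sc in enumerate(cfg.scenarios, start=1):
        intake = sc.replacement_fraction * val("4B")
        out[f"4B.{i}"] = intake
        out[f"4C.{i}"] = out["4A"] * 1000.0 / intake
        out[f"5A.{i}"] = out["3D"] + out[f"4C.{i}"]
        out[f"5C.{i}"] = 100.0 * out[f"5A.{i}"] / val("5B")
    return out
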