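"""Provenance-tagged parameter sets and their validation and I/O.

A country-crop-year configuration is a YAML/JSON document keyed by the
calculation's parameter IDs ("1A" commercial biofortified seed produced,
"1B" total area harvested, ... "5B" national population) plus metadata and
the off-farm replacement scenarios.  Each parameter carries a value, a unit
from the closed unit vocabulary, optional provenance (source type, citation,
year) and an optional high-precision override ``value_precise``.

The override exists because published worked examples typically print
rounded inputs (whole-percent food-balance deductions, integer per-capita
intakes) while the underlying arithmetic used unrounded source values;
storing both keeps the printed table reproducible without losing the
working precision.

Validation is total: any file parses either into a valid config or into a
:class:`~bioreach.errors.ConfigValidationError` carrying *every* violation,
each naming the offending parameter ID.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .errors import ConfigValidationError
from .units import RATE_NUMERATOR, UNITS

#: Parameter IDs that must be present (3B may instead come from grower inputs).
REQUIRED_IDS = ("1A", "1B", "1C", "1E", "2C", "2E", "2F", "2G", "3A", "3C", "4B", "5B")

#: IDs holding deduction shares of the harvest.
FRACTION_IDS = ("2E", "2F", "2G")

#: IDs that must be strictly positive for the arithmetic to be defined.
POSITIVE_IDS = ("1B", "1C", "1E", "2C", "3A", "3C", "4B", "5B")

_EXPECTED_UNIT_FAMILY = {
    "1A": {"kg", "MT", "bundles"},
    "1B": {"ha"},
    "1C": set(RATE_NUMERATOR),
    "1E": {"kg", "MT", "bundles"},
    "2C": {"MT_per_ha"},
    "2E": {"fraction", "percent"},
    "2F": {"fraction", "percent"},
    "2G": {"fraction", "percent"},
    "3A": {"kg_per_person_year"},
    "3B": {"households"},
    "3C": {"persons"},
    "4B": {"kg_per_person_year"},
    "5B": {"persons"},
}


class Provenance(BaseModel):
    model_config = ConfigDict(extra="forbid")

    source_type: Literal["primary_survey", "faostat", "census", "publication", "worldbank"]
    citation: str = ""
    year: Optional[int] = None


class Parameter(BaseModel):
    model_config = ConfigDict(extra="forbid")

    value: float
    unit: str
    value_precise: Optional[float] = None
    provenance: Optional[Provenance] = None

    @property
    def effective(self) -> float:
        """The value the engine computes with (precise override if present)."""
        return self.value if self.value_precise is None else self.value_precise


class Scenario(BaseModel):
    model_config = ConfigDict(extra="forbid")

    label: str
    replacement_fraction: float = Field(gt=0.0, le=1.0)


#: The two conventional off-farm scenarios, available as presets.
DEFAULT_SCENARIOS = (
    Scenario(label="full replacement", replacement_fraction=1.0),
    Scenario(label="half replacement", replacement_fraction=0.5),
)


class GrowerInputs(BaseModel):
    """Inputs for deriving 3B from seed distribution instead of supplying it."""

    model_config = ConfigDict(extra="forbid")

    acquirers_by_year: dict[int, float]
    diffusion_rate: float = 0.0
    attrition_rate: float = 0.0


class Metadata(BaseModel):
    model_config = ConfigDict(extra="forbid")

    country: str
    crop: str
    nutrient: str
    year: int


class CountryCropConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    metadata: Metadata
    parameters: dict[str, Parameter]
    scenarios: list[Scenario] = Field(default_factory=lambda: list(DEFAULT_SCENARIOS))
    grower_model: Optional[GrowerInputs] = None
    # Reserved for a future trade adjustment; currently unused by the engine.
    imports: Optional[Parameter] = None
    exports: Optional[Parameter] = None

    def effective(self, pid: str) -> float:
        return self.parameters[pid].effective

    def fraction(self, pid: str) -> float:
        """Deduction parameter as a plain fraction regardless of stored unit."""
        p = self.parameters[pid]
        return p.effective / 100.0 if p.unit == "percent" else p.effective

    def unit(self, pid: str) -> str:
        return self.parameters[pid].unit

    @property
    def name(self) -> str:
        m = self.metadata
        return f"{m.country} {m.nutrient} {m.crop} {m.year}"


def validate_config(cfg: CountryCropConfig) -> list[str]:
    """All schema violations for an already-parsed config (empty if valid)."""
    v: list[str] = []
    params = cfg.parameters
    for pid in REQUIRED_IDS:
        if pid not in params:
            v.append(f"{pid}: required parameter is missing")
    if "3B" not in params and cfg.grower_model is None:
        v.append("3B: missing and no grower_model inputs were supplied to derive it")
    for pid, p in params.items():
        if p.unit not in UNITS:
            v.append(f"{pid}: unknown unit {p.unit!r}")
            continue
        expected = _EXPECTED_UNIT_FAMILY.get(pid)
        if expected and p.unit not in expected:
            v.append(f"{pid}: unit {p.unit!r} not in expected set {sorted(expected)}")
        for label, val in (("value", p.value), ("value_precise", p.value_precise)):
            if val is not None and not (val >= 0):
                v.append(f"{pid}: {label} must be non-negative, got {val!r}")
    for pid in POSITIVE_IDS:
        if pid in params and not (params[pid].effective > 0):
            v.append(f"{pid}: must be strictly positive, got {params[pid].effective!r}")
    fracs = {}
    for pid in FRACTION_IDS:
        if pid in params:
            f = cfg.fraction(pid)
            fracs[pid] = f
            if not (0.0 <= f < 1.0):
                v.append(f"{pid}: deduction must lie in [0, 1), got fraction {f!r}")
    if len(fracs) == len(FRACTION_IDS) and sum(fracs.values()) >= 1.0:
        v.append(
            "2E+2F+2G: deduction fractions sum to "
            f"{sum(fracs.values()):.4f}, leaving no edible supply"
        )
    if "1A" in params and "1E" in params:
        ua, ue = params["1A"].unit, params["1E"].unit
        mass = {"kg", "MT"}
        if (ua in mass) != (ue in mass):
            v.append(f"1A/1E: incompatible seed units {ua!r} vs {ue!r}")
    if "1C" in params and "1E" in params and params["1C"].unit in RATE_NUMERATOR:
        num = RATE_NUMERATOR[params["1C"].unit]
        if (num == "bundles") != (params["1E"].unit == "bundles"):
            v.append(
                f"1C/1E: seed rate numerator {num!r} incompatible with "
                f"seed stock unit {params['1E'].unit!r}"
            )
    if not cfg.scenarios:
        v.append("scenarios: at least one replacement scenario is required")
    if cfg.grower_model is not None and not cfg.grower_model.acquirers_by_year:
        v.append("grower_model: acquirers_by_year is empty")
    return v


def _pydantic_violations(err: ValidationError) -> list[str]:
    out = []
    for e in err.errors():
        loc = ".".join(str(part) for part in e["loc"]) or "<root>"
        out.append(f"{loc}: {e['msg']}")
    return out


def config_from_dict(data: dict) -> CountryCropConfig:
    """Parse and fully validate a config mapping, raising with all violations."""
    try:
        cfg = CountryCropConfig.model_validate(data)
    except ValidationError as err:
        raise ConfigValidationError(_pydantic_violations(err)) from None
    violations = validate_config(cfg)
    if violations:
        raise ConfigValidationError(violations)
    return cfg


def load_config(path: str | Path) -> CountryCropConfig:
    """Load a YAML or JSON configuration file and validate it."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigValidationError([f"{path.name}: expected a mapping at the top level"])
    return config_from_dict(data)


def write_results(result, path: str | Path, format: str = "json") -> Path:
    """Serialize a pipeline result.

    ``json`` round-trips bit-exactly (floats are serialized at full repr
    precision); ``csv`` writes one row per parameter ID with value and unit.
    """
    path = Path(path)
    doc = result.to_dict()
    if format == "json":
        path.write_text(json.dumps(doc, indent=2, sort_keys=False) + "\n")
    elif format == "csv":
        import pandas as pd

        rows = [
            {"id": pid, "value": doc["values"][pid], "unit": doc["units"].get(pid, "")}
            for pid in doc["values"]
        ]
        pd.DataFrame(rows).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown results format {format!r} (expected 'json' or 'csv')")
    return path


def read_results(path: str | Path) -> dict:
    """Read back a JSON results document written by :func:`write_results`."""
    return json.loads(Path(path).read_text())
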