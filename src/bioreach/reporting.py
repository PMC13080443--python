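"""Rendered result tables and one-at-a-time sensitivity analysis."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .config import CountryCropConfig
from .errors import BioreachError, ConfigValidationError
from .model import PipelineResult, run_pipeline

#: Row order and labels for the rendered results table (one row per
#: parameter ID, two scenario slots for the phase 4/5 scenario parameters).
ROW_LABELS: tuple[tuple[str, str], ...] = (
    ("1A", "Biofortified seed produced (MT or bundles)"),
    ("1B", "Total area harvested (ha)"),
    ("1C", "Seed rate (kg or bundles/ha)"),
    ("1D", "Total quantity of seed used (MT or bundles)"),
    ("1E", "Total seed produced (MT or bundles)"),
    ("1F", "Ratio farm-saved seed / total seed produced"),
    ("1G", "Farm-saved biofortified seed (MT or bundles)"),
    ("1H", "Total biofortified seed used (MT or bundles)"),
    ("2A", "Seed rate (kg or bundles/ha)"),
    ("2B", "Area planted with biofortified crop (ha)"),
    ("2C", "Yield (MT/ha)"),
    ("2D", "Production of the biofortified crop (MT)"),
    ("2E", "Farm-saved seed deduction (fraction)"),
    ("2F", "Animal feed deduction (fraction)"),
    ("2G", "Post-harvest losses (fraction)"),
    ("2H", "Edible supply available for consumption (MT)"),
    ("3A", "Annual per-capita on-farm intake (kg)"),
    ("3B", "Farming households (#)"),
    ("3C", "Farming household size (#)"),
    ("3D", "Farming population (#)"),
    ("3E", "On-farm consumption (MT)"),
    ("4A", "Off-farm consumption (MT)"),
    ("4B.1", "Off-farm per-capita intake, scenario 1 (kg)"),
    ("4B.2", "Off-farm per-capita intake, scenario 2 (kg)"),
    ("4C.1", "Population consuming off-farm, scenario 1 (#)"),
    ("4C.2", "Population consuming off-farm, scenario 2 (#)"),
    ("5A.1", "Reach, scenario 1 (#)"),
    ("5A.2", "Reach, scenario 2 (#)"),
    ("5B", "Population of the country (#)"),
    ("5C.1", "Coverage, scenario 1 (%)"),
    ("5C.2", "Coverage, scenario 2 (%)"),
)


def results_frame(results: Sequence[PipelineResult]) -> pd.DataFrame:
    """One column per country-crop run, one row per parameter ID, values
    rounded per the reporting policy."""
    ids = [pid for pid, _ in ROW_LABELS]
    labels = {pid: label for pid, label in ROW_LABELS}
    columns = {}
    for res in results:
        m = res.metadata
        col = f"{m['country']} {m['crop']} {m['year']}"
        rounded = res.rounded()
        columns[col] = [rounded.get(pid, float("nan")) for pid in ids]
    frame = pd.DataFrame(columns, index=[f"{pid}  {labels[pid]}" for pid in ids])
    frame.index.name = "parameter"
    return frame


def render_table(results: Sequence[PipelineResult], format: str = "text") -> str:
    """Render results for one or more runs as text or CSV.

    Empty input produces a header-only table.
    """
    frame = results_frame(results)
    if format == "csv":
        return frame.to_csv()
    if not results:
        return frame.index.name + "\n"

    def fmt(v: float) -> str:
        if isinstance(v, float) and math.isnan(v):
            return ""
        if v == int(v):
            return f"{int(v):,}"
        return f"{v:,.3f}".rstrip("0").rstrip(".")

    return frame.map(fmt).to_string()


@dataclass
class SensitivityRow:
    """Effect of perturbing one input parameter by ``perturbation_pct``.

    ``elasticity`` maps output keys (farming population "3D", per-scenario
    reach "5A.<i>" and coverage "5C.<i>") to %-change in output per %-change
    in input; ``violations`` is non-empty when the perturbed config is
    invalid (reported, never raised).
    """

    parameter_id: str
    perturbation_pct: float
    baseline: dict[str, float] = field(default_factory=dict)
    perturbed: dict[str, float] = field(default_factory=dict)
    elasticity: dict[str, float] = field(default_factory=dict)
    violations: list[str] = field(default_factory=list)


_SENSITIVITY_OUTPUTS = ("3D", "4A") + tuple(
    f"{p}.{i}" for p in ("4C", "5A", "5C") for i in (1, 2)
)


def sensitivity(
    cfg: CountryCropConfig, parameter_id: str, perturbation_pct: float
) -> SensitivityRow:
    """Deterministic one-at-a-time sensitivity: re-run the pipeline with the
    parameter scaled by (1 + p/100) and report finite-difference
    elasticities of the downstream outputs."""
    if parameter_id not in cfg.parameters:
        return SensitivityRow(
            parameter_id,
            perturbation_pct,
            violations=[f"{parameter_id}: no such parameter in the configuration"],
        )
    row = SensitivityRow(parameter_id, perturbation_pct)
    base = run_pipeline(cfg)
    scale = 1.0 + perturbation_pct / 100.0
    perturbed_cfg = cfg.model_copy(deep=True)
    p = perturbed_cfg.parameters[parameter_id]
    p.value *= scale
    if p.value_precise is not None:
        p.value_precise *= scale
    try:
        pert = run_pipeline(perturbed_cfg)
    except ConfigValidationError as err:
        row.violations = err.violations
        return row
    except BioreachError as err:
        row.violations = [str(err)]
        return row
    keys = [k for k in _SENSITIVITY_OUTPUTS if k in base.values]
    row.baseline = {k: base.values[k] for k in keys}
    row.perturbed = {k: pert.values[k] for k in keys}
    for k in keys:
        b = base.values[k]
        if b == 0 or perturbation_pct == 0:
            row.elasticity[k] = 0.0
        else:
            row.elasticity[k] = ((pert.values[k] - b) / b) / (perturbation_pct / 100.0)
    return row
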