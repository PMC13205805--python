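"""YAML configuration loading.

A config file may define any of the sections below; omitted sections fall
back to package defaults::

    generator:            # GeneratorSpec fields
      n_patients: 12
      target_mean_red_es: 0.179
      target_mean_red_pl: 0.051
      strata:
        - ["10-18", "deep", 5]
        - [">=19", "deep", 7]
    healing_table:        # {depth: {category: median_days}}
      deep: {"<=9": 26, "10-18": 63, ">=19": 259}
      superficial: {"<=9": 15, "10-18": 33, ">=19": 140}
    costs:                # CostParameters fields
      device_cost: 77000
      cases_per_device: 12
    translation:          # TranslationSpec fields
      mode: constant_ratio
      r: 3.52
    scenarios:            # list of ScenarioSpec fields
      - {name: value_8000, per_day_value: 8000}
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import yaml

from .cohort import GeneratorSpec
from .costs import CostParameters
from .exceptions import ConfigurationError
from .healing import HealingTimeTable, TranslationSpec
from .scenarios import ScenarioSpec


@dataclass
class Config:
    generator: GeneratorSpec
    healing_table: HealingTimeTable
    costs: CostParameters
    translation: TranslationSpec
    scenarios: Optional[list[ScenarioSpec]] = None


def load_config(path: str | Path | None = None) -> Config:
    """Load a YAML config; ``None`` returns the package defaults."""
    raw = {}
    if path is not None:
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("config root must be a mapping")
    try:
        generator = GeneratorSpec(**raw.get("generator", {}))
        table = (
            HealingTimeTable.from_mapping(raw["healing_table"])
            if "healing_table" in raw
            else HealingTimeTable()
        )
        costs = CostParameters.from_mapping(raw.get("costs", {}))
        translation = TranslationSpec(**raw.get("translation", {}))
        scenarios = None
        if "scenarios" in raw:
            scenarios = [ScenarioSpec(**entry) for entry in raw["scenarios"]]
    except TypeError as exc:
        raise ConfigurationError(f"invalid config field: {exc}") from exc
    return Config(
        generator=generator,
        healing_table=table,
        costs=costs,
        translation=translation,
        scenarios=scenarios,
    )
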