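"""Declarative sensitivity and structural scenario grid.

The prespecified analyses — one-way sweeps of the per-day monetary value,
+/-20% variation of the acceleration ratio, median-based / trimmed-ratio
translations, the conservative diminishing-acceleration rule, +/-20% and
+/-30% baseline healing-time variation, and a depth-unstratified structural
variant — are expressed as :class:`ScenarioSpec` records and executed by
:func:`run_scenario`, which applies the multipliers and delegates to the
per-case / per-stratum projection chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort
from .costs import (
    CaseProjection,
    CostParameters,
    project_case,
    project_strata,
)
from .effects import ratio_summary
from .exceptions import DependencyError, ValidationError
from .healing import HealingTimeTable, TranslationSpec, mean_baseline

#: Base-case healing acceleration ratio carried as a configurable constant.
#: The cohort-mean ratio from the calibrated summary means (0.179/0.051) is
#: 3.51; the base case uses the value obtained from unrounded patient-level
#: means, 3.52.
BASE_CASE_R = 3.52

RATIO_SOURCES = ("base_case_constant", "mean", "median_based", "trimmed", "explicit")


@dataclass
class ScenarioSpec:
    """One row of the scenario grid."""

    name: str
    per_day_value: float = 4000.0
    ratio_source: str = "base_case_constant"
    ratio_value: Optional[float] = None  # required when ratio_source="explicit"
    ratio_multiplier: float = 1.0
    baseline_multiplier: float = 1.0
    translation_mode: str = "constant_ratio"
    kappa: float = 0.5
    accel_window_days: float = 14.0
    depth_stratified: bool = False
    alternative_table: Optional[HealingTimeTable] = None

    def __post_init__(self) -> None:
        if self.ratio_source not in RATIO_SOURCES:
            raise ValidationError(f"unknown ratio_source {self.ratio_source!r}")
        if self.ratio_source == "explicit" and self.ratio_value is None:
            raise ValidationError("explicit ratio_source needs ratio_value")
        if self.ratio_multiplier <= 0 or self.baseline_multiplier <= 0:
            raise ValidationError("multipliers must be > 0")
        if self.per_day_value < 0:
            raise ValidationError("per_day_value must be >= 0")


@dataclass
class ScenarioResult:
    name: str
    r_used: float
    projection: CaseProjection
    strata: Optional[list[CaseProjection]] = None

    def to_row(self) -> dict:
        row = {"scenario": self.name, "r": round(self.r_used, 4)}
        row.update(
            {k: v for k, v in self.projection.rounded().items() if k != "label"}
        )
        return row


def resolve_ratio(
    spec: ScenarioSpec,
    cohort: Cohort | None = None,
    r_draws: np.ndarray | None = None,
) -> float:
    """Acceleration ratio implied by the scenario's ratio_source."""
    if spec.ratio_source == "base_case_constant":
        r = BASE_CASE_R
    elif spec.ratio_source == "explicit":
        r = float(spec.ratio_value)
    elif spec.ratio_source in ("mean", "median_based"):
        if cohort is None:
            raise DependencyError(
                f"ratio_source {spec.ratio_source!r} needs a cohort"
            )
        r = ratio_summary(cohort, method=spec.ratio_source)
    else:  # trimmed
        if r_draws is None:
            raise DependencyError(
                "trimmed ratio_source needs bootstrap r draws; run the "
                "uncertainty engine first"
            )
        from .bootstrap import trimmed_ratio

        r = trimmed_ratio(np.asarray(r_draws))
    return r * spec.ratio_multiplier


def run_scenario(
    cohort: Cohort,
    table: HealingTimeTable | None = None,
    spec: ScenarioSpec | None = None,
    params: CostParameters | None = None,
    r_draws: np.ndarray | None = None,
) -> ScenarioResult:
    """Execute one scenario: resolve r, scale the table, project.

    Pure: identical inputs give identical outputs; nothing is cached between
    scenarios.
    """
    spec = spec or ScenarioSpec(name="base_case")
    table = spec.alternative_table or table or HealingTimeTable()
    if spec.baseline_multiplier != 1.0:
        table = table.scaled(spec.baseline_multiplier)
    params = params or CostParameters()
    r = resolve_ratio(spec, cohort, r_draws)
    translation = TranslationSpec(
        mode=spec.translation_mode,
        r=r,
        kappa=spec.kappa,
        accel_window_days=spec.accel_window_days,
    )
    projection = project_case(
        mean_baseline(cohort, table),
        translation,
        params,
        per_day_value=spec.per_day_value,
        label=spec.name,
        n=len(cohort),
    )
    strata = None
    if spec.depth_stratified:
        strata = project_strata(
            cohort, table, translation, params, per_day_value=spec.per_day_value
        )
    return ScenarioResult(name=spec.name, r_used=r, projection=projection, strata=strata)


def run_scenarios(
    cohort: Cohort,
    specs: Sequence[ScenarioSpec],
    table: HealingTimeTable | None = None,
    params: CostParameters | None = None,
    r_draws: np.ndarray | None = None,
) -> pd.DataFrame:
    """Run a scenario list and collect one summary row per scenario."""
    results = [run_scenario(cohort, table, s, params, r_draws) for s in specs]
    return pd.DataFrame([r.to_row() for r in results])


def one_way_value_grid(
    t_placebo: float,
    translation: TranslationSpec,
    params: CostParameters | None = None,
    values: Sequence[float] = (3000.0, 5000.0, 7000.0, 8000.0, 9000.0, 10_000.0),
) -> pd.DataFrame:
    """One-way sensitivity of gross offset and net impact to the per-day value.

    Gross offset is exactly proportional to the value; net impact is affine
    in it (the implementation cost does not depend on the valuation).
    """
    if len(values) == 0:
        raise ValidationError("values must be non-empty")
    params = params or CostParameters()
    rows = []
    for value in values:
        proj = project_case(t_placebo, translation, params, per_day_value=value)
        rows.append(
            {
                "per_day_value": value,
                "days_saved": proj.days_saved,
                "gross_offset": proj.gross_offset,
                "impl_total": proj.impl_total,
                "net_impact": proj.net_impact,
            }
        )
    return pd.DataFrame(rows)


def baseline_sweep(
    cohort: Cohort,
    table: HealingTimeTable | None = None,
    translation: TranslationSpec | None = None,
    params: CostParameters | None = None,
    multipliers: Sequence[float] = (0.7, 0.8, 1.0, 1.2, 1.3),
    per_day_value: float | None = None,
) -> pd.DataFrame:
    """Scale every baseline median by each multiplier and re-project.

    Under constant-ratio translation, days saved and gross offset scale
    exactly by the multiplier; net impact does not (its fixed implementation
    component is invariant).
    """
    table = table or HealingTimeTable()
    translation = translation or TranslationSpec()
    params = params or CostParameters()
    rows = []
    for k in multipliers:
        proj = project_case(
            mean_baseline(cohort, table.scaled(k)),
            translation,
            params,
            per_day_value=per_day_value,
        )
        rows.append(
            {
                "baseline_multiplier": k,
                "t_placebo": proj.t_placebo,
                "t_es": proj.t_es,
                "days_saved": proj.days_saved,
                "gross_offset": proj.gross_offset,
                "net_impact": proj.net_impact,
            }
        )
    return pd.DataFrame(rows)


def illustrative_unstratified_table() -> HealingTimeTable:
    """Synthetic depth-pooled table for the no-depth-stratification variant.

    The published medians are depth-specific and no pooled medians are
    available, so this illustrative stand-in applies the deep-wound medians
    to both depth classes (every trial wound was deep).  It is a labelled
    substitute, not published data.
    """
    deep = {
        ("deep", c): HealingTimeTable().lookup("deep", c)
        for c in ("<=9", "10-18", ">=19")
    }
    pooled = dict(deep)
    pooled.update({("superficial", c): v for (_, c), v in deep.items()})
    return HealingTimeTable(pooled)


def prespecified_scenarios() -> list[ScenarioSpec]:
    """The bundled preset of prespecified sensitivity analyses."""
    specs = [ScenarioSpec(name="base_case", depth_stratified=True)]
    specs += [
        ScenarioSpec(name=f"value_{int(v)}", per_day_value=v)
        for v in (3000.0, 5000.0, 7000.0, 8000.0, 9000.0, 10_000.0)
    ]
    specs += [
        ScenarioSpec(name="ratio_minus_20pct", ratio_multiplier=0.8),
        ScenarioSpec(name="ratio_plus_20pct", ratio_multiplier=1.2),
        ScenarioSpec(name="ratio_median_based", ratio_source="median_based"),
        ScenarioSpec(name="ratio_trimmed", ratio_source="trimmed"),
        ScenarioSpec(name="diminishing_acceleration", translation_mode="diminishing"),
    ]
    specs += [
        ScenarioSpec(name=f"baseline_x{k}", baseline_multiplier=k)
        for k in (0.7, 0.8, 1.2, 1.3)
    ]
    specs.append(
        ScenarioSpec(
            name="no_depth_stratification",
            alternative_table=illustrative_unstratified_table(),
        )
    )
    return specs
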