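"""Monetary valuation: per-day value proxy, implementation costs, net impact,
break-even thresholds, and per-case / per-stratum projections.

All monetary quantities are Japanese yen (JPY), nominal, from the provider
(ward/facility) perspective.  Days saved are valued with a per-day
healing-related monetary value proxy (default JPY 4000/day: wound procedures
1000 + labor 1500 + support surfaces 500 + nutrition 1000).  Implementation
cost of electrical stimulation comprises a fixed per-case component (device
allocation across cases plus single-use consumables) and a variable labor
component accruing every day of the estimated ES healing period.

Full precision is kept internally; monetary outputs are rounded to whole JPY
(half away from zero) only at reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Optional

import numpy as np
import pandas as pd

from .cohort import Cohort, DEPTHS
from .exceptions import ValidationError
from .healing import (
    CATEGORIES,
    HealingTimeTable,
    TranslationSpec,
    category_of,
    days_saved,
    translate_time,
)

DEFAULT_PER_DAY_COMPONENTS: dict[str, float] = {
    "procedures": 1000.0,
    "labor": 1500.0,
    "support_surface": 500.0,
    "nutrition": 1000.0,
}


def round_jpy(x: float) -> int:
    """Round to whole JPY, half away from zero (reporting convention)."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


@dataclass
class CostParameters:
    """Unit costs for valuation and ES delivery.

    ``per_day_value`` is derived as the sum of ``per_day_components``; the ES
    incremental labor rate is ``es_staff_minutes_per_day * wage_per_minute``
    (defaults 15 min/day x JPY 50/min = JPY 750/day).
    """

    per_day_components: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PER_DAY_COMPONENTS)
    )
    device_cost: float = 77_000.0
    cases_per_device: int = 12
    consumables_per_case: float = 3_600.0
    es_staff_minutes_per_day: float = 15.0
    wage_per_minute: float = 50.0

    def __post_init__(self) -> None:
        for name, value in self.per_day_components.items():
            if value < 0:
                raise ValidationError(f"per-day component {name!r} must be >= 0")
        for name in (
            "device_cost",
            "consumables_per_case",
            "es_staff_minutes_per_day",
            "wage_per_minute",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.cases_per_device < 1:
            raise ValidationError("cases_per_device must be >= 1")

    @property
    def per_day_value(self) -> float:
        """Healing-related monetary value proxy (JPY/day)."""
        return float(sum(self.per_day_components.values()))

    @property
    def es_labor_per_day(self) -> float:
        """Incremental ES delivery labor (JPY/day)."""
        return self.es_staff_minutes_per_day * self.wage_per_minute

    @property
    def impl_fixed_per_case(self) -> float:
        """Device allocation (rounded to whole JPY) plus consumables."""
        return round_jpy(self.device_cost / self.cases_per_device) + (
            self.consumables_per_case
        )

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "CostParameters":
        kwargs = dict(mapping)
        if "per_day_components" in kwargs:
            kwargs["per_day_components"] = {
                str(k): float(v) for k, v in kwargs["per_day_components"].items()
            }
        return cls(**kwargs)


def gross_offset(days_saved_value: float, per_day_value: float) -> float:
    """Gross monetary value offset (JPY/case) = days saved x per-day value.

    Negative days saved pass through to a negative offset (not clipped), so
    downside scenarios remain visible.
    """
    if per_day_value < 0:
        raise ValidationError("per_day_value must be >= 0")
    return days_saved_value * per_day_value


class ImplementationCost(NamedTuple):
    fixed: float
    variable: float
    total: float
    per_day: float


def implementation_cost(t_es: float, params: CostParameters) -> ImplementationCost:
    """ES implementation cost over the estimated ES healing period.

    fixed   = round(device_cost / cases_per_device) + consumables_per_case
    variable = es labor per day x t_es
    per_day = fixed / t_es + es labor per day  (amortized average)
    """
    if t_es <= 0:
        raise ValidationError("t_es must be > 0 (per-day amortization undefined)")
    fixed = params.impl_fixed_per_case
    variable = params.es_labor_per_day * t_es
    total = fixed + variable
    per_day = fixed / t_es + params.es_labor_per_day
    return ImplementationCost(fixed, variable, total, per_day)


def net_impact(gross: float, impl_total: float) -> float:
    """Net financial impact (JPY/case) = gross offset - implementation cost."""
    return gross - impl_total


def break_even_per_day(
    t_placebo: float, t_es: float, per_day_value: float
) -> float:
    """Maximum average implementation cost per ES day with non-negative net.

    ``per_day_value * (t_placebo - t_es) / t_es``; under constant-ratio
    translation this equals ``per_day_value * (r - 1)``.
    """
    if t_es <= 0:
        raise ValidationError("t_es must be > 0")
    if per_day_value < 0:
        raise ValidationError("per_day_value must be >= 0")
    return per_day_value * (t_placebo - t_es) / t_es


@dataclass
class CaseProjection:
    """Per-case (or per-stratum) modeled healing-time and monetary outcomes."""

    t_placebo: float
    t_es: float
    days_saved: float
    gross_offset: float
    impl_fixed: float
    impl_variable: float
    impl_total: float
    c_impl_per_day: float
    net_impact: float
    break_even_per_day: float
    label: Optional[str] = None
    n: Optional[int] = None

    def rounded(self) -> dict:
        """Reporting view: days to 1 decimal, money to whole JPY."""
        out = {
            "t_placebo": round(self.t_placebo, 1),
            "t_es": round(self.t_es, 1),
            "days_saved": round(self.days_saved, 1),
            "gross_offset": round_jpy(self.gross_offset),
            "impl_total": round_jpy(self.impl_total),
            "c_impl_per_day": round_jpy(self.c_impl_per_day),
            "net_impact": round_jpy(self.net_impact),
            "break_even_per_day": round_jpy(self.break_even_per_day),
        }
        if self.label is not None:
            out = {"label": self.label, **out}
        if self.n is not None:
            out["n"] = self.n
        return out

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "n": self.n,
            "t_placebo": self.t_placebo,
            "t_es": self.t_es,
            "days_saved": self.days_saved,
            "gross_offset": self.gross_offset,
            "impl_fixed": self.impl_fixed,
            "impl_variable": self.impl_variable,
            "impl_total": self.impl_total,
            "c_impl_per_day": self.c_impl_per_day,
            "net_impact": self.net_impact,
            "break_even_per_day": self.break_even_per_day,
        }


def project_case(
    t_placebo: float,
    spec: TranslationSpec,
    params: CostParameters | None = None,
    per_day_value: float | None = None,
    label: str | None = None,
    n: int | None = None,
) -> CaseProjection:
    """Full per-case projection: translation, valuation, costs, thresholds."""
    params = params or CostParameters()
    value = params.per_day_value if per_day_value is None else per_day_value
    t_es = translate_time(t_placebo, spec)
    saved = days_saved(t_placebo, t_es)
    gross = gross_offset(saved, value)
    impl = implementation_cost(t_es, params)
    return CaseProjection(
        t_placebo=t_placebo,
        t_es=t_es,
        days_saved=saved,
        gross_offset=gross,
        impl_fixed=impl.fixed,
        impl_variable=impl.variable,
        impl_total=impl.total,
        c_impl_per_day=impl.per_day,
        net_impact=net_impact(gross, impl.total),
        break_even_per_day=break_even_per_day(t_placebo, t_es, value),
        label=label,
        n=n,
    )


def project_strata(
    cohort: Cohort,
    table: HealingTimeTable | None = None,
    spec: TranslationSpec | None = None,
    params: CostParameters | None = None,
    per_day_value: float | None = None,
) -> list[CaseProjection]:
    """One projection per occupied (depth, DESIGN-R category) stratum.

    The baseline T_placebo of each stratum is fixed to that stratum's
    published median healing time (not re-averaged over patients), so every
    patient in a stratum shares the stratum projection.
    """
    if len(cohort) == 0:
        raise ValidationError("cohort is empty")
    table = table or HealingTimeTable()
    spec = spec or TranslationSpec()
    counts: dict[tuple[str, str], int] = {}
    for rec in cohort:
        key = (rec.depth, category_of(rec.design_r_total))
        counts[key] = counts.get(key, 0) + 1
    projections = []
    for depth in DEPTHS:
        for cat in CATEGORIES:
            if (depth, cat) not in counts:
                continue
            projections.append(
                project_case(
                    table.lookup(depth, cat),
                    spec,
                    params,
                    per_day_value=per_day_value,
                    label=f"{depth}/{cat}",
                    n=counts[(depth, cat)],
                )
            )
    return projections


def strata_frame(projections: list[CaseProjection]) -> pd.DataFrame:
    """Stratum projections as a reporting table (rounded values)."""
    return pd.DataFrame([p.rounded() for p in projections])
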