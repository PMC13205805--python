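"""Severity-stratified healing-time imputation and acceleration translation.

Baseline time to heal under placebo/usual care is imputed from published
median healing times stratified by DESIGN-R total-score category (<=9, 10-18,
>=19 points) and wound depth (superficial d1-d2 vs deep D3-D5).  The
estimated time to heal under electrical stimulation is obtained by dividing
the baseline by the healing acceleration ratio r (constant-ratio rule) or,
conservatively, by letting the acceleration attenuate after the observed
treatment window (diminishing rule).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort import Cohort, DEPTHS
from .exceptions import ConfigurationError, ValidationError

CATEGORIES = ("<=9", "10-18", ">=19")

#: Published median healing days by (depth, DESIGN-R category).
DEFAULT_MEDIANS: dict[tuple[str, str], float] = {
    ("superficial", "<=9"): 15.0,
    ("superficial", "10-18"): 33.0,
    ("superficial", ">=19"): 140.0,
    ("deep", "<=9"): 26.0,
    ("deep", "10-18"): 63.0,
    ("deep", ">=19"): 259.0,
}


def category_of(design_r_total: int) -> str:
    """DESIGN-R total-score category with inclusive integer boundaries."""
    if design_r_total < 0:
        raise ValidationError("design_r_total must be >= 0")
    if design_r_total <= 9:
        return "<=9"
    if design_r_total <= 18:
        return "10-18"
    return ">=19"


@dataclass
class HealingTimeTable:
    """Depth x DESIGN-R-category matrix of median healing days.

    Within each depth the medians must be non-decreasing across categories
    (<=9 -> 10-18 -> >=19): more severe wounds do not heal faster.
    """

    entries: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_MEDIANS)
    )

    def __post_init__(self) -> None:
        for key, value in self.entries.items():
            depth, cat = key
            if depth not in DEPTHS or cat not in CATEGORIES:
                raise ConfigurationError(f"unknown table cell {key!r}")
            if not (math.isfinite(value) and value > 0):
                raise ConfigurationError(
                    f"median days for {key!r} must be > 0, got {value!r}"
                )
        for depth in DEPTHS:
            present = [
                self.entries[(depth, cat)]
                for cat in CATEGORIES
                if (depth, cat) in self.entries
            ]
            if any(b < a for a, b in zip(present, present[1:])):
                raise ConfigurationError(
                    f"median days must be non-decreasing across categories "
                    f"for depth {depth!r}"
                )

    def lookup(self, depth: str, category: str) -> float:
        try:
            return self.entries[(depth, category)]
        except KeyError:
            raise ConfigurationError(
                f"healing-time table has no entry for depth={depth!r}, "
                f"category={category!r}"
            ) from None

    def scaled(self, k: float) -> "HealingTimeTable":
        """Every median multiplied by ``k`` (baseline sensitivity sweeps)."""
        if k <= 0:
            raise ValidationError("scale factor must be > 0")
        return HealingTimeTable({key: v * k for key, v in self.entries.items()})

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"depth": d, "category": c, "median_days": v}
            for (d, c), v in sorted(self.entries.items())
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "HealingTimeTable":
        needed = {"depth", "category", "median_days"}
        if not needed.issubset(frame.columns):
            raise ConfigurationError(
                f"healing-time table needs columns {sorted(needed)}"
            )
        return cls(
            {
                (str(r["depth"]), str(r["category"])): float(r["median_days"])
                for _, r in frame.iterrows()
            }
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "HealingTimeTable":
        return cls.from_frame(pd.read_csv(path))

    @classmethod
    def from_json(cls, path: str | Path) -> "HealingTimeTable":
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        return cls(
            {
                (str(d), str(c)): float(v)
                for d, cats in raw.items()
                for c, v in cats.items()
            }
        )

    @classmethod
    def from_mapping(
        cls, mapping: Mapping[str, Mapping[str, float]]
    ) -> "HealingTimeTable":
        """Build from nested ``{depth: {category: days}}`` (config files)."""
        return cls(
            {
                (str(d), str(c)): float(v)
                for d, cats in mapping.items()
                for c, v in cats.items()
            }
        )


def impute_baseline(
    design_r_total: int, depth: str, table: HealingTimeTable | None = None
) -> float:
    """Imputed baseline time to heal (days) for one patient's stratum."""
    table = table or HealingTimeTable()
    if depth not in DEPTHS:
        raise ValidationError(f"depth must be one of {DEPTHS}, got {depth!r}")
    return table.lookup(depth, category_of(design_r_total))


def mean_baseline(cohort: Cohort, table: HealingTimeTable | None = None) -> float:
    """Arithmetic mean of per-patient imputed baseline healing times."""
    if len(cohort) == 0:
        raise ValidationError("cohort is empty; mean baseline undefined")
    table = table or HealingTimeTable()
    return float(
        np.mean([impute_baseline(r.design_r_total, r.depth, table) for r in cohort])
    )


@dataclass
class TranslationSpec:
    """How the acceleration ratio maps baseline healing time to ES time.

    ``constant_ratio``: T_ES = T_placebo / r over the whole trajectory.
    ``diminishing``: healing progress accrues at rate r per day for the first
    ``accel_window_days`` (the observed treatment window), then at the
    attenuated rate ``1 + kappa * (r - 1)``; ``kappa=1`` recovers the constant
    rule, ``kappa=0`` removes any late benefit.
    """

    mode: str = "constant_ratio"
    r: float = 3.52
    kappa: float = 0.5
    accel_window_days: float = 14.0

    def __post_init__(self) -> None:
        if self.mode not in ("constant_ratio", "diminishing"):
            raise ValidationError(f"unknown translation mode {self.mode!r}")
        if not (math.isfinite(self.r) and self.r > 0):
            raise ValidationError(f"acceleration ratio r must be > 0, got {self.r}")
        if not 0.0 <= self.kappa <= 1.0:
            raise ValidationError("kappa must lie in [0, 1]")
        if self.accel_window_days < 0:
            raise ValidationError("accel_window_days must be >= 0")


def _translate(
    t_placebo,
    r,
    mode: str = "constant_ratio",
    kappa: float = 0.5,
    accel_window_days: float = 14.0,
):
    """Vectorized core of :func:`translate_time` (accepts arrays for r/t)."""
    t = np.asarray(t_placebo, dtype=float)
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValidationError("acceleration ratio r must be > 0")
    if mode == "constant_ratio":
        return t / r
    w = accel_window_days
    r_late = 1.0 + kappa * (r - 1.0)
    # progress accrued in the accelerated window is r*w baseline-equivalent
    # days; any remainder accrues at the attenuated rate
    return np.where(t <= r * w, t / r, w + (t - r * w) / r_late)


def translate_time(t_placebo: float, spec: TranslationSpec) -> float:
    """Estimated time to heal under ES (days) for one baseline."""
    if t_placebo <= 0:
        raise ValidationError(f"t_placebo must be > 0, got {t_placebo}")
    return float(
        _translate(t_placebo, spec.r, spec.mode, spec.kappa, spec.accel_window_days)
    )


def days_saved(t_placebo: float, t_es: float) -> float:
    """Healing days saved; negative when the intervention slows healing."""
    if t_placebo <= 0 or t_es <= 0:
        raise ValidationError("healing times must be > 0")
    return t_placebo - t_es
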