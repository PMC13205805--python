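"""Patient-level nonparametric bootstrap for the full cost-consequence chain.

Each iteration resamples patients with replacement, recomputes the healing
acceleration ratio r (mean method) and the mean imputed baseline from the
resample's stratum mix, and re-runs every downstream quantity (T_ES, days
saved, gross offset, implementation cost, average implementation cost per
day, net impact).  95% uncertainty intervals are the 2.5th/97.5th
percentiles of the retained draws (linear interpolation between order
statistics, numpy's default).

Resamples whose period-mean reductions are not both positive leave r (and
hence T_ES) undefined; such draws are excluded from the percentile
computation, counted in ``n_degenerate``, and a warning is emitted when they
exceed 1% of iterations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .cohort import Cohort
from .costs import CostParameters
from .effects import period_reductions
from .exceptions import EstimationError
from .healing import (
    HealingTimeTable,
    TranslationSpec,
    _translate,
    category_of,
    impute_baseline,
)

#: Outcomes recomputed within each bootstrap iteration.
OUTCOMES = (
    "r",
    "t_placebo",
    "t_es",
    "days_saved",
    "gross_offset",
    "impl_total",
    "c_impl_per_day",
    "net_impact",
)


@dataclass
class OutcomeInterval:
    point: float
    ui_low: float
    ui_high: float


@dataclass
class BootstrapResult:
    """Point estimates and percentile uncertainty intervals per outcome."""

    n_iterations: int
    seed: Optional[int]
    n_degenerate: int
    confidence: float
    estimates: dict[str, OutcomeInterval]
    r_draws: np.ndarray = field(repr=False)

    @property
    def n_retained(self) -> int:
        return self.n_iterations - self.n_degenerate

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "outcome": name,
                "point": interval.point,
                "ui_low": interval.ui_low,
                "ui_high": interval.ui_high,
            }
            for name, interval in self.estimates.items()
        ]
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "n_iterations": self.n_iterations,
            "seed": self.seed,
            "n_degenerate": self.n_degenerate,
            "confidence": self.confidence,
            "estimates": {
                k: {"point": v.point, "ui_low": v.ui_low, "ui_high": v.ui_high}
                for k, v in self.estimates.items()
            },
        }


def _chain_outcomes(
    mean_es: np.ndarray,
    mean_pl: np.ndarray,
    baseline: np.ndarray,
    spec: TranslationSpec,
    params: CostParameters,
    per_day_value: float,
) -> dict[str, np.ndarray]:
    """Vectorized downstream model chain for arrays of period means."""
    r = mean_es / mean_pl
    t_es = _translate(baseline, r, spec.mode, spec.kappa, spec.accel_window_days)
    saved = baseline - t_es
    gross = saved * per_day_value
    fixed = params.impl_fixed_per_case
    labor = params.es_labor_per_day
    impl_total = fixed + labor * t_es
    c_per_day = fixed / t_es + labor
    net = gross - impl_total
    return {
        "r": r,
        "t_placebo": baseline,
        "t_es": t_es,
        "days_saved": saved,
        "gross_offset": gross,
        "impl_total": impl_total,
        "c_impl_per_day": c_per_day,
        "net_impact": net,
    }


def bootstrap_model(
    cohort: Cohort,
    table: HealingTimeTable | None = None,
    spec: TranslationSpec | None = None,
    params: CostParameters | None = None,
    n_iterations: int = 10_000,
    seed: int | None = None,
    per_day_value: float | None = None,
    fixed_baseline: float | None = None,
    confidence: float = 0.95,
) -> BootstrapResult:
    """Bootstrap the full model by resampling patients with replacement.

    ``fixed_baseline`` pins T_placebo to a constant (stratum analyses fix it
    to the stratum's published median); otherwise the mean baseline is
    re-imputed from each resample's stratum composition, so cohort-mix
    uncertainty propagates into the baseline.
    """
    if len(cohort) < 2:
        raise EstimationError("bootstrap needs >= 2 patients")
    if n_iterations < 1:
        raise EstimationError("n_iterations must be >= 1")
    table = table or HealingTimeTable()
    spec = spec or TranslationSpec()
    params = params or CostParameters()
    value = params.per_day_value if per_day_value is None else per_day_value

    red_es, red_pl = period_reductions(cohort)
    baselines = np.array(
        [impute_baseline(r.design_r_total, r.depth, table) for r in cohort]
    )
    n = len(cohort)

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_iterations, n))
    mean_es = red_es[idx].mean(axis=1)
    mean_pl = red_pl[idx].mean(axis=1)
    if fixed_baseline is None:
        base = baselines[idx].mean(axis=1)
    else:
        base = np.full(n_iterations, float(fixed_baseline))

    retained = (mean_es > 0) & (mean_pl > 0)
    n_degenerate = int(n_iterations - retained.sum())
    if retained.sum() == 0:
        raise EstimationError(
            "every bootstrap resample had a non-positive period mean; "
            "the acceleration ratio cannot be bootstrapped on this cohort"
        )
    if n_degenerate > 0.01 * n_iterations:
        warnings.warn(
            f"{n_degenerate}/{n_iterations} bootstrap resamples had a "
            "non-positive period-mean reduction and were excluded from the "
            "percentile computation",
            stacklevel=2,
        )

    draws = _chain_outcomes(
        mean_es[retained], mean_pl[retained], base[retained], spec, params, value
    )

    # point estimates from the full (un-resampled) cohort through the same chain
    if red_es.mean() <= 0 or red_pl.mean() <= 0:
        raise EstimationError(
            "cohort period-mean reductions must both be positive for a "
            "ratio-based point estimate"
        )
    point_base = (
        float(baselines.mean()) if fixed_baseline is None else float(fixed_baseline)
    )
    points = _chain_outcomes(
        np.array([red_es.mean()]),
        np.array([red_pl.mean()]),
        np.array([point_base]),
        spec,
        params,
        value,
    )

    alpha = 100.0 * (1.0 - confidence) / 2.0
    estimates = {}
    for name in OUTCOMES:
        lo, hi = np.percentile(draws[name], [alpha, 100.0 - alpha])
        estimates[name] = OutcomeInterval(
            point=float(points[name][0]), ui_low=float(lo), ui_high=float(hi)
        )
    return BootstrapResult(
        n_iterations=n_iterations,
        seed=seed,
        n_degenerate=n_degenerate,
        confidence=confidence,
        estimates=estimates,
        r_draws=draws["r"],
    )


def bootstrap_strata(
    cohort: Cohort,
    table: HealingTimeTable | None = None,
    spec: TranslationSpec | None = None,
    params: CostParameters | None = None,
    n_iterations: int = 10_000,
    seed: int | None = None,
    per_day_value: float | None = None,
    confidence: float = 0.95,
) -> dict[str, BootstrapResult]:
    """Within-stratum bootstrap with T_placebo fixed to the stratum median.

    Patients are resampled within each occupied (depth, category) stratum;
    r is recomputed from the stratum resample.  Seeds for the per-stratum
    runs are spawned deterministically from ``seed``.
    """
    table = table or HealingTimeTable()
    groups: dict[str, list[int]] = {}
    for i, rec in enumerate(cohort):
        key = f"{rec.depth}/{category_of(rec.design_r_total)}"
        groups.setdefault(key, []).append(i)
    seeds = np.random.SeedSequence(seed).spawn(len(groups))
    results = {}
    for (label, indices), sub_seed in zip(sorted(groups.items()), seeds):
        depth, cat = label.split("/")
        sub = cohort.subset(indices)
        if len(sub) < 2:
            continue  # a singleton stratum has no resampling distribution
        results[label] = bootstrap_model(
            sub,
            table=table,
            spec=spec,
            params=params,
            n_iterations=n_iterations,
            seed=int(sub_seed.generate_state(1)[0] % (2**31)),
            per_day_value=per_day_value,
            fixed_baseline=table.lookup(depth, cat),
            confidence=confidence,
        )
    return results


def trimmed_ratio(r_draws: np.ndarray, lower: float = 2.5, upper: float = 97.5) -> float:
    """Mean of bootstrap r draws strictly inside the central percentile band.

    Discards draws at or beyond the 2.5th/97.5th percentiles of the draw
    distribution, damping the influence of the extreme ratios that arise when
    a resample's placebo mean is close to zero.
    """
    r_draws = np.asarray(r_draws, dtype=float)
    if r_draws.size < 40:
        raise EstimationError(
            f"trimmed ratio needs >= 40 retained draws, got {r_draws.size}"
        )
    lo, hi = np.percentile(r_draws, [lower, upper])
    inside = r_draws[(r_draws > lo) & (r_draws < hi)]
    if inside.size == 0:
        raise EstimationError("no draws strictly inside the percentile band")
    return float(inside.mean())
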