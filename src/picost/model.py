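"""End-to-end estimator: cohort in, cost-consequence projection out.

:class:`CostConsequenceModel` composes the whole chain — crossover effect
estimation, severity-stratified baseline imputation, acceleration
translation, monetary valuation, and the patient-level bootstrap — behind a
scikit-learn style ``fit`` interface so it can be configured with
``get_params``/``set_params`` and cloned in pipelines.
"""

from __future__ import annotations

from typing import Optional

import pandas as pd
from sklearn.base import BaseEstimator

from .bootstrap import bootstrap_model, bootstrap_strata, trimmed_ratio
from .cohort import Cohort
from .costs import CostParameters, project_case, project_strata, strata_frame
from .effects import (
    CrossoverEffectModel,
    _as_cohort,
    crossover_diagnostics,
    ratio_summary,
)
from .exceptions import EstimationError
from .healing import HealingTimeTable, TranslationSpec, mean_baseline
from .scenarios import BASE_CASE_R


class CostConsequenceModel(BaseEstimator):
    """Model-based cost-consequence analysis of a 2x2 crossover cohort.

    Parameters
    ----------
    ratio_source : {"base_case_constant", "mean", "median_based"}
        Where the acceleration ratio used for the headline projection comes
        from: the configurable base-case constant (default), the cohort mean
        ratio, or the cohort median-based ratio.
    base_case_r : float, default 3.52
        The constant used when ``ratio_source="base_case_constant"``.
    translation_mode : {"constant_ratio", "diminishing"}
    kappa, accel_window_days
        Attenuation fraction and full-acceleration window of the diminishing
        rule (ignored under constant-ratio translation).
    healing_table : HealingTimeTable or None
        Median healing-time table; ``None`` uses the published defaults.
    cost_params : CostParameters or None
    per_day_value : float or None
        Healing-related monetary value proxy; ``None`` uses the sum of the
        cost-parameter components (JPY 4000/day by default).
    n_bootstrap : int, default 10_000
        Bootstrap iterations; 0 disables the uncertainty engine.
    random_state : int or None
        Seed for the bootstrap resampling.

    Attributes
    ----------
    effects_ : EffectEstimates
    diagnostics_ : CrossoverDiagnostics or None
    baseline_mean_ : float
    r_used_ : float
    projection_ : CaseProjection
    strata_ : list of CaseProjection
    bootstrap_ : BootstrapResult or None
    bootstrap_strata_ : dict[str, BootstrapResult] or None
    """

    def __init__(
        self,
        ratio_source: str = "base_case_constant",
        base_case_r: float = BASE_CASE_R,
        translation_mode: str = "constant_ratio",
        kappa: float = 0.5,
        accel_window_days: float = 14.0,
        healing_table: Optional[HealingTimeTable] = None,
        cost_params: Optional[CostParameters] = None,
        per_day_value: Optional[float] = None,
        confidence: float = 0.95,
        n_bootstrap: int = 10_000,
        random_state: Optional[int] = None,
    ):
        self.ratio_source = ratio_source
        self.base_case_r = base_case_r
        self.translation_mode = translation_mode
        self.kappa = kappa
        self.accel_window_days = accel_window_days
        self.healing_table = healing_table
        self.cost_params = cost_params
        self.per_day_value = per_day_value
        self.confidence = confidence
        self.n_bootstrap = n_bootstrap
        self.random_state = random_state

    def fit(self, X: Cohort | pd.DataFrame, y=None) -> "CostConsequenceModel":
        cohort = _as_cohort(X)
        table = self.healing_table or HealingTimeTable()
        params = self.cost_params or CostParameters()

        self.effects_ = (
            CrossoverEffectModel(confidence=self.confidence).fit(cohort).estimates_()
        )
        try:
            self.diagnostics_ = crossover_diagnostics(cohort)
        except EstimationError:
            self.diagnostics_ = None

        if self.ratio_source == "base_case_constant":
            self.r_used_ = float(self.base_case_r)
        elif self.ratio_source in ("mean", "median_based"):
            self.r_used_ = ratio_summary(cohort, method=self.ratio_source)
        else:
            raise ValueError(f"unknown ratio_source {self.ratio_source!r}")

        translation = TranslationSpec(
            mode=self.translation_mode,
            r=self.r_used_,
            kappa=self.kappa,
            accel_window_days=self.accel_window_days,
        )
        self.baseline_mean_ = mean_baseline(cohort, table)
        self.projection_ = project_case(
            self.baseline_mean_,
            translation,
            params,
            per_day_value=self.per_day_value,
            label="base_case",
            n=len(cohort),
        )
        self.strata_ = project_strata(
            cohort, table, translation, params, per_day_value=self.per_day_value
        )

        if self.n_bootstrap > 0:
            self.bootstrap_ = bootstrap_model(
                cohort,
                table=table,
                spec=translation,
                params=params,
                n_iterations=self.n_bootstrap,
                seed=self.random_state,
                per_day_value=self.per_day_value,
                confidence=self.confidence,
            )
            self.effects_.r_trimmed = trimmed_ratio(self.bootstrap_.r_draws)
            self.bootstrap_strata_ = bootstrap_strata(
                cohort,
                table=table,
                spec=translation,
                params=params,
                n_iterations=self.n_bootstrap,
                seed=self.random_state,
                per_day_value=self.per_day_value,
                confidence=self.confidence,
            )
        else:
            self.bootstrap_ = None
            self.bootstrap_strata_ = None
        self.n_patients_ = len(cohort)
        return self

    # -- reporting ---------------------------------------------------------

    def summary_table(self) -> pd.DataFrame:
        """Point estimates and, when bootstrapped, 95% uncertainty intervals
        for the headline outcomes (layout mirrors the main results table)."""
        self._check_fitted()
        eff = self.effects_
        rows = [
            {
                "outcome": "delta (cm^2/day)",
                "point": eff.delta_mean,
                "ui_low": eff.delta_ci_low,
                "ui_high": eff.delta_ci_high,
            }
        ]
        if self.bootstrap_ is not None:
            pretty = {
                "r": "acceleration ratio r",
                "t_placebo": "imputed baseline time to heal (days)",
                "t_es": "estimated time to heal under ES (days)",
                "days_saved": "days saved (days)",
                "gross_offset": "gross monetary value offset (JPY/case)",
                "impl_total": "ES implementation cost (JPY/case)",
                "c_impl_per_day": "average implementation cost (JPY/day)",
                "net_impact": "net financial impact (JPY/case)",
            }
            for key, label in pretty.items():
                est = self.bootstrap_.estimates[key]
                rows.append(
                    {
                        "outcome": label,
                        "point": est.point,
                        "ui_low": est.ui_low,
                        "ui_high": est.ui_high,
                    }
                )
        else:
            proj = self.projection_
            for key, label in [
                ("t_placebo", "imputed baseline time to heal (days)"),
                ("t_es", "estimated time to heal under ES (days)"),
                ("days_saved", "days saved (days)"),
                ("gross_offset", "gross monetary value offset (JPY/case)"),
                ("impl_total", "ES implementation cost (JPY/case)"),
                ("c_impl_per_day", "average implementation cost (JPY/day)"),
                ("net_impact", "net financial impact (JPY/case)"),
            ]:
                rows.append(
                    {
                        "outcome": label,
                        "point": getattr(proj, key),
                        "ui_low": float("nan"),
                        "ui_high": float("nan"),
                    }
                )
        return pd.DataFrame(rows)

    def strata_table(self) -> pd.DataFrame:
        """Severity-stratified projections (one row per occupied stratum)."""
        self._check_fitted()
        frame = strata_frame(self.strata_)
        if self.bootstrap_strata_:
            ui_cols = {}
            for key in ("t_es", "days_saved", "gross_offset", "impl_total", "net_impact"):
                ui_cols[f"{key}_ui"] = [
                    _format_ui(self.bootstrap_strata_, label, key)
                    for label in frame["label"]
                ]
            frame = frame.assign(**ui_cols)
        return frame

    def _check_fitted(self) -> None:
        if not hasattr(self, "projection_"):
            raise EstimationError("model is not fitted; call fit(cohort) first")


def _format_ui(results: dict, label: str, key: str) -> str:
    if label not in results:
        return ""
    est = results[label].estimates[key]
    return f"({est.ui_low:.1f}-{est.ui_high:.1f})"
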