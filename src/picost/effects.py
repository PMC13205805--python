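"""Crossover effect estimation: daily reductions, the within-subject effect,
ratio summaries, and 2x2 crossover diagnostics.

The primary effect is the within-subject difference in daily wound-area
reduction, Delta = reduction(ES) - reduction(placebo), summarized with a
paired-t mean/CI and a Wilcoxon signed-rank robustness check.  The healing
acceleration ratio r = mean reduction(ES) / mean reduction(placebo) is a
secondary translation parameter; ratio summaries are unstable when the
placebo denominator is small or negative, so a median-based variant and
(downstream) a bootstrap-trimmed variant are provided as robustness checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .cohort import Cohort
from .exceptions import EstimationError, PolarityWarning, UndefinedRatioError


def daily_reduction(
    area_start: float, area_end: float, period_days: float
) -> float:
    """Daily wound-area reduction (cm^2/day) over one treatment period.

    ``(area_start - area_end) / period_days``; negative when the wound grew.
    """
    if period_days <= 0:
        raise ValueError(f"period_days must be > 0, got {period_days}")
    if area_start < 0 or area_end < 0:
        raise ValueError("areas must be >= 0")
    return (area_start - area_end) / period_days


def period_reductions(cohort: Cohort) -> tuple[np.ndarray, np.ndarray]:
    """Per-patient daily reductions (ES, placebo) in cohort order."""
    length = cohort.period_length_days
    red_es = np.array(
        [daily_reduction(r.area_es_start, r.area_es_end, length) for r in cohort]
    )
    red_pl = np.array(
        [daily_reduction(r.area_pl_start, r.area_pl_end, length) for r in cohort]
    )
    return red_es, red_pl


@dataclass
class EffectEstimates:
    """Within-subject effect and ratio summaries for one cohort."""

    delta_mean: float
    delta_ci_low: float
    delta_ci_high: float
    p_paired_t: float
    p_wilcoxon: float
    mean_red_es: float
    mean_red_pl: float
    r_mean: float
    r_median_based: float
    n_patients: int
    confidence: float = 0.95
    degenerate: bool = False
    wilcoxon_defined: bool = True
    #: Mean of bootstrap r draws inside the central 95% band; populated by the
    #: uncertainty engine, not by :func:`estimate_effects`.
    r_trimmed: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "delta_mean": self.delta_mean,
            "delta_ci_low": self.delta_ci_low,
            "delta_ci_high": self.delta_ci_high,
            "p_paired_t": self.p_paired_t,
            "p_wilcoxon": self.p_wilcoxon,
            "mean_red_es": self.mean_red_es,
            "mean_red_pl": self.mean_red_pl,
            "r_mean": self.r_mean,
            "r_median_based": self.r_median_based,
            "r_trimmed": self.r_trimmed,
            "n_patients": self.n_patients,
            "confidence": self.confidence,
        }


class CrossoverEffectModel(BaseEstimator):
    """Paired estimator of the crossover treatment effect.

    Parameters
    ----------
    confidence : float, default 0.95
        Two-sided confidence level for the paired-t interval.
    median_ratio_method : {"period_medians", "per_patient"}, default "period_medians"
        Definition of the median-based acceleration ratio: ratio of period
        medians (robust default) or median of per-patient ratios (can explode
        when a patient's placebo reduction is near zero).

    Attributes (after ``fit``)
    --------------------------
    delta_mean_, delta_ci_, p_paired_t_, p_wilcoxon_, mean_red_es_,
    mean_red_pl_, r_mean_, r_median_based_, n_patients_, degenerate_,
    wilcoxon_defined_
    """

    def __init__(
        self,
        confidence: float = 0.95,
        median_ratio_method: str = "period_medians",
    ):
        self.confidence = confidence
        self.median_ratio_method = median_ratio_method

    def fit(self, X: Cohort | pd.DataFrame, y=None) -> "CrossoverEffectModel":
        cohort = _as_cohort(X)
        if len(cohort) < 2:
            raise EstimationError(
                f"need >= 2 patients for paired inference, got {len(cohort)}"
            )
        if not 0 < self.confidence < 1:
            raise ValueError("confidence must be in (0, 1)")
        red_es, red_pl = period_reductions(cohort)
        diffs = red_es - red_pl
        n = len(diffs)
        delta = float(diffs.mean())
        sd = float(diffs.std(ddof=1))

        if sd == 0.0:
            # all within-subject differences identical: no sampling variance
            self.degenerate_ = True
            self.p_paired_t_ = 1.0 if delta == 0.0 else 0.0
            self.delta_ci_ = (delta, delta)
        else:
            self.degenerate_ = False
            t_res = stats.ttest_rel(red_es, red_pl)
            ci = t_res.confidence_interval(self.confidence)
            self.p_paired_t_ = float(t_res.pvalue)
            self.delta_ci_ = (float(ci.low), float(ci.high))

        nonzero = diffs[diffs != 0.0]  # zero differences dropped (Wilcoxon)
        if nonzero.size == 0 or sd == 0.0:
            # all differences identical: signed-rank null degenerates
            self.wilcoxon_defined_ = False
            self.p_wilcoxon_ = float("nan")
        else:
            self.wilcoxon_defined_ = True
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                w_res = stats.wilcoxon(nonzero, zero_method="wilcox", method="auto")
            self.p_wilcoxon_ = float(w_res.pvalue)

        self.delta_mean_ = delta
        self.mean_red_es_ = float(red_es.mean())
        self.mean_red_pl_ = float(red_pl.mean())
        self.r_mean_ = (
            self.mean_red_es_ / self.mean_red_pl_
            if self.mean_red_pl_ != 0.0
            else float("nan")
        )
        if self.median_ratio_method == "per_patient":
            with np.errstate(divide="ignore", invalid="ignore"):
                self.r_median_based_ = float(np.median(red_es / red_pl))
        else:
            med_pl = float(np.median(red_pl))
            self.r_median_based_ = (
                float(np.median(red_es)) / med_pl if med_pl != 0.0 else float("nan")
            )
        self.n_patients_ = n
        return self

    def estimates_(self) -> EffectEstimates:
        """Bundle fitted attributes into an :class:`EffectEstimates`."""
        return EffectEstimates(
            delta_mean=self.delta_mean_,
            delta_ci_low=self.delta_ci_[0],
            delta_ci_high=self.delta_ci_[1],
            p_paired_t=self.p_paired_t_,
            p_wilcoxon=self.p_wilcoxon_,
            mean_red_es=self.mean_red_es_,
            mean_red_pl=self.mean_red_pl_,
            r_mean=self.r_mean_,
            r_median_based=self.r_median_based_,
            n_patients=self.n_patients_,
            confidence=self.confidence,
            degenerate=self.degenerate_,
            wilcoxon_defined=self.wilcoxon_defined_,
        )


def estimate_effects(
    cohort: Cohort | pd.DataFrame, confidence: float = 0.95
) -> EffectEstimates:
    """Fit :class:`CrossoverEffectModel` and return its estimates."""
    return CrossoverEffectModel(confidence=confidence).fit(cohort).estimates_()


def ratio_summary(cohort: Cohort | pd.DataFrame, method: str = "mean") -> float:
    """Healing acceleration ratio summary.

    ``mean``: ratio of cohort mean reductions (the translation parameter r).
    ``median_based``: ratio of cohort median reductions.
    A zero denominator raises :class:`UndefinedRatioError`; a negative
    denominator emits a :class:`PolarityWarning` and returns the (negative)
    value unchanged.
    """
    red_es, red_pl = period_reductions(_as_cohort(cohort))
    if method == "mean":
        num, den = float(red_es.mean()), float(red_pl.mean())
    elif method == "median_based":
        num, den = float(np.median(red_es)), float(np.median(red_pl))
    else:
        raise ValueError(f"unknown ratio method {method!r}")
    if den == 0.0:
        raise UndefinedRatioError(
            f"{method} placebo reduction is zero; acceleration ratio undefined"
        )
    if den < 0.0:
        warnings.warn(
            f"{method} placebo reduction is negative ({den:.4g} cm^2/day); "
            "the ratio's sign is inverted",
            PolarityWarning,
            stacklevel=2,
        )
    return num / den


@dataclass
class CrossoverDiagnostics:
    """Classical 2x2 crossover contrasts (Grizzle-style two-sample t tests).

    ``period_effect`` is the additive shift in daily reduction attributable to
    the second period; ``sequence_effect`` is half the between-sequence
    difference of within-patient sums (carryover diagnostic).
    """

    treatment_effect: float
    period_effect: float
    sequence_effect: float
    p_treatment: float
    p_period: float
    p_sequence: float
    first_period_only_effect: float
    n_es_first: int
    n_placebo_first: int

    def to_dict(self) -> dict:
        return {
            "treatment_effect": self.treatment_effect,
            "period_effect": self.period_effect,
            "sequence_effect": self.sequence_effect,
            "p_treatment": self.p_treatment,
            "p_period": self.p_period,
            "p_sequence": self.p_sequence,
            "first_period_only_effect": self.first_period_only_effect,
            "n_es_first": self.n_es_first,
            "n_placebo_first": self.n_placebo_first,
        }


def crossover_diagnostics(cohort: Cohort | pd.DataFrame) -> CrossoverDiagnostics:
    """Treatment, period and sequence (carryover) contrasts for a 2x2 design.

    Within-patient period differences (period 1 minus period 2) compared
    between sequence groups give the treatment and period effects; the
    within-patient sums compared between groups give the carryover
    diagnostic.  Equal-variance two-sample t tests throughout.
    """
    cohort = _as_cohort(cohort)
    red_es, red_pl = period_reductions(cohort)
    es_first = np.array([r.sequence == "ES_first" for r in cohort])
    if es_first.all() or (~es_first).all():
        raise EstimationError(
            "both sequence groups must be non-empty for crossover diagnostics"
        )
    p1 = np.where(es_first, red_es, red_pl)  # period-1 reduction
    p2 = np.where(es_first, red_pl, red_es)  # period-2 reduction
    pdiff = p1 - p2
    psum = p1 + p2
    d_ab, d_ba = pdiff[es_first], pdiff[~es_first]
    s_ab, s_ba = psum[es_first], psum[~es_first]

    treatment = float((d_ab.mean() - d_ba.mean()) / 2.0)
    period = float(-(d_ab.mean() + d_ba.mean()) / 2.0)
    sequence = float((s_ab.mean() - s_ba.mean()) / 2.0)
    first_period = float(p1[es_first].mean() - p1[~es_first].mean())

    def _p(a: np.ndarray, b: np.ndarray) -> float:
        if len(a) < 2 or len(b) < 2:
            return float("nan")
        res = stats.ttest_ind(a, b, equal_var=True)
        return float(res.pvalue)

    return CrossoverDiagnostics(
        treatment_effect=treatment,
        period_effect=period,
        sequence_effect=sequence,
        p_treatment=_p(d_ab, d_ba),
        p_period=_p(d_ab, -d_ba),
        p_sequence=_p(s_ab, s_ba),
        first_period_only_effect=first_period,
        n_es_first=int(es_first.sum()),
        n_placebo_first=int((~es_first).sum()),
    )


def _as_cohort(X: Cohort | pd.DataFrame) -> Cohort:
    if isinstance(X, Cohort):
        return X
    if isinstance(X, pd.DataFrame):
        return Cohort.from_dataframe(X)
    raise TypeError(f"expected a Cohort or DataFrame, got {type(X).__name__}")
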