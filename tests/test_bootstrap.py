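"""Patient-level bootstrap engine and trimmed-ratio summary."""

import itertools

import numpy as np
import pytest

from picost import (
    CostParameters,
    HealingTimeTable,
    TranslationSpec,
    bootstrap_model,
    bootstrap_strata,
    trimmed_ratio,
)
from picost.bootstrap import OUTCOMES
from picost.exceptions import EstimationError


class TestDeterminismAndBookkeeping:
    def test_same_seed_bit_identical(self, default_cohort):
        a = bootstrap_model(default_cohort, n_iterations=500, seed=11)
        b = bootstrap_model(default_cohort, n_iterations=500, seed=11)
        assert np.array_equal(a.r_draws, b.r_draws)
        for name in OUTCOMES:
            assert a.estimates[name] == b.estimates[name]
        c = bootstrap_model(default_cohort, n_iterations=500, seed=12)
        assert not np.array_equal(a.r_draws, c.r_draws)

    def test_degenerate_plus_retained_equals_iterations(self, default_cohort):
        res = bootstrap_model(default_cohort, n_iterations=2000, seed=1)
        assert res.n_degenerate + res.r_draws.size == res.n_iterations
        assert res.n_retained == res.r_draws.size

    def test_interval_ordering_and_point_containment(self, default_cohort):
        res = bootstrap_model(default_cohort, n_iterations=4000, seed=2)
        for name in OUTCOMES:
            est = res.estimates[name]
            assert est.ui_low <= est.ui_high
        r_est = res.estimates["r"]
        assert r_est.ui_low < r_est.point < r_est.ui_high

    def test_right_skew_of_ratio_draws(self, default_cohort):
        """Small placebo-period means make the ratio distribution right-skewed:
        the mean of the draws exceeds their median."""
        res = bootstrap_model(default_cohort, n_iterations=4000, seed=3)
        assert res.r_draws.mean() > np.median(res.r_draws)

    def test_zero_variance_cohort_collapses_intervals(self):
        # identical patients: one stratum, zero reduction dispersion
        from picost import GeneratorSpec, generate_cohort

        cohort = generate_cohort(
            GeneratorSpec(
                sd_red_es=0.0,
                sd_red_pl=0.0,
                strata=[(">=19", "deep", 12)],
                seed=4,
            )
        )
        res = bootstrap_model(cohort, n_iterations=200, seed=4)
        for name in OUTCOMES:
            est = res.estimates[name]
            assert est.ui_low == pytest.approx(est.point, rel=1e-12)
            assert est.ui_high == pytest.approx(est.point, rel=1e-12)

    def test_all_degenerate_cohort_raises(self, make_cohort):
        cohort = make_cohort([0.2, 0.25, 0.3], [-0.1, -0.05, -0.2])
        with pytest.raises(EstimationError):
            bootstrap_model(cohort, n_iterations=100, seed=5)


class TestEnumerationOracle:
    def test_percentiles_match_exhaustive_resample_distribution(self, make_cohort):
        """With n = 3 the bootstrap distribution has 27 equally likely ordered
        resamples; empirical percentiles at large B must converge to the
        discrete distribution's quantiles."""
        cohort = make_cohort([0.30, 0.18, 0.45], [0.10, 0.04, 0.21],
                             design_r=20, depth="deep")
        res = bootstrap_model(cohort, n_iterations=100_000, seed=6)

        red_es = np.array([0.30, 0.18, 0.45])
        red_pl = np.array([0.10, 0.04, 0.21])
        exact_r = []
        for combo in itertools.product(range(3), repeat=3):
            idx = list(combo)
            exact_r.append(red_es[idx].mean() / red_pl[idx].mean())
        exact_r = np.sort(exact_r)

        for q in (2.5, 10.0, 25.0, 50.0, 75.0, 90.0, 97.5):
            boot_q = np.percentile(res.r_draws, q)
            exact_q = np.quantile(exact_r, q / 100.0, method="inverted_cdf")
            # q never falls on an atom boundary of the 27-point distribution,
            # so the empirical percentile must land on the exact atom
            assert boot_q == pytest.approx(exact_q, rel=1e-9), q

    def test_draw_frequencies_match_multinomial_weights(self, make_cohort):
        cohort = make_cohort([0.30, 0.18, 0.45], [0.10, 0.04, 0.21])
        res = bootstrap_model(cohort, n_iterations=100_000, seed=7)
        red_es = np.array([0.30, 0.18, 0.45])
        red_pl = np.array([0.10, 0.04, 0.21])
        exact = {}
        for combo in itertools.product(range(3), repeat=3):
            idx = list(combo)
            key = round(red_es[idx].mean() / red_pl[idx].mean(), 12)
            exact[key] = exact.get(key, 0) + 1 / 27
        values, counts = np.unique(np.round(res.r_draws, 12), return_counts=True)
        assert set(values) == set(exact)
        for value, count in zip(values, counts):
            assert count / res.n_retained == pytest.approx(exact[value], abs=0.01)


class TestMonotoneTransforms:
    def test_gross_offset_ui_is_value_times_days_saved_ui(self, default_cohort):
        res = bootstrap_model(
            default_cohort, n_iterations=3000, seed=8, per_day_value=4000.0
        )
        ds, gross = res.estimates["days_saved"], res.estimates["gross_offset"]
        assert gross.ui_low == pytest.approx(4000.0 * ds.ui_low, rel=1e-12)
        assert gross.ui_high == pytest.approx(4000.0 * ds.ui_high, rel=1e-12)

    def test_fixed_baseline_pins_t_placebo(self, default_cohort):
        res = bootstrap_model(
            default_cohort, n_iterations=500, seed=9, fixed_baseline=259.0
        )
        est = res.estimates["t_placebo"]
        assert est.point == est.ui_low == est.ui_high == 259.0


class TestStratumBootstrap:
    def test_strata_fixed_to_published_medians(self, default_cohort):
        results = bootstrap_strata(default_cohort, n_iterations=400, seed=10)
        assert set(results) == {"deep/10-18", "deep/>=19"}
        table = HealingTimeTable()
        assert results["deep/10-18"].estimates["t_placebo"].point == table.lookup(
            "deep", "10-18"
        )
        assert results["deep/>=19"].estimates["t_placebo"].point == table.lookup(
            "deep", ">=19"
        )

    def test_stratum_bootstrap_deterministic(self, default_cohort):
        a = bootstrap_strata(default_cohort, n_iterations=300, seed=21)
        b = bootstrap_strata(default_cohort, n_iterations=300, seed=21)
        for label in a:
            assert np.array_equal(a[label].r_draws, b[label].r_draws)


class TestTrimmedRatio:
    def test_symmetric_draws_equal_untrimmed_mean(self):
        draws = np.arange(1.0, 101.0)
        assert trimmed_ratio(draws) == pytest.approx(draws.mean())

    def test_outlier_insensitivity(self):
        rng = np.random.default_rng(0)
        draws = rng.normal(3.5, 0.5, size=10_000)
        spiked = np.append(draws, 1e6)
        assert abs(trimmed_ratio(spiked) - trimmed_ratio(draws)) < 0.05

    def test_right_skew_trims_downward_and_matches_sort_oracle(self):
        rng = np.random.default_rng(1)
        draws = np.exp(rng.normal(1.25, 0.6, size=20_000))
        trimmed = trimmed_ratio(draws)
        assert trimmed < draws.mean()
        lo, hi = np.percentile(draws, [2.5, 97.5])
        oracle = np.sort(draws)
        oracle = oracle[(oracle > lo) & (oracle < hi)].mean()
        assert trimmed == pytest.approx(oracle, rel=1e-12)

    def test_too_few_draws_rejected(self):
        with pytest.raises(EstimationError):
            trimmed_ratio(np.arange(10.0))


def test_bootstrap_respects_translation_mode(default_cohort):
    """Diminishing-acceleration bootstrap yields longer ES healing times than
    constant-ratio on the same draws (conservatism propagates)."""
    const = bootstrap_model(
        default_cohort, spec=TranslationSpec(r=3.52), n_iterations=2000, seed=13
    )
    dim = bootstrap_model(
        default_cohort,
        spec=TranslationSpec(mode="diminishing", r=3.52, kappa=0.5),
        n_iterations=2000,
        seed=13,
    )
    assert dim.estimates["t_es"].point > const.estimates["t_es"].point
    assert dim.estimates["t_es"].ui_high >= const.estimates["t_es"].ui_high
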