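"""Weibull survival mathematics: evaluation, transitions, fitting."""

import math

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from alkcea.survival import (
    FitError,
    KmPoints,
    WeibullCurve,
    apply_hazard_ratio,
    cycle_prob_from_median,
    fit_weibull,
    median_survival,
    per_cycle_transition_prob,
    recalibrate_scale,
    weibull_survival,
)

CRIZ = WeibullCurve(0.0211, 1.5326, "month")
CHEMO = WeibullCurve(0.0663, 0.8604, "week")

curves = st.builds(
    WeibullCurve,
    scale=st.floats(1e-4, 1.0),
    shape=st.floats(0.3, 3.0),
    time_unit=st.sampled_from(["cycle", "week", "month"]),
)


class TestWeibullSurvival:
    @pytest.mark.parametrize("curve, t, expected", [
        (CRIZ, 0.0, 1.0),
        (CHEMO, 0.0, 1.0),
        # independent evaluation: exp(-0.0211 * 10**1.5326) = 0.4872
        (CRIZ, 10.0, 0.487),
        # shape 1 reduces to the exponential: exp(-0.663)
        (WeibullCurve(0.0663, 1.0), 10.0, 0.5153),
    ])
    def test_point_values(self, curve, t, expected):
        assert weibull_survival(curve, t) == pytest.approx(expected, abs=5e-4)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            weibull_survival(CRIZ, -0.1)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            WeibullCurve(0.0, 1.0)
        with pytest.raises(ValueError):
            WeibullCurve(0.1, -1.0)
        with pytest.raises(ValueError):
            WeibullCurve(0.1, 1.0, "fortnight")

    @settings(max_examples=50, derandomize=True)
    @given(curve=curves, t=st.floats(0.0, 100.0))
    def test_monotone_non_increasing(self, curve, t):
        assert weibull_survival(curve, t + 1.0) <= weibull_survival(curve, t)


class TestPerCycleTransition:
    def test_exponential_is_memoryless(self):
        curve = WeibullCurve(0.2, 1.0)
        probs = {per_cycle_transition_prob(curve, k) for k in range(10)}
        assert len({round(p, 15) for p in probs}) == 1
        assert probs.pop() == pytest.approx(1.0 - math.exp(-0.2))

    def test_first_cycle_value(self):
        # S(1)/S(0) = exp(-0.0211): p = 0.02088 to 4 significant figures
        assert per_cycle_transition_prob(CRIZ, 0) == pytest.approx(
            0.02088, abs=5e-6)

    def test_decreasing_hazard_gives_decreasing_probs(self):
        probs = [per_cycle_transition_prob(CHEMO, k) for k in range(21)]
        assert all(a > b for a, b in zip(probs, probs[1:]))

    def test_increasing_hazard_gives_increasing_probs(self):
        probs = [per_cycle_transition_prob(CRIZ, k) for k in range(21)]
        assert all(a < b for a, b in zip(probs, probs[1:]))

    @settings(max_examples=50, derandomize=True)
    @given(curve=curves, n=st.integers(1, 60),
           upc=st.floats(0.1, 5.0))
    def test_telescoping_identity(self, curve, n, upc):
        """Survival through n cycles equals the product of per-cycle
        continuation probabilities (exact, by construction on hazards).
        Restricted to cohorts that are not numerically extinct, where the
        1-p factors themselves lose all precision."""
        assume(weibull_survival(curve, n * upc) > 1e-6)
        prod = 1.0
        for k in range(n):
            prod *= 1.0 - per_cycle_transition_prob(curve, k, upc)
        assert prod == pytest.approx(
            weibull_survival(curve, n * upc), rel=1e-6, abs=1e-300)


class TestHazardRatio:
    @pytest.mark.parametrize("s, hr, expected", [
        (0.5, 1.0, 0.5),
        (0.5, 0.77, 0.58639),       # exp(0.77 ln 0.5)
        (0.5, 1 / 0.77, 0.40647),   # supportive-care transform
    ])
    def test_values(self, s, hr, expected):
        assert apply_hazard_ratio(s, hr) == pytest.approx(expected, abs=1e-4)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            apply_hazard_ratio(0.5, 0.0)
        with pytest.raises(ValueError):
            apply_hazard_ratio(1.5, 0.8)

    @settings(max_examples=50, derandomize=True)
    @given(s=st.floats(1e-6, 1.0), a=st.floats(0.1, 3.0),
           b=st.floats(0.1, 3.0))
    def test_composition(self, s, a, b):
        assert apply_hazard_ratio(apply_hazard_ratio(s, a), b) == pytest.approx(
            apply_hazard_ratio(s, a * b), rel=1e-10)


class TestMedianAndRecalibration:
    @pytest.mark.parametrize("curve, expected", [
        (WeibullCurve(math.log(2.0), 1.0), 1.0),
        (CRIZ, 9.76),    # (ln2/0.0211)^(1/1.5326)
        (CHEMO, 15.3),   # (ln2/0.0663)^(1/0.8604)
    ])
    def test_median_values(self, curve, expected):
        assert median_survival(curve) == pytest.approx(expected, rel=5e-3)

    def test_recalibrate_self_consistency(self):
        again = recalibrate_scale(CRIZ, median_survival(CRIZ))
        assert again.scale == pytest.approx(0.0211, rel=1e-12)

    def test_recalibrate_unit_median(self):
        assert recalibrate_scale(CRIZ, 1.0).scale == pytest.approx(math.log(2.0))

    @settings(max_examples=50, derandomize=True)
    @given(curve=curves, target=st.floats(0.5, 40.0))
    def test_recalibrate_round_trip(self, curve, target):
        assert median_survival(recalibrate_scale(curve, target)) == \
            pytest.approx(target, rel=1e-10)


class TestCycleProbFromMedian:
    def test_reproduces_published_progressed_death_probability(self):
        # 5.4-month median post-progression OS, 21-day cycles, 30-day months
        assert cycle_prob_from_median(5.4, 21, 30) == pytest.approx(
            0.086, abs=5e-4)

    def test_one_median_per_cycle_gives_half(self):
        assert cycle_prob_from_median(7.0, 210, 30) == pytest.approx(0.5)

    def test_monthly_cycle_variant(self):
        assert cycle_prob_from_median(5.4, 30, 30) == pytest.approx(
            0.1205, abs=5e-5)


class TestFitWeibull:
    def test_exact_recovery(self):
        t = np.arange(1.0, 31.0)
        pts = KmPoints(tuple(t), tuple(np.exp(-0.0211 * t ** 1.5326)))
        fit = fit_weibull(pts)
        assert fit.scale == pytest.approx(0.0211, rel=1e-6)
        assert fit.shape == pytest.approx(1.5326, rel=1e-6)
        assert fit.fit_r2 == pytest.approx(1.0, abs=1e-12)

    def test_noisy_recovery_within_five_percent(self):
        from alkcea.synthetic_data import SyntheticKmSpec, generate_km_points

        spec = SyntheticKmSpec(CRIZ, tuple(np.arange(1.0, 31.0)),
                               noise_sd=0.01, seed=7)
        fit = fit_weibull(generate_km_points(spec))
        assert fit.scale == pytest.approx(0.0211, rel=0.05)
        assert fit.shape == pytest.approx(1.5326, rel=0.05)
        assert fit.fit_r2 > 0.97

    def test_underdetermined_raises(self):
        with pytest.raises(FitError):
            fit_weibull(KmPoints((1.0, 2.0), (0.9, 0.8)))

    def test_boundary_survival_excluded_and_reported(self):
        pts = KmPoints((1.0, 2.0, 3.0), (1.0, 0.9, 0.8))
        with pytest.raises(FitError, match="excluded"):
            fit_weibull(pts)

    def test_km_points_validation(self):
        with pytest.raises(ValueError):
            KmPoints((2.0, 1.0), (0.9, 0.8))      # times not increasing
        with pytest.raises(ValueError):
            KmPoints((1.0, 2.0), (0.8, 0.9))      # survival increasing
        with pytest.raises(ValueError):
            KmPoints((1.0, 2.0), (0.9, 0.0))      # survival out of (0, 1]
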