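"""Curve evaluation, AIC bookkeeping, model selection and parameter
extraction."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermoperf.errors import ExtractionError, FitError
from thermoperf.tpc import (
    TPCModelFit,
    TPCParams,
    akaike_weights,
    compute_aic,
    evaluate_family,
    extract_parameters,
    fit_candidates,
    fit_family,
    select_best,
    tpc_breadth,
)


class TestEvaluateFamily:
    @pytest.mark.parametrize(
        "family, params, t, expected",
        [
            ("gaussian", (10, 25, 5), 25, 10.0),          # peak value at center
            ("gaussian", (10, 25, 5), 30, 10 * math.exp(-0.5)),
            ("lorentzian", (10, 25, 5), 30, 5.0),         # half maximum at b + c
            ("lorentzian", (10, 25, 5), 25, 10.0),
            ("logistic_peak", (10, 25, 5), 25, 10.0),     # 4 e^0/(1+e^0)^2 = 1
            ("weibull_peak", (10, 25, 5, 3), 25, 10.0),   # mode kept at b
        ],
    )
    def test_known_values(self, family, params, t, expected):
        assert evaluate_family(family, params, t) == pytest.approx(expected, abs=1e-12)

    def test_all_families_peak_at_b(self):
        for family, params in [
            ("gaussian", (7.0, 22.0, 4.0)),
            ("lorentzian", (7.0, 22.0, 4.0)),
            ("logistic_peak", (7.0, 22.0, 4.0)),
            ("weibull_peak", (7.0, 22.0, 4.0, 2.5)),
        ]:
            t = np.linspace(0, 45, 901)
            y = evaluate_family(family, params, t)
            assert evaluate_family(family, params, 22.0) == pytest.approx(7.0)
            assert y.max() <= 7.0 + 1e-9

    def test_zero_width_rejected(self):
        with pytest.raises(ValueError):
            evaluate_family("gaussian", (10, 25, 0), 25)

    def test_unknown_family(self):
        with pytest.raises(FitError):
            evaluate_family("quartic", (1, 2, 3), 25)


class TestAIC:
    def test_hand_value(self):
        assert compute_aic(1.0, 10, 3) == pytest.approx(10 * math.log(0.1) + 6)

    def test_monotone_in_rss(self):
        assert compute_aic(2.0, 10, 3) > compute_aic(1.0, 10, 3)

    def test_parameter_penalty_is_two(self):
        assert compute_aic(1.0, 10, 4) - compute_aic(1.0, 10, 3) == pytest.approx(2.0)

    def test_perfect_fit_sentinel(self):
        with pytest.warns(UserWarning):
            assert compute_aic(0.0, 10, 3) == -math.inf

    def test_aicc_correction(self):
        plain = compute_aic(1.0, 10, 3)
        corrected = compute_aic(1.0, 10, 3, corrected=True)
        assert corrected - plain == pytest.approx(2 * 3 * 4 / (10 - 3 - 1))


class TestAkaikeWeights:
    def test_single_model(self):
        lam, w = akaike_weights([12.3])
        assert lam[0] == 0.0 and w[0] == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            akaike_weights([])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-100, 100), min_size=1, max_size=6))
    def test_weights_sum_to_one_and_track_aic(self, aics):
        lam, w = akaike_weights(aics)
        assert w.sum() == pytest.approx(1.0)
        assert lam.min() == 0.0
        # weights are ordered inversely to AIC
        for i in range(len(aics)):
            for j in range(len(aics)):
                if aics[i] < aics[j]:
                    assert w[i] >= w[j]


class TestSelectBest:
    def test_lowest_aic_wins(self):
        fits = [
            TPCModelFit("lorentzian", (1, 2, 3), 3, 1, 10, -57.22, 0.99),
            TPCModelFit("logistic_peak", (1, 2, 3), 3, 1, 10, -54.80, 0.99),
            TPCModelFit("gaussian", (1, 2, 3), 3, 1, 10, -50.07, 0.98),
        ]
        assert select_best(fits).family == "lorentzian"

    def test_tie_prefers_fewer_parameters(self):
        fits = [
            TPCModelFit("weibull_peak", (1, 2, 3, 4), 4, 1, 10, -50.0, 0.99),
            TPCModelFit("gaussian", (1, 2, 3), 3, 1, 10, -50.0, 0.99),
        ]
        assert select_best(fits).family == "gaussian"

    def test_single_candidate(self):
        only = TPCModelFit("gaussian", (1, 2, 3), 3, 1, 10, -50.0, 0.99)
        assert select_best([only]) is only

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_best([])


class TestFitFamily:
    @pytest.mark.parametrize("family, truth", [
        ("gaussian", (10.0, 25.0, 5.0)),
        ("lorentzian", (10.0, 25.0, 5.0)),
        ("logistic_peak", (10.0, 25.0, 5.0)),
    ])
    def test_noiseless_recovery(self, family, truth):
        t = np.array([5.0, 10, 15, 20, 25, 28, 31, 35])
        y = evaluate_family(family, truth, t)
        fit = fit_family((t, y), family)
        assert np.allclose(fit.params, truth, atol=1e-6)
        assert fit.rss == pytest.approx(0.0, abs=1e-10)

    def test_too_few_temperatures(self):
        t = np.array([10.0, 20.0, 30.0])
        y = evaluate_family("gaussian", (10, 20, 5), t)
        with pytest.raises(FitError, match="distinct"):
            fit_family((t, y), "gaussian")

    def test_population_recovery_from_synthetic(self, performance):
        """Population-level peak position lands within 1 degree of truth."""
        fit = fit_family(performance, "gaussian", level="population",
                         acclimation_c=20.0)
        assert abs(fit.params[1] - 25.98) < 1.0

    def test_candidates_sorted_and_weighted(self, performance):
        fits = fit_candidates(performance, level="population",
                              acclimation_c=25.0)
        aics = [f.aic for f in fits]
        assert aics == sorted(aics)
        assert sum(f.w_i for f in fits) == pytest.approx(1.0)
        assert fits[0].lambda_i == 0.0


class TestExtractParameters:
    def test_gaussian_closed_form(self):
        p = extract_parameters(("gaussian", (10, 25, 5)), epsilon=0.05)
        assert p.ct_max == pytest.approx(25 + 5 * math.sqrt(-2 * math.log(0.05)))
        assert p.ct_max == pytest.approx(37.24, abs=0.005)
        assert p.ct_min == pytest.approx(25 - 5 * math.sqrt(-2 * math.log(0.05)))

    def test_lorentzian_half_maximum(self):
        p = extract_parameters(("lorentzian", (10, 25, 5)), epsilon=0.5)
        assert (p.ct_min, p.ct_max) == (pytest.approx(20.0), pytest.approx(30.0))

    @pytest.mark.parametrize("family", ["gaussian", "lorentzian"])
    def test_bisection_matches_closed_form(self, family):
        for b in (15.0, 25.0):
            for c in (2.0, 6.0):
                for eps in (0.05, 0.2):
                    closed = extract_parameters((family, (8.0, b, c)), eps)
                    numeric = extract_parameters((family, (8.0, b, c)), eps,
                                                 method="bisection")
                    assert numeric.ct_min == pytest.approx(closed.ct_min, abs=1e-6)
                    assert numeric.ct_max == pytest.approx(closed.ct_max, abs=1e-6)

    def test_logistic_and_weibull_limits_hit_epsilon(self):
        for family, params in [("logistic_peak", (9.0, 24.0, 3.0)),
                               ("weibull_peak", (9.0, 24.0, 3.0, 2.2))]:
            p = extract_parameters((family, params), epsilon=0.05)
            for ct in (p.ct_min, p.ct_max):
                level = evaluate_family(family, params, ct)
                assert level == pytest.approx(0.05 * p.v_max, rel=1e-6)
            assert p.ct_min < p.t_opt < p.ct_max

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(
        a=st.floats(0.5, 50), b=st.floats(5, 35), c=st.floats(0.5, 10),
        eps=st.floats(0.01, 0.9), k=st.floats(0.1, 100),
    )
    def test_speed_scaling_leaves_temperatures_unchanged(self, a, b, c, eps, k):
        base = extract_parameters(("gaussian", (a, b, c)), eps)
        scaled = extract_parameters(("gaussian", (k * a, b, c)), eps)
        assert scaled.v_max == pytest.approx(k * base.v_max, rel=1e-9)
        assert scaled.t_opt == base.t_opt
        assert scaled.ct_min == pytest.approx(base.ct_min, rel=1e-12)
        assert scaled.ct_max == pytest.approx(base.ct_max, rel=1e-12)

    def test_epsilon_out_of_range(self):
        with pytest.raises(ExtractionError):
            extract_parameters(("gaussian", (10, 25, 5)), epsilon=1.5)

    def test_ordering_enforced_on_construction(self):
        with pytest.raises(ExtractionError):
            TPCParams(t_opt=20.0, v_max=5.0, ct_min=25.0, ct_max=30.0)


class TestBreadth:
    def test_difference(self):
        p = TPCParams(t_opt=22.0, v_max=8.0, ct_min=0.0, ct_max=32.39)
        assert tpc_breadth(p) == pytest.approx(32.39)

    def test_gaussian_closed_form(self):
        eps = 0.05
        p = extract_parameters(("gaussian", (10, 25, 5)), eps)
        assert tpc_breadth(p) == pytest.approx(2 * 5 * math.sqrt(-2 * math.log(eps)))

    def test_monotone_in_upper_limit(self):
        lo = TPCParams(22.0, 8.0, 0.0, 30.0)
        hi = TPCParams(22.0, 8.0, 0.0, 34.0)
        assert tpc_breadth(hi) > tpc_breadth(lo)
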