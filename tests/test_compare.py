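"""Regression, multiple-comparison and Delta-pH statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cestkit import (InvalidInputError, compare_slopes,
                     delta_cest_significance, delta_ph, fit_ideal_model,
                     holm_sidak, regress_metric, sign_accuracy)
from cestkit.compare import DeltaPHResult, sidak_thresholds


class TestRegression:
    def test_exact_line(self):
        x = np.arange(6, dtype=float)
        res = regress_metric(x, 2 * x + 1)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)
        assert res.p_value < 1e-10

    def test_constant_response(self):
        res = regress_metric(np.arange(6.0), np.full(6, 3.3))
        assert res.slope == pytest.approx(0.0)
        assert res.p_value > 0.99 or res.p_value == 1.0

    def test_degenerate_x_rejected(self):
        with pytest.raises(InvalidInputError):
            regress_metric([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_few_points_rejected(self):
        with pytest.raises(InvalidInputError):
            regress_metric([1.0, 2.0], [1.0, 2.0])


class TestSlopeComparison:
    def test_identical_regressions_not_significant(self, rng):
        x = np.arange(7.0)
        y = 1.5 * x + rng.normal(0, 0.4, 7)
        a = regress_metric(x, y, model="tumour")
        b = regress_metric(x, y, model="brain")
        comp = compare_slopes(a, b, family_size=24)
        assert comp.t_statistic == 0.0
        assert comp.p_value == pytest.approx(1.0)
        assert not comp.significant_rank1

    def test_clearly_different_slopes(self, rng):
        x = np.arange(7.0)
        a = regress_metric(x, 5 * x + rng.normal(0, 0.05, 7))
        b = regress_metric(x, 0.5 * x + rng.normal(0, 0.05, 7))
        comp = compare_slopes(a, b, family_size=24)
        assert comp.p_value < 1e-6
        assert comp.significant_rank1

    def test_invalid_family_size(self, rng):
        x = np.arange(5.0)
        a = regress_metric(x, x + rng.normal(0, 0.1, 5))
        with pytest.raises(InvalidInputError):
            compare_slopes(a, a, family_size=0)


class TestHolmSidak:
    def test_rank1_threshold_m16(self):
        # 1 - 0.95**(1/16) = 0.00320066...; a family of 16 tests yields the
        # "effective significance level" just above 0.003
        assert sidak_thresholds(16)[0] == pytest.approx(
            1 - 0.95 ** (1 / 16), abs=1e-12)
        assert sidak_thresholds(16)[0] == pytest.approx(0.0032007, abs=1e-6)

    def test_rank1_threshold_m24(self):
        assert sidak_thresholds(24)[0] == pytest.approx(0.0021349, abs=1e-6)

    def test_closed_form_all_ranks(self):
        m = 24
        th = sidak_thresholds(m)
        for i in range(m):
            assert th[i] == pytest.approx(1 - 0.95 ** (1 / (m - i)),
                                          abs=1e-12)

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=24),
           st.floats(0.01, 0.1))
    @settings(max_examples=200, deadline=None)
    def test_matches_bruteforce_stepdown(self, pvals, alpha):
        p = np.asarray(pvals)
        reject, p_adj = holm_sidak(p, alpha)
        # brute-force enumeration of the step-down procedure
        m = p.size
        order = np.argsort(p, kind="stable")
        expected = np.zeros(m, dtype=bool)
        for rank, idx in enumerate(order):
            threshold = 1 - (1 - alpha) ** (1 / (m - rank))
            if p[idx] < threshold:
                expected[idx] = True
            else:
                break
        assert np.array_equal(reject, expected)
        # adjusted p values are monotone in raw p
        srt = np.argsort(p, kind="stable")
        assert np.all(np.diff(p_adj[srt]) >= -1e-12)

    @given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=24))
    @settings(max_examples=100, deadline=None)
    def test_never_rejects_where_unadjusted_would_not(self, pvals):
        p = np.asarray(pvals)
        reject, _ = holm_sidak(p, 0.05)
        assert not np.any(reject & (p >= 0.05))


class TestIdealModel:
    def test_exact_linear_recovery(self):
        rng = np.random.default_rng(5)
        ph = rng.uniform(6, 8, 30)
        bsa = rng.uniform(4, 16, 30)
        y = 2 * ph + 0.5 * bsa - 10
        fit = fit_ideal_model(ph, bsa, y)
        assert fit.alpha == pytest.approx(2.0, abs=1e-10)
        assert fit.beta == pytest.approx(0.5, abs=1e-10)
        assert fit.epsilon == pytest.approx(-10.0, abs=1e-8)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_null_specificity(self, rng):
        # metric varies with something other than pH/BSA
        n = 40
        ph = np.concatenate([np.full(n // 2, 7.4), rng.uniform(6, 8, n // 2)])
        bsa = np.concatenate([rng.uniform(4, 16, n // 2), np.full(n // 2, 8.0)])
        y = rng.normal(0, 1, n)  # pure noise
        fit = fit_ideal_model(ph, bsa, y)
        assert fit.r_squared < 0.3

    def test_scale_equivariance(self, rng):
        ph = rng.uniform(6, 8, 25)
        bsa = rng.uniform(4, 16, 25)
        y = 1.2 * ph - 0.3 * bsa + rng.normal(0, 0.5, 25)
        a = fit_ideal_model(ph, bsa, y)
        b = fit_ideal_model(ph, bsa, 3.0 * y)
        assert b.alpha == pytest.approx(3 * a.alpha)
        assert b.beta == pytest.approx(3 * a.beta)
        assert b.epsilon == pytest.approx(3 * a.epsilon)
        assert b.r_squared == pytest.approx(a.r_squared, abs=1e-12)

    def test_rank_deficiency_rejected(self):
        with pytest.raises(InvalidInputError):
            fit_ideal_model([7, 7, 7], [8, 8, 8], [1, 2, 3])


class TestDeltaCest:
    @pytest.mark.parametrize("a,sa,b,sb,delta,sigma,sig", [
        (2.0, 0.3, 1.0, 0.4, 1.0, 0.5, True),
        (2.0, 1.0, 1.5, 1.0, 0.5, np.sqrt(2), False),
        (1.7, 0.2, 1.7, 0.2, 0.0, np.sqrt(0.08), False),
    ])
    def test_quadrature_rule(self, a, sa, b, sb, delta, sigma, sig):
        d, s, significant = delta_cest_significance(a, sa, b, sb)
        assert d == pytest.approx(delta)
        assert s == pytest.approx(sigma)
        assert significant is sig


class TestDeltaPH:
    def test_unit_ph_difference(self):
        fit = fit_ideal_model([6, 7, 8, 7, 7], [8, 8, 8, 4, 12],
                              [12, 14, 16, 12, 16])
        assert delta_ph(fit.alpha, 0.0, fit) == pytest.approx(1.0)

    def test_bsa_only_difference_maps_to_zero(self):
        fit = fit_ideal_model([6, 7, 8, 7, 7], [8, 8, 8, 4, 12],
                              [12, 14, 16, 12, 16])
        assert delta_ph(fit.beta * 4.0, 4.0, fit) == pytest.approx(0.0)

    def test_zero_alpha_rejected(self):
        from cestkit.compare import IdealModelFit

        fit = IdealModelFit("m", 0.0, 1.0, 0.0, 0.5)
        with pytest.raises(InvalidInputError):
            delta_ph(1.0, 0.0, fit)

    def test_forward_inverse_identity(self, rng):
        """Generating effects from known (pH, BSA) with the ideal model
        and inverting pairwise differences recovers the pH differences to
        floating-point precision."""
        ph = rng.uniform(6, 8, 20)
        bsa = rng.uniform(4, 16, 20)
        alpha, beta, eps = -4.2, 0.31, 35.0
        y = alpha * ph + beta * bsa + eps
        fit = fit_ideal_model(ph, bsa, y)
        for i in range(0, 18, 3):
            d_cest = y[i] - y[i + 1]
            d_bsa = bsa[i] - bsa[i + 1]
            recovered = delta_ph(d_cest, d_bsa, fit)
            assert recovered == pytest.approx(ph[i] - ph[i + 1], abs=1e-10)


class TestSignAccuracy:
    def _result(self, calc, exp, significant=True):
        return DeltaPHResult("a", "b", 1.0, 0.1, significant, calc, exp)

    def test_all_correct(self):
        results = [self._result(-1.0, -1.0), self._result(1.0, 0.9),
                   self._result(0.2, 0.3)]
        out = sign_accuracy(results)
        assert out["below"]["accuracy"] == 1.0
        assert out["above"]["accuracy"] == 1.0
        assert out["within"]["accuracy"] == 1.0

    def test_inverted_predictions(self):
        results = [self._result(1.0, -1.0), self._result(-0.9, 0.8)]
        out = sign_accuracy(results)
        assert out["below"]["accuracy"] == 0.0
        assert out["above"]["accuracy"] == 0.0

    def test_insignificant_pairs_excluded_and_empty_group_none(self):
        results = [self._result(-1.0, -1.0, significant=False)]
        out = sign_accuracy(results)
        assert out["below"]["n"] == 0
        assert out["below"]["accuracy"] is None
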