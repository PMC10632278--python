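"""Herd immunity levels h_C and h~_D, closed forms and ordering results."""

import math

import numpy as np
import pytest

from hhepi import (
    ExponentialLaw,
    R_star,
    common_size,
    geometric_size_biased,
    h_C,
    h_C_highly_local,
    h_tilde_D,
    h_tilde_D_highly_local,
    lambda_G_star_two_sizes,
    ordering_high_global,
    ordering_just_supercritical,
    argmax_difference_over_lambda_G,
    two_point_tilde,
    weak_local_difference,
)


class TestVaccineInducedLevel:
    def test_homogeneous_sixty_percent(self, exp1):
        res = h_C(common_size(1), 2.5, 0.0, exp1)
        assert res.level == pytest.approx(0.6, abs=1e-12)

    def test_subcritical_flagged(self, exp1):
        res = h_C(common_size(3), 0.1, 1.0, exp1)
        assert res.level == 0.0 and res.subcritical

    def test_no_local_spread_homogeneous_formula(self, exp1, mix14):
        res = h_C(mix14, 2.0, 0.0, exp1)
        assert res.level == pytest.approx(0.5, abs=1e-10)

    def test_infinite_rate_closed_form_matches_bisection(self, exp1, mix14):
        for lam_G in (0.8, 1.5, 3.0):
            closed = h_C_highly_local(mix14, lam_G, exp1)
            general = h_C(mix14, lam_G, math.inf, exp1).level
            assert general == pytest.approx(closed, abs=1e-10)

    def test_pair_closed_form_value(self, exp1):
        # common n=2, lambda_G = E[T_I] = 1: h_C = 1 - (sqrt(5)-1)/2
        got = h_C_highly_local(common_size(2), 1.0, exp1)
        assert got == pytest.approx(1.0 - (math.sqrt(5.0) - 1.0) / 2.0, abs=1e-12)

    def test_residual_reproduction_at_solution(self, exp1, mix14):
        res = h_C(mix14, 2.0, 1.5, exp1)
        assert res.residual_R == pytest.approx(1.0, abs=1e-9)


class TestDiseaseInducedLevel:
    def test_no_local_spread_homogeneous(self, exp1):
        res = h_tilde_D(common_size(4), 2.0, 0.0, exp1)
        assert res.level == pytest.approx(0.5, abs=1e-10)

    def test_common_size_infinite_rate_closed_form(self, exp1):
        for n, lam_G in ((2, 1.5), (4, 0.8)):
            res = h_tilde_D(common_size(n), lam_G, math.inf, exp1)
            assert res.level == pytest.approx(1.0 - 1.0 / (n * lam_G), abs=1e-10)

    def test_general_matches_highly_local_branch(self, exp1, mix14):
        a = h_tilde_D(mix14, 1.5, math.inf, exp1)
        b = h_tilde_D_highly_local(mix14, 1.5, exp1)
        assert a.level == pytest.approx(b.level, abs=1e-12)

    def test_geometric_tilde_equals_h_C_for_all_rates(self, exp1):
        # the hallmark of a geometric size-biased law (logarithmic households)
        d = geometric_size_biased(2.5, n_max=60)
        for lam_G in (0.6, 1.0, 2.0, 5.0):
            ht = h_tilde_D_highly_local(d, lam_G, exp1).level
            hc = h_C_highly_local(d, lam_G, exp1)
            assert ht == pytest.approx(hc, abs=1e-9)

    def test_diagnostics_self_consistent(self, exp1):
        d = common_size(3)
        res = h_tilde_D(d, 2.0, 1.0, exp1)
        assert res.kappa_hat is not None and 1.0 / R_star(d, 2.0, 1.0, exp1) < res.kappa_hat < 1.0
        assert res.residual_R == pytest.approx(1.0, abs=1e-8)
        assert res.pi == pytest.approx(math.exp(-res.kappa_hat * 2.0 * res.z), abs=1e-10)

    def test_subcritical_flagged(self, exp1):
        res = h_tilde_D(common_size(2), 0.2, 1.0, exp1)
        assert res.level == 0.0 and res.subcritical


class TestCommonSizeInequality:
    @pytest.mark.parametrize("n", [2, 3, 4, 5, 6])
    def test_highly_local_h_tilde_exceeds_h_C(self, exp1, n):
        # closed forms, any supercritical lambda_G
        d = common_size(n)
        for R in (1.2, 2.0, 5.0, 20.0):
            lam_G = R / n
            assert h_tilde_D_highly_local(d, lam_G, exp1).level > h_C_highly_local(d, lam_G, exp1)

    @pytest.mark.parametrize("n", [2, 3])
    @pytest.mark.parametrize("lam_L", [0.25, 1.0, 4.0, 8.0])
    def test_general_solvers_preserve_inequality(self, exp1, n, lam_L):
        from hhepi import single_household_mean_size

        d = common_size(n)
        mu_n = single_household_mean_size(n, lam_L, exp1.phi)
        for R in (1.5, 4.0, 10.0):
            lam_G = R / mu_n
            ht = h_tilde_D(d, lam_G, lam_L, exp1).level
            hc = h_C(d, lam_G, lam_L, exp1).level
            assert ht > hc


class TestTwoSizesCrossover:
    def test_no_crossover_cases(self):
        assert lambda_G_star_two_sizes(2, 0.5) is None
        assert lambda_G_star_two_sizes(3, 0.25) is None  # boundary (n-2)/(2(n-1))

    def test_sign_change_brackets_crossover(self, exp1):
        lam_star = lambda_G_star_two_sizes(4, 0.5)
        assert lam_star is not None
        d = two_point_tilde(4, 0.5)
        below = h_tilde_D_highly_local(d, 0.95 * lam_star, exp1).level - h_C_highly_local(
            d, 0.95 * lam_star, exp1
        )
        above = h_tilde_D_highly_local(d, 1.05 * lam_star, exp1).level - h_C_highly_local(
            d, 1.05 * lam_star, exp1
        )
        assert below > 0 > above

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            lambda_G_star_two_sizes(4, 0.0)


class TestOrderingClassifiers:
    def test_common_size_just_supercritical(self):
        v = ordering_just_supercritical(common_size(5).size_biased())
        assert v.verdict == "h_tilde_D > h_C" and v.witness_index == 2

    def test_geometric_equality(self):
        sb = geometric_size_biased(2.0, 30).size_biased()
        assert ordering_just_supercritical(sb).verdict == "equality"
        assert ordering_high_global(sb).verdict == "equality"

    def test_two_point_seventeen_moment_arithmetic(self):
        # alpha~_1 = alpha~_7 = 0.5: var = 9 < E[H~] E[H~-1] = 12
        sb = two_point_tilde(7, 0.5).size_biased()
        v = ordering_just_supercritical(sb)
        assert v.verdict == "h_tilde_D > h_C"
        assert sb.var == pytest.approx(9.0) and sb.mean * (sb.mean - 1.0) == pytest.approx(12.0)

    def test_common_size_high_global(self):
        v = ordering_high_global(common_size(4).size_biased())
        assert v.verdict == "h_tilde_D > h_C" and v.witness_index == 4

    def test_small_p_mixture_high_global_reverses(self):
        # {1, n>=3} mixtures are dominated by singletons at high lambda_G
        v = ordering_high_global(two_point_tilde(4, 0.2).size_biased())
        assert v.verdict == "h_tilde_D < h_C" and v.witness_index == 2

    def test_verdicts_match_direct_numerics_near_threshold(self, exp1):
        # just-supercritical: compare levels at R_* = 1.02 in the inf regime
        for d in (common_size(3), two_point_tilde(4, 0.2)):
            sb = d.size_biased()
            v = ordering_just_supercritical(sb)
            lam_G = 1.02 / sb.mean
            diff = h_tilde_D_highly_local(d, lam_G, exp1).level - h_C_highly_local(d, lam_G, exp1)
            if v.verdict == "h_tilde_D > h_C":
                assert diff > 0
            else:
                assert diff < 0


class TestWeakLocalExpansion:
    def test_vanishes_on_critical_curve(self):
        # var(H~) = E[H~ - 1] kills the leading term
        sb = type("SB", (), {"mean": 3.0, "var": 2.0})()
        assert weak_local_difference(sb, 2.0, 0.1) == 0.0

    def test_common_size_positive(self):
        sb = common_size(4).size_biased()
        assert weak_local_difference(sb, 1.5, 0.05) > 0

    def test_subcritical_rejected(self):
        sb = common_size(4).size_biased()
        with pytest.raises(ValueError):
            weak_local_difference(sb, 0.9, 0.1)

    def test_corollary_sign_matches_direct_numerics_small_lambda_L(self, exp1):
        lam_L, lam_G = 0.05, 2.0
        for d in (common_size(3), two_point_tilde(5, 0.5)):
            sb = d.size_biased()
            lead = weak_local_difference(sb, lam_G, lam_L)
            diff = h_tilde_D(d, lam_G, lam_L, exp1).level - h_C(d, lam_G, lam_L, exp1).level
            assert np.sign(lead) == np.sign(diff)

    def test_second_order_decay_of_remainder(self, exp1):
        # |(h~_D - h_C) - leading term| = o(lambda_L^2)
        d = common_size(3)
        sb = d.size_biased()
        resid = []
        for lam_L in (0.1, 0.05, 0.025):
            diff = h_tilde_D(d, 2.0, lam_L, exp1).level - h_C(d, 2.0, lam_L, exp1).level
            resid.append(abs(diff - weak_local_difference(sb, 2.0, lam_L)) / lam_L**2)
        assert resid[1] < 0.65 * resid[0]
        assert resid[2] < 0.65 * resid[1]


class TestArgmaxOverLambdaG:
    def test_highly_local_common_size_maximiser(self, exp1):
        # lambda_G = 4/((1+n) E[T_I]) and R0 = 2 at the maximum
        lam_hat, r0 = argmax_difference_over_lambda_G(common_size(4), math.inf, exp1)
        assert lam_hat == pytest.approx(4.0 / 5.0, abs=1e-5)
        assert r0 == pytest.approx(2.0, abs=1e-5)

    def test_flat_objective_rejected(self, exp1):
        with pytest.raises(ValueError):
            argmax_difference_over_lambda_G(common_size(3), 0.0, exp1)
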