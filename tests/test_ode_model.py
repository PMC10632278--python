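"""Deterministic limit ODEs, h_D, restriction scenarios and profiles."""

import math

import numpy as np
import pytest

from hhepi import (
    ExponentialLaw,
    HouseholdODESystem,
    build_state_space,
    common_size,
    final_size,
    h_D,
    h_D_L,
    h_hat_D,
    h_tilde_D,
    initial_condition,
    integrate,
    susceptible_household_profile,
    two_point_tilde,
    R_star,
)
from hhepi.ode_model import HouseholdStateDensity


class TestStateSpace:
    @pytest.mark.parametrize(
        "n_max,model,count",
        [(1, "SIR", 3), (2, "SIR", 9), (2, "SEIR", 14), (3, "SIR", 19), (3, "SEIR", 34)],
    )
    def test_enumeration_counts(self, n_max, model, count):
        states = build_state_space(n_max, model)
        assert len(states) == count
        assert len(set(states)) == count  # no duplicates
        assert all(1 <= sum(st) <= n_max for st in states)

    def test_sir_slice_has_no_exposed(self):
        assert all(st[1] == 0 for st in build_state_space(4, "SIR"))


class TestInitialCondition:
    def test_seeding_of_largest_households(self):
        d = common_size(4)
        ic = initial_condition(d, 1e-5)
        h = ic.as_dict()
        assert h[(3, 0, 1, 0)] == pytest.approx(1e-5)
        assert h[(4, 0, 0, 0)] == pytest.approx(1.0 - 1e-5)

    def test_per_size_mass_conserved(self, mix14):
        ic = initial_condition(mix14, 1e-6)
        assert ic.size_mass(1) == pytest.approx(mix14.probs[0], abs=1e-15)
        assert ic.size_mass(4) == pytest.approx(mix14.probs[3], abs=1e-15)

    def test_oversized_epsilon_rejected(self, mix14):
        with pytest.raises(ValueError):
            initial_condition(mix14, 0.5)  # alpha_4 = 0.2


class TestDerivative:
    def test_fully_susceptible_is_stationary(self, mix14):
        system = HouseholdODESystem(mix14, 2.0, 1.0, 1.0)
        ic = initial_condition(mix14, 0.0)
        np.testing.assert_allclose(system.derivative(ic), 0.0, atol=1e-15)

    def test_size1_reduces_to_homogeneous_sir(self):
        d = common_size(1)
        lam_G, gamma = 2.0, 0.7
        system = HouseholdODESystem(d, lam_G, 0.0, gamma)
        idx = system.index
        h = np.zeros(3)
        h[idx[(1, 0, 0, 0)]] = 0.6
        h[idx[(0, 0, 1, 0)]] = 0.3
        h[idx[(0, 0, 0, 1)]] = 0.1
        dh = system.rhs(1.0)(0.0, h)
        s, i = 0.6, 0.3
        assert dh[idx[(1, 0, 0, 0)]] == pytest.approx(-lam_G * i * s)
        assert dh[idx[(0, 0, 1, 0)]] == pytest.approx(lam_G * i * s - gamma * i)
        assert dh[idx[(0, 0, 0, 1)]] == pytest.approx(gamma * i)

    def test_per_size_mass_derivative_zero(self, mix14):
        system = HouseholdODESystem(mix14, 2.0, 1.5, 1.0, delta=2.0)
        rng = np.random.default_rng(0)
        h = rng.random(len(system.states))
        dh = system.rhs(1.0)(0.0, h)
        for n in (1, 4):
            mask = np.array([sum(st) == n for st in system.states])
            assert dh[mask].sum() == pytest.approx(0.0, abs=1e-12)


class TestIntegration:
    def test_subcritical_epidemic_fizzles(self, exp1):
        d = common_size(2)
        traj = integrate(d, 0.3, 0.5, 1.0, epsilon=1e-6)
        assert 1.0 - traj.S[-1] < 1e-4
        assert traj.T_star is None

    def test_final_size_matches_analytic_fixed_point(self, exp1):
        d = common_size(3)
        traj = integrate(d, 2.0, 1.0, 1.0, epsilon=1e-7)
        z = final_size(d, 2.0, 1.0, exp1).z
        assert 1.0 - traj.S[-1] == pytest.approx(z, abs=1e-4)

    def test_seir_final_size_latency_invariant(self, exp1):
        d = common_size(2)
        traj = integrate(d, 2.5, 1.5, 1.0, delta=0.8, epsilon=1e-7)
        z = final_size(d, 2.5, 1.5, exp1).z
        assert 1.0 - traj.S[-1] == pytest.approx(z, abs=1e-4)

    def test_mass_conservation_and_monotone_summaries(self, mix14):
        traj = integrate(mix14, 2.0, 1.0, 1.0, epsilon=1e-5)
        for n, alpha in ((1, mix14.probs[0]), (4, mix14.probs[3])):
            mask = np.array([sum(st) == n for st in traj.states])
            drift = np.abs(traj.densities[mask].sum(axis=0) - alpha).max()
            assert drift < 1e-8
        assert np.all(np.diff(traj.S) <= 1e-12)
        assert np.all(np.diff(traj.R_V) <= 1e-9)

    def test_R_V_starts_at_R_star(self, exp1, mix14):
        traj = integrate(mix14, 2.0, 1.0, 1.0, epsilon=1e-7)
        assert traj.R_V[0] == pytest.approx(R_star(mix14, 2.0, 1.0, exp1), rel=1e-4)


class TestResidualThreshold:
    def test_fully_recovered_population_is_zero(self, exp1):
        d = common_size(2)
        system = HouseholdODESystem(d, 2.0, 1.0, 1.0)
        h = np.zeros(len(system.states))
        h[system.index[(0, 0, 0, 2)]] = 1.0
        assert system.R_V_of(h) == 0.0

    def test_all_or_nothing_state_matches_pgf_expression(self, exp1):
        # households either untouched or fully removed, as at lambda_L = inf
        d = two_point_tilde(4, 0.5)
        system = HouseholdODESystem(d, 1.2, 50.0, 1.0)
        pi = 0.7
        h = np.zeros(len(system.states))
        for n in (1, 4):
            h[system.index[(n, 0, 0, 0)]] = d.probs[n - 1] * pi**n
            h[system.index[(0, 0, 0, n)]] = d.probs[n - 1] * (1.0 - pi**n)
        sb = d.size_biased()
        # with lambda_L large, mu_s ~ s: R_V ~ lambda_G E[T_I] sum n alpha~_n pi^n
        expect = 1.2 * sum(n * sb.probs[n - 1] * pi**n for n in sb.sizes)
        assert system.R_V_of(h) == pytest.approx(expect, rel=5e-3)


class TestDiseaseInducedLevels:
    def test_no_local_spread_matches_homogeneous(self, exp1):
        res = h_D(common_size(2), 2.0, 0.0, 1.0, epsilon=1e-7)
        assert res.level == pytest.approx(0.5, abs=1e-5)

    def test_level_below_final_epidemic_size(self, exp1):
        d = common_size(3)
        traj = integrate(d, 2.0, 1.0, 1.0)
        res = h_D(d, 2.0, 1.0, 1.0)
        assert res.level < 1.0 - traj.S[-1]

    def test_epsilon_robustness(self):
        d = common_size(3)
        a = h_D(d, 2.0, 1.0, 1.0, epsilon=1e-5).level
        b = h_D(d, 2.0, 1.0, 1.0, epsilon=1e-6).level
        assert abs(a - b) < 1e-3

    def test_seir_approaches_sir_at_fast_latency(self):
        d = common_size(2)
        sir = h_D(d, 2.5, 1.5, 1.0).level
        seir = h_D_L(d, 2.5, 1.5, 1.0, delta=1e3).level
        assert seir == pytest.approx(sir, abs=2e-3)

    def test_sir_exceeds_seir_level_when_highly_local(self):
        # strong within-household spread: latency decouples household fates
        d = common_size(3)
        sir = h_D(d, 1.2, 12.0, 1.0).level
        seir = h_D_L(d, 1.2, 12.0, 1.0, delta=1.0).level
        assert sir > seir


class TestRestrictions:
    def test_kappa_one_recovers_h_D(self):
        d = common_size(3)
        assert h_hat_D(d, 2.0, 1.0, 1.0, kappa=1.0).level == pytest.approx(
            h_D(d, 2.0, 1.0, 1.0).level, abs=1e-12
        )

    def test_monotone_decreasing_in_kappa_and_limit_to_h_tilde(self, exp1):
        d = common_size(3)
        ht = h_tilde_D(d, 2.0, 1.0, exp1)
        kappas = [ht.kappa_hat * 1.02, 0.7, 1.0]
        levels = [h_hat_D(d, 2.0, 1.0, 1.0, kappa=k).level for k in kappas]
        assert levels[0] > levels[1] > levels[2]
        assert levels[0] == pytest.approx(ht.level, abs=5e-3)

    def test_excessive_restrictions_rejected(self, exp1):
        d = common_size(3)
        ht = h_tilde_D(d, 2.0, 1.0, exp1)
        with pytest.raises(RuntimeError):
            h_hat_D(d, 2.0, 1.0, 1.0, kappa=0.9 * ht.kappa_hat)
        with pytest.raises(ValueError):
            h_hat_D(d, 2.0, 1.0, 1.0, kappa=1.4)


class TestSusceptibleProfile:
    def test_binomial_profile_without_local_spread(self):
        # common size 4, R0 = lambda_G = 2, p_L = 0: profile at herd immunity
        # is Bin(4, S(T_*)) with S(T_*) = 1/2
        d = common_size(4)
        traj = integrate(d, 2.0, 0.0, 1.0, epsilon=1e-7)
        assert traj.T_star is not None
        at = traj.sol.sol(traj.T_star)
        density = HouseholdStateDensity(states=traj.states, values=at, time=traj.T_star)
        prof = susceptible_household_profile(density, size=4)
        from scipy.stats import binom

        np.testing.assert_allclose(prof, binom.pmf(np.arange(5), 4, 0.5), atol=2e-4)

    def test_all_or_nothing_state(self):
        states = ((2, 0, 0, 0), (0, 0, 0, 2), (1, 0, 1, 0))
        density = HouseholdStateDensity(states=states, values=np.array([0.3, 0.7, 0.0]))
        prof = susceptible_household_profile(density)
        np.testing.assert_allclose(prof, [0.7, 0.0, 0.3], atol=1e-15)
        assert prof.sum() == pytest.approx(1.0)
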