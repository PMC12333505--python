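"""Closed-form layer: formula values, identities, domain errors, and
cross-checks against independent numerical oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from ecoresist import (
    FitnessProfile,
    UniformEffect,
    WFParams,
    classify_regime,
    coexistence_fixed_point,
    mutant_fitness,
    n_mut_eco,
    n_mut_eco_small_mu,
    n_mut_noeco,
    run_replicates,
    stationary_density,
    stationary_mean_mutants,
    tau_approx,
)
from ecoresist.analytics import n_mut_eco_selfconsistent


class TestTauApprox:
    @pytest.mark.parametrize(
        "fe,expected,tol",
        [
            (0.0, 0.0, 1e-15),
            (0.5, 3 * np.log(0.5) / (0.25 - 3.0), 1e-12),
            (1e-6, 1e-6, 1e-5 * 1e-6),  # leading order: tau ~ fe
        ],
    )
    def test_values(self, fe, expected, tol):
        assert tau_approx(fe) == pytest.approx(expected, abs=tol)

    def test_direct_value_at_half(self):
        assert tau_approx(0.5) == pytest.approx(0.756161, abs=5e-7)

    def test_domain_errors(self):
        for fe in (1.0, 1.2, -0.1):
            with pytest.raises(ValueError):
                tau_approx(fe)

    @pytest.mark.parametrize("fe", [0.3, 0.5, 0.8, 0.95])
    def test_close_to_poisson_branching_oracle(self, fe):
        """Independent oracle: exact E[tau] of a subcritical Galton-Watson
        process with Poisson(fe) offspring, via the generating-function
        recursion E[tau] = sum_t P(tau >= t)."""
        q = 0.0
        expected = 0.0
        for _ in range(100_000):
            q_next = np.exp(fe * (q - 1.0))
            expected += 1.0 - q_next
            q = q_next
            if 1.0 - q < 1e-14:
                break
        assert tau_approx(fe) == pytest.approx(expected, rel=0.08)

    def test_vectorized_nonnegative_and_diverging(self):
        fe = np.linspace(0.0, 0.999999, 200)
        tau = tau_approx(fe)
        assert tau.shape == fe.shape
        assert np.all(tau >= 0)
        assert np.all(np.diff(tau) > 0)


class TestExpectedMutantNumbers:
    def test_noeco_values(self):
        assert n_mut_noeco(1e4, 1e-4, 0.25) == pytest.approx(0.848392, abs=5e-7)
        assert n_mut_noeco(1e4, 1e-4, 0.5) == pytest.approx(0.386294, abs=5e-7)

    def test_noeco_limits_and_domain(self):
        assert n_mut_noeco(1e4, 1e-4, 1.0) == pytest.approx(0.0, abs=1e-12)
        assert n_mut_noeco(1e4, 1e-4, 0.999) == pytest.approx(0.0, abs=1e-3)
        with pytest.raises(ValueError):
            n_mut_noeco(1e4, 1e-4, 0.0)
        assert n_mut_noeco(1e4, 1e-4, 0.1) > n_mut_noeco(1e4, 1e-4, 0.5)

    def test_eco_small_mu_value(self):
        assert n_mut_eco_small_mu(1e4, 1e-4, 0.99) == pytest.approx(
            3.651687, abs=5e-7
        )

    def test_eco_small_mu_domain(self):
        for fmax in (1.0, 1.3):
            with pytest.raises(ValueError):
                n_mut_eco_small_mu(1e4, 1e-4, fmax)

    @given(
        nmu=st.floats(1e-4, 10.0),
        fmax=st.floats(0.01, 0.995),
    )
    @settings(max_examples=100, derandomize=True)
    def test_substitution_identity(self, nmu, fmax):
        """With eco, fmax plays exactly the role 1-fc plays without."""
        N, mu = 1e6, nmu / 1e6
        assert n_mut_eco_small_mu(N, mu, fmax) == pytest.approx(
            n_mut_noeco(N, mu, 1.0 - fmax), rel=1e-12
        )

    def test_eco_to_noeco_ratio_independent_of_Nmu(self):
        r1 = n_mut_eco_small_mu(1e4, 1e-6, 0.99) / n_mut_noeco(1e4, 1e-6, 0.25)
        r2 = n_mut_eco_small_mu(1e7, 1e-5, 0.99) / n_mut_noeco(1e7, 1e-5, 0.25)
        assert r1 == pytest.approx(r2, rel=1e-12)


class TestLambertWForm:
    def test_matches_small_mu_form_at_tiny_mu(self):
        a = n_mut_eco(1e4, 1e-8, 0.25, 0.99, method="lambertw")
        b = n_mut_eco_small_mu(1e4, 1e-8, 0.99)
        assert abs(a - b) / b < 0.01

    def test_auto_switch_is_continuous(self):
        lo = n_mut_eco(1e4, 0.99e-6, 0.25, 0.99)
        hi = n_mut_eco(1e4, 1.01e-6, 0.25, 0.99)
        assert abs(hi - lo) / lo < 0.05

    @pytest.mark.parametrize("mu", [1e-5, 1e-4, 1e-3, 1e-2])
    def test_matches_exact_selfconsistent_balance(self, mu):
        """Closed form vs the numerically solved deterministic balance."""
        closed = n_mut_eco(1e3, mu, 0.25, 0.99, method="lambertw")
        exact = n_mut_eco_selfconsistent(1e3, mu, 0.25, 0.99)
        assert abs(closed - exact) / exact < 0.01

    def test_monotone_in_mu(self):
        mus = np.geomspace(1e-6, 1e-2, 20)
        vals = n_mut_eco(1e3, mus, 0.25, 0.99)
        assert np.all(np.diff(vals) > 0)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            n_mut_eco(1e3, 1e-3, 0.25, 1.0)
        with pytest.raises(ValueError):
            n_mut_eco(1e3, 0.2, 0.25, 0.99)
        with pytest.raises(ValueError):
            n_mut_eco(1e3, 1e-3, 0.0, 0.99)

    def test_noeco_balance_matches_constant_fitness_simulation(self):
        """No-ecology formula vs lineages whose fitness is fi at all times."""
        reps = run_replicates(
            WFParams(
                N=500, mu=2e-3, generations=40_000, fc=0.25,
                burn_in=2000, ecology=False,
            ),
            6,
            seed=53,
        )
        sims = [stationary_mean_mutants(r) for r in reps]
        sim, se = np.mean(sims), np.std(sims, ddof=1) / np.sqrt(len(sims))
        pred = n_mut_noeco(500, 2e-3, 0.25)
        assert abs(sim - pred) < 3 * max(se, 0.02 * pred)


class TestStationaryDensity:
    def test_zero_at_fe_zero(self):
        assert stationary_density(0.0, 1e-3, UniformEffect(0, 0.99)) == 0.0

    def test_uniform_dee_value(self):
        val = stationary_density(0.5, 1e-3, UniformEffect(0, 0.99))
        assert val == pytest.approx(1.0101e-3, rel=1e-4)

    def test_integral_identity_with_expected_mutant_number(self):
        """integral of P(fe) dfe == n_mut_eco_small_mu / N exactly."""
        mu, fmax, N = 1e-4, 0.99, 1e4
        dee = UniformEffect(0.0, fmax)
        integral, _ = quad(lambda x: stationary_density(x, mu, dee), 0, fmax)
        assert integral == pytest.approx(
            n_mut_eco_small_mu(N, mu, fmax) / N, rel=1e-8
        )

    def test_domain_error_at_fe_one(self):
        with pytest.raises(ValueError):
            stationary_density(1.0, 1e-3, UniformEffect(0, 0.99))


class TestRegimeClassification:
    @pytest.mark.parametrize(
        "Nmu,expected",
        [
            (1e-3, "small-Nmu"),
            (0.5, "rare-mutant"),
            (2.0, "many-mutant"),
        ],
    )
    def test_three_regimes(self, Nmu, expected):
        report = classify_regime(1e6, Nmu / 1e6, 0.25, 0.99)
        assert report.regime == expected

    def test_reported_counts_match_formulas(self):
        report = classify_regime(1e6, 5e-7, 0.25, 0.99)
        assert report.n_mut_noeco == pytest.approx(0.424196, abs=1e-5)
        assert report.n_mut_eco == pytest.approx(1.825843, rel=1e-3)


class TestCoexistenceFixedPoint:
    @pytest.mark.parametrize(
        "fi,fe,expected",
        [
            (0.8, 1.1, 2.0 / 3.0),
            (0.9, 1.05, 2.0 / 3.0),  # different profile, same equilibrium
            (0.75, 0.99, None),  # fe <= 1: ancestor wins at all frequencies
        ],
    )
    def test_fixed_point_values(self, fi, fe, expected):
        out = coexistence_fixed_point(FitnessProfile(fi, fe))
        if expected is None:
            assert out is None
        else:
            assert out == pytest.approx(expected, rel=1e-12)

    @given(fi=st.floats(0.0, 0.99), fe=st.floats(1.0001, 1.5))
    @settings(max_examples=100, derandomize=True)
    def test_fixed_point_solves_equal_growth(self, fi, fe):
        profile = FitnessProfile(fi, fe)
        x_star = coexistence_fixed_point(profile)
        assert 0.0 < x_star < 1.0
        assert mutant_fitness(profile, x_star) == pytest.approx(1.0, abs=1e-9)
        # stability: mutant favored when rarer than equilibrium
        assert mutant_fitness(profile, min(x_star + 0.01, 1.0)) > 1.0
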