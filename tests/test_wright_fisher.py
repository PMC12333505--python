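"""Lineage-tracking Wright-Fisher simulator: conservation, determinism,
extinction-time recording, neutral drift, and stationary summaries."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import spearmanr

from ecoresist import (
    FitnessProfile,
    MoranSpec,
    UniformEffect,
    WFParams,
    absorption_probabilities,
    extinction_time_curve,
    run,
    run_replicates,
    simulate_fixation,
    stationary_fe_histogram,
    stationary_mean_mutants,
    tau_approx,
)
from ecoresist.wright_fisher import WFState, wf_generation


class TestGeneration:
    def test_no_mutation_leaves_pure_ancestor_population_unchanged(self):
        params = WFParams(N=200, mu=0.0, generations=50, seed=3)
        result = run(params)
        assert result.n_lineages == 0
        assert np.all(result.mutant_totals == 0)
        assert np.all(result.ancestor_totals == 200)

    def test_population_size_conserved_every_generation(self):
        params = WFParams(
            N=100,
            mu=0.02,
            generations=300,
            fc=0.25,
            dee=UniformEffect(0.0, 0.99),
            seed=5,
            record_trajectories=True,
        )
        result = run(params)
        # rebuild per-generation totals from individual trajectories
        check = np.zeros(params.generations + 1, dtype=int)
        lin = result.lineages
        for lid, traj in result.trajectories.items():
            birth = int(lin.loc[lin["id"] == lid, "birth_generation"].iloc[0])
            check[birth : birth + traj.size] += traj
        assert np.array_equal(check, result.mutant_totals)
        assert np.all(result.mutant_totals + result.ancestor_totals == 100)

    def test_zero_generation_survival_recorded(self):
        # a lineage that leaves no offspring in its first selection step has
        # tau == 0 and still appears in the lineage table
        params = WFParams(
            N=1000, mu=1e-3, generations=2000, fc=0.25,
            dee=UniformEffect(0.0, 0.99), seed=7,
        )
        result = run(params)
        uncensored = result.lineages.loc[~result.lineages["censored"]]
        assert (uncensored["tau"] == 0).any()
        assert result.n_lineages > 0

    def test_generation_op_conserves_and_advances(self, rng):
        params = WFParams(N=500, mu=0.01, generations=10, fc=0.25,
                          dee=UniformEffect(0.0, 0.99))
        state = WFState(500)
        for _ in range(10):
            wf_generation(state, params, rng)
            assert state.anc + state.cnt[: state.L].sum() == 500
        assert state.gen == 10


class TestDeterminism:
    def test_identical_seeds_reproduce_results(self):
        params = WFParams(
            N=500, mu=2e-3, generations=2000, fc=0.25,
            dee=UniformEffect(0.0, 0.99), burn_in=100, seed=42,
        )
        r1, r2 = run(params), run(params)
        assert np.array_equal(r1.mutant_totals, r2.mutant_totals)
        assert r1.lineages.equals(r2.lineages)

    def test_replicates_are_independent_streams(self):
        params = WFParams(
            N=500, mu=2e-3, generations=1000, fc=0.25,
            dee=UniformEffect(0.0, 0.99), seed=42,
        )
        reps = run_replicates(params, 3, seed=9)
        totals = [r.mutant_totals for r in reps]
        assert not np.array_equal(totals[0], totals[1])
        reps2 = run_replicates(params, 3, seed=9)
        for a, b in zip(reps, reps2):
            assert np.array_equal(a.mutant_totals, b.mutant_totals)


class TestNeutralDrift:
    def test_neutral_fixation_probability_matches_moran_one_over_N(self):
        """A neutral lineage starting at one copy fixes with prob 1/N."""
        N = 100
        out = simulate_fixation(
            N, FitnessProfile(fi=1.0, fe=1.0), s0=1, replicates=100_000, seed=17
        )
        assert out["n_pending"] == 0
        p_neutral = absorption_probabilities(MoranSpec(N=N, fc=0.0, fe=1.0, s0=1))[1]
        assert p_neutral == pytest.approx(1 / N, rel=1e-12)
        assert abs(out["p_fix"] - 1 / N) < 3 * np.sqrt((1 / N) * (1 - 1 / N) / 100_000)


class TestExtinctionTimeCurve:
    def test_high_fe_bin_matches_formula_bin_average(self, wf_tau_run):
        """Mean tau in fe [0.99, 1) agrees with the averaged closed form."""
        curve = extinction_time_curve(wf_tau_run, [0.99, 1.0])
        row = curve.iloc[0]
        hi = 1.0 - 5e-7  # integrable log divergence; truncation error ~1e-5
        expected = quad(tau_approx, 0.99, hi)[0] / (hi - 0.99)
        # within 3 SE of the analytic bin average (~8.4 generations)
        assert row["n"] > 100
        assert abs(row["mean_tau"] - expected) < 3 * row["se_tau"]

    def test_low_fe_bin_mean_tau_approaches_fe(self, wf_tau_run):
        """For fe -> 0 the mean extinction time tends to fe itself."""
        curve = extinction_time_curve(wf_tau_run, [0.0, 0.02])
        row = curve.iloc[0]
        assert abs(row["mean_tau"] - 0.01) < 3 * max(row["se_tau"], 1e-4)

    def test_curve_rises_monotonically_with_fe(self, wf_tau_run):
        curve = extinction_time_curve(wf_tau_run, np.linspace(0, 1.0, 21))
        ok = curve.dropna(subset=["mean_tau"])
        rho, _ = spearmanr(ok["fe_mid"], ok["mean_tau"])
        assert rho > 0.95

    def test_empty_bins_reported_as_missing(self, wf_tau_run):
        curve = extinction_time_curve(wf_tau_run, [1.5, 1.6])
        assert curve.iloc[0]["n"] == 0
        assert np.isnan(curve.iloc[0]["mean_tau"])

    def test_censored_lineages_counted_separately(self):
        params = WFParams(
            N=2000, mu=1e-3, generations=30, fc=0.0,
            dee=UniformEffect(0.0, 1.0), seed=23,
        )
        result = run(params)  # short run: late high-fe lineages still alive
        assert result.lineages["censored"].sum() > 0
        curve = extinction_time_curve(result, [0.0, 1.0])
        assert curve.iloc[0]["n_censored"] == result.lineages["censored"].sum()


class TestTauDependsOnlyOnFe:
    def test_curves_collapse_across_N_fc_mu(self):
        """Mean tau binned by fe is invariant to N, fc and mu changes."""
        configs = [
            dict(N=1000, mu=1e-3, fc=0.0),
            dict(N=4000, mu=2.5e-4, fc=0.5),
            dict(N=1000, mu=2e-3, fc=0.25),
        ]
        edges = np.linspace(0.0, 0.96, 9)
        curves = []
        for i, cfg in enumerate(configs):
            params = WFParams(
                generations=25_000, dee=UniformEffect(0.0, 1.0), seed=100 + i, **cfg
            )
            curves.append(extinction_time_curve(run(params), edges))
        base = curves[0]
        for other in curves[1:]:
            diff = (base["mean_tau"] - other["mean_tau"]).abs()
            se = np.hypot(base["se_tau"], other["se_tau"])
            assert (diff < 4 * se).all()


class TestStationarySummaries:
    def test_stationary_mean_matches_lambertw_formula(self):
        # N large enough that the dilute-mutant assumption holds in the
        # excursion tail; at much smaller N the simulated mean falls below
        # the closed form (lineage self-crowding during rare excursions)
        from ecoresist import n_mut_eco

        reps = run_replicates(
            WFParams(
                N=10_000, mu=2e-3, generations=30_000, fc=0.25,
                dee=UniformEffect(0.0, 0.99), burn_in=2000,
            ),
            3,
            seed=31,
        )
        sim = np.mean([stationary_mean_mutants(r) for r in reps])
        pred = n_mut_eco(10_000, 2e-3, 0.25, 0.99)
        assert abs(sim - pred) / pred < 0.10

    def test_histogram_person_generations_sum_to_time_average(self):
        params = WFParams(
            N=500, mu=2e-3, generations=20_000, fc=0.25,
            dee=UniformEffect(0.0, 0.99), burn_in=1000, seed=37,
        )
        result = run(params)
        hist = stationary_fe_histogram(result, np.linspace(0, 0.99, 12))
        assert hist["mean_mutants"].sum() == pytest.approx(
            stationary_mean_mutants(result), rel=1e-9
        )

    def test_fe_above_one_reaches_sustained_intermediate_frequency(self):
        """A mutant with fe > 1 hovers at the coexistence fixed point."""
        profile = FitnessProfile(fi=0.8, fe=1.1)
        x_star = 2.0 / 3.0  # ancestor fraction at equilibrium
        reps = run_replicates(
            WFParams(
                N=2000, mu=0.0, generations=1500, burn_in=750,
                initial_lineages=((profile, 200),),
            ),
            4,
            seed=41,
        )
        fracs = [
            r.mutant_totals[751:].mean() / 2000 for r in reps
        ]
        mean_frac = np.mean(fracs)
        se = np.std(fracs, ddof=1) / np.sqrt(len(fracs))
        assert abs(mean_frac - (1 - x_star)) < 3 * max(se, 0.01)
        # sustained intermediate frequency, no sweep and no extinction
        assert 0.05 < mean_frac < 0.95
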