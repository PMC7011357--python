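"""Viterbi decoding (vs exhaustive argmax), stationary distributions and
curves, activity budgets, and pseudo-residual diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import movestates as ms
from movestates import hmm_core as hc
from conftest import brute_force_viterbi


class TestViterbi:
    def test_single_state_all_ones(self):
        em = ms.EmissionParams([0.3], [0.2], [0.0], [1.0])
        tm = ms.TransitionModel(1, (), np.zeros((0, 1)))
        params = ms.HMMParams(em, tm, [1.0])
        series = pd.DataFrame(
            {"burst_id": 0, "step_km": [0.1, 0.2, 0.3], "angle_rad": [np.nan, 0.1, -0.2]}
        )
        v = ms.viterbi(params, series, ms.HMMSpec(1, False, ()))
        assert np.array_equal(v, [1, 1, 1])

    def test_equals_exhaustive_argmax(self, toy_params, full_spec):
        rng = np.random.default_rng(12)
        series = pd.DataFrame(
            {
                "burst_id": 0,
                "step_km": rng.gamma(1.0, 0.2, 8),
                "angle_rad": np.r_[np.nan, rng.vonmises(0, 1, 7)],
                "hour": rng.uniform(0, 24, 8),
                "temp_c": rng.normal(15, 5, 8),
                "hunger_days": rng.uniform(0, 4, 8),
            }
        )
        ours = ms.viterbi(toy_params, series, full_spec)
        oracle = brute_force_viterbi(toy_params, series, full_spec)
        assert np.array_equal(ours, oracle)

    def test_decoding_accuracy_on_separated_states(self):
        em = ms.resident_emissions(zero_mass=False)
        G = ms.persistent_transition([1 / 3, 1 / 3, 1 / 3], 0.8)
        series, truth = ms.simulate_hmm_series(em, G, 4000, seed=21)
        params = ms.HMMParams(em, ms.transition_from_matrix(G), np.ones(3) / 3)
        v = ms.viterbi(params, series, ms.HMMSpec(3, False, ()))
        assert (v == truth).mean() > 0.90

    def test_path_beats_random_paths(self, toy_params, toy_series, full_spec):
        spec = full_spec
        v = ms.viterbi(toy_params, toy_series, spec)
        rng = np.random.default_rng(0)

        def path_logp(path):
            lp = 0.0
            for _, burst in toy_series.groupby("burst_id"):
                ii = burst.index.to_numpy()
                gammas = hc.transition_matrices(
                    toy_params.transition,
                    np.vstack(
                        [hc.build_design(burst, spec.covariates)[:1],
                         hc.build_design(burst, spec.covariates)[:-1]]
                    ),
                )
                dens = [
                    ms.emission_density(
                        path[t], burst["step_km"].loc[t],
                        burst["angle_rad"].loc[t], toy_params.emissions,
                    )
                    for t in ii
                ]
                lp += np.log(toy_params.delta[path[ii[0]] - 1] * dens[0])
                for k in range(1, len(ii)):
                    lp += np.log(
                        gammas[k, path[ii[k - 1]] - 1, path[ii[k]] - 1] * dens[k]
                    )
            return lp

        v_lp = path_logp(v)
        for _ in range(200):
            rnd = rng.integers(1, 4, len(toy_series))
            assert path_logp(rnd) <= v_lp + 1e-9


class TestStationaryDistribution:
    def test_uniform_matrix(self):
        assert np.allclose(ms.stationary_distribution(np.full((3, 3), 1 / 3)), 1 / 3)

    def test_two_state_closed_form(self):
        a, b = 0.3, 0.1
        G = np.array([[1 - a, a], [b, 1 - b]])
        assert np.allclose(
            ms.stationary_distribution(G), [b / (a + b), a / (a + b)], atol=1e-12
        )

    def test_defining_property_and_power_iteration(self):
        rng = np.random.default_rng(4)
        G = rng.dirichlet(np.ones(4), size=4)
        pi = ms.stationary_distribution(G)
        assert np.linalg.norm(pi @ G - pi) < 1e-12
        assert np.allclose(np.linalg.matrix_power(G, 200)[0], pi, atol=1e-10)

    def test_reducible_matrix_names_closed_class(self):
        G = np.array([[1.0, 0.0], [0.5, 0.5]])
        with pytest.raises(ValueError, match="closed class"):
            ms.stationary_distribution(G)


def _quick_fit(covs=("tod", "temperature", "hunger"), n=1500, seed=8):
    sc = ms.default_scenario("non_resident", seed=seed, n_steps=n)
    sim = ms.simulate_track(sc)
    spec = ms.HMMSpec(3, zero_mass=bool((sim["series"]["step_km"] == 0).any()), covariates=covs)
    return ms.fit_hmm(sim["series"], spec, n_starts=3, seed=seed), sim


class TestStationaryCurves:
    @pytest.fixture(scope="class")
    def fitted(self):
        return _quick_fit()

    def test_unknown_covariate_rejected(self, fitted):
        fit, _ = fitted
        with pytest.raises(ValueError):
            ms.stationary_curves(fit, "elevation", [0, 1], n_draws=0)

    def test_rows_sum_to_one_with_bands(self, fitted):
        fit, _ = fitted
        out = ms.stationary_curves(fit, "hunger", np.linspace(0, 5, 7), n_draws=50, seed=0)
        assert np.allclose(out["pi"].sum(axis=1), 1.0, atol=1e-9)
        assert out["lo"].shape == out["pi"].shape
        assert np.all(out["lo"] <= out["pi"] + 1e-9) and np.all(out["pi"] <= out["hi"] + 1e-9)

    def test_no_covariate_model_gives_flat_curves(self):
        em = ms.resident_emissions(zero_mass=False)
        G = ms.persistent_transition([0.4, 0.3, 0.3], 0.75)
        series, _ = ms.simulate_hmm_series(em, G, 800, seed=3)
        fit = ms.fit_hmm(series, ms.HMMSpec(3, False, ()), n_starts=2, seed=3, compute_cov=False)
        pi0 = ms.stationary_distribution(ms.transition_matrix(fit.params.transition))
        # a covariate-free model has no curves; its budget is the single pi
        assert np.allclose(pi0.sum(), 1.0)

    def test_hunger_slope_monotonicity(self):
        # constructed coefficients: hunger pushes every state toward state 3
        beta = np.zeros((6, 1 + 1))
        beta[:, 0] = np.log(0.15 / 0.7)
        pairs = hc._pair_index(3)
        for k, (i, j) in enumerate(pairs):
            if j == 2:
                beta[k, 1] = 1.0
        tm = ms.TransitionModel(3, ("hunger",), beta)
        grid = np.linspace(0, 6, 8)
        pis = np.stack(
            [ms.stationary_distribution(ms.transition_matrix(tm, [z])) for z in grid]
        )
        assert np.all(np.diff(pis[:, 2]) > 0)


class TestActivityBudget:
    def test_single_phase_proportions(self):
        bt = ms.activity_budget(np.array([1, 1, 2, 3]), np.array(["general"] * 4))
        row = bt.loc[("all", "general")]
        assert (row["state_1"], row["state_2"], row["state_3"]) == (0.5, 0.25, 0.25)

    def test_budget_matches_stationary_on_long_chain(self):
        em = ms.resident_emissions(zero_mass=False)
        pi_t = np.array([0.33, 0.20, 0.47])
        G = ms.persistent_transition(pi_t, 0.7)
        _, truth = ms.simulate_hmm_series(em, G, 50_000, seed=9)
        bt = ms.activity_budget(truth, np.array(["general"] * len(truth)))
        pi = ms.stationary_distribution(G)
        got = bt.loc[("all", "general")][["state_1", "state_2", "state_3"]].to_numpy(float)
        assert np.all(np.abs(got - pi) < 0.02)

    def test_caching_subset_and_layout(self):
        states = np.array([1, 1, 1, 2, 3, 3])
        phases = np.array(["caching", "caching", "general", "general", "general", "general"])
        stages = np.array(["resident"] * 6)
        bt = ms.activity_budget(states, phases, life_stages=stages)
        assert set(bt.index) == {("resident", "general"), ("resident", "caching")}
        # general row covers ALL steps; caching row only the caching subset
        assert bt.loc[("resident", "general"), "state_1"] == pytest.approx(0.5)
        assert bt.loc[("resident", "caching"), "state_1"] == pytest.approx(1.0)
        assert np.allclose(bt[["state_1", "state_2", "state_3"]].sum(axis=1), 1.0)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        states = rng.integers(1, 4, 300)
        phases = np.array(["general"] * 300)
        bt = ms.activity_budget(states, phases)
        perm = {1: 3, 2: 1, 3: 2}
        bt2 = ms.activity_budget(np.vectorize(perm.get)(states), phases)
        for old, new in perm.items():
            assert bt.loc[("all", "general"), f"state_{old}"] == pytest.approx(
                bt2.loc[("all", "general"), f"state_{new}"]
            )

    def test_unlabeled_steps_rejected(self):
        with pytest.raises(ValueError):
            ms.activity_budget(np.array([1, 2]), np.array(["general", None]))


class TestPseudoResiduals:
    def test_self_simulated_residuals_normal(self):
        em = ms.resident_emissions()
        G = ms.persistent_transition([0.33, 0.20, 0.47], 0.7)
        series, _ = ms.simulate_hmm_series(em, G, 3000, seed=17)
        params = ms.HMMParams(em, ms.transition_from_matrix(G), np.ones(3) / 3)
        r = ms.step_pseudo_residuals(params, series, ms.HMMSpec(3, True, ()), seed=0)
        assert stats.jarque_bera(r).pvalue > 0.01
        # little lag-1 autocorrelation
        ac1 = np.corrcoef(r[:-1], r[1:])[0, 1]
        assert abs(ac1) < 2 / np.sqrt(len(r))

    def test_misspecified_single_state_fit_fails_normality(self):
        em = ms.resident_emissions(zero_mass=False)
        G = ms.persistent_transition([1 / 3, 1 / 3, 1 / 3], 0.8)
        series, _ = ms.simulate_hmm_series(em, G, 3000, seed=23)
        fit1 = ms.fit_hmm(series, ms.HMMSpec(1, False, ()), n_starts=2, seed=1, compute_cov=False)
        r = ms.step_pseudo_residuals(fit1, series, ms.HMMSpec(1, False, ()))
        # gross misspecification: decisive rejection of normality, with a
        # strongly distorted tail shape (|excess kurtosis| large)
        assert stats.jarque_bera(r).pvalue < 1e-10
        assert abs(stats.kurtosis(r)) > 0.5
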