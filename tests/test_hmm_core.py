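"""Emission densities, transition link, forward likelihood (vs brute-force
path enumeration), parameter counting, AIC machinery and fitting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import movestates as ms
from movestates import hmm_core as hc
from conftest import brute_force_loglik


class TestExpandCyclic:
    def test_midnight_and_quarter_cycle(self):
        assert ms.expand_cyclic(0) == pytest.approx((1.0, 0.0))
        c, s = ms.expand_cyclic(6)
        assert (c, s) == pytest.approx((0.0, 1.0), abs=1e-12)

    def test_afternoon_value(self):
        c, s = ms.expand_cyclic(14.5)
        assert c == pytest.approx(np.cos(2 * np.pi * 14.5 / 24))
        assert s == pytest.approx(np.sin(2 * np.pi * 14.5 / 24))
        assert (c, s) == pytest.approx((-0.7934, -0.6088), abs=1e-4)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ms.expand_cyclic(24.0)
        with pytest.raises(ValueError):
            ms.expand_cyclic(-0.1)


class TestTransitionMatrix:
    def test_zero_coefficients_give_uniform_rows(self):
        tm = ms.TransitionModel(n_states=3, regressors=(), beta=np.zeros((6, 1)))
        G = ms.transition_matrix(tm)
        assert np.allclose(G, 1.0 / 3.0)

    def test_two_state_closed_form(self):
        beta = np.array([[np.log(2.0)], [0.0]])
        tm = ms.TransitionModel(n_states=2, regressors=(), beta=beta)
        G = ms.transition_matrix(tm)
        assert np.allclose(G[0], [1 / 3, 2 / 3])
        assert np.allclose(G[1], [1 / 2, 1 / 2])

    @given(st.integers(0, 2**32 - 1))
    @settings(deadline=None, max_examples=60)
    def test_rows_stochastic_for_random_coefficients(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(2, 5)
        tm = ms.TransitionModel(
            n_states=int(n),
            regressors=("temperature", "hunger"),
            beta=rng.normal(0, 3, (n * (n - 1), 3)),
        )
        G = ms.transition_matrix(tm, rng.normal(0, 2, 2))
        assert np.allclose(G.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(G >= 0)

    def test_roundtrip_from_matrix(self):
        G = np.array([[0.8, 0.15, 0.05], [0.1, 0.7, 0.2], [0.25, 0.05, 0.7]])
        tm = ms.transition_from_matrix(G)
        assert np.allclose(ms.transition_matrix(tm), G, atol=1e-12)


class TestEmissionDensity:
    def test_exponential_limit(self):
        em = ms.EmissionParams([1.0], [1.0], [0.0], [1.0])
        assert ms.emission_density(1, 0.5, None, em) == pytest.approx(np.exp(-0.5))

    def test_uniform_circle_at_zero_concentration(self):
        em = ms.EmissionParams([1.0], [1.0], [0.0], [0.0])
        d_with = ms.emission_density(1, 0.5, 2.3, em)
        assert d_with == pytest.approx(np.exp(-0.5) / (2 * np.pi))

    def test_matches_independent_gamma_implementation(self):
        # fast-state parameters: mean 0.6, sd 0.43 -> shape ~1.9470, rate ~3.2450
        em = ms.EmissionParams([0.6], [0.43], [0.0], [1.11])
        shape, rate = (0.6 / 0.43) ** 2, 0.6 / 0.43**2
        assert shape == pytest.approx(1.9470, abs=1e-4)
        assert rate == pytest.approx(3.2450, abs=1e-4)
        expected = stats.gamma.pdf(0.6, a=shape, scale=1 / rate)
        assert ms.emission_density(1, 0.6, None, em) == pytest.approx(expected, rel=1e-12)

    def test_zero_step_without_zero_mass_warns_density_zero(self):
        em = ms.EmissionParams([1.0], [1.0], [0.0], [1.0])
        with pytest.warns(RuntimeWarning):
            assert ms.emission_density(1, 0.0, None, em) == 0.0

    def test_zero_step_returns_zero_mass(self):
        em = ms.EmissionParams([1.0], [1.0], [0.0], [1.0], zero_mass=[0.2])
        assert ms.emission_density(1, 0.0, None, em) == pytest.approx(0.2)


class TestForwardLoglik:
    def test_single_observation_is_mixture_density(self, toy_params, toy_series, full_spec):
        one = toy_series.iloc[:1]
        ll = ms.forward_loglik(toy_params, one, full_spec)
        dens = sum(
            toy_params.delta[i]
            * ms.emission_density(i + 1, one["step_km"].iloc[0], None, toy_params.emissions)
            for i in range(3)
        )
        assert ll == pytest.approx(np.log(dens), abs=1e-10)

    def test_equals_brute_force_enumeration(self, toy_params, toy_series, full_spec):
        ll = ms.forward_loglik(toy_params, toy_series, full_spec)
        oracle = brute_force_loglik(toy_params, toy_series, full_spec)
        assert ll == pytest.approx(oracle, abs=1e-8)

    def test_burst_duplication_doubles_loglik(self, toy_params, toy_series, full_spec):
        dup = toy_series.copy()
        dup["burst_id"] = dup["burst_id"] + 10
        both = pd.concat([toy_series, dup], ignore_index=True)
        assert ms.forward_loglik(toy_params, both, full_spec) == pytest.approx(
            2 * ms.forward_loglik(toy_params, toy_series, full_spec), abs=1e-8
        )

    def test_label_permutation_invariance(self, toy_params, toy_series, full_spec):
        perm = np.array([2, 0, 1])
        em = toy_params.emissions
        em2 = ms.EmissionParams(
            em.step_mean[perm], em.step_sd[perm], em.angle_mean[perm],
            em.angle_conc[perm], em.zero_mass[perm],
        )
        pairs = hc._pair_index(3)
        pos = {p: k for k, p in enumerate(pairs)}
        beta2 = np.empty_like(toy_params.transition.beta)
        for k, (i, j) in enumerate(pairs):
            beta2[k] = toy_params.transition.beta[pos[(perm[i], perm[j])]]
        tm2 = ms.TransitionModel(3, toy_params.transition.regressors, beta2)
        p2 = ms.HMMParams(em2, tm2, toy_params.delta[perm])
        assert ms.forward_loglik(p2, toy_series, ms.HMMSpec(3, True, ("tod", "temperature", "hunger"))) == pytest.approx(
            ms.forward_loglik(toy_params, toy_series, ms.HMMSpec(3, True, ("tod", "temperature", "hunger"))), abs=1e-8
        )


class TestCountParameters:
    @pytest.mark.parametrize(
        "zero_mass,covs,expected",
        [
            (True, ("tod", "temperature", "hunger"), 47),
            (True, ("tod", "temperature"), 41),
            (True, ("tod",), 35),
            (True, (), 23),
            (False, ("tod", "temperature", "hunger"), 44),
            (False, ("tod", "temperature"), 38),
            (False, ("tod",), 32),
            (False, (), 20),
        ],
    )
    def test_three_state_bookkeeping(self, zero_mass, covs, expected):
        spec = ms.HMMSpec(n_states=3, zero_mass=zero_mass, covariates=covs)
        assert ms.count_parameters(spec) == expected

    def test_two_state_formula_by_hand(self):
        assert ms.count_parameters(ms.HMMSpec(n_states=2, zero_mass=False)) == 11


class TestAIC:
    def _fit(self, ll, K, fp=(10, 1.0)):
        spec = ms.HMMSpec(3, False, ())
        em = ms.resident_emissions(zero_mass=False)
        params = ms.HMMParams(em, ms.transition_from_matrix(np.full((3, 3), 1 / 3)), np.ones(3) / 3)
        return hc.FittedHMM(
            spec=spec, params=params, loglik=ll, K=K, aic=-2 * ll + 2 * K,
            x=np.zeros(1), cov=None, n_obs=fp[0], seed=0, data_fingerprint=fp,
        )

    def test_aic_formula(self):
        assert ms.aic(self._fit(-10.0, 3)) == pytest.approx(26.0)

    def test_weights_match_direct_formula(self):
        fits = [self._fit(-10.0, 3), self._fit(-10.0 - 27.5 / 2, 3)]
        w = ms.akaike_weights(fits)
        assert w[0] == pytest.approx(1.0, abs=2e-6)
        assert w[1] == pytest.approx(1.06e-6, rel=0.01)

    def test_equal_aics_equal_weights(self):
        w = ms.akaike_weights([self._fit(-5.0, 2), self._fit(-5.0, 2)])
        assert np.allclose(w, 0.5)

    def test_weights_reject_different_data(self):
        with pytest.raises(ValueError):
            ms.akaike_weights([self._fit(-5.0, 2), self._fit(-5.0, 2, fp=(11, 2.0))])


class TestFitting:
    def test_one_state_recovery_method_of_moments(self):
        rng = np.random.default_rng(0)
        mu, sd = 0.3, 0.2
        steps = rng.gamma((mu / sd) ** 2, sd**2 / mu, 4000)
        series = pd.DataFrame(
            {"burst_id": 0, "step_km": steps, "angle_rad": np.r_[np.nan, rng.vonmises(0.2, 1.0, 3999)]}
        )
        fit = ms.fit_hmm(series, ms.HMMSpec(1, False, ()), n_starts=2, seed=1, compute_cov=False)
        assert fit.params.emissions.step_mean[0] == pytest.approx(steps.mean(), rel=0.02)
        assert fit.params.emissions.step_sd[0] == pytest.approx(steps.std(), rel=0.05)

    def test_loglik_at_truth_not_above_optimum(self, covfree_spec):
        em = ms.resident_emissions()
        G = ms.persistent_transition([1 / 3, 1 / 3, 1 / 3], 0.8)
        series, _ = ms.simulate_hmm_series(em, G, 3000, seed=5)
        spec = covfree_spec
        fit = ms.fit_hmm(series, spec, n_starts=4, seed=2, compute_cov=False)
        truth = ms.HMMParams(em, ms.transition_from_matrix(G), np.ones(3) / 3)
        assert ms.forward_loglik(truth, series, spec) <= fit.loglik + 1e-6

    def test_zero_steps_demand_zero_mass_spec(self):
        em = ms.resident_emissions()  # has zero mass -> simulates zero steps
        G = ms.persistent_transition([0.5, 0.3, 0.2], 0.7)
        series, _ = ms.simulate_hmm_series(em, G, 500, seed=3)
        assert (series["step_km"] == 0).any()
        with pytest.raises(ValueError, match="zero"):
            ms.fit_hmm(series, ms.HMMSpec(3, False, ()), n_starts=1, seed=0)


class TestParameterCIs:
    def test_lognormal_closed_form(self):
        # working-scale estimate 0, SE 1 -> natural interval (e^-1.96, e^1.96)
        spec = ms.HMMSpec(1, False, ())
        idx = hc._ParamIndex(spec)
        x = np.zeros(idx.n)
        cov = np.zeros((idx.n, idx.n))
        cov[idx.slices["log_mu"], idx.slices["log_mu"]] = 1.0
        params = idx.unpack(x)
        fit = hc.FittedHMM(
            spec=spec, params=params, loglik=0.0, K=ms.count_parameters(spec),
            aic=0.0, x=x, cov=cov, n_obs=1, seed=0, index=idx,
        )
        cis = ms.parameter_cis(fit)
        z = stats.norm.ppf(0.975)
        assert cis["step_mean"]["lo"][0] == pytest.approx(np.exp(-z), rel=1e-6)
        assert cis["step_mean"]["hi"][0] == pytest.approx(np.exp(z), rel=1e-6)
        # zero-variance parameters give degenerate intervals at the estimate
        assert cis["step_sd"]["lo"][0] == pytest.approx(cis["step_sd"]["hi"][0])

    def test_simulation_cis_cover_truth(self):
        # moderate-n sanity check on one fit: true values inside the 95% CIs
        em = ms.resident_emissions(zero_mass=False)
        G = ms.persistent_transition([1 / 3, 1 / 3, 1 / 3], 0.8)
        series, _ = ms.simulate_hmm_series(em, G, 6000, seed=11)
        fit = ms.fit_hmm(series, ms.HMMSpec(3, False, ()), n_starts=4, seed=1)
        cis = ms.parameter_cis(fit)
        inside = (cis["step_mean"]["lo"] <= em.step_mean) & (em.step_mean <= cis["step_mean"]["hi"])
        assert inside.sum() >= 2  # allow one near-boundary miss at this n
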