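"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import movestates as ms
from movestates import hmm_core as hc


def brute_force_loglik(params: ms.HMMParams, series: pd.DataFrame, spec: ms.HMMSpec) -> float:
    """Independent oracle: sum the joint probability over every one of the
    N^T hidden-state paths, per burst, using scipy densities throughout."""
    N = spec.n_states
    total = 0.0
    for _, burst in series.groupby("burst_id", sort=False):
        T = len(burst)
        gammas = _oracle_gammas(params, burst, spec)
        dens = _oracle_emission_matrix(params, burst, spec)
        prob = 0.0
        for path in itertools.product(range(N), repeat=T):
            p = params.delta[path[0]] * dens[0, path[0]]
            for t in range(1, T):
                p *= gammas[t, path[t - 1], path[t]] * dens[t, path[t]]
            prob += p
        total += np.log(prob)
    return total


def brute_force_viterbi(params: ms.HMMParams, series: pd.DataFrame, spec: ms.HMMSpec) -> np.ndarray:
    """Independent oracle: exhaustive argmax over all state paths (1-based)."""
    N = spec.n_states
    out = []
    for _, burst in series.groupby("burst_id", sort=False):
        T = len(burst)
        gammas = _oracle_gammas(params, burst, spec)
        dens = _oracle_emission_matrix(params, burst, spec)
        best, best_p = None, -1.0
        for path in itertools.product(range(N), repeat=T):
            p = params.delta[path[0]] * dens[0, path[0]]
            for t in range(1, T):
                p *= gammas[t, path[t - 1], path[t]] * dens[t, path[t]]
            if p > best_p:
                best, best_p = path, p
        out.extend(b + 1 for b in best)
    return np.array(out)


def _oracle_gammas(params, burst, spec):
    T = len(burst)
    N = spec.n_states
    if not spec.covariates:
        G = ms.transition_matrix(params.transition)
        return np.broadcast_to(G, (T, N, N))
    Z = hc.build_design(burst, spec.covariates)
    Zprev = np.vstack([Z[:1], Z[:-1]])
    return hc.transition_matrices(params.transition, Zprev)


def _oracle_emission_matrix(params, burst, spec):
    """Per-step emission densities from scipy.stats, independent of the
    package's own density code."""
    em = params.emissions
    N = spec.n_states
    steps = burst["step_km"].to_numpy(dtype=float)
    angles = burst["angle_rad"].to_numpy(dtype=float)
    dens = np.empty((len(steps), N))
    for i in range(N):
        shape = (em.step_mean[i] / em.step_sd[i]) ** 2
        scale = em.step_sd[i] ** 2 / em.step_mean[i]
        d = stats.gamma.pdf(steps, a=shape, scale=scale)
        if em.zero_mass is not None:
            d = np.where(steps == 0, em.zero_mass[i], (1 - em.zero_mass[i]) * d)
        ang = np.where(
            np.isfinite(angles),
            stats.vonmises.pdf(angles, kappa=max(em.angle_conc[i], 1e-12), loc=em.angle_mean[i]),
            1.0,
        )
        dens[:, i] = d * ang
    return dens


@pytest.fixture(scope="session")
def toy_params():
    """Small, well-separated 3-state parameter set with cyclic + linear
    covariates, for oracle comparisons."""
    em = ms.EmissionParams(
        step_mean=[0.01, 0.1, 0.6],
        step_sd=[0.01, 0.1, 0.4],
        angle_mean=[-3.0, 3.0, 0.0],
        angle_conc=[0.5, 0.4, 1.2],
        zero_mass=[0.1, 0.05, 0.01],
    )
    beta = np.zeros((6, 5))
    beta[:, 0] = np.log(0.15 / 0.7)
    beta[:, 1:] = np.array(
        [
            [0.3, -0.2, 0.05, -0.1],
            [-0.4, 0.1, -0.02, 0.2],
            [0.2, 0.3, 0.01, -0.3],
            [-0.1, -0.3, -0.04, 0.1],
            [0.5, 0.2, 0.03, 0.05],
            [-0.2, 0.4, -0.01, -0.2],
        ]
    )
    tm = ms.TransitionModel(
        n_states=3,
        regressors=("cos_tod", "sin_tod", "temperature", "hunger"),
        beta=beta,
    )
    return ms.HMMParams(emissions=em, transition=tm, delta=[0.5, 0.3, 0.2])


@pytest.fixture(scope="session")
def toy_series():
    """7-step, two-burst series with covariates and one zero step."""
    rng = np.random.default_rng(7)
    return pd.DataFrame(
        {
            "burst_id": [0, 0, 0, 0, 1, 1, 1],
            "step_km": [0.02, 0.0, 0.55, 0.08, 0.3, 0.01, 0.7],
            "angle_rad": [np.nan, 0.5, -2.0, 3.0, np.nan, 1.2, -0.3],
            "hour": [1.0, 2.0, 3.0, 4.0, 14.0, 15.0, 16.0],
            "temp_c": rng.normal(15, 5, 7),
            "hunger_days": [0.5, 1.0, 1.5, 2.0, 0.0, 0.5, 1.0],
        }
    )


@pytest.fixture(scope="session")
def covfree_spec():
    return ms.HMMSpec(n_states=3, zero_mass=True, covariates=())


@pytest.fixture(scope="session")
def full_spec():
    return ms.HMMSpec(n_states=3, zero_mass=True, covariates=("tod", "temperature", "hunger"))
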