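"""State decoding, stationary-probability curves, activity budgets and
step-length pseudo-residual diagnostics for a fitted movement HMM."""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .hmm_core import (
    FittedHMM,
    HMMParams,
    HMMSpec,
    _burst_starts,
    _gamma_stack,
    emission_logdensities,
    expand_cyclic,
    forward_filter,
    transition_matrices,
)

__all__ = [
    "viterbi",
    "stationary_distribution",
    "stationary_curves",
    "activity_budget",
    "step_pseudo_residuals",
]


def _params_spec(fit_or_params, spec=None):
    if isinstance(fit_or_params, FittedHMM):
        return fit_or_params.params, fit_or_params.spec
    if spec is None:
        raise ValueError("spec required when passing raw HMMParams")
    return fit_or_params, spec


def viterbi(fit_or_params, series: pd.DataFrame, spec: HMMSpec | None = None) -> np.ndarray:
    """Globally most probable state path (1-based labels), decoded per burst
    under the time-varying transition matrices.  Log-space recursion."""
    params, spec = _params_spec(fit_or_params, spec)
    T = len(series)
    if T == 0:
        return np.empty(0, dtype=int)
    logb = emission_logdensities(series, params.emissions, spec.zero_mass)
    gammas = _gamma_stack(params, series, spec)
    if gammas.shape[0] == 1:
        gammas = np.broadcast_to(gammas, (T, *gammas.shape[1:]))
    starts = _burst_starts(series)
    with np.errstate(divide="ignore"):
        logG = np.log(gammas)
        logdelta = np.log(params.delta)
    N = spec.n_states
    path = np.empty(T, dtype=int)
    psi = np.zeros((T, N), dtype=int)
    phi = np.empty(N)
    burst_start = 0
    for t in range(T):
        if starts[t]:
            if t > burst_start:
                _backtrack(path, psi, phi, burst_start, t)
            burst_start = t
            phi = logdelta + logb[t]
        else:
            cand = phi[:, None] + logG[t]
            psi[t] = np.argmax(cand, axis=0)
            phi = cand[psi[t], np.arange(N)] + logb[t]
    _backtrack(path, psi, phi, burst_start, T)
    return path + 1


def _backtrack(path, psi, phi, start, stop):
    path[stop - 1] = int(np.argmax(phi))
    for t in range(stop - 1, start, -1):
        path[t - 1] = psi[t, path[t]]


def stationary_distribution(G: np.ndarray) -> np.ndarray:
    """Solve pi G = pi, sum(pi) = 1, pi >= 0 for a row-stochastic G.

    Raises on reducible chains, naming the closed (absorbing) class."""
    G = np.asarray(G, dtype=float)
    N = G.shape[0]
    if not np.allclose(G.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("G is not row-stochastic")
    reach = (G > 1e-14).astype(bool) | np.eye(N, dtype=bool)
    for _ in range(N):
        reach = reach | (reach @ reach)
    if not reach.all():
        closed = [i + 1 for i in range(N) if not reach[i].all()]
        raise ValueError(f"reducible transition matrix; closed class containing states {closed}")
    A = np.vstack([G.T - np.eye(N), np.ones(N)])
    b = np.concatenate([np.zeros(N), [1.0]])
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def _curve_design(fit: FittedHMM, covariate_name: str, grid: np.ndarray) -> np.ndarray:
    """Regressor rows with the target covariate on `grid` and all other
    regressors at their sample means."""
    tm = fit.params.transition
    names = list(tm.regressors)
    Z = np.tile(tm.z_mean, (len(grid), 1))
    if covariate_name == "tod":
        c, s = expand_cyclic(np.asarray(grid, dtype=float) % 24)
        Z[:, names.index("cos_tod")] = c
        Z[:, names.index("sin_tod")] = s
    else:
        Z[:, names.index(covariate_name)] = np.asarray(grid, dtype=float)
    return Z


def stationary_curves(
    fit: FittedHMM,
    covariate_name: str,
    grid: Sequence[float],
    n_draws: int = 1000,
    seed: int | None = None,
    level: float = 0.95,
) -> dict:
    """Stationary state probabilities pi(z) along a covariate grid, other
    covariates held at their sample means, with pointwise Monte-Carlo
    confidence bands drawn from the asymptotic normal of the working-scale
    transition coefficients."""
    if covariate_name not in fit.spec.covariates:
        raise ValueError(
            f"covariate {covariate_name!r} not in the fitted model {fit.spec.covariates}"
        )
    grid = np.asarray(grid, dtype=float)
    Z = _curve_design(fit, covariate_name, grid)
    tm = fit.params.transition
    G = transition_matrices(tm, Z)
    pi = np.stack([stationary_distribution(G[g]) for g in range(len(grid))])
    lo = hi = None
    if n_draws > 0 and fit.cov is not None and fit.index is not None:
        rng = np.random.default_rng(seed)
        sl = fit.index.slices["beta"]
        bhat = fit.x[sl]
        cov_b = fit.cov[sl, sl]
        cov_b = (cov_b + cov_b.T) / 2
        try:
            draws = rng.multivariate_normal(bhat, cov_b, size=n_draws, method="eigh")
        except np.linalg.LinAlgError:  # pragma: no cover - defensive
            draws = bhat[None, :] + rng.normal(0, np.sqrt(np.clip(np.diag(cov_b), 0, None)), (n_draws, len(bhat)))
        sims = np.empty((n_draws, len(grid), fit.spec.n_states))
        shape = tm.beta.shape
        for d in range(n_draws):
            tm_d = type(tm)(
                n_states=tm.n_states,
                regressors=tm.regressors,
                beta=draws[d].reshape(shape),
                z_mean=tm.z_mean,
                z_sd=tm.z_sd,
            )
            Gd = transition_matrices(tm_d, Z)
            for g in range(len(grid)):
                sims[d, g] = stationary_distribution(Gd[g])
        a = (1 - level) / 2
        lo = np.quantile(sims, a, axis=0)
        hi = np.quantile(sims, 1 - a, axis=0)
    return {"grid": grid, "pi": pi, "lo": lo, "hi": hi}


def activity_budget(
    states: np.ndarray,
    phase_labels: np.ndarray,
    life_stages: np.ndarray | None = None,
    n_states: int | None = None,
) -> pd.DataFrame:
    """Proportion of decoded time in each state, per phase (and life stage).

    The caching phase is a subset of the data; the general phase covers all
    steps, so the 'general' row is computed over every step and the
    'caching' row over the caching-labelled subset only.  Proportions sum to
    1 within each row.
    """
    states = np.asarray(states)
    phases = np.asarray(phase_labels, dtype=object)
    if len(states) != len(phases):
        raise ValueError("states and phase labels must align")
    bad = pd.isna(phases) | ~np.isin(phases.astype(str), ["general", "caching"])
    if bad.any():
        raise ValueError(f"{bad.sum()} steps lack a valid phase label")
    if n_states is None:
        n_states = int(states.max())
    stages = (
        np.asarray(life_stages, dtype=object)
        if life_stages is not None
        else np.array(["all"] * len(states), dtype=object)
    )
    rows = []
    for stage in pd.unique(stages):
        in_stage = stages == stage
        for phase in ("general", "caching"):
            mask = in_stage if phase == "general" else in_stage & (phases == "caching")
            n = mask.sum()
            if n == 0:
                continue
            props = [(states[mask] == k).mean() for k in range(1, n_states + 1)]
            rows.append([stage, phase, n, *props])
    cols = ["life_stage", "phase", "n_steps"] + [f"state_{k}" for k in range(1, n_states + 1)]
    return pd.DataFrame(rows, columns=cols).set_index(["life_stage", "phase"])


def _state_step_cdf(s, emissions, zero_mass_on):
    """Per-state CDF of step length at value(s) s, including the zero atom."""
    shape = emissions.gamma_shape
    rate = emissions.gamma_rate
    F = stats.gamma.cdf(np.asarray(s, dtype=float)[..., None], a=shape, scale=1.0 / rate)
    if zero_mass_on:
        pi0 = emissions.zero_mass
        F = pi0 + (1 - pi0) * F
    return F


def step_pseudo_residuals(
    fit_or_params, series: pd.DataFrame, spec: HMMSpec | None = None, seed: int | None = None
) -> np.ndarray:
    """One-step-ahead (forecast) quantile residuals of step length.

    r_t = Phi^{-1}(F_t(s_t)) with F_t the forecast CDF given all past
    observations in the burst: a mixture of per-state step CDFs weighted by
    the one-step-ahead state probabilities.  Exact-zero steps, which sit on
    the CDF jump when the zero mass is on, are mapped by drawing uniformly
    within the jump (seeded).  Under a well-specified model the residuals
    are approximately standard normal.
    """
    params, spec = _params_spec(fit_or_params, spec)
    _, alphas, gammas, starts = forward_filter(params, series, spec)
    T = len(series)
    N = spec.n_states
    if gammas.shape[0] == 1:
        gammas = np.broadcast_to(gammas, (T, N, N))
    w = np.empty((T, N))
    for t in range(T):
        w[t] = params.delta if starts[t] else alphas[t - 1] @ gammas[t]
    steps = series["step_km"].to_numpy(dtype=float)
    Fstate = _state_step_cdf(steps, params.emissions, spec.zero_mass)
    F = (w * Fstate).sum(axis=1)
    zero = steps == 0
    if zero.any():
        if not spec.zero_mass:
            raise ValueError("zero steps require a zero-mass model for residuals")
        rng = np.random.default_rng(seed)
        jump = (w[zero] * params.emissions.zero_mass).sum(axis=1)
        F[zero] = rng.uniform(0.0, jump)
    F = np.clip(F, 1e-12, 1 - 1e-12)
    return stats.norm.ppf(F)
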