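"""Core N-state movement hidden Markov model.

Observations are step lengths (gamma, optionally zero-inflated) and turning
angles (von Mises); the hidden behavioural state follows a Markov chain whose
transition probabilities may depend on covariates through a multinomial-logit
link.  Time of day enters through a trigonometric (cyclic) pair so that 23:59
and 00:01 are neighbours.

Fitting is direct numerical maximum likelihood on a working scale (log for
positive parameters, logit for the zero mass, identity for regression
coefficients) from multiple perturbed starts, with the forward recursion
compiled via numba.  States are relabelled in increasing order of step mean
after fitting, so state N is always the fastest ("traveling") state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit
from scipy import optimize, special, stats

__all__ = [
    "EmissionParams",
    "TransitionModel",
    "HMMSpec",
    "HMMParams",
    "FittedHMM",
    "CANDIDATE_COVARIATE_SETS",
    "expand_cyclic",
    "regressor_names",
    "build_design",
    "transition_matrix",
    "transition_matrices",
    "transition_from_matrix",
    "emission_density",
    "emission_logdensities",
    "forward_loglik",
    "forward_filter",
    "fit_hmm",
    "count_parameters",
    "aic",
    "akaike_weights",
    "parameter_cis",
]

# The nested candidate covariate sets used for stepwise selection.
CANDIDATE_COVARIATE_SETS: tuple[tuple[str, ...], ...] = (
    (),
    ("tod",),
    ("tod", "temperature"),
    ("tod", "temperature", "hunger"),
)

_REGRESSORS_OF = {
    "tod": ("cos_tod", "sin_tod"),
    "temperature": ("temperature",),
    "hunger": ("hunger",),
}
_COLUMN_OF = {"temperature": "temp_c", "hunger": "hunger_days"}


def expand_cyclic(hour):
    """Map hour of day in [0, 24) to the trigonometric pair
    (cos(2*pi*h/24), sin(2*pi*h/24)) used as cyclic regressors."""
    h = np.asarray(hour, dtype=float)
    if np.any((h < 0) | (h >= 24)):
        raise ValueError("hour of day must lie in [0, 24)")
    w = 2.0 * np.pi * h / 24.0
    c, s = np.cos(w), np.sin(w)
    if np.isscalar(hour) or np.ndim(hour) == 0:
        return float(c), float(s)
    return c, s


def regressor_names(covariates: Sequence[str]) -> tuple[str, ...]:
    """Expand covariate names into regressor columns (tod -> cos + sin)."""
    names: list[str] = []
    for c in covariates:
        if c not in _REGRESSORS_OF:
            raise ValueError(f"unknown covariate {c!r}")
        names.extend(_REGRESSORS_OF[c])
    return tuple(names)


def build_design(series: pd.DataFrame, covariates: Sequence[str]) -> np.ndarray:
    """Natural-scale regressor matrix (T, p) for a step series.

    `series` must carry `hour` for tod, `temp_c` for temperature and
    `hunger_days` for hunger.
    """
    cols: list[np.ndarray] = []
    for c in covariates:
        if c == "tod":
            ct, st = expand_cyclic(series["hour"].to_numpy())
            cols.extend([np.atleast_1d(ct), np.atleast_1d(st)])
        else:
            col = _COLUMN_OF[c]
            if col not in series:
                raise ValueError(f"series lacks column {col!r} needed for covariate {c!r}")
            v = series[col].to_numpy(dtype=float)
            if not np.all(np.isfinite(v)):
                raise ValueError(f"non-finite values in covariate column {col!r}")
            cols.append(v)
    if not cols:
        return np.empty((len(series), 0))
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


def _wrap_angle(a):
    """Wrap to (-pi, pi]."""
    a = np.asarray(a, dtype=float)
    w = -(np.mod(-a + np.pi, 2 * np.pi) - np.pi)
    return w


@dataclass
class EmissionParams:
    """Natural-scale emission parameters, one entry per state.

    step_mean/step_sd are the gamma mean and standard deviation in km;
    zero_mass is the point mass at step == 0 (None when the model has no
    zero-inflation); angle_mean in (-pi, pi] and angle_conc >= 0 are the
    von Mises location and concentration.
    """

    step_mean: np.ndarray
    step_sd: np.ndarray
    angle_mean: np.ndarray
    angle_conc: np.ndarray
    zero_mass: np.ndarray | None = None

    def __post_init__(self):
        for name in ("step_mean", "step_sd", "angle_mean", "angle_conc"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.zero_mass is not None:
            self.zero_mass = np.asarray(self.zero_mass, dtype=float)
            if np.any((self.zero_mass < 0) | (self.zero_mass >= 1)):
                raise ValueError("zero_mass must lie in [0, 1)")
        if np.any(self.step_mean <= 0) or np.any(self.step_sd <= 0):
            raise ValueError("step_mean and step_sd must be positive")
        if np.any(self.angle_conc < 0):
            raise ValueError("angle_conc must be non-negative")
        self.angle_mean = _wrap_angle(self.angle_mean)

    @property
    def n_states(self) -> int:
        return len(self.step_mean)

    @property
    def gamma_shape(self) -> np.ndarray:
        return (self.step_mean / self.step_sd) ** 2

    @property
    def gamma_rate(self) -> np.ndarray:
        return self.step_mean / self.step_sd**2


def _pair_index(n_states: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(n_states) for j in range(n_states) if j != i]


@dataclass
class TransitionModel:
    """Multinomial-logit transition model.

    beta has one row per ordered state pair (i, j), i != j, in row-major
    order, and columns [intercept, slopes...] on the *standardized* regressor
    scale; z_mean/z_sd hold the standardization so that natural-scale
    covariate values can be fed in directly.
    """

    n_states: int
    regressors: tuple[str, ...]
    beta: np.ndarray
    z_mean: np.ndarray | None = None
    z_sd: np.ndarray | None = None

    def __post_init__(self):
        p = len(self.regressors)
        self.beta = np.asarray(self.beta, dtype=float)
        n_pairs = self.n_states * (self.n_states - 1)
        if self.beta.shape != (n_pairs, 1 + p):
            raise ValueError(
                f"beta must have shape ({n_pairs}, {1 + p}), got {self.beta.shape}"
            )
        if self.z_mean is None:
            self.z_mean = np.zeros(p)
        if self.z_sd is None:
            self.z_sd = np.ones(p)
        self.z_mean = np.asarray(self.z_mean, dtype=float)
        self.z_sd = np.asarray(self.z_sd, dtype=float)

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return _pair_index(self.n_states)

    def standardize(self, Z: np.ndarray) -> np.ndarray:
        Z = np.asarray(Z, dtype=float)
        if Z.ndim == 1:
            Z = Z[None, :]
        if Z.shape[1] != len(self.regressors):
            raise ValueError("regressor values do not match the model's regressor list")
        return (Z - self.z_mean) / self.z_sd

    def linear_predictor(self, Z: np.ndarray) -> np.ndarray:
        """Eta (T, n_pairs) at natural-scale regressor rows Z (T, p)."""
        Zs = self.standardize(Z)
        X = np.column_stack([np.ones(len(Zs)), Zs])
        return X @ self.beta.T

    @property
    def natural_beta(self) -> np.ndarray:
        """Coefficients re-expressed for unstandardized covariates."""
        b = self.beta.copy()
        if b.shape[1] > 1:
            slopes = b[:, 1:] / self.z_sd
            b[:, 0] = b[:, 0] - slopes @ self.z_mean
            b[:, 1:] = slopes
        return b


def transition_matrices(model: TransitionModel, Z: np.ndarray) -> np.ndarray:
    """Row-stochastic transition matrices (T, N, N) at regressor rows Z."""
    N = model.n_states
    if N == 1:
        return np.ones((np.atleast_2d(Z).shape[0], 1, 1))
    eta = model.linear_predictor(Z)
    if not np.all(np.isfinite(eta)):
        t, k = np.argwhere(~np.isfinite(eta))[0]
        i, j = model.pairs[k]
        raise ValueError(
            f"non-finite transition linear predictor for pair {i + 1}->{j + 1} at row {t}"
        )
    T = eta.shape[0]
    G = np.empty((T, N, N))
    k = 0
    for i in range(N):
        e = np.exp(eta[:, k : k + N - 1] - np.clip(eta[:, k : k + N - 1].max(axis=1, keepdims=True), 0, None))
        scale = np.exp(-np.clip(eta[:, k : k + N - 1].max(axis=1), 0, None))
        denom = scale + e.sum(axis=1)
        cols = [j for j in range(N) if j != i]
        for c, j in enumerate(cols):
            G[:, i, j] = e[:, c] / denom
        G[:, i, i] = scale / denom
        k += N - 1
    return G


def transition_matrix(model: TransitionModel, z: np.ndarray | None = None) -> np.ndarray:
    """Single transition matrix at one natural-scale regressor vector."""
    if z is None:
        z = np.zeros(len(model.regressors))
    return transition_matrices(model, np.atleast_2d(np.asarray(z, dtype=float)))[0]


def transition_from_matrix(G: np.ndarray) -> TransitionModel:
    """Intercept-only TransitionModel reproducing a fixed matrix G."""
    G = np.asarray(G, dtype=float)
    N = G.shape[0]
    if not np.allclose(G.sum(axis=1), 1.0):
        raise ValueError("G must be row-stochastic")
    beta = np.empty((N * (N - 1), 1))
    for k, (i, j) in enumerate(_pair_index(N)):
        beta[k, 0] = np.log(G[i, j] / G[i, i])
    return TransitionModel(n_states=N, regressors=(), beta=beta)


@dataclass
class HMMSpec:
    """Model structure: number of states, zero-inflation flag, covariate set.

    The covariate set must be one of the nested candidates
    (), (tod,), (tod, temperature), (tod, temperature, hunger).
    """

    n_states: int = 3
    zero_mass: bool = False
    covariates: tuple[str, ...] = ()

    def __post_init__(self):
        self.covariates = tuple(self.covariates)
        if self.covariates not in CANDIDATE_COVARIATE_SETS:
            raise ValueError(
                f"covariate set {self.covariates!r} is not one of the nested candidates"
            )
        if self.n_states < 1:
            raise ValueError("n_states must be >= 1")

    @property
    def regressors(self) -> tuple[str, ...]:
        return regressor_names(self.covariates)

    def label(self) -> str:
        names = {"tod": "Time of day", "temperature": "Temperature", "hunger": "Hunger"}
        if not self.covariates:
            return "No covariate"
        return " + ".join(names[c] for c in self.covariates)


@dataclass
class HMMParams:
    """A complete natural-scale parameter set: emissions, transition model and
    initial distribution delta (shared across bursts)."""

    emissions: EmissionParams
    transition: TransitionModel
    delta: np.ndarray

    def __post_init__(self):
        self.delta = np.asarray(self.delta, dtype=float)
        if not np.isclose(self.delta.sum(), 1.0):
            raise ValueError("delta must sum to 1")

    @property
    def n_states(self) -> int:
        return self.emissions.n_states


def count_parameters(spec: HMMSpec) -> int:
    """Free-parameter count K.

    2N gamma + N zero-mass (if on) + 2N von Mises + (N-1) initial
    distribution + N(N-1)(1+p) transition coefficients, where p counts the
    regressor columns (time of day counts as two: cos + sin).
    """
    N = spec.n_states
    p = len(spec.regressors)
    K = 2 * N + 2 * N + (N - 1) + N * (N - 1) * (1 + p)
    if spec.zero_mass:
        K += N
    return K


# ---------------------------------------------------------------------------
# densities
# ---------------------------------------------------------------------------


def _gamma_logpdf(s, mean, sd):
    shape = (mean / sd) ** 2
    rate = mean / sd**2
    return (
        special.xlogy(shape - 1.0, s)
        - rate * s
        + shape * np.log(rate)
        - special.gammaln(shape)
    )


def _vonmises_logpdf(a, mu, kappa):
    # log I0 via the exponentially scaled Bessel function for large kappa
    return kappa * np.cos(a - mu) - np.log(2 * np.pi) - (np.log(special.i0e(kappa)) + kappa)


def emission_logdensities(
    series: pd.DataFrame, emissions: EmissionParams, zero_mass_on: bool
) -> np.ndarray:
    """Per-step, per-state log emission densities (T, N).

    Missing angles (burst starts) contribute no angle factor; a zero step
    contributes log(zero_mass) when zero-inflation is on and -inf (with a
    warning) otherwise.
    """
    steps = series["step_km"].to_numpy(dtype=float)
    angles = series["angle_rad"].to_numpy(dtype=float)
    if np.any(steps < 0):
        raise ValueError("negative step length")
    T, N = len(steps), emissions.n_states
    logb = np.zeros((T, N))
    zero = steps == 0
    pos = ~zero
    for i in range(N):
        logb[pos, i] = _gamma_logpdf(steps[pos], emissions.step_mean[i], emissions.step_sd[i])
    if zero_mass_on:
        if emissions.zero_mass is None:
            raise ValueError("zero_mass_on but emissions carry no zero_mass parameters")
        pi0 = emissions.zero_mass
        with np.errstate(divide="ignore"):
            logb[zero] = np.log(pi0)[None, :]
            logb[pos] += np.log1p(-pi0)[None, :]
    elif np.any(zero):
        warnings.warn(
            "zero-length steps with no zero-mass component: density 0 assigned",
            RuntimeWarning,
        )
        logb[zero] = -np.inf
    ok = np.isfinite(angles)
    for i in range(N):
        logb[ok, i] += _vonmises_logpdf(
            angles[ok], emissions.angle_mean[i], emissions.angle_conc[i]
        )
    return logb


def emission_density(state: int, step: float, angle: float | None, params: EmissionParams) -> float:
    """Joint emission density of one (step, angle) pair in a given state
    (1-based).  `angle` may be None/NaN (burst start), contributing factor 1."""
    i = state - 1
    if not 0 <= i < params.n_states:
        raise ValueError(f"state {state} outside 1..{params.n_states}")
    if step < 0:
        raise ValueError("step must be >= 0")
    if step == 0:
        if params.zero_mass is None:
            warnings.warn(
                "zero step with no zero-mass component has density 0", RuntimeWarning
            )
            return 0.0
        d = params.zero_mass[i]
    else:
        d = float(np.exp(_gamma_logpdf(step, params.step_mean[i], params.step_sd[i])))
        if params.zero_mass is not None:
            d *= 1.0 - params.zero_mass[i]
    if angle is not None and np.isfinite(angle):
        d *= float(np.exp(_vonmises_logpdf(angle, params.angle_mean[i], params.angle_conc[i])))
    return d


# ---------------------------------------------------------------------------
# forward recursion
# ---------------------------------------------------------------------------


@njit(cache=True)
def _forward_core(logb, gammas, starts, delta, alphas):  # pragma: no cover - numba
    T, N = logb.shape
    tv = gammas.shape[0] > 1  # time-varying transition stack vs single matrix
    ll = 0.0
    alpha = np.zeros(N)
    for t in range(T):
        m = -1.0e308
        for i in range(N):
            if logb[t, i] > m:
                m = logb[t, i]
        if m < -1.0e307:
            return -np.inf
        g = t if tv else 0
        s = 0.0
        if starts[t]:
            for i in range(N):
                alphas[t, i] = delta[i] * np.exp(logb[t, i] - m)
                s += alphas[t, i]
        else:
            for j in range(N):
                acc = 0.0
                for i in range(N):
                    acc += alpha[i] * gammas[g, i, j]
                alphas[t, j] = acc * np.exp(logb[t, j] - m)
                s += alphas[t, j]
        if not (s > 0.0) or not np.isfinite(s):
            return -np.inf
        ll += m + np.log(s)
        for i in range(N):
            alpha[i] = alphas[t, i] / s
            alphas[t, i] = alpha[i]
    return ll


def _burst_starts(series: pd.DataFrame) -> np.ndarray:
    if "burst_id" in series:
        b = series["burst_id"].to_numpy()
        starts = np.empty(len(b), dtype=np.bool_)
        starts[0] = True
        starts[1:] = b[1:] != b[:-1]
        return starts
    starts = np.zeros(len(series), dtype=np.bool_)
    if len(series):
        starts[0] = True
    return starts


def _gamma_stack(params: HMMParams, series: pd.DataFrame, spec: HMMSpec) -> np.ndarray:
    """Transition matrices aligned so gammas[t] drives the move into step t;
    the covariates recorded at step t-1 apply (gammas at burst starts are
    unused by the recursion)."""
    T = len(series)
    N = spec.n_states
    if not spec.covariates:
        G = transition_matrix(params.transition)
        return G[None, :, :].copy()
    Z = build_design(series, spec.covariates)
    Zprev = np.vstack([Z[:1], Z[:-1]])
    return transition_matrices(params.transition, Zprev)


def forward_filter(params: HMMParams, series: pd.DataFrame, spec: HMMSpec):
    """Scaled forward recursion.

    Returns (loglik, alphas, gammas, starts) where alphas[t] is the filtering
    distribution P(state_t | obs_{1..t}) within each burst.
    """
    logb = emission_logdensities(series, params.emissions, spec.zero_mass)
    gammas = _gamma_stack(params, series, spec)
    starts = _burst_starts(series)
    alphas = np.empty_like(logb)
    ll = _forward_core(logb, gammas, starts, params.delta.astype(float), alphas)
    if not np.isfinite(ll):
        bad = np.where(~np.isfinite(logb).any(axis=1))[0]
        where = f" (first degenerate step index {bad[0]})" if len(bad) else ""
        raise FloatingPointError(f"non-finite log-likelihood{where}")
    return ll, alphas, gammas, starts


def forward_loglik(params: HMMParams, series: pd.DataFrame, spec: HMMSpec) -> float:
    """Log-likelihood of a step series under the model, bursts independent
    with initial distribution delta at each burst start."""
    ll, *_ = forward_filter(params, series, spec)
    return ll


# ---------------------------------------------------------------------------
# working-scale parametrization
# ---------------------------------------------------------------------------


class _ParamIndex:
    """Slice bookkeeping for the working-scale parameter vector."""

    def __init__(self, spec: HMMSpec):
        N = spec.n_states
        p = len(spec.regressors)
        self.spec = spec
        sizes = {
            "log_mu": N,
            "log_sigma": N,
            "logit_pi0": N if spec.zero_mass else 0,
            "angle_mean": N,
            "log_kappa": N,
            "delta_logit": N - 1,
            "beta": N * (N - 1) * (1 + p),
        }
        self.slices: dict[str, slice] = {}
        at = 0
        for k, n in sizes.items():
            self.slices[k] = slice(at, at + n)
            at += n
        self.n = at
        self._z_mean = np.zeros(p)
        self._z_sd = np.ones(p)

    def unpack(self, x: np.ndarray) -> HMMParams:
        N = self.spec.n_states
        p = len(self.spec.regressors)
        s = self.slices
        pi0 = special.expit(x[s["logit_pi0"]]) if self.spec.zero_mass else None
        emissions = EmissionParams(
            step_mean=np.exp(x[s["log_mu"]]),
            step_sd=np.exp(x[s["log_sigma"]]),
            angle_mean=_wrap_angle(x[s["angle_mean"]]),
            angle_conc=np.exp(x[s["log_kappa"]]),
            zero_mass=pi0,
        )
        d = np.concatenate([[0.0], x[s["delta_logit"]]])
        d = np.exp(d - d.max())
        delta = d / d.sum()
        beta = x[s["beta"]].reshape(N * (N - 1), 1 + p)
        tm = TransitionModel(
            n_states=N,
            regressors=self.spec.regressors,
            beta=beta,
            z_mean=self._z_mean,
            z_sd=self._z_sd,
        )
        return HMMParams(emissions=emissions, transition=tm, delta=delta)

    def pack(self, params: HMMParams) -> np.ndarray:
        s = self.slices
        x = np.empty(self.n)
        em = params.emissions
        x[s["log_mu"]] = np.log(em.step_mean)
        x[s["log_sigma"]] = np.log(em.step_sd)
        if self.spec.zero_mass:
            x[s["logit_pi0"]] = special.logit(np.clip(em.zero_mass, 1e-12, 1 - 1e-12))
        x[s["angle_mean"]] = em.angle_mean
        x[s["log_kappa"]] = np.log(np.clip(em.angle_conc, 1e-12, None))
        d = np.log(np.clip(params.delta, 1e-300, None))
        x[s["delta_logit"]] = d[1:] - d[0]
        x[s["beta"]] = params.transition.beta.ravel()
        return x

    def set_standardization(self, z_mean, z_sd):
        self._z_mean = np.asarray(z_mean, dtype=float)
        self._z_sd = np.asarray(z_sd, dtype=float)

    def bounds(self) -> list[tuple[float, float]]:
        b: list[tuple[float, float]] = []
        s = self.slices
        spans = {
            "log_mu": (-14.0, 6.0),
            "log_sigma": (-14.0, 6.0),
            "logit_pi0": (-14.0, 6.0),
            "angle_mean": (-2 * np.pi, 2 * np.pi),
            "log_kappa": (-8.0, 6.0),
            "delta_logit": (-20.0, 20.0),
            "beta": (-30.0, 30.0),
        }
        for k, sl in s.items():
            b.extend([spans[k]] * (sl.stop - sl.start))
        return b


def _reorder_states(index: _ParamIndex, x: np.ndarray) -> np.ndarray:
    """Relabel states by increasing step mean (resolves label switching)."""
    spec = index.spec
    N = spec.n_states
    s = index.slices
    order = np.argsort(x[s["log_mu"]])
    if np.array_equal(order, np.arange(N)):
        return x
    y = x.copy()
    for k in ("log_mu", "log_sigma", "logit_pi0", "angle_mean", "log_kappa"):
        block = x[s[k]]
        if len(block):
            y[s[k]] = block[order]
    # delta: logits relative to new reference state
    d = np.concatenate([[0.0], x[s["delta_logit"]]])[order]
    y[s["delta_logit"]] = d[1:] - d[0]
    p = len(spec.regressors)
    beta = x[s["beta"]].reshape(N * (N - 1), 1 + p)
    pairs = _pair_index(N)
    pos = {pair: k for k, pair in enumerate(pairs)}
    nb = np.empty_like(beta)
    for k, (i, j) in enumerate(pairs):
        nb[k] = beta[pos[(order[i], order[j])]]
    y[s["beta"]] = nb.ravel()
    return y


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


@dataclass
class FittedHMM:
    spec: HMMSpec
    params: HMMParams
    loglik: float
    K: int
    aic: float
    x: np.ndarray
    cov: np.ndarray | None
    n_obs: int
    seed: int | None
    starts: list[dict] = field(default_factory=list)
    data_fingerprint: tuple = ()
    index: _ParamIndex | None = None

    def to_dict(self) -> dict:
        """JSON-serializable summary of the fit."""
        em = self.params.emissions
        return {
            "n_states": self.spec.n_states,
            "zero_mass": self.spec.zero_mass,
            "covariates": list(self.spec.covariates),
            "loglik": float(self.loglik),
            "K": int(self.K),
            "AIC": float(self.aic),
            "step_mean_km": em.step_mean.tolist(),
            "step_sd_km": em.step_sd.tolist(),
            "angle_mean_rad": em.angle_mean.tolist(),
            "angle_concentration": em.angle_conc.tolist(),
            "zero_mass_prob": None if em.zero_mass is None else em.zero_mass.tolist(),
            "delta": self.params.delta.tolist(),
            "beta_standardized": self.params.transition.beta.tolist(),
            "beta_natural": self.params.transition.natural_beta.tolist(),
            "seed": self.seed,
            "n_obs": int(self.n_obs),
        }


def _fingerprint(series: pd.DataFrame) -> tuple:
    steps = series["step_km"].to_numpy(dtype=float)
    return (len(steps), round(float(np.nansum(steps)), 9))


def _nll_factory(series, spec, index):
    logb_cache: dict = {}
    steps = series["step_km"].to_numpy(dtype=float)
    angles = series["angle_rad"].to_numpy(dtype=float)
    starts = _burst_starts(series)
    zero = steps == 0
    pos = ~zero
    ok = np.isfinite(angles)
    N = spec.n_states
    T = len(steps)
    if spec.covariates:
        Z = build_design(series, spec.covariates)
        Zprev = np.vstack([Z[:1], Z[:-1]])
        z_mean = Z.mean(axis=0)
        z_sd = Z.std(axis=0)
        z_sd[z_sd < 1e-12] = 1.0
        Xs = np.column_stack([np.ones(T), (Zprev - z_mean) / z_sd])
    else:
        z_mean = np.empty(0)
        z_sd = np.empty(0)
        Xs = np.ones((1, 1))  # constant transition matrix: single stack entry
    index.set_standardization(z_mean, z_sd)
    s = index.slices
    p = len(spec.regressors)
    alphas = np.empty((T, N))
    if zero.any() and not spec.zero_mass:
        return lambda x: 1e12
    # full-length precomputations (zero-step rows overwritten below)
    logs_full = np.where(pos, np.log(np.where(pos, steps, 1.0)), 0.0)
    cos_a = np.where(ok, np.cos(np.where(ok, angles, 0.0)), 0.0)
    sin_a = np.where(ok, np.sin(np.where(ok, angles, 0.0)), 0.0)
    ok_f = ok.astype(float)
    zero_idx = np.where(zero)[0]

    def nll(x: np.ndarray) -> float:
        mu = np.exp(x[s["log_mu"]])
        sd = np.exp(x[s["log_sigma"]])
        m = x[s["angle_mean"]]
        kappa = np.exp(x[s["log_kappa"]])
        shape = (mu / sd) ** 2
        rate = mu / sd**2
        gconst = shape * np.log(rate) - special.gammaln(shape)
        # von Mises via cos(a - m) = cos a cos m + sin a sin m; the
        # normalizing constant applies only where an angle is observed
        vmconst = -np.log(2 * np.pi) - (np.log(special.i0e(kappa)) + kappa)
        logb = logs_full[:, None] * (shape - 1.0)
        logb -= steps[:, None] * rate
        logb += cos_a[:, None] * (kappa * np.cos(m))
        logb += sin_a[:, None] * (kappa * np.sin(m))
        logb += ok_f[:, None] * vmconst + gconst
        if spec.zero_mass:
            pi0 = special.expit(x[s["logit_pi0"]])
            logb += np.log1p(-pi0)[None, :]
            if len(zero_idx):
                vm_zero = (
                    cos_a[zero_idx, None] * (kappa * np.cos(m))
                    + sin_a[zero_idx, None] * (kappa * np.sin(m))
                    + ok_f[zero_idx, None] * vmconst
                )
                logb[zero_idx] = np.log(np.clip(pi0, 1e-300, None))[None, :] + vm_zero
        d = np.concatenate([[0.0], x[s["delta_logit"]]])
        d = np.exp(d - d.max())
        delta = d / d.sum()
        beta = x[s["beta"]].reshape(N * (N - 1), 1 + p)
        eta = Xs @ beta.T
        Tg = eta.shape[0]
        G = np.ones((Tg, N, N))
        k = 0
        for i in range(N if N > 1 else 0):
            blk = eta[:, k : k + N - 1]
            mx = np.clip(blk.max(axis=1), 0, None)
            e = np.exp(blk - mx[:, None])
            base = np.exp(-mx)
            denom = base + e.sum(axis=1)
            cols = [j for j in range(N) if j != i]
            for c, j in enumerate(cols):
                G[:, i, j] = e[:, c] / denom
            G[:, i, i] = base / denom
            k += N - 1
        ll = _forward_core(logb, G, starts, delta, alphas)
        if not np.isfinite(ll):
            return 1e12
        return -ll

    return nll


def _initial_guess(series, spec, index, rng, perturb: bool):
    N = spec.n_states
    steps = series["step_km"].to_numpy(dtype=float)
    nz = steps[steps > 0]
    if len(nz) < N:
        raise ValueError("too few positive steps to initialize")
    qs = np.quantile(nz, np.linspace(0, 1, N + 1))
    mu0 = np.empty(N)
    sd0 = np.empty(N)
    for i in range(N):
        grp = nz[(nz >= qs[i]) & (nz <= qs[i + 1])]
        mu0[i] = grp.mean() if len(grp) else np.quantile(nz, (i + 0.5) / N)
        sd0[i] = grp.std() if len(grp) > 2 else mu0[i]
        sd0[i] = max(sd0[i], 0.25 * mu0[i])
    x = np.zeros(index.n)
    s = index.slices
    x[s["log_mu"]] = np.log(mu0)
    x[s["log_sigma"]] = np.log(sd0)
    if spec.zero_mass:
        zf = np.clip((steps == 0).mean(), 1e-3, 0.5)
        x[s["logit_pi0"]] = special.logit(zf)
    x[s["angle_mean"]] = 0.0
    x[s["log_kappa"]] = np.log(0.7)
    x[s["delta_logit"]] = 0.0
    p = len(spec.regressors)
    beta = np.zeros((N * (N - 1), 1 + p))
    beta[:, 0] = np.log(0.1 / 0.8) if N > 1 else 0.0
    x[s["beta"]] = beta.ravel()
    if perturb:
        x[s["log_mu"]] += rng.normal(0, 0.4, N)
        x[s["log_sigma"]] += rng.normal(0, 0.4, N)
        x[s["angle_mean"]] = rng.choice([0.0, np.pi], N) + rng.normal(0, 0.5, N)
        x[s["log_kappa"]] += rng.normal(0, 0.7, N)
        bslice = x[s["beta"]].reshape(N * (N - 1), 1 + p)
        bslice[:, 0] += rng.normal(0, 0.7, N * (N - 1))
        x[s["beta"]] = bslice.ravel()
        if spec.zero_mass:
            x[s["logit_pi0"]] += rng.normal(0, 0.5, N)
    return x


def _numerical_hessian(f, x, eps=1e-4):
    n = len(x)
    H = np.empty((n, n))
    h = eps * np.maximum(1.0, np.abs(x))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n)
            ej = np.zeros(n)
            ei[i] = h[i]
            ej[j] = h[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    return H


def fit_hmm(
    series: pd.DataFrame,
    spec: HMMSpec,
    n_starts: int = 25,
    seed: int | None = None,
    maxiter: int = 1000,
    compute_cov: bool = True,
    x0: np.ndarray | None = None,
) -> FittedHMM:
    """Maximum-likelihood fit from `n_starts` perturbed initializations.

    The first start uses quantile-based moment initial values; the rest are
    random perturbations.  An explicit `x0` (working scale, e.g. a nested
    model's optimum padded with zero slopes) is prepended as a warm start.
    """
    if len(series) == 0:
        raise ValueError("empty step series")
    steps = series["step_km"].to_numpy(dtype=float)
    if (steps == 0).any() and not spec.zero_mass:
        raise ValueError(
            "data contain zero-length steps; use a spec with zero_mass=True"
        )
    index = _ParamIndex(spec)
    nll = _nll_factory(series, spec, index)
    rng = np.random.default_rng(seed)
    bounds = index.bounds()
    x0s: list[np.ndarray] = []
    if x0 is not None:
        x0s.append(np.asarray(x0, dtype=float))
    for k in range(n_starts):
        x0s.append(_initial_guess(series, spec, index, rng, perturb=k > 0))
    results = []
    for k, xk in enumerate(x0s):
        try:
            res = optimize.minimize(
                nll,
                xk,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": maxiter, "maxfun": 3 * maxiter},
            )
            results.append(
                {"start": k, "nll": float(res.fun), "converged": bool(res.success),
                 "message": str(res.message), "x": res.x}
            )
        except FloatingPointError as exc:  # pragma: no cover - defensive
            results.append({"start": k, "nll": np.inf, "converged": False,
                            "message": str(exc), "x": None})
    usable = [r for r in results if np.isfinite(r["nll"]) and r["x"] is not None]
    if not usable:
        raise RuntimeError(f"all {len(results)} starts failed: {results}")
    best = min(usable, key=lambda r: r["nll"])
    xbest = _reorder_states(index, best["x"])
    ll = -nll(xbest)
    cov = None
    if compute_cov:
        H = _numerical_hessian(nll, xbest)
        try:
            cov = np.linalg.inv(H)
            if np.any(np.diag(cov) < 0):
                warnings.warn(
                    "Hessian not positive definite; covariance from pseudo-inverse",
                    RuntimeWarning,
                )
                cov = np.linalg.pinv(H)
        except np.linalg.LinAlgError:
            warnings.warn("singular Hessian; covariance from pseudo-inverse", RuntimeWarning)
            cov = np.linalg.pinv(H)
    params = index.unpack(xbest)
    K = count_parameters(spec)
    diags = [{k: v for k, v in r.items() if k != "x"} for r in results]
    return FittedHMM(
        spec=spec,
        params=params,
        loglik=float(ll),
        K=K,
        aic=float(-2 * ll + 2 * K),
        x=xbest,
        cov=cov,
        n_obs=len(series),
        seed=seed,
        starts=diags,
        data_fingerprint=_fingerprint(series),
        index=index,
    )


def aic(fit: FittedHMM) -> float:
    return -2.0 * fit.loglik + 2.0 * fit.K


def akaike_weights(fits: Sequence[FittedHMM]) -> np.ndarray:
    """Akaike weights across candidate fits to the *same* data."""
    fps = {f.data_fingerprint for f in fits}
    if len(fps) != 1:
        raise ValueError("Akaike weights require fits to identical data")
    aics = np.array([f.aic for f in fits])
    delta = aics - aics.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


def parameter_cis(fit: FittedHMM, level: float = 0.95) -> dict:
    """Wald confidence intervals, computed on the working scale and
    back-transformed, hence asymmetric for positive-constrained parameters.

    Returns a dict of blocks, each {'estimate', 'lo', 'hi'} on the natural
    scale; transition coefficients are reported for unstandardized
    covariates.  Parameters with a degenerate working variance are flagged
    in 'boundary'.
    """
    if fit.cov is None:
        raise ValueError("fit carries no covariance; refit with compute_cov=True")
    index = fit.index if fit.index is not None else _ParamIndex(fit.spec)
    var = np.diag(fit.cov).copy()
    boundary = ~(var > 0) | ~np.isfinite(var)
    var[boundary] = 0.0
    se = np.sqrt(var)
    z = stats.norm.ppf(0.5 + level / 2.0)
    lo_w = fit.x - z * se
    hi_w = fit.x + z * se
    s = index.slices
    out: dict = {"boundary": boundary}

    def block(name, transform):
        sl = s[name]
        return {
            "estimate": transform(fit.x[sl]),
            "lo": transform(lo_w[sl]),
            "hi": transform(hi_w[sl]),
        }

    out["step_mean"] = block("log_mu", np.exp)
    out["step_sd"] = block("log_sigma", np.exp)
    if fit.spec.zero_mass:
        out["zero_mass"] = block("logit_pi0", special.expit)
    out["angle_mean"] = block("angle_mean", lambda v: v)
    out["angle_conc"] = block("log_kappa", np.exp)
    out["delta_logit"] = block("delta_logit", lambda v: v)

    # beta: linear map to natural-covariate coefficients, full delta method
    N = fit.spec.n_states
    p = len(fit.spec.regressors)
    sl = s["beta"]
    tm = fit.params.transition
    npairs = N * (N - 1)
    est = tm.natural_beta
    cov_b = fit.cov[sl, sl]
    width = 1 + p
    L = np.zeros((npairs * width, npairs * width))
    for r in range(npairs):
        o = r * width
        L[o, o] = 1.0
        for k in range(p):
            L[o, o + 1 + k] = -tm.z_mean[k] / tm.z_sd[k]
            L[o + 1 + k, o + 1 + k] = 1.0 / tm.z_sd[k]
    cov_nat = L @ cov_b @ L.T
    se_nat = np.sqrt(np.clip(np.diag(cov_nat), 0, None)).reshape(npairs, width)
    out["beta"] = {
        "estimate": est,
        "lo": est - z * se_nat,
        "hi": est + z * se_nat,
    }
    return out
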