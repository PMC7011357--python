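# movestates

Behavioural-state inference from predator GPS telemetry with hidden Markov
models, built around the movement ecology of a food-caching large felid
(Persian leopard, *Panthera pardus saxicolor*) tracked at regular 1-h and
3-h fixes.

The package is for movement ecologists who want a fully scripted, testable
version of the classic multistate workflow: split relocation data into
regular bursts, model step lengths and turning angles with a 3-state HMM
whose transition probabilities depend on covariates, decode behavioural
states, split activity budgets into general vs caching phases around kill
sites, and diagnose range residency from positional variograms.

## The model

Observed steps are summarized per move as a step length `s_t` (km) and a
turning angle `a_t` ∈ (−π, π]. A hidden state `S_t ∈ {1..N}` (N = 3:
resting, moderately active, traveling) follows a Markov chain; conditional
on the state,

- `s_t ~ Gamma(mean μ_i, sd σ_i)`, optionally zero-inflated with a point
  mass `π0_i` at `s_t = 0` when the data contain exact-zero steps;
- `a_t ~ von Mises(m_i, κ_i)` (missing at burst starts).

Transition probabilities use a multinomial-logit link with, per ordered
state pair (i, j):

```
γ_ij(z) = exp(η_ij) / (1 + Σ_{j'≠i} exp(η_ij')),   η_ij = β0_ij + βᵀ z
```

where z can contain time of day (entering through the cyclic pair
`cos(2πh/24), sin(2πh/24)`), collar temperature (°C) and hunger (days since
the last feeding on medium-sized prey, reset to 0 during feeding spans).
Four nested candidate models (no covariates; time of day; + temperature;
+ hunger) are fitted by direct numerical maximum likelihood and compared by
AIC and Akaike weights. The Viterbi algorithm yields the most probable
state path; πΓ(z) = π gives stationary state probabilities along covariate
gradients; one-step-ahead quantile (pseudo-)residuals of step length check
goodness of fit.

Around confirmed kills, the caching phase is every fix within 200 m of the
kill during its feeding span; GPS clusters are runs of fixes that stay
within 200 m of their running centroid over a complete overnight window
(18:00–06:00). Range residency is diagnosed from the empirical
semi-variance of positions: residents asymptote at long lags, dispersers do
not.

## Worked example

```python
import numpy as np
import movestates as ms

# simulate 5,000 hourly steps from the default resident parameter set
em = ms.resident_emissions(zero_mass=False)       # step means 6/95/600 m per h
G = ms.persistent_transition([0.33, 0.20, 0.47], 0.7)
series, truth = ms.simulate_hmm_series(em, G, 5000, seed=1)

fit = ms.fit_hmm(series, ms.HMMSpec(n_states=3, covariates=()), n_starts=10, seed=2)
print(np.round(fit.params.emissions.step_mean, 4))   # [0.006  0.0997 0.6053]
print(round(fit.aic, 1))                             # 6550.8

states = ms.viterbi(fit, series)
print(round((states == truth).mean(), 3))            # 0.942
```

The fitted step means recover the generating values (6.0 m resting, 100 m
moderately active, 605 m traveling versus 6/95/600 simulated), and Viterbi
decoding recovers 94% of the true states — the three states are ~100-fold
separated in step length, so decoding is close to clean.

The full synthetic study lives under `analysis/`, as numbered drivers:

```
python analysis/01_simulate_study.py        # 4 animals, kills, covariates
python analysis/02_run_pipeline.py          # prep -> fits -> AIC -> decoding -> budgets
python analysis/03_parameter_recovery.py    # estimates vs generating values, CIs
python analysis/04_caching_and_residency.py # clusters, dwell, variograms
```

Each writes tidy CSV/JSON tables under `results/` and prints what it found
(AIC tables in the candidate-model layout, activity budgets per life stage
and phase, cluster reports, residency calls).

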