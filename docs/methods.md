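# Methods

## Model

The core model is a discrete-time hidden Markov model on regular-interval
GPS steps. Each move from fix *t* to *t+1* contributes a step length
`s_t ≥ 0` (km, Euclidean in projected planar coordinates) and, where two
consecutive moves exist, a turning angle `a_t ∈ (−π, π]` (change in travel
bearing). Conditional on the hidden behavioural state, steps are gamma
(parameterized by mean μ and standard deviation σ; shape = (μ/σ)², rate =
μ/σ²) and angles are von Mises (location m, concentration κ). Within a
burst the state process is a Markov chain; bursts (runs of fixes at the
nominal interval ± tolerance) are treated as independent, each restarted
from a single initial distribution δ shared across animals and bursts per
fitted data set (N−1 free parameters). Missing angles at burst starts
contribute no angle factor (they are not imputed).

**Zero inflation.** The gamma density assigns zero density to exact-zero
steps, which GPS data at fine intervals do contain (animal stationary below
GPS resolution). A per-state point mass π0 at s = 0 is therefore included
exactly when the data contain zero steps, and omitted otherwise. This is
also what reconciles the per-model free-parameter counts between data sets
with and without zero steps (23 vs 20 for the covariate-free 3-state model,
47 vs 44 for the full model).

**Covariate-dependent transitions.** Off-diagonal transition probabilities
follow a multinomial-logit link with the diagonal as reference:
γ_ij(z) = exp(η_ij)/(1 + Σ_{j'≠i} exp(η_ij')), η_ij = β0_ij + βᵀz. Time of
day enters as the cyclic pair (cos 2πh/24, sin 2πh/24) so that the effect
is periodic over 24 h; temperature (°C) and hunger (days since last
feeding) enter linearly. The covariates recorded at step *t* drive the
transition from *t* to *t+1* (standard convention; the data do not identify
the alternative). The four candidate models are the nested sets
∅ ⊂ {tod} ⊂ {tod, temp} ⊂ {tod, temp, hunger}, compared by AIC = −2ℓ + 2K
and Akaike weights. K counts 2N gamma + N zero-mass (if present) + 2N von
Mises + (N−1) initial + N(N−1)(1+p) transition coefficients, with time of
day counting two regressor columns.

## Estimation

Direct numerical maximum likelihood. The likelihood is evaluated by the
scaled forward recursion (per-step renormalization, so underflow is
impossible by construction; the recursion is compiled with numba).
Optimization is quasi-Newton (L-BFGS-B) on a working scale — log for μ, σ,
κ, logit for π0, multinomial logits for δ, identity for β, with the angle
mean unconstrained and wrapped to (−π, π] on output — from `n_starts`
perturbed initializations (default 25; HMM likelihoods are multimodal). The
first start uses quantile-based moment estimates (steps split at empirical
terciles); the rest perturb it. Temperature and hunger are z-scored
internally for optimization and coefficients are reported back-transformed.
After fitting, states are relabelled in increasing order of step mean, so
state N is always the fastest ("traveling") state; the likelihood is
invariant under this relabelling.

Confidence intervals are Wald intervals from the inverse of a
finite-difference Hessian of the negative log-likelihood at the optimum,
computed on the working scale and back-transformed (hence asymmetric for
positive parameters). For transition coefficients the de-standardization is
an affine map, propagated by the exact linear delta method. A
non-positive-definite Hessian falls back to a pseudo-inverse with a
warning, and zero-variance (boundary) parameters are flagged.

**Stepwise fitting.** The candidate models are fitted in nesting order,
each warm-started from the previous optimum padded with zero slopes (plus
fresh random starts), mirroring stepwise covariate entry and making the
larger fits cheap and stable.

## Decoding and diagnostics

Viterbi decoding (log-space, per burst, time-varying Γ) gives the most
probable state path; activity budgets are the proportions of decoded steps
per state. The caching phase is a subset of the data, so the "general" row
of a budget table covers all steps and the "caching" row only the
caching-labelled subset. Stationary probability curves solve πΓ(z) = π
along a covariate grid with the other covariates held at their sample
means; pointwise bands come from a parametric bootstrap of the working
transition coefficients (default 1,000 draws, seeded) through the same map.

Goodness of fit uses one-step-ahead quantile residuals of step length:
r_t = Φ⁻¹(F_t(s_t)) with F_t the forecast mixture CDF weighted by the
one-step-ahead state probabilities from the forward filter. Exact-zero
steps sit on the CDF jump and are mapped by a uniform draw within the jump
(seeded). Turning-angle residuals are deliberately omitted — their
definition is arbitrary because of the circularity of the variable. A
practical note: a grossly misspecified single-gamma fit to three-state data
produces decisively non-normal residuals, but their excess kurtosis is
*negative* (the forced single CDF compresses the tails), so the diagnostic
tests assert rejection of normality and a distorted tail shape rather than
a kurtosis sign.

## Caching machinery

A GPS cluster is a maximal run of consecutive fixes that stay within a
radius (default 200 m) of their running centroid and whose span covers at
least one complete 18:00–06:00 night. "Remained overnight" is
operationalized as span coverage of the night window, clipped to the
track's observed extent with at least 9 h of the night observed — so a
track ending shortly before 06:00 can still qualify, while a brief
aggregation cannot. The radius is measured from the running centroid
(updated as members join); overlapping qualifying runs are merged toward
the earlier site. Caching-phase labels are temporally gated to each kill's
feeding span so later revisits do not contaminate the caching budget; only
medium-sized prey (wild ungulates, domestic animals) generate caching
phases. Hunger is days since the end of the most recent feeding event,
clamped to 0 during feeding; fixes before the first observed kill are
left-censored and receive the per-animal median with a flag. Excursions are
out-of-radius runs bounded by in-radius fixes on both sides (a trailing
departure is not an excursion); dwell time is the span from first to last
in-radius fix, optionally minus excursion time.

## Residency

The empirical semi-variance function svf(τ) = ½·mean‖x(t+τ) − x(t)‖² over
binned time lags diagnoses range residency: residents asymptote, dispersers
grow without bound. Classification, which replaces visual variogram
inspection with an explicit heuristic, calls a track resident iff over the
final 25% of populated lags (a) the svf slope is flat — statistically
indistinguishable from zero at α = 0.05, *or* practically negligible
(projected relative change below the 15% stability tolerance; with tens of
thousands of pairs per bin, biologically irrelevant slopes are easily
"significant") — and (b) the late-lag svf sits within 15% of the variogram
maximum. Too few long-lag pairs yields "indeterminate", never a silent
"resident", and the variogram is always emitted so a human can override.
Mixed-stage tracks are handled by classifying sliding windows (45-day
windows, 15-day steps, lags to half the window span) and taking the first
persistent flip as the change point.

## Synthetic data

The generator emulates the study conditions the analysis assumes: regular
1-h (or 3-h) fixes; a 3-state chain with multinomial-logit transitions; the
default emission sets describe a range-resident large felid (step means
6/95/600 m per h, SDs 5/100/430 m, angle concentrations 0.46/0.41/1.11,
small zero masses 0.05/0.01/0.001) and a faster non-resident
(9/147/740 m per h, concentrations 0.57/0.08/1.56, no zero mass). Default
transition intercepts come from a persistent matrix λI + (1−λ)1πᵀ (λ = 0.7)
whose stationary distribution matches the target activity budgets
(residents 33/20/47%, non-residents 44/30/26%). Non-resident slopes make
the traveling state more likely when hungry (+0.35 per day on logits into
state 3), colder (−0.08 per °C) and darker (+0.5 on the cos term, peaking
at midnight), qualitatively matching the behaviour of a transient predator
searching for prey; residents carry the diel signal only. Collar
temperature is a diel sinusoid (mean 14 °C, amplitude 8 °C, peak 14:00,
noise SD 1.5 °C). Kills arrive as a Poisson process (default one per six
days while not feeding); feeding durations are truncated normal
(mean 51.9 h, SD 32.3 h, minimum 6 h — matching field-observed dwell at
cache sites). During feeding the transition logits are shifted toward the
resting state by a sojourn bias (default +3) rather than frozen, so the
animal clusters stochastically near the cache point (its position at
feeding start) and decoded caching budgets stay stochastic. Hunger resets
through the same feeding events, with the pre-first-kill level set by an
initial-hunger offset (default 1 day).

What the generator does *not* emulate: positional measurement error,
fix-failure gaps, terrain or boundary effects, mean-reverting home-range
attraction (the travel process is a correlated walk, so simulated
"residents" do not produce asymptoting variograms — residency tests use
purpose-built Ornstein–Uhlenbeck tracks instead), and inter-individual
heterogeneity. Passing tests therefore demonstrate correctness of the
estimation and rule machinery under the model's own assumptions, not
robustness to the ways real telemetry violates them.

## Numerical choices and problem sizes

Forward recursion and all fitted objectives guard against non-finite
intermediates (diagnostics name the burst and index); reducible transition
matrices are rejected naming the closed class; stationary distributions are
solved by least squares on the augmented system πΓ = π, Σπ = 1 to ~1e−15
residual. Working-scale box bounds (e.g. log-parameters in [−14, 6]) keep
the optimizer out of overflow territory without binding at reasonable
optima. Parameter-recovery experiments use 20,000 steps (two fits, ~2–5 min
each at 25 starts); the model-selection consistency experiment uses 20
replicates of 1,500 steps with 4 stepwise fits each; residual-calibration
checks use 100 replicates of 1,000 steps; budget-vs-stationary checks use
50,000-step chains. The demo study under `analysis/` uses four animals at
~2,200 hourly fixes each.

## Known limitations

- δ is estimated freely; with few long bursts it is weakly identified
  (flagged at the bounds rather than fixed at the stationary distribution).
- The overnight-cluster rule is a deterministic operationalization of what
  fieldworkers do visually; borderline aggregations (nights exactly at the
  radius, tracks starting mid-night) depend on the 9-h minimum-night and
  merge tolerances.
- AIC comparisons assume a shared data set; the code refuses weights across
  different series.
- The residency heuristic is deliberately simple (no continuous-time
  movement-model fitting); its thresholds are exposed and its diagnostics
  returned so calls can be audited.
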