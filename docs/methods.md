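# Methods

This note documents the models, the synthetic-data generator, the
numerical choices and the known limitations of `taplearn`.

## The learning-curve model

Day-one performance of subject *s* on trial *t* (correct five-key
sequences per 30 s trial) is modelled with the power law of practice

    y_{s,t} ~ Normal( I_s + C_s (1 − R_s^{t−1}), σ_obs,g(s) ),

with *I* the initial performance at trial one, *C* the day-one change
(asymptote *I + C*) and *R* ∈ (0, 1) the learning rate (small R = fast
approach to the plateau). Counts are treated as continuous with additive
Gaussian observation noise; an optional integer-rounding view of the data
is deliberately not the default so that fitting is exactly
self-consistent with the generator.

Subject parameters are exchangeable within a group g (by default the 16
design cells; a `grouping` option coarsens to the four experience-by-age
groups or any user mapping — the right granularity is a modelling choice,
and the cellwise default is the most flexible):

    I_s ~ N(μ_I,g, σ_I,g),  C_s ~ N(μ_C,g, σ_C,g),
    R_s ~ N(μ_R,g, σ_R,g) restricted to (0, 1).

The restriction on R is imposed as a support constraint (the density is
not renormalized); with the spreads involved (σ_R ≈ 0.1 around central
μ_R) the truncated mass is negligible.

**Hyperpriors** are weakly informative on the scale of the task (single
trials rarely exceed ~40 sequences): μ_I, μ_C ~ N(0, 10²);
μ_R ~ Uniform(0, 1); all standard deviations (σ_I, σ_C, σ_R, σ_obs) ~
Half-Normal(5). Observation noise is per group, for symmetry with the
other group-level scales.

## Sampler

A self-contained adaptive random-walk Metropolis-within-Gibbs sampler:

- Subject-level blocks (I, C, logit R) are conditionally independent
  given the hyperparameters and are updated coordinate-wise but fully
  vectorized across subjects; group-level blocks likewise across groups.
- R and μ_R are proposed on the logit scale, standard deviations on the
  log scale, with the corresponding Jacobians; this removes boundary
  rejections.
- An extra subject-level "seesaw" move proposes I′ = I + d, C′ = C − d
  jointly, traversing the anti-correlated (I, C) ridge left by a tightly
  identified plateau.
- Group-level *translation* moves shift a group mean together with all
  its subjects' values, and *scaling* moves multiply the subject
  deviations while moving log σ by the same step. Standardized deviations
  are invariant under both maps, so the subject-prior terms cancel
  against the proposal Jacobians; these moves are what lets the sampler
  cross the location/scale funnels of the hierarchy.
- Proposal scales adapt per coordinate toward ~0.44 acceptance with a
  decaying Robbins–Monro step during burn-in and are frozen afterwards,
  so the retained draws target the exact posterior.

**Initialization.** Per-subject least squares on a grid
R ∈ {0.05, …, 0.95} with closed-form (I, C) given R; group
hyperparameters start at the moments of these fits; each chain jitters
the start slightly. If the initial density is non-finite the jitter is
retried up to 10 times before an initialization error. The hierarchy
makes results insensitive to these choices.

**Diagnostics.** Split-chain rank-normalized R̂ and bulk effective sample
size, computed with arviz. Note that the rank-normalized R̂ saturates
(near 1.8 for two completely separated chains), which is still far above
any usable convergence threshold. Defaults: 2 chains × 3000 iterations
with 1000 burn-in, which on the 128-subject design gives max R̂ ≲ 1.1 in
a few seconds; longer runs sharpen the tails of the σ posteriors.

**Conjugate cross-check.** With R fixed and the hierarchy disabled
(`hierarchical=False`, fixed σ_obs) the model is an independent linear
regression per subject with a known normal posterior; the test suite
verifies the sampler against that closed form within Monte-Carlo error.

## Consolidation statistics

- **Score**: mean of the three retest trials minus the mean of the last
  three training trials (`last3`); `best3` (three highest day-one trials)
  is the fatigue control. With a 6-trial training phase the last three
  trials are trials 4–6.
- **Transform**: signed square root, sign(x)·√|x| — monotone, defined for
  overnight losses, and shrinks the positive skew of gains. A
  shift-then-root variant (`transform="shift_root"`) is available; how
  negative scores were historically handled is a convention, so both are
  offered with the signed root as default.
- **ANOVA**: effect coding (±1), all main effects and two-way
  interactions by default (`interaction_order=2`); with 128 subjects this
  yields the (1, 117) tests of the full design. Each effect's SS is
  partial (Type-III style): the residual-SS increase from dropping its
  column. On balanced data this equals the classical sequential
  decomposition and the effect SS sum with the residual to the total SS;
  on unbalanced data (the 30-minute control cohort's 20/20/14/13 groups)
  it is the convention that reduces to the balanced answer. Higher-order
  interactions are left in the residual, matching the denominator df
  implied by the design.
- **Simple effects** test the difference of the two target-level means
  within one level of the other factor against the *pooled* residual mean
  square of the full model (denominator df = full-model residual df); a
  separate-variance Welch test is a non-default option.
- **Curve-parameter analyses** apply the same ANOVA to each fitted
  parameter separately (I, R, and the model-implied day-one improvement
  C(1 − R^{n−1})); a multivariate statistic is out of scope since only
  univariate F-tests are of interest downstream.
- **Fisher comparison**: z = (atanh r₁ − atanh r₂)/√(1/(n₁−3)+1/(n₂−3)),
  standard-normal p, tail chosen by the caller (the age-decline
  comparison is one-tailed: the directional hypothesis is a *weaker*
  decline for players).

## The synthetic-data generator

The generator emulates the study conditions: 128 subjects, 8 per cell of
the 2⁴ design; 12 training + 3 retest trials (6 + 3 in the short-training
variant); ages uniform within band (younger 18–29.99, older 30–70 — age
30 is "older"); lifetime piano practice uniform in 500–5000 h for players
and 0–50 h for non-players.

Group-level curve populations encode the online-learning pattern: players
start higher (μ_I 8 → 14) and learn faster (μ_R 0.65 → 0.50), the
high-intelligence group starts higher (+3), day-one improvement μ_C = 8
is shared; σ_I = σ_C = 2, σ_R = 0.08, observation noise σ_obs = 1.5
sequences per trial. These values are chosen to produce realistic trial
counts (≈5–25 sequences) and clearly separated starting levels.

**Day two.** Each subject receives one overnight-gain draw
g_s = cell_gain + N(0, σ_gain); the three retest trials are the subject's
noise-free day-one endpoint (mean of the last three curve values) plus
g_s plus trial noise, clipped at zero. Anchoring day two at the curve
endpoint rather than the asymptote I + C makes the generative gain
coincide *exactly* with the last3 consolidation score in the noise-free
limit, so recovery and calibration checks have a sharp target; the two
anchors differ by C·O(R^{n−3}), at most ~0.2 sequences at the default
parameters.

**Gains.** Baseline 3.0 sequences in every cell. The main scenario
subtracts 2.0 from older subjects and adds 2.0 back for older players, so
only older non-players are reduced — the compensation pattern. σ_gain is
set so the within-cell standard deviation of the raw score
(σ_gain² + ⅔σ_obs²)^½ equals 2.0. Under these conditions the
experience-by-age interaction is an ~2.8-SE contrast, i.e. ≈80% power at
α = .05 — comfortably detectable but not trivial. The 30-minute control
scenario keeps the age effect (−2.5) with no experience terms; the
short-training scenario and the null scenario have no factor effects (the
null additionally equalizes the curve populations across cells).

**Seeding.** One master seed; every subject draws from
`SeedSequence((seed, subject_index, stage))` substreams, with subjects
enumerated replicate-major — so enlarging a design appends new subjects
without perturbing existing data, and the whole cohort is bit-reproducible.

**Ground truth** records every parameter used (hyperparameters, per-cell
mean gains, each subject's drawn (I, C, R) and realized gain), enabling
exact recovery scoring.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: integer trial counts, within-session fatigue or
reactive inhibition (day-one performance is monotone in expectation),
keypress-level errors and timing, learning during the three retest
trials, any parametric age trend beyond the band structure (age affects
the gain only through the age-group factor), and correlations between
piano hours and the gain within the player group. Calibration and power
results transfer to real data only insofar as the normal-noise,
additive-gain approximation holds.

## Numerical choices and degenerate inputs

- Zero-variance inputs to t-tests/correlations raise degenerate-input
  errors rather than returning NaN; |r| = 1 is rejected by the Fisher
  comparison (atanh diverges).
- Rank-deficient ANOVA designs raise a design error naming the aliased
  effects.
- Truncated draws in the generator use rejection sampling with a bounded
  retry count; σ = 0 degenerates to the mean exactly.
- The sampler caches residual matrices and updates them incrementally;
  accepted proposals replace cache rows, so a sweep costs a handful of
  vectorized (subjects × trials) operations.
- Draw-count defaults (2 × 3000, burn-in 1000) and the simulation sizes
  used by the tests and the acceptance script (20 recovery cohorts,
  500 null replicates, 200 power replicates) balance Monte-Carlo error
  against runtime on a single CPU; the binomial tolerance bands quoted in
  the tests correspond to these replicate counts.

## Known limitations

- Random-walk MCMC: effective sample sizes per iteration are far below
  gradient-based samplers; very small groups (2–3 subjects) give noisy σ
  posteriors.
- The unnormalized truncation of the R hierarchy biases (μ_R, σ_R)
  slightly when substantial prior mass falls outside (0, 1).
- The 30-minute control cohort is analyzed with the same
  two-way-interaction model as the main design; with 77 subjects this
  gives residual df 61. Historical analyses of comparable designs have
  reported other denominator dfs, which would correspond to a different
  (unspecified) model; no attempt is made to reproduce that.
- No repeated-measures modelling across trials, no multiple-testing
  correction, and no alternative curve families (exponential, hyperbolic).
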