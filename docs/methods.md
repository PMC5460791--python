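# Methods

## Scientific setting

The package models how people discount the utility of arm movements by
physical effort. The experimental paradigm is a two-alternative forced
choice between reaching movements performed against a resistive force: in
each trial the subject samples a *reference* action and a *test* movement
and picks the one that feels less effortful. An adaptive staircase adjusts
the test force so that, over trials, it converges to the *equivalent
force* — the force at which the test movement feels exactly as effortful
as the reference action (the point of subjective equality, PSE).

Two designs are implemented:

* **Single-movement sessions** (experiment 1 in the package's vocabulary):
  reference and test are single reaches differing in amplitude *or*
  duration, plus direction and force. These produce empirical isoeffort
  curves in force–amplitude and force–duration space and dissociate
  impulse (∫|F| dt) from work (∫|F·v| dt).
* **Doubled-movement sessions** (experiment 2): the reference action is
  the same movement performed twice, the test a single movement, at fixed
  kinematics. Under the assumption that doing a movement twice costs twice
  the effort, the staircase equivalence point satisfies
  E(F_Teq) = 2·E(F_R), which identifies the shape of the force–effort
  function E.

## The choice model

For subject *i*, the probability of choosing the reference action is

    P(R | F_T, F_R) = Φ( (U(n·E_i(F_R)) − U(E_i(F_T))) / γ_i )

with Φ the standard normal CDF, n the number of reference repeats
(generalized from the doubled-movement factor 2; n = 1 reduces to
single-vs-single comparisons), and

    E_i(F) = F^α_i + β_i .

Four utility transforms are compared:

| id              | U(E)     | interpretation                      |
|-----------------|----------|-------------------------------------|
| `log_difference`| −log E   | subtractive, log-scaled effort       |
| `difference`    | −E       | subtractive, linear effort           |
| `hyperbolic`    | 1/E      | hyperbolic discounting               |
| `hyperbolic_log`| 1/log E  | hyperbolic discounting of log effort |

All four share the same equivalent-force curve

    F_Teq = (n·F_R^α + (n−1)·β)^(1/α),

at which the choice probability is exactly ½; they differ only in the
slopes of the psychometric curves. Parameters: α (force exponent,
dimensionless, ≈2 for realistic cohorts), β (effort offset, the effort of
an unloaded movement, in effort units), γ (effort sensitivity, the probit
noise scale).

**Positivity.** α, β, γ are truncated at 1e-6. The hierarchical normals
are formally unconstrained, but E must be positive for the log-based
utilities to be defined at the F = 0 N conditions, so subject-level values
are floored when used. 0^α is defined as 0 (the continuous limit for
α > 0). The `hyperbolic_log` transform is singular at E = 1; scalar calls
raise a domain error there, and the vectorized likelihood applies a 1e-12
guard on log E. Predicted per-trial choice probabilities are floored at
1e-9 inside the likelihood so that tail posterior draws (e.g. β at the
truncation floor, which makes 1/E astronomical at F = 0) cannot produce
unbounded per-trial deviances.

## Staircase engine

One-up one-down tracks with a 2 N step; each condition runs a pair of
tracks starting at 0 N and 16 N. Forces are clamped to [0, 16] N. An
inversion is a direction change of the *applied* (post-clamp) force step,
recorded at the force of the turning trial; a force pinned at a boundary
for two consecutive trials counts one inversion instead (the two rules
never both fire on the same trial — the task description leaves this
detail open, and this is the convention adopted here). A track completes
at 7 inversions. The equivalence estimate is the mean test force over all
inversion trials pooled across the pair; a `skip_first` option discards
early inversions per common psychophysics practice, but the default
includes all of them.

Conditions are interleaved uniformly at random (seeded) among incomplete
tracks. Failed/repeated subtrials are not simulated — they carry no
information for the choice model. Trial timing: single-movement sessions
hold the target for 100 + d_mmax − d_m ms (d_mmax = 2,000 ms in the
duration session, 1,250 ms in the amplitude session) so all subtrials in a
session last equally long; doubled-movement subtrials are padded to a
fixed 4,000 ms. Both rules exist to neutralize temporal discounting.

## Synthetic cohorts

Subject parameters are drawn from population normals with defaults
μ_α = 2.0, σ_α = 0.3, μ_β = 14, σ_β = 5, μ_γ = 2.5, σ_γ = 1 — central
values of the plausible ranges for this task — truncated to positivity.
Choices are Bernoulli draws from the probit model. The generator
reproduces the *structure* of real data (adaptive trial placement
concentrated near the PSE, per-subject heterogeneity, boundary clamping)
but not sequential effects such as learning, fatigue, lapses, or motor
failures; passing recovery tests therefore demonstrates correctness of
the estimation machinery under the model, not robustness to model
violations.

For single-movement sessions a generative extension is used:
E = c_dir · d · (F^α + β), with duration d in seconds and direction
coefficients c_in = 1.0, c_out = 1.15 (outward reaches, away from the
body midline, are more effortful). This is an artifact of the simulator —
a duration-integrated, direction-scaled effort consistent with the
qualitative findings — and is *not* the model fitted to doubled-movement
data. Representative movement durations are duration-window midpoints.

## Inference

The hierarchical probit model has priors μ_α ~ N(1, 10), μ_β ~ N(0, 100)
and half-Cauchy(0, 20) on μ_γ, σ_α, σ_β, σ_γ — all deliberately wide.

Sampling uses the affine-invariant ensemble sampler (emcee). Two
parameterization choices matter and were settled empirically:

* **Centered, not non-centered.** Every simulated subject contributes a
  few hundred trials, so subject parameters are strongly identified and
  the centered hierarchy has no funnel. The non-centered form is actively
  harmful for a density-following ensemble: its density mode sits at
  arbitrarily large population SDs (the volumetric 1/σ penalty is
  invisible to the density), and an ensemble initialized near that mode
  stalls there.
* **Initialization by per-subject MAP.** The centered density is singular
  at σ → 0 with all subjects equal, so a joint MAP search collapses into
  complete pooling. Instead each subject gets an independent 3-parameter
  MAP fit (weakly regularized); walkers start from these differentiated
  estimates with population moments taken from their spread (SD floors
  0.1/1.0/0.3 keep the initial σ off the funnel tip). Likelihood
  differences between subjects then block the collapse.

Positive parameters (μ_γ and the σs) are sampled on the log scale with
the Jacobian correction. `McmcConfig(n_chains, n_warmup, n_samples)`
keeps the conventional vocabulary: warmup and sampling are ensemble
sweeps, and retained draws are thinned to ≈ n_chains × n_samples. Defaults
are 4 × 1,000/1,000; a reduced preset (2 × 500/500) is provided and used
for the repeated simulation studies, whose problem size (8 subjects,
8 conditions, staircases to 7 inversions, ≈2,000 trials) was chosen so a
single fit takes seconds. Convergence is monitored with split R-hat and
bulk ESS (arviz) on the population parameters, grouping walkers into
pseudo-chains; R-hat > 1.05 emits a warning.

**WAIC** is computed on the deviance scale, WAIC = −2(lppd − p_waic),
with p_waic the summed per-trial posterior *sample* variance (ddof = 1,
per the standard recommendation; arviz uses ddof = 0 and the test suite
cross-checks against it with the explicit correction). Evidence ratios
between models are exp(−ΔWAIC/2). Choice-prediction accuracy classifies
each trial by whether the test force exceeds the subject's
posterior-median equivalent force; exact ties predict the test choice.

**Compound posteriors** mix N(μ, σ) over posterior draws (one truncated
sample per draw, seeded) to describe the population distribution of a
parameter; equivalent-force curves and their 95% credible bands are
quantiles of draw-wise curves through the compound (α, β) samples.

## Haptics and biomechanics

The resistive force emulates kinetic friction via a virtual 100-g point
mass coupled to the handle by a virtual spring, integrated
semi-implicitly at the 0.5-ms haptic cycle; friction of condition
magnitude opposes the virtual mass's velocity, with a 1e-4 m/s deadband
below which friction is static-like (cancelling the spring force up to
its magnitude) to avoid chatter. The commanded handle force is the spring
reaction, gated by linear on/off taper envelopes. The nominal spring
coefficient of 1 N/m implies metre-scale extensions at task force levels,
which cannot be literal; it is kept as the configurable default and tests
that need the handle force to track the friction level use a stiff spring
instead. Reaches are generated as minimum-jerk profiles (peak speed
15/8·A/T).

Impulse integrates |F| dt and work |F·v| dt (trapezoidal) over a window
from 100 ms before movement onset to 400 ms after offset; magnitudes are
used because the friction force always opposes motion. The arm model is a
planar two-link chain (upper arm + rigid forearm/hand) in a horizontal
plane (no gravity), with Dempster-style segment constants (masses 0.028/
0.022 of body mass, COM at 0.436/0.682 and radii of gyration 0.322/0.468
of segment length; defaults l1 = 0.30 m, l2 = 0.35 m, body mass 70 kg,
all overridable). Torques decompose into rigid-body inertial compensation
and the Jacobian-transpose image of the hand force the subject must
exert; joint angles are obtained by elbow-down inverse kinematics of the
hand path (embedded 0.35 m in front of the shoulder) and differentiated
numerically.

## Known limitations

* The simulator emits only successful trials; performance confounds and
  movement-failure dynamics are out of scope.
* WAIC differences between utility models on the reduced synthetic
  cohorts are smaller than on a full-size dataset; model identification
  is therefore asserted as a majority over replicates, not per run.
* The ensemble sampler approximates posteriors well for these unimodal,
  well-identified fits but is not a substitute for gradient-based MCMC on
  weakly identified extensions (e.g. very few trials per subject).
* β is the least identified parameter (it only shapes the equivalent
  force curve near F_R = 0) and its population mean is recovered with
  visible shrinkage on small cohorts.
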