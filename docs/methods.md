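# Methods

This note documents the models implemented in `rewardtap`, the parameter
defaults and why they were chosen, what the synthetic performer agents do and
do not emulate, and the numerical choices that affect results. Nothing here
states an empirical result that the test suite does not itself compute.

## 1. Task measures and the reward mapping

A trial is an `n`-keystroke sequence (default `n = 8`, configurable)
described by its `n − 1` inter-keystroke intervals (IKIs, seconds). The
rewarded performance measure is the Euclidean norm of the successive
difference vector `Δz_j = z_{j+1} − z_j`; the trial score is
`100 · exp(−|‖Δz_t‖ − ‖Δz_p‖|)`, bounded in (0, 100] and maximal exactly
when the performed norm matches the target (default target norm 1.9596 s,
the norm of the alternating pattern `[0.2, 1, 0.2, 1, 0.2, 1, 0.2]` s).
Because only the norm matters, the movement-to-reward mapping is
many-to-one.

Variability measures are coefficients of variation (cv = sd/mean), always
with the **population** (ddof = 0) standard deviation:

- `within_trial_cv` — sd over the trial's IKIs / their mean (cvIKI). This is
  the timing measure whose unsigned trial-to-trial change defines
  exploration.
- `block_variability` — per keystroke position, cv across a block's
  non-error trials, averaged over positions. During the isochronous baseline
  this residual variability is read as motor noise.

The divisor convention matters only in degenerate toy cases (both
conventions are tempo-scale invariant); population sd was chosen because it
makes the package's worked examples exact and keeps within-trial and
across-trial cv consistent. Error trials are excluded from cv computations
but kept and counted in the error rate; the generator's default error rate
is 0.

The exploration series is `Y^k = log |cvIKI^k − cvIKI^{k−1}|`. A zero change
makes the log undefined, so `|Δ|` is floored at a configurable epsilon
(default 1e−6) before the log; this preserves series length. In the
pipeline, the last baseline trial serves as the predecessor of learning
trial 1, so a 90-trial learning phase yields 90 response values.

## 2. Perceptual model: two-level continuous-input HGF

Generative model assumed by the filter: the score `u^k ~ N(x1^k, α)`
observes a latent reward tendency `x1`, which random-walks with step
variance `exp(κ·x2 + ω)`; the log-volatility `x2` random-walks with step
variance `θ`. Beliefs are Gaussian, so the filter propagates
`(μ1, σ1, μ2, σ2)` trial by trial; each belief mean moves by its
precision-weighted prediction error (`ε1` for reward, `ε2` for volatility).
The update equations are the standard continuous-input form (level-1
posterior precision = prediction precision + input precision; level-2
precision update quadratic in the volatility weight `w1 = exp(κμ2+ω) /
σ̂1`). The filter is deterministic.

**Defaults** (score units are points on the 0–100 scale):

| parameter | default | meaning / rationale |
|---|---|---|
| κ | 0.3 | volatility coupling; kept < 1 because the level-2 precision update scales with κ² and larger values destabilise the filter on the abrupt score jumps closed-loop performers produce |
| ω | 2.0 | tonic log step variance of the reward tendency (step sd ≈ e¹ ≈ 2.7 points at μ2 = 0) |
| θ | 0.5 | level-2 step variance |
| α | 100 | observation-noise variance (sd 10 points), matching the score spread that motor noise alone produces near the target |
| μ1⁰, σ1⁰ | 50, 100 | uninformed belief at the scale midpoint |
| μ2⁰, σ2⁰ | 0, 1 | neutral volatility belief |

These defaults were fixed by design-time pilot simulations with three
requirements: (i) the constant-input sanity checks hold (constant scores at
the prior mean leave μ1 fixed and send μ2 down); (ii) the filter is stable
across hundreds of closed-loop sessions; (iii) the pwPEs retain enough
spread for the response coefficients to be identifiable at 90 trials. They
are configuration values, not claims about any study's prior table. Scores
are filtered on their native 0–100 scale; rescaling is possible but off by
default.

**Numerical guards.** A level-2 posterior precision in (0, 1e−12] is floored
with a warning; a non-positive precision, or a diverging log-volatility
(|κμ2 + ω| ≥ 700), raises `HGFInstabilityError` naming the trial. Filtering
with aggressive parameters (small α, large κ and θ) on jumpy inputs can
genuinely reach this state; it is an error, not a silent repair.

## 3. Response models and fitting

A response model regresses one trialwise performance measure on belief
quantities of the *previous* trial with Gaussian noise ζ:
`Y^k = β0 + β1·X1^{k−1} + β2·X2^{k−1} + ζ`. The candidate table crosses
four predictor families — (a) belief means {μ1, μ2}, (b) pwPEs {ε1, ε2},
(c) reward-related {μ1, ε1}, (d) volatility-related {μ2, ε2} — with four
response variables (timing exploration log|ΔcvIKI|, velocity exploration,
tempo change, mean-velocity change), giving 16 models. The composition is a
configurable table; the count and the presence of the pwPE model for timing
exploration are asserted in tests. The first response value has no lag-1
predictor and is dropped from the likelihood (89 usable terms at 90 trials).

**Fitting** is per subject/session and follows the observing-the-observer
convention: the likelihood is that of the observed responses given the score
inputs; perceptual parameters enter only through the belief trajectories
they induce. This was a deliberate choice: performers' scores are produced
by their own behaviour, not by the filter's generative model, so maximising
a score predictive density pulls ω toward "what explains the score series"
rather than "what the performer's filter used" — in pilot recovery runs it
biased ω upward and attenuated β1 systematically, whereas the response-only
likelihood recovers both without bias. The score predictive density remains
available (`hgf_predictive_density`) and can be added to the objective via
`FitConfig.include_perceptual_evidence`.

Free parameters: ω per session (Gaussian prior on ω, sd 4, centred at the
configuration default); θ, κ and α fixed at configuration values by default
because θ in particular is weakly identified from 90 trials (pilot fits
spread over twice its value) — each is estimable via `FitConfig` flags.
Priors on βs and log ζ are flat, so conditional on the perceptual parameters
the β optimum is exactly OLS (asserted against statsmodels to 1e−8) and ζ²
is the mean residual square. Optimisation is multistart L-BFGS-B (8
restarts, seeded); proposals that destabilise the filter incur a large
finite penalty rather than an error. The log model evidence is a Laplace
approximation at the joint MAP over (ω, βs, log ζ) with a central-difference
Hessian (relative step 1e−3); non-positive-definite Hessians are clipped at
1e−8 eigenvalues and flagged through `converged`.

In the pipeline, each response series is z-scored within session before
fitting (`standardize_responses`, on by default): the 16 models regress
*different* response variables, and their evidences are only comparable if
the response scales are; on native scales a low-variance noise series wins
the comparison trivially. Native-scale coefficients (the scale on which ζ ≈
1.3 is reported) are obtained by fitting `fit_subject` directly or switching
the flag off.

## 4. Random-effects model selection

Subjects' log evidences enter the standard variational Dirichlet scheme:
E-step softmax of `lme + ψ(α_k) − ψ(Σα)` per subject, M-step Dirichlet
counts, iterated until the full variational bound (including the Dirichlet
KL term) changes by < 1e−8; the bound is asserted non-decreasing. Exceedance
probabilities are Monte-Carlo argmax frequencies over Dirichlet samples
(default 1e6, seeded, chunked). Prior α = 1 per model (uniform). The
pipeline pools sessions within subject by summing their LMEs (fixed effects
within subject, random effects across subjects); this is a documented choice
— the alternative of treating sessions as independent observations is
available by reshaping the input matrix.

## 5. Group statistics

All permutation p-values use the add-one convention
`p = (1 + #{null ≥ obs})/(n_perm + 1)` and lie in (0, 1]; exhaustive
enumeration (seed-free, identity included) replaces Monte-Carlo whenever the
arrangement count is within a cap (default 1e5).

- **One-way repeated measures** (e.g. factor stimulation): condition labels
  permuted within each subject; statistic = between-condition sum of squares
  of condition means.
- **Two-factor factorial** (block × stimulation): each main effect uses
  synchronised rearrangements — the tested factor's levels are permuted
  within subject with the *same* permutation across the other factor's
  levels, preserving the other factor's marginal structure; the statistic is
  the between-level SS of marginal means. The interaction statistic is the
  SS of double-centred cell means, with the second factor's levels permuted
  independently within each level of the first; double-centring removes
  marginal effects, making this an approximate test of non-additivity.
- **Paired contrasts**: sign-flip permutation of within-pair differences,
  two-sided on the mean difference.
- **FDR**: the adaptive two-stage linear step-up procedure (stage 1 at
  q/(1+q) estimates the number of true nulls; stage 2 reruns the step-up at
  the sharpened level). The reported `P_FDR` is the largest rejected
  p-value, so rejections are exactly {p ≤ P_FDR}. Cross-checked in tests
  against an independent transcription and against statsmodels'
  two-stage implementation.
- **Effect sizes**: probability of superiority for dependent samples, ties
  counting 1/2 (which makes `Δ(x,y) = 1 − Δ(y,x)` exact), with
  percentile-bootstrap CIs over resampled pairs (default 5000 resamples,
  clipped to [0, 1] and widened to contain the point estimate).

Defaults: 5000 permutations, q = 0.05, seeds mandatory.

## 6. Synthetic performer agents

The generator emulates the study design — 20 isochronous baseline trials
plus 3 × 30 learning trials per session, 19 subjects × 3 stimulation
conditions — with a closed loop around the reward mapping, the HGF, and the
winning response model:

1. The agent's intended pattern is `base_tempo · (1 + c·d)` with `d` a fixed
   zero-mean unit-sd alternating shape vector, so the intended cvIKI is
   exactly `c` and the difference norm is proportional to `c` (reward is
   maximal at `c* ≈ 0.66` for the defaults).
2. Each trial it draws `Y ~ N(β0 + β1·ε1 + β2·ε2, ζ)` from its own lagged
   pwPEs, steps `c` by `exp(Y)` toward the best-scoring `c` found so far
   (probability `explore_bias`, else a random direction), plays the pattern
   with multiplicative Gaussian motor noise (cv 0.05), receives the score,
   and updates its beliefs.

The perturbation-direction rule is this package's choice (the analysis
constrains only the magnitude law); it is swappable via `explore_policy`.
Steps are capped at `exp(min(Y, 1))` — a perturbation larger than the whole
reachable cv range is simply maximal exploration — and `c` is clipped to
keep every IKI positive.

**Defaults.** ζ = 1.3 is the reported group-average response noise. β signs
follow the reported group-level pattern (β1 < 0: exploitation after reward
pwPEs; β2 > 0: exploration after volatility pwPEs). Magnitudes are this
package's choice, fixed a priori from an identifiability argument: the
sampling sd of an OLS coefficient at m ≈ 89 usable trials is
`ζ/(σ_X·√m)`, so a 20% median recovery error needs `|β| ≳ 3.4·ζ/(σ_X·√m)`
given the pwPE spreads σ_X the chosen HGF defaults produce. Two documented
worlds result:

- **cohort default** (`AgentConfig`): β0 = −5, β1 = −0.45, β2 = 4,
  explore_bias = 0.6 — learning gradual enough that scores still rise and
  timing variability still falls from block 1 to block 3, and exploration is
  larger after score drops than rises, each in ≥ 90% of seeded runs;
- **recovery preset** (`recovery_config`): β0 = −4, β1 = −0.4, β2 = 2 — a
  livelier regime with sustained volatility signal, as recovery studies
  require informative designs.

Per-subject heterogeneity is Gaussian on the βs (sd 0.3/0.05/0.3), shared
across a subject's sessions. All randomness flows from explicit seeds; a
cohort is reproducible from (config, seed).

**What the generator does not emulate:** wrong-note errors beyond a constant
configurable rate (default 0); reward-coupled keystroke velocities (velocity
is non-task-related by design and simulated as stationary noise);
session-order, fatigue or carry-over effects; any physiological effect of
the stimulation conditions (condition labels differ only if the user
supplies different configs). A green end-to-end test therefore establishes
that the analysis chain recovers what this generative family encodes — not
that real performers behave this way.

## 7. MIDI input

A minimal Standard MIDI File reader (no third-party MIDI library is
required) extracts note-on events with a tempo-map-correct tick-to-second
conversion (formats 0/1, default 120 bpm when no tempo event precedes the
notes; SMPTE divisions unsupported). Trials are segmented at silent gaps
longer than `gap_s` (default 2 s — trials are separated by feedback
presentation); suspiciously short trials trigger a warning. A small writer
exists for test fixtures; round trips are verified to 1 ms.

## 8. Known limitations

- The 16-model table composition and the BMS pooling rule across sessions
  are documented choices among several defensible readings of the design.
- The interaction permutation test is approximate (exchangeability holds
  exactly only under additivity); its calibration is checked by simulation,
  not proven.
- The Laplace evidence is a local approximation; with 8 restarts
  multimodality is unlikely but not excluded.
- θ, κ and α are not identifiable per session at 90 trials and are fixed by
  default; fits with these freed should be interpreted with caution.
- Percentile-bootstrap CIs for Δ_dep are first-order accurate only; the
  coverage test tolerates the resulting small undercoverage.
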