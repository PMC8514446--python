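# rewardtap

Analysis toolkit for **reward-based motor sequence learning** on a keyboard:
how people (or simulated performer agents) use trialwise feedback scores to
discover a hidden timing pattern, and how their trial-to-trial **exploration**
of the timing dimension is driven by hierarchical Bayesian beliefs about
reward and volatility.

It is aimed at motor-learning and computational-psychiatry researchers who
record keystroke performances (MIDI or CSV), score them with a continuous
reward function, and want the full model-based analysis chain — belief
filtering, response-model comparison, and non-parametric group statistics —
as reusable, tested Python.

## The task and the models

**Reward mapping.** A trial is an 8-keystroke sequence described by its 7
inter-keystroke intervals (IKIs) `z`. The rewarded performance measure is the
Euclidean norm of the successive-difference vector
`Δz = (z₂−z₁, …, z₇−z₆)`, and the trial score is

```
score = 100 · exp(−| ‖Δz_target‖ − ‖Δz_performed‖ |)
```

Many IKI patterns share one norm, so the movement-to-reward mapping is
many-to-one and the reward structure is uncertain from the performer's side.

**Perceptual model.** Scores `u` are filtered with a two-level Hierarchical
Gaussian Filter (HGF) for continuous inputs: a reward tendency `x₁`
(belief `μ₁, σ₁`) performing a random walk whose step variance
`exp(κ·x₂ + ω)` is governed by the log-volatility `x₂` (belief `μ₂, σ₂`).
Each belief mean moves by a precision-weighted prediction error (pwPE):
`ε₁` updates the reward belief, `ε₂` the volatility belief.

**Response models.** Trialwise behaviour — chiefly the timing exploration
`Y^k = log |Δ cvIKI^k|`, the unsigned change in the within-trial coefficient
of variation of IKIs — is regressed on lagged belief quantities:

```
Y^k = β₀ + β₁·ε₁^(k−1) + β₂·ε₂^(k−1) + ζ,   ζ ~ N(0, ζ²)
```

Four predictor families (belief means, pwPEs, reward-related, and
volatility-related pairs) crossed with four response variables give 16
candidate models, compared per subject by Laplace log model evidence and
across subjects by random-effects Bayesian model selection (Dirichlet
variational scheme + Monte-Carlo exceedance probabilities).

**Group statistics.** Repeated-measures permutation tests with synchronised
rearrangements (one-way and block × stimulation factorials), paired
sign-flip permutation tests, adaptive two-stage linear step-up FDR control,
and the probability of superiority for dependent samples (Δ_dep) with
percentile-bootstrap confidence intervals.

**Synthetic performers.** Because the package must be testable without raw
study data, `rewardtap.simulate` provides closed-loop agents: each trial the
agent draws its exploration magnitude from the response model using its own
pwPEs, perturbs its timing pattern toward the best-scoring pattern found so
far, receives the reward score, and updates its HGF beliefs. Sessions emit
both observable data and the generating latents, so parameter- and
model-recovery close the loop end to end.

## Worked example

```python
import numpy as np
from rewardtap import (
    iki_difference_norm, reward_score,
    AgentConfig, simulate_agent_session,
    ResponseModelSpec, FitConfig, fit_subject,
)

# the task's winning timing pattern
norm = iki_difference_norm([0.2, 1, 0.2, 1, 0.2, 1, 0.2])
print(norm)                      # 1.9595917942265426  (printed as 1.9596)
print(reward_score(norm))        # 99.99917942602099   (100 points at target)

# one simulated session: 20 baseline + 90 learning trials
session = simulate_agent_session(AgentConfig(seed=42))
print([round(float(session.scores.u[i*30:(i+1)*30].mean()), 1)
       for i in range(3)])       # [62.1, 83.4, 89.2] — scores rise by block

# recover the agent's response coefficients from its scores + exploration
spec = ResponseModelSpec("timing_exploration", ("eps1", "eps2"), family="b")
fit = fit_subject(session.scores, session.exploration, spec, FitConfig(seed=0))
print(round(fit.beta1, 3), round(fit.beta2, 3), round(fit.zeta, 3))
# -0.42 3.839 1.398   (generating values: -0.45, 4.0, 1.3)
```

The fitted `β₁ < 0` means larger reward pwPEs (rising reward expectation) are
followed by *less* exploration — exploitation; `β₂ > 0` means larger
volatility pwPEs are followed by *more* exploration.

A full cohort pipeline (simulate → metrics → fit → BMS → stats → report)
runs from the command line:

```bash
rewardtap all --out out/ --seed 1          # or: rewardtap simulate / fit / ...
```

writing tidy TSV/JSON artifacts plus a Markdown report with full seed and
config-hash provenance.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch through the package, the self-contained
reward-function quantities of the task — the difference-vector norm of the
printed IKI pattern and its score against the sequence's target norm — and
writes them as JSON.

## Layout

- `rewardtap.metrics` — reward mapping, cv measures, exploration series
- `rewardtap.hgf` — two-level continuous-input HGF (`HGFFilter`)
- `rewardtap.response` — 16-model response family, joint MAP fit + Laplace
  LME (`HGFResponseRegressor`)
- `rewardtap.bms` — random-effects Bayesian model selection (`DirichletBMS`)
- `rewardtap.stats` — permutation tests, adaptive FDR, Δ_dep + bootstrap
- `rewardtap.simulate` — baseline and closed-loop performer agents
- `rewardtap.midi` / `rewardtap.pipeline` / `rewardtap.cli` — I/O and
  orchestration

See `docs/methods.md` for the modelling assumptions, parameter defaults and
their rationale, and known limitations.
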