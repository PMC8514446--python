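"""Generative performer agents for the reward-learning task.

The study design is emulated end to end: an isochronous baseline block of 20
trials whose residual timing variability is pure motor noise, followed by 3
learning blocks of 30 trials in which an agent explores the timing dimension
under trialwise reward feedback.

The agent moves through a one-parameter slice of the timing space: its
intended pattern is ``base_tempo * (1 + c * d)`` where ``d`` is a fixed
zero-mean, unit-sd alternating shape vector and ``c`` is the intended
within-trial cvIKI.  The difference-vector norm is then exactly proportional
to ``c``, so reward is maximal at ``c* = target_norm / (base_tempo *
‖Δd‖)``.  Each trial the agent draws its log exploration magnitude from the
response model ``N(beta0 + beta1*eps1 + beta2*eps2, zeta)`` using its own
precision-weighted prediction errors from the previous trial, steps ``c`` by
that magnitude in a direction biased toward the best-scoring value found so
far, performs the pattern with multiplicative Gaussian motor noise, receives
the reward score, and updates its beliefs with the HGF.  The perturbation
policy (best-so-far bias) is a modelling choice of this package; only the
magnitude law matters for the downstream analysis and the policy is swappable
via ``explore_policy``.

Every session emits both the observable data (trials, scores) and the
generating latents (pwPEs, exploration draws) so that parameter-recovery
tests can close the loop.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .hgf import BeliefTrajectory, HGFParams, hgf_filter, hgf_step, initial_state
from .metrics import (
    TARGET_NORM,
    Block,
    ScoreSeries,
    Trial,
    iki_difference_norm,
    reward_score,
)

__all__ = [
    "AgentConfig",
    "AgentSession",
    "shape_direction",
    "simulate_baseline",
    "simulate_agent_session",
    "simulate_cohort",
    "recovery_config",
    "CSV_COLUMNS",
]

CSV_COLUMNS = [
    "subject_id", "condition", "phase", "block", "trial", "position",
    "iki_s", "velocity", "pitch", "is_error",
]

#: Eight-note sequence (four white keys up then down), MIDI note numbers.
DEFAULT_PITCHES = (60, 62, 64, 65, 65, 64, 62, 60)


def shape_direction(n_iki: int = 7) -> np.ndarray:
    """Alternating short-long shape vector: zero mean, unit population sd."""
    if n_iki < 2:
        raise ValueError("need at least 2 intervals")
    raw = np.where(np.arange(n_iki) % 2 == 0, 1.0, -1.0)
    centred = raw - raw.mean()
    return centred / np.std(centred)


@dataclass(frozen=True)
class AgentConfig:
    """Generative settings for one simulated performer.

    The response coefficients follow the observed group-level signs (negative
    ``beta1``: larger reward pwPEs are followed by exploitation; positive
    ``beta2``: larger volatility pwPEs by exploration) and the noise scale
    ``zeta_gen`` matches the reported group-average residual noise.
    Magnitudes are chosen for identifiability at 90 trials given the pwPE
    scales the default perceptual parameters produce on 0-100 scores.
    """

    beta0: float = -5.0
    beta1: float = -0.45
    beta2: float = 4.0
    zeta_gen: float = 1.3
    hgf_params: HGFParams = field(default_factory=HGFParams)
    target_norm: float = TARGET_NORM
    n_baseline: int = 20
    n_learning: int = 90
    block_size: int = 30
    n_iki: int = 7
    base_tempo: float = 0.6
    motor_noise_cv: float = 0.05
    explore_bias: float = 0.6
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_baseline <= 0 or self.n_learning <= 0 or self.block_size <= 0:
            raise ValueError("trial counts must be positive")
        if self.n_learning % self.block_size != 0:
            raise ValueError("n_learning must be a multiple of block_size")
        if self.motor_noise_cv < 0:
            raise ValueError("motor_noise_cv must be non-negative")
        if self.zeta_gen <= 0:
            raise ValueError("zeta_gen must be positive")
        if not 0 <= self.explore_bias <= 1:
            raise ValueError("explore_bias must lie in [0, 1]")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must lie in [0, 1)")
        if self.base_tempo <= 0 or self.n_iki < 2:
            raise ValueError("invalid sequence geometry")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    @property
    def n_blocks(self) -> int:
        return self.n_learning // self.block_size

    def optimal_cv(self) -> float:
        """Intended cvIKI at which the reward score is exactly 100."""
        d = shape_direction(self.n_iki)
        return self.target_norm / (self.base_tempo * np.linalg.norm(np.diff(d)))


def recovery_config(seed: int = 0, **overrides) -> AgentConfig:
    """Agent configuration for parameter-recovery studies.

    Recovery of the volatility coefficient needs sessions with sustained
    volatility signal, so this preset keeps the agent livelier than the
    cohort default (larger baseline exploration, response coefficients sized
    to the resulting pwPE spread); the residual noise scale stays at the
    group-average value.  See the methods note for the sizing argument.
    """
    kw = dict(beta0=-4.0, beta1=-0.4, beta2=2.0, explore_bias=0.6, seed=seed)
    kw.update(overrides)
    return AgentConfig(**kw)


@dataclass
class AgentSession:
    """One simulated session: observable blocks plus generating latents."""

    baseline: Block
    learning_blocks: list[Block]
    scores: ScoreSeries
    trajectory: BeliefTrajectory
    exploration: np.ndarray      # latent log exploration magnitudes, one/trial
    intended_cv: np.ndarray      # intended cvIKI per learning trial
    config: AgentConfig

    @property
    def learning_trials(self) -> list[Trial]:
        return [t for b in self.learning_blocks for t in b.trials]


def _noisy_pattern(
    intended: np.ndarray, noise_cv: float, rng: np.random.Generator
) -> np.ndarray:
    """Multiplicative Gaussian motor noise; resamples to keep IKIs positive."""
    for _ in range(100):
        iki = intended * (1.0 + noise_cv * rng.standard_normal(intended.size))
        if np.all(iki > 0):
            return iki
    raise RuntimeError("could not draw a positive IKI pattern")


def simulate_baseline(cfg: AgentConfig, rng: np.random.Generator | None = None) -> Block:
    """Isochronous baseline block with multiplicative Gaussian motor noise."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    intended = np.full(cfg.n_iki, cfg.base_tempo)
    trials = []
    for _ in range(cfg.n_baseline):
        iki = _noisy_pattern(intended, cfg.motor_noise_cv, rng) \
            if cfg.motor_noise_cv > 0 else intended.copy()
        vel = np.clip(np.round(64 + 4 * rng.standard_normal(cfg.n_iki + 1)), 1, 127)
        trials.append(Trial(
            iki=iki, velocity=vel,
            pitches=np.resize(DEFAULT_PITCHES, cfg.n_iki + 1),
            is_error=bool(rng.random() < cfg.error_rate),
        ))
    return Block(phase="baseline", trials=trials)


def simulate_agent_session(
    cfg: AgentConfig,
    explore_policy: Callable[[float, float, float, np.random.Generator], float]
    | None = None,
) -> AgentSession:
    """Simulate one full session (baseline + learning) of one agent.

    ``explore_policy(c, best_c, step, rng)`` maps the current intended cv, the
    best-scoring cv so far and the drawn step magnitude to the next intended
    cv; the default steps toward ``best_c`` with probability ``explore_bias``.
    """
    rng = np.random.default_rng(cfg.seed)
    baseline = simulate_baseline(cfg, rng)

    d = shape_direction(cfg.n_iki)
    c_max = 0.95 / float(np.max(np.abs(d)))
    c_min = 1e-3

    def default_policy(c, best_c, step, rng):
        if best_c is None or rng.random() > cfg.explore_bias:
            direction = 1.0 if rng.random() < 0.5 else -1.0
        else:
            direction = math.copysign(1.0, best_c - c) if best_c != c else 1.0
        return float(np.clip(c + direction * step, c_min, c_max))

    policy = explore_policy or default_policy

    params = cfg.hgf_params
    state = initial_state(params)
    eps1_prev = 0.0
    eps2_prev = 0.0
    c = max(cfg.motor_noise_cv, c_min)  # start near the isochronous baseline
    best_c: float | None = None
    best_u = -math.inf

    u = np.empty(cfg.n_learning)
    ys = np.empty(cfg.n_learning)
    cs = np.empty(cfg.n_learning)
    trials: list[Trial] = []
    for k in range(cfg.n_learning):
        y = cfg.beta0 + cfg.beta1 * eps1_prev + cfg.beta2 * eps2_prev \
            + cfg.zeta_gen * rng.standard_normal()
        # a step beyond the whole reachable cv range is just maximal exploration
        c = policy(c, best_c, math.exp(min(y, 1.0)), rng)
        intended = cfg.base_tempo * (1.0 + c * d)
        iki = _noisy_pattern(intended, cfg.motor_noise_cv, rng) \
            if cfg.motor_noise_cv > 0 else intended
        score = reward_score(iki_difference_norm(iki), cfg.target_norm)
        vel = np.clip(np.round(64 + 4 * rng.standard_normal(cfg.n_iki + 1)), 1, 127)
        trials.append(Trial(
            iki=iki, velocity=vel,
            pitches=np.resize(DEFAULT_PITCHES, cfg.n_iki + 1),
            is_error=bool(rng.random() < cfg.error_rate),
        ))
        if score > best_u:
            best_u, best_c = score, c
        state, rec = hgf_step(state, score, params, trial=k + 1)
        eps1_prev, eps2_prev = rec["eps1"], rec["eps2"]
        u[k], ys[k], cs[k] = score, y, c

    blocks = [
        Block(
            phase="learning",
            trials=trials[i * cfg.block_size:(i + 1) * cfg.block_size],
            block_index=i + 1,
            scores=u[i * cfg.block_size:(i + 1) * cfg.block_size],
        )
        for i in range(cfg.n_blocks)
    ]
    return AgentSession(
        baseline=baseline,
        learning_blocks=blocks,
        scores=ScoreSeries(u),
        trajectory=hgf_filter(u, params),
        exploration=ys,
        intended_cv=cs,
        config=cfg,
    )


def _session_rows(
    session: AgentSession, subject_id: str, condition: str
) -> list[dict]:
    rows = []

    def add(trial: Trial, phase: str, block: int, trial_no: int):
        n_keys = trial.iki.size + 1
        for pos in range(n_keys):
            rows.append({
                "subject_id": subject_id,
                "condition": condition,
                "phase": phase,
                "block": block,
                "trial": trial_no,
                "position": pos + 1,
                "iki_s": np.nan if pos == 0 else trial.iki[pos - 1],
                "velocity": int(trial.velocity[pos]) if trial.velocity is not None
                else np.nan,
                "pitch": int(trial.pitches[pos]) if trial.pitches is not None
                else np.nan,
                "is_error": int(trial.is_error),
            })

    for i, t in enumerate(session.baseline.trials):
        add(t, "baseline", 0, i + 1)
    for b in session.learning_blocks:
        for i, t in enumerate(b.trials):
            add(t, "learning", b.block_index, i + 1)
    return rows


def simulate_cohort(
    n_subjects: int = 19,
    condition_configs: dict[str, AgentConfig] | None = None,
    seed: int = 0,
    beta_sd: Sequence[float] = (0.3, 0.05, 0.3),
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a full crossed cohort (subjects x stimulation conditions).

    Per-subject random effects (Gaussian, sd ``beta_sd``) are added to the
    condition-mean response coefficients and shared across that subject's
    sessions, emulating stable individual traits.

    Returns
    -------
    data : DataFrame
        Trialwise keystroke table in the package CSV schema.
    latents : DataFrame
        Per learning trial: generating pwPEs, exploration draw, intended cv.
    gen_params : DataFrame
        Per subject/condition generating coefficients (recovery ground truth).
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    if condition_configs is None:
        condition_configs = {
            "lM1": AgentConfig(),
            "rFPC": AgentConfig(),
            "sham": AgentConfig(),
        }
    if len(condition_configs) < 1:
        raise ValueError("need at least 1 condition")

    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    subj_offsets = rng.standard_normal((n_subjects, 3)) * np.asarray(beta_sd)

    rows: list[dict] = []
    latent_rows: list[dict] = []
    gen_rows: list[dict] = []
    session_seeds = np.random.SeedSequence(seed + 1).generate_state(
        n_subjects * len(condition_configs)) % (2 ** 31)
    i_sess = 0
    for i_subj in range(n_subjects):
        subject_id = f"S{i_subj + 1:02d}"
        for cond, base_cfg in condition_configs.items():
            cfg = replace(
                base_cfg,
                beta0=base_cfg.beta0 + subj_offsets[i_subj, 0],
                beta1=base_cfg.beta1 + subj_offsets[i_subj, 1],
                beta2=base_cfg.beta2 + subj_offsets[i_subj, 2],
                seed=int(session_seeds[i_sess]),
            )
            i_sess += 1
            session = simulate_agent_session(cfg)
            rows.extend(_session_rows(session, subject_id, cond))
            for k in range(cfg.n_learning):
                latent_rows.append({
                    "subject_id": subject_id,
                    "condition": cond,
                    "trial": k + 1,
                    "u": session.scores.u[k],
                    "eps1": session.trajectory.eps1[k],
                    "eps2": session.trajectory.eps2[k],
                    "exploration": session.exploration[k],
                    "intended_cv": session.intended_cv[k],
                })
            gen_rows.append({
                "subject_id": subject_id,
                "condition": cond,
                "beta0": cfg.beta0,
                "beta1": cfg.beta1,
                "beta2": cfg.beta2,
                "zeta": cfg.zeta_gen,
                "seed": cfg.seed,
            })

    return (
        pd.DataFrame(rows, columns=CSV_COLUMNS),
        pd.DataFrame(latent_rows),
        pd.DataFrame(gen_rows),
    )
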