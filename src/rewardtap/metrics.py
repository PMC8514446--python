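"""Behavioural performance measures and the reward mapping.

A trial is one rendition of an 8-keystroke sequence, represented by its 7
inter-keystroke intervals (IKI, seconds).  The rewarded performance measure is
the Euclidean norm of the vector of successive IKI differences, and the trial
score maps the distance between performed and target norm through a negative
exponential onto a 0-100 point scale.  Because many distinct IKI patterns share
one difference norm, the movement-to-reward mapping is many-to-one.

Motor variability is quantified with coefficients of variation (cv = sd/mean):
within a trial across keystroke positions (``within_trial_cv``, the
exploration-relevant timing measure) and across trials per position within a
block (``block_variability``; during the isochronous baseline this residual
variability is read as motor noise).  All cv's use the population (ddof=0)
standard deviation and are dimensionless and invariant to global tempo changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "Trial",
    "Block",
    "ScoreSeries",
    "TARGET_NORM",
    "iki_difference_norm",
    "reward_score",
    "within_trial_cv",
    "block_variability",
    "exploration_series",
    "exploration_after_outcome",
]

#: Target difference-vector norm of the hidden rewarded timing pattern (s).
#: One maximally rewarded performance is [0.2, 1, 0.2, 1, 0.2, 1, 0.2] s.
TARGET_NORM = 1.9596

#: Floor applied to |Δcv| before the log transform (see ``exploration_series``).
DEFAULT_LOG_EPS = 1e-6


class InsufficientDataError(ValueError):
    """Raised when a measure is requested from too few usable observations."""


@dataclass(frozen=True)
class Trial:
    """One sequence rendition.

    Parameters
    ----------
    iki : array-like of float
        Ordered inter-keystroke intervals in seconds, length ``n - 1`` for an
        ``n``-keystroke sequence.  All entries must be strictly positive.
    velocity : array-like of float, optional
        MIDI key velocities (arbitrary units, 0-127), one per keystroke.
    pitches : array-like of int, optional
        MIDI note numbers, one per keystroke.
    is_error : bool
        Wrong-note flag.  Error trials are kept (never silently dropped) but
        are excluded from cv-based measures.
    """

    iki: np.ndarray
    velocity: np.ndarray | None = None
    pitches: np.ndarray | None = None
    is_error: bool = False

    def __post_init__(self) -> None:
        iki = np.asarray(self.iki, dtype=float)
        if iki.ndim != 1 or iki.size < 1:
            raise ValueError("iki must be a non-empty 1-d vector")
        if not np.all(np.isfinite(iki)) or np.any(iki <= 0):
            raise ValueError("all IKI values must be finite and strictly positive")
        object.__setattr__(self, "iki", iki)
        if self.velocity is not None:
            vel = np.asarray(self.velocity, dtype=float)
            if vel.size not in (iki.size, iki.size + 1):
                raise ValueError(
                    "velocity length inconsistent with sequence length "
                    f"(got {vel.size} for {iki.size} IKIs)"
                )
            object.__setattr__(self, "velocity", vel)
        if self.pitches is not None:
            object.__setattr__(self, "pitches", np.asarray(self.pitches))

    @property
    def n_keystrokes(self) -> int:
        return self.iki.size + 1


@dataclass
class Block:
    """An ordered set of trials from one phase.

    Baseline blocks carry no scores; learning blocks carry one score per trial.
    """

    phase: Literal["baseline", "learning"]
    trials: list[Trial] = field(default_factory=list)
    block_index: int | None = None
    scores: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.phase not in ("baseline", "learning"):
            raise ValueError(f"unknown phase {self.phase!r}")
        if self.phase == "baseline" and self.scores is not None:
            raise ValueError("baseline blocks carry no scores")
        if self.scores is not None:
            scores = np.asarray(self.scores, dtype=float)
            if scores.size != len(self.trials):
                raise ValueError("one score per learning trial required")
            object.__setattr__(self, "scores", scores)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def error_rate(self) -> float:
        """Fraction of wrong-note trials in the block."""
        if not self.trials:
            raise InsufficientDataError("empty block")
        return float(np.mean([t.is_error for t in self.trials]))


@dataclass(frozen=True)
class ScoreSeries:
    """Trialwise feedback scores ``u``, dimensionless in [0, 100]."""

    u: np.ndarray

    def __post_init__(self) -> None:
        u = np.asarray(self.u, dtype=float)
        if u.ndim != 1 or u.size == 0:
            raise ValueError("u must be a non-empty 1-d vector")
        if not np.all(np.isfinite(u)):
            raise ValueError("scores must be finite")
        if np.any(u < 0) or np.any(u > 100):
            raise ValueError("scores must lie in [0, 100]")
        object.__setattr__(self, "u", u)

    def __len__(self) -> int:
        return self.u.size


def _as_iki(iki: Sequence[float] | np.ndarray | Trial) -> np.ndarray:
    if isinstance(iki, Trial):
        return iki.iki
    arr = np.asarray(iki, dtype=float)
    if arr.ndim != 1:
        raise ValueError("IKI input must be 1-d")
    return arr


def iki_difference_norm(iki: Sequence[float] | np.ndarray | Trial) -> float:
    """Euclidean norm of the successive-difference vector of an IKI pattern.

    ``Δz_j = z_{j+1} - z_j`` over the ordered intervals ``z``; the returned
    ``‖Δz‖`` is the rewarded performance measure.  It is zero exactly for an
    isochronous performance and invariant to reversing the pattern.

    Examples
    --------
    >>> round(iki_difference_norm([0.2, 1, 0.2, 1, 0.2, 1, 0.2]), 4)
    1.9596
    """
    z = _as_iki(iki)
    if z.size < 2:
        raise ValueError("need at least 2 intervals to form a difference vector")
    if not np.all(np.isfinite(z)) or np.any(z <= 0):
        raise ValueError("all intervals must be finite and strictly positive")
    return float(np.linalg.norm(np.diff(z)))


def reward_score(performed_norm: float, target_norm: float = TARGET_NORM) -> float:
    """Trial score: ``100 * exp(-|target_norm - performed_norm|)``.

    Strictly decreasing in the norm mismatch; 100 points exactly when the
    performed difference norm matches the target.
    """
    if performed_norm < 0 or target_norm < 0:
        raise ValueError("norms must be non-negative")
    return float(100.0 * np.exp(-abs(target_norm - performed_norm)))


def within_trial_cv(trial: Trial | Sequence[float] | np.ndarray) -> float:
    """Trialwise cvIKI: population sd of the trial's IKIs over their mean.

    Dimensionless and invariant under global tempo scaling.  This is the
    timing measure whose trial-to-trial unsigned change quantifies
    exploration.
    """
    z = _as_iki(trial)
    if z.size < 2:
        raise ValueError("need at least 2 intervals for a cv")
    if np.any(z <= 0):
        raise ValueError("all intervals must be strictly positive")
    return float(np.std(z) / np.mean(z))


def block_variability(
    block: Block | Sequence[Trial],
    dimension: Literal["timing", "velocity"] = "timing",
) -> float:
    """Across-trial cv per keystroke position, averaged over positions.

    For each position the cv (population sd / mean) is taken across the
    block's non-error trials, then averaged across positions.  During the
    baseline phase this is the motor-noise measure.
    """
    trials = block.trials if isinstance(block, Block) else list(block)
    usable = [t for t in trials if not t.is_error]
    if len(usable) < 2:
        raise InsufficientDataError("need at least 2 non-error trials")
    if dimension == "timing":
        mat = np.array([t.iki for t in usable], dtype=float)
    elif dimension == "velocity":
        if any(t.velocity is None for t in usable):
            raise ValueError("velocity not recorded for all trials")
        mat = np.array([t.velocity for t in usable], dtype=float)
    else:
        raise ValueError(f"unknown dimension {dimension!r}")
    if mat.ndim != 2:
        raise ValueError("trials must share one sequence length")
    cv_per_position = np.std(mat, axis=0) / np.mean(mat, axis=0)
    return float(np.mean(cv_per_position))


def exploration_series(
    trials: Sequence[Trial] | Sequence[float] | np.ndarray,
    eps: float = DEFAULT_LOG_EPS,
) -> np.ndarray:
    """Trialwise timing exploration ``Y^k = log|cvIKI^k - cvIKI^{k-1}|``.

    Accepts either a sequence of trials (cvIKI computed per trial) or a
    precomputed cvIKI series.  The unsigned change is floored at ``eps``
    before the log so that exact repeats stay finite and the series keeps
    length ``n_trials - 1``.
    """
    if len(trials) >= 1 and isinstance(trials[0], Trial):
        cv = np.array([within_trial_cv(t) for t in trials], dtype=float)
    else:
        cv = np.asarray(trials, dtype=float)
    if cv.size < 2:
        raise ValueError("need at least 2 trials for an exploration series")
    dcv = np.abs(np.diff(cv))
    return np.log(np.maximum(dcv, eps))


def exploration_after_outcome(
    scores: ScoreSeries | Sequence[float] | np.ndarray,
    exploration: Sequence[float] | np.ndarray,
) -> tuple[float, float]:
    """Conditional mean exploration after score drops vs. score rises.

    ``exploration[j]`` is taken to be ``Y^{k}`` for trial ``k = j + 2`` (the
    unsigned change from trial ``k-1`` to ``k``).  Each ``Y^k`` with
    ``k >= 3`` is classified by the sign of the preceding score change
    ``u^{k-1} - u^{k-2}``; zero changes are left out of both groups.

    Returns
    -------
    (mean_after_drop, mean_after_rise)
    """
    u = scores.u if isinstance(scores, ScoreSeries) else np.asarray(scores, float)
    y = np.asarray(exploration, dtype=float)
    if y.size != u.size - 1:
        raise ValueError(
            f"exploration length {y.size} does not match {u.size} scores "
            "(expected one fewer)"
        )
    change = np.diff(u)[:-1]  # u^{k-1} - u^{k-2} preceding Y^k, k = 3..n
    y_usable = y[1:]
    drops = y_usable[change < 0]
    rises = y_usable[change > 0]
    if drops.size == 0 or rises.size == 0:
        raise InsufficientDataError("need at least one score drop and one rise")
    return float(np.mean(drops)), float(np.mean(rises))
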