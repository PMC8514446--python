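"""Non-parametric group inference for repeated-measures designs.

Permutation tests respect the within-subject structure of the crossed design:
condition labels are rearranged only within each subject (synchronised across
the other factor for factorial main effects), so the null distribution
preserves between-subject differences.  All permutation p-values use the
add-one convention ``p = (1 + #{perm >= obs}) / (n_perm + 1)`` and therefore
lie in (0, 1]; exhaustive enumeration (which includes the identity
rearrangement and is seed-free) is used whenever the arrangement count is
within the configured cap.

Multiple comparisons are handled with the adaptive two-stage linear step-up
false-discovery-rate procedure, which first estimates the number of true null
hypotheses with a step-up pass at level q/(1+q) and then reruns the step-up at
the correspondingly sharpened level.  Effect sizes for paired contrasts use
the probability of superiority for dependent samples (ties counting 1/2) with
percentile-bootstrap confidence intervals.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PermutationResult",
    "FactorialResult",
    "EffectSize",
    "FDRResult",
    "perm_oneway_rm",
    "perm_factorial_rm",
    "paired_perm_test",
    "adaptive_fdr",
    "delta_dep",
    "bootstrap_ci_delta",
]

#: Exhaustive enumeration is used when the arrangement count is at most this.
DEFAULT_EXHAUSTIVE_CAP = 100_000

_EPS = 1e-12


@dataclass(frozen=True)
class PermutationResult:
    observed_stat: float
    p: float
    n_perm: int
    exhaustive: bool


@dataclass(frozen=True)
class FactorialResult:
    """Main effects and interaction of a fully crossed two-factor RM design."""

    factor_a: PermutationResult
    factor_b: PermutationResult
    interaction: PermutationResult


@dataclass(frozen=True)
class EffectSize:
    delta_dep: float
    ci_low: float = math.nan
    ci_high: float = math.nan
    n_boot: int = 0


@dataclass(frozen=True)
class FDRResult:
    q: float
    p_fdr: float
    rejected: np.ndarray
    m0_hat: int


def _pvalue(obs: float, null: np.ndarray, exhaustive: bool) -> float:
    ge = int(np.sum(null >= obs - _EPS))
    if exhaustive:
        return ge / null.size
    return (1 + ge) / (null.size + 1)


def _check_matrix(data, name="data") -> np.ndarray:
    arr = np.asarray(data, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains missing or non-finite cells; "
                         "the design must be fully crossed and complete")
    return arr


def _between_ss(means: np.ndarray) -> float:
    return float(np.sum((means - means.mean()) ** 2))


def perm_oneway_rm(
    data,
    n_perm: int = 5000,
    seed: int = 0,
    exhaustive_cap: int = DEFAULT_EXHAUSTIVE_CAP,
) -> PermutationResult:
    """One-way repeated-measures permutation test (synchronised rearrangements).

    ``data`` is ``(n_subjects, n_conditions)``; the statistic is the
    between-condition sum of squares of condition means, and the null is
    generated by independently permuting the condition labels within each
    subject.  Enumeration is exhaustive when ``(k!)^n`` is within the cap.
    """
    x = _check_matrix(data)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("data must be (>=2 subjects, >=2 conditions)")
    n, k = x.shape
    obs = _between_ss(x.mean(axis=0))

    perms = np.array(list(itertools.permutations(range(k))))
    total = perms.shape[0] ** n
    rows = np.arange(n)[None, :, None]
    if total <= exhaustive_cap:
        combos = np.array(
            list(itertools.product(range(perms.shape[0]), repeat=n)))
        permuted = x[rows, perms[combos]]          # (total, n, k)
        null = ((permuted.mean(axis=1)
                 - permuted.mean(axis=(1, 2), keepdims=True)[:, 0]) ** 2
                ).sum(axis=1)
        return PermutationResult(obs, _pvalue(obs, null, True), total, True)

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, perms.shape[0], size=(n_perm, n))
    permuted = x[rows, perms[idx]]
    null = ((permuted.mean(axis=1)
             - permuted.mean(axis=(1, 2), keepdims=True)[:, 0]) ** 2
            ).sum(axis=1)
    return PermutationResult(obs, _pvalue(obs, null, False), n_perm, False)


def _interaction_ss(x: np.ndarray) -> float:
    """Sum of squared double-centred cell means of an (n, a, b) array."""
    cell = x.mean(axis=0)
    resid = cell - cell.mean(axis=0, keepdims=True) \
        - cell.mean(axis=1, keepdims=True) + cell.mean()
    return float(np.sum(resid ** 2))


def perm_factorial_rm(
    data,
    n_perm: int = 5000,
    seed: int = 0,
) -> FactorialResult:
    """Two-factor fully crossed repeated-measures permutation test.

    ``data`` is ``(n_subjects, a_levels, b_levels)`` (e.g. blocks x
    stimulation conditions).  Each main effect is tested with synchronised
    rearrangements: the tested factor's levels are permuted within each
    subject with the *same* permutation applied across all levels of the
    other factor, which preserves the other factor's marginal structure.
    The statistic is the between-level sum of squares of marginal means.
    The interaction statistic is the sum of squared double-centred cell
    means, with a null generated by permuting the second factor's levels
    independently within each level of the first (marginal means are removed
    by the double-centring, so only non-additive structure is measured).
    """
    x = _check_matrix(data)
    if x.ndim != 3:
        raise ValueError("data must be (subjects, factor A levels, factor B levels)")
    n, a, b = x.shape
    if n < 2 or a < 2 or b < 2:
        raise ValueError("need >=2 subjects and >=2 levels per factor")
    rng = np.random.default_rng(seed)

    def _main(axis: int) -> PermutationResult:
        levels = x.shape[axis]
        marg_axes = tuple(i for i in range(3) if i != axis)
        obs = _between_ss(x.mean(axis=marg_axes))
        null = np.empty(n_perm)
        for i in range(n_perm):
            perm_x = np.empty_like(x)
            for s in range(n):
                order = rng.permutation(levels)
                perm_x[s] = np.take(x[s], order, axis=axis - 1)
            null[i] = _between_ss(perm_x.mean(axis=marg_axes))
        return PermutationResult(obs, _pvalue(obs, null, False), n_perm, False)

    def _inter() -> PermutationResult:
        obs = _interaction_ss(x)
        null = np.empty(n_perm)
        for i in range(n_perm):
            perm_x = np.empty_like(x)
            for s in range(n):
                for j in range(a):
                    perm_x[s, j] = x[s, j, rng.permutation(b)]
            null[i] = _interaction_ss(perm_x)
        return PermutationResult(obs, _pvalue(obs, null, False), n_perm, False)

    return FactorialResult(_main(1), _main(2), _inter())


def paired_perm_test(
    x,
    y,
    n_perm: int = 5000,
    seed: int = 0,
    exhaustive_cap: int = DEFAULT_EXHAUSTIVE_CAP,
) -> PermutationResult:
    """Paired permutation test via within-pair sign flips.

    The statistic is the mean paired difference, compared two-sidedly (by
    absolute value) with its sign-flip null; exhaustive over all ``2^n``
    flips when within the cap.
    """
    xv = _check_matrix(x, "x").ravel()
    yv = _check_matrix(y, "y").ravel()
    if xv.size != yv.size:
        raise ValueError("x and y must have equal length")
    if xv.size < 2:
        raise ValueError("need at least 2 pairs")
    d = xv - yv
    n = d.size
    obs = abs(float(d.mean()))

    if 2 ** n <= exhaustive_cap:
        signs = np.array(list(itertools.product((1.0, -1.0), repeat=n)))
        null = np.abs((signs * d).mean(axis=1))
        return PermutationResult(
            float(d.mean()), _pvalue(obs, null, True), signs.shape[0], True)

    rng = np.random.default_rng(seed)
    signs = rng.choice((1.0, -1.0), size=(n_perm, n))
    null = np.abs((signs * d).mean(axis=1))
    return PermutationResult(
        float(d.mean()), _pvalue(obs, null, False), n_perm, False)


def adaptive_fdr(pvals, q: float = 0.05) -> FDRResult:
    """Adaptive two-stage linear step-up FDR control.

    Stage 1 runs the linear step-up procedure at level ``q' = q/(1+q)`` and
    uses its rejection count ``r1`` to estimate the number of true nulls as
    ``m0 = m - r1``; stage 2 reruns the step-up at the sharpened level
    ``q' * m / m0``.  Returns the adapted threshold ``P_FDR`` (the largest
    rejected p-value, 0 when nothing is rejected) and per-hypothesis flags.
    """
    p = np.asarray(pvals, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("empty p-value set")
    if np.any(p < 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    m = p.size
    q1 = q / (1.0 + q)

    def _step_up(level: float) -> int:
        ps = np.sort(p)
        crit = level * np.arange(1, m + 1) / m
        passed = np.nonzero(ps <= crit + _EPS)[0]
        return 0 if passed.size == 0 else int(passed[-1] + 1)

    r1 = _step_up(q1)
    if r1 == 0:
        return FDRResult(q, 0.0, np.zeros(m, dtype=bool), m)
    if r1 == m:
        return FDRResult(q, float(np.max(p)), np.ones(m, dtype=bool), 0)
    m0 = m - r1
    r2 = _step_up(q1 * m / m0)
    if r2 == 0:
        return FDRResult(q, 0.0, np.zeros(m, dtype=bool), m0)
    p_fdr = float(np.sort(p)[r2 - 1])
    return FDRResult(q, p_fdr, p <= p_fdr + _EPS, m0)


def delta_dep(x, y) -> EffectSize:
    """Probability of superiority for dependent samples.

    The fraction of pairs with ``x_i > y_i``, ties contributing 1/2, so that
    ``delta_dep(x, y) = 1 - delta_dep(y, x)`` holds exactly.
    """
    xv = _check_matrix(x, "x").ravel()
    yv = _check_matrix(y, "y").ravel()
    if xv.size != yv.size:
        raise ValueError("x and y must have equal length")
    if xv.size < 1:
        raise ValueError("need at least 1 pair")
    wins = (xv > yv).astype(float) + 0.5 * (xv == yv)
    return EffectSize(float(wins.mean()))


def bootstrap_ci_delta(
    x,
    y,
    n_boot: int = 5000,
    level: float = 0.95,
    seed: int = 0,
) -> EffectSize:
    """Percentile-bootstrap confidence interval for the paired superiority.

    Pairs are resampled with replacement; CI bounds are the symmetric
    percentiles of the bootstrap distribution, clipped to [0, 1] and to
    contain the point estimate.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    point = delta_dep(x, y).delta_dep
    xv = np.asarray(x, dtype=float).ravel()
    yv = np.asarray(y, dtype=float).ravel()
    wins = (xv > yv).astype(float) + 0.5 * (xv == yv)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, wins.size, size=(n_boot, wins.size))
    boots = wins[idx].mean(axis=1)
    lo_q = (1.0 - level) / 2.0
    lo, hi = np.quantile(boots, [lo_q, 1.0 - lo_q])
    lo = float(np.clip(min(lo, point), 0.0, 1.0))
    hi = float(np.clip(max(hi, point), 0.0, 1.0))
    return EffectSize(point, lo, hi, n_boot)
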