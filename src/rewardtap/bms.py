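"""Random-effects Bayesian model selection over subjects' log model evidences.

Treats the model identity as a random effect across subjects: model
frequencies in the population carry a Dirichlet prior, and a variational
scheme alternates between subject-wise model posteriors (softmax of LME plus
the expected log frequency) and Dirichlet count updates.  Exceedance
probabilities — the probability that each model is the most frequent in the
population — are estimated by Monte-Carlo sampling of the fitted Dirichlet.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import digamma, gammaln, logsumexp
from sklearn.base import BaseEstimator

__all__ = ["BMSResult", "DirichletBMS", "random_effects_bms"]


@dataclass(frozen=True)
class BMSResult:
    """Posterior Dirichlet over model frequencies and derived summaries."""

    alpha: np.ndarray          # Dirichlet concentrations, one per model
    r: np.ndarray              # expected model frequencies (sum 1)
    xp: np.ndarray             # exceedance probabilities (sum 1, Monte-Carlo)
    n_subjects: int
    n_models: int
    n_iter: int
    converged: bool
    elbo_trace: np.ndarray     # variational objective per iteration

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha.tolist(),
            "r": self.r.tolist(),
            "xp": self.xp.tolist(),
            "n_subjects": self.n_subjects,
            "n_models": self.n_models,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "elbo_trace": self.elbo_trace.tolist(),
        }


def _responsibilities(lme: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Subject-wise model posteriors given current Dirichlet counts (E-step)."""
    log_u = lme + (digamma(alpha) - digamma(alpha.sum()))[None, :]
    return np.exp(log_u - logsumexp(log_u, axis=1, keepdims=True))


class DirichletBMS(BaseEstimator):
    """Random-effects BMS estimator.

    ``fit`` expects an ``(n_subjects, n_models)`` matrix of log model
    evidences; fitted attributes are ``alpha_`` (Dirichlet counts), ``r_``
    (expected frequencies), ``xp_`` (exceedance probabilities) and ``g_``
    (subject-wise model posteriors).

    Parameters
    ----------
    prior_alpha : float
        Dirichlet prior count per model (uniform prior by default).
    n_samples : int
        Monte-Carlo sample count for the exceedance probabilities.
    tol : float
        Convergence tolerance on the change of the variational objective.
    """

    def __init__(
        self,
        prior_alpha: float = 1.0,
        n_samples: int = 1_000_000,
        max_iter: int = 500,
        tol: float = 1e-8,
        seed: int = 0,
    ):
        self.prior_alpha = prior_alpha
        self.n_samples = n_samples
        self.max_iter = max_iter
        self.tol = tol
        self.seed = seed

    def fit(self, X, y=None):
        lme = np.asarray(X, dtype=float)
        if lme.ndim != 2:
            raise ValueError("lme must be a (n_subjects, n_models) matrix")
        n, k = lme.shape
        if n < 1 or k < 2:
            raise ValueError("need at least 1 subject and 2 models")
        if not np.all(np.isfinite(lme)):
            raise ValueError("lme contains non-finite values")
        if self.prior_alpha <= 0:
            raise ValueError("prior_alpha must be positive")

        alpha0 = np.full(k, float(self.prior_alpha))
        alpha = alpha0.copy()
        trace = []
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            g = _responsibilities(lme, alpha)
            alpha = alpha0 + g.sum(axis=0)
            # Full variational lower bound:
            # E_q[log p(lme|m)] + E_q[log p(m|r)] + H[q(m)] - KL(q(r)||p(r)).
            elnr = digamma(alpha) - digamma(alpha.sum())
            ent = -np.where(g > 0, g * np.log(np.where(g > 0, g, 1.0)), 0.0).sum()
            kl_dir = float(
                gammaln(alpha.sum()) - gammaln(alpha).sum()
                - gammaln(alpha0.sum()) + gammaln(alpha0).sum()
                + ((alpha - alpha0) * elnr).sum()
            )
            obj = float((g * (lme + elnr[None, :])).sum() + ent - kl_dir)
            trace.append(obj)
            if len(trace) > 1 and abs(trace[-1] - trace[-2]) < self.tol:
                converged = True
                break
        if not converged:
            raise RuntimeError(
                f"BMS did not converge within {self.max_iter} iterations")

        rng = np.random.default_rng(self.seed)
        xp = np.zeros(k)
        remaining = int(self.n_samples)
        chunk = 200_000
        while remaining > 0:
            take = min(chunk, remaining)
            samples = rng.dirichlet(alpha, size=take)
            idx, counts = np.unique(samples.argmax(axis=1), return_counts=True)
            xp[idx] += counts
            remaining -= take
        xp /= self.n_samples

        self.alpha_ = alpha
        self.r_ = alpha / alpha.sum()
        self.xp_ = xp
        self.g_ = _responsibilities(lme, alpha)
        self.n_subjects_ = n
        self.n_models_ = k
        self.n_iter_ = it
        self.elbo_trace_ = np.asarray(trace)
        return self

    def to_result(self) -> BMSResult:
        if not hasattr(self, "alpha_"):
            raise AttributeError("estimator is not fitted")
        return BMSResult(
            alpha=self.alpha_,
            r=self.r_,
            xp=self.xp_,
            n_subjects=self.n_subjects_,
            n_models=self.n_models_,
            n_iter=self.n_iter_,
            converged=True,
            elbo_trace=self.elbo_trace_,
        )


def random_effects_bms(
    lme,
    prior_alpha: float = 1.0,
    n_samples: int = 1_000_000,
    seed: int = 0,
) -> BMSResult:
    """Random-effects BMS on a subjects-by-models LME matrix (thin wrapper)."""
    est = DirichletBMS(prior_alpha=prior_alpha, n_samples=n_samples, seed=seed)
    return est.fit(lme).to_result()
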