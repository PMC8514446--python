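"""Response models linking lagged HGF belief quantities to trialwise behaviour.

A response model explains one trialwise performance measure ``Y^k`` (e.g. the
timing exploration ``log|ΔcvIKI^k|``) as a linear function of belief
quantities from the *preceding* trial plus Gaussian noise::

    Y^k = beta0 + beta1 * X1^{k-1} + beta2 * X2^{k-1} + zeta

The candidate predictor families follow four scenarios: (a) the posterior
belief means {mu1, mu2}; (b) the precision-weighted prediction errors
{eps1, eps2} — the winning family for timing exploration; (c) the
reward-related quantities {mu1, eps1}; (d) the volatility-related quantities
{mu2, eps2}.  Crossing the four families with four response variables yields
the default table of 16 candidate models.

Fitting is per subject/session and follows the observing-the-observer
convention: the likelihood is that of the observed responses given the score
inputs, with the perceptual parameters entering only through the belief
trajectories they induce; the score series itself is treated as given.  A MAP
search runs over the free perceptual parameters (omega by default) with the
regression coefficients concentrated out in closed form (flat priors on betas
and log zeta make the conditional optimum exactly OLS), followed by a Laplace
approximation of the log model evidence (LME) at the joint optimum.  The
score predictive density can optionally be added to the objective
(``FitConfig.include_perceptual_evidence``).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize
from sklearn.base import BaseEstimator, RegressorMixin

from .hgf import (
    LOG2PI,
    BeliefTrajectory,
    HGFInstabilityError,
    HGFParams,
    hgf_filter,
)
from .metrics import ScoreSeries

__all__ = [
    "PREDICTOR_NAMES",
    "DEFAULT_FAMILIES",
    "DEFAULT_RESPONSE_VARIABLES",
    "ResponseModelSpec",
    "ResponseFit",
    "FitConfig",
    "FitFailureError",
    "enumerate_response_models",
    "response_loglik",
    "HGFResponseRegressor",
    "fit_subject",
]

PREDICTOR_NAMES = ("mu1", "mu2", "eps1", "eps2")

#: Predictor families (a)-(d); each is one candidate predictor set.
DEFAULT_FAMILIES: dict[str, tuple[str, ...]] = {
    "a": ("mu1", "mu2"),
    "b": ("eps1", "eps2"),
    "c": ("mu1", "eps1"),
    "d": ("mu2", "eps2"),
}

#: Trialwise performance measures a participant might tie to reward.
DEFAULT_RESPONSE_VARIABLES = (
    "timing_exploration",    # log|Δ cvIKI|
    "velocity_exploration",  # log|Δ cvVel|
    "tempo_change",          # log|Δ mean IKI|
    "velocity_change",       # log|Δ mean velocity|
)


class FitFailureError(RuntimeError):
    """Optimiser failed to converge after all restarts; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass(frozen=True)
class ResponseModelSpec:
    """One candidate response model: a response variable plus lagged predictors."""

    response_variable: str
    predictors: tuple[str, ...]
    family: str = ""
    model_id: str = ""

    def __post_init__(self) -> None:
        if not self.predictors:
            raise ValueError("at least one predictor required")
        bad = set(self.predictors) - set(PREDICTOR_NAMES)
        if bad:
            raise ValueError(f"unknown predictors {sorted(bad)}")
        if len(set(self.predictors)) != len(self.predictors):
            raise ValueError("duplicate predictors")
        if not self.model_id:
            object.__setattr__(
                self,
                "model_id",
                f"{self.response_variable}~" + "+".join(self.predictors),
            )


def enumerate_response_models(
    response_variables: tuple[str, ...] = DEFAULT_RESPONSE_VARIABLES,
    families: dict[str, tuple[str, ...]] | None = None,
) -> list[ResponseModelSpec]:
    """Deterministic enumeration of the candidate response-model table.

    The default crosses the four predictor families (a)-(d) with the four
    response variables, giving 16 models; both axes are configurable.
    """
    fams = DEFAULT_FAMILIES if families is None else families
    return [
        ResponseModelSpec(response_variable=rv, predictors=tuple(preds), family=fam)
        for rv, (fam, preds) in itertools.product(response_variables, fams.items())
    ]


def _lagged_design(traj: BeliefTrajectory, predictors: tuple[str, ...]) -> np.ndarray:
    """Design matrix with intercept; row k predicts Y at trial k+1 (lag 1)."""
    cols = [np.ones(len(traj) - 1)]
    cols += [np.asarray(getattr(traj, p))[:-1] for p in predictors]
    return np.column_stack(cols)


def _align_response(y: np.ndarray, n_trials: int) -> np.ndarray:
    """Return the usable response values (length ``n_trials - 1``).

    Accepts a series with one value per trial (the first, which has no lag-1
    predictor, is dropped) or an already-differenced series of length
    ``n_trials - 1``.
    """
    y = np.asarray(y, dtype=float).ravel()
    if y.size == n_trials:
        return y[1:]
    if y.size == n_trials - 1:
        return y
    raise ValueError(
        f"response length {y.size} incompatible with {n_trials} trials")


def response_loglik(
    Y,
    traj: BeliefTrajectory,
    spec: ResponseModelSpec,
    betas,
    zeta: float,
) -> float:
    """Gaussian log-likelihood of the response series under a model.

    ``betas`` is ``(beta0, beta_1, ..)`` matching the intercept-plus-predictor
    design; ``zeta`` is the residual standard deviation.
    """
    if zeta <= 0:
        raise ValueError("zeta must be strictly positive")
    yu = _align_response(np.asarray(Y, float), len(traj))
    X = _lagged_design(traj, spec.predictors)
    b = np.asarray(betas, dtype=float)
    if b.size != X.shape[1]:
        raise ValueError(f"expected {X.shape[1]} coefficients, got {b.size}")
    resid = yu - X @ b
    m = yu.size
    return float(-0.5 * m * (LOG2PI + 2.0 * math.log(zeta))
                 - 0.5 * np.sum(resid ** 2) / zeta ** 2)


@dataclass(frozen=True)
class ResponseFit:
    """MAP fit of one subject/session under one response model."""

    spec: ResponseModelSpec
    beta0: float
    beta1: float
    beta2: float  # NaN for single-predictor models
    zeta: float
    params: HGFParams
    lme: float
    converged: bool
    n_used: int
    log_joint: float

    @property
    def betas(self) -> np.ndarray:
        b = [self.beta0, self.beta1]
        if not math.isnan(self.beta2):
            b.append(self.beta2)
        return np.array(b)


@dataclass(frozen=True)
class FitConfig:
    """Optimiser and prior settings for the joint MAP fit.

    Gaussian priors act on the unbounded perceptual transforms (omega and
    log theta, and log alpha when estimated); betas and log zeta carry flat
    priors so the conditional beta optimum is exactly OLS.
    """

    base_params: HGFParams = field(default_factory=HGFParams)
    estimate_omega: bool = True
    estimate_theta: bool = False  # weakly identified at ~90 trials; fixed by default
    estimate_alpha: bool = False
    prior_sd: float = 4.0
    include_perceptual_evidence: bool = False
    n_restarts: int = 8
    restart_scale: float = 1.0
    seed: int = 0
    maxiter: int = 200
    hessian_step: float = 1e-3


#: Penalty for proposals that destabilise the filter (finite, so numerical
#: differentiation inside the optimiser stays well-defined).
_REJECTED = 1e15


def _perceptual_loglik(traj: BeliefTrajectory, alpha: float) -> float:
    var = traj.sigmahat1 + alpha
    return float(np.sum(-0.5 * (LOG2PI + np.log(var) + traj.delta1 ** 2 / var)))


class HGFResponseRegressor(RegressorMixin, BaseEstimator):
    """Joint perceptual + response model fitted to one subject/session.

    ``fit(u, y)`` takes the trialwise score series ``u`` and the response
    series ``y`` (one value per trial, or the already-differenced series one
    shorter), maximises the joint log-posterior over perceptual parameters by
    multistart quasi-Newton with the regression coefficients concentrated out,
    and stores the Laplace log model evidence.

    Attributes
    ----------
    beta_ : ndarray
        Intercept followed by one coefficient per predictor.
    zeta_ : float
        Residual noise scale of the response model.
    params_ : HGFParams
        Fitted perceptual parameters.
    lme_ : float
        Laplace log model evidence (nats).
    trajectory_ : BeliefTrajectory
        Belief trajectory at the fitted perceptual parameters.
    """

    def __init__(
        self,
        spec: ResponseModelSpec | None = None,
        config: FitConfig | None = None,
    ):
        self.spec = spec
        self.config = config

    # -- internals ---------------------------------------------------------

    def _theta_names(self, cfg: FitConfig) -> list[str]:
        names = []
        if cfg.estimate_omega:
            names.append("omega")
        if cfg.estimate_theta:
            names.append("log_theta")
        if cfg.estimate_alpha:
            names.append("log_alpha")
        if not names:
            raise ValueError("at least one perceptual parameter must be free")
        return names

    def _params_from_vec(self, p: np.ndarray, cfg: FitConfig) -> HGFParams:
        kw = {}
        for name, value in zip(self._theta_names(cfg), p):
            if name == "omega":
                kw["omega"] = float(value)
            elif name == "log_theta":
                kw["theta"] = float(math.exp(value))
            else:
                kw["alpha"] = float(math.exp(value))
        return replace(cfg.base_params, **kw)

    def _prior_center(self, cfg: FitConfig) -> np.ndarray:
        base = cfg.base_params
        centers = {"omega": base.omega, "log_theta": math.log(base.theta),
                   "log_alpha": math.log(base.alpha)}
        return np.array([centers[n] for n in self._theta_names(cfg)])

    def _log_prior(self, p: np.ndarray, cfg: FitConfig) -> float:
        z = (p - self._prior_center(cfg)) / cfg.prior_sd
        return float(np.sum(-0.5 * (LOG2PI + 2 * math.log(cfg.prior_sd) + z ** 2)))

    def _concentrated(self, p, u, yu, spec, cfg):
        """Return (neg log posterior, betas, zeta, traj) at perceptual vector p."""
        try:
            params = self._params_from_vec(p, cfg)
            traj = hgf_filter(u, params)
        except (HGFInstabilityError, OverflowError, ValueError):
            return _REJECTED, None, None, None
        X = _lagged_design(traj, spec.predictors)
        beta, *_ = np.linalg.lstsq(X, yu, rcond=None)
        resid = yu - X @ beta
        m = yu.size
        rss = float(np.sum(resid ** 2))
        zeta2 = max(rss / m, 1e-12)
        lp = -0.5 * m * (LOG2PI + math.log(zeta2) + 1.0) + self._log_prior(p, cfg)
        if cfg.include_perceptual_evidence:
            lp += _perceptual_loglik(traj, params.alpha)
        if not np.isfinite(lp):
            return _REJECTED, None, None, None
        return -lp, beta, math.sqrt(zeta2), traj

    def _log_posterior_full(self, q, u, yu, spec, cfg) -> float:
        """Joint log posterior over (perceptual transforms, betas, log zeta)."""
        d = len(self._theta_names(cfg))
        p, betas, log_zeta = q[:d], q[d:-1], q[-1]
        try:
            params = self._params_from_vec(p, cfg)
            traj = hgf_filter(u, params)
        except (HGFInstabilityError, OverflowError, ValueError):
            return -np.inf
        X = _lagged_design(traj, spec.predictors)
        zeta2 = math.exp(2.0 * log_zeta)
        resid = yu - X @ betas
        m = yu.size
        lp = -0.5 * m * (LOG2PI + math.log(zeta2)) \
            - 0.5 * float(np.sum(resid ** 2)) / zeta2 + self._log_prior(p, cfg)
        if cfg.include_perceptual_evidence:
            lp += _perceptual_loglik(traj, params.alpha)
        return lp

    def _laplace_lme(self, q_star, u, yu, spec, cfg) -> tuple[float, bool]:
        """Laplace approximation of the log model evidence at the joint MAP."""
        f = lambda q: self._log_posterior_full(q, u, yu, spec, cfg)
        d = q_star.size
        h = cfg.hessian_step * (1.0 + np.abs(q_star))
        H = np.empty((d, d))
        f0 = f(q_star)
        for i in range(d):
            for j in range(i, d):
                ei = np.zeros(d); ei[i] = h[i]
                ej = np.zeros(d); ej[j] = h[j]
                if i == j:
                    val = (f(q_star + ei) - 2 * f0 + f(q_star - ei)) / h[i] ** 2
                else:
                    val = (
                        f(q_star + ei + ej) - f(q_star + ei - ej)
                        - f(q_star - ei + ej) + f(q_star - ei - ej)
                    ) / (4 * h[i] * h[j])
                H[i, j] = H[j, i] = val
        neg_H = -H
        eigvals = np.linalg.eigvalsh(neg_H)
        ok = bool(np.all(eigvals > 0))
        clipped = np.clip(eigvals, 1e-8, None)
        lme = f0 + 0.5 * d * LOG2PI - 0.5 * float(np.sum(np.log(clipped)))
        return lme, ok

    # -- public API --------------------------------------------------------

    def fit(self, X, y):
        """Fit to a score series ``X`` and response series ``y``."""
        spec = self.spec if self.spec is not None else ResponseModelSpec(
            response_variable="timing_exploration",
            predictors=("eps1", "eps2"),
            family="b",
        )
        cfg = self.config if self.config is not None else FitConfig()
        u = X.u if isinstance(X, ScoreSeries) else np.asarray(X, float).ravel()
        if u.size < 3:
            raise ValueError("need at least 3 trials")
        yu = _align_response(np.asarray(y, float), u.size)

        rng = np.random.default_rng(cfg.seed)
        center = self._prior_center(cfg)
        starts = [center]
        starts += [
            center + cfg.restart_scale * rng.standard_normal(center.size)
            for _ in range(max(cfg.n_restarts - 1, 0))
        ]

        best = None
        n_failed = 0
        for p0 in starts:
            res = minimize(
                lambda p: self._concentrated(p, u, yu, spec, cfg)[0],
                p0,
                method="L-BFGS-B",
                options={"maxiter": cfg.maxiter},
            )
            if not np.isfinite(res.fun) or res.fun >= _REJECTED:
                n_failed += 1
                continue
            if best is None or res.fun < best.fun:
                best = res
        if best is None:
            raise FitFailureError(
                "all optimiser restarts failed",
                {"n_restarts": len(starts), "n_failed": n_failed},
            )

        nlp, beta, zeta, traj = self._concentrated(best.x, u, yu, spec, cfg)
        q_star = np.concatenate([best.x, beta, [math.log(zeta)]])
        lme, hess_ok = self._laplace_lme(q_star, u, yu, spec, cfg)

        self.spec_ = spec
        self.beta_ = beta
        self.zeta_ = float(zeta)
        self.params_ = self._params_from_vec(best.x, cfg)
        self.trajectory_ = traj
        self.lme_ = float(lme)
        self.log_joint_ = float(-nlp)
        self.converged_ = bool(best.success and hess_ok)
        self.n_used_ = yu.size
        self.n_features_in_ = 1
        return self

    def predict(self, X) -> np.ndarray:
        """Predicted response values for score series ``X`` (lag-1 design)."""
        if not hasattr(self, "beta_"):
            raise AttributeError("regressor is not fitted")
        u = X.u if isinstance(X, ScoreSeries) else np.asarray(X, float).ravel()
        traj = hgf_filter(u, self.params_)
        return _lagged_design(traj, self.spec_.predictors) @ self.beta_

    def to_fit(self) -> ResponseFit:
        """Export fitted attributes as an immutable :class:`ResponseFit`."""
        if not hasattr(self, "beta_"):
            raise AttributeError("regressor is not fitted")
        b = self.beta_
        return ResponseFit(
            spec=self.spec_,
            beta0=float(b[0]),
            beta1=float(b[1]),
            beta2=float(b[2]) if b.size > 2 else math.nan,
            zeta=self.zeta_,
            params=self.params_,
            lme=self.lme_,
            converged=self.converged_,
            n_used=self.n_used_,
            log_joint=self.log_joint_,
        )


def fit_subject(
    u,
    Y,
    spec: ResponseModelSpec,
    config: FitConfig | None = None,
) -> ResponseFit:
    """Fit one subject/session under one response model (thin wrapper)."""
    return HGFResponseRegressor(spec=spec, config=config).fit(u, Y).to_fit()
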