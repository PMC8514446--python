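"""Two-level Hierarchical Gaussian Filter (HGF) for continuous score inputs.

The generative model assumed by the filter: the trialwise feedback score
``u^k`` is a noisy observation of a latent reward tendency ``x1``
(``u^k ~ N(x1^k, alpha)``); ``x1`` performs a Gaussian random walk whose step
variance ``exp(kappa * x2 + omega)`` is controlled by a second latent state
``x2``, the log-volatility, itself a Gaussian random walk with step variance
``theta``.  Beliefs about both states are Gaussian, so the filter propagates
sufficient statistics ``(mu1, sigma1, mu2, sigma2)`` one trial at a time.

Each update moves the belief mean by a precision-weighted prediction error
(pwPE): ``eps1`` — the input prediction error ``u^k - muhat1`` scaled by the
ratio of input precision to posterior precision — updates the reward belief,
and ``eps2`` — the volatility prediction error weighted by the level-2
precision ratio — updates the log-volatility belief.  By construction the
update step of each mean equals its pwPE exactly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .metrics import ScoreSeries

__all__ = [
    "HGFParams",
    "BeliefTrajectory",
    "HGFFilter",
    "HGFInstabilityError",
    "hgf_filter",
    "hgf_predictive_density",
    "hgf_step",
    "initial_state",
]

#: Floor on posterior precisions before the instability error is raised.
PRECISION_FLOOR = 1e-12

LOG2PI = math.log(2.0 * math.pi)


class HGFInstabilityError(FloatingPointError):
    """Loss of positive-definiteness of a posterior variance during filtering."""

    def __init__(self, trial: int, message: str):
        super().__init__(f"trial {trial}: {message}")
        self.trial = trial


@dataclass(frozen=True)
class HGFParams:
    """Perceptual parameters of the two-level continuous-input HGF.

    Parameters
    ----------
    kappa : float
        Coupling of the log-volatility state to the level-1 step variance.
    omega : float
        Tonic log-volatility of the reward tendency (log-variance units).
    theta : float
        Step variance of the log-volatility random walk.
    alpha : float
        Observation-noise variance of the score input (squared score units).
    mu1_0, sigma1_0 : float
        Initial mean and variance of the reward-tendency belief.  The default
        mean sits at the midpoint of the 0-100 score scale.
    mu2_0, sigma2_0 : float
        Initial mean and variance of the log-volatility belief.
    """

    kappa: float = 0.3
    omega: float = 2.0
    theta: float = 0.5
    alpha: float = 100.0
    mu1_0: float = 50.0
    sigma1_0: float = 100.0
    mu2_0: float = 0.0
    sigma2_0: float = 1.0

    def __post_init__(self) -> None:
        for name in ("theta", "alpha", "sigma1_0", "sigma2_0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.kappa <= 0:
            raise ValueError("kappa must be strictly positive")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class BeliefTrajectory:
    """Per-trial belief statistics and precision-weighted prediction errors.

    All arrays share the input length.  ``muhat1``/``sigmahat1`` are the
    pre-update (predictive) statistics of the reward belief; ``delta1`` is the
    raw input prediction error ``u - muhat1``; ``eps1`` and ``eps2`` are the
    pwPEs, equal to the update steps of ``mu1`` and ``mu2``.
    """

    u: np.ndarray
    mu1: np.ndarray
    sigma1: np.ndarray
    mu2: np.ndarray
    sigma2: np.ndarray
    muhat1: np.ndarray
    sigmahat1: np.ndarray
    delta1: np.ndarray
    eps1: np.ndarray
    eps2: np.ndarray
    params: HGFParams

    def __len__(self) -> int:
        return self.u.size

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-trial table (trial, u, mu1, sigma1, mu2, sigma2, eps1, eps2)."""
        return pd.DataFrame(
            {
                "trial": np.arange(1, len(self) + 1),
                "u": self.u,
                "mu1": self.mu1,
                "sigma1": self.sigma1,
                "mu2": self.mu2,
                "sigma2": self.sigma2,
                "eps1": self.eps1,
                "eps2": self.eps2,
            }
        )


def _validate_input(u) -> np.ndarray:
    if isinstance(u, ScoreSeries):
        u = u.u
    arr = np.asarray(u, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError("input series is empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError("input series contains non-finite values")
    return arr


class HGFFilter(TransformerMixin, BaseEstimator):
    """Sequential two-level HGF over a trialwise score series.

    A deterministic, one-pass transformer: ``transform`` maps a score series
    to the tidy belief-trajectory table, ``filter_series`` returns the full
    :class:`BeliefTrajectory`.  Parameters follow :class:`HGFParams`.

    Examples
    --------
    >>> f = HGFFilter(omega=2.0, theta=0.5, alpha=100.0)
    >>> traj = f.filter_series([50., 60., 70.])
    >>> bool(np.all(traj.mu1 - traj.muhat1 == traj.eps1))
    True
    """

    def __init__(
        self,
        kappa: float = 0.3,
        omega: float = 2.0,
        theta: float = 0.5,
        alpha: float = 100.0,
        mu1_0: float = 50.0,
        sigma1_0: float = 100.0,
        mu2_0: float = 0.0,
        sigma2_0: float = 1.0,
    ):
        self.kappa = kappa
        self.omega = omega
        self.theta = theta
        self.alpha = alpha
        self.mu1_0 = mu1_0
        self.sigma1_0 = sigma1_0
        self.mu2_0 = mu2_0
        self.sigma2_0 = sigma2_0

    def _params(self) -> HGFParams:
        return HGFParams(
            kappa=self.kappa,
            omega=self.omega,
            theta=self.theta,
            alpha=self.alpha,
            mu1_0=self.mu1_0,
            sigma1_0=self.sigma1_0,
            mu2_0=self.mu2_0,
            sigma2_0=self.sigma2_0,
        )

    def fit(self, X, y=None):
        """Validate parameters and input; filtering itself is stateless."""
        self._params()
        u = _validate_input(X)
        self.n_trials_ = u.size
        return self

    def filter_series(self, u) -> BeliefTrajectory:
        """Run the filter over a score series and return the trajectory."""
        return hgf_filter(u, self._params())

    def transform(self, X) -> pd.DataFrame:
        return self.filter_series(X).to_frame()

    def predictive_logdensity(self, u) -> np.ndarray:
        """Per-trial predictive log-density of the inputs (see module docs)."""
        return hgf_predictive_density(u, self._params())


def hgf_filter(u, params: HGFParams) -> BeliefTrajectory:
    """Filter a score series with the two-level continuous-input HGF.

    Per trial ``k`` (hats denote pre-update predictions):

    - level-1 prediction: ``muhat1 = mu1``, ``sigmahat1 = sigma1 +
      exp(kappa*mu2 + omega)``;
    - input update: with precisions ``pihat1 = 1/sigmahat1`` and
      ``pi_u = 1/alpha``, the posterior precision is ``pi1 = pihat1 + pi_u``
      and ``eps1 = (pi_u/pi1) * (u^k - muhat1)`` moves the mean;
    - volatility prediction error ``dv = (sigma1 + eps1^2)/sigmahat1 - 1``
      with weight ``w1 = exp(kappa*mu2 + omega)/sigmahat1``;
    - level-2 update: ``pihat2 = 1/(sigma2 + theta)``, posterior precision
      ``pi2 = pihat2 + (kappa^2/2) * w1 * (w1 + (2*w1 - 1)*dv)``, and
      ``eps2 = (kappa/2) * (w1/pi2) * dv`` moves ``mu2``.

    Raises
    ------
    HGFInstabilityError
        If a posterior precision falls below the floor (negative posterior
        variance), identifying the offending trial (1-based).
    """
    uu = _validate_input(u)
    n = uu.size
    state = initial_state(params)

    out = {name: np.empty(n) for name in (
        "mu1", "sigma1", "mu2", "sigma2", "muhat1", "sigmahat1",
        "delta1", "eps1", "eps2")}

    for t in range(n):
        state, step = hgf_step(state, uu[t], params, trial=t + 1)
        out["mu1"][t], out["sigma1"][t], out["mu2"][t], out["sigma2"][t] = state
        out["muhat1"][t] = step["muhat1"]
        out["sigmahat1"][t] = step["sigmahat1"]
        out["delta1"][t] = step["delta1"]
        out["eps1"][t] = step["eps1"]
        out["eps2"][t] = step["eps2"]

    return BeliefTrajectory(u=uu, params=params, **out)


def initial_state(params: HGFParams) -> tuple[float, float, float, float]:
    """Prior belief state ``(mu1, sigma1, mu2, sigma2)`` before any input."""
    return (params.mu1_0, params.sigma1_0, params.mu2_0, params.sigma2_0)


def hgf_step(
    state: tuple[float, float, float, float],
    u: float,
    params: HGFParams,
    trial: int = 0,
) -> tuple[tuple[float, float, float, float], dict]:
    """One belief update on a single input; returns (new state, step record).

    The step record carries the predictive statistics and the pwPEs for the
    trial (keys ``muhat1, sigmahat1, delta1, eps1, eps2``).
    """
    mu1, s1, mu2, s2 = state
    k, om, th = params.kappa, params.omega, params.theta
    pi_u = 1.0 / params.alpha

    log_vol = k * mu2 + om
    if not -700.0 < log_vol < 700.0:
        raise HGFInstabilityError(
            trial, f"log-volatility diverged (kappa*mu2 + omega = {log_vol:.3g})")
    vol = math.exp(log_vol)
    muhat1 = mu1
    sigmahat1 = s1 + vol
    pihat1 = 1.0 / sigmahat1

    d_in = u - muhat1
    pi1 = pihat1 + pi_u
    s1_new = 1.0 / pi1
    e1 = (pi_u / pi1) * d_in
    mu1_new = muhat1 + e1

    dv = (s1_new + e1 * e1) * pihat1 - 1.0
    w1 = vol * pihat1

    sigmahat2 = s2 + th
    pihat2 = 1.0 / sigmahat2
    pi2 = pihat2 + 0.5 * k * k * w1 * (w1 + (2.0 * w1 - 1.0) * dv)
    if pi2 <= PRECISION_FLOOR:
        if pi2 > 0:
            warnings.warn(
                f"trial {trial}: level-2 posterior precision {pi2:.3e} floored",
                RuntimeWarning, stacklevel=2)
            pi2 = PRECISION_FLOOR
        else:
            raise HGFInstabilityError(
                trial, f"level-2 posterior precision non-positive ({pi2:.3e})")
    s2_new = 1.0 / pi2
    e2 = 0.5 * k * (w1 / pi2) * dv
    mu2_new = mu2 + e2

    record = {"muhat1": muhat1, "sigmahat1": sigmahat1, "delta1": d_in,
              "eps1": e1, "eps2": e2}
    return (mu1_new, s1_new, mu2_new, s2_new), record


def hgf_predictive_density(u, params: HGFParams) -> np.ndarray:
    """Per-trial predictive log-density of the inputs under the filter.

    Before seeing trial ``k`` the input is predicted as Gaussian with mean
    ``muhat1^k`` and variance ``sigmahat1^k + alpha``; the summed log-density
    is the perceptual part of the joint model evidence.
    """
    traj = hgf_filter(u, params)
    var = traj.sigmahat1 + params.alpha
    return -0.5 * (LOG2PI + np.log(var) + traj.delta1 ** 2 / var)
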