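"""Parametric survival families used for progression-free-survival extrapolation.

Six families are supported: exponential, Weibull, log-logistic, log-normal,
generalized gamma and Gompertz.  Each family exposes its log-density and
log-survival on an *unconstrained* parameter vector (positive parameters are
log-transformed), which is the scale on which maximum-likelihood optimization
and the Wald covariance are computed.

A treatment covariate enters either proportionally on the hazard
(exponential, Weibull, Gompertz) or as an acceleration factor on the time
scale (log-logistic, log-normal, generalized gamma); see
:mod:`ros1ce.survfit`.

Closed forms (t > 0):

========  ==========================================  ====================
family    S(t)                                        natural parameters
========  ==========================================  ====================
exp       exp(-lam*t)                                 rate lam
weibull   exp(-(t/lam)^rho)                           shape rho, scale lam
loglog    1 / (1 + (t/alpha)^beta)                    shape beta, scale alpha
lognorm   1 - Phi((ln t - mu)/sigma)                  mu, sigma
gengamma  scipy.stats.gengamma(a, c, scale)           a, c, scale (c > 0)
gompertz  exp(-(b/eta)(e^(eta*t)-1))                  shape eta, rate b
========  ==========================================  ====================

A Gompertz shape eta < 0 gives an improper survival function (a plateau of
never-progressors); it is permitted but flagged by the fitting layer.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["Family", "FAMILIES", "get_family"]

_TINY = 1e-300


class Family:
    """Base class; subclasses define closed forms on the unconstrained scale."""

    name: str = ""
    param_names: tuple[str, ...] = ()
    effect_type: str = "proportional_hazards"  # or "acceleration_factor"

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    # -- parameter transforms (default: all positive, log-transformed) ------
    def to_natural(self, theta: np.ndarray) -> np.ndarray:
        return np.exp(np.asarray(theta, dtype=float))

    def from_natural(self, params: np.ndarray) -> np.ndarray:
        return np.log(np.asarray(params, dtype=float))

    # -- closed forms --------------------------------------------------------
    def logsf(self, t, theta) -> np.ndarray:
        raise NotImplementedError

    def logpdf(self, t, theta) -> np.ndarray:
        raise NotImplementedError

    def sf(self, t, theta) -> np.ndarray:
        return np.exp(self.logsf(t, theta))

    def cumhaz(self, t, theta) -> np.ndarray:
        return -self.logsf(t, theta)

    def median(self, theta) -> float:
        raise NotImplementedError

    def init(self, times: np.ndarray, events: np.ndarray) -> np.ndarray:
        """Moment-style starting values from the observed data."""
        raise NotImplementedError

    def rvs(self, theta, size: int, rng: np.random.Generator) -> np.ndarray:
        """Draw event times (may be +inf for improper survival functions)."""
        raise NotImplementedError

    def is_proper(self, theta) -> bool:
        return True


def _logmean_std(times, events):
    """Mean/std of log event times with a censored-data fallback."""
    lt = np.log(np.maximum(times[events.astype(bool)], 1e-8))
    if lt.size == 0:
        lt = np.log(np.maximum(times, 1e-8))
    mu = float(np.mean(lt))
    sd = float(np.std(lt)) or 0.5
    return mu, sd


class Exponential(Family):
    name = "exponential"
    param_names = ("rate",)
    effect_type = "proportional_hazards"

    def logsf(self, t, theta):
        lam = np.exp(theta[0])
        return -lam * np.asarray(t, dtype=float)

    def logpdf(self, t, theta):
        lam = np.exp(theta[0])
        return theta[0] - lam * np.asarray(t, dtype=float)

    def median(self, theta):
        return float(np.log(2.0) / np.exp(theta[0]))

    def init(self, times, events):
        d = max(float(np.sum(events)), 0.5)
        return np.array([np.log(d / np.sum(times))])

    def rvs(self, theta, size, rng):
        return rng.exponential(1.0 / np.exp(theta[0]), size=size)


class Weibull(Family):
    name = "weibull"
    param_names = ("shape", "scale")
    effect_type = "proportional_hazards"

    def logsf(self, t, theta):
        rho, lam = np.exp(theta)
        return -((np.asarray(t, dtype=float) / lam) ** rho)

    def logpdf(self, t, theta):
        rho, lam = np.exp(theta)
        t = np.asarray(t, dtype=float)
        return (
            theta[0]
            - theta[1]
            + (rho - 1.0) * (np.log(np.maximum(t, _TINY)) - theta[1])
            - (t / lam) ** rho
        )

    def median(self, theta):
        rho, lam = np.exp(theta)
        return float(lam * np.log(2.0) ** (1.0 / rho))

    def init(self, times, events):
        mu, sd = _logmean_std(times, events)
        rho = min(max(1.2 / sd, 0.2), 20.0)
        return np.array([np.log(rho), mu])

    def rvs(self, theta, size, rng):
        rho, lam = np.exp(theta)
        return lam * rng.weibull(rho, size=size)


class LogLogistic(Family):
    name = "log_logistic"
    param_names = ("shape", "scale")
    effect_type = "acceleration_factor"

    def logsf(self, t, theta):
        beta, alpha = np.exp(theta)
        z = np.asarray(t, dtype=float) / alpha
        return -np.log1p(np.power(np.maximum(z, 0.0), beta))

    def logpdf(self, t, theta):
        beta, alpha = np.exp(theta)
        t = np.asarray(t, dtype=float)
        logz = np.log(np.maximum(t, _TINY)) - theta[1]
        return theta[0] - theta[1] + (beta - 1.0) * logz - 2.0 * np.log1p(np.exp(beta * logz))

    def median(self, theta):
        return float(np.exp(theta[1]))

    def init(self, times, events):
        mu, sd = _logmean_std(times, events)
        beta = min(max(1.8 / sd, 0.2), 20.0)
        return np.array([np.log(beta), mu])

    def rvs(self, theta, size, rng):
        beta, alpha = np.exp(theta)
        u = rng.uniform(size=size)
        return alpha * (u / (1.0 - u)) ** (1.0 / beta)


class LogNormal(Family):
    name = "log_normal"
    param_names = ("mu", "sigma")
    effect_type = "acceleration_factor"

    def to_natural(self, theta):
        return np.array([theta[0], np.exp(theta[1])])

    def from_natural(self, params):
        return np.array([params[0], np.log(params[1])])

    def logsf(self, t, theta):
        mu, sigma = theta[0], np.exp(theta[1])
        z = (np.log(np.maximum(np.asarray(t, dtype=float), _TINY)) - mu) / sigma
        return stats.norm.logsf(z)

    def logpdf(self, t, theta):
        mu, sigma = theta[0], np.exp(theta[1])
        t = np.asarray(t, dtype=float)
        lt = np.log(np.maximum(t, _TINY))
        z = (lt - mu) / sigma
        return stats.norm.logpdf(z) - theta[1] - lt

    def median(self, theta):
        return float(np.exp(theta[0]))

    def init(self, times, events):
        mu, sd = _logmean_std(times, events)
        return np.array([mu, np.log(sd)])

    def rvs(self, theta, size, rng):
        return np.exp(theta[0] + np.exp(theta[1]) * rng.standard_normal(size))


class GeneralizedGamma(Family):
    name = "generalized_gamma"
    param_names = ("a", "c", "scale")
    effect_type = "acceleration_factor"

    def logsf(self, t, theta):
        a, c, s = np.exp(theta)
        return stats.gengamma.logsf(np.asarray(t, dtype=float), a, c, scale=s)

    def logpdf(self, t, theta):
        a, c, s = np.exp(theta)
        return stats.gengamma.logpdf(np.asarray(t, dtype=float), a, c, scale=s)

    def median(self, theta):
        a, c, s = np.exp(theta)
        return float(stats.gengamma.median(a, c, scale=s))

    def init(self, times, events):
        mu, sd = _logmean_std(times, events)
        # a=1 reduces to Weibull with shape c
        c = min(max(1.2 / sd, 0.2), 20.0)
        return np.array([0.0, np.log(c), mu])

    def rvs(self, theta, size, rng):
        a, c, s = np.exp(theta)
        return stats.gengamma.rvs(a, c, scale=s, size=size, random_state=rng)


class Gompertz(Family):
    name = "gompertz"
    param_names = ("shape", "rate")
    effect_type = "proportional_hazards"

    def to_natural(self, theta):
        return np.array([theta[0], np.exp(theta[1])])

    def from_natural(self, params):
        return np.array([params[0], np.log(params[1])])

    def _cumhaz(self, t, eta, b):
        t = np.asarray(t, dtype=float)
        if abs(eta) < 1e-10:
            return b * t
        return (b / eta) * np.expm1(eta * t)

    def logsf(self, t, theta):
        eta, b = theta[0], np.exp(theta[1])
        return -self._cumhaz(t, eta, b)

    def logpdf(self, t, theta):
        eta, b = theta[0], np.exp(theta[1])
        t = np.asarray(t, dtype=float)
        return theta[1] + eta * t - self._cumhaz(t, eta, b)

    def median(self, theta):
        eta, b = theta[0], np.exp(theta[1])
        if abs(eta) < 1e-10:
            return float(np.log(2.0) / b)
        arg = 1.0 + eta * np.log(2.0) / b
        if arg <= 0:
            return float("inf")  # improper: the plateau sits above 0.5
        return float(np.log(arg) / eta)

    def is_proper(self, theta) -> bool:
        return theta[0] >= 0

    def init(self, times, events):
        d = max(float(np.sum(events)), 0.5)
        return np.array([0.01, np.log(d / np.sum(times))])

    def rvs(self, theta, size, rng):
        eta, b = theta[0], np.exp(theta[1])
        x = rng.exponential(size=size)  # unit-exponential cumulative hazards
        if abs(eta) < 1e-10:
            return x / b
        arg = 1.0 + eta * x / b
        out = np.full(size, np.inf)
        ok = arg > 0
        out[ok] = np.log(arg[ok]) / eta
        return out


FAMILIES: dict[str, Family] = {
    f.name: f
    for f in [
        Exponential(),
        Weibull(),
        LogLogistic(),
        LogNormal(),
        GeneralizedGamma(),
        Gompertz(),
    ]
}


def get_family(name: str) -> Family:
    try:
        return FAMILIES[name]
    except KeyError:
        raise KeyError(
            f"unknown family {name!r}; choose from {sorted(FAMILIES)}"
        ) from None
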