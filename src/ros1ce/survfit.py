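"""Censored maximum-likelihood survival fitting and transition-probability tools.

The pooled progression-free-survival data (both arms) are fitted with a
common treatment parameter: a proportional-hazards (PH) multiplier for
hazard-parameterized families (exponential, Weibull, Gompertz) or an
acceleration factor (AFT time ratio) for log-time families (log-logistic,
log-normal, generalized gamma).  The right-censored log-likelihood is

    sum_i [ delta_i * log f(t_i) + (1 - delta_i) * log S(t_i) ]

maximized on the unconstrained parameter scale; the Wald covariance is the
inverse of the numerically differentiated observed information, and feeds the
correlated (Cholesky) parameter draws of the probabilistic analysis.

The Cox hazard ratio and the scaled-Schoenfeld proportional-hazards test are
delegated to lifelines, serving as the semi-parametric companion to the
parametric shared-parameter fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .distributions import FAMILIES, Family, get_family
from .errors import (
    AbsorbingStateError,
    ConvergenceError,
    NonIdentifiableError,
    ValidationError,
)
from .km_ipd import IPDSet

TREATED_ARM = "crizotinib"
CONTROL_ARM = "chemotherapy"

__all__ = [
    "SurvivalFit",
    "HazardRatio",
    "fit_parametric",
    "fit_all_families",
    "cox_hr_and_ph_test",
    "select_distribution",
    "conditional_transition_probability",
    "apply_hazard_ratio",
    "rate_from_median",
]


@dataclass
class SurvivalFit:
    """A fitted parametric family with covariance and information criteria."""

    family_name: str
    theta: np.ndarray  # unconstrained scale; last entry = treatment coef if shared
    covariance: np.ndarray  # on the unconstrained scale
    loglik: float
    n: int
    n_events: int
    shared_treatment: bool
    flags: list[str] = field(default_factory=list)

    @property
    def family(self) -> Family:
        return get_family(self.family_name)

    @property
    def k(self) -> int:
        return len(self.theta)

    @property
    def aic(self) -> float:
        return 2.0 * self.k - 2.0 * self.loglik

    @property
    def bic(self) -> float:
        return self.k * np.log(self.n) - 2.0 * self.loglik

    @property
    def effect_type(self) -> str | None:
        return self.family.effect_type if self.shared_treatment else None

    @property
    def base_theta(self) -> np.ndarray:
        return self.theta[:-1] if self.shared_treatment else self.theta

    @property
    def beta(self) -> float | None:
        return float(self.theta[-1]) if self.shared_treatment else None

    def treatment_effect(self) -> dict | None:
        """Treatment effect on its natural scale (HR for PH, time ratio for AFT)."""
        if not self.shared_treatment:
            return None
        se = float(np.sqrt(max(self.covariance[-1, -1], 0.0)))
        lo, hi = self.beta - 1.96 * se, self.beta + 1.96 * se
        return {
            "type": self.effect_type,
            "value": float(np.exp(self.beta)),
            "ci": (float(np.exp(lo)), float(np.exp(hi))),
        }

    def params_natural(self) -> dict[str, float]:
        nat = self.family.to_natural(self.base_theta)
        out = dict(zip(self.family.param_names, map(float, nat)))
        if self.shared_treatment:
            key = "hazard_ratio" if self.effect_type == "proportional_hazards" else "time_ratio"
            out[key] = float(np.exp(self.beta))
        return out

    # -- survival curves -----------------------------------------------------
    def logsf(self, t, arm: str = CONTROL_ARM) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        fam = self.family
        if not self.shared_treatment or arm != TREATED_ARM:
            return fam.logsf(t, self.base_theta)
        if fam.effect_type == "proportional_hazards":
            return np.exp(self.beta) * fam.logsf(t, self.base_theta)
        return fam.logsf(t / np.exp(self.beta), self.base_theta)

    def sf(self, t, arm: str = CONTROL_ARM) -> np.ndarray:
        return np.exp(self.logsf(t, arm))

    def median(self, arm: str = CONTROL_ARM) -> float:
        """Numeric root of S(t) = 1/2 (inf if the curve plateaus above 1/2)."""
        hi = 1.0
        for _ in range(60):
            if self.sf(hi, arm) < 0.5:
                break
            hi *= 2.0
        else:
            return float("inf")
        return float(optimize.brentq(lambda t: self.sf(t, arm) - 0.5, 1e-12, hi))

    def to_report(self) -> dict:
        rep = {
            "family": self.family_name,
            "params": self.params_natural(),
            "loglik": self.loglik,
            "aic": self.aic,
            "bic": self.bic,
            "n": self.n,
            "n_events": self.n_events,
            "covariance": self.covariance.tolist(),
            "flags": list(self.flags),
        }
        te = self.treatment_effect()
        if te:
            rep["treatment_effect"] = te
        return rep


@dataclass
class HazardRatio:
    """Cox partial-likelihood HR (treated vs control) with a PH diagnostic."""

    value: float
    ci_lower: float
    ci_upper: float
    p_ph_test: float

    def __post_init__(self):
        if not (self.ci_lower <= self.value <= self.ci_upper):
            raise ValidationError("hazard-ratio CI must bracket the estimate")


# ---------------------------------------------------------------------------
# likelihood machinery


def _extract(records) -> pd.DataFrame:
    if isinstance(records, IPDSet):
        df = records.to_dataframe()
    elif isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = IPDSet(list(records)).to_dataframe()
    df["event"] = df["event"].astype(bool)
    return df


def _negloglik(theta, fam: Family, t, e, x, shared: bool) -> float:
    with np.errstate(all="ignore"):
        if shared:
            base, beta = theta[:-1], theta[-1]
            if fam.effect_type == "proportional_hazards":
                logsf0 = fam.logsf(t, base)
                logpdf0 = fam.logpdf(t, base)
                loghaz = logpdf0 - logsf0
                logsf = np.where(x, np.exp(beta) * logsf0, logsf0)
                logpdf = np.where(x, beta + loghaz + np.exp(beta) * logsf0, logpdf0)
            else:
                ts = np.where(x, t * np.exp(-beta), t)
                logsf = fam.logsf(ts, base)
                logpdf = fam.logpdf(ts, base) - np.where(x, beta, 0.0)
        else:
            logsf = fam.logsf(t, theta)
            logpdf = fam.logpdf(t, theta)
        ll = np.where(e, logpdf, logsf)
    if np.any(~np.isfinite(ll)):
        return 1e10
    return -float(np.sum(ll))


def _numerical_hessian(f, x0: np.ndarray) -> np.ndarray:
    """Central-difference Hessian; symmetric by construction."""
    k = len(x0)
    h = 1e-4 * (1.0 + np.abs(x0))
    H = np.zeros((k, k))
    f0 = f(x0)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = h[i]
            ej[j] = h[j]
            if i == j:
                H[i, i] = (f(x0 + ei) - 2.0 * f0 + f(x0 - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(x0 + ei + ej) - f(x0 + ei - ej) - f(x0 - ei + ej) + f(x0 - ei - ej)
                ) / (4.0 * h[i] * h[j])
    return H


def fit_parametric(
    records,
    family: str | Family,
    shared_treatment: bool = False,
    *,
    n_starts: int = 3,
    seed: int = 0,
) -> SurvivalFit:
    """Maximum-likelihood fit of one family, optionally with a common treatment parameter.

    With ``shared_treatment`` the records must contain both arms and at least
    one event per arm; the chemotherapy arm is the baseline and the treatment
    coefficient acts as a hazard ratio (PH families) or log time ratio (AFT
    families) for crizotinib.
    """
    fam = get_family(family) if isinstance(family, str) else family
    df = _extract(records)
    t = df["time_months"].to_numpy(dtype=float)
    e = df["event"].to_numpy(dtype=bool)
    if int(e.sum()) == 0:
        raise NonIdentifiableError("no events: the likelihood carries no information")
    if shared_treatment:
        x = (df["arm"] == TREATED_ARM).to_numpy(dtype=bool)
        for arm_name, mask in ((TREATED_ARM, x), (CONTROL_ARM, ~x)):
            if mask.sum() == 0 or e[mask].sum() == 0:
                raise NonIdentifiableError(
                    f"shared-treatment fit needs >= 1 event in arm {arm_name!r}"
                )
    else:
        x = np.zeros(len(t), dtype=bool)

    theta0 = fam.init(t, e)
    if shared_treatment:
        # initialise the baseline on the control arm, effect near null
        theta0 = fam.init(t[~x], e[~x])
        theta0 = np.append(theta0, 0.1 if fam.effect_type == "acceleration_factor" else -0.1)

    nll = lambda th: _negloglik(th, fam, t, e, x, shared_treatment)
    rng = np.random.default_rng(seed)
    best = None
    for s in range(n_starts):
        start = theta0 if s == 0 else theta0 + rng.normal(0, 0.3, size=len(theta0))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = optimize.minimize(
                nll, start, method="Nelder-Mead",
                options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 4000},
            )
            res = optimize.minimize(nll, res.x, method="BFGS", options={"gtol": 1e-6})
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun - 1e-9):
            best = res
        if best is not None and s == 0 and best.fun < 1e9:
            break  # first start converged; extra starts only on trouble
    if best is None or best.fun >= 1e9:
        raise ConvergenceError(
            f"{fam.name}: optimizer failed", {"n": len(t), "events": int(e.sum())}
        )

    H = _numerical_hessian(nll, best.x)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    flags = []
    if np.any(np.diag(cov) <= 0):
        cov = np.abs(cov)  # keep usable variances; flag the defect
        flags.append("non_positive_definite_information")
    if not fam.is_proper(best.x[: fam.n_params]):
        flags.append("improper_survival_function")

    return SurvivalFit(
        family_name=fam.name,
        theta=np.asarray(best.x, dtype=float),
        covariance=np.asarray(cov, dtype=float),
        loglik=-float(best.fun),
        n=len(t),
        n_events=int(e.sum()),
        shared_treatment=shared_treatment,
        flags=flags,
    )


def fit_all_families(records, shared_treatment: bool = True, **kw) -> list[SurvivalFit]:
    """Fit every supported family to the same records."""
    fits = []
    for name in FAMILIES:
        try:
            fits.append(fit_parametric(records, name, shared_treatment, **kw))
        except ConvergenceError:
            continue
    if not fits:
        raise ConvergenceError("no family converged")
    return fits


# ---------------------------------------------------------------------------
# Cox model and PH diagnostics


def cox_hr_and_ph_test(records) -> HazardRatio:
    """Cox HR (crizotinib vs chemotherapy) with 95% Wald CI and a
    scaled-Schoenfeld-residual proportional-hazards score test."""
    from lifelines import CoxPHFitter
    from lifelines.statistics import proportional_hazard_test

    df = _extract(records)
    arms = set(df["arm"])
    if not {TREATED_ARM, CONTROL_ARM} <= arms:
        raise ValidationError(f"both arms required, got {sorted(arms)}")
    for arm in (TREATED_ARM, CONTROL_ARM):
        sub = df[df["arm"] == arm]
        if int(sub["event"].sum()) == 0:
            raise NonIdentifiableError(f"arm {arm!r} has zero events")
    dd = pd.DataFrame(
        {
            "t": df["time_months"].astype(float),
            "e": df["event"].astype(int),
            "treated": (df["arm"] == TREATED_ARM).astype(int),
        }
    )
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(dd, duration_col="t", event_col="e")
        ph = proportional_hazard_test(cph, dd, time_transform="rank")
    summ = cph.summary.loc["treated"]
    return HazardRatio(
        value=float(np.exp(summ["coef"])),
        ci_lower=float(np.exp(summ["coef"] - 1.96 * summ["se(coef)"])),
        ci_upper=float(np.exp(summ["coef"] + 1.96 * summ["se(coef)"])),
        p_ph_test=float(np.atleast_1d(ph.p_value)[0]),
    )


# ---------------------------------------------------------------------------
# selection and transition probabilities


def select_distribution(fits: list[SurvivalFit]) -> tuple[SurvivalFit, pd.DataFrame]:
    """Pick the minimum-AIC fit (ties: BIC, then fewer parameters) and report all."""
    if len(fits) < 2:
        raise ValidationError("need at least two candidate fits to select among")
    ns = {f.n for f in fits}
    nev = {f.n_events for f in fits}
    if len(ns) > 1 or len(nev) > 1:
        raise ValidationError(
            f"fits are not on the same data: n={sorted(ns)}, events={sorted(nev)}"
        )
    ranked = sorted(fits, key=lambda f: (f.aic, f.bic, f.k))
    report = pd.DataFrame(
        {
            "family": [f.family_name for f in ranked],
            "k": [f.k for f in ranked],
            "loglik": [f.loglik for f in ranked],
            "aic": [f.aic for f in ranked],
            "bic": [f.bic for f in ranked],
            "flags": [";".join(f.flags) for f in ranked],
        }
    )
    return ranked[0], report


def conditional_transition_probability(fit, t: float, delta: float, arm: str = CONTROL_ARM) -> float:
    """P(transition within (t, t+delta] | state occupied at t) = 1 - S(t+delta)/S(t).

    ``fit`` may be a :class:`SurvivalFit` (pass ``arm``) or any callable
    S(t) -> survival probability.
    """
    if t < 0 or delta <= 0:
        raise ValidationError("need t >= 0 and delta > 0")
    sf = (lambda u: fit.sf(u, arm)) if hasattr(fit, "sf") else fit
    st = float(sf(t))
    if st <= 0.0:
        raise AbsorbingStateError(f"S({t}) = 0: state already exhausted")
    tp = 1.0 - float(sf(t + delta)) / st
    return float(min(max(tp, 0.0), 1.0))


def apply_hazard_ratio(tp: float, hr: float) -> float:
    """Apply a hazard ratio to a per-cycle transition probability:
    1 - (1 - tp)^hr."""
    if not 0.0 <= tp < 1.0:
        raise ValidationError(f"transition probability must be in [0, 1), got {tp}")
    if hr <= 0:
        raise ValidationError(f"hazard ratio must be positive, got {hr}")
    return 1.0 - (1.0 - tp) ** hr


def rate_from_median(median: float) -> float:
    """Exponential rate (per month) with the given median: ln 2 / median."""
    if not median > 0:
        raise ValidationError(f"median must be positive, got {median}")
    return float(np.log(2.0) / median)
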