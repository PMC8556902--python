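"""Shared fixtures: the synthetic benchmark suite, fitted curves, and the
two-arm simulation oracle used by the parameter-recovery checks."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import brentq

import ros1ce as r
from ros1ce.distributions import get_family
from ros1ce.synth import theta_from_median

#: per-family shape parameters used by the recovery simulations
RECOVERY_SHAPES = {
    "exponential": None,
    "weibull": 1.4,
    "log_logistic": 1.5,
    "log_normal": 0.8,
    "generalized_gamma": 1.4,
    "gompertz": 0.05,
}


def two_arm_sample(
    family: str,
    rng: np.random.Generator,
    n_per_arm: int = 500,
    medians: tuple[float, float] = (16.2, 7.8),
    censor_quantile: float = 0.8,
) -> list[r.IPDRecord]:
    """Simulate a two-arm censored study whose true arm medians are known.

    The control arm draws from the family at the lower median; the treated
    arm is generated under the family's own treatment mechanism (time
    scaling for AFT families, a hazard multiplier chosen to hit the treated
    median for PH families).  Administrative censoring at the per-arm
    ``censor_quantile`` empirical quantile yields the target censoring rate.
    """
    fam = get_family(family)
    med_trt, med_ctrl = medians
    th0 = theta_from_median(family, med_ctrl, RECOVERY_SHAPES[family])
    t_ctrl = fam.rvs(th0, n_per_arm, rng)
    if fam.effect_type == "acceleration_factor":
        t_trt = fam.rvs(th0, n_per_arm, rng) * (med_trt / med_ctrl)
    else:
        # PH truth: H_trt = hr * H_ctrl with hr fixed by the treated median;
        # invert the control cumulative hazard at Exp(1)/hr draws
        hr_true = np.log(2.0) / float(fam.cumhaz(med_trt, th0))
        u = rng.exponential(size=n_per_arm) / hr_true
        t_trt = np.empty(n_per_arm)
        for i, x in enumerate(u):
            hi = 1.0
            while fam.cumhaz(hi, th0) < x and hi < 1e7:
                hi *= 2.0
            t_trt[i] = brentq(lambda t: float(fam.cumhaz(t, th0)) - x, 1e-12, hi)
    records = []
    for arm, tt in (("chemotherapy", t_ctrl), ("crizotinib", t_trt)):
        cut = np.quantile(tt, censor_quantile)
        for t in tt:
            records.append(
                r.IPDRecord(float(max(min(t, cut), 1e-6)), bool(t <= cut), arm, "sim")
            )
    return records


@pytest.fixture(scope="session")
def benchmark_suite() -> r.BenchmarkSuite:
    return r.generate_benchmark_suite(seed=1)


@pytest.fixture(scope="session")
def all_fits(benchmark_suite):
    return r.fit_all_families(benchmark_suite.true_ipd, shared_treatment=True, seed=1)


@pytest.fixture(scope="session")
def best_fit(all_fits):
    best, _ = r.select_distribution(all_fits)
    return best


@pytest.fixture(scope="session")
def pfs_inputs(best_fit):
    return r.PFSInputs.from_fit(best_fit)


@pytest.fixture
def base_config() -> r.ModelConfig:
    return r.ModelConfig()
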