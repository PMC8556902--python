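"""Probabilistic, deterministic and scenario sensitivity analysis.

The probabilistic sensitivity analysis (PSA) re-evaluates the full decision
model under parameter sets drawn from conventional health-economic
distributions: beta for quantities bounded in [0, 1] (utilities,
proportions, test characteristics), gamma for costs, normal for population
values (body surface area), log-normal for the maintenance hazard ratio
(moment-matched to its published 95% CI), and a correlated multivariate
normal — sampled through the Cholesky factor of the maximum-likelihood
covariance — for the fitted survival parameters.  Outputs are per-simulation
incremental cost/effect pairs, their means, and the cost-effectiveness
acceptability curve (CEAC) over a willingness-to-pay grid.

The one-way deterministic sensitivity analysis sweeps each parameter to its
low/high bounds holding the rest at base case (tornado table), and the
scenario engine evaluates named structural/parameter variants without
mutating the base configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ModelConfig, get_path, set_path
from .errors import ValidationError
from .markov import (
    ARM_CHEMOTHERAPY,
    ARM_CRIZOTINIB,
    EconResult,
    ICERResult,
    compute_icer,
    evaluate_strategy,
)
from .survfit import SurvivalFit, rate_from_median

__all__ = [
    "PFSInputs",
    "ParamDistribution",
    "PSAResult",
    "Scenario",
    "SCENARIOS",
    "evaluate_incremental",
    "default_psa_distributions",
    "sample_psa_parameters",
    "run_psa",
    "one_way_dsa",
    "run_scenario",
    "run_all_scenarios",
]


# ---------------------------------------------------------------------------
# PFS inputs and deterministic evaluation


@dataclass
class PFSInputs:
    """First-line PFS survival functions per arm, plus the fit they came from
    (the fit's covariance feeds the correlated PSA draws)."""

    crizotinib_sf: object  # callable t_months -> S(t)
    chemotherapy_sf: object
    fit: SurvivalFit | None = None

    @classmethod
    def from_fit(cls, fit: SurvivalFit) -> "PFSInputs":
        if not fit.shared_treatment:
            raise ValidationError("PFSInputs.from_fit needs a shared-treatment fit")
        return cls(
            crizotinib_sf=lambda t, f=fit: f.sf(t, ARM_CRIZOTINIB),
            chemotherapy_sf=lambda t, f=fit: f.sf(t, ARM_CHEMOTHERAPY),
            fit=fit,
        )

    @classmethod
    def from_fits(cls, fit_crizo: SurvivalFit, fit_chemo: SurvivalFit) -> "PFSInputs":
        """Individually fitted arms (no common treatment parameter)."""
        return cls(
            crizotinib_sf=lambda t, f=fit_crizo: f.sf(t),
            chemotherapy_sf=lambda t, f=fit_chemo: f.sf(t),
        )

    @classmethod
    def from_medians(cls, median_crizotinib: float, median_chemotherapy: float) -> "PFSInputs":
        """Exponential curves with the given medians (constant-risk variant)."""
        rc = rate_from_median(median_crizotinib)
        rh = rate_from_median(median_chemotherapy)
        return cls(
            crizotinib_sf=lambda t, r=rc: math.exp(-r * t),
            chemotherapy_sf=lambda t, r=rh: math.exp(-r * t),
        )

    def medians(self) -> tuple[float, float]:
        from scipy.optimize import brentq

        def med(sf):
            hi = 1.0
            while sf(hi) > 0.5 and hi < 1e6:
                hi *= 2
            return float(brentq(lambda t: sf(t) - 0.5, 1e-9, hi))

        return med(self.crizotinib_sf), med(self.chemotherapy_sf)


def evaluate_incremental(cfg: ModelConfig, pfs: PFSInputs) -> tuple[EconResult, EconResult, ICERResult]:
    """Deterministic model evaluation of both strategies and their ICER."""
    chemo_sf = pfs.crizotinib_sf if cfg.chemo_uses_crizotinib_pfs else pfs.chemotherapy_sf
    _, res_c = evaluate_strategy(ARM_CRIZOTINIB, pfs.crizotinib_sf, cfg)
    _, res_h = evaluate_strategy(ARM_CHEMOTHERAPY, chemo_sf, cfg)
    return res_c, res_h, compute_icer(res_c, res_h)


# ---------------------------------------------------------------------------
# parameter distributions


@dataclass
class ParamDistribution:
    """Sampling rule for one configuration leaf (or the survival-parameter block)."""

    path: str
    family: str  # beta | gamma | normal | lognormal_ci | multivariate_normal_cholesky | fixed
    mean: float | None = None
    se: float | None = None
    ci: tuple[float, float] | None = None
    mean_vector: np.ndarray | None = None
    cov: np.ndarray | None = None

    def sample(self, rng: np.random.Generator):
        if self.family == "fixed":
            return self.mean
        if self.family == "beta":
            m, v = self.mean, self.se**2
            vmax = m * (1.0 - m)
            if vmax <= 0:  # boundary mean: degenerate
                return m
            v = min(v, 0.81 * vmax)  # cap dispersion to keep the support
            nu = vmax / v - 1.0
            return float(rng.beta(m * nu, (1.0 - m) * nu))
        if self.family == "gamma":
            if self.mean <= 0:
                return self.mean
            v = self.se**2
            shape = self.mean**2 / v
            scale = v / self.mean
            return float(rng.gamma(shape, scale))
        if self.family == "normal":
            return float(rng.normal(self.mean, self.se))
        if self.family == "lognormal_ci":
            lo, hi = self.ci
            mu = math.log(self.mean)
            sigma = (math.log(hi) - math.log(lo)) / (2.0 * 1.959963985)
            return float(rng.lognormal(mu, sigma))
        if self.family == "multivariate_normal_cholesky":
            L = _cholesky_psd(np.asarray(self.cov, dtype=float))
            z = rng.standard_normal(len(self.mean_vector))
            return np.asarray(self.mean_vector) + L @ z
        raise ValidationError(f"unknown distribution family {self.family!r}")


def _cholesky_psd(cov: np.ndarray) -> np.ndarray:
    """Cholesky factor with a nearest-PSD eigenvalue-clip fallback."""
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh((cov + cov.T) / 2.0)
        w = np.clip(w, 1e-12, None)
        return np.linalg.cholesky(v @ np.diag(w) @ v.T)


def default_psa_distributions(cfg: ModelConfig, fit: SurvivalFit | None = None) -> list[ParamDistribution]:
    """Conventional defaults: costs gamma (SE 20% of mean), probabilities and
    utilities beta (SE 10% of mean, capped), BSA normal, maintenance HR
    log-normal from its 95% CI, survival parameters from the fit covariance.
    Drug unit list prices are held fixed."""
    dists: list[ParamDistribution] = []

    def beta10(path):
        m = float(get_path(cfg, path))
        dists.append(ParamDistribution(path, "beta", mean=m, se=0.10 * m if m > 0 else 0.0))

    def gamma20(path):
        m = float(get_path(cfg, path))
        dists.append(ParamDistribution(path, "gamma", mean=m, se=0.20 * m))

    for p in (
        "utilities.pfs_crizotinib",
        "utilities.pfs_chemotherapy",
        "utilities.later_line",
        "utilities.palliation",
        "testing.ihc_spec",
        "econ.maintenance_fraction",
        "econ.docetaxel_vs_checkpoint_split",
        "econ.palliation_active_fraction_crizotinib",
        "splits.pfs_to_2l",
        "splits.l2_to_3l",
        "splits.l3_to_palliation",
    ):
        beta10(p)
    for p in (
        "testing.ihc_cost",
        "testing.fish_cost",
        "econ.admin_monitor_monthly_crizotinib",
        "econ.admin_monitor_monthly_chemotherapy",
        "econ.ae_cost_crizotinib",
        "econ.ae_cost_chemotherapy",
        "econ.palliation_monthly",
        "econ.second_line_median_crizotinib_arm",
        "econ.second_line_median_chemotherapy_arm",
        "econ.third_line_median",
        "econ.palliation_os_median",
    ):
        gamma20(p)
    dists.append(
        ParamDistribution("dosing.bsa_m2", "normal", mean=cfg.dosing.bsa_m2,
                          se=0.10 * cfg.dosing.bsa_m2)
    )
    dists.append(
        ParamDistribution("econ.maintenance_hr", "lognormal_ci",
                          mean=cfg.econ.maintenance_hr, ci=(0.49, 0.79))
    )
    if fit is not None:
        dists.append(
            ParamDistribution(
                "survival.theta", "multivariate_normal_cholesky",
                mean_vector=np.asarray(fit.theta, dtype=float),
                cov=np.asarray(fit.covariance, dtype=float),
            )
        )
    return dists


def sample_psa_parameters(dists: list[ParamDistribution], rng: np.random.Generator) -> dict:
    """One joint draw: independent across distributions, correlated within the
    survival-parameter block."""
    return {d.path: d.sample(rng) for d in dists}


# coupled split groups: setting the lead rebalances the complements
_SPLIT_GROUPS = {
    "splits.pfs_to_2l": ("splits.pfs_to_palliation", "splits.pfs_to_death"),
    "splits.l2_to_3l": ("splits.l2_to_palliation", "splits.l2_to_death"),
    "splits.l3_to_palliation": ("splits.l3_to_death",),
}


def apply_override(cfg: ModelConfig, path: str, value) -> None:
    """Set one leaf; transition-split leads rebalance their complements
    proportionally so each destination set keeps summing to one."""
    if path in _SPLIT_GROUPS:
        others = _SPLIT_GROUPS[path]
        value = float(min(max(value, 0.0), 1.0))
        old_rest = sum(get_path(cfg, o) for o in others)
        set_path(cfg, path, value)
        rest = 1.0 - value
        for o in others:
            share = get_path(cfg, o) / old_rest if old_rest > 0 else 1.0 / len(others)
            set_path(cfg, o, rest * share)
        return
    set_path(cfg, path, value)


def _configure_draw(cfg: ModelConfig, pfs: PFSInputs, sampled: dict) -> tuple[ModelConfig, PFSInputs]:
    cfg_i = cfg.copy()
    pfs_i = pfs
    for path, value in sampled.items():
        if path == "survival.theta":
            base = pfs.fit
            if base is None:
                raise ValidationError("survival-parameter draws need PFSInputs.fit")
            fit_i = SurvivalFit(
                family_name=base.family_name,
                theta=np.asarray(value, dtype=float),
                covariance=base.covariance,
                loglik=base.loglik,
                n=base.n,
                n_events=base.n_events,
                shared_treatment=base.shared_treatment,
            )
            pfs_i = PFSInputs.from_fit(fit_i)
        else:
            apply_override(cfg_i, path, value)
    cfg_i.validate()
    return cfg_i, pfs_i


# ---------------------------------------------------------------------------
# PSA


@dataclass
class PSAResult:
    draws: pd.DataFrame  # one row per simulation: delta_cost, delta_ly, delta_qaly
    ceac: pd.DataFrame  # columns wtp, probability
    seed: int
    n_sims: int
    n_failures: int = 0
    sampled: pd.DataFrame | None = None  # per-sim sampled scalar parameters

    @property
    def means(self) -> dict[str, float]:
        return {
            "delta_cost": float(self.draws["delta_cost"].mean()),
            "delta_ly": float(self.draws["delta_ly"].mean()),
            "delta_qaly": float(self.draws["delta_qaly"].mean()),
        }

    def icer_qaly_of_means(self) -> float:
        m = self.means
        return m["delta_cost"] / m["delta_qaly"]

    def prob_cost_effective(self, wtp: float) -> float:
        dq = self.draws["delta_qaly"].to_numpy()
        dc = self.draws["delta_cost"].to_numpy()
        return float(np.mean(wtp * dq - dc > 0.0))


def run_psa(
    cfg: ModelConfig,
    pfs: PFSInputs,
    dists: list[ParamDistribution] | None = None,
    n_sims: int = 5000,
    seed: int = 0,
    wtp_grid: np.ndarray | None = None,
    max_failure_fraction: float = 0.01,
) -> PSAResult:
    """Monte-Carlo re-evaluation of the incremental comparison.

    Each simulation draws one joint parameter set, rebuilds the configuration
    and survival inputs, and evaluates both strategies.  Failed evaluations
    are logged and re-drawn (never silently dropped), with a hard cap on the
    failure fraction.  The per-simulation random streams are spawned from
    ``seed`` so that extending ``n_sims`` leaves earlier draws unchanged.
    """
    if dists is None:
        dists = default_psa_distributions(cfg, pfs.fit)
    if wtp_grid is None:
        wtp_grid = np.linspace(0.0, 500_000.0, 5001)

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_sims)
    retry_stream = ss.spawn(1)[0]
    rows, sampled_rows = [], []
    n_failures = 0
    max_failures = max(int(max_failure_fraction * n_sims), 1)
    for i in range(n_sims):
        rng = np.random.default_rng(children[i])
        while True:
            try:
                sampled = sample_psa_parameters(dists, rng)
                cfg_i, pfs_i = _configure_draw(cfg, pfs, sampled)
                res_c, res_h, icer = evaluate_incremental(cfg_i, pfs_i)
                break
            except Exception:
                n_failures += 1
                if n_failures > max_failures:
                    raise ValidationError(
                        f"PSA failure cap exceeded ({n_failures} failed draws)"
                    )
                rng = np.random.default_rng(retry_stream.spawn(1)[0])
        rows.append(
            {
                "sim": i,
                "delta_cost": icer.delta_cost,
                "delta_ly": icer.delta_ly,
                "delta_qaly": icer.delta_qaly,
            }
        )
        sampled_rows.append(
            {k: v for k, v in sampled.items() if np.isscalar(v)} | {"sim": i}
        )
    draws = pd.DataFrame(rows)

    dq = draws["delta_qaly"].to_numpy()
    dc = draws["delta_cost"].to_numpy()
    prob = (wtp_grid[:, None] * dq[None, :] - dc[None, :] > 0.0).mean(axis=1)
    ceac = pd.DataFrame({"wtp": wtp_grid, "probability": prob})
    return PSAResult(
        draws=draws, ceac=ceac, seed=seed, n_sims=n_sims,
        n_failures=n_failures, sampled=pd.DataFrame(sampled_rows),
    )


# ---------------------------------------------------------------------------
# one-way deterministic sensitivity analysis


def one_way_dsa(
    cfg: ModelConfig,
    pfs: PFSInputs,
    ranges: dict[str, tuple[float, float]],
) -> pd.DataFrame:
    """Tornado table: ICER (per QALY) at each parameter's low/high bound.

    Every range must contain the base value; the sweep never mutates the base
    configuration.
    """
    _, _, base_icer = evaluate_incremental(cfg, pfs)
    rows = []
    for path, (lo, hi) in ranges.items():
        base_val = float(get_path(cfg, path))
        if not (min(lo, hi) <= base_val <= max(lo, hi)):
            raise ValidationError(
                f"DSA range for {path} is [{lo}, {hi}] but base value is {base_val}"
            )
        vals = {}
        for tag, v in (("low", lo), ("high", hi)):
            c = cfg.copy()
            apply_override(c, path, v)
            c.validate()
            _, _, icer = evaluate_incremental(c, pfs)
            vals[tag] = icer.icer_qaly
        rows.append(
            {
                "parameter": path,
                "low": lo,
                "high": hi,
                "base_value": base_val,
                "icer_low": vals["low"],
                "icer_high": vals["high"],
                "spread": abs(vals["high"] - vals["low"]),
            }
        )
    out = pd.DataFrame(rows).sort_values("spread", ascending=False).reset_index(drop=True)
    out.attrs["base_icer_qaly"] = base_icer.icer_qaly
    return out


def default_dsa_ranges(cfg: ModelConfig) -> dict[str, tuple[float, float]]:
    """+/- 20% around base (clipped into [0, 1] for probabilities/utilities)."""
    paths_unit = [
        "utilities.pfs_crizotinib",
        "utilities.pfs_chemotherapy",
        "utilities.later_line",
        "utilities.palliation",
        "econ.maintenance_fraction",
        "econ.docetaxel_vs_checkpoint_split",
        "econ.palliation_active_fraction_crizotinib",
        "splits.pfs_to_2l",
        "splits.l2_to_3l",
        "testing.ihc_spec",
    ]
    paths_pos = [
        "drugs.crizotinib_per_tablet",
        "econ.maintenance_hr",
        "econ.admin_monitor_monthly_crizotinib",
        "econ.admin_monitor_monthly_chemotherapy",
        "econ.palliation_monthly",
        "econ.second_line_median_crizotinib_arm",
        "econ.second_line_median_chemotherapy_arm",
        "econ.third_line_median",
        "econ.palliation_os_median",
        "econ.discount_rate_annual",
    ]
    ranges = {}
    for p in paths_unit:
        v = float(get_path(cfg, p))
        ranges[p] = (max(0.8 * v, 0.0), min(1.2 * v, 1.0))
    for p in paths_pos:
        v = float(get_path(cfg, p))
        ranges[p] = (0.8 * v, 1.2 * v)
    return ranges


# ---------------------------------------------------------------------------
# scenario engine


@dataclass
class Scenario:
    """A named variant: parameter overrides plus optional structural switches."""

    id: str
    description: str
    overrides: dict = field(default_factory=dict)
    exponential_pfs: bool = False  # replace PFS curves by same-median exponentials
    pfs_source: str | None = None  # key into alternative PFS inputs, if any


SCENARIOS: dict[str, Scenario] = {
    s.id: s
    for s in [
        Scenario("base", "Base case deterministic results"),
        Scenario(
            "exponential_pfs",
            "Constant progression risk: exponential first-line curves at the fitted medians",
            exponential_pfs=True,
        ),
        Scenario(
            "individual_fits",
            "Arms fitted separately instead of with a common treatment parameter",
            pfs_source="individual_fits",
        ),
        Scenario(
            "no_pfs_difference",
            "Chemotherapy arm evaluated on the crizotinib PFS curve",
            overrides={"chemo_uses_crizotinib_pfs": True},
        ),
        Scenario(
            "no_maintenance_benefit",
            "Pemetrexed-maintenance hazard ratio removed (HR = 1)",
            overrides={"econ.maintenance_hr": 1.0},
        ),
        Scenario(
            "lower_second_line_median",
            "Crizotinib-arm second-line PFS median lowered to 4.2 months",
            overrides={"econ.second_line_median_crizotinib_arm": 4.2},
        ),
        Scenario(
            "equal_utility_crizotinib_values",
            "Both arms get the crizotinib first-line utility",
            overrides={"utilities.pfs_chemotherapy": 0.806},
        ),
        Scenario(
            "equal_utility_chemotherapy_values",
            "Both arms get the chemotherapy first-line utility",
            overrides={"utilities.pfs_crizotinib": 0.776},
        ),
        Scenario(
            "alk_proxy_utilities",
            "First-line utilities from the ALK+ proxy trial (0.81 / 0.72)",
            overrides={"utilities.pfs_crizotinib": 0.81, "utilities.pfs_chemotherapy": 0.72},
        ),
        Scenario(
            "third_line_30pct",
            "Only 30% of second-line progressors receive active third-line therapy",
            overrides={"splits.l2_to_3l": 0.30},
        ),
        Scenario(
            "reanalysis_combined",
            "Combined: 4.2-month second-line median, ALK+ proxy utilities, 30% third line",
            overrides={
                "econ.second_line_median_crizotinib_arm": 4.2,
                "utilities.pfs_crizotinib": 0.81,
                "utilities.pfs_chemotherapy": 0.72,
                "splits.l2_to_3l": 0.30,
            },
        ),
    ]
}


def run_scenario(
    cfg: ModelConfig,
    pfs: PFSInputs,
    scenario: Scenario,
    alt_pfs: dict[str, PFSInputs] | None = None,
) -> dict:
    """Deterministic evaluation under one scenario; the base config is never
    mutated (a deep copy receives the overrides)."""
    c = cfg.copy()
    for path, value in scenario.overrides.items():
        apply_override(c, path, value)
    c.validate()
    p = pfs
    if scenario.pfs_source is not None:
        if not alt_pfs or scenario.pfs_source not in alt_pfs:
            raise ValidationError(
                f"scenario {scenario.id!r} needs alternative PFS inputs "
                f"{scenario.pfs_source!r}; available: {sorted(alt_pfs or {})}"
            )
        p = alt_pfs[scenario.pfs_source]
    if scenario.exponential_pfs:
        mc, mh = p.medians()
        p = PFSInputs.from_medians(mc, mh)
    res_c, res_h, icer = evaluate_incremental(c, p)
    return {
        "scenario": scenario.id,
        "description": scenario.description,
        "delta_ly": icer.delta_ly,
        "delta_qaly": icer.delta_qaly,
        "delta_cost": icer.delta_cost,
        "icer_ly": icer.icer_ly,
        "icer_qaly": icer.icer_qaly,
    }


def run_all_scenarios(
    cfg: ModelConfig,
    pfs: PFSInputs,
    alt_pfs: dict[str, PFSInputs] | None = None,
) -> pd.DataFrame:
    """Every catalog scenario whose inputs are available, as a results table."""
    rows = []
    for s in SCENARIOS.values():
        if s.pfs_source is not None and (not alt_pfs or s.pfs_source not in alt_pfs):
            continue
        rows.append(run_scenario(cfg, pfs, s, alt_pfs))
    return pd.DataFrame(rows)
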