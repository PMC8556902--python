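"""Decision tree plus five-state Markov cohort model for one treatment strategy.

Tested-positive patients enter a weekly-cycle cohort model over a 10-year
horizon with states PFS (first line), second line, third line, palliation
and death.  The first-line exit probability is time-varying, derived from
the fitted PFS curve as 1 - S(t+d)/S(t) at the cycle length d; later-line
exits are exponential with published medians.  Exits are allocated across
next line / palliation / death by fixed transition splits.

Sub-cohorts (strata) are tracked where treatment within a state differs:

* chemotherapy-arm PFS splits, at the end of platinum-doublet induction
  (6 x 21-day cycles = 18 weekly cycles), into pemetrexed-maintenance
  (a hazard ratio of 0.62 applies to the progression probability) and
  observation strata;
* the crizotinib arm's second line is platinum doublet and carries the same
  maintenance sub-cohort; the chemotherapy arm's later lines are a
  checkpoint-inhibitor/docetaxel mix.

Costs (drug acquisition, administration + monitoring, palliation, one-off
adverse events and ROS1 testing) and utilities accrue per cycle and are
discounted at the cycle midpoint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ModelConfig
from .errors import ValidationError
from .survfit import apply_hazard_ratio, rate_from_median

DAYS_PER_MONTH = 30.4375  # 365.25 / 12
DAYS_PER_YEAR = 365.25

ARM_CRIZOTINIB = "crizotinib"
ARM_CHEMOTHERAPY = "chemotherapy"

STATES = ("PFS", "2L", "3L", "PALLIATION", "DEATH")

__all__ = [
    "testing_cost_per_case",
    "calvert_carboplatin_dose",
    "DrugRegimen",
    "regimen_cycle_cost",
    "discount_factor",
    "CohortTrace",
    "EconResult",
    "ICERResult",
    "run_cohort_trace",
    "accrue_outcomes",
    "evaluate_strategy",
    "compute_icer",
    "weekly_costs",
]


# ---------------------------------------------------------------------------
# decision tree and cost primitives


def testing_cost_per_case(p) -> float:
    """Expected testing cost per true ROS1+ case detected.

    Per patient tested: IHC on everyone, confirmatory FISH on IHC-positives,
    so cost = c_IHC + P(IHC+) * c_FISH with
    P(IHC+) = prev * sens_IHC + (1 - prev) * (1 - spec_IHC).
    Dividing by the detection probability prev * sens_IHC * sens_FISH gives
    the cost attributable to each case found.
    """
    if p.prevalence <= 0:
        raise ValidationError("prevalence must be > 0: no cases can be detected")
    p_ihc_pos = p.prevalence * p.ihc_sens + (1.0 - p.prevalence) * (1.0 - p.ihc_spec)
    per_tested = p.ihc_cost + p_ihc_pos * p.fish_cost
    p_detect = p.prevalence * p.ihc_sens * p.fish_sens
    if p_detect <= 0:
        raise ValidationError("detection probability is zero under these test characteristics")
    return per_tested / p_detect


def calvert_carboplatin_dose(target_auc: float, creatinine_clearance: float) -> float:
    """Carboplatin dose (mg) = AUC x (CrCl + 25)."""
    if target_auc <= 0 or creatinine_clearance <= 0:
        raise ValidationError("Calvert formula needs positive AUC and creatinine clearance")
    return target_auc * (creatinine_clearance + 25.0)


@dataclass
class DrugRegimen:
    """One drug's dosing/pricing rule, amortizable into model cycles."""

    name: str
    dosing_basis: str  # per_tablet_fixed | per_mg_per_m2 | per_mg_flat | per_mg_per_kg
    dose: float  # tablets/day, mg/m2, mg, or mg/kg according to basis
    unit_cost: float  # CAD per tablet or per mg
    cycle_length_days: float = 21.0
    administrations_per_cycle: int = 1
    max_cycles: int | None = None
    continuous_until_progression: bool = True

    def __post_init__(self):
        if self.unit_cost < 0 or self.dose < 0:
            raise ValidationError(f"{self.name}: dose and unit cost must be non-negative")
        if (self.max_cycles is not None) == self.continuous_until_progression:
            raise ValidationError(
                f"{self.name}: exactly one of max_cycles / continuous_until_progression"
            )


def regimen_cycle_cost(r: DrugRegimen, cfg: ModelConfig) -> float:
    """Drug cost per model cycle while on treatment (uniform amortization)."""
    d = cfg.dosing
    if r.dosing_basis == "per_tablet_fixed":
        return r.dose * r.unit_cost * cfg.econ.cycle_days
    if r.dosing_basis == "per_mg_per_m2":
        per_admin = r.dose * d.bsa_m2 * r.unit_cost
    elif r.dosing_basis == "per_mg_flat":
        per_admin = r.dose * r.unit_cost
    elif r.dosing_basis == "per_mg_per_kg":
        per_admin = r.dose * d.weight_kg * r.unit_cost
    else:
        raise ValidationError(f"unknown dosing basis {r.dosing_basis!r}")
    per_day = per_admin * r.administrations_per_cycle / r.cycle_length_days
    return per_day * cfg.econ.cycle_days


def discount_factor(t_years: float, annual_rate: float):
    """(1 + r)^(-t); applied identically to costs and outcomes."""
    t = np.asarray(t_years, dtype=float)
    if np.any(t < 0):
        raise ValidationError("discounting time must be >= 0")
    if annual_rate < 0:
        raise ValidationError("discount rate must be >= 0")
    return (1.0 + annual_rate) ** (-t)


# ---------------------------------------------------------------------------
# per-compartment weekly cost/utility schedules


def weekly_costs(cfg: ModelConfig) -> dict[str, float]:
    """Per-model-cycle costs of each treatment component."""
    e, d, pr = cfg.econ, cfg.dosing, cfg.drugs
    prorate = e.cycle_days / DAYS_PER_MONTH

    crizotinib = regimen_cycle_cost(
        DrugRegimen("crizotinib", "per_tablet_fixed", d.crizotinib_tablets_per_day,
                    pr.crizotinib_per_tablet), cfg)
    pemetrexed = regimen_cycle_cost(
        DrugRegimen("pemetrexed", "per_mg_per_m2", d.pemetrexed_mg_per_m2,
                    pr.pemetrexed_per_mg, d.chemo_cycle_days), cfg)
    platinum_mg = calvert_carboplatin_dose(d.carboplatin_target_auc,
                                           d.creatinine_clearance_ml_min)
    platinum = regimen_cycle_cost(
        DrugRegimen("carboplatin", "per_mg_flat", platinum_mg,
                    pr.platinum_per_mg, d.chemo_cycle_days), cfg)
    docetaxel = regimen_cycle_cost(
        DrugRegimen("docetaxel", "per_mg_per_m2", d.docetaxel_mg_per_m2,
                    pr.docetaxel_per_mg, d.chemo_cycle_days), cfg)
    pembrolizumab = regimen_cycle_cost(
        DrugRegimen("pembrolizumab", "per_mg_flat", d.pembrolizumab_mg_flat,
                    pr.pembrolizumab_per_mg, d.chemo_cycle_days), cfg)
    nivolumab = regimen_cycle_cost(
        DrugRegimen("nivolumab", "per_mg_per_kg", d.nivolumab_mg_per_kg,
                    pr.nivolumab_per_mg, d.nivolumab_cycle_days), cfg)

    checkpoint = 0.5 * pembrolizumab + 0.5 * nivolumab
    w = e.docetaxel_vs_checkpoint_split
    mix_2l3l = w * docetaxel + (1.0 - w) * checkpoint

    return {
        "crizotinib": crizotinib,
        "platinum_doublet": pemetrexed + platinum,
        "pemetrexed_maintenance": pemetrexed,
        "mix_2l3l": mix_2l3l,
        "admin_crizotinib": e.admin_monitor_monthly_crizotinib * prorate,
        "admin_iv": e.admin_monitor_monthly_chemotherapy * prorate,
        "palliation": e.palliation_monthly * prorate,
    }


# ---------------------------------------------------------------------------
# cohort trace


@dataclass
class CohortTrace:
    """Cycle-by-compartment occupancy for one strategy.

    ``labels`` pair each compartment with its reporting state; row ``c`` is
    the occupancy during cycle ``c`` (the model starts with the whole cohort
    in the first compartment).
    """

    arm: str
    labels: list[tuple[str, str]]  # (state, stratum)
    occupancy: np.ndarray  # [n_cycles + 1, n_compartments]
    cycle_days: float

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def validate(self) -> None:
        rows = self.occupancy.sum(axis=1)
        if np.any(np.abs(rows - 1.0) > 1e-9):
            raise ValidationError("trace rows must sum to 1 within 1e-9")
        if np.any((self.occupancy < -1e-12) | (self.occupancy > 1.0 + 1e-12)):
            raise ValidationError("occupancy outside [0, 1]")
        dead = self.state_occupancy("DEATH")
        if np.any(np.diff(dead) < -1e-12):
            raise ValidationError("DEATH occupancy must be non-decreasing")

    def state_occupancy(self, state: str) -> np.ndarray:
        cols = [i for i, (s, _) in enumerate(self.labels) if s == state]
        return self.occupancy[:, cols].sum(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        cols = [f"{s}:{st}" if st else s for s, st in self.labels]
        df = pd.DataFrame(self.occupancy, columns=cols)
        df.insert(0, "cycle", np.arange(self.occupancy.shape[0]))
        return df


def _exit_splits(cfg: ModelConfig):
    s = cfg.splits
    s.validate()
    return {
        "PFS": (s.pfs_to_2l, s.pfs_to_palliation, s.pfs_to_death),
        "2L": (s.l2_to_3l, s.l2_to_palliation, s.l2_to_death),
        "3L": (s.l3_to_palliation, s.l3_to_death),
    }


def run_cohort_trace(arm: str, pfs_sf, cfg: ModelConfig) -> CohortTrace:
    """Run the weekly five-state cohort model for one arm.

    ``pfs_sf`` is the first-line survival function S(t months) for this arm.
    Maintenance sub-cohorts are entered at the end of induction by
    ``econ.maintenance_fraction`` of progression-free patients and progress
    under ``econ.maintenance_hr``.
    """
    if arm not in (ARM_CRIZOTINIB, ARM_CHEMOTHERAPY):
        raise ValidationError(f"unknown arm {arm!r}")
    e = cfg.econ
    e.validate()
    splits = _exit_splits(cfg)
    dm = e.cycle_days / DAYS_PER_MONTH  # cycle length in months
    n_cycles = math.ceil(e.horizon_years * DAYS_PER_YEAR / e.cycle_days)
    W = int(round(cfg.dosing.induction_cycles * cfg.dosing.chemo_cycle_days / e.cycle_days))

    # exponential per-cycle exit probabilities for the memoryless states
    second_median = (
        e.second_line_median_crizotinib_arm
        if arm == ARM_CRIZOTINIB
        else e.second_line_median_chemotherapy_arm
    )
    tp2 = 1.0 - math.exp(-rate_from_median(second_median) * dm)
    tp3 = 1.0 - math.exp(-rate_from_median(e.third_line_median) * dm)
    tpp = 1.0 - math.exp(-rate_from_median(e.palliation_os_median) * dm)
    mf, hr = e.maintenance_fraction, e.maintenance_hr

    # compartment layout
    labels: list[tuple[str, str]] = []
    if arm == ARM_CRIZOTINIB:
        labels.append(("PFS", ""))
        labels += [("2L", f"induction_{k}") for k in range(W)]
        labels += [("2L", "maintenance"), ("2L", "observation")]
        pfs_cols = [0]
        l2_ind = list(range(1, 1 + W))
        l2_maint, l2_obs = 1 + W, 2 + W
        next_idx = 3 + W
    else:
        labels += [("PFS", f"induction_{k}") for k in range(W)]
        labels += [("PFS", "maintenance"), ("PFS", "observation")]
        pfs_cols = list(range(W + 2))
        l2_ind, l2_maint, l2_obs = [], None, None
        next_idx = W + 2
        labels.append(("2L", ""))
        l2_plain = next_idx
        next_idx += 1
    if arm == ARM_CRIZOTINIB:
        l2_plain = None
    labels += [("3L", ""), ("PALLIATION", ""), ("DEATH", "")]
    i3, ip, idd = next_idx, next_idx + 1, next_idx + 2
    ncomp = len(labels)

    occ = np.zeros((n_cycles + 1, ncomp))
    occ[0, pfs_cols[0]] = 1.0

    p2l, p2pall, p2death = splits["PFS"]
    q3l, qpall, qdeath = splits["2L"]
    rpall, rdeath = splits["3L"]

    for c in range(n_cycles):
        cur = occ[c]
        nxt = np.zeros(ncomp)
        t0, t1 = c * dm, (c + 1) * dm
        s0, s1 = float(pfs_sf(t0)), float(pfs_sf(t1))
        tp_pfs = 1.0 if s0 <= 1e-12 else min(max(1.0 - s1 / s0, 0.0), 1.0)

        exits_pfs = 0.0
        if arm == ARM_CRIZOTINIB:
            stay = cur[0] * (1.0 - tp_pfs)
            exits_pfs = cur[0] * tp_pfs
            nxt[0] += stay
        else:
            # induction ages 0..W-1 progress at the fitted curve's probability;
            # survivors of age W-1 split into maintenance/observation
            for k in range(W):
                col = pfs_cols[k]
                stay = cur[col] * (1.0 - tp_pfs)
                exits_pfs += cur[col] * tp_pfs
                if k < W - 1:
                    nxt[pfs_cols[k + 1]] += stay
                else:
                    nxt[pfs_cols[W]] += stay * mf  # maintenance
                    nxt[pfs_cols[W + 1]] += stay * (1.0 - mf)  # observation
            tp_m = apply_hazard_ratio(tp_pfs, hr) if tp_pfs < 1.0 else 1.0
            m_col, o_col = pfs_cols[W], pfs_cols[W + 1]
            nxt[m_col] += cur[m_col] * (1.0 - tp_m)
            exits_pfs += cur[m_col] * tp_m
            nxt[o_col] += cur[o_col] * (1.0 - tp_pfs)
            exits_pfs += cur[o_col] * tp_pfs

        to_2l = exits_pfs * p2l
        to_pall = exits_pfs * p2pall
        to_death = exits_pfs * p2death

        # second line
        exits_2l = 0.0
        if arm == ARM_CRIZOTINIB:
            nxt[l2_ind[0]] += to_2l
            tp2_m = apply_hazard_ratio(tp2, hr)
            for k in range(W):
                col = l2_ind[k]
                stay = cur[col] * (1.0 - tp2)
                exits_2l += cur[col] * tp2
                if k < W - 1:
                    nxt[l2_ind[k + 1]] += stay
                else:
                    nxt[l2_maint] += stay * mf
                    nxt[l2_obs] += stay * (1.0 - mf)
            nxt[l2_maint] += cur[l2_maint] * (1.0 - tp2_m)
            exits_2l += cur[l2_maint] * tp2_m
            nxt[l2_obs] += cur[l2_obs] * (1.0 - tp2)
            exits_2l += cur[l2_obs] * tp2
        else:
            nxt[l2_plain] += to_2l + cur[l2_plain] * (1.0 - tp2)
            exits_2l = cur[l2_plain] * tp2

        # third line, palliation, death
        nxt[i3] += exits_2l * q3l + cur[i3] * (1.0 - tp3)
        exits_3l = cur[i3] * tp3
        nxt[ip] += (
            to_pall + exits_2l * qpall + exits_3l * rpall + cur[ip] * (1.0 - tpp)
        )
        nxt[idd] += (
            cur[idd] + to_death + exits_2l * qdeath + exits_3l * rdeath + cur[ip] * tpp
        )
        # renormalize away accumulated floating-point drift
        nxt *= 1.0 / nxt.sum()
        occ[c + 1] = nxt

    trace = CohortTrace(arm=arm, labels=labels, occupancy=occ, cycle_days=e.cycle_days)
    trace.validate()
    return trace


# ---------------------------------------------------------------------------
# accrual


@dataclass
class EconResult:
    """Discounted per-state costs, life-years and QALYs for one strategy."""

    arm: str
    cost: dict[str, float] = field(default_factory=dict)
    ly: dict[str, float] = field(default_factory=dict)
    qaly: dict[str, float] = field(default_factory=dict)

    @property
    def total_cost(self) -> float:
        return sum(self.cost.values())

    @property
    def total_ly(self) -> float:
        return sum(self.ly.values())

    @property
    def total_qaly(self) -> float:
        return sum(self.qaly.values())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for section, d in (("COSTS", self.cost), ("LYs", self.ly), ("QALYs", self.qaly)):
            for k, v in d.items():
                rows.append({"section": section, "component": k, "value": v})
        rows.append({"section": "COSTS", "component": "TOTAL", "value": self.total_cost})
        rows.append({"section": "LYs", "component": "TOTAL", "value": self.total_ly})
        rows.append({"section": "QALYs", "component": "TOTAL", "value": self.total_qaly})
        return pd.DataFrame(rows)


def _compartment_schedules(trace: CohortTrace, cfg: ModelConfig):
    """Weekly cost and utility per compartment."""
    w = weekly_costs(cfg)
    u = cfg.utilities
    e = cfg.econ
    arm = trace.arm
    pall_active = (
        e.palliation_active_fraction_crizotinib
        if arm == ARM_CRIZOTINIB
        else e.palliation_active_fraction_chemotherapy
    )
    cost = np.zeros(len(trace.labels))
    util = np.zeros(len(trace.labels))
    for i, (state, stratum) in enumerate(trace.labels):
        if state == "PFS":
            if arm == ARM_CRIZOTINIB:
                cost[i] = w["crizotinib"] + w["admin_crizotinib"]
                util[i] = u.pfs_crizotinib
            else:
                if stratum.startswith("induction"):
                    cost[i] = w["platinum_doublet"] + w["admin_iv"]
                elif stratum == "maintenance":
                    cost[i] = w["pemetrexed_maintenance"] + w["admin_iv"]
                else:  # observation: off treatment
                    cost[i] = 0.0
                util[i] = u.pfs_chemotherapy
        elif state == "2L":
            if arm == ARM_CRIZOTINIB:
                if stratum.startswith("induction"):
                    cost[i] = w["platinum_doublet"] + w["admin_iv"]
                elif stratum == "maintenance":
                    cost[i] = w["pemetrexed_maintenance"] + w["admin_iv"]
                else:
                    cost[i] = 0.0
            else:
                cost[i] = w["mix_2l3l"] + w["admin_iv"]
            util[i] = u.later_line
        elif state == "3L":
            cost[i] = w["mix_2l3l"] + w["admin_iv"]
            util[i] = u.later_line
        elif state == "PALLIATION":
            cost[i] = w["palliation"] + pall_active * (w["mix_2l3l"] + w["admin_iv"])
            util[i] = u.palliation
        else:  # DEATH
            cost[i] = 0.0
            util[i] = 0.0
    return cost, util


def accrue_outcomes(trace: CohortTrace, cfg: ModelConfig, *, include_testing: bool = True) -> EconResult:
    """Accrue discounted costs, LYs and QALYs over a cohort trace.

    Testing cost (crizotinib strategy only) and adverse-event one-offs apply
    at model entry; everything else accrues per cycle at the occupancy of
    that cycle, discounted at the cycle midpoint.
    """
    e = cfg.econ
    n = trace.n_cycles
    dy = trace.cycle_days / DAYS_PER_YEAR  # cycle length in years
    df = discount_factor((np.arange(n) + 0.5) * dy, e.discount_rate_annual)
    occ = trace.occupancy[:n]  # occupancy during each cycle
    cost_pc, util_pc = _compartment_schedules(trace, cfg)

    res = EconResult(arm=trace.arm)
    state_names = {"PFS": "pfs_first_line", "2L": "second_line", "3L": "third_line",
                   "PALLIATION": "palliation"}
    for state, key in state_names.items():
        cols = [i for i, (s, _) in enumerate(trace.labels) if s == state]
        occ_s = occ[:, cols]
        res.cost[key] = float(np.sum((occ_s * cost_pc[cols]).sum(axis=1) * df))
        res.ly[key] = float(np.sum(occ_s.sum(axis=1) * df) * dy)
        res.qaly[key] = float(np.sum((occ_s * util_pc[cols]).sum(axis=1) * df) * dy)

    if trace.arm == ARM_CRIZOTINIB:
        if include_testing:
            res.cost["testing"] = testing_cost_per_case(cfg.testing)
        res.cost["adverse_events"] = e.ae_cost_crizotinib
        res.qaly["adverse_events"] = e.ae_disutility_crizotinib
    else:
        res.cost["adverse_events"] = e.ae_cost_chemotherapy
        res.qaly["adverse_events"] = e.ae_disutility_chemotherapy
    return res


def evaluate_strategy(arm: str, pfs_sf, cfg: ModelConfig) -> tuple[CohortTrace, EconResult]:
    """Trace + accrual for one arm in one call."""
    trace = run_cohort_trace(arm, pfs_sf, cfg)
    return trace, accrue_outcomes(trace, cfg)


# ---------------------------------------------------------------------------
# ICER


@dataclass
class ICERResult:
    """Incremental comparison a (intervention) vs b (comparator)."""

    delta_cost: float
    delta_ly: float
    delta_qaly: float
    icer_ly: float
    icer_qaly: float
    flag_ly: str = ""
    flag_qaly: str = ""

    def to_dict(self) -> dict:
        return {
            "delta_cost": self.delta_cost,
            "delta_ly": self.delta_ly,
            "delta_qaly": self.delta_qaly,
            "icer_ly": self.icer_ly,
            "icer_qaly": self.icer_qaly,
            "flag_ly": self.flag_ly,
            "flag_qaly": self.flag_qaly,
        }


def _ratio_and_flag(dc: float, de: float) -> tuple[float, str]:
    if de == 0.0:
        return (float("nan"), "undefined" if dc != 0.0 else "")
    if de < 0.0 and dc >= 0.0:
        return (float("nan"), "dominated")
    if de > 0.0 and dc <= 0.0:
        return (dc / de, "dominant")
    return (dc / de, "")


def compute_icer(a: EconResult, b: EconResult) -> ICERResult:
    """ICER = (Cost_a - Cost_b) / (Effect_a - Effect_b), with dominance flags."""
    dc = a.total_cost - b.total_cost
    dly = a.total_ly - b.total_ly
    dq = a.total_qaly - b.total_qaly
    r_ly, f_ly = _ratio_and_flag(dc, dly)
    r_q, f_q = _ratio_and_flag(dc, dq)
    return ICERResult(dc, dly, dq, r_ly, r_q, f_ly, f_q)
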