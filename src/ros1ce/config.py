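"""Model configuration: costs, utilities, transition splits, dosing and timing.

Defaults reproduce the published Canadian input set (2018 CAD): ROS1 testing
characteristics, first/second/third-line medians, the pemetrexed-maintenance
hazard ratio, per-unit drug prices, administration/monitoring and palliation
costs, state utilities and adverse-event one-offs, a 10-year horizon with
one-week cycles and 1.5% annual discounting.

Every leaf is reachable by a dot path (e.g. ``"econ.maintenance_hr"``),
which is how the deterministic sensitivity analysis and the scenario engine
override values without touching code.
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field

import yaml

from .errors import ValidationError

__all__ = [
    "TestingParams",
    "TransitionSplits",
    "DrugPrices",
    "Dosing",
    "Utilities",
    "EconParams",
    "ModelConfig",
    "get_path",
    "set_path",
    "load_config",
    "save_config",
]


@dataclass
class TestingParams:
    """IHC screen followed by confirmatory FISH on positives."""

    prevalence: float = 0.0164
    ihc_sens: float = 1.0
    ihc_spec: float = 0.83
    fish_sens: float = 1.0
    fish_spec: float = 1.0
    ihc_cost: float = 42.36
    fish_cost: float = 410.93

    def validate(self) -> None:
        for f in ("prevalence", "ihc_sens", "ihc_spec", "fish_sens", "fish_spec"):
            v = getattr(self, f)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"testing.{f} must be a probability, got {v}")
        if self.ihc_cost < 0 or self.fish_cost < 0:
            raise ValidationError("test costs must be non-negative")


@dataclass
class TransitionSplits:
    """Destination proportions for patients leaving each pre-palliation state."""

    pfs_to_2l: float = 0.70
    pfs_to_palliation: float = 0.10
    pfs_to_death: float = 0.20
    l2_to_3l: float = 0.60
    l2_to_palliation: float = 0.20
    l2_to_death: float = 0.20
    l3_to_palliation: float = 0.60
    l3_to_death: float = 0.40

    def validate(self) -> None:
        groups = {
            "PFS": self.pfs_to_2l + self.pfs_to_palliation + self.pfs_to_death,
            "2L": self.l2_to_3l + self.l2_to_palliation + self.l2_to_death,
            "3L": self.l3_to_palliation + self.l3_to_death,
        }
        for name, s in groups.items():
            if abs(s - 1.0) > 1e-9:
                raise ValidationError(f"{name} exit splits sum to {s}, expected 1")


@dataclass
class DrugPrices:
    """Unit acquisition costs (CAD). Platinum agents carry no printed unit
    cost in the source tables and default to zero (override if needed)."""

    crizotinib_per_tablet: float = 130.00
    pemetrexed_per_mg: float = 0.21
    docetaxel_per_mg: float = 0.27
    pembrolizumab_per_mg: float = 44.00
    nivolumab_per_mg: float = 19.56
    platinum_per_mg: float = 0.0


@dataclass
class Dosing:
    """Dosing assumptions; BSA-based doses use the cohort-average 1.75 m2."""

    bsa_m2: float = 1.75
    weight_kg: float = 75.0
    crizotinib_tablets_per_day: float = 2.0  # 250 mg twice daily
    pemetrexed_mg_per_m2: float = 500.0  # q21d
    docetaxel_mg_per_m2: float = 75.0  # q21d
    pembrolizumab_mg_flat: float = 200.0  # q21d
    nivolumab_mg_per_kg: float = 3.0  # q14d
    carboplatin_target_auc: float = 5.0
    creatinine_clearance_ml_min: float = 60.0
    induction_cycles: int = 6  # platinum-doublet, 21-day cycles
    chemo_cycle_days: float = 21.0
    nivolumab_cycle_days: float = 14.0


@dataclass
class Utilities:
    pfs_crizotinib: float = 0.806
    pfs_chemotherapy: float = 0.776
    later_line: float = 0.660
    palliation: float = 0.473

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"utilities.{f.name} must be in [0, 1], got {v}")


@dataclass
class EconParams:
    admin_monitor_monthly_crizotinib: float = 1176.83
    admin_monitor_monthly_chemotherapy: float = 1566.81
    ae_cost_crizotinib: float = 67.06
    ae_cost_chemotherapy: float = 318.68
    ae_disutility_crizotinib: float = -0.0194
    ae_disutility_chemotherapy: float = -0.0546
    palliation_monthly: float = 3124.07
    maintenance_fraction: float = 0.50
    maintenance_hr: float = 0.62
    docetaxel_vs_checkpoint_split: float = 0.50  # share receiving docetaxel
    palliation_active_fraction_crizotinib: float = 0.50
    palliation_active_fraction_chemotherapy: float = 0.0
    second_line_median_crizotinib_arm: float = 7.79  # months, platinum doublet
    second_line_median_chemotherapy_arm: float = 3.26  # checkpoint/docetaxel
    third_line_median: float = 3.26
    palliation_os_median: float = 4.60
    discount_rate_annual: float = 0.015
    horizon_years: float = 10.0
    cycle_days: float = 7.0

    def validate(self) -> None:
        for f in (
            "maintenance_fraction",
            "docetaxel_vs_checkpoint_split",
            "palliation_active_fraction_crizotinib",
            "palliation_active_fraction_chemotherapy",
        ):
            v = getattr(self, f)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"econ.{f} must be in [0, 1], got {v}")
        if self.discount_rate_annual < 0:
            raise ValidationError("discount rate must be >= 0")
        if self.cycle_days <= 0 or self.horizon_years * 365.25 < self.cycle_days:
            raise ValidationError("horizon must cover at least one cycle")
        for f in ("second_line_median_crizotinib_arm", "second_line_median_chemotherapy_arm",
                  "third_line_median", "palliation_os_median"):
            if getattr(self, f) <= 0:
                raise ValidationError(f"econ.{f} must be positive")


@dataclass
class ModelConfig:
    """Full model input set; the unit consumed by the Markov/PSA/scenario layers."""

    testing: TestingParams = field(default_factory=TestingParams)
    splits: TransitionSplits = field(default_factory=TransitionSplits)
    drugs: DrugPrices = field(default_factory=DrugPrices)
    dosing: Dosing = field(default_factory=Dosing)
    utilities: Utilities = field(default_factory=Utilities)
    econ: EconParams = field(default_factory=EconParams)
    # structural switch used by the "no PFS difference" scenario: the
    # chemotherapy arm is evaluated on the crizotinib PFS curve
    chemo_uses_crizotinib_pfs: bool = False
    seed: int = 12345

    def validate(self) -> None:
        self.testing.validate()
        self.splits.validate()
        self.utilities.validate()
        self.econ.validate()

    def copy(self) -> "ModelConfig":
        return copy.deepcopy(self)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        cfg = cls()
        for f in dataclasses.fields(cls):
            if f.name not in d:
                continue
            v = d[f.name]
            cur = getattr(cfg, f.name)
            if dataclasses.is_dataclass(cur) and isinstance(v, dict):
                unknown = set(v) - {g.name for g in dataclasses.fields(cur)}
                if unknown:
                    raise ValidationError(f"unknown keys in {f.name}: {sorted(unknown)}")
                setattr(cfg, f.name, type(cur)(**v))
            else:
                setattr(cfg, f.name, v)
        cfg.validate()
        return cfg


def _walk(cfg, path: str):
    parts = path.split(".")
    obj = cfg
    for p in parts[:-1]:
        if not hasattr(obj, p):
            raise ValidationError(f"unknown config path {path!r} (no field {p!r})")
        obj = getattr(obj, p)
    if not hasattr(obj, parts[-1]):
        valid = [f.name for f in dataclasses.fields(obj)] if dataclasses.is_dataclass(obj) else []
        raise ValidationError(f"unknown config path {path!r}; valid leaves here: {valid}")
    return obj, parts[-1]


def get_path(cfg: ModelConfig, path: str):
    obj, leaf = _walk(cfg, path)
    return getattr(obj, leaf)


def set_path(cfg: ModelConfig, path: str, value) -> None:
    obj, leaf = _walk(cfg, path)
    setattr(obj, leaf, value)


def load_config(path) -> ModelConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    return ModelConfig.from_dict(d)


def save_config(cfg: ModelConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
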