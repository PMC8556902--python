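"""End-to-end orchestration: generate -> reconstruct -> fit -> model -> PSA/DSA/scenarios.

Each stage reads what the previous one wrote under the run's output
directory, so stages can be re-run individually from the CLI.  Every stage
logs its inputs and seeds; randomness flows exclusively from the run seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import ModelConfig, load_config, save_config
from .errors import Ros1ceError, ValidationError
from .km_ipd import (
    IPDSet,
    clean_digitized_curve,
    pool_ipd,
    read_curve_csv,
    read_risk_csv,
    reconstruct_ipd,
    replicate_small_study,
    write_ipd_csv,
    read_ipd_csv,
)
from .markov import ARM_CHEMOTHERAPY, ARM_CRIZOTINIB
from .psa import (
    PFSInputs,
    default_dsa_ranges,
    evaluate_incremental,
    one_way_dsa,
    run_all_scenarios,
    run_psa,
)
from .survfit import (
    SurvivalFit,
    cox_hr_and_ph_test,
    fit_all_families,
    fit_parametric,
    select_distribution,
)
from .synth import generate_benchmark_suite

log = logging.getLogger("ros1ce")

STAGES = ("generate", "reconstruct", "fit", "model", "psa", "dsa", "scenarios")

#: distinct exit codes per failing stage class (CLI contract)
STAGE_EXIT_CODES = {s: 10 + i for i, s in enumerate(STAGES)}


@dataclass
class RunConfig:
    """What to run and where; file inputs default to the generate stage's outputs."""

    outdir: Path
    seed: int = 12345
    stages: tuple[str, ...] = STAGES
    curves_csv: Path | None = None
    risk_csv: Path | None = None
    model_config: Path | None = None
    n_sims: int = 5000
    small_study_max_n: int = 25
    make_plots: bool = True

    def __post_init__(self):
        self.outdir = Path(self.outdir)
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValidationError(f"unknown stages {sorted(unknown)}; valid: {STAGES}")


@dataclass
class PipelineResult:
    summary: dict
    outputs: dict[str, str] = field(default_factory=dict)


def _setup_logging(outdir: Path, level: str = "INFO") -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    handlers = [logging.StreamHandler()]
    handlers.append(logging.FileHandler(outdir / "pipeline.log"))
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )


def stage_generate(rc: RunConfig) -> dict:
    data_dir = rc.outdir / "data"
    suite = generate_benchmark_suite(seed=rc.seed, outdir=data_dir,
                                     small_study_max_n=rc.small_study_max_n)
    totals = suite.arm_totals()
    log.info("generated benchmark suite: arm totals %s", totals)
    return {"files": suite.files, "arm_totals": totals}


def stage_reconstruct(rc: RunConfig) -> dict:
    curves_csv = rc.curves_csv or rc.outdir / "data" / "curves.csv"
    risk_csv = rc.risk_csv or rc.outdir / "data" / "risk_tables.csv"
    curves = read_curve_csv(curves_csv)
    if Path(risk_csv).exists():
        curves = read_risk_csv(risk_csv, curves)
    studies: list[IPDSet] = []
    for raw in curves:
        curve = clean_digitized_curve(raw)
        n0 = curve.n0
        if n0 is not None and n0 <= rc.small_study_max_n:
            records = replicate_small_study(curve)
            method = "exact_replication"
        else:
            records = reconstruct_ipd(curve)
            method = "guyot"
        studies.append(IPDSet(records, {curve.study_id: method}))
        log.info("reconstructed %s (%s): %d records", curve.study_id, method, len(records))
    pooled = pool_ipd(studies)
    out = rc.outdir / "ipd_reconstructed.csv"
    write_ipd_csv(pooled, out)
    counts = pooled.arm_counts()
    log.info("pooled IPD: %s", counts)
    return {"ipd_csv": str(out), "arm_counts": counts, "provenance": pooled.provenance}


def _load_model_config(rc: RunConfig) -> ModelConfig:
    path = rc.model_config or rc.outdir / "data" / "model_config.yaml"
    if Path(path).exists():
        return load_config(path)
    return ModelConfig(seed=rc.seed)


def stage_fit(rc: RunConfig) -> dict:
    ipd = read_ipd_csv(rc.outdir / "ipd_reconstructed.csv")
    fits = fit_all_families(ipd, shared_treatment=True, seed=rc.seed)
    best, report = select_distribution(fits)
    hr = cox_hr_and_ph_test(ipd)
    report_path = rc.outdir / "fit_report.json"
    aic_path = rc.outdir / "aic_table.csv"
    report.to_csv(aic_path, index=False)
    payload = {
        "selected_family": best.family_name,
        "fits": {f.family_name: f.to_report() for f in fits},
        "cox": {
            "hr": hr.value, "ci": [hr.ci_lower, hr.ci_upper],
            "p_ph_test": hr.p_ph_test,
        },
        "medians": {
            "crizotinib": best.median(ARM_CRIZOTINIB),
            "chemotherapy": best.median(ARM_CHEMOTHERAPY),
        },
    }
    report_path.write_text(json.dumps(payload, indent=2))
    # fitted curves on a monthly grid, for plotting / external checks
    grid = np.linspace(0.0, 120.0, 481)
    pd.DataFrame(
        {
            "time_months": grid,
            "S_crizotinib": best.sf(grid, ARM_CRIZOTINIB),
            "S_chemotherapy": best.sf(grid, ARM_CHEMOTHERAPY),
        }
    ).to_csv(rc.outdir / "fitted_curves.csv", index=False)
    # per-arm individual fits of the selected family (scenario input)
    for arm in (ARM_CRIZOTINIB, ARM_CHEMOTHERAPY):
        sub = ipd.subset(arm)
        fit_arm = fit_parametric(sub, best.family_name, shared_treatment=False, seed=rc.seed)
        payload[f"individual_{arm}"] = fit_arm.to_report()
    report_path.write_text(json.dumps(payload, indent=2))
    log.info(
        "selected %s; Cox HR %.3f [%.3f, %.3f], PH p=%.3f",
        best.family_name, hr.value, hr.ci_lower, hr.ci_upper, hr.p_ph_test,
    )
    return payload


def _rebuild_fit(rep: dict, family: str, shared: bool) -> SurvivalFit:
    from .distributions import get_family

    fam = get_family(family)
    params = rep["params"]
    theta = fam.from_natural([params[p] for p in fam.param_names])
    if shared:
        key = "hazard_ratio" if fam.effect_type == "proportional_hazards" else "time_ratio"
        theta = np.append(theta, np.log(params[key]))
    return SurvivalFit(
        family_name=family,
        theta=np.asarray(theta, dtype=float),
        covariance=np.asarray(rep["covariance"], dtype=float),
        loglik=rep["loglik"],
        n=rep["n"],
        n_events=rep["n_events"],
        shared_treatment=shared,
        flags=list(rep.get("flags", [])),
    )


def _load_pfs(rc: RunConfig) -> tuple[PFSInputs, dict[str, PFSInputs]]:
    payload = json.loads((rc.outdir / "fit_report.json").read_text())
    family = payload["selected_family"]
    best = _rebuild_fit(payload["fits"][family], family, shared=True)
    pfs = PFSInputs.from_fit(best)
    alt = {}
    if f"individual_{ARM_CRIZOTINIB}" in payload:
        fc = _rebuild_fit(payload[f"individual_{ARM_CRIZOTINIB}"], family, shared=False)
        fh = _rebuild_fit(payload[f"individual_{ARM_CHEMOTHERAPY}"], family, shared=False)
        alt["individual_fits"] = PFSInputs.from_fits(fc, fh)
    return pfs, alt


def stage_model(rc: RunConfig) -> dict:
    cfg = _load_model_config(rc)
    pfs, _ = _load_pfs(rc)
    res_c, res_h, icer = evaluate_incremental(cfg, pfs)
    table = pd.concat(
        [
            res_c.to_frame().assign(arm=ARM_CRIZOTINIB),
            res_h.to_frame().assign(arm=ARM_CHEMOTHERAPY),
        ]
    )
    table.to_csv(rc.outdir / "base_case_table.csv", index=False)
    out = {
        "crizotinib": {
            "cost": res_c.total_cost, "ly": res_c.total_ly, "qaly": res_c.total_qaly,
        },
        "chemotherapy": {
            "cost": res_h.total_cost, "ly": res_h.total_ly, "qaly": res_h.total_qaly,
        },
        "incremental": icer.to_dict(),
    }
    (rc.outdir / "base_case.json").write_text(json.dumps(out, indent=2))
    log.info("base case ICER: %.0f per QALY", icer.icer_qaly)
    return out


def stage_psa(rc: RunConfig) -> dict:
    cfg = _load_model_config(rc)
    pfs, _ = _load_pfs(rc)
    res = run_psa(cfg, pfs, n_sims=rc.n_sims, seed=rc.seed)
    res.draws.to_csv(rc.outdir / "psa_draws.csv", index=False)
    res.ceac.to_csv(rc.outdir / "psa_ceac.csv", index=False)
    if res.sampled is not None:
        res.sampled.to_csv(rc.outdir / "psa_sampled_params.csv", index=False)
    if rc.make_plots:
        from .plots import plot_ce_plane, plot_ceac

        plot_ce_plane(res, rc.outdir / "ce_plane.png")
        plot_ceac(res, rc.outdir / "ceac.png")
    out = {
        "n_sims": res.n_sims,
        "n_failures": res.n_failures,
        "means": res.means,
        "icer_of_means": res.icer_qaly_of_means(),
        "p_ce_100k": res.prob_cost_effective(100_000.0),
        "p_ce_150k": res.prob_cost_effective(150_000.0),
    }
    (rc.outdir / "psa_summary.json").write_text(json.dumps(out, indent=2))
    return out


def stage_dsa(rc: RunConfig) -> dict:
    cfg = _load_model_config(rc)
    pfs, _ = _load_pfs(rc)
    tornado = one_way_dsa(cfg, pfs, default_dsa_ranges(cfg))
    tornado.to_csv(rc.outdir / "tornado.csv", index=False)
    if rc.make_plots:
        from .plots import plot_tornado

        plot_tornado(tornado, rc.outdir / "tornado.png")
    return {"top_parameters": tornado["parameter"].head(5).tolist()}


def stage_scenarios(rc: RunConfig) -> dict:
    cfg = _load_model_config(rc)
    pfs, alt = _load_pfs(rc)
    table = run_all_scenarios(cfg, pfs, alt_pfs=alt)
    table.to_csv(rc.outdir / "scenarios.csv", index=False)
    return {"n_scenarios": len(table)}


_STAGE_FN = {
    "generate": stage_generate,
    "reconstruct": stage_reconstruct,
    "fit": stage_fit,
    "model": stage_model,
    "psa": stage_psa,
    "dsa": stage_dsa,
    "scenarios": stage_scenarios,
}


def run_pipeline(rc: RunConfig, log_level: str = "INFO") -> PipelineResult:
    """Run the enabled stages in order and write a consolidated summary."""
    _setup_logging(rc.outdir, log_level)
    log.info("ros1ce %s, seed %d, stages %s", __version__, rc.seed, list(rc.stages))
    summary: dict = {"version": __version__, "seed": rc.seed}
    for stage in STAGES:
        if stage not in rc.stages:
            continue
        log.info("=== stage %s ===", stage)
        try:
            summary[stage] = _STAGE_FN[stage](rc)
        except Exception as exc:
            log.error("stage %s failed: %s", stage, exc)
            (rc.outdir / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
            raise StageFailure(stage, exc) from exc
    (rc.outdir / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    return PipelineResult(summary=summary)


class StageFailure(Ros1ceError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.exit_code = STAGE_EXIT_CODES.get(stage, 1)
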