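"""Testing decision tree, costing primitives, cohort trace, accrual and ICER."""

import math

import numpy as np
import pytest

import ros1ce as r
from ros1ce import config as cfgmod
from ros1ce.errors import ValidationError
from ros1ce.markov import (
    DrugRegimen,
    regimen_cycle_cost,
    weekly_costs,
)
from ros1ce.psa import PFSInputs, evaluate_incremental


class TestTestingTree:
    def test_published_inputs_give_expected_costs(self, base_config):
        p = base_config.testing
        p_pos = 0.0164 * 1.0 + (1 - 0.0164) * (1 - 0.83)
        per_tested = 42.36 + p_pos * 410.93
        assert per_tested == pytest.approx(117.81, abs=0.01)
        assert r.testing_cost_per_case(p) == pytest.approx(per_tested / 0.0164, rel=1e-12)
        assert r.testing_cost_per_case(p) == pytest.approx(7183.8, abs=1.0)

    def test_perfect_ihc_specificity(self):
        p = cfgmod.TestingParams(ihc_spec=1.0)
        per_tested = 42.36 + 0.0164 * 410.93
        assert per_tested == pytest.approx(49.10, abs=0.01)
        assert r.testing_cost_per_case(p) == pytest.approx(per_tested / 0.0164, rel=1e-12)

    def test_certain_prevalence_with_perfect_tests(self):
        p = cfgmod.TestingParams(prevalence=1.0, ihc_spec=1.0)
        assert r.testing_cost_per_case(p) == pytest.approx(42.36 + 410.93)

    def test_zero_prevalence_rejected(self):
        with pytest.raises(ValidationError):
            r.testing_cost_per_case(cfgmod.TestingParams(prevalence=0.0))


class TestCostPrimitives:
    @pytest.mark.parametrize("auc, crcl, dose", [(5, 60, 425.0), (6, 100, 750.0)])
    def test_calvert_formula(self, auc, crcl, dose):
        assert r.calvert_carboplatin_dose(auc, crcl) == dose

    def test_calvert_rejects_non_positive(self):
        with pytest.raises(ValidationError):
            r.calvert_carboplatin_dose(5, 0)

    def test_crizotinib_weekly_cost(self, base_config):
        reg = DrugRegimen("crizotinib", "per_tablet_fixed", 2.0, 130.0)
        assert regimen_cycle_cost(reg, base_config) == pytest.approx(1820.0)

    def test_pemetrexed_amortized_weekly(self, base_config):
        reg = DrugRegimen("pemetrexed", "per_mg_per_m2", 500.0, 0.21, 21.0)
        # 875 mg x $0.21 = $183.75 per q21d administration -> $61.25/week
        assert regimen_cycle_cost(reg, base_config) == pytest.approx(61.25)

    def test_pembrolizumab_flat_dose(self, base_config):
        reg = DrugRegimen("pembrolizumab", "per_mg_flat", 200.0, 44.0, 21.0)
        per_admin = 200.0 * 44.0
        assert per_admin == 8800.0
        assert regimen_cycle_cost(reg, base_config) == pytest.approx(per_admin * 7 / 21)

    def test_unknown_basis_rejected(self, base_config):
        reg = DrugRegimen("x", "per_vial", 1.0, 1.0)
        with pytest.raises(ValidationError):
            regimen_cycle_cost(reg, base_config)

    @pytest.mark.parametrize(
        "t, rate, expected",
        [(0.0, 0.015, 1.0), (2.0, 0.015, 1.015**-2), (10.0, 0.0, 1.0)],
    )
    def test_discount_factor(self, t, rate, expected):
        assert float(r.discount_factor(t, rate)) == pytest.approx(expected)

    def test_discount_rejects_negative_time(self):
        with pytest.raises(ValidationError):
            r.discount_factor(-1.0, 0.015)


class TestCohortTrace:
    def test_degenerate_model_stays_in_pfs(self, base_config):
        trace = r.run_cohort_trace("crizotinib", lambda t: 1.0, base_config)
        assert np.all(trace.state_occupancy("PFS") == 1.0)
        assert np.all(trace.state_occupancy("DEATH") == 0.0)

    def test_conservation_and_death_monotone(self, base_config, pfs_inputs):
        for arm, sf in (
            ("crizotinib", pfs_inputs.crizotinib_sf),
            ("chemotherapy", pfs_inputs.chemotherapy_sf),
        ):
            trace = r.run_cohort_trace(arm, sf, base_config)
            trace.validate()  # rows sum to 1 within 1e-9, DEATH monotone
            assert trace.n_cycles == 522

    def test_maintenance_prolongs_chemo_pfs(self, base_config, pfs_inputs):
        occ = {}
        for frac in (0.0, 1.0):
            cfg = base_config.copy()
            cfg.econ.maintenance_fraction = frac
            trace = r.run_cohort_trace(
                "chemotherapy", pfs_inputs.chemotherapy_sf, cfg
            )
            occ[frac] = trace.state_occupancy("PFS")
        # HR 0.62 < 1: full maintenance keeps at least as many progression-free
        after_induction = slice(19, None)
        assert np.all(occ[1.0][after_induction] >= occ[0.0][after_induction] - 1e-12)
        assert occ[1.0][40] > occ[0.0][40]

    def test_invalid_splits_rejected(self, base_config):
        cfg = base_config.copy()
        cfg.splits.pfs_to_2l = 0.9  # group now sums to 1.2
        with pytest.raises(ValidationError):
            r.run_cohort_trace("crizotinib", lambda t: 1.0, cfg)


class TestAccrual:
    def test_alive_state_conserves_time(self, base_config):
        cfg = base_config.copy()
        cfg.econ.discount_rate_annual = 0.0
        cfg.econ.horizon_years = 1.0
        cfg.utilities.pfs_crizotinib = 1.0
        cfg.econ.ae_disutility_crizotinib = 0.0
        trace, res = r.evaluate_strategy("crizotinib", lambda t: 1.0, cfg)
        cycle_years = 7.0 / 365.25
        assert res.total_ly == pytest.approx(1.0, abs=cycle_years)
        assert res.total_qaly == pytest.approx(res.total_ly)

    def test_qaly_linear_in_utility(self, base_config, pfs_inputs):
        halves = []
        for u in (1.0, 0.5):
            cfg = base_config.copy()
            cfg.utilities.pfs_crizotinib = u
            cfg.econ.ae_disutility_crizotinib = 0.0
            _, res = r.evaluate_strategy(
                "crizotinib", pfs_inputs.crizotinib_sf, cfg
            )
            halves.append(res.qaly["pfs_first_line"])
        assert halves[1] == pytest.approx(halves[0] / 2.0, rel=1e-12)

    def test_qalys_equal_lys_with_unit_utilities(self, base_config, pfs_inputs):
        cfg = base_config.copy()
        for f in ("pfs_crizotinib", "pfs_chemotherapy", "later_line", "palliation"):
            setattr(cfg.utilities, f, 1.0)
        cfg.econ.ae_disutility_crizotinib = 0.0
        cfg.econ.ae_disutility_chemotherapy = 0.0
        for arm, sf in (
            ("crizotinib", pfs_inputs.crizotinib_sf),
            ("chemotherapy", pfs_inputs.chemotherapy_sf),
        ):
            _, res = r.evaluate_strategy(arm, sf, cfg)
            assert res.total_qaly == pytest.approx(res.total_ly, rel=1e-12)

    def test_discounting_strictly_shrinks_totals(self, base_config, pfs_inputs):
        totals = []
        for rate in (0.0, 0.015, 0.05):
            cfg = base_config.copy()
            cfg.econ.discount_rate_annual = rate
            _, res = r.evaluate_strategy("crizotinib", pfs_inputs.crizotinib_sf, cfg)
            totals.append((res.total_cost, res.total_ly))
        costs, lys = zip(*totals)
        assert costs[0] > costs[1] > costs[2]
        assert lys[0] > lys[1] > lys[2]

    def test_first_line_cost_close_to_published_value(self, base_config):
        """Crizotinib-arm first-line accrual under the published input set and
        a log-logistic PFS with the published 16.2-month median."""
        from ros1ce.distributions import get_family
        from ros1ce.synth import theta_from_median

        fam = get_family("log_logistic")
        th = theta_from_median("log_logistic", 16.2, 1.5)
        _, res = r.evaluate_strategy(
            "crizotinib", lambda t: float(fam.sf(t, th)), base_config
        )
        assert res.cost["pfs_first_line"] == pytest.approx(246_127, rel=0.15)
        # implied monthly on-treatment cost is drug + administration/monitoring
        w = weekly_costs(base_config)
        monthly = (w["crizotinib"] + w["admin_crizotinib"]) * 30.4375 / 7.0
        assert monthly == pytest.approx(7913.75 + 1176.83, rel=1e-9)

    def test_microsim_oracle_three_state(self, base_config):
        """Cohort expected state times match a 100k-subject individual-level
        simulation of the same discrete-cycle process within 3 MC SEs."""
        cfg = base_config.copy()
        cfg.econ.discount_rate_annual = 0.0
        cfg.splits.pfs_to_2l = 0.0
        cfg.splits.pfs_to_palliation = 0.5
        cfg.splits.pfs_to_death = 0.5
        pfs_median = 8.0
        rate = math.log(2.0) / pfs_median
        sf = lambda t: math.exp(-rate * t)
        trace = r.run_cohort_trace("crizotinib", sf, cfg)
        dy = 7.0 / 365.25
        t_pfs_model = float(np.sum(trace.state_occupancy("PFS")[:-1])) * dy
        t_pall_model = float(np.sum(trace.state_occupancy("PALLIATION")[:-1])) * dy

        dm = 7.0 / 30.4375
        tp_pfs = 1.0 - math.exp(-rate * dm)
        tp_pall = 1.0 - math.exp(-math.log(2.0) / cfg.econ.palliation_os_median * dm)
        n = 100_000
        rng = np.random.default_rng(77)
        n_cycles = trace.n_cycles
        c_pfs = np.minimum(rng.geometric(tp_pfs, n), n_cycles)
        to_pall = rng.uniform(size=n) < 0.5
        room = n_cycles - c_pfs
        c_pall = np.where(
            to_pall, np.minimum(rng.geometric(tp_pall, n), room), 0
        )
        t_pfs_sim = c_pfs.mean() * dy
        t_pall_sim = c_pall.mean() * dy
        se_pfs = c_pfs.std(ddof=1) / math.sqrt(n) * dy
        se_pall = c_pall.std(ddof=1) / math.sqrt(n) * dy
        assert abs(t_pfs_model - t_pfs_sim) < 3 * se_pfs
        assert abs(t_pall_model - t_pall_sim) < 3 * se_pall
        # single-state closed form: mean time to exit = median / ln 2
        assert t_pfs_model * 12 == pytest.approx(pfs_median / math.log(2.0), rel=0.02)


class TestICER:
    @staticmethod
    def econ(cost, ly, qaly, arm="crizotinib"):
        return r.EconResult(arm=arm, cost={"total": cost}, ly={"total": ly},
                            qaly={"total": qaly})

    def test_published_table_ratio(self):
        a = self.econ(288_945, 3.349, 2.541)
        b = self.econ(78_071, 2.465, 1.769, "chemotherapy")
        icer = r.compute_icer(a, b)
        assert icer.delta_cost == pytest.approx(210_874)
        assert icer.delta_qaly == pytest.approx(0.772)
        assert icer.icer_qaly == pytest.approx(210_874 / 0.772, rel=1e-12)
        assert icer.icer_qaly == pytest.approx(273_153, abs=1.0)

    def test_dominance_flags(self):
        base = self.econ(100.0, 1.0, 1.0, "chemotherapy")
        assert r.compute_icer(self.econ(99.0, 1.05, 1.1), base).flag_qaly == "dominant"
        assert r.compute_icer(self.econ(200.0, 0.95, 0.9), base).flag_qaly == "dominated"
        undef = r.compute_icer(self.econ(200.0, 1.0, 1.0), base)
        assert undef.flag_qaly == "undefined" and math.isnan(undef.icer_qaly)

    def test_antisymmetry_of_increments(self):
        a = self.econ(250.0, 2.0, 1.5)
        b = self.econ(100.0, 1.0, 1.0, "chemotherapy")
        ab, ba = r.compute_icer(a, b), r.compute_icer(b, a)
        assert ab.delta_cost == -ba.delta_cost
        assert ab.delta_qaly == -ba.delta_qaly

    def test_currency_rescaling_leaves_effects_alone(self):
        a = self.econ(250.0, 2.0, 1.5)
        b = self.econ(100.0, 1.0, 1.0, "chemotherapy")
        a2 = self.econ(2500.0, 2.0, 1.5)
        b2 = self.econ(1000.0, 1.0, 1.0, "chemotherapy")
        assert r.compute_icer(a2, b2).icer_qaly == pytest.approx(
            10.0 * r.compute_icer(a, b).icer_qaly
        )


class TestDeterministicBaseCase:
    def test_two_arm_evaluation_shape(self, base_config, pfs_inputs):
        res_c, res_h, icer = evaluate_incremental(base_config, pfs_inputs)
        for res in (res_c, res_h):
            assert set(res.ly) == {
                "pfs_first_line", "second_line", "third_line", "palliation"
            }
            assert res.total_ly > 0 and res.total_cost > 0
        assert "testing" in res_c.cost and "testing" not in res_h.cost
        assert res_c.cost["testing"] == pytest.approx(7183.8, abs=1.0)
        # crizotinib gains survival and QALYs at higher cost on the benchmark
        assert icer.delta_qaly > 0 and icer.delta_cost > 0
        assert icer.icer_qaly > 100_000
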