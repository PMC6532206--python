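import warnings

import pytest

from lungcea import (
    SCENARIOS,
    ParameterError,
    ScenarioSpec,
    apply_scenario,
    exploratory_extra_transplants,
    exploratory_removed_state,
    run_deterministic,
    run_scenario,
)
from lungcea.parameters import get_value, iter_paths
from lungcea.scenarios import get_scenario


def diff_paths(a, b):
    return [p for p in iter_paths(a) if get_value(a, p) != get_value(b, p)]


class TestRegistry:
    def test_nine_scenarios_registered(self):
        assert sorted(SCENARIOS, key=int) == [str(i) for i in range(1, 10)]

    def test_unknown_id_rejected(self, base):
        with pytest.raises(ParameterError):
            get_scenario("12")


class TestApplyScenario:
    def test_empty_override_leaves_base_unchanged(self, base):
        p_std, p_evlp = apply_scenario(base, ScenarioSpec("x", "noop"))
        assert not diff_paths(p_std, base)
        assert not diff_paths(p_evlp, base)

    def test_scenario4_changes_only_evlp_transplant_cost(self, base):
        p_std, p_evlp = apply_scenario(base, SCENARIOS["4"])
        assert p_evlp.costs.c_tx["evlp"] == 89455
        assert diff_paths(p_evlp, base) == ["costs.c_tx.evlp"]
        assert diff_paths(p_std, base) == ["costs.c_tx.evlp"]

    def test_scenario9_changes_only_waiting_cost(self, base):
        _, p_evlp = apply_scenario(base, SCENARIOS["9"])
        assert p_evlp.costs.c_wait_per_year == 50830
        assert diff_paths(p_evlp, base) == ["costs.c_wait_per_year"]

    def test_scenario6_diverges_arms(self, base):
        p_std, p_evlp = apply_scenario(base, SCENARIOS["6"])
        # standard arm uses pre-trial transitions; 'EVLP' arm keeps within-trial
        assert p_std.transitions["year1"].p_std_tx == 0.40
        assert p_evlp.transitions["year1"].p_std_tx == 0.510
        assert not SCENARIOS["6"].evlp_arm_includes_evlp

    def test_scenario7_survival_per_transplant_type(self, base):
        p_std, p_evlp = apply_scenario(base, SCENARIOS["7"])
        assert p_std.survival["standard"].s1 == 0.80
        assert p_evlp.survival["standard"].s1 == 0.80
        assert p_evlp.survival["evlp"].s1 == 0.67
        # later survival points stay at (clamped) base values
        assert p_evlp.survival["evlp"].s3 == pytest.approx(0.67)
        assert p_evlp.survival["standard"].s3 == 0.72


class TestScenarioResults:
    def test_scenario2_raises_total_transplants_to_published_count(self, base):
        _, p_evlp = apply_scenario(base, SCENARIOS["2"])
        res = run_deterministic(p_evlp, "evlp")
        base_res = run_deterministic(base, "evlp")
        total = res.n_std_tx + res.n_evlp_tx
        assert total > base_res.n_std_tx + base_res.n_evlp_tx
        assert round(total) == 762
        assert round(res.n_std_tx) == 635
        assert round(res.n_evlp_tx) == 127

    def test_scenario4_cheapens_evlp_arm(self, base):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            row4 = run_scenario(base, SCENARIOS["4"], n_sims=200, seed=11)
            row0 = run_scenario(base, None, n_sims=200, seed=11)
        assert row4["cost_evlp"] < row0["cost_evlp"]
        assert row4["cost_standard"] == pytest.approx(row0["cost_standard"])

    def test_reproducible_with_same_seed(self, base):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            a = run_scenario(base, SCENARIOS["9"], n_sims=50, seed=21)
            b = run_scenario(base, SCENARIOS["9"], n_sims=50, seed=21)
        assert a == b


class TestExploratoryRemovedState:
    def test_zero_months_identical_to_base(self, base):
        p = base.copy()
        from lungcea.parameters import RemovedStateAccrual

        p.removed_accrual = RemovedStateAccrual(months=0.0, monthly_cost=1173.0, utility=0.563)
        res = run_deterministic(p, "standard")
        ref = run_deterministic(base, "standard")
        assert res.mean_cost == pytest.approx(ref.mean_cost)
        assert res.mean_qaly == pytest.approx(ref.mean_qaly)

    def test_six_month_undiscounted_cost_per_removed_patient(self):
        # 6 months at 1644/month
        assert 6 * 1644.0 == 9864.0

    def test_removed_accrual_adds_costs_in_both_arms(self, base):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            table = exploratory_removed_state(
                base, months=(6.0,), monthly_costs=(1644.0,), utilities=(0.563,),
                n_sims=100, seed=5,
            )
        row = table.iloc[0]
        assert row["replicates_published"]
        # the standard arm has more removals, so its cost rises more
        assert row["cost_standard"] > 0
        assert row["cost_evlp"] > 0


class TestExploratoryExtraTransplants:
    def test_restoring_activity_yields_finite_positive_results(self, base):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out = exploratory_extra_transplants(base, n_sims=200, seed=9)
        assert out["extra_std_transplants"] == pytest.approx(46.0, abs=0.5)
        assert out["net_cost_per_transplant"] == pytest.approx(56200, rel=0.05)
        assert out["qaly_gain_per_transplant"] == pytest.approx(4.09, rel=0.05)
        assert 0 < out["icer_between_services"] < 50000

    def test_zero_uplift_flagged(self, base):
        p = base.copy()
        p.evlp_uplift = 0.0
        out = exploratory_extra_transplants(p, n_sims=10, seed=1)
        assert out["flag"] is not None
        assert out["icer_between_services"] is None
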