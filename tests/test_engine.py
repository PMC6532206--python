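import numpy as np
import pytest

from lungcea import (
    ParameterError,
    TransitionBand,
    TruncationError,
    discount_factor,
    run_deterministic,
    waiting_list_step,
)

from .oracles import geometric_tail_std_transplants


class TestDiscountFactor:
    def test_first_year_undiscounted(self):
        assert discount_factor(1, 0.035) == 1.0

    def test_zero_rate(self):
        assert all(discount_factor(k, 0.0) == 1.0 for k in range(1, 50))

    def test_second_year(self):
        assert discount_factor(2, 0.035) == pytest.approx(0.96618, abs=1e-5)

    def test_invalid_year(self):
        with pytest.raises(ParameterError):
            discount_factor(0, 0.035)


class TestWaitingListStep:
    def test_base_year1_band_no_uplift(self, base):
        f = waiting_list_step(1000.0, base.transitions["year1"], 0.0)
        assert (f.removed, f.death, f.std_tx) == pytest.approx((20.0, 150.0, 510.0))
        assert f.evlp_tx == 0.0
        assert f.remain == pytest.approx(320.0)

    def test_base_year1_band_with_uplift(self, base):
        f = waiting_list_step(1000.0, base.transitions["year1"], 0.10)
        assert f.evlp_tx == pytest.approx(51.0)
        assert f.remain == pytest.approx(269.0)

    def test_zero_occupancy(self, base):
        f = waiting_list_step(0.0, base.transitions["year1"], 0.5)
        assert all(v == 0.0 for v in f)

    def test_flows_conserve_occupancy(self, base):
        for band in base.transitions.values():
            f = waiting_list_step(137.5, band, 0.10)
            assert sum(f) == pytest.approx(137.5, rel=1e-12)

    def test_overflow_renormalized_with_warning(self):
        band = TransitionBand(p_removed=0.2, p_death=0.3, p_std_tx=0.45)
        with pytest.warns(RuntimeWarning):
            f = waiting_list_step(100.0, band, 0.5)  # exits sum to 1.175
        assert f.remain == 0.0
        assert sum(f) == pytest.approx(100.0)
        assert f.std_tx / f.evlp_tx == pytest.approx(2.0)  # proportions kept


class TestDeterministicRun:
    def test_transplant_counts_match_published_table(self, base):
        std = run_deterministic(base, "standard")
        evlp = run_deterministic(base, "evlp")
        assert round(std.n_std_tx) == 721
        assert std.n_evlp_tx == 0.0
        assert round(evlp.n_std_tx) == 675
        # exact arithmetic yields 67.50 EVLP transplants (printed as 67)
        assert abs(evlp.n_evlp_tx - 67.5) < 0.05

    def test_engine_agrees_with_geometric_tail_oracle(self, base):
        std = run_deterministic(base, "standard")
        closed_form = geometric_tail_std_transplants(base)
        assert closed_form == pytest.approx(0.721, abs=5e-4)
        assert std.n_std_tx / base.cohort_size == pytest.approx(closed_form, abs=1e-9)

    def test_zero_uplift_evlp_arm_equals_standard_arm(self, base):
        p = base.copy()
        p.evlp_uplift = 0.0
        std = run_deterministic(p, "standard")
        evlp = run_deterministic(p, "evlp")
        assert evlp.mean_cost == pytest.approx(std.mean_cost, abs=1e-9)
        assert evlp.mean_qaly == pytest.approx(std.mean_qaly, abs=1e-9)
        assert evlp.mean_ly == pytest.approx(std.mean_ly, abs=1e-9)
        assert evlp.n_evlp_tx == 0.0

    @pytest.mark.parametrize("arm", ["standard", "evlp"])
    def test_cohort_conservation_every_cycle(self, base, arm):
        """Waiting occupancy plus cumulative exits equals the cohort size."""
        res = run_deterministic(base, arm)
        tr = res.trace
        cum_exits = np.cumsum(tr.to_removed + tr.to_death + tr.to_std_tx + tr.to_evlp_tx)
        active = tr.waiting_start > 0
        total = tr.waiting_end + cum_exits
        assert np.all(np.abs(total[active] - base.cohort_size) < 1e-6)

    def test_qaly_never_exceeds_life_years(self, base):
        for arm in ("standard", "evlp"):
            res = run_deterministic(base, arm)
            assert res.mean_qaly <= res.mean_ly

    def test_discounting_reduces_totals(self, base):
        undisc = base.copy()
        undisc.discount_rate = 0.0
        for arm in ("standard", "evlp"):
            d = run_deterministic(base, arm)
            u = run_deterministic(undisc, arm)
            assert d.mean_cost < u.mean_cost
            assert d.mean_qaly < u.mean_qaly
            assert d.mean_ly < u.mean_ly

    def test_evlp_arm_has_more_transplants_in_total(self, base):
        std = run_deterministic(base, "standard")
        evlp = run_deterministic(base, "evlp")
        assert evlp.n_std_tx + evlp.n_evlp_tx > std.n_std_tx

    def test_short_horizon_raises_truncation_error(self, base):
        p = base.copy()
        p.horizon_years = 5
        with pytest.raises(TruncationError, match="residual"):
            run_deterministic(p, "standard")

    def test_unknown_arm_rejected(self, base):
        with pytest.raises(ParameterError):
            run_deterministic(base, "both")

    def test_trace_exports_tidy_frame(self, base):
        frame = run_deterministic(base, "standard").trace.to_frame()
        assert {"cycle", "waiting_end", "disc_cost", "disc_qaly", "disc_ly"} <= set(
            frame.columns
        )
        assert (frame["disc_cost"] >= 0).all()
        assert len(frame) >= base.horizon_years
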