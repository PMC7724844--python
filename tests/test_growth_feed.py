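import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plucksim import growth_feed as gf


class TestGompertz:
    def test_weight_at_age_zero_is_w0(self):
        p = gf.GompertzParams(w0=1.8, mu0=0.055, d=0.0115)
        assert gf.gompertz_bw(0.0, p) == pytest.approx(1.8, abs=1e-12)

    def test_asymptote(self):
        p = gf.calibrate_gompertz(adg=760.0)
        assert gf.gompertz_bw(1e6, p) == pytest.approx(230.0, rel=1e-9)

    def test_calibrated_curve_hits_anchors(self):
        p = gf.calibrate_gompertz(adg=760.0)
        age_sale = 28.0 + (110.8 - 7.0) * 1000.0 / 760.0
        assert age_sale == pytest.approx(164.6, abs=0.05)
        assert gf.gompertz_bw(28.0, p) == pytest.approx(7.0, abs=1e-6)
        assert gf.gompertz_bw(age_sale, p) == pytest.approx(110.8, abs=1e-6)

    def test_mean_adg_over_span_equals_target(self):
        p = gf.calibrate_gompertz(adg=725.0)
        span = gf.wean_to_finish_days(725.0)
        gain = gf.gompertz_bw(28.0 + span, p) - gf.gompertz_bw(28.0, p)
        assert gain * 1000.0 / span == pytest.approx(725.0, rel=1e-9)

    @given(st.floats(500, 1000), st.floats(150, 400))
    @settings(max_examples=200, deadline=None)
    def test_calibration_residuals_for_random_parameterisations(self, adg, mature):
        p = gf.calibrate_gompertz(adg=adg, mature_weight=mature)
        age_sale = 28.0 + gf.wean_to_finish_days(adg)
        assert abs(gf.gompertz_bw(28.0, p) - 7.0) < 1e-6
        assert abs(gf.gompertz_bw(age_sale, p) - 110.8) < 1e-6

    @given(st.floats(550, 900))
    @settings(max_examples=50, deadline=None)
    def test_curve_strictly_increasing(self, adg):
        p = gf.calibrate_gompertz(adg=adg)
        t = np.linspace(0.0, 400.0, 500)
        assert (np.diff(gf.gompertz_bw(t, p)) > 0).all()

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            gf.calibrate_gompertz(adg=-5.0)
        with pytest.raises(ValueError):
            gf.calibrate_gompertz(w_wean=120.0)
        p = gf.calibrate_gompertz(adg=760.0)
        with pytest.raises(ValueError):
            gf.gompertz_bw(-1.0, p)
        with pytest.raises(ValueError):
            gf.gompertz_age_at_weight(250.0, p)


class TestStageDurations:
    def test_partition_of_wean_to_finish(self):
        p = gf.calibrate_gompertz(adg=760.0)
        spans = gf.stage_durations(p)
        assert sum(spans) == pytest.approx(gf.wean_to_finish_days(760.0))

    def test_slower_pigs_spend_longer_in_every_stage(self):
        fast = gf.stage_durations(gf.calibrate_gompertz(adg=760.0))
        slow = gf.stage_durations(gf.calibrate_gompertz(adg=671.0))
        assert all(s >= f for f, s in zip(fast, slow))

    def test_empty_transfer_list_gives_single_span(self):
        p = gf.calibrate_gompertz(adg=760.0)
        spans = gf.stage_durations(p, transfer_weights=())
        assert len(spans) == 1
        assert spans[0] == pytest.approx(gf.wean_to_finish_days(760.0))


class TestSlaughterAge:
    @pytest.mark.parametrize("adg,weeks", [(760.0, 24.0), (725.0, 25.0)])
    def test_ceiling_rule_reproduces_reference_ages(self, adg, weeks):
        assert gf.slaughter_age_weeks(adg) == weeks

    def test_rounding_rules_differ_at_boundary_case(self):
        # 671 g/day implies 26.10 exact weeks: nearest gives 26, ceiling 27
        assert gf.slaughter_age_weeks(671.0, rounding="exact") == pytest.approx(26.10, abs=0.01)
        assert gf.slaughter_age_weeks(671.0, rounding="nearest") == 26.0
        assert gf.slaughter_age_weeks(671.0, rounding="ceil") == 27.0

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError):
            gf.slaughter_age_weeks(760.0, rounding="floor")


class TestFeedUsage:
    def kwargs(self, **over):
        base = dict(sows=728.0, weaned_pigs=20000.0, weaner_in=20000.0,
                    weaner_out=19500.0, finisher_in=19500.0,
                    finisher_out=19200.0, weaner_gain_kg=31.0,
                    finisher_gain_kg=72.8, weaner_days=58.0,
                    finisher_days=79.0)
        base.update(over)
        return base

    def test_zero_pigs_leaves_only_sow_feed(self):
        usage = gf.annual_feed_usage(**self.kwargs(
            weaned_pigs=0.0, weaner_in=0.0, weaner_out=0.0,
            finisher_in=0.0, finisher_out=0.0))
        assert usage["weaner"] == 0.0 and usage["finisher"] == 0.0
        assert usage["creep"] == 0.0 and usage["link"] == 0.0
        fd = gf.DEFAULT_FEED_PARAMS
        assert usage["gestation"] == pytest.approx(728 * fd.gestation_per_sow_kg / 1000)
        assert usage["lactation"] == pytest.approx(728 * fd.lactation_per_sow_kg / 1000)

    def test_lower_adg_never_lowers_feed_per_pig(self):
        """Same weight span but more days in stage => at least as much feed."""
        p_fast = gf.calibrate_gompertz(adg=760.0)
        p_slow = gf.calibrate_gompertz(adg=671.0)
        for fast_d, slow_d in zip(gf.stage_durations(p_fast),
                                  gf.stage_durations(p_slow)):
            assert slow_d >= fast_d
        fast = gf.annual_feed_usage(**self.kwargs(weaner_days=57.8, finisher_days=78.8))
        slow = gf.annual_feed_usage(**self.kwargs(weaner_days=65.5, finisher_days=89.2))
        assert slow["weaner"] >= fast["weaner"]
        assert slow["finisher"] >= fast["finisher"]

    def test_negative_coefficient_rejected(self):
        with pytest.raises(ValueError):
            gf.FeedDemandParams(weaner_per_kg_gain=-1, weaner_per_day=1,
                                finisher_per_kg_gain=1, finisher_per_day=1,
                                creep_per_weaned_kg=1, link_per_weaned_kg=1,
                                gestation_per_sow_kg=1, lactation_per_sow_kg=1)

    def test_coefficient_calibration_solver(self):
        ref_a = {"gain_kg_total": 1000.0, "pig_days_total": 2000.0,
                 "feed_kg": 1000.0 * 0.5 + 2000.0 * 1.5}
        ref_b = {"gain_kg_total": 900.0, "pig_days_total": 2600.0,
                 "feed_kg": 900.0 * 0.5 + 2600.0 * 1.5}
        out = gf.calibrate_feed_coefficients(ref_a, ref_b)
        assert out["per_kg_gain"] == pytest.approx(0.5)
        assert out["per_day"] == pytest.approx(1.5)
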