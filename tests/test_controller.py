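"""Target-range controller: setpoint inversion, clamps, cohort replay."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import burnfluid as bf
from burnfluid.controller import (
    TargetRange,
    decide_rate,
    replay_cohort,
    target_range_by_weight,
    target_range_fixed,
)
from burnfluid.uop import PredictionState, UrineOutputResults


def make_results(c1=0.0, c2=1.0, d1=0.0, d2=0.0, **kw):
    return UrineOutputResults(model=None, c1=c1, c2=c2, d1=d1, d2=d2, **kw)


def state_after(*hours):
    s = PredictionState()
    for h, r, u in hours:
        s.observe(h, r, u)
    return s


class TestTargetRange:
    def test_fixed_adult_band(self):
        tr = target_range_fixed(30, 60)
        assert tr.target == 45.0
        tr2 = target_range_fixed(40, 80)
        assert tr2.target == 60.0

    def test_degenerate_bounds_rejected(self):
        with pytest.raises(ValueError):
            TargetRange(45.0, 45.0)
        with pytest.raises(ValueError):
            TargetRange(60.0, 30.0)

    @pytest.mark.parametrize(
        "weight, lower, upper, target",
        [(61.76, 30.88, 61.76, 46.32), (60.0, 30.0, 60.0, 45.0), (1.0, 0.5, 1.0, 0.75)],
    )
    def test_weight_scaled_band(self, weight, lower, upper, target):
        tr = target_range_by_weight(weight)
        assert tr.lower == pytest.approx(lower)
        assert tr.upper == pytest.approx(upper)
        assert tr.target == pytest.approx(target)


class TestDecideRate:
    def test_in_range_retains_base_rate(self):
        res = make_results()  # pure instant term, ratio 0.2 below
        s = state_after((1, 300.0, 60.0), (2, 300.0, 60.0))
        d = decide_rate(res, s, 225.0, target_range_fixed(30, 60))
        assert d.branch == "retained"
        assert d.rate == 225.0

    def test_inversion_hits_target_midpoint(self):
        # predicted 80 at base 400 (instant ratio 0.2); inversion gives 225
        res = make_results()
        s = state_after((1, 400.0, 80.0), (2, 400.0, 80.0))
        d = decide_rate(res, s, 400.0, target_range_fixed(30, 60))
        assert d.branch == "adjusted-down"
        assert d.rate == pytest.approx(225.0)
        assert d.predicted_uop_at_rate == pytest.approx(45.0, abs=1e-12)

    def test_under_range_raises_rate(self):
        res = make_results()
        s = state_after((1, 400.0, 10.0), (2, 400.0, 10.0))  # instant ratio 0.025
        d = decide_rate(res, s, 400.0, target_range_fixed(30, 60))
        assert d.branch == "adjusted-up"
        assert d.rate > 400.0

    def test_zero_slope_falls_back_to_protocol_rule(self):
        res = make_results(c1=1.0, c2=0.0)
        s = state_after((1, 300.0, 90.0), (2, 300.0, 90.0))
        d = decide_rate(res, s, 300.0, target_range_fixed(30, 60))
        assert d.fallback
        assert d.rate == pytest.approx(300.0 * 0.75)  # over range: -25%

    @given(
        uop=st.floats(min_value=1.0, max_value=300.0),
        rate=st.floats(min_value=100.0, max_value=600.0),
        base=st.floats(min_value=50.0, max_value=600.0),
    )
    def test_clamp_safety_and_inversion(self, uop, rate, base):
        res = make_results(c1=0.2, c2=0.9, d1=0.3, d2=-0.3)
        s = state_after((1, rate, uop), (2, rate, uop))
        tr = target_range_fixed(30, 60)
        d = decide_rate(res, s, base, tr)
        assert 50.0 <= d.rate <= 2.0 * base or d.branch == "retained"
        if d.branch != "retained" and not d.saturated and not d.fallback:
            assert d.predicted_uop_at_rate == pytest.approx(tr.target, abs=1e-9)

    def test_monotone_in_predicted_excess(self):
        """Higher instant over-production leads to a lower decided rate."""
        res = make_results()
        tr = target_range_fixed(30, 60)
        decided = []
        for uop in (70.0, 90.0, 120.0):
            s = state_after((1, 300.0, uop), (2, 300.0, uop))
            decided.append(decide_rate(res, s, 300.0, tr).rate)
        assert decided[0] >= decided[1] >= decided[2]


class TestReplay:
    def test_all_in_range_is_identity(self, noiseless_cohorts, noiseless_models):
        _, validation, _ = noiseless_cohorts
        base, uop = noiseless_models
        wide = TargetRange(1e-6, 1e9)
        rep = replay_cohort(validation, base, uop, wide, use_actual_when_in_range=True)
        for p in rep.patients:
            assert p.notional_volume() == pytest.approx(p.actual_volume(), rel=1e-12)
            assert all(b == "retained" for b in p.branches)

    def test_over_range_patient_matches_hand_computation(self):
        """Single over-producing patient: volumes equal the hand-walked sum."""
        res = make_results()  # prediction = instant_ratio * rate
        base = bf.BaseRateResults.from_dict(
            {"a1": 300.0, "a2": 0.0, "b1": 1.0, "b2": 0.0, "cohort_mean_rate": 300.0}
        )
        profile = bf.PatientProfile(patient_id="p", weight=60.0, tbsa=50.0)
        records = [bf.HourlyRecord(hour=h, infusion_rate=300.0, uop=90.0) for h in range(1, 6)]
        series = bf.PatientSeries(profile=profile, records=records)
        tr = target_range_fixed(30, 60)
        rep = replay_cohort([series], base, res, tr)
        p = rep.patients[0]
        # hours 1-2 burn-in keep 300; hours 3-5 invert 0.3*rate = 45 -> 150
        assert p.decided_rates == pytest.approx([300.0, 300.0, 150.0, 150.0, 150.0])
        assert p.notional_volume() == pytest.approx(300.0 * 2 + 150.0 * 3)
        assert p.fraction_adjusted() == pytest.approx(3 / 5)

    def test_diuresis_cohort_reduces_second_day_volume(self, default_cohorts, default_models):
        """With rising urine responsiveness the controller cuts day-2 fluid."""
        _, validation, _ = default_cohorts
        base, uop = default_models
        rep = replay_cohort(validation, base, uop, target_range_fixed(30, 60))
        vt = rep.volume_table()
        assert vt["notional_24_48_L"].mean() < vt["actual_24_48_L"].mean()

    def test_replay_frame_columns(self, default_cohorts, default_models):
        _, validation, _ = default_cohorts
        base, uop = default_models
        rep = replay_cohort(validation[:2], base, uop, target_range_fixed(30, 60))
        df = rep.to_frame()
        assert list(df.columns) == [
            "patient_id", "hour", "branch", "rate_actual", "rate_decided", "uop_pred", "uop_actual",
        ]
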