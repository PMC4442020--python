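"""Recursive urine-output predictor: ratios, feedback, fitting, replay."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import burnfluid as bf
from burnfluid.cohort import HourlyRecord, PatientSeries
from burnfluid.uop import (
    PredictionState,
    UndefinedRatioError,
    UrineOutputModel,
    UrineOutputResults,
    instant_ratio,
    overall_ratio,
    pred_err,
    predict_uop,
    run_predictions,
)


def make_results(c1=0.0, c2=1.0, d1=0.0, d2=0.0, **kw):
    return UrineOutputResults(model=None, c1=c1, c2=c2, d1=d1, d2=d2, **kw)


def state_after(*hours):
    """Build a state by observing (hour, rate, uop) triples in order."""
    st_ = PredictionState()
    for h, r, u in hours:
        st_.observe(h, r, u)
    return st_


class TestRatios:
    def test_overall_ratio(self):
        assert overall_ratio(1200.0, 6000.0) == pytest.approx(0.2)
        assert overall_ratio(5.5, 5.5) == 1.0
        with pytest.raises(UndefinedRatioError):
            overall_ratio(10.0, 0.0)

    def test_instant_ratio(self):
        assert instant_ratio(60.0, 300.0) == pytest.approx(0.2)
        assert instant_ratio(0.0, 300.0) == 0.0
        with pytest.raises(UndefinedRatioError):
            instant_ratio(60.0, 0.0)

    def test_first_day_cohort_ratios(self):
        # derivation first-24h means: 1.2 L urine / 5.5 L fluid; 65.8 / 307.9 mL/hr
        assert overall_ratio(1200.0, 5500.0) == pytest.approx(0.218, abs=5e-4)
        assert instant_ratio(65.8, 307.9) == pytest.approx(0.2137, abs=5e-5)

    @given(
        k=st.floats(min_value=1e-3, max_value=1e3),
        uop=st.floats(min_value=0.0, max_value=500.0),
        fluid=st.floats(min_value=1.0, max_value=1e4),
    )
    def test_scale_invariance(self, k, uop, fluid):
        assert overall_ratio(k * uop, k * fluid) == pytest.approx(overall_ratio(uop, fluid), rel=1e-12)
        assert instant_ratio(k * uop, k * fluid) == pytest.approx(instant_ratio(uop, fluid), rel=1e-12)

    def test_zero_infusion_carries_instant_ratio_forward(self):
        s = state_after((1, 300.0, 60.0), (2, 0.0, 10.0))
        assert s.instant_ratio == pytest.approx(0.2)  # from hour 1


class TestPredErr:
    def test_direct_arithmetic(self):
        assert pred_err(1.0, 0.0, 65.0, 60.0, 99.0) == pytest.approx(5.0)
        assert pred_err(0.0, 0.0, 65.0, 60.0, 99.0) == 0.0
        # 0.4 * (60 - 50) + (-0.39) * (50 - 45)
        assert pred_err(0.4, -0.39, 60.0, 50.0, 45.0) == pytest.approx(2.05)


class TestPredict:
    def test_pure_instant_term(self):
        res = make_results(c1=0.0, c2=1.0)
        s = state_after((1, 300.0, 60.0), (2, 300.0, 60.0))
        assert predict_uop(res, s, 300.0) == pytest.approx(60.0)  # 1 * 0.2 * 300

    def test_pure_long_term(self):
        res = make_results(c1=1.0, c2=0.0)
        s = PredictionState(t=10, cum_fluid=4000.0, cum_uop=1000.0, n_obs=10,
                            last_uop=100.0, prev_uop=100.0, _instant=0.25)
        # 0.25 * (4000 - 1000) / 10 = 75
        assert predict_uop(res, s, 500.0) == pytest.approx(75.0)

    def test_affine_in_rate(self):
        res = make_results(c1=0.3, c2=0.9, d1=0.2, d2=-0.1)
        s = state_after((1, 300.0, 55.0), (2, 290.0, 63.0))
        p0, p1, p2 = (predict_uop(res, s, r) for r in (100.0, 200.0, 300.0))
        assert p2 - p1 == pytest.approx(p1 - p0, rel=1e-9)
        slope = (p1 - p0) / 100.0
        assert slope == pytest.approx(res.c2 * s.instant_ratio, rel=1e-9)

    def test_steady_state_fixed_point(self):
        """Constant rate/UOP: the instant term reproduces the constant."""
        res = make_results(c1=0.0, c2=1.0)
        s = state_after(*((h, 300.0, 66.0) for h in range(1, 6)))
        assert predict_uop(res, s, 300.0) == pytest.approx(66.0, rel=1e-12)

    def test_floor_at_zero(self):
        res = make_results(c1=0.0, c2=1.0, d2=-10.0)
        s = state_after((1, 300.0, 5.0), (2, 300.0, 80.0))
        assert predict_uop(res, s, 0.0) == 0.0

    def test_eq_parse_variants_differ(self):
        s = state_after((1, 300.0, 50.0), (2, 280.0, 70.0))
        vals = {
            parse: predict_uop(make_results(c1=1.0, c2=0.0, eq_parse=parse), s, 300.0)
            for parse in ("current", "lagged", "inverse")
        }
        assert vals["current"] != vals["inverse"]
        assert len(vals) == 3


class TestFit:
    def test_noiseless_exact_recovery(self, noiseless_cfg, noiseless_models):
        _, uop = noiseless_models
        assert uop.c1 == pytest.approx(noiseless_cfg.c1, abs=1e-6)
        assert uop.c2 == pytest.approx(noiseless_cfg.c2, abs=1e-6)
        assert uop.d1 == pytest.approx(noiseless_cfg.d1, abs=1e-6)
        assert uop.d2 == pytest.approx(noiseless_cfg.d2, abs=1e-6)
        assert uop.converged

    def test_two_stage_matches_normal_equations_oracle(self, default_cohorts, default_models):
        """max_iter=1 reproduces an independent hand-rolled two-stage OLS."""
        derivation, _, _ = default_cohorts
        base, _ = default_models
        res = UrineOutputModel(derivation, base, max_iter=1).fit()

        # independent walk: build the design matrices from scratch
        lt_l, ib_l, duop_l, y_l, first_l = [], [], [], [], []
        for s in derivation:
            recs = s.records
            cum_f = cum_u = 0.0
            for i, rec in enumerate(recs):
                if i >= 2:
                    t_prev = recs[i - 1].hour
                    lt_l.append((cum_u / cum_f) * (cum_f - cum_u) / t_prev)
                    inst = recs[i - 1].uop / recs[i - 1].infusion_rate
                    ib_l.append(inst * base.base_rate(s.profile.tbsa, rec.hour))
                    duop_l.append(recs[i - 1].uop - recs[i - 2].uop)
                    y_l.append(rec.uop)
                    first_l.append(i == 2)
                cum_f += rec.infusion_rate
                cum_u += rec.uop
        X = np.column_stack([lt_l, ib_l])
        y = np.array(y_l)
        c = np.linalg.solve(X.T @ X, X.T @ y)
        p1 = X @ c
        x1 = np.zeros_like(y)
        first = np.array(first_l)
        x1[~first] = (p1 - y)[np.flatnonzero(~first) - 1]
        D = np.column_stack([x1, duop_l])
        e = y - p1
        d = np.linalg.solve(D.T @ D, D.T @ e)
        assert res.c1 == pytest.approx(c[0], abs=1e-9)
        assert res.c2 == pytest.approx(c[1], abs=1e-9)
        assert res.d1 == pytest.approx(d[0], abs=1e-9)
        assert res.d2 == pytest.approx(d[1], abs=1e-9)

    def test_feedback_signs_on_generator_defaults(self, default_models):
        _, uop = default_models
        assert uop.d1 > 0
        assert uop.d2 < 0

    def test_bias_shrinks_with_cohort_size(self):
        """The estimator concentrates on the truth as patients are added."""
        errs = {}
        for n in (13, 100):
            per_seed = []
            for seed in (21, 22, 23):
                cfg = bf.SimulationConfig(seed=seed, n_derivation=n, n_validation=1, diuresis_slope=0.0)
                der, _, _ = bf.generate_cohorts(cfg)
                base = bf.BaseRateModel(der).fit()
                r = bf.UrineOutputModel(der, base).fit()
                per_seed.append(
                    abs(r.c1 - cfg.c1) + abs(r.c2 - cfg.c2) + abs(r.d1 - cfg.d1) + abs(r.d2 - cfg.d2)
                )
            errs[n] = np.mean(per_seed)
        assert errs[100] < errs[13]

    def test_requires_two_patients(self, noiseless_cohorts, noiseless_models):
        derivation, _, _ = noiseless_cohorts
        base, _ = noiseless_models
        with pytest.raises(ValueError):
            UrineOutputModel(derivation[:1], base)


class TestRunPredictions:
    def _truncate(self, series, n):
        return PatientSeries(profile=series.profile, records=series.records[:n])

    def test_prediction_count_975_hours(self, noiseless_cohorts, noiseless_models):
        """24 contiguous patients totalling 975 hours yield 927 predictions."""
        _, validation, _ = noiseless_cohorts
        base, uop = noiseless_models
        lengths = [41] * 15 + [40] * 9
        cohort = [self._truncate(s, n) for s, n in zip(validation, lengths)]
        assert sum(len(s) for s in cohort) == 975
        traces = run_predictions(cohort, base, uop)
        assert sum(t.n_predictions for t in traces) == 927

    @pytest.mark.parametrize("n_hours, n_preds", [(3, 1), (2, 0)])
    def test_burn_in_consumes_two_hours(self, noiseless_cohorts, noiseless_models, n_hours, n_preds):
        _, validation, _ = noiseless_cohorts
        base, uop = noiseless_models
        cohort = [self._truncate(validation[0], n_hours)]
        traces = run_predictions(cohort, base, uop)
        assert traces[0].n_predictions == n_preds

    def test_gap_reapplies_burn_in(self, noiseless_cohorts, noiseless_models):
        _, validation, _ = noiseless_cohorts
        base, uop = noiseless_models
        s = validation[0]
        records = [r for r in s.records if r.hour <= 5 or 8 <= r.hour <= 12]
        gappy = PatientSeries(profile=s.profile, records=records)
        traces = run_predictions([gappy], base, uop)
        assert traces[0].n_predictions == (5 - 2) + (5 - 2)

    def test_noiseless_predictions_match_actuals(self, noiseless_cohorts, noiseless_models):
        """On data generated by the model itself, predictions are exact."""
        _, validation, _ = noiseless_cohorts
        base, uop = noiseless_models
        traces = run_predictions(validation, base, uop)
        for t in traces:
            assert np.allclose(t.preds, t.actuals, atol=1e-4)

    def test_trace_frame_columns(self, noiseless_cohorts, noiseless_models):
        _, validation, _ = noiseless_cohorts
        base, uop = noiseless_models
        trange = bf.target_range_fixed(30, 60)
        traces = run_predictions(validation[:2], base, uop, target_range=trange)
        df = traces[0].to_frame()
        assert list(df.columns) == [
            "patient_id", "hour", "uop_pred", "pred_err_term", "uop_actual", "rate_used", "in_range",
        ]
        assert df["in_range"].notna().all()


def test_results_roundtrip_and_summary():
    res = make_results(c1=0.3, c2=0.8, d1=0.4, d2=-0.39, n_obs=500, r_squared=0.9)
    back = UrineOutputResults.from_dict(res.to_dict())
    assert back.c1 == res.c1 and back.d2 == res.d2
    assert "c1" in res.summary() and "R-squared" in res.summary()


def test_non_finite_coefficients_rejected():
    with pytest.raises(ValueError):
        make_results(c1=float("nan"))
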