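"""Evaluation of the prediction and titration models.

Covers the validation analyses: absolute and relative absolute prediction
errors of the hourly UOP forecast, the sensitivity/specificity/accuracy of
flagging out-of-range UOP ahead of time, paired comparisons of actual
versus notional volumes, and Table-style cohort summaries (mean +/- SD).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import PatientSeries
from .controller import TargetRange
from .protocol import tmmu_schedule
from .uop import PredictionTrace

__all__ = [
    "ErrorSummary",
    "prediction_errors",
    "ConfusionSummary",
    "over_range_confusion",
    "PairedComparison",
    "paired_comparison",
    "cohort_summary",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ErrorSummary:
    """Hourly UOP prediction-error summaries."""

    abs_err_mean: float
    abs_err_sd: float
    rel_err_mean: float  # fraction, not percent
    rel_err_sd: float
    n: int
    n_zero_actual: int  # hours excluded from the relative error


def _flatten(trace) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(trace, PredictionTrace):
        trace = [trace]
    preds = np.concatenate([t.preds for t in trace]) if trace else np.array([])
    actuals = np.concatenate([t.actuals for t in trace]) if trace else np.array([])
    return preds, actuals


def prediction_errors(trace) -> tuple[np.ndarray, np.ndarray, ErrorSummary]:
    """Per-hour absolute and relative errors plus their summaries.

    ``trace`` is a PredictionTrace, a list of them, or a (pred, actual)
    pair of arrays. Absolute error |pred - actual| uses every hour;
    relative error (|pred - actual| / actual) excludes hours with zero
    actual UOP, whose count is reported. SDs use the n-1 denominator.
    """
    if isinstance(trace, tuple):
        preds, actuals = (np.asarray(a, dtype=float) for a in trace)
    else:
        preds, actuals = _flatten(trace)
    if preds.size == 0:
        raise ValueError("empty prediction trace")
    abs_err = np.abs(preds - actuals)
    nonzero = actuals > 0
    rel_err = np.full_like(abs_err, np.nan)
    rel_err[nonzero] = abs_err[nonzero] / actuals[nonzero]
    n_zero = int((~nonzero).sum())
    if nonzero.sum() == 0:
        logger.warning("all actual UOP are zero; relative error undefined")
        rel_mean = rel_sd = float("nan")
    else:
        rel = rel_err[nonzero]
        rel_mean = float(rel.mean())
        rel_sd = float(rel.std(ddof=1)) if rel.size > 1 else 0.0
    summary = ErrorSummary(
        abs_err_mean=float(abs_err.mean()),
        abs_err_sd=float(abs_err.std(ddof=1)) if abs_err.size > 1 else 0.0,
        rel_err_mean=rel_mean,
        rel_err_sd=rel_sd,
        n=int(abs_err.size),
        n_zero_actual=n_zero,
    )
    return abs_err, rel_err, summary


@dataclass(frozen=True)
class ConfusionSummary:
    sensitivity: float
    specificity: float
    accuracy: float
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def prevalence(self) -> float:
        n = self.tp + self.fp + self.tn + self.fn
        return (self.tp + self.fn) / n if n else float("nan")


def over_range_confusion(preds, actuals, target_range: TargetRange) -> ConfusionSummary:
    """Detection of out-of-range UOP: positive = outside [lower, upper].

    Over-upper and under-lower hours are pooled into a single positive
    class. Sensitivity is undefined (nan, logged) when no actual hour is
    out of range, and likewise specificity when none is in range.
    """
    p = np.asarray(preds, dtype=float)
    a = np.asarray(actuals, dtype=float)
    if p.shape != a.shape or p.ndim != 1:
        raise ValueError("preds and actuals must be 1-D of equal length")
    pred_pos = ~np.array([target_range.contains(v) for v in p])
    act_pos = ~np.array([target_range.contains(v) for v in a])
    tp = int(np.sum(pred_pos & act_pos))
    fp = int(np.sum(pred_pos & ~act_pos))
    tn = int(np.sum(~pred_pos & ~act_pos))
    fn = int(np.sum(~pred_pos & act_pos))
    if tp + fn == 0:
        logger.warning("no out-of-range actual hours; sensitivity undefined")
        sens = float("nan")
    else:
        sens = tp / (tp + fn)
    if tn + fp == 0:
        logger.warning("no in-range actual hours; specificity undefined")
        spec = float("nan")
    else:
        spec = tn / (tn + fp)
    acc = (tp + tn) / p.size if p.size else float("nan")
    return ConfusionSummary(sens, spec, acc, tp, fp, tn, fn)


@dataclass(frozen=True)
class PairedComparison:
    mean_a: float
    mean_b: float
    t: float
    p_two_sided: float
    n: int
    degenerate: bool = False


def paired_comparison(a, b) -> PairedComparison:
    """Paired two-sided t-test on per-patient values.

    Identical pairs give t = 0, p = 1; a spread-free nonzero difference is
    flagged degenerate (the statistic is unbounded).
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("need two equal-length vectors with at least 2 pairs")
    d = x - y
    if d.std(ddof=1) == 0:
        if d.mean() == 0:
            return PairedComparison(float(x.mean()), float(y.mean()), 0.0, 1.0, x.size)
        logger.warning("zero variance of paired differences; t statistic degenerate")
        return PairedComparison(
            float(x.mean()), float(y.mean()), float("nan"), float("nan"), x.size, degenerate=True
        )
    t, p = stats.ttest_rel(x, y)
    return PairedComparison(float(x.mean()), float(y.mean()), float(t), float(p), x.size)


def _mean_sd(values) -> tuple[float, float]:
    v = np.asarray(values, dtype=float)
    return float(v.mean()), float(v.std(ddof=1)) if v.size > 1 else 0.0


def cohort_summary(cohort: list[PatientSeries]) -> pd.DataFrame:
    """Demographic and fluid-resuscitation summary, mean +/- SD per row.

    Block fluid volumes are split into crystalloid/colloid/water using each
    patient's protocol composition fractions (1 : 0.5 mL/kg/%TBSA plus the
    2 L daily water), since the hourly records carry only total infusion.
    """
    if not cohort:
        raise ValueError("empty cohort")
    rows: dict[str, tuple[float, float]] = {}

    def fractions(series, block):
        plan = tmmu_schedule(series.profile)
        if block == 1:
            total = plan.first24_total
            return plan.first24_crystalloid / total, plan.first24_colloid / total
        total = plan.second24_total
        return plan.second24_crystalloid / total, plan.second24_colloid / total

    def block_stats(lo, hi, block):
        vols = np.array([s.block_volume(lo, hi) for s in cohort])
        urine = np.array([s.block_urine(lo, hi) for s in cohort])
        hours = np.array([max(sum(lo <= r.hour <= hi for r in s.records), 1) for s in cohort])
        fracs = np.array([fractions(s, block) for s in cohort])
        return vols, urine, hours, fracs

    rows["age_years"] = _mean_sd([s.profile.age for s in cohort])
    rows["weight_kg"] = _mean_sd([s.profile.weight for s in cohort])
    rows["start_hour"] = _mean_sd([s.profile.start_hour for s in cohort])
    rows["tbsa_pct"] = _mean_sd([s.profile.tbsa for s in cohort])
    rows["full_thickness_pct"] = _mean_sd([s.profile.full_thickness_tbsa for s in cohort])

    for (lo, hi, block, tag) in ((1, 24, 1, "1_24"), (25, 48, 2, "25_48")):
        vols, urine, hours, fracs = block_stats(lo, hi, block)
        rows[f"crystalloids_{tag}_L"] = _mean_sd(vols * fracs[:, 0] / 1000.0)
        rows[f"colloids_{tag}_L"] = _mean_sd(vols * fracs[:, 1] / 1000.0)
        rows[f"total_fluids_{tag}_L"] = _mean_sd(vols / 1000.0)
        rows[f"fluid_rate_{tag}_ml_hr"] = _mean_sd(vols / hours)
        rows[f"total_urine_{tag}_L"] = _mean_sd(urine / 1000.0)
        rows[f"urine_rate_{tag}_ml_hr"] = _mean_sd(urine / hours)

    return pd.DataFrame(
        {"mean": {k: v[0] for k, v in rows.items()}, "sd": {k: v[1] for k, v in rows.items()}}
    )
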