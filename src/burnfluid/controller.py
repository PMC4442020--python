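"""Target-range infusion controller.

Each hour the predictor estimates the coming hour's urine output at the
basic infusion rate. If the prediction lies within the accepted target band
(30-60 mL/hr, or 0.5-1.0 mL/kg/hr scaled by body weight) the basic rate is
retained. Otherwise the prediction, which is affine in the coming hour's
rate,

    UOP_Pred(rate) = intercept + c2 * Instant_Ratio(t) * rate,

is inverted at the band midpoint UOP_target to give the adjusted rate

    rate = (UOP_target - intercept) / (c2 * Instant_Ratio(t)),

clamped to a physiologic window (default 50 mL/hr to twice the basic
rate). When the slope is zero the inversion is unavailable and the
rule-based 20-30% protocol adjustment is used instead (logged).

``replay_cohort`` walks recorded patients hour by hour to compute the
notional fluid volumes the controller would have ordered; for validation
purposes the recorded actual rate stands in for the basic rate during
in-range hours.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .base_rate import BaseRateResults
from .cohort import PatientSeries
from .protocol import tmmu_adjust_rate
from .uop import (
    MissingHistoryError,
    PredictionState,
    UndefinedRatioError,
    UrineOutputResults,
    predict_components,
)

__all__ = [
    "TargetRange",
    "target_range_fixed",
    "target_range_by_weight",
    "RateDecision",
    "decide_rate",
    "ReplayPatient",
    "ReplayResult",
    "replay_cohort",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TargetRange:
    """Accepted UOP band; the control setpoint is its midpoint."""

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not 0 < self.lower < self.upper:
            raise ValueError(f"need 0 < lower < upper, got ({self.lower}, {self.upper})")

    @property
    def target(self) -> float:
        return 0.5 * (self.lower + self.upper)

    def contains(self, uop: float) -> bool:
        return self.lower <= uop <= self.upper

    def __str__(self) -> str:
        return f"{self.lower:g}-{self.upper:g} mL/hr (target {self.target:g})"


def target_range_fixed(lower: float = 30.0, upper: float = 60.0) -> TargetRange:
    """Fixed UOP band, default the 30-60 mL/hr used for adults."""
    return TargetRange(lower, upper)


def target_range_by_weight(weight: float) -> TargetRange:
    """Weight-scaled band 0.5-1.0 mL/kg/hr."""
    if weight <= 0:
        raise ValueError("weight must be positive")
    return TargetRange(0.5 * weight, 1.0 * weight)


@dataclass(frozen=True)
class RateDecision:
    """The controller's infusion-rate decision for the coming hour."""

    hour: int
    rate: float
    branch: str  # {"retained", "adjusted-up", "adjusted-down"}
    predicted_uop_at_base: float
    predicted_uop_at_rate: float
    saturated: bool = False  # a clamp bound, not the inversion, set the rate
    fallback: bool = False  # non-invertible slope; protocol rule used


def decide_rate(
    uop_results: UrineOutputResults,
    state: PredictionState,
    base_rate_next: float,
    target_range: TargetRange,
    hour: int | None = None,
    rate_min: float = 50.0,
    rate_max: float | None = None,
    step_fraction: float = 0.25,
) -> RateDecision:
    """Keep the basic rate when the predicted UOP is in range, else invert.

    ``rate_max`` defaults to twice the basic rate. If the affine slope
    c2 * Instant_Ratio(t) is zero the model cannot be inverted; the
    rule-based protocol step is applied to the basic rate instead.
    """
    if base_rate_next < 0:
        raise ValueError("base_rate_next must be >= 0")
    if rate_max is None:
        rate_max = 2.0 * base_rate_next
    hr = int(hour) if hour is not None else (state.t + 1 if state.t is not None else 0)

    intercept, slope, _ = predict_components(uop_results, state)
    pred_at_base = max(0.0, intercept + slope * base_rate_next)

    if target_range.contains(pred_at_base):
        return RateDecision(hr, base_rate_next, "retained", pred_at_base, pred_at_base)

    branch = "adjusted-down" if pred_at_base > target_range.upper else "adjusted-up"
    if slope == 0:
        logger.warning(
            "hour %d: zero rate sensitivity (c2*instant_ratio = 0); "
            "falling back to the rule-based protocol step",
            hr,
        )
        rate = tmmu_adjust_rate(
            base_rate_next,
            pred_at_base,
            low=target_range.lower,
            high=target_range.upper,
            step_fraction=step_fraction,
        )
        rate_c = float(np.clip(rate, rate_min, rate_max))
        return RateDecision(
            hr, rate_c, branch, pred_at_base, pred_at_base, saturated=rate_c != rate, fallback=True
        )

    rate = (target_range.target - intercept) / slope
    rate_c = float(np.clip(rate, rate_min, rate_max))
    saturated = rate_c != rate
    if saturated:
        logger.debug("hour %d: adjusted rate %.1f clamped to %.1f", hr, rate, rate_c)
    pred_at_rate = max(0.0, intercept + slope * rate_c)
    return RateDecision(hr, rate_c, branch, pred_at_base, pred_at_rate, saturated=saturated)


@dataclass
class ReplayPatient:
    """Hour-by-hour controller replay of one recorded patient."""

    patient_id: str
    decisions: list[RateDecision] = field(default_factory=list)
    hours: list[int] = field(default_factory=list)
    actual_rates: list[float] = field(default_factory=list)
    decided_rates: list[float] = field(default_factory=list)
    branches: list[str] = field(default_factory=list)
    uop_preds: list[float] = field(default_factory=list)
    uop_actuals: list[float] = field(default_factory=list)

    def _block(self, values, lo, hi):
        return sum(v for h, v in zip(self.hours, values) if lo <= h <= hi)

    def actual_volume(self, lo: int = 1, hi: int = 48) -> float:
        return float(self._block(self.actual_rates, lo, hi))

    def notional_volume(self, lo: int = 1, hi: int = 48) -> float:
        return float(self._block(self.decided_rates, lo, hi))

    def fraction_adjusted(self, lo: int = 1, hi: int = 48) -> float:
        flags = [
            b != "retained"
            for h, b in zip(self.hours, self.branches)
            if lo <= h <= hi
        ]
        return float(np.mean(flags)) if flags else float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": self.patient_id,
                "hour": self.hours,
                "branch": self.branches,
                "rate_actual": self.actual_rates,
                "rate_decided": self.decided_rates,
                "uop_pred": self.uop_preds,
                "uop_actual": self.uop_actuals,
            }
        )


@dataclass
class ReplayResult:
    patients: list[ReplayPatient]
    target_range: TargetRange

    def to_frame(self) -> pd.DataFrame:
        return pd.concat([p.to_frame() for p in self.patients], ignore_index=True)

    def volume_table(self) -> pd.DataFrame:
        """Per-patient actual vs notional volumes (L) per 24-hour block."""
        recs = []
        for p in self.patients:
            recs.append(
                {
                    "patient_id": p.patient_id,
                    "actual_0_24_L": p.actual_volume(1, 24) / 1000.0,
                    "notional_0_24_L": p.notional_volume(1, 24) / 1000.0,
                    "actual_24_48_L": p.actual_volume(25, 48) / 1000.0,
                    "notional_24_48_L": p.notional_volume(25, 48) / 1000.0,
                    "frac_adjusted_0_24": p.fraction_adjusted(1, 24),
                    "frac_adjusted_24_48": p.fraction_adjusted(25, 48),
                }
            )
        return pd.DataFrame(recs)


def replay_cohort(
    cohort: list[PatientSeries],
    base_results: BaseRateResults,
    uop_results: UrineOutputResults,
    target_range: TargetRange,
    use_actual_when_in_range: bool = True,
    rate_min: float = 50.0,
    rate_max: float | None = None,
) -> ReplayResult:
    """Notional replay: what would the controller have infused?

    The state always advances on the *recorded* intake and UOP, so this is
    an offline what-if, not a closed-loop simulation. Burn-in hours (the
    first two of each contiguous segment) count their actual rate as the
    decision. With ``use_actual_when_in_range`` (the validation convention)
    the recorded actual rate, rather than the model's basic rate, is kept
    during in-range hours.
    """
    patients = []
    for series in cohort:
        rp = ReplayPatient(series.profile.patient_id)
        for seg in series.segments():
            state = PredictionState()
            for i, rec in enumerate(seg):
                decided = rec.infusion_rate
                branch = "retained"
                pred = float("nan")
                if i >= 2:
                    b_next = float(base_results.base_rate(series.profile.tbsa, rec.hour))
                    try:
                        decision = decide_rate(
                            uop_results,
                            state,
                            b_next,
                            target_range,
                            hour=rec.hour,
                            rate_min=rate_min,
                            rate_max=rate_max,
                        )
                    except (UndefinedRatioError, MissingHistoryError) as exc:
                        logger.warning(
                            "patient %s hour %d: %s; actual rate kept",
                            series.profile.patient_id,
                            rec.hour,
                            exc,
                        )
                        decision = None
                    if decision is not None:
                        pred = decision.predicted_uop_at_base
                        branch = decision.branch
                        if branch == "retained":
                            decided = rec.infusion_rate if use_actual_when_in_range else b_next
                        else:
                            decided = decision.rate
                        intercept, slope, fb = predict_components(uop_results, state)
                        p1 = (intercept - fb) + slope * b_next
                        state.register_prediction(p1, pred)
                rp.hours.append(rec.hour)
                rp.actual_rates.append(rec.infusion_rate)
                rp.decided_rates.append(decided)
                rp.branches.append(branch)
                rp.uop_preds.append(pred)
                rp.uop_actuals.append(rec.uop)
                state.observe(rec.hour, rec.infusion_rate, rec.uop)
        patients.append(rp)
    return ReplayResult(patients, target_range)
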