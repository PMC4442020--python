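"""TMMU burn-resuscitation protocol arithmetic.

The Third Military Medical University (TMMU) protocol prescribes, for adult
burn patients, 1 mL of crystalloid (lactated Ringer's) plus 0.5 mL of
colloid (plasma) per kg body weight per %TBSA burned during the first 24
hours post-burn, plus 2 L of water (5% glucose) as the daily basic
requirement. Half of the first-24h fluid is given within the first 8 hours,
the remainder homogeneously over hours 9-24. In the second 24 hours the
crystalloid and colloid are halved and another 2 L of water is given.

Bedside titration is rule-based: if hourly urine output leaves the target
band (30-60 mL/hr), the rate is raised or lowered by 20-30%.

This module is the baseline comparator for the dynamic model; all volumes
are continuous mL, rounded only at display time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import PatientProfile

__all__ = [
    "CRYSTALLOID_ML_PER_KG_PCT",
    "COLLOID_ML_PER_KG_PCT",
    "DAILY_WATER_ML",
    "ProtocolPlan",
    "tmmu_volume_first24",
    "tmmu_volume_second24",
    "tmmu_schedule",
    "tmmu_adjust_rate",
]

CRYSTALLOID_ML_PER_KG_PCT = 1.0
COLLOID_ML_PER_KG_PCT = 0.5
DAILY_WATER_ML = 2000.0


@dataclass(frozen=True)
class ProtocolPlan:
    """A 48-hour TMMU fluid plan for one patient.

    ``hourly_rates[i]`` is the scheduled rate (mL/hr) for post-burn hour
    ``i + 1``; hours 1-8 carry half of the first-24h total.
    """

    first24_crystalloid: float
    first24_colloid: float
    first24_water: float
    second24_crystalloid: float
    second24_colloid: float
    second24_water: float
    hourly_rates: np.ndarray = field(repr=False)

    @property
    def first24_total(self) -> float:
        return self.first24_crystalloid + self.first24_colloid + self.first24_water

    @property
    def second24_total(self) -> float:
        return self.second24_crystalloid + self.second24_colloid + self.second24_water

    @property
    def total(self) -> float:
        return self.first24_total + self.second24_total

    def rate_at(self, hour: int) -> float:
        """Scheduled rate for post-burn hour 1..48."""
        if not 1 <= hour <= 48:
            raise ValueError(f"hour must be in 1..48, got {hour}")
        return float(self.hourly_rates[hour - 1])


def tmmu_volume_first24(profile: PatientProfile) -> float:
    """First-24h TMMU volume in mL: 1.5 mL/kg/%TBSA plus 2 L water."""
    burn = profile.weight * profile.tbsa
    return (CRYSTALLOID_ML_PER_KG_PCT + COLLOID_ML_PER_KG_PCT) * burn + DAILY_WATER_ML


def tmmu_volume_second24(profile: PatientProfile) -> float:
    """Second-24h TMMU volume in mL: half the colloid/crystalloid, 2 L water."""
    burn = profile.weight * profile.tbsa
    return 0.5 * (CRYSTALLOID_ML_PER_KG_PCT + COLLOID_ML_PER_KG_PCT) * burn + DAILY_WATER_ML


def tmmu_schedule(profile: PatientProfile, catch_up: bool = False) -> ProtocolPlan:
    """Build the hourly 48-hour schedule.

    Half of the first-24h total is spread over hours 1-8, the rest over
    hours 9-24; the second-24h total is uniform over hours 25-48. The 2 L
    daily water follows the same temporal split as the rest of the fluid.

    With ``catch_up`` (off by default) a late admission (``start_hour`` > 0)
    zeroes the pre-admission hours and compresses their volume into the
    remaining hours of the same block, so the block totals are preserved.
    """
    burn = profile.weight * profile.tbsa
    first24 = tmmu_volume_first24(profile)
    second24 = tmmu_volume_second24(profile)

    rates = np.empty(48, dtype=float)
    rates[0:8] = first24 / 2.0 / 8.0
    rates[8:24] = first24 / 2.0 / 16.0
    rates[24:48] = second24 / 24.0

    if catch_up and profile.start_hour > 0:
        s = int(np.floor(profile.start_hour))
        s = min(s, 47)
        missed = rates[:s].sum()
        rates[:s] = 0.0
        if s < 24:
            # fold the missed volume into the rest of the first-24h block
            end = 8 if s < 8 else 24
            rates[s:end] += missed / (end - s)
        else:
            rates[s:48] += missed / (48 - s)

    return ProtocolPlan(
        first24_crystalloid=CRYSTALLOID_ML_PER_KG_PCT * burn,
        first24_colloid=COLLOID_ML_PER_KG_PCT * burn,
        first24_water=DAILY_WATER_ML,
        second24_crystalloid=0.5 * CRYSTALLOID_ML_PER_KG_PCT * burn,
        second24_colloid=0.5 * COLLOID_ML_PER_KG_PCT * burn,
        second24_water=DAILY_WATER_ML,
        hourly_rates=rates,
    )


def tmmu_adjust_rate(
    current_rate: float,
    uop: float,
    low: float = 30.0,
    high: float = 60.0,
    step_fraction: float = 0.25,
) -> float:
    """Rule-based hourly titration: +/- ``step_fraction`` when UOP leaves the band.

    The protocol states a 20-30% adjustment without a selection rule, so the
    step is a parameter constrained to [0.20, 0.30] (default midpoint 0.25).
    """
    if current_rate < 0:
        raise ValueError("current_rate must be >= 0")
    if not 0 < low < high:
        raise ValueError(f"need 0 < low < high, got ({low}, {high})")
    if not 0.20 <= step_fraction <= 0.30:
        raise ValueError(f"step_fraction must be in [0.20, 0.30], got {step_fraction}")
    if uop < low:
        return current_rate * (1.0 + step_fraction)
    if uop > high:
        return current_rate * (1.0 - step_fraction)
    return current_rate
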