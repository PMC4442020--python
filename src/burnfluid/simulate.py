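"""Synthetic burn-resuscitation cohorts with known ground truth.

No patient-level records from the study population are publicly deposited,
so testing and parameter-recovery experiments run on simulated cohorts that
reproduce its statistical structure: adults with 30-97% TBSA burns, body
weight near 62 +/- 9.5 kg, an hourly infusion rate that decays
exponentially over the 48-hour resuscitation while urine output rises, and
patient-level rate variation driven by burn extent.

Two infusion mechanisms are available: ``model_truth`` draws each hour's
rate from the decay-times-adjuster curve with multiplicative lognormal
noise, and ``tmmu_rule_based`` follows the protocol schedule with the
rule-based 20-30% titration. Urine output is generated from the
prediction-model recursion itself (so the estimator is well-specified and
recovery is exact without noise), with an optional linear diuresis trend on
the instant-ratio responsiveness emulating the mobilization phase, plus an
alternative misspecified ``retention`` mechanism (delayed fluid
mobilization) for robustness probes.

All randomness flows from one integer seed through named substreams, so
regeneration is byte-identical and single components can be held fixed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .cohort import HourlyRecord, PatientProfile, PatientSeries
from .protocol import tmmu_adjust_rate, tmmu_schedule

__all__ = ["SimulationConfig", "GroundTruth", "generate_patient", "generate_cohorts"]

_STREAMS = ("weight", "tbsa", "age", "full", "start", "adjuster", "rate_noise", "uop_noise")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters of the synthetic cohort generator.

    Defaults emulate the derivation/validation populations: 13 + 24
    patients, weight 61.8 +/- 9.5 kg, TBSA uniform on 30.2-97.0%, an
    infusion-rate decay averaging ~308 mL/hr over the first day and ~228
    over the second, urine responsiveness starting near 0.21 and drifting
    upward (diuresis), and prediction-model coefficients
    (c1, c2, d1, d2) = (0.25, 0.8, 0.4, -0.39). Those c's put the
    recursion's stable urine/fluid operating ratio at 1 - (1 - c2)/c1 =
    0.2, close to the observed overall ratio, and keep the hour-to-hour
    feedback gain subcritical (c2 < 1) so trajectories do not run away.
    """

    n_derivation: int = 13
    n_validation: int = 24
    seed: int = 0
    hours: int = 48
    # covariates
    weight_mean: float = 61.8
    weight_sd: float = 9.5
    weight_bounds: tuple[float, float] = (40.0, 100.0)
    tbsa_range: tuple[float, float] = (30.2, 97.0)
    age_mean: float = 41.7
    age_sd: float = 13.9
    age_bounds: tuple[float, float] = (16.0, 60.0)
    full_thickness_frac_max: float = 0.7  # fraction of TBSA, uniform from 0
    # infusion-rate truth
    a1: float = 360.0
    a2: float = 0.0126
    b1: float = 0.492
    b2: float = 0.008
    adjuster_noise_sd: float = 0.08  # patient scatter around the adjuster line
    rate_noise_sd: float = 0.15  # lognormal sigma on hourly rates
    # urine-output truth
    c1: float = 0.25
    c2: float = 0.8
    d1: float = 0.4
    d2: float = -0.39
    uop_noise_sd: float = 5.0  # mL/hr
    resp0: float = 0.21  # initial instant-ratio responsiveness
    diuresis_slope: float = 0.002  # per-hour increase in responsiveness
    # mechanisms
    protocol: str = "model_truth"  # or "tmmu_rule_based"
    uop_mechanism: str = "model"  # or "retention" (misspecified probe)
    step_fraction: float = 0.25
    truncate_start: bool = False  # random admission delay uniform on 0-12 h

    def __post_init__(self) -> None:
        if self.n_derivation < 1 or self.n_validation < 0:
            raise ValueError("cohort sizes must be positive")
        for name in ("weight_sd", "age_sd", "adjuster_noise_sd", "rate_noise_sd", "uop_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.tbsa_range
        if not 0 < lo <= hi <= 100:
            raise ValueError(f"tbsa_range must lie within (0, 100], got {self.tbsa_range}")
        if self.protocol not in ("model_truth", "tmmu_rule_based"):
            raise ValueError(f"unknown protocol {self.protocol!r}")
        if self.uop_mechanism not in ("model", "retention"):
            raise ValueError(f"unknown uop_mechanism {self.uop_mechanism!r}")
        if self.diuresis_slope < 0:
            raise ValueError("diuresis_slope must be >= 0")
        if not 1 <= self.hours <= 48:
            raise ValueError("hours must be in 1..48")

    @property
    def design_adjuster_correlation(self) -> float:
        """The TBSA~factor Pearson r implied by slope and scatter."""
        sd_tbsa = (self.tbsa_range[1] - self.tbsa_range[0]) / np.sqrt(12.0)
        signal = self.b2 * sd_tbsa
        denom = np.hypot(signal, self.adjuster_noise_sd)
        return float(signal / denom) if denom > 0 else float("nan")


@dataclass
class GroundTruth:
    """The parameter set actually used to generate a pair of cohorts."""

    config: dict = field(default_factory=dict)
    design_adjuster_correlation: float = float("nan")

    @classmethod
    def from_config(cls, config: SimulationConfig) -> "GroundTruth":
        # normalize through JSON so the persisted form round-trips unchanged
        return cls(json.loads(json.dumps(asdict(config))), config.design_adjuster_correlation)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"config": self.config, "design_adjuster_correlation": self.design_adjuster_correlation},
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["config"], d["design_adjuster_correlation"])


@dataclass
class _Streams:
    """Named random substreams for one cohort."""

    rngs: dict

    @classmethod
    def for_cohort(cls, seed: int, cohort_index: int) -> "_Streams":
        return cls(
            {
                name: np.random.default_rng(np.random.SeedSequence([int(seed), cohort_index, i]))
                for i, name in enumerate(_STREAMS)
            }
        )

    def __getattr__(self, name):
        try:
            return self.rngs[name]
        except KeyError as exc:  # pragma: no cover
            raise AttributeError(name) from exc


def _truncated_normal(rng, mean, sd, lo, hi) -> float:
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mean, lo, hi))  # pragma: no cover


def _draw_profile(config: SimulationConfig, streams: _Streams, patient_id: str) -> tuple[PatientProfile, float]:
    weight = _truncated_normal(streams.weight, config.weight_mean, config.weight_sd, *config.weight_bounds)
    tbsa = float(streams.tbsa.uniform(*config.tbsa_range))
    age = _truncated_normal(streams.age, config.age_mean, config.age_sd, *config.age_bounds)
    full = float(streams.full.uniform(0.0, config.full_thickness_frac_max) * tbsa)
    start = int(streams.start.integers(0, 13)) if config.truncate_start else 0
    factor = config.b1 + config.b2 * tbsa + float(streams.adjuster.normal(0.0, config.adjuster_noise_sd))
    factor = max(factor, 0.1)
    profile = PatientProfile(
        patient_id=patient_id,
        weight=weight,
        tbsa=tbsa,
        age=age,
        full_thickness_tbsa=full,
        start_hour=float(start),
    )
    return profile, factor


def _generate_series(
    config: SimulationConfig,
    profile: PatientProfile,
    factor: float,
    rng_rate: np.random.Generator,
    rng_uop: np.random.Generator,
) -> PatientSeries:
    first_hour = int(profile.start_hour) + 1
    hours = list(range(first_hour, config.hours + 1))
    plan = tmmu_schedule(profile) if config.protocol == "tmmu_rule_based" else None

    records: list[HourlyRecord] = []
    cum_f = cum_u = 0.0
    uops: list[float] = []
    rates: list[float] = []
    prev_p1: float | None = None

    for idx, t in enumerate(hours):
        # --- infusion rate for hour t
        if config.protocol == "model_truth":
            rate = config.a1 * np.exp(-config.a2 * t) * factor
            if config.rate_noise_sd > 0:
                rate *= float(np.exp(rng_rate.normal(0.0, config.rate_noise_sd)))
        else:
            rate = plan.rate_at(t)
            if idx > 0:
                rate = tmmu_adjust_rate(rate, uops[-1], step_fraction=config.step_fraction)
        rate = float(rate)

        # --- urine output for hour t
        resp = config.resp0 + config.diuresis_slope * t
        if idx < 2 or config.uop_mechanism == "retention":
            if config.uop_mechanism == "retention" and idx >= 2:
                # misspecified: urine follows mobilized fluid, a lagged blend
                driver = 0.6 * rate + 0.4 * float(np.mean(rates[-3:]))
            else:
                driver = rate
            uop = resp * driver
            p1 = None
        else:
            t_prev = hours[idx - 1]
            ovr = cum_u / cum_f
            lt = ovr * (cum_f - cum_u) / t_prev
            inst = uops[-1] / rates[-1] + config.diuresis_slope * t_prev
            # the instant response scales with the systematic infusion
            # intensity for this burn size, not the hour's recorded rate
            # (whose fluctuations are treated as recording noise)
            base_t = config.a1 * np.exp(-config.a2 * t) * (config.b1 + config.b2 * profile.tbsa)
            p1 = config.c1 * lt + config.c2 * inst * base_t
            if prev_p1 is None:
                err = config.d2 * (uops[-1] - uops[-2])
            else:
                err = config.d1 * (prev_p1 - uops[-1]) + config.d2 * (uops[-1] - uops[-2])
            uop = p1 + err
        if config.uop_noise_sd > 0:
            uop += float(rng_uop.normal(0.0, config.uop_noise_sd))
        uop = max(0.0, float(uop))

        records.append(HourlyRecord(hour=t, infusion_rate=rate, uop=uop))
        cum_f += rate
        cum_u += uop
        rates.append(rate)
        uops.append(uop)
        prev_p1 = p1

    return PatientSeries(profile=profile, records=records)


def generate_patient(config: SimulationConfig, streams: _Streams, patient_id: str) -> PatientSeries:
    """Draw one patient's covariates and 48-hour trajectory."""
    profile, factor = _draw_profile(config, streams, patient_id)
    return _generate_series(config, profile, factor, streams.rate_noise, streams.uop_noise)


def _generate_cohort(config: SimulationConfig, n: int, cohort_index: int, prefix: str) -> list[PatientSeries]:
    streams = _Streams.for_cohort(config.seed, cohort_index)
    return [generate_patient(config, streams, f"{prefix}{i + 1:03d}") for i in range(n)]


def generate_cohorts(config: SimulationConfig | None = None, **overrides):
    """Generate disjoint derivation and validation cohorts.

    Returns ``(derivation, validation, ground_truth)``; sizes default to
    13 and 24 patients. Keyword overrides build a modified config.
    """
    if config is None:
        config = SimulationConfig(**overrides)
    elif overrides:
        config = SimulationConfig(**{**asdict(config), **overrides})
    derivation = _generate_cohort(config, config.n_derivation, 0, "D")
    validation = _generate_cohort(config, config.n_validation, 1, "V")
    return derivation, validation, GroundTruth.from_config(config)
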