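"""Empirical basic infusion-rate model.

The cohort-level infusion rate over the first 48 post-burn hours follows an
exponential decay

    Rate(t) = a1 * exp(-a2 * t),

and patient-level variation is captured by a linear adjusting function of
burn extent,

    Adjust_TBSA = b1 + b2 * TBSA,

where each patient's adjusting factor is their mean infusion rate over the
observed hours in 1-48 divided by the cohort mean. The basic infusion rate
for a patient is the product

    Base_Rate(t) = Rate(t) * Adjust_TBSA.

``BaseRateModel`` is built from a cohort and ``fit()`` returns a
``BaseRateResults`` carrying (a1, a2, b1, b2), the cohort mean rate, and fit
diagnostics; prediction, plotting and persistence hang off the results.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .cohort import PatientSeries

__all__ = [
    "DecayFit",
    "AdjusterFit",
    "fit_decay",
    "empirical_rate",
    "adjusting_factor",
    "fit_adjuster",
    "base_rate_at",
    "BaseRateModel",
    "BaseRateResults",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DecayFit:
    """Least-squares exponential decay coefficients and diagnostics."""

    a1: float
    a2: float
    rss: float
    n_points: int
    cov: np.ndarray | None = field(default=None, repr=False)

    @property
    def bse(self) -> np.ndarray:
        """Approximate standard errors of (a1, a2) from the fit covariance."""
        if self.cov is None:
            return np.array([np.nan, np.nan])
        return np.sqrt(np.diag(self.cov))


@dataclass(frozen=True)
class AdjusterFit:
    b1: float
    b2: float
    pearson_r: float
    p_value: float
    n_patients: int
    weight_coef: float | None = None  # optional body-weight term
    degenerate: bool = False


def empirical_rate(a1: float, a2: float, t) -> float | np.ndarray:
    """Cohort decay curve Rate(t) = a1 * exp(-a2 * t)."""
    return a1 * np.exp(-a2 * np.asarray(t, dtype=float))


def fit_decay(hours, rates) -> DecayFit:
    """Fit Rate(t) = a1 * exp(-a2 * t) by least squares on the rate scale.

    A log-linear regression of log(rate) on t supplies starting values, then
    a bounded trust-region least-squares refines them on the original scale
    (a1 > 0, a2 >= 0).

    Raises ``ValueError`` for fewer than 3 points or non-positive rates.
    """
    t = np.asarray(hours, dtype=float)
    y = np.asarray(rates, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("hours and rates must be 1-D of equal length")
    if t.size < 3:
        raise ValueError(f"need at least 3 points to fit the decay, got {t.size}")
    if np.any(y <= 0):
        raise ValueError("all rates must be positive (log-linear initialization)")

    slope, intercept = np.polyfit(t, np.log(y), 1)
    a1_0 = float(np.exp(intercept))
    a2_0 = float(max(-slope, 0.0))

    try:
        popt, pcov = optimize.curve_fit(
            lambda tt, a1, a2: a1 * np.exp(-a2 * tt),
            t,
            y,
            p0=(a1_0, a2_0),
            bounds=([1e-12, 0.0], [np.inf, np.inf]),
            maxfev=10000,
        )
    except RuntimeError as exc:  # pragma: no cover - pathological inputs
        raise RuntimeError(f"exponential decay fit did not converge: {exc}") from exc

    resid = y - empirical_rate(popt[0], popt[1], t)
    return DecayFit(
        a1=float(popt[0]),
        a2=float(popt[1]),
        rss=float(resid @ resid),
        n_points=int(t.size),
        cov=pcov,
    )


def adjusting_factor(patient_mean_rate: float, cohort_mean_rate: float) -> float:
    """Patient mean infusion rate over hours 1-48 divided by the cohort mean."""
    if cohort_mean_rate <= 0:
        raise ZeroDivisionError("cohort_mean_rate must be positive")
    return patient_mean_rate / cohort_mean_rate


def fit_adjuster(factors, tbsas, weights=None) -> AdjusterFit:
    """OLS line factor = b1 + b2 * TBSA, plus the Pearson r between the two.

    With ``weights`` (body weight, kg) given, an additional linear weight
    term is estimated; by default weight is excluded (its correlation with
    the adjusting factor is weak in this population).

    A cohort with constant factors has no usable correlation; the result is
    flagged ``degenerate`` with r = nan.
    """
    f = np.asarray(factors, dtype=float)
    x = np.asarray(tbsas, dtype=float)
    if f.shape != x.shape or f.ndim != 1:
        raise ValueError("factors and tbsas must be 1-D of equal length")
    if f.size < 3:
        raise ValueError(f"need at least 3 patients, got {f.size}")
    if np.var(x) == 0:
        raise ValueError("TBSA has zero variance; the adjuster slope is not identifiable")

    if weights is not None:
        w = np.asarray(weights, dtype=float)
        X = np.column_stack([np.ones_like(x), x, w])
    else:
        X = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(X, f, rcond=None)

    if np.var(f) == 0:
        return AdjusterFit(
            b1=float(coef[0]),
            b2=float(coef[1]),
            pearson_r=float("nan"),
            p_value=float("nan"),
            n_patients=int(f.size),
            weight_coef=float(coef[2]) if weights is not None else None,
            degenerate=True,
        )
    r, p = stats.pearsonr(x, f)
    return AdjusterFit(
        b1=float(coef[0]),
        b2=float(coef[1]),
        pearson_r=float(r),
        p_value=float(p),
        n_patients=int(f.size),
        weight_coef=float(coef[2]) if weights is not None else None,
    )


def base_rate_at(
    a1: float,
    a2: float,
    b1: float,
    b2: float,
    tbsa: float,
    t,
    adjuster_floor: float = 0.1,
):
    """Base_Rate(t) = Rate(t) * (b1 + b2*TBSA), with the adjuster floored.

    An extrapolated TBSA can push the linear adjuster to zero or below; it
    is clamped at ``adjuster_floor`` with a logged warning so the rate stays
    positive.
    """
    adj = b1 + b2 * tbsa
    if adj < adjuster_floor:
        logger.warning(
            "adjusting factor %.4f at TBSA %.1f%% below floor %.2f; clamped",
            adj,
            tbsa,
            adjuster_floor,
        )
        adj = adjuster_floor
    return empirical_rate(a1, a2, t) * adj


class BaseRateModel:
    """Basic infusion-rate model for a derivation cohort.

    Parameters
    ----------
    cohort : list of PatientSeries
        Derivation patients with hourly infusion records.
    decay_fit : {"cohort_mean", "pooled"}
        Fit the decay to the mean rate at each post-burn hour (default) or
        to the pooled patient-hours.
    min_hours : int
        Patients with fewer observed hours in 1-48 are excluded from the
        adjusting-factor regression (logged).
    include_weight : bool
        Add a body-weight term to the adjusting function.
    adjuster_floor : float
        Lower clamp on the evaluated adjusting factor.
    """

    def __init__(
        self,
        cohort: list[PatientSeries],
        decay_fit: str = "cohort_mean",
        min_hours: int = 12,
        include_weight: bool = False,
        adjuster_floor: float = 0.1,
    ):
        if decay_fit not in ("cohort_mean", "pooled"):
            raise ValueError(f"unknown decay_fit {decay_fit!r}")
        if not cohort:
            raise ValueError("cohort is empty")
        self.cohort = cohort
        self.decay_fit = decay_fit
        self.min_hours = min_hours
        self.include_weight = include_weight
        self.adjuster_floor = adjuster_floor

    @classmethod
    def from_dataframe(cls, patients: pd.DataFrame, hourly: pd.DataFrame, **kwargs) -> "BaseRateModel":
        from .io import cohort_from_frames

        return cls(cohort_from_frames(patients, hourly), **kwargs)

    def _mean_rate_curve(self) -> tuple[np.ndarray, np.ndarray]:
        """(hours, mean rate over patients observed at that hour) for 1..48."""
        frames = pd.concat([s.to_frame() for s in self.cohort], ignore_index=True)
        frames = frames[frames["hour"].between(1, 48)]
        grouped = frames.groupby("hour")["infusion_ml_hr"].mean()
        return grouped.index.to_numpy(dtype=float), grouped.to_numpy(dtype=float)

    def fit(self) -> "BaseRateResults":
        if self.decay_fit == "cohort_mean":
            hours, rates = self._mean_rate_curve()
        else:
            frames = pd.concat([s.to_frame() for s in self.cohort], ignore_index=True)
            frames = frames[frames["hour"].between(1, 48)]
            hours = frames["hour"].to_numpy(dtype=float)
            rates = frames["infusion_ml_hr"].to_numpy(dtype=float)
        decay = fit_decay(hours, rates)

        usable = [s for s in self.cohort if sum(1 <= r.hour <= 48 for r in s.records) >= self.min_hours]
        dropped = len(self.cohort) - len(usable)
        if dropped:
            logger.info("%d patients excluded from adjuster fit (< %d hours)", dropped, self.min_hours)
        if len(usable) < 1:
            raise ValueError("no patients with enough hours for the adjusting factor")
        patient_means = np.array([s.mean_rate(1, 48) for s in usable])
        cohort_mean = float(patient_means.mean())
        factors = patient_means / cohort_mean
        tbsas = np.array([s.profile.tbsa for s in usable])
        weights = np.array([s.profile.weight for s in usable]) if self.include_weight else None

        if len(usable) == 1:
            # single patient: factor is identically 1, no regression possible
            adjuster = AdjusterFit(1.0, 0.0, float("nan"), float("nan"), 1, degenerate=True)
        else:
            adjuster = fit_adjuster(factors, tbsas, weights=weights)

        return BaseRateResults(
            model=self,
            decay=decay,
            adjuster=adjuster,
            cohort_mean_rate=cohort_mean,
            factors=factors,
            factor_tbsas=tbsas,
            n_patients_used=len(usable),
        )


@dataclass
class BaseRateResults:
    """Fitted basic infusion-rate model."""

    model: BaseRateModel
    decay: DecayFit
    adjuster: AdjusterFit
    cohort_mean_rate: float
    factors: np.ndarray = field(repr=False)
    factor_tbsas: np.ndarray = field(repr=False)
    n_patients_used: int = 0

    @property
    def a1(self) -> float:
        return self.decay.a1

    @property
    def a2(self) -> float:
        return self.decay.a2

    @property
    def b1(self) -> float:
        return self.adjuster.b1

    @property
    def b2(self) -> float:
        return self.adjuster.b2

    def mean_rate(self, t):
        """Cohort-level Rate(t)."""
        return empirical_rate(self.a1, self.a2, t)

    def base_rate(self, tbsa: float, t):
        """Patient-level Base_Rate(t) = Rate(t) * Adjust_TBSA."""
        floor = self.model.adjuster_floor if self.model is not None else 0.1
        return base_rate_at(self.a1, self.a2, self.b1, self.b2, tbsa, t, adjuster_floor=floor)

    def to_dict(self) -> dict:
        return {
            "a1": self.a1,
            "a2": self.a2,
            "b1": self.b1,
            "b2": self.b2,
            "weight_coef": self.adjuster.weight_coef,
            "cohort_mean_rate": self.cohort_mean_rate,
            "decay_rss": self.decay.rss,
            "decay_n_points": self.decay.n_points,
            "adjuster_pearson_r": self.adjuster.pearson_r,
            "adjuster_p_value": self.adjuster.p_value,
            "n_patients_used": self.n_patients_used,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BaseRateResults":
        decay = DecayFit(
            a1=d["a1"], a2=d["a2"], rss=d.get("decay_rss", float("nan")),
            n_points=int(d.get("decay_n_points", 0)),
        )
        adjuster = AdjusterFit(
            b1=d["b1"], b2=d["b2"],
            pearson_r=d.get("adjuster_pearson_r", float("nan")),
            p_value=d.get("adjuster_p_value", float("nan")),
            n_patients=int(d.get("n_patients_used", 0)),
            weight_coef=d.get("weight_coef"),
        )
        return cls(
            model=None,  # type: ignore[arg-type]
            decay=decay,
            adjuster=adjuster,
            cohort_mean_rate=d["cohort_mean_rate"],
            factors=np.array([]),
            factor_tbsas=np.array([]),
            n_patients_used=int(d.get("n_patients_used", 0)),
        )

    def summary(self) -> str:
        se1, se2 = self.decay.bse
        lines = [
            "Basic infusion-rate model",
            "=" * 46,
            f"decay amplitude a1      {self.a1:12.4f} mL/hr  (se {se1:.3g})",
            f"decay constant  a2      {self.a2:12.6f} 1/hr   (se {se2:.3g})",
            f"adjuster intercept b1   {self.b1:12.4f}",
            f"adjuster slope     b2   {self.b2:12.6f} per %TBSA",
            f"cohort mean rate        {self.cohort_mean_rate:12.4f} mL/hr",
            f"TBSA~factor Pearson r   {self.adjuster.pearson_r:12.4f} (p={self.adjuster.p_value:.3g})",
            f"decay RSS               {self.decay.rss:12.4f} over {self.decay.n_points} points",
            f"patients in adjuster    {self.n_patients_used:12d}",
        ]
        if self.adjuster.weight_coef is not None:
            lines.insert(6, f"adjuster weight coef    {self.adjuster.weight_coef:12.6f} per kg")
        if self.adjuster.degenerate:
            lines.append("note: adjusting factors degenerate (no variation)")
        return "\n".join(lines)

    def plot_fit(self, ax=None):
        """Plot observed mean hourly rates against the fitted decay curve."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if self.model is not None:
            hours, rates = self.model._mean_rate_curve()
            ax.plot(hours, rates, "o", ms=4, label="cohort mean rate")
        tt = np.linspace(1, 48, 200)
        ax.plot(tt, self.mean_rate(tt), "-", label=f"{self.a1:.0f}·exp(−{self.a2:.4f}·t)")
        ax.set_xlabel("hours post-burn")
        ax.set_ylabel("infusion rate (mL/hr)")
        ax.legend()
        return ax
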