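"""Recursive one-step-ahead urine-output (UOP) prediction.

The predictor combines two urine-production ratios that summarise a burn
patient's response to fluid over different horizons:

* overall ratio   OR(t) = Σ UOP / Σ Fluid_Rate   (cumulative since injury),
  the long-term conversion of infused fluid into urine;
* instant ratio   IR(t) = UOP(t) / Fluid_Rate(t), the immediate hourly
  response.

The coming hour's UOP is estimated from the basic infusion rate B(t+1) as

    UOP_Pred(t+1) = c1 * OR(t) * (ΣFluid − ΣUOP)/t
                  + c2 * IR(t) * B(t+1)
                  + Pred_Err(t+1)

with a recursive error-feedback term driven by the previous hour's
prediction error and the change in measured UOP:

    Pred_Err(t+1) = d1 * (UOP_Pred(t) − UOP(t)) + d2 * (UOP(t) − UOP(t−1)).

Two hours of history are required before the first prediction; that first
prediction has no prior prediction error, so its feedback term uses the
d2 (UOP-change) part only.

Conventions that the source model leaves open are configurable:

* ``eq_parse`` — the long-term term's ratio may be read as the current
  overall ratio (default, ``"current"``), the previous hour's ratio
  (``"lagged"``), or the reciprocal (``"inverse"``).
* ``error_feedback`` — the prediction whose error is fed back can be the
  regression part alone (default, ``"regression"``; the feedback then
  corrects the c-term prediction and all four coefficients are identifiable
  even from noise-free data) or the full corrected prediction
  (``"full"``, the literal reading).

``UrineOutputModel`` fits (c1, c2, d1, d2) on a derivation cohort
sequentially: the c's by (by default zero-intercept) least squares of
next-hour UOP on the two ratio terms, the d's by regressing the residuals
on the previous prediction error and the UOP change; the pair then seeds a
joint nonlinear least-squares refinement (the residual is bilinear in the
coefficients). ``max_iter=1`` gives the plain two-stage fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

from .base_rate import BaseRateResults
from .cohort import PatientSeries

__all__ = [
    "UndefinedRatioError",
    "MissingHistoryError",
    "overall_ratio",
    "instant_ratio",
    "pred_err",
    "PredictionState",
    "predict_components",
    "predict_uop",
    "UrineOutputModel",
    "UrineOutputResults",
    "PredictionRow",
    "PredictionTrace",
    "run_predictions",
]

logger = logging.getLogger(__name__)

EQ_PARSES = ("current", "lagged", "inverse")
FEEDBACKS = ("regression", "full")


class UndefinedRatioError(ValueError):
    """A production ratio is undefined (zero denominator); defer prediction."""


class MissingHistoryError(ValueError):
    """Fewer than two observed hours; use the base rate without prediction."""


def overall_ratio(cum_uop: float, cum_fluid: float) -> float:
    """Cumulative urine divided by cumulative fluid infused."""
    if cum_fluid <= 0:
        raise UndefinedRatioError("cumulative fluid is zero; overall ratio undefined")
    return cum_uop / cum_fluid


def instant_ratio(uop_t: float, fluid_rate_t: float) -> float:
    """Current hour's urine output divided by the hour's infusion rate."""
    if fluid_rate_t <= 0:
        raise UndefinedRatioError("zero infusion this hour; instant ratio undefined")
    return uop_t / fluid_rate_t


def pred_err(d1: float, d2: float, last_pred: float, last_uop: float, prev_uop: float) -> float:
    """Error-feedback term d1*(UOP_Pred(t) − UOP(t)) + d2*(UOP(t) − UOP(t−1))."""
    return d1 * (last_pred - last_uop) + d2 * (last_uop - prev_uop)


@dataclass
class PredictionState:
    """Running per-patient state, advanced once per observed hour in order."""

    t: int | None = None  # last observed post-burn hour
    cum_fluid: float = 0.0
    cum_uop: float = 0.0
    n_obs: int = 0
    last_uop: float | None = None
    prev_uop: float | None = None
    _instant: float | None = None
    _prev_overall: float | None = None
    _pending_p1: float | None = None
    _pending_full: float | None = None
    err_input_p1: float | None = None  # regression-part prediction error at t
    err_input_full: float | None = None  # full prediction error at t

    @property
    def overall_ratio(self) -> float:
        return overall_ratio(self.cum_uop, self.cum_fluid)

    @property
    def prev_overall_ratio(self) -> float | None:
        return self._prev_overall

    @property
    def instant_ratio(self) -> float:
        if self._instant is None:
            raise UndefinedRatioError("no infused hour seen yet; instant ratio undefined")
        return self._instant

    def register_prediction(self, p1: float, full: float) -> None:
        """Record the predictions just issued for the next hour, for feedback."""
        self._pending_p1 = p1
        self._pending_full = full

    def observe(self, hour: int, rate: float, uop: float) -> None:
        """Fold in the hour's actual infusion rate and measured UOP."""
        if self.t is not None and hour != self.t + 1:
            raise ValueError(f"non-contiguous hour {hour} after {self.t}; split the series")
        if self.cum_fluid > 0:
            self._prev_overall = self.cum_uop / self.cum_fluid
        self.t = int(hour)
        self.n_obs += 1
        self.cum_fluid += rate
        self.cum_uop += uop
        self.prev_uop = self.last_uop
        self.last_uop = float(uop)
        if rate > 0:
            self._instant = uop / rate
        elif self._instant is not None:
            logger.warning("zero infusion at hour %d; instant ratio carried forward", hour)
        if self._pending_p1 is not None:
            self.err_input_p1 = self._pending_p1 - uop
            self.err_input_full = (self._pending_full if self._pending_full is not None else self._pending_p1) - uop
        else:
            self.err_input_p1 = None
            self.err_input_full = None
        self._pending_p1 = None
        self._pending_full = None


def _long_term_term(state: PredictionState, eq_parse: str) -> float:
    """Long-term regressor: retained fluid per hour scaled by the overall ratio."""
    if state.t is None or state.t <= 0:
        raise MissingHistoryError("no observed hours")
    retained_per_hour = (state.cum_fluid - state.cum_uop) / state.t
    if eq_parse == "current":
        return state.overall_ratio * retained_per_hour
    if eq_parse == "lagged":
        ratio = state.prev_overall_ratio
        if ratio is None:
            ratio = state.overall_ratio
        return ratio * retained_per_hour
    if eq_parse == "inverse":
        ratio = state.overall_ratio
        if ratio == 0:
            raise UndefinedRatioError("overall ratio is zero; inverse parse undefined")
        return retained_per_hour / ratio
    raise ValueError(f"unknown eq_parse {eq_parse!r}")


def _feedback_term(state: PredictionState, d1: float, d2: float, error_feedback: str) -> float:
    if state.last_uop is None or state.prev_uop is None:
        raise MissingHistoryError("two hours of UOP history required before predicting")
    err_in = state.err_input_p1 if error_feedback == "regression" else state.err_input_full
    duop = state.last_uop - state.prev_uop
    if err_in is None:
        # first prediction of a run: no prior prediction error exists
        return d2 * duop
    return d1 * err_in + d2 * duop


def predict_components(results: "UrineOutputResults", state: PredictionState):
    """Decompose the prediction as intercept + slope * rate.

    Returns ``(intercept, slope, feedback)`` with
    ``UOP_Pred(rate) = intercept + slope * rate`` (before the floor at 0);
    the affine dependence on the coming hour's rate is what the controller
    inverts. ``feedback`` is the Pred_Err component of the intercept.
    """
    lt = _long_term_term(state, results.eq_parse)
    fb = _feedback_term(state, results.d1, results.d2, results.error_feedback)
    slope = results.c2 * state.instant_ratio
    intercept = results.c0 + results.c1 * lt + fb
    return intercept, slope, fb


def predict_uop(results: "UrineOutputResults", state: PredictionState, base_rate_next: float) -> float:
    """One-step-ahead UOP prediction at the given coming-hour rate, floored at 0."""
    if base_rate_next < 0:
        raise ValueError("base_rate_next must be >= 0")
    intercept, slope, _ = predict_components(results, state)
    return max(0.0, intercept + slope * base_rate_next)


# ---------------------------------------------------------------------------
# fitting


@dataclass
class _FitRows:
    """Flattened regression rows across all patients/segments."""

    lt: np.ndarray  # long-term regressor
    ib: np.ndarray  # instant_ratio * base_rate regressor
    duop: np.ndarray  # UOP(t) - UOP(t-1)
    y: np.ndarray  # UOP(t+1), the target
    prev_row: np.ndarray  # index of the previous prediction row in the same segment, or -1


class UrineOutputModel:
    """UOP prediction model to be fitted on a derivation cohort.

    Parameters
    ----------
    cohort : list of PatientSeries
        Derivation patients; each contiguous run of >= 4 hours contributes
        regression rows (two burn-in hours, then one row per later hour).
    base_results : BaseRateResults
        Fitted basic infusion-rate model supplying Base_Rate(t+1).
    eq_parse, error_feedback : str
        Structural conventions, see the module docstring.
    fit_intercept : bool
        Allow a constant c0 in the c-stage (diagnostic; the model proper
        has none).
    max_iter, tol : int, float
        The sequential two-stage estimates seed a joint Gauss-Newton
        refinement of all four coefficients; ``max_iter=1`` keeps the
        plain two-stage fit.
    """

    def __init__(
        self,
        cohort: list[PatientSeries],
        base_results: BaseRateResults,
        eq_parse: str = "current",
        error_feedback: str = "regression",
        fit_intercept: bool = False,
        max_iter: int = 50,
        tol: float = 1e-12,
    ):
        if eq_parse not in EQ_PARSES:
            raise ValueError(f"eq_parse must be one of {EQ_PARSES}")
        if error_feedback not in FEEDBACKS:
            raise ValueError(f"error_feedback must be one of {FEEDBACKS}")
        usable = [s for s in cohort if any(len(seg) >= 4 for seg in s.segments())]
        if len(usable) < 2:
            raise ValueError("need at least 2 patients with >= 4 contiguous hours")
        self.cohort = cohort
        self.base_results = base_results
        self.eq_parse = eq_parse
        self.error_feedback = error_feedback
        self.fit_intercept = fit_intercept
        self.max_iter = max_iter
        self.tol = tol

    @classmethod
    def from_dataframe(cls, patients: pd.DataFrame, hourly: pd.DataFrame, base_results: BaseRateResults, **kwargs):
        from .io import cohort_from_frames

        return cls(cohort_from_frames(patients, hourly), base_results, **kwargs)

    def _build_rows(self) -> _FitRows:
        lt, ib, duop, y, prev = [], [], [], [], []
        for series in self.cohort:
            tbsa = series.profile.tbsa
            for seg in series.segments():
                if len(seg) < 3:
                    continue
                state = PredictionState()
                last_row = -1
                for i, rec in enumerate(seg):
                    if i >= 2:
                        try:
                            lt_i = _long_term_term(state, self.eq_parse)
                            ir = state.instant_ratio
                        except UndefinedRatioError:
                            logger.warning(
                                "undefined ratio before hour %d of %s; row skipped",
                                rec.hour,
                                series.profile.patient_id,
                            )
                            state.observe(rec.hour, rec.infusion_rate, rec.uop)
                            last_row = -1
                            continue
                        b_next = float(self.base_results.base_rate(tbsa, rec.hour))
                        lt.append(lt_i)
                        ib.append(ir * b_next)
                        duop.append(state.last_uop - state.prev_uop)
                        y.append(rec.uop)
                        prev.append(last_row)
                        last_row = len(y) - 1
                    state.observe(rec.hour, rec.infusion_rate, rec.uop)
        if len(y) < 4:
            raise ValueError(f"only {len(y)} usable regression rows; need >= 4")
        return _FitRows(
            lt=np.array(lt), ib=np.array(ib), duop=np.array(duop),
            y=np.array(y), prev_row=np.array(prev, dtype=int),
        )

    def fit(self) -> "UrineOutputResults":
        rows = self._build_rows()
        X = np.column_stack([rows.lt, rows.ib])
        if self.fit_intercept:
            X = np.column_stack([np.ones(len(rows.y)), X])
        cond = np.linalg.cond(X)
        if cond > 1e10:
            raise np.linalg.LinAlgError(
                f"long-term and instant regressors are collinear (condition number {cond:.3g})"
            )

        # shifted copies for the feedback chain: row i sees the regressors and
        # target of its previous prediction row (zero where none exists)
        has_prev_mask = rows.prev_row >= 0
        X_prev = np.zeros_like(X)
        X_prev[has_prev_mask] = X[rows.prev_row[has_prev_mask]]
        y_prev = np.zeros_like(rows.y)
        y_prev[has_prev_mask] = rows.y[rows.prev_row[has_prev_mask]]

        def err_regressor(c: np.ndarray) -> np.ndarray:
            """Previous row's regression-part prediction error, 0 for first rows."""
            return X_prev @ c - y_prev

        # Stage 1/2: plain sequential fit (c's on the ratio terms, d's on
        # the residuals against the previous prediction error and the UOP
        # change).
        c, *_ = np.linalg.lstsq(X, rows.y, rcond=None)
        D0 = np.column_stack([err_regressor(c), rows.duop])
        d, *_ = np.linalg.lstsq(D0, rows.y - X @ c, rcond=None)
        converged = True

        # The full residual y - Xc - d1*(X_prev c - y_prev) - d2*duop is
        # bilinear in (c, d): the two-stage estimates seed a joint
        # Gauss-Newton refinement, whose solution is exact (zero residual)
        # on data generated by the model itself. max_iter=1 keeps the plain
        # two-stage fit.
        if self.max_iter > 1:
            nc = X.shape[1]

            def residual(theta):
                cc, dd = theta[:nc], theta[nc:]
                return rows.y - X @ cc - dd[0] * (X_prev @ cc - y_prev) - dd[1] * rows.duop

            def jacobian(theta):
                cc, dd = theta[:nc], theta[nc:]
                return -np.column_stack(
                    [X + dd[0] * X_prev, X_prev @ cc - y_prev, rows.duop]
                )

            sol = least_squares(
                residual,
                np.concatenate([c, d]),
                jac=jacobian,
                method="lm",
                xtol=self.tol,
                ftol=self.tol,
                gtol=self.tol,
                max_nfev=200 * self.max_iter,
            )
            c, d = sol.x[:nc], sol.x[nc:]
            converged = bool(sol.status > 0)
            if not converged:
                logger.warning("joint coefficient refinement did not converge: %s", sol.message)

        # diagnostics at the final coefficients
        x1 = err_regressor(c)
        D = np.column_stack([x1, rows.duop])
        fitted = X @ c + D @ d
        resid = rows.y - fitted
        tss = float(np.sum((rows.y - rows.y.mean()) ** 2))
        rss = float(resid @ resid)
        r_squared = 1.0 - rss / tss if tss > 0 else float("nan")
        n, k = len(rows.y), X.shape[1] + 2
        sigma2 = rss / max(n - k, 1)
        bse_c = np.sqrt(np.diag(sigma2 * np.linalg.pinv(X.T @ X)))
        bse_d = np.sqrt(np.diag(sigma2 * np.linalg.pinv(D.T @ D)))

        # correlations motivating the feedback term: stage-1 residual vs its
        # own lag, and vs the UOP rate change
        e1 = rows.y - X @ c
        has_prev = rows.prev_row >= 0
        if has_prev.sum() >= 3 and np.std(e1[has_prev]) > 0 and np.std(e1[rows.prev_row[has_prev]]) > 0:
            r_lag = float(stats.pearsonr(e1[rows.prev_row[has_prev]], e1[has_prev])[0])
        else:
            r_lag = float("nan")
        if np.std(rows.duop) > 0 and np.std(e1) > 0:
            r_duop = float(stats.pearsonr(rows.duop, e1)[0])
        else:
            r_duop = float("nan")

        if self.fit_intercept:
            c0, c1, c2 = (float(v) for v in c)
            bse = {"c0": bse_c[0], "c1": bse_c[1], "c2": bse_c[2], "d1": bse_d[0], "d2": bse_d[1]}
        else:
            c0, (c1, c2) = 0.0, (float(c[0]), float(c[1]))
            bse = {"c1": bse_c[0], "c2": bse_c[1], "d1": bse_d[0], "d2": bse_d[1]}

        if c2 == 0:
            logger.warning("fitted c2 = 0; the controller inversion is not available")

        return UrineOutputResults(
            model=self,
            c1=c1,
            c2=c2,
            d1=float(d[0]),
            d2=float(d[1]),
            c0=c0,
            eq_parse=self.eq_parse,
            error_feedback=self.error_feedback,
            n_obs=n,
            r_squared=r_squared,
            rss=rss,
            bse=bse,
            resid_lag_corr=r_lag,
            resid_duop_corr=r_duop,
            converged=converged,
            condition_number=float(cond),
        )


@dataclass
class UrineOutputResults:
    """Fitted UOP prediction coefficients with diagnostics."""

    model: UrineOutputModel | None
    c1: float
    c2: float
    d1: float
    d2: float
    c0: float = 0.0
    eq_parse: str = "current"
    error_feedback: str = "regression"
    n_obs: int = 0
    r_squared: float = float("nan")
    rss: float = float("nan")
    bse: dict = field(default_factory=dict)
    resid_lag_corr: float = float("nan")
    resid_duop_corr: float = float("nan")
    converged: bool = True
    condition_number: float = float("nan")

    def __post_init__(self) -> None:
        for name in ("c1", "c2", "d1", "d2", "c0"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"coefficient {name} is not finite")
        if self.c2 == 0:
            logger.warning("c2 = 0: predictions do not respond to the rate; inversion unavailable")

    def predict(self, state: PredictionState, base_rate_next: float) -> float:
        return predict_uop(self, state, base_rate_next)

    def to_dict(self) -> dict:
        return {
            "c1": self.c1, "c2": self.c2, "d1": self.d1, "d2": self.d2, "c0": self.c0,
            "eq_parse": self.eq_parse, "error_feedback": self.error_feedback,
            "n_obs": self.n_obs, "r_squared": self.r_squared, "rss": self.rss,
            "resid_lag_corr": self.resid_lag_corr, "resid_duop_corr": self.resid_duop_corr,
            "converged": self.converged, "condition_number": self.condition_number,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "UrineOutputResults":
        return cls(
            model=None,
            c1=d["c1"], c2=d["c2"], d1=d["d1"], d2=d["d2"], c0=d.get("c0", 0.0),
            eq_parse=d.get("eq_parse", "current"),
            error_feedback=d.get("error_feedback", "regression"),
            n_obs=int(d.get("n_obs", 0)),
            r_squared=d.get("r_squared", float("nan")),
            rss=d.get("rss", float("nan")),
            resid_lag_corr=d.get("resid_lag_corr", float("nan")),
            resid_duop_corr=d.get("resid_duop_corr", float("nan")),
            converged=bool(d.get("converged", True)),
            condition_number=d.get("condition_number", float("nan")),
        )

    def summary(self) -> str:
        lines = [
            "Urine-output prediction model",
            "=" * 46,
            f"long-term coef   c1   {self.c1:12.6f}  (se {self.bse.get('c1', float('nan')):.3g})",
            f"instant coef     c2   {self.c2:12.6f}  (se {self.bse.get('c2', float('nan')):.3g})",
            f"error feedback   d1   {self.d1:12.6f}  (se {self.bse.get('d1', float('nan')):.3g})",
            f"UOP-change coef  d2   {self.d2:12.6f}  (se {self.bse.get('d2', float('nan')):.3g})",
            f"observations          {self.n_obs:12d}",
            f"R-squared             {self.r_squared:12.4f}",
            f"residual lag corr     {self.resid_lag_corr:12.4f}",
            f"residual dUOP corr    {self.resid_duop_corr:12.4f}",
            f"parse / feedback      {self.eq_parse} / {self.error_feedback}",
        ]
        if self.c0:
            lines.insert(2, f"intercept        c0   {self.c0:12.6f}")
        if not self.converged:
            lines.append("warning: backfitting did not converge")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# one-step-ahead replay over a cohort


@dataclass(frozen=True)
class PredictionRow:
    hour: int
    uop_pred: float
    pred_err_term: float
    uop_actual: float
    rate_used: float
    in_range: bool | None = None


@dataclass
class PredictionTrace:
    """Per-patient one-step-ahead predictions (from the 3rd observed hour on)."""

    patient_id: str
    rows: list[PredictionRow] = field(default_factory=list)

    @property
    def n_predictions(self) -> int:
        return len(self.rows)

    @property
    def preds(self) -> np.ndarray:
        return np.array([r.uop_pred for r in self.rows])

    @property
    def actuals(self) -> np.ndarray:
        return np.array([r.uop_actual for r in self.rows])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": self.patient_id,
                "hour": [r.hour for r in self.rows],
                "uop_pred": [r.uop_pred for r in self.rows],
                "pred_err_term": [r.pred_err_term for r in self.rows],
                "uop_actual": [r.uop_actual for r in self.rows],
                "rate_used": [r.rate_used for r in self.rows],
                "in_range": [r.in_range for r in self.rows],
            }
        )


def run_predictions(
    cohort: list[PatientSeries],
    base_results: BaseRateResults,
    uop_results: UrineOutputResults,
    target_range=None,
) -> list[PredictionTrace]:
    """One-step-ahead predictions for every patient hour after the burn-in.

    The state is updated each hour with the *actual* infusion rate and
    measured UOP; a gap in the hourly records splits the series and the
    two-hour burn-in is re-applied to the new segment (logged).
    """
    traces = []
    for series in cohort:
        trace = PredictionTrace(series.profile.patient_id)
        segments = series.segments()
        if len(segments) > 1:
            logger.warning(
                "patient %s: %d gaps in hourly records; burn-in re-applied per segment",
                series.profile.patient_id,
                len(segments) - 1,
            )
        for seg in segments:
            state = PredictionState()
            for i, rec in enumerate(seg):
                if i >= 2:
                    try:
                        intercept, slope, fb = predict_components(uop_results, state)
                    except (UndefinedRatioError, MissingHistoryError) as exc:
                        logger.warning(
                            "patient %s hour %d: %s; prediction deferred",
                            series.profile.patient_id,
                            rec.hour,
                            exc,
                        )
                        state.observe(rec.hour, rec.infusion_rate, rec.uop)
                        continue
                    b_next = float(base_results.base_rate(series.profile.tbsa, rec.hour))
                    pred = max(0.0, intercept + slope * b_next)
                    p1 = (intercept - fb) + slope * b_next
                    in_range = None
                    if target_range is not None:
                        in_range = bool(target_range.lower <= pred <= target_range.upper)
                    trace.rows.append(
                        PredictionRow(rec.hour, pred, fb, rec.uop, rec.infusion_rate, in_range)
                    )
                    state.register_prediction(p1, pred)
                state.observe(rec.hour, rec.infusion_rate, rec.uop)
        traces.append(trace)
    return traces
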