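"""Interrupted time-series analysis by segmented linear regression.

Monthly outcome series (percentage of iv prescriptions exceeding 72 h, or
median iv duration in days) are modelled as

    y_t = b0 + b1*t + b2*post_t + b3*(t - t_break)*post_t + e_t

with ``post_t = 1`` for periods at or after the break (the first month of
the intervention).  The three quantities of interest are the
pre-intervention slope ``b1``, the change in level at the break ``b2``
(the immediate impact), and the post-intervention slope ``b1 + b3`` (the
long-term trend after the intervention); the standard error of the latter
combines var(b1), var(b3) and their covariance.

A controlled analysis fits both arms jointly with full arm interactions;
the intervention-minus-control differences in pre-slope, level change and
post-slope are the interaction coefficients (and, for the post-slope, a
linear combination of two of them).

Estimation is ordinary least squares (an AR(1) option is available behind
a flag); p-values are two-sided t tests on the residual degrees of freedom.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from datetime import date, datetime, timedelta
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .records import Cohort, MedicationOrder, Route, WardGroup, duration_hours

__all__ = [
    "Outcome",
    "MonthlyPoint",
    "monthly_series",
    "series_values",
    "Estimate",
    "SegmentedITS",
    "SegmentedITSResults",
    "ControlledITS",
    "ControlledITSResults",
    "plot_its",
]


class Outcome(str, enum.Enum):
    PCT_OVER_72H = "pct_over_72h"
    MEDIAN_DURATION = "median_duration"


@dataclass(frozen=True)
class MonthlyPoint:
    """One aggregated period observation for one arm."""

    period_index: int
    arm: WardGroup
    pct_over_72h: float
    median_duration_days: float
    n_orders: int

    def __post_init__(self) -> None:
        if self.n_orders > 0 and not (0.0 <= self.pct_over_72h <= 100.0):
            raise ValueError("pct_over_72h must be within [0, 100]")
        if self.n_orders < 0:
            raise ValueError("n_orders must be non-negative")


def _month_starts(window_start: date, n_months: int) -> list[date]:
    first = window_start.replace(day=1)
    periods = pd.period_range(start=first, periods=n_months + 1, freq="M")
    return [p.start_time.date() for p in periods]


def monthly_series(
    orders: Iterable[MedicationOrder],
    arm: WardGroup,
    window: tuple[date, date],
    n_months: int | None = None,
) -> list[MonthlyPoint]:
    """Aggregate iv orders of one arm into calendar-month outcome points.

    Each iv order is attributed to the month of its *start* (its outcome is
    credited to the conditions under which it was initiated).  Open orders
    are censored at the window end.  ``pct_over_72h`` uses a strict
    inequality: a duration of exactly 72.0 h does not count.  Months with
    zero orders yield NaN outcomes and are dropped from regression input by
    :func:`series_values`.
    """
    arm = WardGroup(arm)
    sel = [o for o in orders if o.route is Route.IV and o.ward_group is arm]
    if not sel:
        raise ValueError(f"no iv orders found for arm {arm.value!r}")
    lo, hi = window
    if n_months is None:
        n_months = (hi.year - lo.year) * 12 + (hi.month - lo.month) + 1
    edges = _month_starts(lo, n_months)
    end_dt = datetime.combine(hi, datetime.max.time())
    durations: list[list[float]] = [[] for _ in range(n_months)]
    for o in sel:
        day = o.start.date()
        idx = (day.year - edges[0].year) * 12 + (day.month - edges[0].month)
        if not 0 <= idx < n_months:
            raise ValueError(
                f"order {o.order_id!r} starts outside the {n_months}-month calendar"
            )
        durations[idx].append(duration_hours(o, end_dt))
    points = []
    for t, durs in enumerate(durations, start=1):
        if durs:
            arr = np.asarray(durs)
            pct = 100.0 * float(np.mean(arr > 72.0))
            med = float(np.median(arr)) / 24.0
            n = len(durs)
        else:
            pct, med, n = float("nan"), float("nan"), 0
        points.append(MonthlyPoint(t, arm, pct, med, n))
    return points


def series_values(
    points: Sequence[MonthlyPoint], outcome: Outcome | str = Outcome.PCT_OVER_72H
) -> tuple[np.ndarray, np.ndarray]:
    """(t, y) regression arrays for one outcome, skipping empty months."""
    outcome = Outcome(outcome)
    t, y = [], []
    for p in points:
        if p.n_orders == 0:
            continue
        t.append(p.period_index)
        y.append(
            p.pct_over_72h if outcome is Outcome.PCT_OVER_72H else p.median_duration_days
        )
    return np.asarray(t, dtype=float), np.asarray(y, dtype=float)


class Estimate(NamedTuple):
    """Point estimate with its standard error and two-sided p-value."""

    value: float
    se: float
    pvalue: float

    def __str__(self) -> str:
        return f"{self.value:.2f} ({self.se:.2f}), p={self.pvalue:.3f}"


def _design(t: np.ndarray, break_index: int) -> np.ndarray:
    post = (t >= break_index).astype(float)
    return np.column_stack([np.ones_like(t), t, post, (t - break_index) * post])


class SegmentedITS:
    """Single-arm segmented-regression model.

    Parameters
    ----------
    y : array-like
        Outcome values, one per period.
    break_index : int
        Period index (1-based) of the first post-intervention month.
    t : array-like, optional
        Period indices; defaults to ``1..len(y)``.  Pass explicitly when
        empty months were dropped.
    """

    def __init__(self, y, break_index: int, t=None):
        self.y = np.asarray(y, dtype=float)
        if t is None:
            t = np.arange(1, len(self.y) + 1, dtype=float)
        self.t = np.asarray(t, dtype=float)
        if self.t.shape != self.y.shape:
            raise ValueError("t and y must have the same length")
        if np.any(np.isnan(self.y)):
            raise ValueError("y contains NaN; drop empty periods first")
        self.break_index = int(break_index)
        n_pre = int(np.sum(self.t < self.break_index))
        n_post = int(np.sum(self.t >= self.break_index))
        if n_pre < 3 or n_post < 3:
            raise ValueError(
                f"need >=3 points on each side of the break (got {n_pre} pre, {n_post} post)"
            )

    @classmethod
    def from_monthly_points(
        cls,
        points: Sequence[MonthlyPoint],
        break_index: int,
        outcome: Outcome | str = Outcome.PCT_OVER_72H,
    ) -> "SegmentedITS":
        t, y = series_values(points, outcome)
        return cls(y, break_index, t=t)

    def fit(self, ar1: bool = False) -> "SegmentedITSResults":
        X = _design(self.t, self.break_index)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("rank-deficient design matrix (degenerate period indices)")
        if ar1:
            model = sm.GLSAR(self.y, X, rho=1)
            res = model.iterative_fit(maxiter=8)
        else:
            res = sm.OLS(self.y, X).fit()
        return SegmentedITSResults(self, res)


class SegmentedITSResults:
    """Fitted single-arm segmented regression.

    Exposes the three reporting quantities (``pre_slope``,
    ``level_change``, ``post_slope``) as :class:`Estimate` tuples, plus the
    raw coefficient vector and covariance for diagnostics.
    """

    def __init__(self, model: SegmentedITS, res):
        self.model = model
        self._res = res
        self.params = np.asarray(res.params)
        self.cov_params = np.asarray(res.cov_params())
        self.df_resid = int(res.df_resid)
        self.n_points = len(model.y)
        self.break_index = model.break_index
        self.residual_variance = float(res.scale)

    def _coef(self, i: int) -> Estimate:
        return Estimate(
            float(self.params[i]),
            float(np.sqrt(self.cov_params[i, i])),
            float(self._res.pvalues[i]),
        )

    @property
    def pre_slope(self) -> Estimate:
        return self._coef(1)

    @property
    def level_change(self) -> Estimate:
        return self._coef(2)

    @property
    def slope_change(self) -> Estimate:
        """b3: the change in slope at the break (post minus pre trend)."""
        return self._coef(3)

    @property
    def post_slope(self) -> Estimate:
        """b1 + b3 with SE from var(b1) + var(b3) + 2 cov(b1, b3)."""
        tt = self._res.t_test(np.array([0.0, 1.0, 0.0, 1.0]))
        return Estimate(
            float(np.squeeze(tt.effect)),
            float(np.squeeze(tt.sd)),
            float(np.squeeze(tt.pvalue)),
        )

    def predicted(self, t=None) -> np.ndarray:
        t = self.model.t if t is None else np.asarray(t, dtype=float)
        return _design(t, self.break_index) @ self.params

    def to_dict(self) -> dict:
        return {
            name: {"estimate": e.value, "se": e.se, "p": e.pvalue}
            for name, e in [
                ("pre_slope", self.pre_slope),
                ("level_change", self.level_change),
                ("post_slope", self.post_slope),
                ("slope_change", self.slope_change),
            ]
        }

    def summary(self) -> str:
        lines = [
            "Segmented interrupted time-series regression (OLS)",
            f"  periods: {self.n_points}   break at t={self.break_index}   "
            f"df_resid: {self.df_resid}   resid var: {self.residual_variance:.4g}",
            f"  pre-intervention slope : {self.pre_slope}",
            f"  change in level        : {self.level_change}",
            f"  post-intervention slope: {self.post_slope}",
            f"  change in slope        : {self.slope_change}",
        ]
        return "\n".join(lines)


class ControlledITS:
    """Two-arm (intervention vs control) segmented-regression model.

    Fits a joint OLS model with an arm main effect and arm interactions
    with trend, level and post-trend terms; the arm-interaction
    coefficients estimate the intervention-minus-control differences.
    """

    def __init__(self, y_intervention, y_control, break_index: int,
                 t_intervention=None, t_control=None):
        self.intervention = SegmentedITS(y_intervention, break_index, t=t_intervention)
        self.control = SegmentedITS(y_control, break_index, t=t_control)
        if len(self.intervention.y) != len(self.control.y):
            raise ValueError(
                "intervention and control series must cover the same periods "
                f"(got {len(self.intervention.y)} vs {len(self.control.y)})"
            )
        self.break_index = int(break_index)

    @classmethod
    def from_monthly_points(
        cls,
        points_by_arm: Mapping[WardGroup, Sequence[MonthlyPoint]],
        break_index: int,
        outcome: Outcome | str = Outcome.PCT_OVER_72H,
    ) -> "ControlledITS":
        ti, yi = series_values(points_by_arm[WardGroup.INTERVENTION], outcome)
        tc, yc = series_values(points_by_arm[WardGroup.CONTROL], outcome)
        return cls(yi, yc, break_index, t_intervention=ti, t_control=tc)

    def fit(self) -> "ControlledITSResults":
        mi, mc = self.intervention, self.control
        t = np.concatenate([mi.t, mc.t])
        y = np.concatenate([mi.y, mc.y])
        g = np.concatenate([np.ones_like(mi.t), np.zeros_like(mc.t)])
        base = _design(t, self.break_index)
        X = np.column_stack([base, g[:, None] * base])  # 8 columns
        joint = sm.OLS(y, X).fit()
        return ControlledITSResults(self, joint, mi.fit(), mc.fit())


class ControlledITSResults:
    """Per-arm fits plus between-arm difference estimates.

    The per-arm coefficient estimates from the fully interacted joint model
    coincide with the standalone per-arm fits; the difference terms carry
    the joint model's (pooled-variance) standard errors.
    """

    def __init__(self, model, joint, fit_intervention, fit_control):
        self.model = model
        self._joint = joint
        self.intervention = fit_intervention
        self.control = fit_control
        self.break_index = model.break_index

    def _contrast(self, vec) -> Estimate:
        tt = self._joint.t_test(np.asarray(vec, dtype=float))
        return Estimate(
            float(np.squeeze(tt.effect)),
            float(np.squeeze(tt.sd)),
            float(np.squeeze(tt.pvalue)),
        )

    @property
    def diff_pre_slope(self) -> Estimate:
        return self._contrast([0, 0, 0, 0, 0, 1, 0, 0])

    @property
    def diff_level_change(self) -> Estimate:
        return self._contrast([0, 0, 0, 0, 0, 0, 1, 0])

    @property
    def diff_post_slope(self) -> Estimate:
        return self._contrast([0, 0, 0, 0, 0, 1, 0, 1])

    def to_dict(self) -> dict:
        return {
            "intervention": self.intervention.to_dict(),
            "control": self.control.to_dict(),
            "difference": {
                name: {"estimate": e.value, "se": e.se, "p": e.pvalue}
                for name, e in [
                    ("pre_slope", self.diff_pre_slope),
                    ("level_change", self.diff_level_change),
                    ("post_slope", self.diff_post_slope),
                ]
            },
        }

    def summary(self) -> str:
        lines = [
            "Controlled interrupted time-series analysis",
            "== intervention arm ==",
            self.intervention.summary(),
            "== control arm ==",
            self.control.summary(),
            "== intervention - control ==",
            f"  pre-slope difference   : {self.diff_pre_slope}",
            f"  level-change difference: {self.diff_level_change}",
            f"  post-slope difference  : {self.diff_post_slope}",
        ]
        return "\n".join(lines)


def plot_its(
    points_by_arm: Mapping[WardGroup, Sequence[MonthlyPoint]],
    fits: Mapping[WardGroup, SegmentedITSResults],
    path,
    outcome: Outcome | str = Outcome.PCT_OVER_72H,
) -> None:
    """Chart the monthly points with per-arm fitted pre/post trend segments
    and the pre-intervention period shaded."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outcome = Outcome(outcome)
    fig, ax = plt.subplots(figsize=(8, 5))
    markers = {WardGroup.INTERVENTION: "^", WardGroup.CONTROL: "s"}
    styles = {WardGroup.INTERVENTION: "-", WardGroup.CONTROL: "--"}
    break_index = None
    for arm, points in points_by_arm.items():
        arm = WardGroup(arm)
        t, y = series_values(points, outcome)
        ax.plot(t, y, markers[arm], ms=5, label=f"{arm.value}")
        res = fits[arm]
        break_index = res.break_index
        pre = t[t < break_index]
        post = t[t >= break_index]
        ls = styles[arm]
        if len(pre):
            ax.plot(pre, res.predicted(pre), ls, color="k", lw=1.2)
        if len(post):
            ax.plot(post, res.predicted(post), ls, color="k", lw=1.2)
    if break_index is not None:
        ax.axvspan(ax.get_xlim()[0], break_index - 0.5, color="0.9", zorder=0)
    ax.set_xlabel("month")
    ax.set_ylabel(
        "% of iv prescriptions > 72 h"
        if outcome is Outcome.PCT_OVER_72H
        else "median iv duration (days)"
    )
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
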