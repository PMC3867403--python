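"""Wound-gap closure kinetics.

A scratch-wound time course is the cell-free gap area imaged at regular
intervals, normalized to 100 % at time zero and 0 % at complete closure.
Closure may proceed at a single constant rate (monophasic) or show an
initial slow phase followed by a faster second phase (biphasic), a
signature of growth-factor or lumican stimulation in corneal epithelial
cultures.

The healing rate constant is the arithmetic decline of gap percent per
hour, ``(%_t - %_{t+w}) / w`` over a window ``w`` within one kinetic
phase, so it is positive for a closing wound and carries units of
delta-percent per hour. Biphasic courses are modelled as a continuous
two-segment (hinge) line with the breakpoint restricted to the observed
sampling grid; the breakpoint is selected by exhaustive closed-form
least squares over all admissible grid times. Mono- versus biphasic
classification uses an extra-sum-of-squares F-test plus the requirement
that the second phase be faster than the first.

Goodness of fit is R^2 = 1 - SSC/TSS, where SSC is the sum of squared
distances of the observations from the fitted curve and TSS the sum of
squared distances from the horizontal line through the observation mean.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import scipy.stats

from .errors import (
    DegenerateDataError,
    DegenerateSeriesError,
    InsufficientDataError,
    InvalidInputError,
    MissingTimepointError,
)

__all__ = [
    "ClosureSeries",
    "KineticsFit",
    "ModelSelection",
    "normalize_gap",
    "trim_to_closure",
    "window_rate",
    "fit_monophasic",
    "fit_biphasic",
    "select_model",
    "fit_series",
    "r_squared",
]

#: Grid-matching tolerance in hours when locating observed time points.
_TIME_TOL = 1e-9


@dataclass(frozen=True)
class ClosureSeries:
    """One replicate's wound-gap time course.

    Parameters
    ----------
    condition : str
        Treatment / culture-condition label.
    replicate : str
        Replicate identifier within the condition.
    times : array of float
        Sampling times in hours, strictly increasing, at least two.
    gap_area : array of float, optional
        Raw cell-free area in arbitrary area units.
    gap_pct : array of float, optional
        Gap area as percent of the time-zero gap (100 at t = 0 after
        normalization, 0 at complete closure). Non-negative.
    """

    condition: str
    replicate: str
    times: np.ndarray
    gap_area: Optional[np.ndarray] = None
    gap_pct: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.ndim != 1 or t.size < 2:
            raise InvalidInputError("a closure series needs at least 2 time points")
        if not np.all(np.diff(t) > 0):
            raise InvalidInputError("times must be strictly increasing")
        for name in ("gap_area", "gap_pct"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                object.__setattr__(self, name, v)
                if v.shape != t.shape:
                    raise InvalidInputError(f"{name} length must match times")
                if not np.all(np.isfinite(v)):
                    raise InvalidInputError(f"{name} contains non-finite values")
        if self.gap_pct is not None and np.any(self.gap_pct < 0):
            raise InvalidInputError("gap_pct values must be >= 0")
        if self.gap_area is None and self.gap_pct is None:
            raise InvalidInputError("series needs gap_area or gap_pct")

    @property
    def n_points(self) -> int:
        return int(self.times.size)

    @property
    def is_normalized(self) -> bool:
        return self.gap_pct is not None


@dataclass(frozen=True)
class KineticsFit:
    """A fitted closure-kinetics model.

    ``k1`` (and ``k2`` for biphasic fits) are decline rates in
    delta-percent per hour, positive for a closing wound. ``breakpoint_h``
    is a member of the observed time grid and present only for biphasic
    fits. ``r_squared`` follows the 1 - SSC/TSS construction and equals 1
    exactly when ``sse`` is 0.
    """

    model: str  # "monophasic" | "biphasic"
    k1: float
    intercept: float
    r_squared: float
    sse: float
    n_points: int
    fit_window: tuple
    k2: Optional[float] = None
    breakpoint_h: Optional[float] = None

    def __post_init__(self) -> None:
        if self.model not in ("monophasic", "biphasic"):
            raise InvalidInputError(f"unknown model {self.model!r}")
        if self.model == "biphasic" and (self.k2 is None or self.breakpoint_h is None):
            raise InvalidInputError("biphasic fit requires k2 and breakpoint_h")
        if self.model == "monophasic" and (self.k2 is not None or self.breakpoint_h is not None):
            raise InvalidInputError("monophasic fit must not carry k2 or breakpoint_h")
        if self.sse < 0:
            raise InvalidInputError("sse must be >= 0")

    def predict(self, times: Sequence[float]) -> np.ndarray:
        """Fitted gap percent at the given times (hours)."""
        t = np.asarray(times, dtype=float)
        y = self.intercept - self.k1 * t
        if self.model == "biphasic":
            y = np.where(
                t > self.breakpoint_h,
                self.intercept
                - self.k1 * self.breakpoint_h
                - self.k2 * (t - self.breakpoint_h),
                y,
            )
        return y


@dataclass(frozen=True)
class ModelSelection:
    """Outcome of the mono/biphasic extra-sum-of-squares F-test."""

    alpha: float
    f_statistic: float
    p_value: float
    chosen: KineticsFit

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise InvalidInputError("p_value must lie in [0, 1]")


def normalize_gap(series: ClosureSeries) -> ClosureSeries:
    """Express gap areas as percent of the time-zero gap.

    ``gap_pct[i] = 100 * gap_area[i] / gap_area[0]``, so the first point
    is exactly 100 and complete closure maps to 0.
    """
    if series.gap_area is None:
        raise InvalidInputError("normalize_gap needs raw gap areas")
    a = series.gap_area
    if a[0] <= 0:
        raise InvalidInputError("initial gap area must be positive")
    if np.any(a < 0):
        raise InvalidInputError("gap areas must be non-negative")
    return replace(series, gap_pct=100.0 * a / a[0])


def trim_to_closure(series: ClosureSeries, floor_pct: float = 2.0) -> ClosureSeries:
    """Drop saturated post-closure points.

    Returns the prefix of the series up to and including the first point
    with ``gap_pct <= floor_pct`` (the full series if closure is never
    reached). Points recorded after the gap has effectively closed sit on
    a floor and would bias the phase slopes.
    """
    if not series.is_normalized:
        raise InvalidInputError("trim_to_closure needs a normalized series")
    below = np.nonzero(series.gap_pct <= floor_pct)[0]
    if below.size == 0:
        return series
    end = int(below[0]) + 1
    if end < 2:
        raise DegenerateSeriesError(
            f"fewer than 2 points remain above the {floor_pct}% closure floor"
        )
    return replace(
        series,
        times=series.times[:end],
        gap_pct=series.gap_pct[:end],
        gap_area=None if series.gap_area is None else series.gap_area[:end],
    )


def _index_of(times: np.ndarray, t: float) -> int:
    hits = np.nonzero(np.abs(times - t) <= _TIME_TOL)[0]
    if hits.size == 0:
        raise MissingTimepointError(f"time {t} h is not on the observed grid")
    return int(hits[0])


def window_rate(series: ClosureSeries, t: float, window: float = 6.0) -> float:
    """Healing rate constant over a window: ``(%_t - %_{t+window}) / window``.

    Both ``t`` and ``t + window`` must be observed times within a single
    kinetic phase. Positive for a closing wound (magnitude of percent
    decline per hour).
    """
    if not series.is_normalized:
        raise InvalidInputError("window_rate needs a normalized series")
    if window <= 0:
        raise InvalidInputError("window must be positive")
    i = _index_of(series.times, t)
    j = _index_of(series.times, t + window)
    return float((series.gap_pct[i] - series.gap_pct[j]) / window)


def r_squared(observed: Sequence[float], fitted: Sequence[float]) -> float:
    """Goodness of fit: ``1 - SSC/TSS``.

    TSS is the sum of squared distances of the observations from the
    horizontal line through their mean; SSC is the sum of squared
    distances from the fitted curve. A perfect fit returns exactly 1;
    flat data with nonzero residuals have no defined value and raise
    :class:`DegenerateDataError`.
    """
    obs = np.asarray(observed, dtype=float)
    fit = np.asarray(fitted, dtype=float)
    if obs.shape != fit.shape:
        raise InvalidInputError("observed and fitted must have equal length")
    if obs.size < 2:
        raise InvalidInputError("need at least 2 points")
    ssc = float(np.sum((obs - fit) ** 2))
    tss = float(np.sum((obs - obs.mean()) ** 2))
    if ssc == 0.0:
        return 1.0
    if tss == 0.0:
        raise DegenerateDataError("flat observations with nonzero residuals")
    return 1.0 - ssc / tss


def _snap_sse(sse: float, y: np.ndarray) -> float:
    # floating-point residue of an exact fit is reported as an exact fit
    return 0.0 if sse <= 1e-12 * (1.0 + float(np.sum(y * y))) else sse


def fit_monophasic(series: ClosureSeries) -> KineticsFit:
    """Ordinary least-squares line through the closure course.

    ``k1`` is the negated slope, positive for a closing wound.
    """
    if not series.is_normalized:
        raise InvalidInputError("fit_monophasic needs a normalized series")
    t, y = series.times, series.gap_pct
    if t.size < 2:
        raise DegenerateSeriesError("monophasic fit needs at least 2 points")
    X = np.column_stack([np.ones_like(t), t])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ coef
    sse = _snap_sse(float(np.sum((y - fitted) ** 2)), y)
    return KineticsFit(
        model="monophasic",
        k1=float(-coef[1]),
        intercept=float(coef[0]),
        sse=sse,
        r_squared=1.0 if sse == 0.0 else r_squared(y, fitted),
        n_points=t.size,
        fit_window=(float(t[0]), float(t[-1])),
    )


def _hinge_design(t: np.ndarray, tb: float) -> np.ndarray:
    return np.column_stack([np.ones_like(t), t, np.maximum(t - tb, 0.0)])


def candidate_breakpoints(times: np.ndarray) -> np.ndarray:
    """Admissible breakpoint grid: interior observed times with at least
    three observations on each side (the boundary point counts for both)."""
    n = times.size
    if n < 6:
        return times[:0]
    return times[2 : n - 2]


def fit_biphasic(series: ClosureSeries) -> KineticsFit:
    """Continuous two-segment piecewise-linear (hinge) fit.

    For every admissible breakpoint on the observed time grid the linear
    least-squares problem in (intercept, k1, k2) is solved in closed
    form; the breakpoint with minimal SSE wins, earliest first on ties.
    """
    if not series.is_normalized:
        raise InvalidInputError("fit_biphasic needs a normalized series")
    t, y = series.times, series.gap_pct
    cands = candidate_breakpoints(t)
    if cands.size == 0:
        raise InsufficientDataError(
            f"biphasic fit needs >= 6 observed times, got {t.size}"
        )
    best = None
    for tb in cands:
        X = _hinge_design(t, float(tb))
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        sse = _snap_sse(float(np.sum((y - X @ coef) ** 2)), y)
        if best is None or sse < best[0]:
            best = (sse, float(tb), coef)
    sse, tb, coef = best
    a, b, c = coef
    return KineticsFit(
        model="biphasic",
        k1=float(-b),
        k2=float(-(b + c)),
        breakpoint_h=tb,
        intercept=float(a),
        sse=sse,
        r_squared=1.0 if sse == 0.0 else r_squared(y, _hinge_design(t, tb) @ coef),
        n_points=t.size,
        fit_window=(float(t[0]), float(t[-1])),
    )


def select_model(
    mono: KineticsFit, bi: KineticsFit, n: int, alpha: float = 0.05
) -> ModelSelection:
    """Choose between the monophasic and biphasic fit.

    Extra-sum-of-squares F-test with 2 extra parameters (second slope and
    breakpoint): ``F = ((SSE_mono - SSE_bi)/2) / (SSE_bi/(n-4))`` referred
    to F(2, n-4). The biphasic model is chosen only when the test is
    significant at ``alpha`` *and* the second phase accelerates
    (``k2 > k1``); a perfect biphasic fit of an imperfect line is chosen
    directly, subject to the same acceleration constraint.
    """
    if n <= 4:
        raise InsufficientDataError("model selection needs n > 4 observations")
    if not (0.0 < alpha < 1.0):
        raise InvalidInputError("alpha must be in (0, 1)")
    sse_m, sse_b = mono.sse, bi.sse
    if sse_b == 0.0:
        if sse_m > 0.0:
            f_stat, p = float("inf"), 0.0
        else:
            f_stat, p = 0.0, 1.0
    else:
        f_stat = max(0.0, ((sse_m - sse_b) / 2.0) / (sse_b / (n - 4)))
        p = float(scipy.stats.f.sf(f_stat, 2, n - 4))
    accelerating = bi.k2 is not None and bi.k2 > bi.k1
    chosen = bi if (p < alpha and accelerating) else mono
    return ModelSelection(alpha=alpha, f_statistic=f_stat, p_value=p, chosen=chosen)


def fit_series(
    series: ClosureSeries,
    alpha: float = 0.05,
    floor_pct: float = 2.0,
    min_biphasic_points: int = 6,
) -> ModelSelection:
    """Trim, fit both models where possible, and select one.

    Series too short for the hinge model fall back to the monophasic fit
    (reported with p-value 1, no test performed).
    """
    trimmed = trim_to_closure(series, floor_pct=floor_pct)
    mono = fit_monophasic(trimmed)
    if trimmed.n_points < max(6, min_biphasic_points):
        return ModelSelection(alpha=alpha, f_statistic=0.0, p_value=1.0, chosen=mono)
    bi = fit_biphasic(trimmed)
    return select_model(mono, bi, trimmed.n_points, alpha=alpha)
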