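"""Diel activity analysis on the 24-hour clock.

The day is partitioned, per season, into dawn (two hours either side of
mean sunrise), day, dusk (two hours either side of mean sunset) and night.
Detection clock-times are smoothed with a von Mises kernel density on the
circle; the density mass falling in each period ("use") is compared with
the period's share of the 24 h ("availability") through Manly's design-I
selection ratio w = use / availability, with simultaneous Bonferroni
confidence intervals. A period is classified *selected* when the interval
lies above 1, *avoided* when below 1, and *as expected* otherwise.

Clock time (camera timestamps) is the circular coordinate; sun times enter
only through the seasonal mean partition.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .data_model import DetectionEvent, ValidationError

DAY_HOURS = 24.0
PERIODS = ("dawn", "day", "dusk", "night")
_TO_RAD = 2 * np.pi / DAY_HOURS


def hours_from_str(s: str) -> float:
    h, m = s.split(":")
    return int(h) + int(m) / 60.0


def detection_hours(events: Iterable[DetectionEvent]) -> np.ndarray:
    """Clock-times (decimal hours) of detection events."""
    return np.array(
        [e.timestamp.hour + e.timestamp.minute / 60.0 + e.timestamp.second / 3600.0
         for e in events]
    )


def read_sun_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", dtype=str)
    missing = {"date", "sunrise", "sunset"} - set(df.columns)
    if missing:
        raise ValidationError(f"sun table missing columns: {sorted(missing)}")
    return df


def circular_mean_hours(hours: np.ndarray) -> float:
    """Mean on the 24-h circle (so 23:50 and 00:10 average to 00:00)."""
    hours = np.asarray(hours, float)
    return float(stats.circmean(hours * _TO_RAD, high=2 * np.pi, low=0) / _TO_RAD) % DAY_HOURS


def season_sun_times(
    sun_table: pd.DataFrame, operative_dates: Sequence[dt.date] | Sequence[str]
) -> tuple[float, float]:
    """Circular-mean sunrise and sunset over the camera-operative days."""
    wanted = {d.isoformat() if isinstance(d, dt.date) else str(d) for d in operative_dates}
    sub = sun_table[sun_table["date"].isin(wanted)]
    if sub.empty:
        raise ValidationError("sun table covers none of the operative days")
    sr = circular_mean_hours(np.array([hours_from_str(s) for s in sub["sunrise"]]))
    ss = circular_mean_hours(np.array([hours_from_str(s) for s in sub["sunset"]]))
    return sr, ss


# ---------------------------------------------------------------------------
# period partition


def _wrap_interval(lo: float, hi: float) -> list[tuple[float, float]]:
    """Split a half-open circular interval into linear segments in [0, 24)."""
    lo %= DAY_HOURS
    hi %= DAY_HOURS
    if hi > lo:
        return [(lo, hi)]
    segs = []
    if lo < DAY_HOURS:
        segs.append((lo, DAY_HOURS))
    if hi > 0:
        segs.append((0.0, hi))
    return segs


@dataclass
class PeriodPartition:
    """Dawn/day/dusk/night intervals tiling the 24-h circle.

    ``intervals`` maps period name to half-open segments in [0, 24);
    ``availability`` is each period's share of the 24 h. Dawn and dusk span
    exactly 4 h each.
    """

    sunrise: float
    sunset: float
    season: str | None = None
    intervals: dict[str, list[tuple[float, float]]] = field(default_factory=dict)
    availability: dict[str, float] = field(default_factory=dict)

    def period_of(self, hour: float) -> str:
        hour = hour % DAY_HOURS
        for name in PERIODS:
            for lo, hi in self.intervals[name]:
                if lo <= hour < hi:
                    return name
        raise RuntimeError("partition does not tile the circle")  # pragma: no cover

    def availabilities(self) -> np.ndarray:
        return np.array([self.availability[p] for p in PERIODS])


def partition(sunrise: float, sunset: float, season: str | None = None) -> PeriodPartition:
    """Build the four-period partition from mean sunrise/sunset (hours).

    dawn = [sunrise-2, sunrise+2), day = [sunrise+2, sunset-2),
    dusk = [sunset-2, sunset+2), night = the remainder. Day length must
    exceed 4 h and be under 20 h so that day and night are non-empty.
    """
    daylen = (sunset - sunrise) % DAY_HOURS
    if daylen <= 4.0:
        raise ValidationError(
            f"day interval empty: sunset-sunrise = {daylen:.2f} h <= 4 h"
        )
    if daylen >= 20.0:
        raise ValidationError(
            f"night interval empty: sunset-sunrise = {daylen:.2f} h >= 20 h"
        )
    bounds = {
        "dawn": (sunrise - 2, sunrise + 2),
        "day": (sunrise + 2, sunset - 2),
        "dusk": (sunset - 2, sunset + 2),
        "night": (sunset + 2, sunrise - 2 + DAY_HOURS),
    }
    intervals = {k: _wrap_interval(lo, hi) for k, (lo, hi) in bounds.items()}
    availability = {
        "dawn": 4 / DAY_HOURS,
        "day": (daylen - 4) / DAY_HOURS,
        "dusk": 4 / DAY_HOURS,
        "night": (DAY_HOURS - daylen - 4) / DAY_HOURS,
    }
    return PeriodPartition(
        sunrise=sunrise % DAY_HOURS, sunset=sunset % DAY_HOURS, season=season,
        intervals=intervals, availability=availability,
    )


# ---------------------------------------------------------------------------
# circular kernel density


class CircularActivityKDE(BaseEstimator):
    """Von Mises kernel density of activity times on the 24-h circle.

    f(t) = (1/n) sum_j K_kappa(t - t_j), normalized per hour so the circle
    integral is 1. ``concentration="auto"`` picks kappa by maximizing the
    leave-one-out cross-validated log-likelihood over a log-spaced grid,
    divided by ``adjust`` squared (adjust > 1 smooths more).

    Fitted attributes: ``kappa_``, ``grid_`` (hours), ``density_`` (per
    hour), ``n_``.
    """

    _KAPPA_GRID = np.geomspace(0.3, 300.0, 40)

    def __init__(self, concentration: float | str = "auto", grid_size: int = 512,
                 adjust: float = 1.0):
        self.concentration = concentration
        self.grid_size = grid_size
        self.adjust = adjust

    def fit(self, times_hours: np.ndarray, y=None) -> "CircularActivityKDE":
        t = np.asarray(times_hours, float) % DAY_HOURS
        if t.size < 2:
            raise ValidationError("need at least 2 detection times for a density")
        self.times_ = t
        self.n_ = t.size
        if self.concentration == "auto":
            kappa = self._cv_kappa(t) / self.adjust**2
        else:
            kappa = float(self.concentration)
            if kappa <= 0:
                raise ValidationError("concentration must be > 0")
        self.kappa_ = kappa
        self.grid_ = np.arange(self.grid_size) * DAY_HOURS / self.grid_size
        self.density_ = self.density(self.grid_)
        return self

    @classmethod
    def _cv_kappa(cls, t: np.ndarray) -> float:
        # subsample for the bandwidth search only; the density uses all points
        rng = np.random.default_rng(0)
        ts = rng.choice(t, 1500, replace=False) if t.size > 1500 else t
        n = ts.size
        diff = (ts[:, None] - ts[None, :]) * _TO_RAD
        cosd = np.cos(diff)
        best_kappa, best_score = cls._KAPPA_GRID[0], -np.inf
        for kappa in cls._KAPPA_GRID:
            kern = np.exp(kappa * (cosd - 1.0))  # scaled von Mises kernel
            norm = 2 * np.pi * stats.vonmises.pdf(0, kappa)  # e^k / (2 pi I0(k)) scale
            with np.errstate(divide="ignore"):
                loo = (kern.sum(axis=1) - 1.0) / (n - 1) * norm / (2 * np.pi)
                score = np.sum(np.log(np.clip(loo, 1e-300, None)))
            if score > best_score:
                best_kappa, best_score = kappa, score
        return float(best_kappa)

    def density(self, at_hours: np.ndarray) -> np.ndarray:
        """Density (per hour) at arbitrary clock-times."""
        at = np.atleast_1d(np.asarray(at_hours, float)) * _TO_RAD
        t = self.times_ * _TO_RAD
        pdf = stats.vonmises.pdf(at[:, None] - t[None, :], self.kappa_).mean(axis=1)
        return pdf * _TO_RAD  # radians -> hours

    def integral(self) -> float:
        """Circle integral via the periodic rectangle rule on the grid."""
        return float(self.density_.mean() * DAY_HOURS)


def circular_kde(
    times_hours: np.ndarray, concentration: float | str = "auto", grid_size: int = 512,
    adjust: float = 1.0,
) -> CircularActivityKDE:
    return CircularActivityKDE(concentration, grid_size, adjust).fit(times_hours)


#: spec-facing alias: the fitted estimator carries grid, density and kappa
ActivityKDE = CircularActivityKDE


def period_mass(kde: CircularActivityKDE, part: PeriodPartition,
                points_per_segment: int = 256) -> dict[str, float]:
    """Proportion of the activity density in each daily period.

    Each interval segment is integrated by the trapezoid rule on its own
    fine grid; proportions are normalized by the circle total so they sum
    to 1.
    """
    raw = {}
    for name in PERIODS:
        total = 0.0
        for lo, hi in part.intervals[name]:
            xs = np.linspace(lo, hi, points_per_segment)
            total += float(np.trapezoid(kde.density(xs), xs))
        raw[name] = total
    s = sum(raw.values())
    return {k: v / s for k, v in raw.items()}


def period_counts(times_hours: np.ndarray, part: PeriodPartition) -> dict[str, float]:
    """Raw per-period detection proportions (the unsmoothed alternative)."""
    times_hours = np.asarray(times_hours, float)
    if times_hours.size == 0:
        raise ValidationError("no detection times")
    counts = {p: 0 for p in PERIODS}
    for h in times_hours:
        counts[part.period_of(h)] += 1
    n = times_hours.size
    return {k: v / n for k, v in counts.items()}


# ---------------------------------------------------------------------------
# selection ratios


@dataclass
class SelectionRatioResult:
    """Design-I selection ratios with simultaneous Bonferroni intervals."""

    table: pd.DataFrame
    n_detections: int
    alpha: float

    def classification(self) -> dict[str, str]:
        return dict(zip(self.table["period"], self.table["classification"]))


def selection_ratios(
    use_proportions: dict[str, float] | Sequence[float],
    availabilities: dict[str, float] | Sequence[float],
    n_detections: int,
    alpha: float = 0.05,
) -> SelectionRatioResult:
    """Manly design-I selection ratios w_i = use_i / availability_i.

    SE(w_i) = sqrt(o_i (1 - o_i) / (n pi_i^2)); the simultaneous intervals
    use the Bonferroni quantile z at 1 - alpha / (2 I) for I periods, with
    lower bounds clipped at 0. A period is *selected* when the interval's
    lower bound exceeds 1 and *avoided* when its upper bound is below 1.
    """
    if isinstance(use_proportions, dict):
        o = np.array([use_proportions[p] for p in PERIODS])
        labels = list(PERIODS)
    else:
        o = np.asarray(use_proportions, float)
        labels = list(PERIODS)[: o.size]
    pi = (
        np.array([availabilities[p] for p in labels])
        if isinstance(availabilities, dict)
        else np.asarray(availabilities, float)
    )
    if o.shape != pi.shape:
        raise ValidationError("use and availability lengths differ")
    if np.any(pi <= 0):
        raise ValidationError("every period needs positive availability")
    if not (0 < alpha < 1):
        raise ValidationError("alpha must be in (0, 1)")
    if n_detections < 1:
        raise ValidationError("need at least one detection")
    if abs(o.sum() - 1) > 1e-6 or abs(pi.sum() - 1) > 1e-6:
        raise ValidationError("use and availability proportions must each sum to 1")
    n_periods = o.size
    w = o / pi
    se = np.sqrt(o * (1 - o) / (n_detections * pi**2))
    z = stats.norm.ppf(1 - alpha / (2 * n_periods))
    lo = np.clip(w - z * se, 0.0, None)
    hi = w + z * se
    cls = np.where(lo > 1, "selected", np.where(hi < 1, "avoided", "as_expected"))
    table = pd.DataFrame(
        {
            "period": labels, "use": o, "availability": pi, "ratio": w,
            "se": se, "ci_low": lo, "ci_high": hi, "classification": cls,
        }
    )
    return SelectionRatioResult(table=table, n_detections=n_detections, alpha=alpha)


def seasonal_activity(
    times_hours: np.ndarray,
    part: PeriodPartition,
    concentration: float | str = "auto",
    use_mode: str = "kde",
    alpha: float = 0.05,
) -> tuple[CircularActivityKDE, dict[str, float], SelectionRatioResult]:
    """KDE, per-period use and selection ratios for one season's detections.

    ``use_mode="kde"`` feeds the smoothed per-period density mass to the
    ratios (default); ``"counts"`` uses raw detection proportions.
    """
    kde = circular_kde(times_hours, concentration)
    if use_mode == "kde":
        use = period_mass(kde, part)
    elif use_mode == "counts":
        use = period_counts(times_hours, part)
    else:
        raise ValidationError(f"unknown use_mode {use_mode!r}")
    ratios = selection_ratios(use, part.availability, n_detections=len(times_hours), alpha=alpha)
    return kde, use, ratios
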