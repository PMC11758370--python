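"""Model-free hazard summaries used as goodness-of-fit diagnostics.

The join-point model is judged against the data in two ways: the daily
empirical hazard (deaths over at-risk, per day) is compared with the model
hazard, and the Nelson–Aalen cumulative hazard with pointwise confidence
intervals is compared with the model's cumulative hazard. A separate
constant-rate check on the 180–360-day window verifies that mortality
beyond the administrative horizon is approximately flat, which is the
premise of the background-rate plateau.

At-risk convention: a subject whose follow-up time falls in day ``d``
(i.e. ``floor(time) == d``) is counted at risk on day ``d`` — deaths and
censorings happen at the end of the day. This makes the daily counts
reproducible from registry-style integer data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .estimation import Cohort
from .model import REPORT_SCALE

__all__ = ["daily_hazard", "peak_day", "nelson_aalen", "LateWindowFit", "late_window_rate"]


def _daily_counts(cohort: Cohort, start: int, end: int):
    days = np.arange(start, end + 1)
    day_of = np.floor(cohort.time).astype(int)
    at_risk = (cohort.time[None, :] >= days[:, None]).sum(axis=1)
    deaths = np.zeros_like(days)
    sel = cohort.event & (day_of >= start) & (day_of <= end)
    np.add.at(deaths, day_of[sel] - start, 1)
    return days, deaths, at_risk


def daily_hazard(cohort: Cohort, window: tuple[int, int] = (0, 180)) -> pd.DataFrame:
    """Per-day deaths, at-risk counts and empirical hazard.

    Returns a frame with columns ``day``, ``deaths``, ``at_risk``, ``rate``
    (deaths / at-risk) and ``rate_per_1000`` (the reporting scale). Days
    with nobody at risk get ``NaN`` rates — undefined, not zero.
    """
    start, end = int(window[0]), int(window[1])
    if start < 0 or end < start:
        raise ValueError("window must satisfy 0 <= start <= end")
    if cohort.n == 0:
        raise ValueError("cohort is empty")
    days, deaths, at_risk = _daily_counts(cohort, start, end)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(at_risk > 0, deaths / np.maximum(at_risk, 1), np.nan)
    return pd.DataFrame(
        {
            "day": days,
            "deaths": deaths,
            "at_risk": at_risk,
            "rate": rate,
            "rate_per_1000": rate * REPORT_SCALE,
        }
    )


def peak_day(series: pd.DataFrame, search_window: tuple[int, int] | None = None):
    """Day of maximum empirical hazard.

    Returns ``(primary_day, tied_days)`` where ``tied_days`` is the set of
    days attaining the maximum and the primary day is the earliest of them.
    """
    frame = series
    if search_window is not None:
        lo, hi = search_window
        frame = frame[(frame["day"] >= lo) & (frame["day"] <= hi)]
    rates = frame["rate"].to_numpy(float)
    if frame.empty or np.all(np.isnan(rates)):
        raise ValueError("no defined hazard values in the search window")
    top = np.nanmax(rates)
    tied = set(frame["day"].to_numpy()[rates == top].tolist())
    return min(tied), tied


def nelson_aalen(cohort: Cohort, horizon: int = 180, coverage: float = 0.95) -> pd.DataFrame:
    """Nelson–Aalen cumulative hazard by day with pointwise CIs.

    ``cum_hazard(day)`` is the running sum of deaths(d)/at_risk(d); the
    variance estimate is the running sum of deaths/at_risk**2, and the
    pointwise interval uses the standard log-transformed normal
    approximation (degenerate where no events have accrued).
    """
    if cohort.n == 0:
        raise ValueError("cohort is empty")
    series = daily_hazard(cohort, (0, int(horizon)))
    increments = np.where(series["at_risk"] > 0, series["deaths"] / series["at_risk"].clip(lower=1), 0.0)
    cum = np.cumsum(increments)
    var = np.cumsum(
        np.where(series["at_risk"] > 0, series["deaths"] / series["at_risk"].clip(lower=1) ** 2, 0.0)
    )
    z = stats.norm.ppf(0.5 + coverage / 2.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        spread = np.exp(z * np.sqrt(var) / np.where(cum > 0, cum, np.nan))
    ci_low = np.where(cum > 0, cum / spread, 0.0)
    ci_high = np.where(cum > 0, cum * spread, 0.0)
    out = series.copy()
    out["cum_hazard"] = cum
    out["ci_low"] = ci_low
    out["ci_high"] = ci_high
    return out


@dataclass(frozen=True)
class LateWindowFit:
    """Constant-hazard fit on a late follow-up window, with a constancy check."""

    rate: float
    rate_per_1000: float
    events: int
    person_days: float
    lrt_statistic: float
    p_value: float
    approximately_constant: bool
    window: tuple[float, float]


def _window_exposure(cohort: Cohort, lo: float, hi: float):
    exposure = float(np.sum(np.clip(cohort.time, lo, hi) - lo))
    in_window = cohort.event & (cohort.time > lo) & (cohort.time <= hi)
    return exposure, int(in_window.sum())


def late_window_rate(cohort: Cohort, window: tuple[float, float] = (180.0, 360.0)) -> LateWindowFit:
    """Constant-hazard MLE on ``window`` plus a two-segment constancy LRT.

    The rate is events per person-day in the window. The check splits the
    window at its midpoint, fits a separate constant rate to each half, and
    refers twice the log-likelihood gain to chi-square with 1 df;
    "approximately constant" means that test does not reject at 5%.
    """
    lo, hi = float(window[0]), float(window[1])
    if hi <= lo:
        raise ValueError("window must have positive length")
    exposure, events = _window_exposure(cohort, lo, hi)
    if exposure <= 0:
        raise ValueError("no person-time in the late window")

    def seg_loglik(e: int, pd_: float) -> float:
        if e == 0:
            return 0.0
        if pd_ <= 0:
            return -math.inf
        rate = e / pd_
        return e * math.log(rate) - e

    mid = (lo + hi) / 2.0
    exp1, ev1 = _window_exposure(cohort, lo, mid)
    exp2, ev2 = _window_exposure(cohort, mid, hi)
    ll_const = seg_loglik(events, exposure)
    ll_split = seg_loglik(ev1, exp1) + seg_loglik(ev2, exp2)
    stat = max(2.0 * (ll_split - ll_const), 0.0)
    p = float(stats.chi2.sf(stat, 1))
    rate = events / exposure
    return LateWindowFit(
        rate=rate,
        rate_per_1000=rate * REPORT_SCALE,
        events=events,
        person_days=exposure,
        lrt_statistic=stat,
        p_value=p,
        approximately_constant=p >= 0.05,
        window=(lo, hi),
    )
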