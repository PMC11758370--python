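"""Maximum-likelihood estimation and inference for the join-point hazard.

The data are right-censored survival times left-truncated at the
acute-phase origin: subjects enter the risk set at day 3 (deaths before
the origin are excluded upstream) and are administratively censored at the
follow-up horizon. The log-likelihood for subject ``i`` with follow-up
time ``t_i`` and event indicator ``delta_i`` is

    l_i = delta_i * log h(t_i) - [H(t_i) - H(t0)]

with ``h`` and ``H`` from :mod:`fatality_window.model` and ``t0`` the
origin (so ``H(t0) = 0`` by construction).

Fitting profiles the join point: at each candidate phase-shift the
likelihood is concave in the two rates and is maximized by a safeguarded
Newton iteration; the phase shift is then scanned on a grid and refined by
bounded scalar minimization. Confidence intervals invert the likelihood
ratio test (profile likelihood), and group comparisons are likelihood
ratio tests between nested parameterizations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import optimize, stats

from .model import JoinPointParams, cumulative_hazard, hazard_value

__all__ = [
    "Cohort",
    "FitConfig",
    "ParamCI",
    "FitResult",
    "ComparisonResult",
    "NoEventsError",
    "log_likelihood",
    "fit_mle",
    "profile_ci",
    "fit_with_ci",
    "overall_test",
    "parameter_equality_test",
    "fixed_value_test",
]

_PARAM_NAMES = ("acute_rate", "background_rate", "phase_shift")


class NoEventsError(ValueError):
    """Raised when a cohort (or stratum) contains no deaths: the hazard
    rates are unidentifiable without at least one event."""


@dataclass(frozen=True)
class Cohort:
    """Analyzable survival data: one follow-up time and event flag per subject.

    ``time`` is days since surgery (event day if ``event`` is true, else
    censoring day); times must be at or after the modelling origin before
    the likelihood can be evaluated.
    """

    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        e = np.asarray(self.event, dtype=bool)
        if t.ndim != 1 or e.shape != t.shape:
            raise ValueError("time and event must be 1-d arrays of equal length")
        if t.size and (not np.all(np.isfinite(t)) or np.any(t <= 0)):
            raise ValueError("follow-up times must be finite and positive")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "event", e)

    @property
    def n(self) -> int:
        return self.time.size

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    @classmethod
    def from_frame(cls, frame, time_col: str = "time", event_col: str = "event") -> "Cohort":
        return cls(frame[time_col].to_numpy(float), frame[event_col].to_numpy(bool))


@dataclass(frozen=True)
class FitConfig:
    """Tuning knobs for the profile-likelihood fit.

    ``origin``/``horizon`` frame the model (days); ``tau_step`` is the
    phase-shift scan resolution with ``tau_tol`` the refinement width;
    ``profile_tau_step`` is the coarser scan used inside confidence-interval
    profiling where the phase shift is a nuisance parameter.
    """

    origin: float = 3.0
    horizon: float = 180.0
    tau_step: float = 0.5
    tau_tol: float = 0.01
    profile_tau_step: float = 2.0


@dataclass(frozen=True)
class ParamCI:
    lower: float
    upper: float
    coverage: float = 0.95
    lower_unbounded: bool = False
    upper_unbounded: bool = False


@dataclass(frozen=True)
class FitResult:
    params: JoinPointParams
    loglik: float
    n_subjects: int
    n_events: int
    converged: bool = True
    boundary_flag: bool = False
    warnings: tuple = ()
    ci: Mapping[str, ParamCI] = field(default_factory=dict)


@dataclass(frozen=True)
class ComparisonResult:
    statistic: float
    df: int
    p_value: float
    hypothesis: str


# ---------------------------------------------------------------------------
# likelihood


def _validate_times(cohort: Cohort, origin: float) -> None:
    if cohort.n == 0:
        raise ValueError("cohort is empty")
    if np.any(cohort.time < origin - 1e-12):
        raise ValueError(
            f"cohort contains follow-up times before the origin (day {origin}); "
            "apply the early-death exclusion (modeling subset) before fitting"
        )


def log_likelihood(params: JoinPointParams, cohort: Cohort) -> float:
    """Right-censored, left-truncated-at-origin log-likelihood, in nats."""
    _validate_times(cohort, params.origin)
    h = np.asarray(hazard_value(params, cohort.time[cohort.event]))
    if np.any(h <= 0.0):
        return -math.inf
    H = np.asarray(cumulative_hazard(params, cohort.time))
    return float(np.sum(np.log(h)) - np.sum(H))


# ---------------------------------------------------------------------------
# inner problem: rates at a fixed phase shift
#
# With tau fixed and d = acute - background >= 0, writing w_i for the
# normalized decline weight at t_i and W_i for its integral from the origin,
#   l(b, d) = sum_events log(b + d w_e) - b * S_T - d * S_W
# with S_T = sum(t_i - t0), S_W = sum W_i.  l is concave in (b, d).


def _tau_stats(time: np.ndarray, te: np.ndarray, t0: float, tau: float):
    width = tau - t0
    tc = np.minimum(time, tau)
    S_W = float(np.sum((width * width - (tau - tc) ** 2) / (2.0 * width)))
    w_e = np.clip((tau - te) / width, 0.0, 1.0)
    return w_e, S_W


def _rate_loglik(b: float, d: float, w_e: np.ndarray, S_T: float, S_W: float) -> float:
    h = b + d * w_e
    if np.any(h <= 0.0):
        return -math.inf
    return float(np.sum(np.log(h)) - b * S_T - d * S_W)


def _newton_rates(w_e, S_T, S_W, b0, d0):
    """Safeguarded Newton ascent of the concave rate likelihood."""
    b, d = max(b0, 1e-300), max(d0, 0.0)
    ll = _rate_loglik(b, d, w_e, S_T, S_W)
    for _ in range(80):
        h = b + d * w_e
        inv = 1.0 / h
        g_b = float(inv.sum()) - S_T
        g_d = float((w_e * inv).sum()) - S_W
        inv2 = inv * inv
        Hbb = -float(inv2.sum())
        Hbd = -float((w_e * inv2).sum())
        Hdd = -float((w_e * w_e * inv2).sum())
        det = Hbb * Hdd - Hbd * Hbd
        if det <= 0.0 or not math.isfinite(det):
            step_b, step_d = 1e-2 * b * np.sign(g_b), 1e-2 * max(d, b) * np.sign(g_d)
        else:
            step_b = -(Hdd * g_b - Hbd * g_d) / det
            step_d = -(Hbb * g_d - Hbd * g_b) / det
        alpha = 1.0
        improved = False
        for _bt in range(40):
            nb, nd = b + alpha * step_b, d + alpha * step_d
            if nd < 0.0:
                nd = 0.0
            if nb > 0.0:
                nll = _rate_loglik(nb, nd, w_e, S_T, S_W)
                if nll >= ll:
                    improved = nll > ll + 1e-13 * (abs(ll) + 1.0)
                    b, d, ll = nb, nd, nll
                    break
            alpha *= 0.5
        else:
            break
        if not improved:
            break
    return b, d, ll


def _fit_rates_free(w_e, S_T, S_W, warm=None):
    """Maximize over (background b, decline d) at a fixed phase shift."""
    n_e = w_e.size
    r = n_e / S_T
    # KKT check for the flat boundary d = 0 (constant hazard): b = n_e / S_T
    if float(w_e.sum()) / r <= S_W + 1e-12 * max(S_W, 1.0):
        return r, 0.0, _rate_loglik(r, 0.0, w_e, S_T, S_W)
    starts = [(r, r), (2 * r, 2 * r), (0.5 * r, 0.5 * r)]
    if warm is not None and warm[0] > 0:
        starts.insert(0, warm)
    best = (r, 0.0, -math.inf)
    for b0, d0 in starts:
        cand = _newton_rates(w_e, S_T, S_W, b0, d0)
        if cand[2] > best[2]:
            best = cand
    return best


def _fit_rates_fixed_background(w_e, S_T, S_W, b: float):
    """Maximize over d >= 0 with the background rate pinned at ``b``."""
    if b < 0:
        raise ValueError("background rate must be non-negative")
    if b == 0.0 and np.any(w_e <= 0.0):
        return 0.0, -math.inf  # an event sits on a zero-hazard plateau
    def grad(d):
        return float((w_e / (b + d * w_e)).sum()) - S_W
    if b > 0.0 and grad(0.0) <= 0.0:
        return 0.0, _rate_loglik(b, 0.0, w_e, S_T, S_W)
    d_hi = max((w_e > 0).sum() / S_W, b, 1e-12)
    for _ in range(200):
        if grad(d_hi) < 0.0:
            break
        d_hi *= 4.0
    d = optimize.brentq(grad, 0.0 if b > 0 else 1e-300, d_hi, xtol=1e-14, rtol=1e-12)
    return d, _rate_loglik(b, d, w_e, S_T, S_W)


def _fit_rates_fixed_acute(w_e, S_T, S_W, a: float):
    """Maximize over background b in [0, a] with the acute rate pinned."""
    if a < 0:
        raise ValueError("acute rate must be non-negative")
    if a == 0.0:
        return 0.0, _rate_loglik(0.0, 0.0, w_e, S_T, S_W)
    def grad(b):
        h = a * w_e + b * (1.0 - w_e)
        return float(((1.0 - w_e) / h).sum()) - (S_T - S_W)
    if grad(a) >= 0.0:
        return a, _rate_loglik(a, 0.0, w_e, S_T, S_W)
    lo = a * 0.5
    while grad(lo) < 0.0:
        lo *= 0.125
        if lo < a * 1e-18:
            b = 0.0 if not np.any(w_e <= 0.0) else lo
            return b, _rate_loglik(b, a - b, w_e, S_T, S_W)
    hi = min(lo * 8.0, a)
    b = optimize.brentq(grad, lo, hi, xtol=1e-300, rtol=1e-13)
    return b, _rate_loglik(b, a - b, w_e, S_T, S_W)


def _profile_at_tau(time, te, S_T, t0, tau, fixed=None, warm=None):
    """Best rates (and log-likelihood) at a fixed phase shift ``tau``.

    ``fixed`` optionally pins one rate: {'acute_rate': a} or
    {'background_rate': b}. Returns (loglik, acute, background).
    """
    w_e, S_W = _tau_stats(time, te, t0, tau)
    if not fixed:
        b, d, ll = _fit_rates_free(w_e, S_T, S_W, warm=warm)
        return ll, b + d, b
    if "acute_rate" in fixed:
        a = fixed["acute_rate"]
        b, ll = _fit_rates_fixed_acute(w_e, S_T, S_W, a)
        return ll, a, b
    b = fixed["background_rate"]
    d, ll = _fit_rates_fixed_background(w_e, S_T, S_W, b)
    return ll, b + d, b


def _maximize_over_tau(time, te, S_T, cfg: FitConfig, fixed=None, step=None):
    """Scan the phase shift on a grid, then refine by bounded minimization.

    Returns (tau, loglik, acute, background)."""
    t0, horizon = cfg.origin, cfg.horizon
    step = step or cfg.tau_step
    taus = np.arange(t0 + step, horizon + 1e-9, step)
    if taus.size == 0 or taus[-1] < horizon - 1e-9:
        taus = np.append(taus, horizon)
    best = (-math.inf, taus[0], None, None)
    warm = None
    for tau in taus:
        ll, a, b = _profile_at_tau(time, te, S_T, t0, tau, fixed=fixed, warm=warm)
        warm = (b, a - b)
        if ll > best[0]:
            best = (ll, tau, a, b)
    ll_best, tau_best, a_best, b_best = best

    lo = max(t0 + cfg.tau_tol, tau_best - step)
    hi = min(horizon, tau_best + step)
    res = optimize.minimize_scalar(
        lambda tau: -_profile_at_tau(time, te, S_T, t0, tau, fixed=fixed)[0],
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": cfg.tau_tol},
    )
    if res.success and -res.fun >= ll_best:
        tau_best = float(res.x)
        ll_best, a_best, b_best = _profile_at_tau(time, te, S_T, t0, tau_best, fixed=fixed)
    return tau_best, ll_best, a_best, b_best


def _arrays(cohort: Cohort, cfg: FitConfig):
    _validate_times(cohort, cfg.origin)
    te = cohort.time[cohort.event]
    S_T = float(np.sum(cohort.time - cfg.origin))
    return cohort.time, te, S_T


def fit_mle(cohort: Cohort, config: FitConfig = FitConfig()) -> FitResult:
    """Maximum-likelihood fit of the join-point hazard to a cohort.

    Raises :class:`NoEventsError` when the cohort has no deaths. A fit in
    which the decline vanishes (acute equals background, a constant hazard)
    or the phase shift lands on the search boundary sets ``boundary_flag``.
    """
    time, te, S_T = _arrays(cohort, config)
    if te.size == 0:
        raise NoEventsError("no events in cohort: hazard rates are unidentifiable")
    warnings = ()
    if te.size == cohort.n:
        warnings = ("all subjects experienced the event; the background plateau "
                    "is weakly identified without censored follow-up",)
    tau, ll, a, b = _maximize_over_tau(time, te, S_T, config)
    # the decline is weakly identified when the constant-hazard submodel
    # (acute = background, no join point) sits inside the 2-df likelihood
    # band of the maximum, or when the join point hits the search edge
    r = te.size / S_T
    w_e, S_W = _tau_stats(time, te, config.origin, tau)
    ll_const = _rate_loglik(r, 0.0, w_e, S_T, S_W)
    boundary = (
        (a - b) <= 1e-9 * max(a, 1e-300)
        or 2.0 * (ll - ll_const) < stats.chi2.ppf(0.95, 2)
        or tau <= config.origin + 2 * config.tau_tol
        or tau >= config.horizon - 2 * config.tau_tol
    )
    params = JoinPointParams(a, b, tau, config.origin)
    return FitResult(
        params=params,
        loglik=ll,
        n_subjects=cohort.n,
        n_events=int(te.size),
        converged=bool(math.isfinite(ll)),
        boundary_flag=bool(boundary),
        warnings=warnings,
    )


# ---------------------------------------------------------------------------
# profile-likelihood confidence intervals


def _profile_value(cohort_arrays, cfg: FitConfig, which: str, value: float) -> float:
    """Profile log-likelihood with one parameter pinned at ``value``."""
    time, te, S_T = cohort_arrays
    if which == "phase_shift":
        if value <= cfg.origin:
            return -math.inf
        return _profile_at_tau(time, te, S_T, cfg.origin, value)[0]
    if which not in ("acute_rate", "background_rate"):
        raise ValueError(f"unknown parameter name: {which!r}")
    if value < 0:
        return -math.inf
    return _maximize_over_tau(time, te, S_T, cfg, fixed={which: value},
                              step=cfg.profile_tau_step)[1]


def profile_ci(
    cohort: Cohort,
    fit: FitResult,
    which: str,
    coverage: float = 0.95,
    config: FitConfig = FitConfig(),
) -> ParamCI:
    """Profile-likelihood confidence interval for one parameter.

    The interval collects values whose profile log-likelihood stays within
    ``chi2_1(coverage) / 2`` of the maximum (1.921 nats at 95%), the
    likelihood-ratio inversion that yields the asymmetric intervals typical
    of the phase shift. Endpoints are located by monotone bisection; if the
    profile never crosses the threshold before the search bound the
    corresponding side is flagged unbounded.
    """
    if not fit.converged:
        raise ValueError("cannot profile an unconverged fit")
    if which not in _PARAM_NAMES:
        raise ValueError(f"unknown parameter name: {which!r}")
    arrays = _arrays(cohort, config)
    threshold = fit.loglik - stats.chi2.ppf(coverage, 1) / 2.0
    v0 = getattr(fit.params, which)

    def excess(v: float) -> float:
        return _profile_value(arrays, config, which, v) - threshold

    if which == "phase_shift":
        lo_limit, hi_limit = config.origin + config.tau_tol, config.horizon
        steps_down = [v0 - (2.0**k) * 1.0 for k in range(12)]
        steps_up = [v0 + (2.0**k) * 1.0 for k in range(12)]
        xtol = config.tau_tol
    else:
        lo_limit, hi_limit = 0.0, v0 * 64.0 if v0 > 0 else 1.0
        steps_down = [v0 / (1.3**k) for k in range(1, 40)]
        steps_up = [v0 * (1.3**k) for k in range(1, 40)]
        xtol = max(v0, 1e-12) * 1e-5

    def find_endpoint(candidates, limit, side):
        prev = v0
        for v in candidates:
            v = min(max(v, lo_limit), hi_limit)
            if excess(v) < 0.0:
                lo, hi = (v, prev) if side == "lower" else (prev, v)
                root = optimize.brentq(excess, lo, hi, xtol=xtol)
                return float(root), False
            prev = v
            if v == limit:
                break
        return float(limit), True

    lower, lower_unb = find_endpoint(steps_down, lo_limit, "lower")
    upper, upper_unb = find_endpoint(steps_up, hi_limit, "upper")
    return ParamCI(lower, upper, coverage, lower_unb, upper_unb)


def fit_with_ci(
    cohort: Cohort,
    config: FitConfig = FitConfig(),
    coverage: float = 0.95,
) -> FitResult:
    """Convenience wrapper: MLE plus profile CIs for all three parameters."""
    fit = fit_mle(cohort, config)
    ci = {name: profile_ci(cohort, fit, name, coverage, config) for name in _PARAM_NAMES}
    return FitResult(
        params=fit.params, loglik=fit.loglik, n_subjects=fit.n_subjects,
        n_events=fit.n_events, converged=fit.converged,
        boundary_flag=fit.boundary_flag, warnings=fit.warnings, ci=ci,
    )


# ---------------------------------------------------------------------------
# likelihood-ratio group comparisons


def _check_levels(cohorts_by_level: Mapping[str, Cohort]) -> None:
    if len(cohorts_by_level) < 2:
        raise ValueError("need at least two levels to compare")
    for label, cohort in cohorts_by_level.items():
        if cohort.n_events == 0:
            raise NoEventsError(
                f"level {label!r} has no events; merge it with a neighbouring "
                "stratum before testing"
            )


def overall_test(
    cohorts_by_level: Mapping[str, Cohort],
    config: FitConfig = FitConfig(),
) -> ComparisonResult:
    """Global LRT of a common hazard structure across levels.

    Null: one parameter triple shared by every level; alternative: a free
    triple per level. Degrees of freedom 3(k-1) for k levels.
    """
    _check_levels(cohorts_by_level)
    k = len(cohorts_by_level)
    pooled = Cohort(
        np.concatenate([c.time for c in cohorts_by_level.values()]),
        np.concatenate([c.event for c in cohorts_by_level.values()]),
    )
    ll0 = fit_mle(pooled, config).loglik
    ll1 = sum(fit_mle(c, config).loglik for c in cohorts_by_level.values())
    stat = 2.0 * (ll1 - ll0)
    df = 3 * (k - 1)
    return ComparisonResult(
        statistic=stat,
        df=df,
        p_value=float(stats.chi2.sf(max(stat, 0.0), df)),
        hypothesis=f"common (acute, background, phase shift) across {k} levels: "
                   + ", ".join(map(str, cohorts_by_level)),
    )


def _shared_parameter_loglik(arrays_by_level, cfg: FitConfig, which: str, value: float) -> float:
    return sum(_profile_value(arrays, cfg, which, value) for arrays in arrays_by_level)


def parameter_equality_test(
    cohorts_by_level: Mapping[str, Cohort],
    which: str,
    config: FitConfig = FitConfig(),
) -> ComparisonResult:
    """LRT that one named parameter is shared across levels.

    Null: ``which`` takes one common value while the other two parameters
    remain free per level; alternative: everything free. df = k - 1.
    """
    if which not in _PARAM_NAMES:
        raise ValueError(f"unknown parameter name: {which!r}")
    _check_levels(cohorts_by_level)
    k = len(cohorts_by_level)
    fits = {lab: fit_mle(c, config) for lab, c in cohorts_by_level.items()}
    ll1 = sum(f.loglik for f in fits.values())
    arrays_by_level = [_arrays(c, config) for c in cohorts_by_level.values()]
    values = np.array([getattr(f.params, which) for f in fits.values()])

    def neg(value: float) -> float:
        return -_shared_parameter_loglik(arrays_by_level, config, which, value)

    if which == "phase_shift":
        lo = max(config.origin + config.tau_tol, values.min() - 20.0)
        hi = min(config.horizon, values.max() + 20.0)
        xatol = config.tau_tol
    else:
        lo, hi = values.min() / 3.0, values.max() * 3.0
        xatol = float(values.mean()) * 1e-4
    res = optimize.minimize_scalar(neg, bounds=(lo, hi), method="bounded",
                                   options={"xatol": xatol})
    ll0 = -res.fun
    # the shared optimum can never beat per-level freedom; guard numerics
    stat = 2.0 * (ll1 - ll0)
    df = k - 1
    return ComparisonResult(
        statistic=stat,
        df=df,
        p_value=float(stats.chi2.sf(max(stat, 0.0), df)),
        hypothesis=f"{which} shared across {k} levels (other parameters free): "
                   + ", ".join(map(str, cohorts_by_level)),
    )


def fixed_value_test(
    cohort: Cohort,
    which: str,
    value: float,
    config: FitConfig = FitConfig(),
) -> ComparisonResult:
    """Single-cohort LRT that ``which`` equals ``value`` (df = 1).

    Dual of :func:`profile_ci`: a value on the 95% interval boundary gives
    p close to 0.05.
    """
    if which not in _PARAM_NAMES:
        raise ValueError(f"unknown parameter name: {which!r}")
    fit = fit_mle(cohort, config)
    ll0 = _profile_value(_arrays(cohort, config), config, which, value)
    stat = 2.0 * (fit.loglik - ll0)
    return ComparisonResult(
        statistic=stat,
        df=1,
        p_value=float(stats.chi2.sf(max(stat, 0.0), 1)),
        hypothesis=f"{which} = {value}",
    )
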