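"""Join-point hazard model for early postoperative mortality.

The hazard of death after surgery is modelled as a linear decline from the
*acute phase death rate* (the hazard at the acute-phase origin, day 3 by
default) down to the *background death rate*, reached at the *phase shift
time* ``tau``; beyond ``tau`` the hazard stays constant:

    h(t) = b + (a - b) * (tau - t) / (tau - t0)   for t0 <= t <= tau
    h(t) = b                                      for t > tau

with ``a`` the acute rate, ``b`` the background rate and ``t0`` the origin.
All rates are internal events-per-person-day; the conventional reporting
scale of deaths per 1000 patients per day is applied only when formatting
output (see :data:`REPORT_SCALE`).

Everything here is a pure function of the parameters; the estimation,
simulation and diagnostic layers are built on top of these primitives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "REPORT_SCALE",
    "JoinPointParams",
    "hazard_value",
    "cumulative_hazard",
    "survival_given_origin",
    "event_density",
    "invert_cumulative_hazard",
]

#: Multiplier taking internal rates (events/person-day) to the reporting
#: scale of deaths per 1000 patients per day.
REPORT_SCALE = 1000.0


@dataclass(frozen=True)
class JoinPointParams:
    """Parameters of the join-point (decline-to-plateau) hazard.

    Parameters
    ----------
    acute_rate
        Hazard at the acute-phase origin, events per person-day. This is the
        model's maximum: the hazard declines from here.
    background_rate
        Plateau hazard after the phase shift, events per person-day.
    phase_shift
        Join-point day ``tau`` at which the declining segment meets the
        plateau; days since surgery.
    origin
        Day the acute phase starts (default 3); the model is undefined
        before it, mirroring the exclusion of the first two postoperative
        days from modelling.
    """

    acute_rate: float
    background_rate: float
    phase_shift: float
    origin: float = 3.0

    def __post_init__(self) -> None:
        if not (self.acute_rate >= self.background_rate >= 0.0):
            raise ValueError(
                "require acute_rate >= background_rate >= 0, got "
                f"acute={self.acute_rate!r}, background={self.background_rate!r}"
            )
        if not self.phase_shift > self.origin:
            raise ValueError(
                f"phase_shift ({self.phase_shift!r}) must exceed origin ({self.origin!r})"
            )
        for name in ("acute_rate", "background_rate", "phase_shift", "origin"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    @classmethod
    def from_per_1000(
        cls,
        acute_rate: float,
        background_rate: float,
        phase_shift: float,
        origin: float = 3.0,
    ) -> "JoinPointParams":
        """Build params from rates quoted on the per-1000-per-day scale."""
        return cls(
            acute_rate / REPORT_SCALE, background_rate / REPORT_SCALE, phase_shift, origin
        )

    def per_1000(self) -> "JoinPointParams":
        """Return a copy with rates multiplied onto the reporting scale."""
        return replace(
            self,
            acute_rate=self.acute_rate * REPORT_SCALE,
            background_rate=self.background_rate * REPORT_SCALE,
        )


def _check_domain(params: JoinPointParams, t: np.ndarray) -> None:
    if np.any(t < params.origin - 1e-12):
        raise ValueError(
            f"model is undefined before the acute-phase origin (day {params.origin}); "
            f"got t={np.min(t)}"
        )


def hazard_value(params: JoinPointParams, t):
    """Hazard at time ``t`` (days since surgery), events per person-day.

    Linear between ``origin`` and ``phase_shift``, constant at
    ``background_rate`` afterwards; continuous and non-increasing.
    """
    t_arr = np.asarray(t, dtype=float)
    _check_domain(params, t_arr)
    a, b, tau, t0 = params.acute_rate, params.background_rate, params.phase_shift, params.origin
    frac = np.clip((tau - t_arr) / (tau - t0), 0.0, 1.0)
    out = b + (a - b) * frac
    return out if out.ndim else float(out)


def cumulative_hazard(params: JoinPointParams, t):
    """Integrated hazard from ``origin`` to ``t`` (dimensionless).

    Closed form: quadratic in ``t`` on the declining segment, linear with
    slope ``background_rate`` beyond the phase shift.
    """
    t_arr = np.asarray(t, dtype=float)
    _check_domain(params, t_arr)
    a, b, tau, t0 = params.acute_rate, params.background_rate, params.phase_shift, params.origin
    width = tau - t0
    tc = np.minimum(t_arr, tau)
    # integral of the declining linear segment from t0 to min(t, tau)
    decline = b * (tc - t0) + (a - b) * (width**2 - (tau - tc) ** 2) / (2.0 * width)
    plateau = b * np.maximum(t_arr - tau, 0.0)
    out = decline + plateau
    return out if out.ndim else float(out)


def survival_given_origin(params: JoinPointParams, t):
    """P(survive to ``t`` | alive at ``origin``) = exp(-H(t))."""
    out = np.exp(-np.asarray(cumulative_hazard(params, t)))
    return out if out.ndim else float(out)


def event_density(params: JoinPointParams, t):
    """Density of the event time conditional on survival to ``origin``:
    f(t) = h(t) * S(t)."""
    out = np.asarray(hazard_value(params, t)) * np.asarray(survival_given_origin(params, t))
    return out if out.ndim else float(out)


def invert_cumulative_hazard(params: JoinPointParams, h):
    """Solve ``cumulative_hazard(t) = h`` for ``t``.

    Piecewise closed form: a quadratic root on the declining segment, a
    linear continuation on the plateau. This is the workhorse of
    inverse-transform simulation of event times.

    Raises
    ------
    ValueError
        If ``h`` is negative, or exceeds the attainable total hazard when
        ``background_rate`` is zero (the cumulative hazard then saturates
        at its value at the phase shift).
    """
    h_arr = np.asarray(h, dtype=float)
    if np.any(h_arr < 0):
        raise ValueError("cumulative hazard must be non-negative")
    a, b, tau, t0 = params.acute_rate, params.background_rate, params.phase_shift, params.origin
    width = tau - t0
    h_tau = cumulative_hazard(params, tau)
    if b == 0.0 and np.any(h_arr > h_tau + 1e-12):
        raise ValueError(
            "requested cumulative hazard exceeds the attainable range "
            f"(H saturates at {h_tau:.6g} when the background rate is 0)"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        # declining segment: h = b*(t-t0) + (a-b)*(width^2 - (tau-t)^2)/(2 width)
        # substitute u = t - t0, slope s = (a-b)/width:  (s/2)u^2 - ... easier via
        # the quadratic in u: h = a*u - s*u^2/2  =>  u = (a - sqrt(a^2 - 2 s h)) / s
        s = (a - b) / width
        if s > 0:
            disc = np.maximum(a * a - 2.0 * s * h_arr, 0.0)
            u_decl = (a - np.sqrt(disc)) / s
        else:  # constant hazard: linear everywhere
            u_decl = np.divide(h_arr, a, out=np.full_like(h_arr, np.inf), where=a > 0)
        t_decl = t0 + u_decl
        t_plat = tau + np.divide(
            h_arr - h_tau, b, out=np.full_like(h_arr, np.inf), where=b > 0
        )
    out = np.where(h_arr <= h_tau, t_decl, t_plat)
    # exact endpoints
    out = np.where(h_arr == 0.0, t0, out)
    return out if out.ndim else float(out)
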