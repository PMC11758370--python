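"""Registry-like synthetic cohort generator.

Emulates the patient table the analysis pipeline expects: one row per
operated patient with survival day, vital status and covariates, generated
so that the hazard structure on days 3–180 follows stratum-specific
join-point parameters. Event times are drawn by inverse-transform sampling
of the model's cumulative hazard conditional on survival to the origin
(day 3); a small mass of day-0–2 deaths, an emergency-surgery fraction,
sporadic missingness in ASA and age, and administrative censoring at the
horizon are planted on top, so the exclusion bookkeeping of the pipeline
is exercised end to end.

Covariates not tied to a stratum (sex, age band, period, stage) are drawn
independently from published per-site margins — adequate because only the
hazard structure is load-bearing for the analysis; registry
cross-tabulations are not reproduced.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import reference
from .model import JoinPointParams, invert_cumulative_hazard

__all__ = [
    "Stratum", "GeneratorConfig", "generate_cohort", "registry_preset",
    "single_stratum_config", "model_exact_cohort",
]

#: Column order of the raw cohort CSV dialect.
RAW_COLUMNS = [
    "id", "age", "sex", "asa", "year", "site", "stage", "urgency",
    "survival_time", "vital_status", "status_known",
]

_AGE_SAMPLERS = {
    "0-69": (45, 69),
    "70-79": (70, 79),
    "80+": (80, 94),
}
_PERIOD_YEARS = {
    "2007-2011": (2007, 2011),
    "2012-2016": (2012, 2016),
    "2017-2020": (2017, 2020),
}
_ASA_FROM_GROUP = {"I": ("I",), "II": ("II",), "III-IV": ("III", "IV")}


@dataclass(frozen=True)
class Stratum:
    """One generator stratum: a covariate label set and its hazard."""

    site: str
    asa_group: str
    weight: float
    params: JoinPointParams


@dataclass(frozen=True)
class GeneratorConfig:
    """Everything needed to draw a reproducible registry-like cohort.

    Probabilities are per subject; ``strata`` weights must sum to one.
    ``horizon`` is the administrative censoring day (180 in the main
    analysis, 360 when the late constant-rate window is needed).
    """

    n: int
    seed: int
    strata: Sequence[Stratum]
    horizon: float = 180.0
    origin: float = 3.0
    early_death_prob: float = reference.EARLY_DEATH_FRACTION
    emergency_prob: float = reference.EMERGENCY_FRACTION
    status_unknown_prob: float = reference.STATUS_UNKNOWN_FRACTION
    missing_asa_prob: float = reference.MISSING_ASA_FRACTION
    missing_age_prob: float = reference.MISSING_AGE_FRACTION
    site_margins: Mapping[str, Mapping[str, Mapping[str, float]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("cohort size must be positive")
        if not self.strata:
            raise ValueError("at least one stratum is required")
        total = sum(s.weight for s in self.strata)
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"stratum weights must sum to 1, got {total}")
        for p in (self.early_death_prob, self.emergency_prob, self.status_unknown_prob,
                  self.missing_asa_prob, self.missing_age_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        for s in self.strata:
            if s.weight < 0:
                raise ValueError("stratum weights must be non-negative")
            if s.params.origin != self.origin:
                raise ValueError("stratum hazard origin must match the config origin")


def _margins_for_site(config: GeneratorConfig, site: str, factor: str) -> dict[str, float]:
    if config.site_margins and factor in config.site_margins.get(site, {}):
        return dict(config.site_margins[site][factor])
    counts = {
        level: by_site[site]
        for level, by_site in reference.TABLE1_COUNTS[factor].items()
    }
    total = sum(counts.values())
    return {level: c / total for level, c in counts.items()}


def _draw_categorical(rng: np.random.Generator, margins: dict[str, float], n: int) -> np.ndarray:
    levels = list(margins)
    probs = np.array([margins[k] for k in levels], dtype=float)
    probs = probs / probs.sum()
    return np.array(levels, dtype=object)[rng.choice(len(levels), size=n, p=probs)]


def generate_cohort(config: GeneratorConfig):
    """Draw a raw cohort table plus a ground-truth sidecar.

    Returns ``(table, truth)``: ``table`` follows the CohortRow CSV
    dialect (integer survival days, missing encoded as NA); ``truth``
    carries the per-subject stratum index, the true parameter triple and
    the latent continuous event time for oracle tests. Deterministic for a
    given config (same seed, same table).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n
    stratum_idx = rng.choice(
        len(config.strata), size=n, p=np.array([s.weight for s in config.strata])
    )

    # latent continuous event time conditional on surviving to the origin,
    # via inverse-transform sampling of each stratum's cumulative hazard
    u = rng.uniform(size=n)
    target = -np.log(u)
    latent = np.empty(n)
    for j, stratum in enumerate(config.strata):
        mask = stratum_idx == j
        if not mask.any():
            continue
        p = stratum.params
        if p.background_rate <= 0.0:
            # cumulative hazard saturates: targets beyond it never die
            h_max = (p.acute_rate + p.background_rate) / 2.0 * (p.phase_shift - p.origin)
            capped = np.minimum(target[mask], h_max)
            latent[mask] = np.where(
                target[mask] > h_max,
                np.inf,
                np.asarray(invert_cumulative_hazard(p, capped)),
            )
        else:
            latent[mask] = invert_cumulative_hazard(p, target[mask])

    early = rng.uniform(size=n) < config.early_death_prob
    early_day = rng.integers(0, 3, size=n)

    event = np.where(early, True, latent <= config.horizon)
    day = np.where(
        early,
        early_day,
        np.where(latent <= config.horizon, np.floor(latent), config.horizon),
    ).astype(int)

    site = np.array([config.strata[j].site for j in stratum_idx], dtype=object)
    asa_group = np.array([config.strata[j].asa_group for j in stratum_idx], dtype=object)
    asa = np.array(
        [rng.choice(_ASA_FROM_GROUP[g]) for g in asa_group], dtype=object
    )

    age = np.empty(n, dtype=float)
    year = np.empty(n, dtype=int)
    sex = np.empty(n, dtype=object)
    stage = np.empty(n, dtype=object)
    for s in set(site):
        mask = site == s
        m = int(mask.sum())
        age_band = _draw_categorical(rng, _margins_for_site(config, s, "age_group"), m)
        lo = np.array([_AGE_SAMPLERS[b][0] for b in age_band])
        hi = np.array([_AGE_SAMPLERS[b][1] for b in age_band])
        age[mask] = rng.integers(lo, hi + 1)
        period = _draw_categorical(rng, _margins_for_site(config, s, "period"), m)
        ylo = np.array([_PERIOD_YEARS[p][0] for p in period])
        yhi = np.array([_PERIOD_YEARS[p][1] for p in period])
        year[mask] = rng.integers(ylo, yhi + 1)
        sex[mask] = _draw_categorical(rng, _margins_for_site(config, s, "sex"), m)
        stage[mask] = _draw_categorical(rng, _margins_for_site(config, s, "stage"), m)

    urgency = np.where(rng.uniform(size=n) < config.emergency_prob, "emergency", "elective")
    status_known = rng.uniform(size=n) >= config.status_unknown_prob
    age_out = pd.array(age, dtype="Int64")
    age_out[rng.uniform(size=n) < config.missing_age_prob] = pd.NA
    asa_out = pd.array(asa, dtype="string")
    asa_out[rng.uniform(size=n) < config.missing_asa_prob] = pd.NA

    table = pd.DataFrame(
        {
            "id": np.arange(1, n + 1),
            "age": age_out,
            "sex": sex,
            "asa": asa_out,
            "year": year,
            "site": site,
            "stage": stage,
            "urgency": urgency,
            "survival_time": day,
            "vital_status": np.where(event, "dead", "alive"),
            "status_known": status_known.astype(int),
        }
    )
    truth = pd.DataFrame(
        {
            "id": table["id"],
            "stratum": stratum_idx,
            "early_death": early,
            "latent_time": latent,
            "acute_rate": [config.strata[j].params.acute_rate for j in stratum_idx],
            "background_rate": [config.strata[j].params.background_rate for j in stratum_idx],
            "phase_shift": [config.strata[j].params.phase_shift for j in stratum_idx],
        }
    )
    return table, truth


def model_exact_cohort(truth: pd.DataFrame, config: GeneratorConfig):
    """Estimation cohort built from the latent continuous event times.

    The registry table records whole days (death times floored to the
    calendar day), which carries a small day-level recording error into
    the fit. Calibration experiments that ask whether the estimator and
    its confidence intervals behave as advertised *under the model* must
    simulate from the model exactly; this view applies only the
    administrative censoring at the horizon to the latent times and drops
    the planted pre-origin deaths, whose times do not come from the
    join-point hazard.
    """
    from .estimation import Cohort

    latent = truth.loc[~truth["early_death"], "latent_time"].to_numpy(float)
    event = latent <= config.horizon
    time = np.minimum(latent, config.horizon)
    return Cohort(time, event)


def registry_preset(n: int = reference.HEADLINE_COUNTS["n"], seed: int = 20070101,
                    horizon: float = 180.0) -> GeneratorConfig:
    """Standard end-to-end fixture: site x ASA strata with published hazards.

    Stratum weights combine the published site split (colon 67%, rectal
    33%) with the per-site ASA distribution; each stratum's join-point
    parameters are the published per-site ASA fits.
    """
    strata = []
    total = sum(reference.SITE_TOTALS.values())
    for site, site_n in reference.SITE_TOTALS.items():
        asa_counts = {
            g: by_site[site] for g, by_site in reference.TABLE1_COUNTS["asa_group"].items()
        }
        asa_total = sum(asa_counts.values())
        fits = reference.PUBLISHED_FITS[f"{site}_asa"]
        for grp, count in asa_counts.items():
            a, b, tau = fits[grp]
            strata.append(
                Stratum(
                    site=site,
                    asa_group=grp,
                    weight=(site_n / total) * (count / asa_total),
                    params=JoinPointParams.from_per_1000(a, b, tau),
                )
            )
    # renormalize against float round-off
    w = sum(s.weight for s in strata)
    strata = [replace(s, weight=s.weight / w) for s in strata]
    return GeneratorConfig(n=n, seed=seed, strata=tuple(strata), horizon=horizon)


def single_stratum_config(
    params: JoinPointParams,
    n: int,
    seed: int,
    horizon: float = 180.0,
    **overrides,
) -> GeneratorConfig:
    """One-stratum cohort from a given hazard — the workhorse of the
    recovery, coverage and calibration simulations."""
    defaults = dict(
        early_death_prob=0.0, emergency_prob=0.0, status_unknown_prob=0.0,
        missing_asa_prob=0.0, missing_age_prob=0.0,
    )
    defaults.update(overrides)
    return GeneratorConfig(
        n=n, seed=seed, horizon=horizon, origin=params.origin,
        strata=(Stratum(site="colon", asa_group="II", weight=1.0, params=params),),
        **defaults,
    )
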