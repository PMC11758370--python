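"""Published benchmark values for Swedish elective colorectal cancer surgery.

These constants transcribe the headline counts, demographic margins and
fitted join-point parameters reported for the nationwide cohort of
elective colorectal cancer resections in Sweden, 2007–2020 (56 096
analyzable patients, 180-day follow-up). They serve two purposes: they
parameterize the registry-like synthetic cohort preset, and they are the
frozen inputs for the descriptive-arithmetic checks (every percentage in
the published demography table must recompute exactly from its counts).

Rates are on the reporting scale, deaths per 1000 patients per day; the
phase shift is in days since surgery.
"""

from __future__ import annotations

#: Exclusion chain of the source cohort: all resections -> elective only
#: -> survival status known.
EXCLUSION_CHAIN = {
    "all_resections": 64433,
    "elective": 56239,
    "status_known": 56096,
}

#: Headline fatality counts in the analyzable cohort (denominator 56 096).
HEADLINE_COUNTS = {
    "n": 56096,
    "dead_0_30": 805,
    "dead_0_90": 1458,
    "dead_0_2": 59,
    "dead_3_180": 2216,
    "dead_0_180": 2275,  # 59 early deaths + 2216 modelled-window deaths
    "censored": 53821,
}

#: Demography table: per-site counts by category (colon, rectal).
#: Site totals: colon 37 568 (67%), rectal 18 528 (33%).
SITE_TOTALS = {"colon": 37568, "rectal": 18528}

TABLE1_COUNTS = {
    "sex": {
        "male": {"colon": 18464, "rectal": 11262},
        "female": {"colon": 19104, "rectal": 7266},
    },
    "asa_group": {
        "I": {"colon": 4697, "rectal": 3421},
        "II": {"colon": 19727, "rectal": 10265},
        "III-IV": {"colon": 12368, "rectal": 4512},
    },
    "age_group": {
        "0-69": {"colon": 13362, "rectal": 9331},
        "70-79": {"colon": 13973, "rectal": 6430},
        "80+": {"colon": 10225, "rectal": 2763},
    },
    "period": {
        "2007-2011": {"colon": 12580, "rectal": 6557},
        "2012-2016": {"colon": 13149, "rectal": 6699},
        "2017-2020": {"colon": 11839, "rectal": 5272},
    },
    "stage": {
        "I": {"colon": 6084, "rectal": 4630},
        "II": {"colon": 12987, "rectal": 4675},
        "III": {"colon": 10899, "rectal": 5628},
        "IV": {"colon": 4313, "rectal": 1866},
        "complete_response": {"colon": 10, "rectal": 449},
    },
    "fatality": {
        "dead_0_30": {"colon": 583, "rectal": 222},
        "dead_0_90": {"colon": 1066, "rectal": 392},
        "dead_0_2": {"colon": 45, "rectal": 14},
        "dead_3_180": {"colon": 1636, "rectal": 580},
        "censored": {"colon": 35887, "rectal": 17934},
    },
}

#: Published join-point fits: analysis -> level -> (acute, background, phase
#: shift) on the per-1000-per-day reporting scale, origin day 3.
PUBLISHED_FITS = {
    "overall": {"combined": (0.917, 0.185, 23.8)},
    "site": {"rectal": (0.84, 0.14, 22.9), "colon": (0.90, 0.20, 27.3)},
    "colon_period": {
        "2007-2011": (1.07, 0.25, 31.4),
        "2012-2016": (0.79, 0.20, 27.0),
        "2017-2020": (0.84, 0.16, 22.5),
    },
    "colon_age": {
        "0-69": (0.28, 0.12, 27.9),
        "70-79": (0.95, 0.19, 19.8),
        "80+": (1.62, 0.33, 35.5),
    },
    "colon_asa": {
        "I": (0.39, 0.07, 13.3),
        "II": (0.57, 0.14, 19.8),
        "III-IV": (1.55, 0.34, 38.7),
    },
    "rectal_period": {
        "2007-2011": (1.80, 0.21, 10.1),
        "2012-2016": (0.90, 0.12, 19.1),
        "2017-2020": (0.34, 0.10, 23.1),
    },
    "rectal_age": {
        "0-69": (0.51, 0.07, 9.3),
        "70-79": (1.38, 0.18, 12.0),
        "80+": (1.98, 0.27, 43.0),
    },
    "rectal_asa": {
        "I": (0.24, 0.04, 24.4),
        "II": (0.96, 0.11, 13.2),
        "III-IV": (1.59, 0.30, 25.8),
    },
}

#: Published 95% profile confidence intervals for the overall fit.
OVERALL_CI = {
    "acute_rate": (0.794, 1.012),
    "background_rate": (0.176, 0.194),
    "phase_shift": (21.5, 28.2),
}

#: Small-count fractions of the analyzable cohort used by the generator.
EMERGENCY_FRACTION = 1.0 - EXCLUSION_CHAIN["elective"] / EXCLUSION_CHAIN["all_resections"]
STATUS_UNKNOWN_FRACTION = (
    EXCLUSION_CHAIN["elective"] - EXCLUSION_CHAIN["status_known"]
) / EXCLUSION_CHAIN["elective"]
EARLY_DEATH_FRACTION = HEADLINE_COUNTS["dead_0_2"] / HEADLINE_COUNTS["n"]
MISSING_ASA_FRACTION = 0.02
MISSING_AGE_FRACTION = 12 / HEADLINE_COUNTS["n"]
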