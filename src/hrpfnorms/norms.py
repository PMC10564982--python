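"""Published reference norms for South Punjab adolescents aged 12-16.

Age- and sex-specific LMS triples for BMI and hand-grip strength, grade-band
edge tables for the four health-related fitness indicators, the expert
pairwise judgment matrices, and the final expert-adjusted indicator weights.
These are the operational constants of the evaluation system; the synthetic
cohort generator treats them as ground truth, and the table builders
reproduce them from the triples.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .bccg import LMSTriple
from .curves import ReferenceCurve

__all__ = [
    "BMI_LMS",
    "HANDGRIP_LMS",
    "HRPF_BAND_EDGES",
    "COMPOSITE_JUDGMENT",
    "HRPF_JUDGMENT",
    "FINAL_WEIGHTS",
    "printed_curves",
    "printed_band_edges",
]

# --- LMS triples: {sex: {age: (L, M, S)}} ---------------------------------

BMI_LMS = {
    "boys": {
        12: (0.203, 16.59, 0.141),
        13: (-0.318, 16.81, 0.131),
        14: (-0.838, 17.03, 0.125),
        15: (-1.358, 17.26, 0.124),
        16: (-1.879, 17.48, 0.125),
    },
    "girls": {
        12: (0.283, 15.26, 0.202),
        13: (-0.173, 15.71, 0.172),
        14: (-0.495, 15.73, 0.168),
        15: (-0.234, 16.74, 0.159),
        16: (0.382, 16.81, 0.120),
    },
}

HANDGRIP_LMS = {
    "boys": {
        12: (0.227, 22.53, 0.483),
        13: (-0.004, 25.77, 0.432),
        14: (-0.198, 29.00, 0.393),
        15: (-0.339, 32.24, 0.364),
        16: (-0.413, 35.47, 0.345),
    },
    "girls": {
        12: (0.268, 14.12, 0.279),
        13: (0.442, 15.01, 0.317),
        14: (0.615, 16.48, 0.331),
        15: (0.789, 18.16, 0.293),
        16: (0.963, 20.18, 0.286),
    },
}

# --- Grade-band edge tables ------------------------------------------------
# For each indicator/sex/age: (vp_lo, vp_hi, poor_hi, medium_hi, good_hi) in
# measurement units.  vp_lo is the published minimum-score line (~P3); the
# other four edges sit at ~P10/P35/P65/P90.  The Excellent band is open above
# good_hi; values below vp_lo receive no score.

HRPF_BAND_EDGES = {
    "hand_grip": {
        "boys": {
            12: (8.14, 11.56, 18.63, 27.03, 40.21),
            13: (11.45, 14.82, 21.82, 30.43, 44.86),
            14: (14.55, 17.94, 24.98, 33.82, 49.31),
            15: (17.42, 20.90, 28.11, 37.22, 53.58),
            16: (19.96, 23.63, 31.17, 40.66, 57.81),
        },
        "girls": {
            12: (8.02, 9.59, 12.66, 15.70, 19.87),
            13: (7.51, 9.69, 13.24, 16.90, 21.81),
            14: (7.52, 10.08, 14.43, 18.63, 24.03),
            15: (8.81, 11.63, 16.14, 20.23, 25.23),
            16: (9.46, 12.84, 17.96, 22.41, 27.62),
        },
    },
    "modified_pullup": {
        "boys": {
            12: (1.0, 2.58, 6.98, 12.51, 21.29),
            13: (1.0, 2.70, 7.53, 13.70, 23.06),
            14: (1.0, 2.83, 8.24, 14.64, 23.56),
            15: (1.0, 3.57, 9.14, 15.21, 23.94),
            16: (3.0, 4.78, 9.77, 16.37, 27.52),
        },
        "girls": {
            12: (1.0, 1.13, 2.35, 4.53, 10.61),
            13: (1.0, 1.16, 2.39, 4.63, 11.87),
            14: (1.0, 1.17, 2.39, 4.66, 10.81),
            15: (1.0, 1.17, 2.41, 4.72, 10.68),
            16: (1.0, 1.24, 2.44, 4.81, 11.40),
        },
    },
    "shuttle_vo2max": {
        "boys": {
            12: (33.64, 35.84, 44.21, 47.53, 50.18),
            13: (30.63, 32.83, 41.85, 45.70, 48.85),
            14: (29.11, 31.31, 39.59, 43.86, 47.58),
            15: (22.60, 30.13, 37.37, 42.02, 46.48),
            16: (24.64, 29.06, 35.23, 40.20, 45.71),
        },
        "girls": {
            12: (34.28, 36.54, 40.15, 43.46, 47.59),
            13: (33.07, 34.83, 37.96, 41.32, 46.40),
            14: (31.83, 33.17, 35.81, 39.16, 46.17),
            15: (30.18, 31.24, 33.56, 37.28, 38.40),
            16: (31.31, 31.72, 32.46, 33.27, 34.58),
        },
    },
    "plank": {
        "boys": {
            12: (7.59, 15.29, 38.48, 79.14, 156.37),
            13: (8.27, 15.40, 38.86, 77.91, 161.88),
            14: (8.67, 16.73, 40.06, 78.20, 166.88),
            15: (12.88, 20.45, 41.72, 78.57, 168.61),
            16: (13.32, 21.07, 42.40, 83.38, 202.18),
        },
        "girls": {
            12: (8.50, 14.20, 33.15, 54.38, 83.63),
            13: (7.13, 16.74, 34.30, 60.75, 111.24),
            14: (10.93, 17.71, 36.82, 69.66, 148.01),
            15: (16.33, 23.61, 43.39, 78.12, 171.31),
            16: (17.43, 25.86, 49.07, 90.00, 197.90),
        },
    },
}

# --- Expert weighting ------------------------------------------------------

#: 2x2 top-level judgment matrix: body shape vs health-related fitness.
COMPOSITE_JUDGMENT = (
    ["body_shape", "hrpf"],
    np.array([[1.0, 3.44], [1.0 / 3.44, 1.0]]),
)

#: 4x4 judgment matrix over the four fitness indicators.  The printed matrix
#: carries a small reciprocity rounding blemish (2.44 vs 1/2.444), preserved
#: here on purpose; validation absorbs it by tolerance.
HRPF_JUDGMENT = (
    ["hand_grip", "shuttle_vo2max", "plank", "modified_pullup"],
    np.array([
        [1.0, 2.56, 2.33, 2.44],
        [1.0 / 2.56, 1.0, 2.56, 3.89],
        [1.0 / 2.33, 1.0 / 2.56, 1.0, 3.56],
        [1.0 / 2.444, 1.0 / 3.89, 1.0 / 3.56, 1.0],
    ]),
)

#: Final expert-adjusted weight of each indicator in the composite score.
#: These are the operational coefficients of the total-score formula; they
#: sum to 0.9958, not 1 (kept as published).
FINAL_WEIGHTS = {
    "bmi": 0.2807,
    "shuttle_vo2max": 0.2031,
    "hand_grip": 0.2823,
    "modified_pullup": 0.1066,
    "plank": 0.1231,
}


def printed_curves() -> dict[tuple[str, str], ReferenceCurve]:
    """The published LMS reference curves, keyed by (indicator, sex)."""
    out = {}
    for indicator, table in (("bmi", BMI_LMS), ("hand_grip", HANDGRIP_LMS)):
        for sex, rows in table.items():
            entries = {age: LMSTriple(*lms) for age, lms in rows.items()}
            out[(indicator, sex)] = ReferenceCurve(
                indicator, sex, entries, provenance="printed"
            )
    return out


def printed_band_edges() -> pd.DataFrame:
    """Published grade-band edges as a long frame.

    Columns: indicator, sex, age, vp_lo, vp_hi, poor_hi, medium_hi, good_hi.
    """
    rows = []
    for indicator, by_sex in HRPF_BAND_EDGES.items():
        for sex, by_age in by_sex.items():
            for age, edges in by_age.items():
                rows.append((indicator, sex, age, *edges))
    return pd.DataFrame(
        rows,
        columns=["indicator", "sex", "age",
                 "vp_lo", "vp_hi", "poor_hi", "medium_hi", "good_hi"],
    )
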