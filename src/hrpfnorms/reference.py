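"""Build the evaluation system's published artifacts from reference curves.

Two table shapes come out of an LMS reference curve:

* a *centile table* — per age, the (L, M, S) triple plus the measurement
  value at each percentile of a scheme (body-composition scheme:
  P5/P15/P50/P85/P90/P95; fitness scheme: P3/P10/P35/P50/P65/P90);
* a *grade-band table* — per age, contiguous closed measurement intervals
  at 0.01 resolution mapped to labels and integer scores.

Band semantics follow the five-point single-indicator standard: fitness
indicators score 1 (Very poor, [P3, P10]) through 5 (Excellent, above P90),
with no score below P3; BMI scores 1 for lean ([P5, P15]) and obese (above
P95), 3 for overweight ((P85, P95]) and 5 for normal weight, with no
minimum line (anything below the lean edge still scores 1 as lean).
"""

from __future__ import annotations

import pandas as pd

from .bccg import centile_value
from .curves import ReferenceCurve
from .utils import round_half_up

__all__ = [
    "BMI_SCHEME",
    "HRPF_SCHEME",
    "make_centile_table",
    "make_bmi_bands",
    "make_hrpf_bands",
    "bands_from_edges",
    "chart_data",
]

#: Percentiles of the body-composition (BMI) table.
BMI_SCHEME: tuple[int, ...] = (5, 15, 50, 85, 90, 95)
#: Percentiles of the health-related fitness tables.
HRPF_SCHEME: tuple[int, ...] = (3, 10, 35, 50, 65, 90)

BMI_LABELS = ("lean", "normal", "overweight", "obese")
BMI_SCORES = (1, 5, 3, 1)
HRPF_LABELS = ("very_poor", "poor", "medium", "good", "excellent")
HRPF_SCORES = (1, 2, 3, 4, 5)

BAND_COLUMNS = ["indicator", "sex", "age", "label", "score", "lo", "hi"]


def make_centile_table(curve: ReferenceCurve, scheme=HRPF_SCHEME) -> pd.DataFrame:
    """Centile table for one curve: L/M/S plus 2-dp centile columns.

    Cells are rounded half-up to two decimals, the convention of the
    published norm tables.
    """
    scheme = tuple(scheme)
    if any(not (0 < p < 100) for p in scheme) or list(scheme) != sorted(set(scheme)):
        raise ValueError(f"percentile scheme must be strictly increasing in (0,100): {scheme}")
    rows = []
    for age in curve.ages:
        t = curve[age]
        row = {"indicator": curve.indicator, "sex": curve.sex, "age": age,
               "L": t.lambda_, "M": t.mu, "S": t.sigma}
        for p in scheme:
            row[f"p{p:g}"] = round_half_up(centile_value(t, p / 100.0), 2)
        rows.append(row)
    return pd.DataFrame(rows)


def _bands(indicator, sex, age, edges, labels, scores, resolution=0.01):
    """Contiguous closed bands from sorted edge values.

    ``edges`` holds the lower edge of the first band followed by the upper
    edges of all bands but the last; each next band starts one resolution
    step above the previous upper edge, and the last band is unbounded.
    """
    ndigits = max(0, -_decimal_exponent(resolution))
    lo = edges[0]
    out = []
    uppers = list(edges[1:]) + [float("inf")]
    for label, score, hi in zip(labels, scores, uppers):
        if hi <= lo:
            raise ValueError(
                f"zero-width {label} band for {indicator}/{sex}/{age}: "
                f"[{lo}, {hi}]"
            )
        out.append((indicator, sex, age, label, score, lo, hi))
        if hi != float("inf"):
            lo = round_half_up(hi + resolution, ndigits)
    return out


def _decimal_exponent(resolution: float) -> int:
    import math

    exp = round(math.log10(resolution))
    if abs(resolution - 10.0 ** exp) > 1e-12:
        raise ValueError(f"resolution must be a power of ten, got {resolution}")
    return exp


def make_bmi_bands(table: pd.DataFrame, resolution: float = 0.01,
                   lean_upper: str = "p15") -> pd.DataFrame:
    """Four-band BMI grade table (lean/normal/overweight/obese -> 1/5/3/1).

    ``table`` must be a centile table carrying the p5/p15/p85/p95 columns.
    ``lean_upper`` picks the lean band's upper edge: ``"p15"`` (the
    published band tables' realised cut, the default) or ``"p5"`` (the
    stricter reading under which lean is everything at or below P5; the
    lean band then has no lower edge).
    """
    needed = {"p5", "p15", "p85", "p95"}
    if not needed.issubset(table.columns):
        raise ValueError(f"centile table lacks columns {sorted(needed - set(table.columns))}")
    if lean_upper not in ("p15", "p5"):
        raise ValueError(f"lean_upper must be 'p15' or 'p5', got {lean_upper!r}")
    rows = []
    for r in table.itertuples():
        if lean_upper == "p15":
            edges = [r.p5, r.p15, r.p85, r.p95]
        else:
            edges = [resolution, r.p5, r.p85, r.p95]
        rows += _bands(r.indicator, r.sex, int(r.age),
                       edges, BMI_LABELS, BMI_SCORES, resolution)
    return pd.DataFrame(rows, columns=BAND_COLUMNS)


def make_hrpf_bands(table: pd.DataFrame, resolution: float = 0.01) -> pd.DataFrame:
    """Five-band fitness grade table (very_poor..excellent -> 1..5).

    ``table`` must be a centile table carrying the p3/p10/p35/p65/p90
    columns.  Values below the very_poor lower edge receive no score.
    """
    needed = {"p3", "p10", "p35", "p65", "p90"}
    if not needed.issubset(table.columns):
        raise ValueError(f"centile table lacks columns {sorted(needed - set(table.columns))}")
    rows = []
    for r in table.itertuples():
        rows += _bands(r.indicator, r.sex, int(r.age),
                       [r.p3, r.p10, r.p35, r.p65, r.p90],
                       HRPF_LABELS, HRPF_SCORES, resolution)
    return pd.DataFrame(rows, columns=BAND_COLUMNS)


def bands_from_edges(edges: pd.DataFrame, resolution: float = 0.01) -> pd.DataFrame:
    """Grade-band table from a published band-edge frame.

    ``edges`` uses the schema of
    :func:`hrpfnorms.norms.printed_band_edges`: per row the very-poor lower
    edge plus the upper edges of the very-poor..good bands.
    """
    rows = []
    for r in edges.itertuples():
        rows += _bands(r.indicator, r.sex, int(r.age),
                       [r.vp_lo, r.vp_hi, r.poor_hi, r.medium_hi, r.good_hi],
                       HRPF_LABELS, HRPF_SCORES, resolution)
    return pd.DataFrame(rows, columns=BAND_COLUMNS)


def chart_data(table: pd.DataFrame) -> pd.DataFrame:
    """Long-format centile-curve data (age, percentile, value) for plotting."""
    pcols = [c for c in table.columns if c.startswith("p") and c[1:].replace(".", "").isdigit()]
    long = table.melt(
        id_vars=["indicator", "sex", "age"], value_vars=pcols,
        var_name="percentile", value_name="value",
    )
    long["percentile"] = long["percentile"].str.lstrip("p").astype(float)
    return long.sort_values(["percentile", "age"]).reset_index(drop=True)
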