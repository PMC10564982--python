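"""Back-substitution cross-validation of the reference norms.

The norms are refit on a random stratified subsample and the subsample's
fitted medians (P50, i.e. the M parameter) are compared age by age with the
full-sample medians through the mean absolute percentage error

    MAPE = |actual - fitted| / actual

with "actual" the full-data median.  A lower average error indicates a more
stable reference standard; no pass/fail bound is imposed unless the caller
sets one.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .curves import ReferenceCurve
from .utils import round_half_up

__all__ = [
    "split_subsample",
    "mape",
    "backsub_frame",
    "back_substitution",
    "repeated_back_substitution",
]


def split_subsample(
    records: pd.DataFrame,
    fraction: float,
    seed,
    min_cell: int = 30,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a stratified (age x sex) subsample without replacement.

    Each age/sex cell contributes ``round(fraction * n_cell)`` records.
    Returns ``(full, subsample)``; ``fraction=1.0`` returns the full set as
    its own subsample.  Raises if any cell's allocation falls below
    ``min_cell`` (too small to refit an LMS triple).
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if fraction == 1.0:
        return records, records.copy()
    rng = np.random.default_rng(seed)
    parts = []
    for (_, _), cell in records.groupby(["age", "sex"]):
        k = int(round(fraction * len(cell)))
        if k < min_cell:
            raise ValueError(
                f"fraction {fraction} leaves {k} records in an age/sex cell; "
                f"floor is {min_cell}"
            )
        idx = rng.choice(cell.index.to_numpy(), size=k, replace=False)
        parts.append(records.loc[np.sort(idx)])
    sub = pd.concat(parts).sort_index()
    return records, sub


def mape(actual: float, fitted: float) -> float:
    """Absolute percentage error |actual - fitted| / actual (unrounded)."""
    if not actual > 0:
        raise ValueError(f"actual value must be > 0, got {actual}")
    return abs(actual - fitted) / actual


def backsub_frame(ages, actual, fitted) -> pd.DataFrame:
    """Table of per-age median comparison plus an Average row.

    Row MAPEs are reported rounded half-up to 3 decimals; the Average row
    is the arithmetic mean of the raw (unrounded) row errors, rounded the
    same way.
    """
    actual = np.asarray(actual, dtype=float)
    fitted = np.asarray(fitted, dtype=float)
    if len(ages) != len(actual) or len(actual) != len(fitted):
        raise ValueError("ages, actual and fitted must have equal length")
    raw = np.array([mape(a, f) for a, f in zip(actual, fitted)])
    rows = [
        {"age": str(age), "actual": a, "fitted": f,
         "mape": round_half_up(e, 3)}
        for age, a, f, e in zip(ages, actual, fitted, raw)
    ]
    rows.append({"age": "Average", "actual": np.nan, "fitted": np.nan,
                 "mape": round_half_up(float(raw.mean()), 3)})
    return pd.DataFrame(rows)


def back_substitution(
    full_curve: ReferenceCurve,
    sub_curve: ReferenceCurve,
    bound: float | None = None,
) -> pd.DataFrame:
    """Compare P50 (M) of a full-data curve against a subsample refit.

    Both curves must describe the same indicator, sex and age range.
    By default the report carries no pass/fail judgment; with ``bound``
    set, a ``within_bound`` column marks whether each (rounded) MAPE stays
    at or below it.
    """
    if (full_curve.indicator, full_curve.sex) != (sub_curve.indicator, sub_curve.sex):
        raise ValueError("curves describe different indicator/sex")
    if full_curve.ages != sub_curve.ages:
        raise ValueError(
            f"age mismatch: {full_curve.ages} vs {sub_curve.ages}"
        )
    ages = full_curve.ages
    out = backsub_frame(
        ages,
        [full_curve[a].mu for a in ages],
        [sub_curve[a].mu for a in ages],
    )
    out.insert(0, "sex", full_curve.sex)
    out.insert(0, "indicator", full_curve.indicator)
    if bound is not None:
        out["within_bound"] = out["mape"] <= bound
    return out


def repeated_back_substitution(
    records: pd.DataFrame,
    indicator: str,
    sex: str,
    fraction: float = 0.2,
    seeds=range(20),
) -> pd.DataFrame:
    """Average back-substitution MAPE across several subsample seeds.

    A stability probe around the single-split procedure: the norms are
    refit once on the full data and once per seed on a stratified
    subsample.  Returns one row per seed with the run's average MAPE.
    """
    from .fitting import AgeGroupSample, fit_curve

    def curve_of(df: pd.DataFrame) -> ReferenceCurve:
        samples = [
            AgeGroupSample(indicator, sex, int(age),
                           g[indicator].dropna().to_numpy())
            for age, g in df[df["sex"] == sex].groupby("age")
        ]
        return fit_curve(samples)

    full_curve = curve_of(records)
    rows = []
    for seed in seeds:
        _, sub = split_subsample(records, fraction, seed)
        rep = back_substitution(full_curve, curve_of(sub))
        rows.append({"seed": int(seed), "indicator": indicator, "sex": sex,
                     "average_mape": rep.iloc[-1]["mape"]})
    return pd.DataFrame(rows)
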