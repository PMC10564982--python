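"""Single-indicator grading and weighted composite classification.

Each measurement is graded 1-5 by lookup in its age/sex grade-band table.
Fitness indicators below the minimum-score line (the very-poor lower edge,
~P3) receive no score; BMI has no minimum line, so values below the lean
band still grade as lean.  The composite is the weighted sum of the scored
indicators,

    total = bmi*0.2807 + shuttle*0.2031 + grip*0.2823
            + pullup*0.1066 + plank*0.1231

(the published expert-adjusted coefficients; they sum to 0.9958).  When an
indicator is unscored it is excluded and the remaining weights are scaled
back up to the original weight sum, and the record is flagged.  Totals map
to five grades: Very poor (<1.5), Poor ([1.5, 2.5)), Medium ([2.5, 3.5)),
Good ([3.5, 4.5)) and Excellent (>= 4.5, including a perfect 5).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .ahp import WeightScheme
from .curves import INDICATORS
from .norms import FINAL_WEIGHTS
from .utils import round_half_up

__all__ = [
    "CATEGORIES",
    "score_indicator",
    "composite_total",
    "classify",
    "cohort_distribution",
    "FitnessScorer",
    "expert_final_weights",
]

CATEGORIES = ("Very poor", "Poor", "Medium", "Good", "Excellent")
CATEGORY_BOUNDS = (1.5, 2.5, 3.5, 4.5)


def expert_final_weights() -> WeightScheme:
    """The published expert-adjusted composite weights."""
    return WeightScheme(dict(FINAL_WEIGHTS), source="expert_final")


def score_indicator(value: float, bands: pd.DataFrame,
                    resolution: float = 0.01) -> int | None:
    """Grade one measurement against one age/sex band-table slice.

    ``bands`` holds the rows (label, score, lo, hi) for a single
    indicator/sex/age.  The raw value is rounded half-up to the band
    resolution before lookup.  Returns ``None`` (no score) below the lowest
    band of a table with a minimum-score line; tables whose lowest band is
    ``lean`` (BMI) clamp low values into that band instead.
    """
    if bands.empty:
        raise KeyError("no band rows for the requested age/sex")
    import math

    ndigits = max(0, -round(math.log10(resolution)))
    v = round_half_up(float(value), ndigits)
    b = bands.sort_values("lo")
    hit = b[(b["lo"] <= v) & (v <= b["hi"])]
    if not hit.empty:
        return int(hit.iloc[0]["score"])
    lowest = b.iloc[0]
    if v < lowest["lo"]:
        if lowest["label"] == "lean":  # no minimum line for body shape
            return int(lowest["score"])
        return None
    raise ValueError(f"value {v} falls in a gap of the band table")


def composite_total(
    scores: dict[str, int | None], weights: WeightScheme
) -> tuple[float, bool]:
    """Weighted total of the scored indicators.

    Returns ``(total, renormalized)``; ``renormalized`` is True when at
    least one indicator was unscored and the remaining weights were scaled
    to preserve the scheme's original weight sum.  Raises if nothing was
    scored.
    """
    w = weights.weights
    scored = {k: s for k, s in scores.items() if s is not None and k in w}
    if not scored:
        raise ValueError("no scored indicators; composite undefined")
    full_sum = sum(w[k] for k in scores if k in w)
    used_sum = sum(w[k] for k in scored)
    renorm = len(scored) < sum(k in w for k in scores)
    factor = full_sum / used_sum if renorm else 1.0
    total = sum(w[k] * factor * s for k, s in scored.items())
    return float(total), renorm


def classify(total: float) -> str:
    """Five-grade category of a composite total in (0, 5]."""
    if not (0.0 < total <= 5.0):
        raise ValueError(f"total score must lie in (0, 5], got {total}")
    idx = int(np.searchsorted(CATEGORY_BOUNDS, total, side="right"))
    return CATEGORIES[idx]


def cohort_distribution(results: pd.DataFrame) -> pd.Series:
    """Percentage of classified records in each grade, to 1 decimal place.

    Records without a composite (drop mode) are excluded from the base.
    """
    if results.empty:
        raise ValueError("no results to summarise")
    classified = results[results["category"].isin(CATEGORIES)]
    if classified.empty:
        raise ValueError("no classified records to summarise")
    counts = classified["category"].value_counts()
    pct = counts.reindex(CATEGORIES, fill_value=0) / counts.sum() * 100.0
    return pct.map(lambda x: round_half_up(x, 1)).rename("percent")


class FitnessScorer(BaseEstimator):
    """Grade individual records and classify their composite fitness.

    Parameters
    ----------
    bands : pandas.DataFrame
        Grade-band table covering every indicator/sex/age to be scored
        (columns indicator, sex, age, label, score, lo, hi).
    weights : WeightScheme, optional
        Composite weights; defaults to the published expert-adjusted scheme.
    resolution : float
        Band lookup resolution (measurements are rounded to it first).
    on_unscored : {"renormalize", "drop"}
        How to composite records with an unscored indicator: rescale the
        remaining weights to the scheme's original sum (default), or emit
        no composite for the record at all.

    After :meth:`fit`, :meth:`transform` returns a per-record result frame
    (per-indicator scores, total, category, flags) and :meth:`predict`
    the category labels alone.
    """

    def __init__(self, bands: pd.DataFrame | None = None,
                 weights: WeightScheme | None = None,
                 resolution: float = 0.01,
                 on_unscored: str = "renormalize"):
        self.bands = bands
        self.weights = weights
        self.resolution = resolution
        self.on_unscored = on_unscored

    def fit(self, X=None, y=None):
        if self.bands is None or self.bands.empty:
            raise ValueError("a band table is required")
        if self.on_unscored not in ("renormalize", "drop"):
            raise ValueError(
                f"on_unscored must be 'renormalize' or 'drop', got {self.on_unscored!r}"
            )
        missing = set(["indicator", "sex", "age", "label", "score", "lo", "hi"]) \
            - set(self.bands.columns)
        if missing:
            raise ValueError(f"band table lacks columns {sorted(missing)}")
        self.weights_ = self.weights if self.weights is not None else expert_final_weights()
        self.bands_ = {
            key: grp for key, grp in self.bands.groupby(["indicator", "sex", "age"])
        }
        self.indicators_ = [
            i for i in INDICATORS if i in set(self.bands["indicator"])
        ]
        return self

    def _check_fitted(self):
        if not hasattr(self, "bands_"):
            raise AttributeError("call fit() before scoring")

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Score a cohort frame (one row per adolescent)."""
        self._check_fitted()
        rows = []
        for r in X.itertuples():
            scores: dict[str, int | None] = {}
            flags = []
            for ind in self.indicators_:
                val = getattr(r, ind, None)
                if val is None or (isinstance(val, float) and np.isnan(val)):
                    scores[ind] = None
                    flags.append(f"missing:{ind}")
                    continue
                key = (ind, r.sex, int(r.age))
                if key not in self.bands_:
                    raise KeyError(f"no band row for {key}")
                s = score_indicator(val, self.bands_[key], self.resolution)
                scores[ind] = s
                if s is None:
                    flags.append(f"unscored:{ind}")
            row = {"id": r.id}
            row.update({f"score_{k}": v for k, v in scores.items()})
            any_unscored = any(v is None for v in scores.values())
            if any_unscored and self.on_unscored == "drop":
                # no composite for incomplete records in drop mode
                row["total"] = np.nan
                row["category"] = ""
                flags.append("no_composite")
            else:
                total, renorm = composite_total(scores, self.weights_)
                if renorm:
                    flags.append("renormalized")
                row["total"] = round_half_up(total, 4)
                row["category"] = classify(total)
            row["flags"] = ";".join(flags)
            rows.append(row)
        return pd.DataFrame(rows)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Composite grade label per record."""
        return self.transform(X)["category"].to_numpy()
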