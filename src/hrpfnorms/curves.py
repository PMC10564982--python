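"""Age-indexed LMS reference curves and their CSV representation."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .bccg import LMSTriple

__all__ = ["ReferenceCurve", "curves_to_frame", "frame_to_curves"]

INDICATORS = ("bmi", "hand_grip", "modified_pullup", "plank", "shuttle_vo2max")
SEXES = ("boys", "girls")


@dataclass
class ReferenceCurve:
    """LMS triples across age for one indicator and sex.

    ``entries`` maps whole-year age to :class:`~hrpfnorms.bccg.LMSTriple`;
    ``provenance`` records whether the triples were fitted from data or
    taken from a published table.
    """

    indicator: str
    sex: str
    entries: dict[int, LMSTriple] = field(default_factory=dict)
    provenance: str = "fitted"

    def __post_init__(self) -> None:
        if self.indicator not in INDICATORS:
            raise ValueError(f"unknown indicator {self.indicator!r}")
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        ages = self.ages
        if ages and ages != list(range(ages[0], ages[-1] + 1)):
            raise ValueError(f"ages must be contiguous, got {ages}")

    @property
    def ages(self) -> list[int]:
        return sorted(self.entries)

    def __getitem__(self, age: int) -> LMSTriple:
        return self.entries[age]


def curves_to_frame(curves: list[ReferenceCurve]) -> pd.DataFrame:
    """Flatten curves to the on-disk schema: indicator,sex,age,L,M,S."""
    rows = []
    for c in curves:
        for age in c.ages:
            t = c[age]
            rows.append(
                {"indicator": c.indicator, "sex": c.sex, "age": age,
                 "L": t.lambda_, "M": t.mu, "S": t.sigma}
            )
    return pd.DataFrame(rows, columns=["indicator", "sex", "age", "L", "M", "S"])


def frame_to_curves(df: pd.DataFrame, provenance: str = "fitted") -> list[ReferenceCurve]:
    """Inverse of :func:`curves_to_frame`."""
    out = []
    for (ind, sex), grp in df.groupby(["indicator", "sex"], sort=False):
        entries = {
            int(r.age): LMSTriple(float(r.L), float(r.M), float(r.S))
            for r in grp.itertuples()
        }
        out.append(ReferenceCurve(ind, sex, entries, provenance=provenance))
    return out
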