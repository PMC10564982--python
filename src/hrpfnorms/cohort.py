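"""Synthetic stratified school cohort with known ground-truth norms.

Emulates the study design behind the published norms: three districts
(Multan, Bahawalpur, D.G. Khan), 20 higher schools per district, 50
students per school (ages 12-16 in near-equal shares, balanced sexes),
with ~1% nonresponse removed at random — 3,000 generated, 2,970 retained
at the defaults.  Indicator values are drawn from Box-Cox-normal
distributions: BMI and hand grip directly from the published LMS triples,
and the three indicators whose norms are printed only as grade bands
(modified pull-up, plank, shuttle-run VO2max) from triples recovered from
their band edges.

Because every record's generating distribution is known, each pipeline
stage (fitting, band construction, grading, back substitution) can be
tested for recovery against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm as _norm

from scipy.special import ndtr as _ndtr

from .bccg import (
    LAMBDA_EPS,
    LMSTriple,
    centile_value,
    random_sample,
    sample_from_uniforms,
)
from .curves import INDICATORS, ReferenceCurve, curves_to_frame
from .norms import HRPF_BAND_EDGES, printed_curves

__all__ = [
    "CohortConfig",
    "generate_cohort",
    "triple_from_centiles",
    "bands_to_triple",
    "generating_curves",
    "ground_truth_frame",
]

COHORT_COLUMNS = ["id", "stratum", "school", "sex", "age", *INDICATORS]

#: Band-edge probabilities shared by every published band row: the upper
#: edges of the very-poor, poor and good bands sit at ~P10, ~P35 and ~P90.
BAND_ANCHOR_PROBS = (0.10, 0.35, 0.90)

#: All five probabilities a published band row pins down.
BAND_EDGE_PROBS = (0.03, 0.10, 0.35, 0.65, 0.90)

#: Largest sigma*|lambda| a *generating* triple may have.  The Box-Cox
#: support only covers standard-normal deviates |z| < 1/(sigma*|lambda|);
#: 0.37 keeps every quantile between P0.3 and P99.7 inside the support, so
#: sampling, density evaluation and P3-P90 table building all stay
#: mutually consistent.  A handful of published band rows are so skewed
#: that their exact three-anchor solution violates this; those fall back
#: to a bounded least-squares fit over all five edges.
MAX_GENERATING_SKEW = 0.37


def triple_from_centiles(anchors: dict[float, float]) -> LMSTriple:
    """Recover an LMS triple from three exact centile anchors.

    ``anchors`` maps probability -> measurement value for exactly three
    strictly increasing centiles.  For fixed L the LMS relation is linear
    in (M**L, M**L * L * S), so two anchors determine M and S and the third
    leaves a one-dimensional residual in L, solved by bracketed
    root-finding.  The residual is divided by L to remove the spurious root
    the raw power-branch residual has at L = 0.
    """
    if len(anchors) != 3:
        raise ValueError(f"exactly three anchors required, got {len(anchors)}")
    ps = np.array(sorted(anchors))
    xs = np.array([anchors[p] for p in ps], dtype=float)
    if not (np.all(np.diff(xs) > 0) and np.all(xs > 0)):
        raise ValueError(f"anchor values must be positive and increasing in p: {xs}")
    z = _norm.ppf(ps)

    lx = np.log(xs)
    s_log = (lx[2] - lx[0]) / (z[2] - z[0])
    log_resid = lx[0] - s_log * z[0] + s_log * z[1] - lx[1]

    def g(L: float) -> float:
        if abs(L) < LAMBDA_EPS:
            return log_resid
        xl = xs ** L
        b = (xl[2] - xl[0]) / (z[2] - z[0])
        a = xl[0] - b * z[0]
        return (a + b * z[1] - xl[1]) / L

    # band-implied distributions can be strongly skewed (|L| up to ~10)
    grid = np.linspace(-15.0, 15.0, 301)
    vals = [g(L) for L in grid]
    candidates = []
    for i in range(len(grid) - 1):
        if vals[i] == 0.0:
            candidates.append(grid[i])
        elif vals[i] * vals[i + 1] < 0:
            candidates.append(brentq(g, grid[i], grid[i + 1], xtol=1e-12))
    if not candidates:
        raise ValueError("no Box-Cox power in [-15, 15] reproduces the anchors")

    def build(L: float) -> LMSTriple:
        if abs(L) < LAMBDA_EPS:
            return LMSTriple(0.0, float(np.exp(lx[0] - s_log * z[0])), float(s_log))
        xl = xs ** L
        b = (xl[2] - xl[0]) / (z[2] - z[0])
        a = xl[0] - b * z[0]
        if a <= 0 or b / (a * L) <= 0:
            raise ValueError(f"anchors admit no valid triple at L={L:.4f}")
        return LMSTriple(float(L), float(a ** (1.0 / L)), float(b / (a * L)))

    best, best_err = None, np.inf
    for L in candidates:
        try:
            t = build(L)
        except ValueError:
            continue
        err = max(abs(centile_value(t, p) - anchors[p]) for p in ps)
        if err < best_err:
            best, best_err = t, err
    if best is None or best_err > 0.02 * xs[1]:
        raise ValueError("anchor reproduction failed beyond tolerance")
    return best


def bands_to_triple(vp_hi: float, poor_hi: float, good_hi: float) -> LMSTriple:
    """Generating triple implied by a published band row's shared edges.

    The three arguments are the upper edges of the very-poor, poor and good
    bands, which sit at the ~P10, ~P35 and ~P90 centiles of the underlying
    distribution.
    """
    return triple_from_centiles(dict(zip(BAND_ANCHOR_PROBS, (vp_hi, poor_hi, good_hi))))


def _ls_triple(probs, values, max_skew: float = MAX_GENERATING_SKEW) -> LMSTriple:
    """Least-squares LMS triple over several centile anchors, skew-bounded.

    Minimises the squared log-ratio between model and target centiles over
    (lambda, ln M, ln S) subject to sigma*|lambda| <= ``max_skew``.  Used
    when a band row is too skewed for an exact in-support solution.
    """
    from scipy.optimize import minimize

    probs = np.asarray(probs, dtype=float)
    xs = np.asarray(values, dtype=float)
    z = _norm.ppf(probs)

    def obj(theta):
        lam, ln_m, ln_s = theta
        s = np.exp(ln_s)
        if abs(lam) * s > max_skew:
            return 1e6 * (1.0 + abs(lam) * s - max_skew)
        arg = 1.0 + lam * s * z
        if np.any(arg <= 0):
            return 1e9
        model = (np.exp(ln_m) * arg ** (1.0 / lam) if abs(lam) >= LAMBDA_EPS
                 else np.exp(ln_m + s * z))
        return float(np.sum((np.log(model) - np.log(xs)) ** 2))

    best = None
    for lam0 in (-2.0, -0.5, 0.5, 2.0):
        res = minimize(obj, [lam0, np.log(xs[len(xs) // 2]), np.log(0.2)],
                       method="Nelder-Mead",
                       options={"maxiter": 2000, "xatol": 1e-9, "fatol": 1e-12})
        if best is None or res.fun < best.fun:
            best = res
    lam, ln_m, ln_s = best.x
    return LMSTriple(float(lam), float(np.exp(ln_m)), float(np.exp(ln_s)))


def _generating_triple(edges: tuple[float, ...]) -> LMSTriple:
    """Generating triple for one published band row.

    Prefers the exact three-anchor solution (P10/P35/P90 edges); rows whose
    exact solution is too skewed to keep P0.3-P99.7 inside the Box-Cox
    support instead get the skew-bounded least-squares fit over all five
    edges.
    """
    try:
        t = bands_to_triple(edges[1], edges[2], edges[4])
        if abs(t.lambda_) * t.sigma < MAX_GENERATING_SKEW:
            return t
    except ValueError:
        pass
    return _ls_triple(BAND_EDGE_PROBS, edges)


@lru_cache(maxsize=1)
def _band_implied_curves() -> tuple[tuple[tuple[str, str], ReferenceCurve], ...]:
    out = []
    for indicator, by_sex in HRPF_BAND_EDGES.items():
        if indicator == "hand_grip":  # printed triples take precedence
            continue
        for sex, by_age in by_sex.items():
            entries = {
                age: _generating_triple(e) for age, e in by_age.items()
            }
            out.append(((indicator, sex),
                        ReferenceCurve(indicator, sex, entries, provenance="printed")))
    return tuple(out)


def generating_curves() -> dict[tuple[str, str], ReferenceCurve]:
    """Ground-truth curves for all five indicators and both sexes.

    BMI and hand grip use the published LMS triples verbatim; the band-only
    indicators get band-implied triples (exact where possible, otherwise
    skew-bounded least squares; see :func:`_generating_triple`).
    """
    out = dict(printed_curves())
    out.update(dict(_band_implied_curves()))
    return out


@dataclass
class CohortConfig:
    """Design of the synthetic cohort.

    Defaults reproduce the study design the published norms came from:
    3 strata x 20 schools x 50 students, ages 12-16 at ~20% each, a 50/50
    sex split and 1% nonresponse.
    """

    strata: tuple[str, ...] = ("Multan", "Bahawalpur", "DG_Khan")
    schools_per_stratum: int = 20
    students_per_school: int = 50
    ages: tuple[int, ...] = (12, 13, 14, 15, 16)
    age_shares: tuple[float, ...] | None = None  # None -> equal shares
    sex_share_boys: float = 0.5
    nonresponse_rate: float = 0.01
    seed: int = 0
    curves: dict[tuple[str, str], ReferenceCurve] | None = None
    #: optional Gaussian-copula correlation matrix between the five
    #: indicators (order of :data:`hrpfnorms.curves.INDICATORS`); None
    #: draws indicators independently
    correlation: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.correlation is not None:
            R = np.asarray(self.correlation, dtype=float)
            k = len(INDICATORS)
            if R.shape != (k, k) or not np.allclose(R, R.T):
                raise ValueError(f"correlation must be a symmetric {k}x{k} matrix")
            if not np.allclose(np.diag(R), 1.0):
                raise ValueError("correlation diagonal must be 1")
            self.correlation = R
        if self.age_shares is not None:
            if len(self.age_shares) != len(self.ages):
                raise ValueError("age_shares length must match ages")
            if abs(sum(self.age_shares) - 1.0) > 1e-9:
                raise ValueError("age_shares must sum to 1")
        if not (0.0 <= self.nonresponse_rate < 1.0):
            raise ValueError("nonresponse_rate must lie in [0, 1)")
        if not (0.0 < self.sex_share_boys < 1.0):
            raise ValueError("sex_share_boys must lie in (0, 1)")

    @property
    def total_students(self) -> int:
        return len(self.strata) * self.schools_per_stratum * self.students_per_school


def _largest_remainder(n: int, shares: np.ndarray) -> np.ndarray:
    """Integer allocation of n by shares, exact and deterministic."""
    raw = n * shares
    base = np.floor(raw).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:rem]] += 1
    return base


def generate_cohort(config: CohortConfig | None = None) -> pd.DataFrame:
    """Generate the synthetic cohort frame (one row per retained student).

    Each school receives a balanced allocation — ages by largest-remainder
    on the configured shares, sexes split to the configured ratio — so the
    realised age and sex shares match the study's near-exact demographic
    balance rather than fluctuating binomially.  Age and sex are paired by
    random permutation within school.  Nonresponders
    (``round(rate * N)`` of them) are removed uniformly at random.
    """
    config = config or CohortConfig()
    curves = config.curves if config.curves is not None else generating_curves()
    for ind in INDICATORS:
        for sex in ("boys", "girls"):
            if (ind, sex) not in curves:
                raise ValueError(f"missing generating curve for ({ind}, {sex})")
            missing_ages = set(config.ages) - set(curves[(ind, sex)].ages)
            if missing_ages:
                raise ValueError(
                    f"curve ({ind}, {sex}) lacks ages {sorted(missing_ages)}"
                )

    rng = np.random.default_rng(config.seed)
    shares = (
        np.asarray(config.age_shares, dtype=float)
        if config.age_shares is not None
        else np.full(len(config.ages), 1.0 / len(config.ages))
    )
    n_school = config.students_per_school
    age_alloc = _largest_remainder(n_school, shares)
    n_boys = int(round(n_school * config.sex_share_boys))

    rows = []
    sid = 0
    for stratum in config.strata:
        for school_i in range(1, config.schools_per_stratum + 1):
            school = f"{stratum}_S{school_i:02d}"
            ages = np.repeat(config.ages, age_alloc)
            sexes = np.array(["boys"] * n_boys + ["girls"] * (n_school - n_boys))
            rng.shuffle(ages)
            rng.shuffle(sexes)
            for age, sex in zip(ages, sexes):
                sid += 1
                rows.append((f"id{sid:05d}", stratum, school, sex, int(age)))
    frame = pd.DataFrame(rows, columns=["id", "stratum", "school", "sex", "age"])

    # indicator values, drawn in bulk per (sex, age) cell for speed; with a
    # correlation matrix, dependence enters through a Gaussian copula on
    # the per-record uniforms
    uniforms = None
    if config.correlation is not None:
        chol = np.linalg.cholesky(config.correlation)
        uniforms = {}
        for (sex, age), idx in frame.groupby(["sex", "age"]).groups.items():
            zs = rng.standard_normal((len(idx), len(INDICATORS))) @ chol.T
            uniforms[(sex, age)] = _ndtr(zs)
    for j, ind in enumerate(INDICATORS):
        values = np.empty(len(frame))
        for (sex, age), idx in frame.groupby(["sex", "age"]).groups.items():
            triple = curves[(ind, sex)][int(age)]
            pos = frame.index.get_indexer(idx)
            if uniforms is not None:
                values[pos] = sample_from_uniforms(triple, uniforms[(sex, age)][:, j])
            else:
                values[pos] = random_sample(triple, len(idx), rng)
        # record at 0.01 measurement resolution; tiny pull-up tail values
        # are floored at the resolution rather than recorded as 0
        frame[ind] = np.maximum(np.round(values, 2), 0.01)

    n_drop = int(round(config.nonresponse_rate * len(frame)))
    if n_drop:
        drop = rng.choice(frame.index.to_numpy(), size=n_drop, replace=False)
        frame = frame.drop(index=drop).reset_index(drop=True)
    return frame


def ground_truth_frame(curves=None) -> pd.DataFrame:
    """Sidecar CSV content: the generating triples, for recovery tests."""
    curves = curves if curves is not None else generating_curves()
    return curves_to_frame(list(curves.values()))
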