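"""Maximum-likelihood estimation of LMS reference curves.

Each age/sex group is summarised by a Box-Cox Cole-Green triple fitted by
maximising the BCCG log-likelihood over (lambda, log mu, log sigma); the
log parameterisation enforces positivity of the median and scale.  Ages are
treated as whole-year groups (the resolution at which adolescent fitness
norms are published), with optional squared-second-difference roughness
penalties tying the per-age parameter series together.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from .bccg import LMSTriple, log_density
from .curves import ReferenceCurve

__all__ = ["AgeGroupSample", "GroupFit", "fit_group", "fit_curve", "LMSCurveFitter"]

DEFAULT_MIN_GROUP_SIZE = 30
MAX_ITER = 500
#: Relative log-likelihood change at which the optimiser is declared converged.
LOGLIK_RTOL = 1e-8
#: Upper bound on sigma*|lambda| during fitting.  Beyond it the Box-Cox
#: support no longer contains the +/-2 SD range, so the triple cannot
#: define the outer reference centiles (P3/P97); the truncation-corrected
#: likelihood otherwise admits degenerate heavily-truncated modes.
MAX_FIT_SKEW = 0.5


@dataclass
class AgeGroupSample:
    """Measurements of one indicator for one sex and whole-year age group."""

    indicator: str
    sex: str
    age: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(~np.isfinite(self.values)) or np.any(self.values <= 0):
            raise ValueError("all measurements must be finite and > 0")


@dataclass
class GroupFit:
    """Result of one per-group fit: the triple plus convergence diagnostics."""

    triple: LMSTriple
    loglik: float
    converged: bool
    n_iter: int
    n_obs: int


class ConvergenceWarning(UserWarning):
    pass


def _default_init(values: np.ndarray) -> LMSTriple:
    """Robust start: lambda=1, median, and a MAD-based coefficient of variation."""
    med = float(np.median(values))
    mad = float(np.median(np.abs(values - med)))
    sigma0 = 1.4826 * mad / med
    if sigma0 <= 0:
        sigma0 = float(np.std(values) / med)
    return LMSTriple(1.0, med, max(sigma0, 1e-4))


def _negloglik(theta: np.ndarray, values: np.ndarray) -> float:
    lam, log_mu, log_sigma = theta
    if abs(lam) > 20 or abs(log_sigma) > 12 or abs(log_mu) > 50:
        return np.inf
    if abs(lam) * math.exp(log_sigma) > MAX_FIT_SKEW:
        return np.inf
    triple = LMSTriple(lam, math.exp(log_mu), math.exp(log_sigma))
    return -float(np.sum(log_density(triple, values)))


def fit_group(
    sample: AgeGroupSample,
    init: LMSTriple | None = None,
    min_size: int = DEFAULT_MIN_GROUP_SIZE,
) -> GroupFit:
    """Fit one LMS triple to an age/sex group by maximum likelihood.

    Parameters
    ----------
    sample : AgeGroupSample
        Must contain at least ``min_size`` observations.
    init : LMSTriple, optional
        Starting point; defaults to lambda=1, the sample median and a
        MAD-based coefficient of variation.

    Returns
    -------
    GroupFit
        The fitted triple with log-likelihood, iteration count and a
        convergence flag.  Non-convergence raises a :class:`ConvergenceWarning`
        (the partial result is still returned, flagged).
    """
    values = sample.values
    if len(values) < min_size:
        raise ValueError(
            f"group {sample.indicator}/{sample.sex}/{sample.age} has "
            f"{len(values)} observations; floor is {min_size}"
        )
    if np.ptp(values) == 0:
        raise ValueError(
            "degenerate sample: all values equal, scale parameter collapses"
        )
    start = init if init is not None else _default_init(values)
    # keep the start strictly inside the sigma*|lambda| feasibility wall
    lam0 = start.lambda_
    if abs(lam0) * start.sigma > 0.8 * MAX_FIT_SKEW:
        lam0 = math.copysign(0.8 * MAX_FIT_SKEW / start.sigma, lam0 or 1.0)
    theta0 = np.array(
        [lam0, math.log(start.mu), math.log(start.sigma)]
    )
    f0 = _negloglik(theta0, values)
    res = minimize(
        _negloglik,
        theta0,
        args=(values,),
        method="Nelder-Mead",
        options={
            "maxiter": MAX_ITER,
            "xatol": 1e-7,
            "fatol": LOGLIK_RTOL * max(abs(f0), 1.0),
        },
    )
    lam, log_mu, log_sigma = res.x
    triple = LMSTriple(float(lam), math.exp(log_mu), math.exp(log_sigma))
    if not res.success:
        warnings.warn(
            f"LMS fit for {sample.indicator}/{sample.sex}/{sample.age} did not "
            f"converge in {res.nit} iterations",
            ConvergenceWarning,
            stacklevel=2,
        )
    return GroupFit(triple, -float(res.fun), bool(res.success), int(res.nit), len(values))


def _roughness(series: np.ndarray) -> float:
    if len(series) < 3:
        return 0.0
    return float(np.sum(np.diff(series, n=2) ** 2))


def fit_curve(
    samples: list[AgeGroupSample],
    penalties: tuple[float, float, float] = (0.0, 0.0, 0.0),
    min_size: int = DEFAULT_MIN_GROUP_SIZE,
) -> ReferenceCurve:
    """Fit a full reference curve across ages, optionally smoothed.

    With zero penalties (the default) this reduces exactly to independent
    per-age fits.  Positive penalties maximise the joint penalised
    log-likelihood

        sum_a loglik_a - p_L*R(L) - p_M*R(M) - p_S*R(S)

    where R is the sum of squared second differences of the parameter's
    age series; in the large-penalty limit each series becomes linear in age.

    Requires at least three consecutive ages; any group failing its
    individual fit aborts the curve with that group identified.
    """
    if not samples:
        raise ValueError("no age groups supplied")
    indicator, sex = samples[0].indicator, samples[0].sex
    by_age = {s.age: s for s in samples}
    ages = sorted(by_age)
    if len(ages) < 3 or ages != list(range(ages[0], ages[-1] + 1)):
        raise ValueError(f"need >= 3 consecutive ages, got {ages}")

    fits: dict[int, GroupFit] = {}
    for age in ages:
        try:
            fits[age] = fit_group(by_age[age], min_size=min_size)
        except ValueError as exc:
            raise ValueError(f"group age={age} ({indicator}/{sex}) failed: {exc}") from exc

    entries = {age: fits[age].triple for age in ages}
    if any(p > 0 for p in penalties):
        entries = _smooth_joint(by_age, ages, entries, penalties)
    return ReferenceCurve(indicator, sex, entries, provenance="fitted")


def _smooth_joint(by_age, ages, init_entries, penalties) -> dict[int, LMSTriple]:
    p_l, p_m, p_s = penalties
    n = len(ages)

    def unpack(theta):
        lam = theta[:n]
        mu = np.exp(theta[n:2 * n])
        sig = np.exp(theta[2 * n:])
        return lam, mu, sig

    def objective(theta):
        lam, mu, sig = unpack(theta)
        total = 0.0
        for i, age in enumerate(ages):
            total += _negloglik(
                np.array([lam[i], math.log(mu[i]), math.log(sig[i])]),
                by_age[age].values,
            )
            if not np.isfinite(total):
                return np.inf
        total += p_l * _roughness(lam) + p_m * _roughness(mu) + p_s * _roughness(sig)
        return total

    theta0 = np.concatenate([
        [init_entries[a].lambda_ for a in ages],
        [math.log(init_entries[a].mu) for a in ages],
        [math.log(init_entries[a].sigma) for a in ages],
    ])
    res = minimize(objective, theta0, method="Powell",
                   options={"maxiter": 20000, "xtol": 1e-8, "ftol": 1e-10})
    lam, mu, sig = unpack(res.x)
    return {
        age: LMSTriple(float(lam[i]), float(mu[i]), float(sig[i]))
        for i, age in enumerate(ages)
    }


class LMSCurveFitter(BaseEstimator):
    """Scikit-learn style estimator producing an LMS reference curve.

    Parameters
    ----------
    indicator, sex : str
        Labels attached to the fitted curve.
    penalties : tuple of 3 floats
        Roughness penalty weights for the lambda, mu and sigma age series.
        Default (0, 0, 0): independent per-age fits, appropriate for the
        five whole-year ages these norms cover.
    min_group_size : int
        Smallest age group accepted for fitting.

    Attributes
    ----------
    curve_ : ReferenceCurve
        Fitted age -> (L, M, S) mapping.
    loglik_ : float
        Total unpenalised log-likelihood at the fitted parameters.
    ages_ : list of int
    """

    def __init__(self, indicator: str = "bmi", sex: str = "boys",
                 penalties: tuple[float, float, float] = (0.0, 0.0, 0.0),
                 min_group_size: int = DEFAULT_MIN_GROUP_SIZE):
        self.indicator = indicator
        self.sex = sex
        self.penalties = penalties
        self.min_group_size = min_group_size

    def fit(self, X: pd.DataFrame, y=None):
        """Fit from a long-format frame with ``age`` and ``value`` columns."""
        if not {"age", "value"}.issubset(X.columns):
            raise ValueError("X must have 'age' and 'value' columns")
        samples = [
            AgeGroupSample(self.indicator, self.sex, int(age),
                           grp["value"].to_numpy())
            for age, grp in X.groupby("age")
        ]
        self.curve_ = fit_curve(samples, tuple(self.penalties),
                                min_size=self.min_group_size)
        self.ages_ = self.curve_.ages
        self.loglik_ = sum(
            float(np.sum(log_density(self.curve_[s.age], s.values)))
            for s in samples
        )
        return self

    def centiles(self, p: float) -> pd.Series:
        """Per-age centile values of the fitted curve at probability ``p``."""
        from .bccg import centile_value

        if not hasattr(self, "curve_"):
            raise AttributeError("fit the estimator before requesting centiles")
        return pd.Series(
            {age: centile_value(self.curve_[age], p) for age in self.ages_},
            name=f"p{p:g}",
        )
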