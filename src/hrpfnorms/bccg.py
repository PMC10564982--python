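"""Box-Cox Cole-Green (BCCG) distribution machinery.

The LMS method summarises an age-dependent, positively supported and
possibly skewed measurement distribution by three parameters:

* ``lambda_`` (L) — the Box-Cox power that removes skewness,
* ``mu`` (M) — the median, in measurement units,
* ``sigma`` (S) — a coefficient-of-variation-like scale.

For a measurement ``x > 0`` the Box-Cox deviate

    z = ((x / mu)**lambda_ - 1) / (lambda_ * sigma)       (lambda_ != 0)
    z = log(x / mu) / sigma                               (lambda_ == 0)

is modelled as standard normal, truncated to the region where the power
transform is defined (``1 + lambda_*sigma*z > 0``).  Centiles follow by
inverting the transform at the standard-normal quantile.

Everything else in this package (reference-curve fitting, centile tables,
grade bands, the synthetic cohort) is built on this module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr, ndtri
from scipy.stats import norm

__all__ = [
    "LAMBDA_EPS",
    "LMSTriple",
    "centile_value",
    "z_score",
    "log_density",
    "sample_from_uniforms",
    "random_sample",
]

#: Below this |lambda| the log (lambda = 0) branch of the Box-Cox transform
#: is used.  Kept tiny on purpose: published triples with lambda as small as
#: -0.004 must still take the power branch, which is numerically stable down
#: to ~1e-7 in double precision.
LAMBDA_EPS = 1e-7


@dataclass(frozen=True)
class LMSTriple:
    """The (L, M, S) parameters of one age/sex indicator distribution.

    Parameters
    ----------
    lambda_ : float
        Box-Cox power; dimensionless, may be negative or zero.
    mu : float
        Median, in the indicator's measurement units; strictly positive.
    sigma : float
        Coefficient-of-variation-like scale; strictly positive.
    """

    lambda_: float
    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.lambda_):
            raise ValueError(f"lambda_ must be finite, got {self.lambda_!r}")
        if not (math.isfinite(self.mu) and self.mu > 0):
            raise ValueError(f"mu must be finite and > 0, got {self.mu!r}")
        if not (math.isfinite(self.sigma) and self.sigma > 0):
            raise ValueError(f"sigma must be finite and > 0, got {self.sigma!r}")

    @property
    def is_log_branch(self) -> bool:
        return abs(self.lambda_) < LAMBDA_EPS


def _check_percentile(p: float) -> None:
    if not (0.0 < p < 1.0):
        raise ValueError(f"percentile probability must lie in (0, 1), got {p!r}")


def centile_value(lms: LMSTriple, p: float) -> float:
    """Measurement value at probability ``p`` of the BCCG distribution.

    Inverts the LMS relation: ``X = M * (1 + L*S*z_p)**(1/L)`` for the power
    branch and ``X = M * exp(S*z_p)`` at ``L = 0``, with ``z_p`` the
    standard-normal quantile.

    Raises
    ------
    ValueError
        If ``p`` is outside (0, 1) or the power-branch argument
        ``1 + L*S*z_p`` is non-positive (the requested centile falls outside
        the distribution's support).
    """
    _check_percentile(p)
    z = ndtri(p)
    if lms.is_log_branch:
        return lms.mu * math.exp(lms.sigma * z)
    arg = 1.0 + lms.lambda_ * lms.sigma * z
    if arg <= 0.0:
        raise ValueError(
            f"centile p={p} outside BCCG support for triple {lms}: "
            f"1 + L*S*z = {arg:.6g} <= 0"
        )
    return lms.mu * arg ** (1.0 / lms.lambda_)


def z_score(lms: LMSTriple, x: float) -> float:
    """Standard-normal deviate of measurement ``x`` under the triple.

    The inverse of :func:`centile_value`:
    ``z = ((x/M)**L - 1) / (L*S)`` (power branch) or ``z = ln(x/M)/S``.
    """
    x = float(x)
    if not (math.isfinite(x) and x > 0):
        raise ValueError(f"measurement must be finite and > 0, got {x!r}")
    if lms.is_log_branch:
        return math.log(x / lms.mu) / lms.sigma
    return ((x / lms.mu) ** lms.lambda_ - 1.0) / (lms.lambda_ * lms.sigma)


def _truncation_bounds(lms: LMSTriple) -> tuple[float, float]:
    """z-range over which the Box-Cox deviate is defined.

    The power transform requires 1 + L*S*z > 0: a one-sided truncation at
    -1/(L*S) for L > 0 (lower) or L < 0 (upper).  Untruncated at L = 0.
    """
    if lms.is_log_branch:
        return -math.inf, math.inf
    edge = -1.0 / (lms.lambda_ * lms.sigma)
    if lms.lambda_ > 0:
        return edge, math.inf
    return -math.inf, edge


def log_density(lms: LMSTriple, x) -> np.ndarray | float:
    """Log of the BCCG probability density at ``x`` (scalar or array).

    Normal density of the Box-Cox deviate times the Jacobian
    ``(x/M)**(L-1) / (M*S)``, renormalised by the truncation constant
    ``Phi(1/(S*|L|))`` so the density integrates to one on its support.
    """
    x_arr = np.asarray(x, dtype=float)
    if np.any(~np.isfinite(x_arr)) or np.any(x_arr <= 0):
        raise ValueError("measurements must be finite and > 0")
    L, M, S = lms.lambda_, lms.mu, lms.sigma
    if lms.is_log_branch:
        z = np.log(x_arr / M) / S
        log_trunc = 0.0
    else:
        z = ((x_arr / M) ** L - 1.0) / (L * S)
        log_trunc = math.log(ndtr(1.0 / (S * abs(L))))
    log_jac = (L - 1.0) * np.log(x_arr / M) - math.log(M * S)
    out = norm.logpdf(z) + log_jac - log_trunc
    return out if out.ndim else float(out)


def sample_from_uniforms(lms: LMSTriple, u: np.ndarray) -> np.ndarray:
    """Map uniform(0,1) variates to BCCG variates by inverse CDF.

    The uniforms index the standard normal truncated to the Box-Cox
    support; exposing this stage separately lets callers impose dependence
    between indicators through a Gaussian copula.
    """
    u = np.asarray(u, dtype=float)
    lo, hi = _truncation_bounds(lms)
    lo_cdf = ndtr(lo) if math.isfinite(lo) else 0.0
    hi_cdf = ndtr(hi) if math.isfinite(hi) else 1.0
    z = ndtri(lo_cdf + u * (hi_cdf - lo_cdf))
    L, M, S = lms.lambda_, lms.mu, lms.sigma
    if lms.is_log_branch:
        return M * np.exp(S * z)
    return M * (1.0 + L * S * z) ** (1.0 / L)


def random_sample(lms: LMSTriple, n: int, seed) -> np.ndarray:
    """Draw ``n`` reproducible BCCG variates.

    Samples z from the standard normal truncated to the support region by
    inverse-CDF on uniforms from ``numpy.random.default_rng(seed)``, then
    maps through the inverse Box-Cox transform.  ``seed`` may be an int or
    an existing :class:`numpy.random.Generator`.
    """
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    rng = np.random.default_rng(seed)
    return sample_from_uniforms(lms, rng.uniform(size=n))
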