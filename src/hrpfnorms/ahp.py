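"""Analytic-hierarchy-process weighting of the fitness indicators.

Indicator weights come from a positive reciprocal pairwise judgment matrix
C, where C[i, j] states how much more important indicator i is than j.
Weights are the normalised row geometric means

    W_i = (prod_j C[i, j])**(1/m),      w_i = W_i / sum_k W_k

and internal coherence is checked through the consistency index

    lambda_i = (C w)_i / w_i,   lambda_max = mean_i lambda_i,
    C.I. = (lambda_max - m) / (m - 1)

with C.I. < 0.1 taken as acceptably consistent.  A perfectly consistent
matrix (C[i, j] = w_i / w_j) gives lambda_max = m and C.I. = 0; any 2x2
reciprocal matrix is consistent by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "WeightScheme",
    "ConsistencyReport",
    "validate_matrix",
    "geometric_mean_weights",
    "ahp_computed_weights",
    "consistency",
]

RECIPROCITY_RTOL = 0.01  # absorbs printed-table rounding such as 2.44 vs 1/2.444
CONSISTENCY_BOUND = 0.1


@dataclass
class WeightScheme:
    """Normalised indicator weights and where they came from.

    ``source`` is ``"ahp_computed"`` for weights derived from a judgment
    matrix or ``"expert_final"`` for the published expert-adjusted scheme
    (whose weights deliberately sum to 0.9958, hence the loose sum check).
    """

    weights: dict[str, float]
    source: str = "ahp_computed"

    def __post_init__(self) -> None:
        vals = np.array(list(self.weights.values()), dtype=float)
        if np.any(vals <= 0):
            raise ValueError("all weights must be positive")
        if not (0.99 <= vals.sum() <= 1.01):
            raise ValueError(f"weights must sum to ~1, got {vals.sum():.4f}")

    @property
    def labels(self) -> list[str]:
        return list(self.weights)

    def as_array(self) -> np.ndarray:
        return np.array(list(self.weights.values()), dtype=float)


@dataclass
class ConsistencyReport:
    lambda_values: np.ndarray
    lambda_max: float
    consistency_index: float
    consistent: bool


def validate_matrix(C, labels=None, rtol: float = RECIPROCITY_RTOL) -> np.ndarray:
    """Check that C is a positive reciprocal judgment matrix.

    Requires a square matrix with positive entries, unit diagonal and
    C[j, i] = 1 / C[i, j] within relative tolerance ``rtol``.
    Returns the validated matrix as a float array.
    """
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError(f"judgment matrix must be square, got shape {C.shape}")
    m = C.shape[0]
    if labels is not None and len(labels) != m:
        raise ValueError("label count does not match matrix dimension")
    if np.any(C <= 0):
        raise ValueError("judgment matrix entries must be positive")
    if np.any(np.abs(np.diag(C) - 1.0) > 1e-9):
        raise ValueError("judgment matrix diagonal must be 1")
    prod = C * C.T  # exactly 1 for a perfect reciprocal matrix
    bad = np.abs(prod - 1.0) > rtol
    if np.any(bad):
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"reciprocity violated at ({i},{j}): C[i,j]*C[j,i] = {prod[i, j]:.4f}"
        )
    return C


def geometric_mean_weights(C, labels=None) -> WeightScheme:
    """Normalised row-geometric-mean weights of a validated judgment matrix."""
    C = validate_matrix(C, labels)
    m = C.shape[0]
    gm = np.prod(C, axis=1) ** (1.0 / m)
    w = gm / gm.sum()
    if labels is None:
        labels = [f"c{i + 1}" for i in range(m)]
    return WeightScheme(dict(zip(labels, w.tolist())), source="ahp_computed")


def ahp_computed_weights() -> WeightScheme:
    """Hierarchical AHP weights from the published judgment matrices.

    The top-level 2x2 matrix splits weight between body shape and overall
    fitness; the 4x4 fitness matrix splits the fitness share among the four
    test indicators.  BMI receives the body-shape weight directly.  This is
    the purely computed alternative to the expert-adjusted final scheme.
    """
    from .norms import COMPOSITE_JUDGMENT, HRPF_JUDGMENT

    top_labels, top_C = COMPOSITE_JUDGMENT
    sub_labels, sub_C = HRPF_JUDGMENT
    top = geometric_mean_weights(top_C, top_labels)
    sub = geometric_mean_weights(sub_C, sub_labels)
    w_fit = top.weights["hrpf"]
    weights = {"bmi": top.weights["body_shape"]}
    weights.update({k: w_fit * v for k, v in sub.weights.items()})
    return WeightScheme(weights, source="ahp_computed")


def consistency(C, scheme: WeightScheme) -> ConsistencyReport:
    """Consistency diagnostics of matrix C under weight scheme ``scheme``."""
    C = np.asarray(C, dtype=float)
    w = scheme.as_array()
    m = C.shape[0]
    if len(w) != m:
        raise ValueError(f"matrix is {m}x{m} but scheme has {len(w)} weights")
    lam = (C @ w) / w
    lam_max = float(lam.mean())
    ci = (lam_max - m) / (m - 1)
    return ConsistencyReport(lam, lam_max, float(ci), bool(ci < CONSISTENCY_BOUND))
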