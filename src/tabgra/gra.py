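"""Grey relational analysis (GRA) weighting and composite risk scoring.

Grey relational analysis scores how similar the *shapes* of indicator
sequences are across samples.  Each indicator in turn serves as the
reference sequence; the grey relational coefficient between the reference
and every other indicator is averaged over samples into a relational
degree, the m x m relational matrix is reduced to row means, and those
means are normalized into indicator weights W.  A sample's composite risk
is then the W-weighted sum of its hazard quotients d_ik = x_ik / l_i
(detection value over regulatory maximum limit): a risk above 1 can only
arise when at least one indicator exceeds its limit.

Pipeline, for data matrix X (m indicators x n samples):

    y_i(k)  = (x_i(k) - min_k x_i) / (max_k x_i - min_k x_i)
    xi_i(k) = (Dmin + rho * Dmax) / (D_i(k) + rho * Dmax),
              D_i(k) = |y_ref(k) - y_i(k)|,  Dmin/Dmax over i != ref, all k
    gamma_{ref,i} = mean_k xi_i(k)
    w_i     = mean_q gamma_iq / sum_i mean_q gamma_iq
    r_k     = sum_i w_i * x_ik / l_i
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .detection_io import ConfigurationError, DetectionMatrix

__all__ = [
    "GRAConfig",
    "GRAResult",
    "normalize_minmax",
    "grey_coefficients",
    "relational_degree",
    "relational_matrix",
    "indicator_weights",
    "hazard_matrix",
    "composite_risk",
    "compute_risk",
]


class DegenerateInputError(ValueError):
    """Too few samples or indicators for the requested operation."""


@dataclass(frozen=True)
class GRAConfig:
    """Settings of the grey relational computation.

    rho is the adjustment (distinguishing) parameter of the grey relational
    coefficient, in (0, 1); smaller values spread the coefficients further
    apart.  0.5 is the customary default.
    """

    rho: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.rho < 1.0):
            raise ValueError(f"rho must lie in (0, 1), got {self.rho}")


@dataclass
class GRAResult:
    """Weights, relational matrix, hazard quotients and composite risks."""

    indicator_names: list[str]
    samples: list[str]
    weights: np.ndarray          # (m,), sums to 1
    gamma: np.ndarray            # (m, m) relational matrix, diagonal 1
    hazard: np.ndarray           # (m, n) hazard quotients d_ik
    risks: np.ndarray            # (n,) composite risk values r_k
    config: GRAConfig = field(default_factory=GRAConfig)


def normalize_minmax(X: np.ndarray) -> np.ndarray:
    """Row-wise min-max scaling of an m x n data matrix into [0, 1].

    Constant rows (max == min) map to all zeros rather than 0/0; they then
    behave as maximally flat sequences in the coefficient computation.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected an m x n matrix")
    if X.shape[1] < 2:
        raise DegenerateInputError("min-max normalization needs at least 2 samples")
    lo = X.min(axis=1, keepdims=True)
    span = X.max(axis=1, keepdims=True) - lo
    out = np.zeros_like(X)
    np.divide(X - lo, span, out=out, where=span > 0)
    return out


def grey_coefficients(
    Y: np.ndarray, ref: int, cfg: GRAConfig = GRAConfig()
) -> np.ndarray:
    """Grey relational coefficients xi_i(k) of every comparison indicator vs ``ref``.

    Returns an (m-1) x n array ordered by comparison index i skipping the
    reference row.  Dmin and Dmax range over all comparison indicators and
    all samples for this reference; when every comparison sequence is
    identical to the reference (Dmax == 0) all coefficients are 1.
    """
    Y = np.asarray(Y, dtype=float)
    m, _ = Y.shape
    if m < 2:
        raise DegenerateInputError("grey coefficients need at least 2 indicators")
    if not 0 <= ref < m:
        raise IndexError(f"reference index {ref} out of range for {m} indicators")
    others = [i for i in range(m) if i != ref]
    delta = np.abs(Y[ref][np.newaxis, :] - Y[others])
    dmax = delta.max()
    if dmax == 0.0:
        return np.ones_like(delta)
    dmin = delta.min()
    return (dmin + cfg.rho * dmax) / (delta + cfg.rho * dmax)


def relational_degree(coefficients: np.ndarray) -> float:
    """Relational degree: arithmetic mean of one comparison's coefficients over samples."""
    coefficients = np.asarray(coefficients, dtype=float)
    if coefficients.size == 0:
        raise ValueError("cannot average an empty coefficient sequence")
    return float(coefficients.mean())


def relational_matrix(Y: np.ndarray, cfg: GRAConfig = GRAConfig()) -> np.ndarray:
    """The m x m relational matrix: each indicator serves as reference once.

    Off-diagonal entries gamma_iq are means over samples of the grey
    coefficients with reference i; the diagonal is 1 exactly (an indicator
    is perfectly related to itself).  The matrix is not symmetrized: the
    Dmin/Dmax scopes differ between references, and that asymmetry is kept.
    """
    Y = np.asarray(Y, dtype=float)
    m = Y.shape[0]
    gamma = np.eye(m)
    for ref in range(m):
        xi = grey_coefficients(Y, ref, cfg)
        others = [i for i in range(m) if i != ref]
        gamma[ref, others] = xi.mean(axis=1)
    return gamma


def indicator_weights(gamma: np.ndarray) -> np.ndarray:
    """Normalize relational-matrix row means into indicator weights summing to 1."""
    gamma = np.asarray(gamma, dtype=float)
    if gamma.ndim != 2 or gamma.shape[0] != gamma.shape[1]:
        raise ValueError("gamma must be square")
    if gamma.shape[0] < 2:
        raise DegenerateInputError("weights need at least 2 indicators")
    row_means = gamma.mean(axis=1)
    return row_means / row_means.sum()


def hazard_matrix(matrix: DetectionMatrix) -> np.ndarray:
    """Hazard quotients d_ik = x_ik / l_i as an m x n array (indicators x samples)."""
    limits = matrix.max_limits
    if not np.all(limits > 0):
        bad = [s.name for s in matrix.indicators if not s.max_limit > 0]
        raise ConfigurationError(f"indicators without positive maximum limit: {bad}")
    return (matrix.values / limits[np.newaxis, :]).T


def composite_risk(weights: np.ndarray, hazard: np.ndarray) -> np.ndarray:
    """Composite risk r_k = sum_i w_i d_ik for every sample column of the hazard matrix."""
    weights = np.asarray(weights, dtype=float)
    hazard = np.asarray(hazard, dtype=float)
    if weights.ndim != 1 or hazard.ndim != 2 or weights.shape[0] != hazard.shape[0]:
        raise ValueError(
            f"weight length {weights.shape} does not match hazard rows {hazard.shape}"
        )
    return weights @ hazard


def compute_risk(matrix: DetectionMatrix, cfg: GRAConfig = GRAConfig()) -> GRAResult:
    """Full pipeline: normalize, relational matrix, weights, hazard quotients, risks."""
    if matrix.n_samples < 2:
        raise DegenerateInputError("GRA needs at least 2 samples")
    if matrix.n_indicators < 2:
        raise DegenerateInputError("GRA needs at least 2 indicators")
    X = matrix.values.T  # analysis orientation: indicators x samples
    Y = normalize_minmax(X)
    gamma = relational_matrix(Y, cfg)
    weights = indicator_weights(gamma)
    hazard = hazard_matrix(matrix)
    risks = composite_risk(weights, hazard)
    return GRAResult(
        indicator_names=matrix.indicator_names,
        samples=list(matrix.samples),
        weights=weights,
        gamma=gamma,
        hazard=hazard,
        risks=risks,
        config=cfg,
    )
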