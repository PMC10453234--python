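"""Grey relational analysis: worked examples, properties, and a brute-force oracle."""

import numpy as np
import pytest

from tabgra.detection_io import DetectionMatrix, IndicatorSpec
from tabgra.gra import (
    GRAConfig,
    composite_risk,
    compute_risk,
    grey_coefficients,
    hazard_matrix,
    indicator_weights,
    normalize_minmax,
    relational_degree,
    relational_matrix,
)

from conftest import random_detection_matrix


# ---------------------------------------------------------------------------
# independent straight-from-the-equations oracle (loops, no vectorization)

def oracle_normalize(X):
    m, n = X.shape
    Y = np.zeros((m, n))
    for i in range(m):
        lo, hi = min(X[i]), max(X[i])
        for k in range(n):
            Y[i, k] = 0.0 if hi == lo else (X[i, k] - lo) / (hi - lo)
    return Y


def oracle_relational_matrix(Y, rho):
    m, n = Y.shape
    gamma = np.eye(m)
    for ref in range(m):
        deltas = {}
        all_d = []
        for i in range(m):
            if i == ref:
                continue
            deltas[i] = [abs(Y[ref][k] - Y[i][k]) for k in range(n)]
            all_d.extend(deltas[i])
        dmin, dmax = min(all_d), max(all_d)
        for i in range(m):
            if i == ref:
                continue
            if dmax == 0:
                gamma[ref, i] = 1.0
            else:
                xis = [(dmin + rho * dmax) / (d + rho * dmax) for d in deltas[i]]
                gamma[ref, i] = sum(xis) / n
    return gamma


def oracle_weights_and_risks(matrix: DetectionMatrix, rho: float):
    X = matrix.values.T
    Y = oracle_normalize(X)
    gamma = oracle_relational_matrix(Y, rho)
    row_means = [sum(gamma[i]) / gamma.shape[0] for i in range(gamma.shape[0])]
    weights = np.array(row_means) / sum(row_means)
    limits = matrix.max_limits
    m, n = X.shape
    risks = np.zeros(n)
    for k in range(n):
        risks[k] = sum(weights[i] * X[i, k] / limits[i] for i in range(m))
    return weights, gamma, risks


# ---------------------------------------------------------------------------
# worked examples per operation

@pytest.mark.parametrize(
    "row, expected",
    [
        ([1.0, 2.0, 3.0], [0.0, 0.5, 1.0]),
        ([5.0, 5.0, 5.0], [0.0, 0.0, 0.0]),
        ([0.1, 0.4, 0.2], [0.0, 1.0, 1.0 / 3.0]),
    ],
)
def test_normalize_minmax_rows(row, expected):
    out = normalize_minmax(np.array([row]))
    np.testing.assert_allclose(out[0], expected, atol=1e-15)


def test_normalize_rejects_single_sample():
    with pytest.raises(Exception):
        normalize_minmax(np.array([[1.0]]))


def test_grey_coefficients_identical_and_reversed():
    # reference [0,1]; comparisons: identical [0,1] and reversed [1,0].
    # With rho=0.5, Dmin=0, Dmax=1: identical -> xi=1, reversed -> xi=1/3.
    Y = np.array([[0.0, 1.0], [0.0, 1.0], [1.0, 0.0]])
    xi = grey_coefficients(Y, ref=0, cfg=GRAConfig(rho=0.5))
    np.testing.assert_allclose(xi[0], [1.0, 1.0], atol=1e-15)
    np.testing.assert_allclose(xi[1], [1.0 / 3.0, 1.0 / 3.0], atol=1e-15)


def test_grey_coefficients_all_identical_sequences():
    Y = np.tile(np.array([0.0, 0.5, 1.0]), (3, 1))
    xi = grey_coefficients(Y, ref=0)
    np.testing.assert_array_equal(xi, np.ones((2, 3)))


def test_grey_coefficient_monotone_in_rho():
    # increasing rho never decreases a coefficient whose Delta exceeds Dmin
    rng = np.random.default_rng(7)
    Y = rng.uniform(size=(4, 6))
    lo = grey_coefficients(Y, 0, GRAConfig(rho=0.25))
    hi = grey_coefficients(Y, 0, GRAConfig(rho=0.5))
    assert np.all(hi - lo >= -1e-12)


def test_relational_degree_is_mean():
    assert relational_degree([1.0, 1.0, 1.0]) == 1.0
    assert relational_degree([1 / 3, 1 / 3]) == pytest.approx(1 / 3)
    assert relational_degree([1.0, 1 / 3]) == pytest.approx(2 / 3)
    with pytest.raises(ValueError):
        relational_degree([])


def test_relational_matrix_identical_rows():
    Y = np.array([[0.0, 0.5, 1.0], [0.0, 0.5, 1.0]])
    np.testing.assert_allclose(relational_matrix(Y), np.ones((2, 2)))


def test_relational_matrix_range_and_diagonal():
    rng = np.random.default_rng(3)
    Y = rng.uniform(size=(5, 8))
    gamma = relational_matrix(Y)
    assert np.all(gamma > 0) and np.all(gamma <= 1)
    np.testing.assert_array_equal(np.diag(gamma), np.ones(5))


@pytest.mark.parametrize(
    "gamma, expected",
    [
        (np.ones((3, 3)), [1 / 3, 1 / 3, 1 / 3]),
        (np.array([[1.0, 0.5], [0.5, 1.0]]), [0.5, 0.5]),
        (np.array([[1.0, 0.2], [0.6, 1.0]]), [3 / 7, 4 / 7]),
    ],
)
def test_indicator_weights(gamma, expected):
    np.testing.assert_allclose(indicator_weights(gamma), expected, atol=1e-15)


def test_hazard_matrix_worked_values(two_indicator_matrix):
    D = hazard_matrix(two_indicator_matrix)
    assert D[0, 0] == pytest.approx(0.0425 / 0.5)  # lead 0.0425 over limit 0.5
    assert D[1, 0] == pytest.approx(0.357 / 1.0)   # chromium at its printed ratio
    # detection equal to limit is exactly 1
    specs = [IndicatorSpec("a", 2.0, None, "mg/kg"), IndicatorSpec("b", 5.0, None, "mg/kg")]
    mat = DetectionMatrix(["s1", "s2"], specs, np.array([[2.0, 1.0], [0.5, 5.0]]))
    D2 = hazard_matrix(mat)
    assert D2[0, 0] == 1.0 and D2[1, 1] == 1.0


@pytest.mark.parametrize(
    "w, column, expected",
    [
        ([0.5, 0.5], [1.0, 3.0], 2.0),
        ([1.0, 0.0], [7.0, 9.0], 7.0),
        ([3 / 7, 4 / 7], [0.7, 1.4], 1.1),
    ],
)
def test_composite_risk_dot_product(w, column, expected):
    risks = composite_risk(np.array(w), np.array(column)[:, None])
    assert risks[0] == pytest.approx(expected)


def test_composite_risk_alignment_error():
    with pytest.raises(ValueError):
        composite_risk(np.array([0.5, 0.5]), np.zeros((3, 4)))


# ---------------------------------------------------------------------------
# oracle equivalence and invariants

def test_pipeline_matches_bruteforce_oracle():
    rng = np.random.default_rng(42)
    for _ in range(100):
        m = int(rng.integers(2, 7))
        n = int(rng.integers(3, 13))
        matrix = random_detection_matrix(rng, m, n)
        result = compute_risk(matrix)
        w_ref, gamma_ref, risks_ref = oracle_weights_and_risks(matrix, 0.5)
        np.testing.assert_allclose(result.gamma, gamma_ref, atol=1e-10)
        np.testing.assert_allclose(result.weights, w_ref, atol=1e-10)
        np.testing.assert_allclose(result.risks, risks_ref, atol=1e-10)
        assert abs(result.weights.sum() - 1.0) < 1e-12
        assert np.all(result.weights > 0)


def test_sample_permutation_permutes_risks():
    rng = np.random.default_rng(11)
    matrix = random_detection_matrix(rng, 5, 10)
    perm = rng.permutation(10)
    permuted = DetectionMatrix(
        [matrix.samples[i] for i in perm], matrix.indicators, matrix.values[perm]
    )
    base = compute_risk(matrix)
    shuffled = compute_risk(permuted)
    np.testing.assert_allclose(shuffled.weights, base.weights, atol=1e-12)
    np.testing.assert_allclose(shuffled.risks, base.risks[perm], atol=1e-12)


def test_indicator_rescaling_leaves_weights_invariant():
    rng = np.random.default_rng(13)
    matrix = random_detection_matrix(rng, 4, 8)
    scaled_values = matrix.values.copy()
    scaled_values[:, 2] *= 3.7  # min-max normalization removes the scale
    scaled = DetectionMatrix(matrix.samples, matrix.indicators, scaled_values)
    base = compute_risk(matrix)
    after = compute_risk(scaled)
    np.testing.assert_allclose(after.weights, base.weights, atol=1e-12)
    np.testing.assert_allclose(after.hazard[2], base.hazard[2] * 3.7, rtol=1e-12)


def test_risk_convex_combination_bound():
    # if every hazard quotient is <= 1 the composite risk cannot exceed 1
    rng = np.random.default_rng(17)
    specs = [IndicatorSpec(f"i{j}", 1.0, None, "mg/kg") for j in range(4)]
    values = rng.uniform(0, 1, size=(12, 4))
    matrix = DetectionMatrix([str(k) for k in range(12)], specs, values)
    result = compute_risk(matrix)
    assert np.all(result.risks <= 1.0 + 1e-12)


def test_rho_must_be_in_open_unit_interval():
    for bad in (0.0, 1.0, -0.2, 2.0):
        with pytest.raises(ValueError):
            GRAConfig(rho=bad)
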