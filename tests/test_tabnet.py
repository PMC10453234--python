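"""TabNet encoder: sparsemax, masks, prior dynamics, training and persistence."""

import itertools

import numpy as np
import pytest

from tabgra.synthetic import GeneratorConfig, simulate_dataset
from tabgra.tabnet import (
    ConfigError,
    EncodeOutput,
    TabNetConfig,
    TabNetRegressor,
    aggregate_mask_importance,
    sparsemax,
    split_features,
    update_prior,
)


# ---------------------------------------------------------------------------
# sparsemax

def bruteforce_simplex_projection(z: np.ndarray) -> np.ndarray:
    """Independent oracle: enumerate support sets, solve the KKT system on each."""
    d = z.size
    best, best_dist = None, np.inf
    for r in range(1, d + 1):
        for support in itertools.combinations(range(d), r):
            tau = (z[list(support)].sum() - 1.0) / r
            p = np.zeros(d)
            p[list(support)] = z[list(support)] - tau
            if np.any(p < -1e-12):
                continue
            p = np.maximum(p, 0.0)
            dist = np.sum((p - z) ** 2)
            if dist < best_dist - 1e-15:
                best, best_dist = p, dist
    return best


@pytest.mark.parametrize(
    "z, expected",
    [
        ([0.5, 0.5], [0.5, 0.5]),
        ([2.0, 1.0, 0.1], [1.0, 0.0, 0.0]),
        ([1.0, 0.0], [1.0, 0.0]),
    ],
)
def test_sparsemax_worked_examples(z, expected):
    np.testing.assert_allclose(sparsemax(np.array(z)), expected, atol=1e-12)


def test_sparsemax_matches_bruteforce_on_dense_grid():
    grid = np.linspace(-1.5, 1.5, 7)
    for z in itertools.product(grid, grid, grid):
        z = np.array(z)
        p = sparsemax(z)
        ref = bruteforce_simplex_projection(z)
        np.testing.assert_allclose(p, ref, atol=1e-9)
        assert abs(p.sum() - 1.0) < 1e-9
        assert np.all(p >= 0)


# ---------------------------------------------------------------------------
# spec-level primitives

def test_split_features_contract():
    y = np.array([[5.0, 6.0, 7.0]])
    d, a = split_features(y, n_d=2, n_a=1)
    np.testing.assert_array_equal(d, [[5.0, 6.0]])
    np.testing.assert_array_equal(a, [[7.0]])
    np.testing.assert_array_equal(np.hstack([d, a]), y)
    with pytest.raises(ValueError):
        split_features(y, n_d=2, n_a=2)


@pytest.mark.parametrize(
    "prior, mask, relaxation, expected",
    [
        ([1.0, 1.0, 1.0], [1.0, 0.0, 0.0], 1.0, [0.0, 1.0, 1.0]),
        ([1.0, 1.0, 1.0], [1.0, 0.0, 0.0], 1.3, [0.3, 1.3, 1.3]),
        ([1.0, 2.0], [0.0, 0.0], 1.5, [1.5, 3.0]),
    ],
)
def test_update_prior(prior, mask, relaxation, expected):
    out = update_prior(np.array(prior), np.array(mask), relaxation)
    np.testing.assert_allclose(out, expected, atol=1e-15)


def test_update_prior_rejects_relaxation_below_one():
    with pytest.raises(ConfigError):
        update_prior(np.ones(3), np.zeros(3), 0.9)


def test_aggregate_mask_importance():
    uniform = EncodeOutput(np.zeros(2), [np.full((2, 4), 0.25)], [], [], [],
                           np.zeros((2, 1)))
    np.testing.assert_allclose(aggregate_mask_importance(uniform), np.full(4, 0.25))
    masks = [np.array([[0.6, 0.4, 0.0], [0.8, 0.2, 0.0]])]
    out = EncodeOutput(np.zeros(2), masks, [], [], [], np.zeros((2, 1)))
    imp = aggregate_mask_importance(out)
    assert imp[2] == 0.0
    assert imp.sum() == pytest.approx(1.0, abs=1e-9)


# ---------------------------------------------------------------------------
# encoder invariants

def fitted_model(n=80, seed=0, epochs=30, **kw):
    ds = simulate_dataset(GeneratorConfig(n_samples=n, seed=seed))
    cfg = TabNetConfig(max_epochs=epochs, seed=seed, **kw)
    model = TabNetRegressor(cfg).fit(ds.clean_matrix.values, ds.true_risks)
    return model, ds


def test_mask_rows_sum_to_one_every_step():
    model, ds = fitted_model()
    out = model.encode_forward(ds.clean_matrix.values)
    for mask in out.masks:
        np.testing.assert_allclose(mask.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(mask >= 0)


def test_prior_product_identity():
    # P[i] = prod_{j<=i} (relaxation - M[j]), verified exactly per step
    model, ds = fitted_model()
    out = model.encode_forward(ds.clean_matrix.values)
    relaxation = model.config.relaxation
    prod = np.ones_like(out.priors[0])
    for mask, prior in zip(out.masks, out.priors[1:]):
        prod = prod * (relaxation - mask)
        np.testing.assert_allclose(prior, prod, atol=1e-12)
        assert np.all(prior >= 0)


def test_relaxation_one_forces_single_use():
    # once a feature's prior hits zero it receives zero mask weight afterwards
    model, ds = fitted_model(relaxation=1.0, epochs=10)
    # drive step 0 to fully select feature 0: a[0] = 0, so the step-0 scores
    # equal the attention batch-norm shift; a large lead makes sparsemax
    # concentrate all weight on that one feature
    model.attentives[0].bn.beta.data[:] = 0.0
    model.attentives[0].bn.beta.data[0] = 10.0
    out = model.encode_forward(ds.clean_matrix.values)
    np.testing.assert_array_equal(out.masks[0][:, 0], 1.0)
    np.testing.assert_array_equal(out.priors[1][:, 0], 0.0)
    for later in out.masks[1:]:
        np.testing.assert_array_equal(later[:, 0], 0.0)
    # the general invariant: zero prior always means zero mask weight
    for step in range(1, len(out.masks)):
        dead = out.priors[step] == 0.0
        assert np.all(out.masks[step][dead] == 0.0)


def test_dout_relu_aggregation_identity():
    model, ds = fitted_model()
    out = model.encode_forward(ds.clean_matrix.values)
    agg = np.sum([np.maximum(d, 0.0) for d in out.d_steps], axis=0)
    np.testing.assert_allclose(out.d_out, agg, atol=1e-6)


def test_inference_is_deterministic_and_permutation_equivariant():
    model, ds = fitted_model()
    X = ds.clean_matrix.values
    p1, p2 = model.predict(X), model.predict(X)
    np.testing.assert_array_equal(p1, p2)
    perm = np.random.default_rng(0).permutation(X.shape[0])
    np.testing.assert_allclose(model.predict(X[perm]), p1[perm], atol=1e-10)


def test_mask_simplex_property_random_parameters():
    # fresh random-initialized models on random inputs: every mask row on simplex
    rng = np.random.default_rng(0)
    trials = 0
    for seed in range(10):
        model = TabNetRegressor(TabNetConfig(max_epochs=1, seed=seed))
        X = rng.uniform(0, 5, size=(100, 6))
        y = rng.uniform(0, 1, size=100)
        model.fit(X, y)
        out = model.encode_forward(rng.uniform(0, 5, size=(100, 6)))
        for mask in out.masks:
            np.testing.assert_allclose(mask.sum(axis=1), 1.0, atol=1e-6)
            trials += mask.shape[0]
    assert trials >= 1000


# ---------------------------------------------------------------------------
# training behaviour

def test_constant_target_is_learned():
    rng = np.random.default_rng(4)
    X = rng.uniform(0, 1, size=(64, 5))
    y = np.full(64, 0.7)
    model = TabNetRegressor(TabNetConfig(max_epochs=300, seed=1)).fit(X, y)
    assert model.loss_log[-1] < 1e-3
    np.testing.assert_allclose(model.predict(X), 0.7, atol=0.05)


def test_training_is_seed_deterministic():
    rng = np.random.default_rng(9)
    X = rng.uniform(0, 2, size=(40, 4))
    y = rng.uniform(0, 1, size=40)
    runs = [TabNetRegressor(TabNetConfig(max_epochs=25, seed=3)).fit(X, y)
            for _ in range(2)]
    assert runs[0].loss_log[-1] == runs[1].loss_log[-1]
    np.testing.assert_array_equal(runs[0].predict(X), runs[1].predict(X))


def test_minibatch_training_runs():
    rng = np.random.default_rng(2)
    X = rng.uniform(0, 2, size=(50, 4))
    y = rng.uniform(0, 1, size=50)
    model = TabNetRegressor(
        TabNetConfig(max_epochs=5, seed=0, batch_size=16, virtual_batch_size=8)
    ).fit(X, y)
    assert len(model.loss_log) == 5 and np.isfinite(model.loss_log).all()


def test_sparse_penalty_training_runs():
    rng = np.random.default_rng(2)
    X = rng.uniform(0, 2, size=(40, 4))
    y = rng.uniform(0, 1, size=40)
    model = TabNetRegressor(
        TabNetConfig(max_epochs=5, seed=0, sparse_penalty=1e-3)
    ).fit(X, y)
    assert np.isfinite(model.loss_log).all()


def test_feature_count_mismatch_rejected():
    model, ds = fitted_model(epochs=2)
    with pytest.raises(ValueError):
        model.predict(np.zeros((3, 4)))
    with pytest.raises(RuntimeError):
        TabNetRegressor().predict(np.zeros((3, 9)))


def test_save_load_round_trip_is_bit_stable(tmp_path):
    model, ds = fitted_model(epochs=10)
    X = ds.clean_matrix.values
    path = tmp_path / "model.npz"
    model.save(str(path))
    reloaded = TabNetRegressor.load(str(path))
    np.testing.assert_array_equal(reloaded.predict(X), model.predict(X))
    assert reloaded.config == model.config
    np.testing.assert_array_equal(reloaded.loss_log, model.loss_log)


def test_config_validation():
    with pytest.raises(ConfigError):
        TabNetConfig(relaxation=0.5)
    with pytest.raises(ConfigError):
        TabNetConfig(n_steps=0)
    with pytest.raises(ConfigError):
        TabNetConfig(learning_rate=-1.0)
    with pytest.raises(ConfigError):
        TabNetConfig(sparse_penalty=-0.1)
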