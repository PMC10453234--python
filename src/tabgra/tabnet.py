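"""A from-scratch TabNet encoder and regression head for risk prediction.

TabNet processes a batch of tabular detection data through ``n_steps``
sequential decision steps.  At step i an attentive transformer turns the
previous step's attention features a[i-1] and a feature-usage prior P[i-1]
into a sparse feature mask M[i] (sparsemax of the prior-scaled scores, so
each sample's mask weights sum to 1); the prior is relaxed by
P[i] = P[i-1] * (relaxation - M[i]), the masked features pass through a
feature transformer of gated linear-unit blocks, and the result is split
into the step output d[i] and the next attention input a[i].  The ReLU-
aggregated step outputs d_out = sum_i ReLU(d[i]) feed a final affine head
producing one composite risk value per sample.

Training minimizes mean squared error with Adam; there is no GPU path and
no pretraining decoder.  All randomness (initialization, mini-batch
shuffling) is governed by the config seed.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np

from ._autodiff import Tensor, cat_rows, sparsemax_np

__all__ = [
    "TabNetConfig",
    "TabNetRegressor",
    "EncodeOutput",
    "DivergenceError",
    "sparsemax",
    "split_features",
    "update_prior",
    "aggregate_mask_importance",
]


class DivergenceError(RuntimeError):
    """Training loss became non-finite."""


class ConfigError(ValueError):
    """Invalid TabNet configuration."""


@dataclass(frozen=True)
class TabNetConfig:
    """Hyperparameters of the TabNet risk regressor.

    ``batch_size=None`` means full-batch training (the whole training set
    each step).  ``virtual_batch_size`` is the ghost-batch-normalization
    chunk size; it is clipped to the actual batch size at run time.
    ``relaxation`` is the prior update parameter: at 1.0 each feature can be
    selected at only one decision step; larger values let features recur.
    """

    n_d: int = 8
    n_a: int = 8
    n_steps: int = 3
    relaxation: float = 1.3
    learning_rate: float = 0.01
    max_epochs: int = 1000
    batch_size: int | None = None
    virtual_batch_size: int = 128
    sparse_penalty: float = 0.0
    seed: int = 0
    bn_momentum: float = 0.02

    def __post_init__(self) -> None:
        if min(self.n_d, self.n_a, self.n_steps) < 1:
            raise ConfigError("n_d, n_a and n_steps must all be >= 1")
        if self.relaxation < 1.0:
            raise ConfigError("relaxation must be >= 1 (priors could go negative)")
        if self.learning_rate <= 0 or self.max_epochs < 1:
            raise ConfigError("learning_rate must be > 0 and max_epochs >= 1")
        if self.batch_size is not None and self.batch_size < 1:
            raise ConfigError("batch_size must be >= 1 or None for full batch")
        if self.virtual_batch_size < 1:
            raise ConfigError("virtual_batch_size must be >= 1")
        if self.sparse_penalty < 0:
            raise ConfigError("sparse_penalty must be >= 0")


@dataclass
class EncodeOutput:
    """Everything one encoder pass produces, as plain arrays."""

    predictions: np.ndarray           # (B,)
    masks: list[np.ndarray]           # n_steps x (B, D)
    priors: list[np.ndarray]          # n_steps+1 x (B, D), priors[0] = ones
    d_steps: list[np.ndarray]         # n_steps x (B, n_d)
    a_steps: list[np.ndarray]         # n_steps x (B, n_a)
    d_out: np.ndarray                 # (B, n_d)


# ---------------------------------------------------------------------------
# spec-level primitives (plain numpy, also used inside the network)

def sparsemax(z: np.ndarray) -> np.ndarray:
    """Euclidean projection of score vector(s) onto the probability simplex."""
    return sparsemax_np(z)


def split_features(y: np.ndarray, n_d: int, n_a: int) -> tuple[np.ndarray, np.ndarray]:
    """Split transformer output into decision part (first n_d) and attention part."""
    y = np.asarray(y)
    if y.shape[-1] != n_d + n_a:
        raise ValueError(f"width {y.shape[-1]} != n_d + n_a = {n_d + n_a}")
    return y[..., :n_d], y[..., n_d:]


def update_prior(prior: np.ndarray, mask: np.ndarray, relaxation: float) -> np.ndarray:
    """Prior update P[i] = P[i-1] * (relaxation - M[i]), elementwise."""
    if relaxation < 1.0:
        raise ConfigError("relaxation must be >= 1 (priors could go negative)")
    return np.asarray(prior) * (relaxation - np.asarray(mask))


def aggregate_mask_importance(output: EncodeOutput) -> np.ndarray:
    """Per-feature mean mask weight across steps and rows, normalized to sum 1."""
    stacked = np.stack(output.masks)           # (n_steps, B, D)
    importance = stacked.mean(axis=(0, 1))
    total = importance.sum()
    if total == 0:
        return np.full_like(importance, 1.0 / importance.size)
    return importance / total


# ---------------------------------------------------------------------------
# layers

class _Linear:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, bias: bool = True):
        limit = math.sqrt(6.0 / (n_in + n_out))
        self.W = Tensor(rng.uniform(-limit, limit, size=(n_in, n_out)), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.W
        return out + self.b if self.b is not None else out

    def parameters(self) -> list[Tensor]:
        return [self.W] + ([self.b] if self.b is not None else [])


class _GhostBatchNorm:
    """Batch normalization computed over virtual mini-batches.

    In training, the batch is split into chunks of at most
    ``virtual_batch_size`` rows; each chunk is normalized with its own
    statistics and running statistics accumulate a size-weighted average.
    In inference the fixed running statistics are used, making prediction a
    deterministic per-row map.  ``virtual_batch_size=None`` gives plain
    batch normalization (a single chunk).
    """

    def __init__(self, dim: int, virtual_batch_size: int | None,
                 momentum: float = 0.02, eps: float = 1e-5):
        self.vbs = virtual_batch_size
        self.momentum = momentum
        self.eps = eps
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        if not training:
            scale = 1.0 / np.sqrt(self.running_var + self.eps)
            return (x - self.running_mean) * scale * self.gamma + self.beta
        B = x.shape[0]
        vbs = B if self.vbs is None else min(self.vbs, B)
        n_chunks = max(1, math.ceil(B / vbs))
        bounds = np.linspace(0, B, n_chunks + 1).astype(int)
        spans = list(zip(bounds[:-1], bounds[1:]))
        # running statistics are updated from this batch's chunk statistics
        # *before* use, so the renormalized forward tracks the current batch
        weights = np.array([(hi - lo) / B for lo, hi in spans])
        chunk_means = np.stack([x.data[lo:hi].mean(axis=0) for lo, hi in spans])
        chunk_vars = np.stack([x.data[lo:hi].var(axis=0) for lo, hi in spans])
        self.running_mean = ((1 - self.momentum) * self.running_mean
                             + self.momentum * (weights @ chunk_means))
        self.running_var = ((1 - self.momentum) * self.running_var
                            + self.momentum * (weights @ chunk_vars))
        run_scale = np.sqrt(self.running_var + self.eps)
        outs = []
        for (lo, hi), mu_np, var_np in zip(spans, chunk_means, chunk_vars):
            chunk = x.slice_rows(int(lo), int(hi)) if n_chunks > 1 else x
            mu = chunk.mean(axis=0, keepdims=True)
            centered = chunk - mu
            var = (centered * centered).mean(axis=0, keepdims=True)
            xhat = centered / (var + self.eps).sqrt()
            # batch renormalization: r and d are constants (no gradient), so the
            # forward value equals running-stat normalization exactly while the
            # gradient still flows through the virtual-chunk statistics
            r = np.sqrt(var_np + self.eps) / run_scale
            d = (mu_np - self.running_mean) / run_scale
            outs.append(xhat * r + d)
        xhat = cat_rows(outs) if n_chunks > 1 else outs[0]
        return xhat * self.gamma + self.beta

    def parameters(self) -> list[Tensor]:
        return [self.gamma, self.beta]


class _GLUBlock:
    """Affine map to twice the width, ghost batch norm, gated linear unit."""

    def __init__(self, n_in: int, n_out: int, vbs: int | None, momentum: float,
                 rng: np.random.Generator):
        self.n_out = n_out
        self.fc = _Linear(n_in, 2 * n_out, rng, bias=False)
        self.bn = _GhostBatchNorm(2 * n_out, vbs, momentum)

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        h = self.bn(self.fc(x), training)
        return h.slice_cols(0, self.n_out) * h.slice_cols(self.n_out, 2 * self.n_out).sigmoid()

    def parameters(self) -> list[Tensor]:
        return self.fc.parameters() + self.bn.parameters()


class _FeatureTransformer:
    """Two blocks shared across steps, then two step-specific blocks.

    After the first block, each block output is added to the running value
    and rescaled by sqrt(0.5) to keep the variance stable through the
    residual chain.
    """

    SCALE = math.sqrt(0.5)

    def __init__(self, shared: list[_GLUBlock], n_in: int, width: int,
                 vbs: int | None, momentum: float, rng: np.random.Generator):
        self.shared = shared
        self.specific = [
            _GLUBlock(width, width, vbs, momentum, rng),
            _GLUBlock(width, width, vbs, momentum, rng),
        ]

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        out = self.shared[0](x, training)
        for block in self.shared[1:] + self.specific:
            out = (block(out, training) + out) * self.SCALE
        return out

    def parameters(self) -> list[Tensor]:
        return [p for b in self.specific for p in b.parameters()]


class _AttentiveTransformer:
    """Learnable scores from a[i-1], scaled by the prior, projected by sparsemax.

    The sparsemax support is restricted to features with strictly positive
    prior, so a feature whose prior has been driven to zero (fully used
    under relaxation 1) receives exactly zero mask weight at later steps.
    With all-positive priors this coincides with plain sparsemax.
    """

    def __init__(self, n_a: int, n_features: int, vbs: int | None, momentum: float,
                 rng: np.random.Generator):
        self.fc = _Linear(n_a, n_features, rng, bias=False)
        self.bn = _GhostBatchNorm(n_features, vbs, momentum)

    def __call__(self, a_prev: Tensor, prior: Tensor, training: bool) -> Tensor:
        scores = self.bn(self.fc(a_prev), training) * prior
        return scores.sparsemax(support=prior.data > 0)

    def parameters(self) -> list[Tensor]:
        return self.fc.parameters() + self.bn.parameters()


class _Adam:
    def __init__(self, params: Sequence[Tensor], lr: float,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * p.grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * p.grad ** 2
            m_hat = self.m[i] / (1 - b1 ** self.t)
            v_hat = self.v[i] / (1 - b2 ** self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


# ---------------------------------------------------------------------------
# the regressor

class TabNetRegressor:
    """TabNet encoder + affine head mapping detection rows to composite risk."""

    def __init__(self, config: TabNetConfig = TabNetConfig()):
        self.config = config
        self.n_features: int | None = None
        self.loss_log: list[float] = []
        self._modules: dict[str, object] = {}

    # -- construction -------------------------------------------------------

    def _build(self, n_features: int) -> None:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        self.n_features = n_features
        width = cfg.n_d + cfg.n_a
        vbs = cfg.virtual_batch_size
        mom = cfg.bn_momentum
        # initial full-batch normalization of the raw features (no ghost chunks)
        self.initial_bn = _GhostBatchNorm(n_features, None, momentum=mom)
        shared = [
            _GLUBlock(n_features, width, vbs, mom, rng),
            _GLUBlock(width, width, vbs, mom, rng),
        ]
        self.shared_blocks = shared
        self.attentives = [
            _AttentiveTransformer(cfg.n_a, n_features, vbs, mom, rng)
            for _ in range(cfg.n_steps)
        ]
        self.transformers = [
            _FeatureTransformer(shared, n_features, width, vbs, mom, rng)
            for _ in range(cfg.n_steps)
        ]
        self.head = _Linear(cfg.n_d, 1, rng)

    def parameters(self) -> list[Tensor]:
        params = self.initial_bn.parameters()
        for b in self.shared_blocks:
            params += b.parameters()
        for at in self.attentives:
            params += at.parameters()
        for ft in self.transformers:
            params += ft.parameters()
        params += self.head.parameters()
        return params

    # -- forward ------------------------------------------------------------

    def _forward(self, X: np.ndarray, training: bool) -> dict:
        cfg = self.config
        B = X.shape[0]
        x = Tensor(X)
        c = self.initial_bn(x, training)
        prior = Tensor(np.ones((B, self.n_features)))
        a = Tensor(np.zeros((B, cfg.n_a)))
        masks, priors, d_list, a_list = [], [prior], [], []
        d_out = None
        for step in range(cfg.n_steps):
            mask = self.attentives[step](a, prior, training)
            prior = prior * (cfg.relaxation - mask)
            y = self.transformers[step](mask * c, training)
            d = y.slice_cols(0, cfg.n_d)
            a = y.slice_cols(cfg.n_d, cfg.n_d + cfg.n_a)
            relu_d = d.relu()
            d_out = relu_d if d_out is None else d_out + relu_d
            masks.append(mask)
            priors.append(prior)
            d_list.append(d)
            a_list.append(a)
        pred = self.head(d_out)  # (B, 1)
        return {"pred": pred, "masks": masks, "priors": priors,
                "d": d_list, "a": a_list, "d_out": d_out}

    def encode_forward(self, X: np.ndarray) -> EncodeOutput:
        """One inference-mode encoder pass, returning all intermediates."""
        self._check_fitted(X)
        out = self._forward(np.asarray(X, dtype=float), training=False)
        return EncodeOutput(
            predictions=out["pred"].data[:, 0].copy(),
            masks=[m.data.copy() for m in out["masks"]],
            priors=[p.data.copy() for p in out["priors"]],
            d_steps=[d.data.copy() for d in out["d"]],
            a_steps=[a.data.copy() for a in out["a"]],
            d_out=out["d_out"].data.copy(),
        )

    # -- training -----------------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray) -> "TabNetRegressor":
        """Train on detection rows X (n, D) against composite risks y (n,)."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("fit needs a 2-D X with at least 2 rows")
        if X.shape[0] != y.shape[0]:
            raise ValueError("X rows and targets must align")
        cfg = self.config
        self._build(X.shape[1])
        rng = np.random.default_rng(cfg.seed + 1)  # shuffling stream
        params = self.parameters()
        optimizer = _Adam(params, cfg.learning_rate)
        n = X.shape[0]
        batch = n if cfg.batch_size is None else min(cfg.batch_size, n)
        self.loss_log = []
        for epoch in range(cfg.max_epochs):
            order = np.arange(n) if batch == n else rng.permutation(n)
            epoch_loss = 0.0
            for lo in range(0, n, batch):
                idx = order[lo:lo + batch]
                out = self._forward(X[idx], training=True)
                err = out["pred"].slice_cols(0, 1) - y[idx][:, np.newaxis]
                loss = (err * err).mean()
                if cfg.sparse_penalty > 0:
                    ent = None
                    for mask in out["masks"]:
                        term = (mask * (-1.0) * (mask + 1e-10).log()).sum(axis=1).mean()
                        ent = term if ent is None else ent + term
                    loss = loss + (cfg.sparse_penalty / cfg.n_steps) * ent
                value = float(loss.data)
                if not np.isfinite(value):
                    raise DivergenceError(f"non-finite training loss at epoch {epoch}")
                epoch_loss += value * len(idx) / n
                optimizer.zero_grad()
                loss.backward()
                optimizer.step()
            self.loss_log.append(epoch_loss)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predicted composite risk per row, in input order (non-mutating)."""
        self._check_fitted(X)
        out = self._forward(np.asarray(X, dtype=float), training=False)
        return out["pred"].data[:, 0].copy()

    def feature_importances(self, X: np.ndarray) -> np.ndarray:
        """Aggregate mask importance of each feature over an inference pass."""
        return aggregate_mask_importance(self.encode_forward(X))

    def _check_fitted(self, X: np.ndarray) -> None:
        if self.n_features is None:
            raise RuntimeError("model is not fitted")
        X = np.asarray(X)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} features, got shape {X.shape}"
            )

    # -- persistence ---------------------------------------------------------

    def _named_arrays(self) -> dict[str, np.ndarray]:
        named: dict[str, np.ndarray] = {}

        def add_bn(prefix: str, bn: _GhostBatchNorm) -> None:
            named[f"{prefix}.gamma"] = bn.gamma.data
            named[f"{prefix}.beta"] = bn.beta.data
            named[f"{prefix}.running_mean"] = bn.running_mean
            named[f"{prefix}.running_var"] = bn.running_var

        def add_linear(prefix: str, lin: _Linear) -> None:
            named[f"{prefix}.W"] = lin.W.data
            if lin.b is not None:
                named[f"{prefix}.b"] = lin.b.data

        def add_glu(prefix: str, blk: _GLUBlock) -> None:
            add_linear(f"{prefix}.fc", blk.fc)
            add_bn(f"{prefix}.bn", blk.bn)

        add_bn("initial_bn", self.initial_bn)
        for i, blk in enumerate(self.shared_blocks):
            add_glu(f"shared.{i}", blk)
        for i, at in enumerate(self.attentives):
            add_linear(f"att.{i}.fc", at.fc)
            add_bn(f"att.{i}.bn", at.bn)
        for i, ft in enumerate(self.transformers):
            for j, blk in enumerate(ft.specific):
                add_glu(f"ft.{i}.specific.{j}", blk)
        add_linear("head", self.head)
        return named

    def save(self, path: str) -> None:
        """Archive config (JSON) + parameters + running statistics + loss log."""
        if self.n_features is None:
            raise RuntimeError("cannot save an unfitted model")
        meta = {"config": asdict(self.config), "n_features": self.n_features}
        arrays = dict(self._named_arrays())
        arrays["__loss_log__"] = np.asarray(self.loss_log)
        buf = io.BytesIO()
        np.savez(buf, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)
        with open(path, "wb") as fh:
            fh.write(buf.getvalue())

    @classmethod
    def load(cls, path: str) -> "TabNetRegressor":
        with np.load(path) as archive:
            meta = json.loads(bytes(archive["__meta__"]).decode())
            arrays = {k: archive[k] for k in archive.files if k != "__meta__"}
        model = cls(TabNetConfig(**meta["config"]))
        model._build(meta["n_features"])
        model.loss_log = list(arrays.pop("__loss_log__"))
        named = model._named_arrays()
        for name, stored in arrays.items():
            target = named[name]
            np.copyto(target, stored)
        return model
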