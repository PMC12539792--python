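"""Small trainable networks approximating the likelihood ratio and estimator.

The detection network is trained with the binary cross-entropy loss to
approximate the posterior probability Pr(H1 | g), a monotone function of
the likelihood ratio; the estimation network is trained to maximize the
mean Gaussian utility between its amplitude predictions and the truth on
signal-present images.  Both are small fully-connected networks over
average-pooled, standardized pixel inputs, trained with Adam on CPU.  The
architecture is configuration, not contract: every learned component has a
closed-form or sample-based substitute, and the default ("oracle") pipeline
runs with no training at all.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import TrainingDataError
from .imaging import ImageBatch

__all__ = ["NetHyperparams", "DetectionNet", "EstimationNet", "train_detection", "train_estimation"]


@dataclass(frozen=True)
class NetHyperparams:
    hidden_sizes: tuple[int, ...] = ()  # () = regularized linear readout
    pool: int = 4  # average-pooling factor applied to each image axis
    epochs: int = 600
    batch_size: int = 0  # 0 = full batch
    learning_rate: float = 0.5
    momentum: float = 0.9
    weight_decay: float = 0.3  # ridge penalty added to the loss gradient
    val_fraction: float = 0.1
    patience: int = 50
    seed: int = 0


def _pool(images: np.ndarray, p: int) -> np.ndarray:
    n, h, w = images.shape
    if p <= 1:
        return images.reshape(n, h * w)
    hp, wp = h // p, w // p
    pooled = images[:, : hp * p, : wp * p].reshape(n, hp, p, wp, p).mean(axis=(2, 4))
    return pooled.reshape(n, hp * wp)


class _MLP:
    """Dense network with tanh hidden layers; manual backprop + Adam."""

    def __init__(self, sizes: list[int], rng: np.random.Generator):
        # hidden layers: He-scaled random; output layer: zero, so the model
        # starts at the maximally shrunk point of the ridge path
        self.W = [
            rng.standard_normal((a, b)) * np.sqrt(2.0 / a)
            for a, b in zip(sizes[:-1], sizes[1:])
        ]
        self.W[-1] = np.zeros_like(self.W[-1])
        self.b = [np.zeros(b) for b in sizes[1:]]

    def forward(self, X: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        acts = [X]
        a = X
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            z = a @ W + b
            a = z if i == len(self.W) - 1 else np.tanh(z)
            acts.append(a)
        return a[:, 0], acts

    def backward(self, acts: list[np.ndarray], dout: np.ndarray) -> list[np.ndarray]:
        grads = []
        delta = dout[:, None]
        for i in range(len(self.W) - 1, -1, -1):
            gW = acts[i].T @ delta / len(delta)
            gb = delta.mean(axis=0)
            grads.append((gW, gb))
            if i > 0:
                delta = (delta @ self.W[i].T) * (1.0 - acts[i] ** 2)
        return grads[::-1]

    def params(self):
        return self.W + self.b

    def state(self):
        return [w.copy() for w in self.W], [b.copy() for b in self.b]

    def load(self, state):
        self.W = [w.copy() for w in state[0]]
        self.b = [b.copy() for b in state[1]]


def _train(
    mlp: _MLP,
    X: np.ndarray,
    y: np.ndarray,
    hp: NetHyperparams,
    loss_grad,
    loss_value,
    rng: np.random.Generator,
) -> None:
    """Gradient descent with momentum, ridge penalty, and validation stop.

    Full-batch by default: at the shrinkage levels these low-contrast tasks
    need, stochastic-gradient noise measurably distorts the learned
    template, so the exact regularized gradient is preferred.
    """
    n = len(X)
    n_val = max(1, int(round(hp.val_fraction * n)))
    perm = rng.permutation(n)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    Xtr, ytr, Xval, yval = X[tr_idx], y[tr_idx], X[val_idx], y[val_idx]
    batch = len(Xtr) if hp.batch_size <= 0 else hp.batch_size

    params = mlp.params()
    vel = [np.zeros_like(p) for p in params]
    best_val = np.inf
    best_state = mlp.state()
    stale = 0

    for _epoch in range(hp.epochs):
        order = rng.permutation(len(Xtr))
        for start in range(0, len(Xtr), batch):
            idx = order[start : start + batch]
            out, acts = mlp.forward(Xtr[idx])
            grads = mlp.backward(acts, loss_grad(out, ytr[idx]))
            # parameter order: all W then all b (matches mlp.params())
            flat = [g[0] for g in grads] + [g[1] for g in grads]
            for p, g, v in zip(params, flat, vel):
                v *= hp.momentum
                v += g + hp.weight_decay * p
                p -= hp.learning_rate * v
        val_out, _ = mlp.forward(Xval)
        val_loss = loss_value(val_out, yval)
        if val_loss < best_val - 1e-7:
            best_val = val_loss
            best_state = mlp.state()
            stale = 0
        else:
            stale += 1
            if stale > hp.patience:
                break
    mlp.load(best_state)


@dataclass
class _Preprocessor:
    pool: int
    mean: np.ndarray
    sd: np.ndarray

    def __call__(self, images: np.ndarray) -> np.ndarray:
        X = _pool(np.asarray(images, dtype=float), self.pool)
        return (X - self.mean) / self.sd

    @staticmethod
    def fit(images: np.ndarray, pool: int) -> "_Preprocessor":
        X = _pool(np.asarray(images, dtype=float), pool)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        return _Preprocessor(pool=pool, mean=X.mean(axis=0), sd=sd)


_EPS = 1e-12


class DetectionNet:
    """Predicts the posterior probability Pr(H1 | g), strictly inside (0, 1)."""

    def __init__(self, mlp: _MLP, prep: _Preprocessor):
        self._mlp = mlp
        self._prep = prep

    def predict(self, images: np.ndarray) -> np.ndarray:
        logits, _ = self._mlp.forward(self._prep(images))
        p = 1.0 / (1.0 + np.exp(-logits))
        return np.clip(p, _EPS, 1.0 - _EPS)

    def predict_logit(self, images: np.ndarray) -> np.ndarray:
        """Raw log-odds output (a monotone surrogate for log Lambda)."""
        logits, _ = self._mlp.forward(self._prep(images))
        return logits


class EstimationNet:
    """Predicts the signal amplitude on signal-present images."""

    def __init__(self, mlp: _MLP, prep: _Preprocessor):
        self._mlp = mlp
        self._prep = prep

    def predict(self, images: np.ndarray) -> np.ndarray:
        out, _ = self._mlp.forward(self._prep(images))
        return out


def train_detection(
    train_batch: ImageBatch, hyperparams: NetHyperparams = NetHyperparams()
) -> DetectionNet:
    """Train the detection network by minimizing mean binary cross-entropy."""
    hp = hyperparams
    y = np.asarray(train_batch.labels, dtype=float)
    if len(np.unique(y)) < 2:
        raise TrainingDataError("detection training needs both classes present")
    prep = _Preprocessor.fit(train_batch.images, hp.pool)
    X = prep(train_batch.images)
    rng = np.random.default_rng(hp.seed)
    mlp = _MLP([X.shape[1], *hp.hidden_sizes, 1], rng)

    def grad(logits, yy):  # d(BCE)/d(logit) = sigmoid(logit) - y
        return 1.0 / (1.0 + np.exp(-logits)) - yy

    def value(logits, yy):
        p = np.clip(1.0 / (1.0 + np.exp(-logits)), _EPS, 1 - _EPS)
        return float(-np.mean(yy * np.log(p) + (1 - yy) * np.log(1 - p)))

    _train(mlp, X, y, hp, grad, value, rng)
    return DetectionNet(mlp, prep)


def train_estimation(
    train_batch: ImageBatch,
    utility_width: float,
    hyperparams: NetHyperparams = NetHyperparams(),
) -> EstimationNet:
    """Train the estimation network by maximizing the mean Gaussian utility.

    Training minimizes ``-mean u(theta_hat, theta)``; because the utility
    loss has vanishing gradients far from the truth, the network is warmed
    up for a few epochs with squared error before switching losses.
    """
    hp = hyperparams
    present = train_batch.labels == 1
    y = np.asarray(train_batch.amplitudes, dtype=float)[present]
    if y.size == 0 or not np.all(np.isfinite(y)):
        raise TrainingDataError(
            "estimation training needs signal-present images with true amplitudes"
        )
    prep = _Preprocessor.fit(train_batch.images[present], hp.pool)
    X = prep(train_batch.images[present])
    rng = np.random.default_rng(hp.seed + 1)
    mlp = _MLP([X.shape[1], *hp.hidden_sizes, 1], rng)

    # scale targets to O(1) for stable optimization; predictions are unscaled
    y_loc, y_scale = float(np.mean(y)), float(np.std(y)) or 1.0
    ys = (y - y_loc) / y_scale
    su = utility_width / y_scale

    def mse_grad(out, yy):
        return out - yy

    def mse_value(out, yy):
        return float(np.mean((out - yy) ** 2))

    def util_grad(out, yy):  # d/d(out) of -exp(-(out-y)^2 / (2 su^2))
        u = np.exp(-((out - yy) ** 2) / (2 * su**2))
        return u * (out - yy) / su**2

    def util_value(out, yy):
        return float(-np.mean(np.exp(-((out - yy) ** 2) / (2 * su**2))))

    warm = NetHyperparams(**{**hp.__dict__, "epochs": max(5, hp.epochs // 4)})
    _train(mlp, X, ys, warm, mse_grad, mse_value, rng)
    _train(mlp, X, ys, hp, util_grad, util_value, rng)

    # fold the target scaling into the output layer
    mlp.W[-1] = mlp.W[-1] * y_scale
    mlp.b[-1] = mlp.b[-1] * y_scale + y_loc
    return EstimationNet(mlp, prep)
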