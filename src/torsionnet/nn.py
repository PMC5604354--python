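"""Dense feed-forward network trained on trigonometric angle targets.

The network maps a windowed feature vector through sigmoid hidden layers
to a linear 4-unit output (sin/cos of phi and psi).  The loss is the
masked least-squares error E = 1/2 sum (pred - true)^2; gradients are
exact backpropagation, verified in the test suite against central finite
differences.  Optimization is by minibatch SGD or Adam — pluggable, with
the adaptive scheme as default — and every stochastic choice flows from a
single seed, so a (seed, config, data) triple reproduces training
bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DenseParams",
    "ForwardTrace",
    "TrainConfig",
    "sigmoid",
    "init_dense",
    "forward_dnn",
    "loss",
    "backward_dnn",
    "gradient_check",
    "make_optimizer",
    "train",
]


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class DenseParams:
    """Weights W (fan_in x fan_out) and biases per layer; output width 4."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]

    @property
    def layer_sizes(self) -> list[int]:
        return [self.weights[0].shape[0]] + [w.shape[1] for w in self.weights]

    def copy(self) -> "DenseParams":
        return DenseParams([w.copy() for w in self.weights], [b.copy() for b in self.biases])

    # -- flat-vector view used by the finite-difference checker ------------
    def to_vector(self) -> np.ndarray:
        return np.concatenate([t.ravel() for t in self.tensors()])

    def from_vector(self, vec: np.ndarray) -> None:
        i = 0
        for t in self.tensors():
            t[...] = vec[i:i + t.size].reshape(t.shape)
            i += t.size
        if i != vec.size:
            raise ValueError("vector length does not match parameter count")

    def tensors(self) -> list[np.ndarray]:
        return [*self.weights, *self.biases]


def init_dense(layer_sizes, rng: np.random.Generator) -> DenseParams:
    """Glorot-uniform initialization on +-sqrt(6 / (fan_in + fan_out))."""
    weights, biases = [], []
    for fan_in, fan_out in zip(layer_sizes[:-1], layer_sizes[1:]):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return DenseParams(weights, biases)


@dataclass
class ForwardTrace:
    """Intermediates of one forward pass: input, pre-activations, activations."""

    x: np.ndarray
    pre: list[np.ndarray]
    act: list[np.ndarray]  # act[-1] is the linear output

    @property
    def output(self) -> np.ndarray:
        return self.act[-1]


def forward_dnn(params: DenseParams, x: np.ndarray) -> ForwardTrace:
    """Forward pass; hidden layers sigmoid, output layer linear.

    ``x`` is (n, d) or (d,); the trace keeps every intermediate for the
    backward pass.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != params.weights[0].shape[0]:
        raise ValueError(
            f"input width {x.shape[1]} does not match layer 0 fan-in "
            f"{params.weights[0].shape[0]}"
        )
    pre, act = [], []
    h = x
    n_layers = len(params.weights)
    for n, (W, b) in enumerate(zip(params.weights, params.biases)):
        z = h @ W + b
        pre.append(z)
        h = z if n == n_layers - 1 else sigmoid(z)
        act.append(h)
    return ForwardTrace(x=x, pre=pre, act=act)


def loss(pred: np.ndarray, true: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Masked least-squares loss 1/2 sum (pred - true)^2.

    ``mask`` selects the target components that correspond to defined
    angles; fully masked samples contribute zero.
    """
    pred = np.asarray(pred, dtype=float)
    true = np.asarray(true, dtype=float)
    d = pred - true
    if mask is not None:
        d = np.where(np.asarray(mask, bool), d, 0.0)
    else:
        d = np.where(np.isfinite(d), d, 0.0)
    return float(0.5 * np.sum(d * d))


def _residual(pred, true, mask):
    d = np.asarray(pred, float) - np.asarray(true, float)
    if mask is not None:
        d = np.where(np.asarray(mask, bool), d, 0.0)
    else:
        d = np.where(np.isfinite(d), d, 0.0)
    return d


def backward_dnn(trace: ForwardTrace, true: np.ndarray, params: DenseParams,
                 mask: np.ndarray | None = None) -> DenseParams:
    """Exact gradients of the masked least-squares loss, batch-summed."""
    true = np.atleast_2d(np.asarray(true, dtype=float))
    if true.shape != trace.output.shape:
        raise ValueError("target shape does not match network output")
    if mask is not None:
        mask = np.atleast_2d(mask)
    delta = _residual(trace.output, true, mask)  # output layer is linear
    gw = [None] * len(params.weights)
    gb = [None] * len(params.biases)
    for n in range(len(params.weights) - 1, -1, -1):
        below = trace.x if n == 0 else trace.act[n - 1]
        if below.shape[0] != delta.shape[0]:
            raise ValueError("stale trace: batch size drifted")
        gw[n] = below.T @ delta
        gb[n] = delta.sum(axis=0)
        if n > 0:
            s = trace.act[n - 1]
            delta = (delta @ params.weights[n].T) * s * (1.0 - s)
    return DenseParams(gw, gb)


def gradient_check(loss_fn, get_vector, set_vector, analytic: np.ndarray,
                   epsilon: float = 1e-6):
    """Compare an analytic gradient against central finite differences.

    ``loss_fn()`` evaluates the scalar loss at the current parameters;
    ``get_vector``/``set_vector`` expose them as one flat vector.  Returns
    (max relative error, index of the worst coordinate).

    The per-coordinate error is |num - ana| / max(|num| + |ana|, 1e-4):
    coordinates where both gradients are smaller than the floor are
    compared absolutely, since there the central difference is dominated
    by floating-point cancellation noise rather than by the gradient.
    """
    if not (1e-8 <= epsilon <= 1e-4):
        raise ValueError("epsilon outside [1e-8, 1e-4]")
    theta = get_vector().copy()
    base = loss_fn()
    if not np.isfinite(base):
        raise ValueError("loss is not finite at the evaluation point")
    worst, worst_i = 0.0, -1
    for i in range(theta.size):
        orig = theta[i]
        theta[i] = orig + epsilon
        set_vector(theta)
        up = loss_fn()
        theta[i] = orig - epsilon
        set_vector(theta)
        down = loss_fn()
        theta[i] = orig
        numeric = (up - down) / (2.0 * epsilon)
        denom = max(abs(numeric) + abs(analytic[i]), 1e-4)
        rel = abs(numeric - analytic[i]) / denom
        if rel > worst:
            worst, worst_i = rel, i
    set_vector(theta)
    return worst, worst_i


@dataclass
class TrainConfig:
    """Minibatch training configuration; the seed is mandatory."""

    learning_rate: float = 0.01
    epochs: int = 30
    batch_size: int = 64
    optimizer_name: str = "adam"
    seed: int = 0
    shuffle: bool = True

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


class SGD:
    def __init__(self, lr: float):
        self.lr = lr

    def step(self, tensors, grads):
        for t, g in zip(tensors, grads):
            t -= self.lr * g


class Adam:
    def __init__(self, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = None
        self.v = None
        self.t = 0

    def step(self, tensors, grads):
        if self.m is None:
            self.m = [np.zeros_like(t) for t in tensors]
            self.v = [np.zeros_like(t) for t in tensors]
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (t, g) in enumerate(zip(tensors, grads)):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            t -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def make_optimizer(name: str, lr: float):
    if name == "sgd":
        return SGD(lr)
    if name == "adam":
        return Adam(lr)
    raise ValueError(f"unknown optimizer {name!r}")


class DivergenceError(RuntimeError):
    def __init__(self, epoch: int, checkpoint: DenseParams):
        super().__init__(f"training diverged (non-finite loss) at epoch {epoch}")
        self.checkpoint = checkpoint


def train(params: DenseParams, X: np.ndarray, Y: np.ndarray,
          mask: np.ndarray | None, cfg: TrainConfig):
    """Minibatch training; returns (params, per-epoch mean loss history).

    Aborts with the last finite-loss checkpoint if the loss diverges.
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    n = X.shape[0]
    rng = np.random.default_rng(cfg.seed)
    opt = make_optimizer(cfg.optimizer_name, cfg.learning_rate)
    history = []
    last_good = params.copy()
    for epoch in range(cfg.epochs):
        order = rng.permutation(n) if cfg.shuffle else np.arange(n)
        total = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb, yb = X[idx], Y[idx]
            mb = mask[idx] if mask is not None else None
            trace = forward_dnn(params, xb)
            total += loss(trace.output, yb, mb)
            grads = backward_dnn(trace, yb, params, mb)
            # mean-gradient semantics: step size independent of batch size
            scale = 1.0 / xb.shape[0]
            opt.step(params.tensors(), [g * scale for g in grads.tensors()])
        epoch_loss = total / n
        if not np.isfinite(epoch_loss):
            raise DivergenceError(epoch, last_good)
        history.append(epoch_loss)
        last_good = params.copy()
    return params, history
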