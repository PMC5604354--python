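"""Restricted Boltzmann machines and greedy stacked pre-training.

A binary RBM assigns energy E(v, h) = -sum_i b_i v_i - sum_j c_j h_j
- sum_ij h_j v_i w_ij and Boltzmann probability p(v, h) proportional to
exp(-E).  Training follows contrastive divergence: hidden units are
sampled binary from P(h|v); the visible reconstruction uses the sigmoid
probabilities directly (mean-field, no binary sampling) to reduce
gradient variance.  Real-valued inputs in [0, 1] are treated as Bernoulli
mean-field values clamped on the visible layer.

For verification the module also evaluates the exact log-likelihood of
tiny RBMs by enumerating all joint states, which the tests use as an
independent oracle for the CD update direction.

``pretrain_stack`` trains one RBM per hidden layer greedily — the hidden
probabilities of each trained RBM become the visible data of the next —
and returns the weights as the initialization of a dense network, with an
untrained linear output layer appended on top.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import DenseParams, sigmoid

__all__ = [
    "RBMParams",
    "rbm_energy",
    "hidden_probs",
    "visible_probs",
    "cd_update",
    "exact_loglik",
    "exact_loglik_grad",
    "pretrain_stack",
]


@dataclass
class RBMParams:
    """Weights W (n_visible x n_hidden), visible bias b, hidden bias c."""

    W: np.ndarray
    b: np.ndarray
    c: np.ndarray

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, float)
        self.b = np.asarray(self.b, float)
        self.c = np.asarray(self.c, float)
        if self.W.shape != (self.b.size, self.c.size):
            raise ValueError("RBM parameter shapes inconsistent")
        if not all(np.all(np.isfinite(t)) for t in (self.W, self.b, self.c)):
            raise ValueError("RBM parameters must be finite")

    @property
    def n_visible(self) -> int:
        return self.b.size

    @property
    def n_hidden(self) -> int:
        return self.c.size

    def copy(self) -> "RBMParams":
        return RBMParams(self.W.copy(), self.b.copy(), self.c.copy())


def rbm_energy(params: RBMParams, v, h):
    """E(v, h); accepts single states or (n, d) batches."""
    v = np.atleast_2d(np.asarray(v, float))
    h = np.atleast_2d(np.asarray(h, float))
    if v.shape[1] != params.n_visible or h.shape[1] != params.n_hidden:
        raise ValueError("state shapes do not match RBM")
    e = -(v @ params.b) - (h @ params.c) - np.einsum("nj,ij,ni->n", h, params.W, v)
    return float(e[0]) if e.size == 1 else e


def hidden_probs(params: RBMParams, v) -> np.ndarray:
    """P(h_j = 1 | v) = sigmoid(W^T v + c), factorial over units."""
    v = np.atleast_2d(np.asarray(v, float))
    return sigmoid(v @ params.W + params.c)


def visible_probs(params: RBMParams, h) -> np.ndarray:
    """P(v_i = 1 | h) = sigmoid(W h + b)."""
    h = np.atleast_2d(np.asarray(h, float))
    return sigmoid(h @ params.W.T + params.b)


def _cd_core(W, b_eff, c_eff, batch, k, rng):
    """Shared CD-k inner step given (possibly shifted) effective biases.

    Hidden samples are binary; visible reconstructions are mean-field
    probabilities.  Returns batch-mean gradients of ln P w.r.t. (W, b, c)
    plus the positive/negative phase statistics needed by the conditional
    variant.  The RNG is consumed identically regardless of the bias
    shifts, which makes the conditional model with zero coupling replay
    the plain model exactly.
    """
    if k < 1:
        raise ValueError("CD requires k >= 1")
    v0 = np.atleast_2d(np.asarray(batch, float))
    n = v0.shape[0]
    h0_p = sigmoid(v0 @ W + c_eff)
    vk = v0
    hk_p = h0_p
    for _ in range(k):
        h_sample = (rng.random(hk_p.shape) < hk_p).astype(float)
        vk = sigmoid(h_sample @ W.T + b_eff)
        hk_p = sigmoid(vk @ W + c_eff)
    gW = (v0.T @ h0_p - vk.T @ hk_p) / n
    dv = v0 - vk          # per-sample visible difference
    dh = h0_p - hk_p      # per-sample hidden-probability difference
    return gW, dv, dh, vk


def cd_update(params: RBMParams, batch, k: int = 1,
              rng: np.random.Generator | None = None, seed: int | None = None):
    """CD-k gradient estimate of the data log-likelihood (ascent direction).

    Returns an RBMParams holding (dW, db, dc), batch-averaged.  Provide
    either a Generator or a seed; given the same one the update is
    reproducible.
    """
    if rng is None:
        rng = np.random.default_rng(0 if seed is None else seed)
    gW, dv, dh, _ = _cd_core(params.W, params.b, params.c, batch, k, rng)
    return RBMParams(gW, dv.mean(axis=0), dh.mean(axis=0))


_ENUM_LIMIT = 20


def _all_states(n: int) -> np.ndarray:
    return ((np.arange(2 ** n)[:, None] >> np.arange(n)) & 1).astype(float)


def exact_loglik(params: RBMParams, batch) -> float:
    """Mean exact log P(v) by enumeration; refuses RBMs beyond 20 units.

    Oracle support only — the partition function is summed over all
    2^(n_v + n_h) joint states.
    """
    if params.n_visible + params.n_hidden > _ENUM_LIMIT:
        raise ValueError("RBM too large for exact enumeration")
    v_states = _all_states(params.n_visible)
    h_states = _all_states(params.n_hidden)
    # energies over the full joint grid
    logZ_terms = []
    for h in h_states:
        e = rbm_energy(params, v_states, np.tile(h, (v_states.shape[0], 1)))
        logZ_terms.append(-np.atleast_1d(e))
    logZ = _logsumexp(np.concatenate(logZ_terms))
    batch = np.atleast_2d(np.asarray(batch, float))
    lls = []
    for v in batch:
        e = rbm_energy(params, np.tile(v, (h_states.shape[0], 1)), h_states)
        lls.append(_logsumexp(-np.atleast_1d(e)) - logZ)
    return float(np.mean(lls))


def _logsumexp(x: np.ndarray) -> float:
    m = np.max(x)
    return float(m + np.log(np.sum(np.exp(x - m))))


def exact_loglik_grad(params: RBMParams, batch) -> RBMParams:
    """Exact gradient of mean log P(v): data-clamped minus model expectation."""
    if params.n_visible + params.n_hidden > _ENUM_LIMIT:
        raise ValueError("RBM too large for exact enumeration")
    batch = np.atleast_2d(np.asarray(batch, float))
    # positive phase: h analytically marginalised given each data v
    h_p = hidden_probs(params, batch)
    pos_W = batch.T @ h_p / batch.shape[0]
    pos_b = batch.mean(axis=0)
    pos_c = h_p.mean(axis=0)
    # negative phase: exact model expectation over all visible states
    v_states = _all_states(params.n_visible)
    h_states = _all_states(params.n_hidden)
    joint_e = np.array(
        [
            rbm_energy(params, v_states, np.tile(h, (v_states.shape[0], 1)))
            for h in h_states
        ]
    )  # (2^nh, 2^nv)
    logp = -joint_e
    logp -= _logsumexp(logp.ravel())
    p = np.exp(logp)
    neg_W = np.einsum("hv,vi,hj->ij", p, v_states, h_states)
    neg_b = np.einsum("hv,vi->i", p, v_states)
    neg_c = np.einsum("hv,hj->j", p, h_states)
    return RBMParams(pos_W - neg_W, pos_b - neg_b, pos_c - neg_c)


def train_rbm(params: RBMParams, data: np.ndarray, epochs: int, lr: float,
              batch_size: int, rng: np.random.Generator, shuffle: bool = False):
    """In-place CD-1 training; returns per-epoch mean reconstruction error.

    Minibatches run in corpus order by default so that conditional-variant
    reductions can replay the exact same update stream.
    """
    n = data.shape[0]
    recon_history = []
    for _ in range(epochs):
        order = rng.permutation(n) if shuffle else np.arange(n)
        recon = 0.0
        for start in range(0, n, batch_size):
            batch = data[order[start:start + batch_size]]
            gW, dv, dh, vk = _cd_core(params.W, params.b, params.c, batch, 1, rng)
            params.W += lr * gW
            params.b += lr * dv.mean(axis=0)
            params.c += lr * dh.mean(axis=0)
            recon += float(np.sum((batch - vk) ** 2))
        recon_history.append(recon / n)
    return recon_history


def pretrain_stack(layer_sizes, data: np.ndarray, epochs: int = 20,
                   seed: int = 0, lr: float = 0.01, batch_size: int = 32,
                   rng: np.random.Generator | None = None) -> DenseParams:
    """Greedy layer-wise RBM pre-training of a dense stack.

    ``layer_sizes`` is the full dense architecture (input, hidden...,
    output); each adjacent hidden pair is trained as an RBM on the
    propagated hidden probabilities of the previous one.  The final
    (linear output) layer is appended untrained with a small random
    initialization.  Deterministic given the seed.
    """
    data = np.asarray(data, float)
    if data.size == 0:
        raise ValueError("empty pre-training data")
    if rng is None:
        rng = np.random.default_rng(seed)
    weights, biases = [], []
    visible = data
    for fan_in, fan_out in zip(layer_sizes[:-2], layer_sizes[1:-1]):
        if visible.shape[1] != fan_in:
            raise ValueError("layer sizes do not match propagated data width")
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        rbm = RBMParams(
            rng.uniform(-limit, limit, size=(fan_in, fan_out)),
            np.zeros(fan_in),
            np.zeros(fan_out),
        )
        train_rbm(rbm, visible, epochs=epochs, lr=lr, batch_size=batch_size, rng=rng)
        weights.append(rbm.W.copy())
        biases.append(rbm.c.copy())
        visible = hidden_probs(rbm, visible)
    # untrained linear readout appended at zero: the first fine-tuning
    # steps fit the readout on the frozen pretrained features
    weights.append(np.zeros((layer_sizes[-2], layer_sizes[-1])))
    biases.append(np.zeros(layer_sizes[-1]))
    return DenseParams(weights, biases)
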