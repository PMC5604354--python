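"""Recurrent network and conditional-RBM pre-training for sequences.

The recurrent architecture makes the first hidden layer stateful: its
pre-activation at residue t adds U-weighted hidden outputs of residue
t-1 to the W-weighted inputs, so information can flow along the chain
from the N- to the C-terminus.  Deeper layers and the linear 4-unit
output head are ordinary feed-forward layers applied per residue.
Gradients come from backpropagation through time, optionally truncated
to a memory horizon: the error signal of each residue's loss travels at
most ``memory_length`` recurrent transitions backwards.  A horizon at
least the sequence length reproduces full BPTT exactly.

The conditional (recurrent) RBM extends the plain RBM energy with
bias shifts that depend linearly on the previous residue's hidden state:

    E(v, h | h_prev) = -sum_i (b_i + sum_k V_ik h_prev_k) v_i
                       -sum_j (c_j + sum_k U_jk h_prev_k) h_j
                       -sum_ij h_j v_i w_ij

CD updates use the same Gibbs machinery as the plain RBM with the
shifted biases; the gradients for V and U are the visible/hidden bias
gradients scaled by h_prev.  During pre-training, h_prev is the previous
residue's mean-field hidden probability vector (zeros at the first
residue), never a binary sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import DenseParams, sigmoid
from .rbm import RBMParams, _cd_core, hidden_probs

__all__ = [
    "RecurrentParams",
    "CRBMParams",
    "forward_drnn",
    "bptt_gradients",
    "crbm_energy",
    "crbm_cd_update",
    "pretrain_recurrent_stack",
    "init_recurrent",
]


@dataclass
class RecurrentParams:
    """First-layer recurrent weights plus the dense head.

    ``W_in`` (d x h1) and ``U_rec`` (h1 x h1) feed the stateful first
    hidden layer with bias ``b_h``; ``head`` maps h1 through optional
    deeper sigmoid layers to the linear 4-unit output.
    """

    W_in: np.ndarray
    U_rec: np.ndarray
    b_h: np.ndarray
    head: DenseParams
    memory_length: int = 5

    def __post_init__(self) -> None:
        h1 = self.W_in.shape[1]
        if self.U_rec.shape != (h1, h1):
            raise ValueError("U_rec must be square in the hidden width")
        if self.head.layer_sizes[0] != h1 or self.head.layer_sizes[-1] != 4:
            raise ValueError("head must map h1 -> ... -> 4")
        if self.memory_length < 1:
            raise ValueError("memory_length must be >= 1")

    def copy(self) -> "RecurrentParams":
        return RecurrentParams(self.W_in.copy(), self.U_rec.copy(), self.b_h.copy(),
                               self.head.copy(), self.memory_length)

    def tensors(self) -> list[np.ndarray]:
        return [self.W_in, self.U_rec, self.b_h, *self.head.tensors()]

    def to_vector(self) -> np.ndarray:
        return np.concatenate([t.ravel() for t in self.tensors()])

    def from_vector(self, vec: np.ndarray) -> None:
        i = 0
        for t in self.tensors():
            t[...] = vec[i:i + t.size].reshape(t.shape)
            i += t.size
        if i != vec.size:
            raise ValueError("vector length mismatch")


def init_recurrent(layer_sizes, rng: np.random.Generator,
                   memory_length: int = 5) -> RecurrentParams:
    """Glorot-uniform init of a recurrent stack given full layer sizes."""
    from .nn import init_dense

    d, h1 = layer_sizes[0], layer_sizes[1]
    limit = np.sqrt(6.0 / (d + h1))
    W_in = rng.uniform(-limit, limit, size=(d, h1))
    limit_u = np.sqrt(6.0 / (2 * h1))
    U_rec = rng.uniform(-limit_u, limit_u, size=(h1, h1))
    head = init_dense(list(layer_sizes[1:]), rng)
    return RecurrentParams(W_in, U_rec, np.zeros(h1), head, memory_length)


def _head_forward(head: DenseParams, H: np.ndarray):
    """Dense head forward over all residues at once; returns (acts, output)."""
    acts = []
    h = H
    last = len(head.weights) - 1
    for n, (W, b) in enumerate(zip(head.weights, head.biases)):
        z = h @ W + b
        h = z if n == last else sigmoid(z)
        acts.append(h)
    return acts, acts[-1]


def forward_drnn(params: RecurrentParams, inputs: np.ndarray):
    """Run a whole sequence through the recurrent net.

    Returns (Y, H, head_acts): per-residue linear outputs (L x 4), the
    first-layer hidden states (L x h1), and the head activations.  The
    initial hidden state is the zero vector.
    """
    X = np.atleast_2d(np.asarray(inputs, float))
    if X.shape[0] == 0:
        raise ValueError("empty sequence")
    L = X.shape[0]
    h1 = params.W_in.shape[1]
    H = np.empty((L, h1))
    h_prev = np.zeros(h1)
    for t in range(L):
        H[t] = sigmoid(X[t] @ params.W_in + h_prev @ params.U_rec + params.b_h)
        h_prev = H[t]
    acts, Y = _head_forward(params.head, H)
    return Y, H, acts


def _head_backward(head: DenseParams, H, acts, delta_out):
    """Backprop the head; returns (grads as DenseParams, delta at head input)."""
    gw = [None] * len(head.weights)
    gb = [None] * len(head.biases)
    delta = delta_out
    for n in range(len(head.weights) - 1, -1, -1):
        below = H if n == 0 else acts[n - 1]
        gw[n] = below.T @ delta
        gb[n] = delta.sum(axis=0)
        delta = delta @ head.weights[n].T
        if n > 0:
            s = acts[n - 1]
            delta = delta * s * (1.0 - s)
    return DenseParams(gw, gb), delta


def bptt_gradients(params: RecurrentParams, inputs: np.ndarray,
                   targets: np.ndarray, mask: np.ndarray | None = None,
                   memory_length: int | None = None):
    """Gradients of the masked least-squares loss by (truncated) BPTT.

    ``memory_length`` limits how many recurrent transitions the error of
    each residue's loss may traverse; None uses ``params.memory_length``.
    A horizon >= L runs the exact single-pass full BPTT.  Returns
    (grads: RecurrentParams, total loss).
    """
    m = params.memory_length if memory_length is None else memory_length
    if m < 1:
        raise ValueError("memory_length must be >= 1")
    X = np.atleast_2d(np.asarray(inputs, float))
    T = np.atleast_2d(np.asarray(targets, float))
    Y, H, acts = forward_drnn(params, X)
    if not np.all(np.isfinite(H)):
        raise FloatingPointError("non-finite activations in forward pass")
    d = Y - T
    if mask is not None:
        d = np.where(np.atleast_2d(mask), d, 0.0)
    else:
        d = np.where(np.isfinite(d), d, 0.0)
    total_loss = float(0.5 * np.sum(d * d))
    head_grads, delta_h = _head_backward(params.head, H, acts, d)

    L = X.shape[0]
    gW = np.zeros_like(params.W_in)
    gU = np.zeros_like(params.U_rec)
    gb = np.zeros_like(params.b_h)
    sprime = H * (1.0 - H)

    if m >= L:
        # full BPTT in one backward sweep
        carry = np.zeros(params.b_h.size)
        for t in range(L - 1, -1, -1):
            g = (delta_h[t] + carry) * sprime[t]
            gW += np.outer(X[t], g)
            gb += g
            if t > 0:
                gU += np.outer(H[t - 1], g)
            carry = g @ params.U_rec.T
    else:
        # truncated: each residue's error travels at most m transitions back
        for t in range(L):
            g = delta_h[t] * sprime[t]
            tau = t
            for _ in range(m + 1):
                gW += np.outer(X[tau], g)
                gb += g
                if tau > 0:
                    gU += np.outer(H[tau - 1], g)
                if tau == 0 or (t - tau) == m:
                    break
                g = (g @ params.U_rec.T) * sprime[tau - 1]
                tau -= 1
    grads = RecurrentParams(gW, gU, gb, head_grads, params.memory_length)
    return grads, total_loss


# ---------------------------------------------------------------------------
# Conditional (recurrent) RBM


@dataclass
class CRBMParams:
    """Plain RBM parameters plus linear bias couplings to h_prev."""

    W: np.ndarray
    b: np.ndarray
    c: np.ndarray
    V_cond: np.ndarray  # n_visible x n_hidden_prev
    U_cond: np.ndarray  # n_hidden x n_hidden_prev

    def __post_init__(self) -> None:
        nv, nh = self.W.shape
        if self.b.size != nv or self.c.size != nh:
            raise ValueError("bias shapes inconsistent with W")
        if self.V_cond.shape[0] != nv or self.U_cond.shape[0] != nh:
            raise ValueError("conditional coupling shapes inconsistent")
        if self.V_cond.shape[1] != self.U_cond.shape[1]:
            raise ValueError("V_cond and U_cond must share the h_prev width")

    @property
    def n_visible(self) -> int:
        return self.b.size

    @property
    def n_hidden(self) -> int:
        return self.c.size

    def copy(self) -> "CRBMParams":
        return CRBMParams(self.W.copy(), self.b.copy(), self.c.copy(),
                          self.V_cond.copy(), self.U_cond.copy())

    def as_rbm(self) -> RBMParams:
        return RBMParams(self.W.copy(), self.b.copy(), self.c.copy())


def crbm_energy(params: CRBMParams, v, h, h_prev) -> float:
    """Conditional energy; with h_prev = 0 it equals the plain RBM energy."""
    v = np.asarray(v, float).ravel()
    h = np.asarray(h, float).ravel()
    h_prev = np.asarray(h_prev, float).ravel()
    if v.size != params.n_visible or h.size != params.n_hidden:
        raise ValueError("state shapes do not match CRBM")
    if h_prev.size != params.V_cond.shape[1]:
        raise ValueError("h_prev width does not match couplings")
    b_eff = params.b + params.V_cond @ h_prev
    c_eff = params.c + params.U_cond @ h_prev
    return float(-(b_eff @ v) - (c_eff @ h) - h @ params.W.T @ v)


def crbm_cd_update(params: CRBMParams, v_batch, h_prev_batch, k: int = 1,
                   rng: np.random.Generator | None = None,
                   seed: int | None = None) -> CRBMParams:
    """CD-k ascent direction for all five parameter groups.

    The Gibbs chain runs with effective biases b + V h_prev, c + U h_prev;
    the coupling gradients are the per-sample bias gradients scaled by
    h_prev.  With h_prev = 0 the (W, b, c) block and the RNG consumption
    are identical to the plain ``cd_update``.
    """
    if rng is None:
        rng = np.random.default_rng(0 if seed is None else seed)
    v0 = np.atleast_2d(np.asarray(v_batch, float))
    hp = np.atleast_2d(np.asarray(h_prev_batch, float))
    if hp.shape[0] == 1 and v0.shape[0] > 1:
        hp = np.broadcast_to(hp, (v0.shape[0], hp.shape[1]))
    n = v0.shape[0]
    b_eff = params.b + hp @ params.V_cond.T
    c_eff = params.c + hp @ params.U_cond.T
    gW, dv, dh, _ = _cd_core(params.W, b_eff, c_eff, v0, k, rng)
    gV = dv.T @ hp / n
    gU = dh.T @ hp / n
    return CRBMParams(gW, dv.mean(axis=0), dh.mean(axis=0), gV, gU)


def pretrain_recurrent_stack(layer_sizes, sequences, epochs: int = 20,
                             seed: int = 0, lr: float = 0.01,
                             batch_size: int = 32, memory_length: int = 5,
                             freeze_conditional: bool = False) -> RecurrentParams:
    """Pre-train a recurrent stack with a conditional RBM at layer 1.

    The first hidden layer is trained as a CRBM: at each epoch the mean-
    field hidden trajectory of every sequence is computed under the
    current parameters (h_prev of the first residue is zero), then CD-1
    updates run over sequential minibatches of residues in corpus order.
    Deeper hidden layers are pre-trained as plain RBMs on the propagated
    hidden probabilities; the linear output layer is appended untrained.

    With ``freeze_conditional`` the couplings stay at zero and the result
    is bit-identical to ``pretrain_stack`` on the flattened residues with
    the same seed.  Returns RecurrentParams with U_rec = U_cond^T.
    """
    from .rbm import train_rbm

    seqs = [np.atleast_2d(np.asarray(s, float)) for s in sequences]
    if not seqs:
        raise ValueError("empty sequence corpus")
    rng = np.random.default_rng(seed)
    d, h1 = layer_sizes[0], layer_sizes[1]
    limit = np.sqrt(6.0 / (d + h1))
    crbm = CRBMParams(
        rng.uniform(-limit, limit, size=(d, h1)),
        np.zeros(d),
        np.zeros(h1),
        np.zeros((d, h1)),
        np.zeros((h1, h1)),
    )
    flat_v = np.concatenate(seqs, axis=0)
    recon_history: list[float] = []
    for _ in range(epochs):
        # mean-field hidden trajectories under current parameters
        hp_rows = np.empty((flat_v.shape[0], h1))
        row = 0
        for s in seqs:
            h_prev = np.zeros(h1)
            for t in range(s.shape[0]):
                hp_rows[row] = h_prev
                h_prev = sigmoid(
                    s[t] @ crbm.W + crbm.c + crbm.U_cond @ h_prev
                )
                row += 1
        recon = 0.0
        for start in range(0, flat_v.shape[0], batch_size):
            vb = flat_v[start:start + batch_size]
            hb = hp_rows[start:start + batch_size]
            b_eff = crbm.b + hb @ crbm.V_cond.T
            c_eff = crbm.c + hb @ crbm.U_cond.T
            gW, dv, dh, vk = _cd_core(crbm.W, b_eff, c_eff, vb, 1, rng)
            recon += float(np.sum((vb - vk) ** 2))
            crbm.W += lr * gW
            crbm.b += lr * dv.mean(axis=0)
            crbm.c += lr * dh.mean(axis=0)
            if not freeze_conditional:
                crbm.V_cond += lr * (dv.T @ hb / vb.shape[0])
                crbm.U_cond += lr * (dh.T @ hb / vb.shape[0])
        recon_history.append(recon / flat_v.shape[0])

    # propagate every sequence through layer 1 (mean-field, conditioned);
    # the data term is batched so the zero-coupling case reproduces the
    # plain stacked-RBM propagation bit-for-bit
    prop_rows = np.empty((flat_v.shape[0], h1))
    row = 0
    for s in seqs:
        base = s @ crbm.W + crbm.c
        h_prev = np.zeros(h1)
        for t in range(s.shape[0]):
            h_prev = sigmoid(base[t] + crbm.U_cond @ h_prev)
            prop_rows[row] = h_prev
            row += 1

    # deeper hidden layers: plain stacked RBMs on the propagated data
    weights = [crbm.W.copy()]
    biases = [crbm.c.copy()]
    visible = prop_rows
    for fan_in, fan_out in zip(layer_sizes[1:-2], layer_sizes[2:-1]):
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
    # untrained linear readout appended at zero (same recipe as the
    # feed-forward stack, keeping the two paths' RNG streams aligned)
    weights.append(np.zeros((layer_sizes[-2], layer_sizes[-1])))
    biases.append(np.zeros(layer_sizes[-1]))

    head = DenseParams(weights[1:], biases[1:])
    params = RecurrentParams(weights[0], crbm.U_cond.T.copy(), biases[0],
                             head, memory_length)
    params.layer1_recon_history = recon_history
    return params
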