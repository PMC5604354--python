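"""Scikit-learn style estimators for torsion-angle prediction.

Four architectures share one interface: ``fit(X, y)`` takes a list of
per-protein feature matrices (L x 56 arrays or FeatureMatrix objects)
and a list of matching angle tables; ``predict(X)`` returns per-protein
(L x 2) arrays of phi/psi in degrees.  All estimators subclass
``sklearn.base.BaseEstimator`` so ``get_params``/``set_params``, cloning
and sklearn model selection work as usual.

* ``TorsionDNN``       — windowed feed-forward network, random init.
* ``TorsionDRBM``      — the same network initialized by greedy stacked
                         RBM pre-training, then fine-tuned by backprop.
* ``TorsionDRNN``      — first hidden layer recurrent along the chain,
                         trained by truncated BPTT.
* ``TorsionDReRBM``    — recurrent net whose first layer is pre-trained
                         as a conditional RBM coupling each residue to
                         the previous residue's hidden state.

Window sizes default to the per-architecture choices that performed best
in model selection (11, 7, 7 and 3 residues respectively); the hidden
stack defaults to 500-200-50.  Every stochastic path is driven by
``random_state`` alone, so a (seed, config, data) triple reproduces
training bit-for-bit.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from . import nn
from .angles import AngleTable, mean_absolute_error
from .checkpoint import load_checkpoint, save_checkpoint
from .features import LAYOUT_V1, FeatureMatrix, WindowConfig, extract_windows
from .recurrent import (RecurrentParams, bptt_gradients, forward_drnn,
                        init_recurrent, pretrain_recurrent_stack)
from .rbm import pretrain_stack

__all__ = [
    "TorsionDNN",
    "TorsionDRBM",
    "TorsionDRNN",
    "TorsionDReRBM",
    "CircularMeanBaseline",
    "decode_outputs",
]


def _as_values(x) -> np.ndarray:
    if isinstance(x, FeatureMatrix):
        return x.values
    return np.atleast_2d(np.asarray(x, float))


def _as_angles(y) -> tuple[np.ndarray, np.ndarray]:
    """Return (L x 2 degrees with NaN for undefined, L x 2 defined mask)."""
    if isinstance(y, AngleTable):
        ang = np.column_stack([y.phi, y.psi])
        mask = np.column_stack([y.phi_defined, y.psi_defined])
        return ang, mask
    ang = np.atleast_2d(np.asarray(y, float))
    return ang, np.isfinite(ang)


def _targets(y) -> tuple[np.ndarray, np.ndarray]:
    """Trig targets (L x 4) and component mask from an angle container."""
    ang, mask = _as_angles(y)
    r = np.deg2rad(ang)
    t = np.column_stack([np.sin(r[:, 0]), np.cos(r[:, 0]),
                         np.sin(r[:, 1]), np.cos(r[:, 1])])
    m = np.column_stack([mask[:, 0], mask[:, 0], mask[:, 1], mask[:, 1]])
    t = np.where(m, t, 0.0)
    return t, m


def decode_outputs(Y: np.ndarray) -> np.ndarray:
    """Decode network outputs (n x 4 trig values) to degrees in (-180, 180]."""
    Y = np.atleast_2d(np.asarray(Y, float))
    phi = np.rad2deg(np.arctan2(Y[:, 0], Y[:, 1]))
    psi = np.rad2deg(np.arctan2(Y[:, 2], Y[:, 3]))
    out = np.column_stack([phi, psi])
    out[out <= -180.0] = 180.0
    return out


class _TorsionBase(BaseEstimator):
    """Shared plumbing: input validation, windowing, decode, persistence."""

    _arch = "base"

    def _validate(self, X, y=None):
        mats = [_as_values(x) for x in X]
        if not mats:
            raise ValueError("X must contain at least one protein")
        width = mats[0].shape[1]
        if any(m.shape[1] != width for m in mats):
            raise ValueError("all proteins must share one feature width")
        if y is not None and len(y) != len(mats):
            raise ValueError("X and y must have equal length")
        return mats, width

    def _window_cfg(self) -> WindowConfig:
        return WindowConfig(self.window)

    def _check_fitted(self):
        if not hasattr(self, "params_"):
            raise RuntimeError("estimator is not fitted")

    def _check_width(self, width):
        if width != self.n_features_in_:
            raise ValueError(
                f"feature width {width} does not match fitted width "
                f"{self.n_features_in_} (layout {self.layout_version_})"
            )

    def score(self, X, y):
        """Negative mean of pooled phi/psi MAE (higher is better)."""
        preds = self.predict(X)
        errs = []
        for p, yi in zip(preds, y):
            ang, mask = _as_angles(yi)
            for j in (0, 1):
                errs.append(mean_absolute_error(p[:, j][mask[:, j]],
                                                ang[:, j][mask[:, j]]))
        return -float(np.mean(errs))

    def save(self, path) -> None:
        self._check_fitted()
        meta = {"arch": self._arch, "params": self.get_params(),
                "layout_version": self.layout_version_,
                "n_features_in": int(self.n_features_in_),
                "loss_history": list(self.loss_history_)}
        save_checkpoint(path, self.params_, meta)

    @classmethod
    def load(cls, path):
        params, meta = load_checkpoint(path)
        if meta["arch"] != cls._arch:
            raise ValueError(f"checkpoint is {meta['arch']!r}, expected {cls._arch!r}")
        est = cls(**meta["params"])
        est.params_ = params
        est.n_features_in_ = meta["n_features_in"]
        est.layout_version_ = meta["layout_version"]
        est.loss_history_ = list(meta["loss_history"])
        return est


class _WindowedDense(_TorsionBase):
    """Common fit/predict for the two windowed feed-forward models."""

    def _init_params(self, layer_sizes, Xw, rng):
        raise NotImplementedError

    def fit(self, X, y):
        mats, width = self._validate(X, y)
        cfg = self._window_cfg()
        Xw = np.concatenate([extract_windows(m, cfg) for m in mats], axis=0)
        T, M = zip(*(_targets(yi) for yi in y))
        T = np.concatenate(T, axis=0)
        M = np.concatenate(M, axis=0)
        if Xw.shape[0] != T.shape[0]:
            raise ValueError("feature and angle tables disagree on protein lengths")
        layer_sizes = [Xw.shape[1], *self.hidden_sizes, 4]
        rng = np.random.default_rng(self.random_state)
        params = self._init_params(layer_sizes, Xw, rng)
        tc = nn.TrainConfig(
            learning_rate=self.learning_rate, epochs=self.epochs,
            batch_size=self.batch_size, optimizer_name=self.optimizer,
            seed=self.random_state,
        )
        self.params_, self.loss_history_ = nn.train(params, Xw, T, M, tc)
        self.n_features_in_ = width
        self.layout_version_ = self.layout_version
        return self

    def predict(self, X):
        self._check_fitted()
        mats, width = self._validate(X)
        self._check_width(width)
        cfg = self._window_cfg()
        out = []
        for m in mats:
            trace = nn.forward_dnn(self.params_, extract_windows(m, cfg))
            out.append(decode_outputs(trace.output))
        return out


class TorsionDNN(_WindowedDense):
    """Feed-forward network on sliding windows, randomly initialized."""

    _arch = "dnn"

    def __init__(self, window=11, hidden_sizes=(500, 200, 50), epochs=30,
                 learning_rate=0.001, batch_size=64, optimizer="adam",
                 layout_version="v1", random_state=0):
        self.window = window
        self.hidden_sizes = tuple(hidden_sizes)
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.optimizer = optimizer
        self.layout_version = layout_version
        self.random_state = random_state

    def _init_params(self, layer_sizes, Xw, rng):
        return nn.init_dense(layer_sizes, rng)


class TorsionDRBM(_WindowedDense):
    """Feed-forward network initialized by greedy stacked-RBM pre-training.

    Each adjacent pair of hidden layers is trained as an RBM by CD-1 on
    the propagated hidden probabilities; the resulting weights seed the
    dense network, which is then fine-tuned by backprop exactly as the
    randomly initialized variant.
    """

    _arch = "drbm"

    def __init__(self, window=7, hidden_sizes=(500, 200, 50), epochs=30,
                 learning_rate=0.001, batch_size=64, optimizer="adam",
                 pretrain_epochs=10, pretrain_lr=0.01, pretrain_batch_size=32,
                 layout_version="v1", random_state=0):
        self.window = window
        self.hidden_sizes = tuple(hidden_sizes)
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.optimizer = optimizer
        self.pretrain_epochs = pretrain_epochs
        self.pretrain_lr = pretrain_lr
        self.pretrain_batch_size = pretrain_batch_size
        self.layout_version = layout_version
        self.random_state = random_state

    def _init_params(self, layer_sizes, Xw, rng):
        return pretrain_stack(layer_sizes, Xw, epochs=self.pretrain_epochs,
                              lr=self.pretrain_lr,
                              batch_size=self.pretrain_batch_size, rng=rng)


class _RecurrentBase(_TorsionBase):
    """Common fit/predict for the two recurrent models."""

    def _init_params(self, layer_sizes, seqs, rng):
        raise NotImplementedError

    def fit(self, X, y):
        mats, width = self._validate(X, y)
        cfg = self._window_cfg()
        seqs = [extract_windows(m, cfg) for m in mats]
        tm = [_targets(yi) for yi in y]
        layer_sizes = [seqs[0].shape[1], *self.hidden_sizes, 4]
        rng = np.random.default_rng(self.random_state)
        params = self._init_params(layer_sizes, seqs, rng)
        opt = nn.make_optimizer(self.optimizer, self.learning_rate)
        n_res = sum(s.shape[0] for s in seqs)
        history = []
        order_rng = np.random.default_rng(self.random_state)
        for _ in range(self.epochs):
            order = order_rng.permutation(len(seqs))
            total = 0.0
            for i in order:
                grads, l = bptt_gradients(params, seqs[i], tm[i][0], tm[i][1],
                                          memory_length=self.memory_length)
                total += l
                # mean-gradient semantics: step size independent of length
                scale = 1.0 / seqs[i].shape[0]
                opt.step(params.tensors(), [g * scale for g in grads.tensors()])
            epoch_loss = total / n_res
            if not np.isfinite(epoch_loss):
                raise nn.DivergenceError(len(history), params)
            history.append(epoch_loss)
        self.params_ = params
        self.loss_history_ = history
        self.n_features_in_ = width
        self.layout_version_ = self.layout_version
        return self

    def predict(self, X):
        self._check_fitted()
        mats, width = self._validate(X)
        self._check_width(width)
        cfg = self._window_cfg()
        out = []
        for m in mats:
            Y, _, _ = forward_drnn(self.params_, extract_windows(m, cfg))
            out.append(decode_outputs(Y))
        return out


class TorsionDRNN(_RecurrentBase):
    """Recurrent network: first hidden layer carries state along the chain."""

    _arch = "drnn"

    def __init__(self, window=7, hidden_sizes=(500, 200, 50), memory_length=5,
                 epochs=15, learning_rate=0.001, optimizer="adam",
                 layout_version="v1", random_state=0):
        self.window = window
        self.hidden_sizes = tuple(hidden_sizes)
        self.memory_length = memory_length
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.optimizer = optimizer
        self.layout_version = layout_version
        self.random_state = random_state

    def _init_params(self, layer_sizes, seqs, rng):
        return init_recurrent(layer_sizes, rng, memory_length=self.memory_length)


class TorsionDReRBM(_RecurrentBase):
    """Recurrent network pre-trained by a conditional RBM.

    The first hidden layer is pre-trained as an RBM whose visible and
    hidden biases are shifted linearly by the previous residue's hidden
    state; the hidden-to-hidden coupling learned this way becomes the
    initial recurrent weight matrix.  Fine-tuning uses truncated BPTT,
    identical to the randomly initialized recurrent model.
    """

    _arch = "drerbm"

    def __init__(self, window=3, hidden_sizes=(500, 200, 50), memory_length=5,
                 epochs=15, learning_rate=0.001, optimizer="adam",
                 pretrain_epochs=10, pretrain_lr=0.01, pretrain_batch_size=32,
                 layout_version="v1", random_state=0):
        self.window = window
        self.hidden_sizes = tuple(hidden_sizes)
        self.memory_length = memory_length
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.optimizer = optimizer
        self.pretrain_epochs = pretrain_epochs
        self.pretrain_lr = pretrain_lr
        self.pretrain_batch_size = pretrain_batch_size
        self.layout_version = layout_version
        self.random_state = random_state

    def _init_params(self, layer_sizes, seqs, rng):
        return pretrain_recurrent_stack(
            layer_sizes, seqs, epochs=self.pretrain_epochs,
            seed=self.random_state, lr=self.pretrain_lr,
            batch_size=self.pretrain_batch_size,
            memory_length=self.memory_length,
        )


class CircularMeanBaseline(BaseEstimator):
    """Constant predictor at the circular mean of the training angles."""

    def __init__(self):
        pass

    def fit(self, X, y):
        sins = np.zeros(2)
        coss = np.zeros(2)
        n = np.zeros(2)
        for yi in y:
            ang, mask = _as_angles(yi)
            for j in (0, 1):
                r = np.deg2rad(ang[:, j][mask[:, j]])
                sins[j] += np.sum(np.sin(r))
                coss[j] += np.sum(np.cos(r))
                n[j] += r.size
        if np.any(n == 0):
            raise ValueError("no defined angles in training data")
        mean = np.rad2deg(np.arctan2(sins / n, coss / n))
        mean[mean <= -180.0] = 180.0
        self.mean_angles_ = mean
        return self

    def predict(self, X):
        if not hasattr(self, "mean_angles_"):
            raise RuntimeError("estimator is not fitted")
        out = []
        for x in X:
            L = _as_values(x).shape[0]
            out.append(np.tile(self.mean_angles_, (L, 1)))
        return out
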