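"""Recurrent net, truncated BPTT, conditional RBM, recurrent pre-training."""

import numpy as np
import pytest

from torsionnet.nn import DenseParams, forward_dnn, gradient_check, init_dense, sigmoid
from torsionnet.rbm import RBMParams, cd_update, exact_loglik_grad, rbm_energy
from torsionnet.recurrent import (CRBMParams, RecurrentParams, bptt_gradients,
                                  crbm_cd_update, crbm_energy, forward_drnn,
                                  init_recurrent, pretrain_recurrent_stack)
from torsionnet.rbm import pretrain_stack


def _shared_pair(rng, d=8, h=(6, 5)):
    """A dense net and the recurrent net with identical weights, U = 0."""
    dense = init_dense([d, *h, 4], rng)
    rec = RecurrentParams(
        dense.weights[0].copy(), np.zeros((h[0], h[0])), dense.biases[0].copy(),
        DenseParams([w.copy() for w in dense.weights[1:]],
                    [b.copy() for b in dense.biases[1:]]))
    return dense, rec


class TestForward:
    def test_zero_recurrence_reduces_to_dnn(self, rng):
        dense, rec = _shared_pair(rng)
        X = rng.random((15, 8))
        Y, _, _ = forward_drnn(rec, X)
        assert np.allclose(Y, forward_dnn(dense, X).output, atol=1e-12)

    def test_two_step_hand_computation(self):
        # scalar hidden unit, direct linear readout
        w, u, b = 0.5, -0.3, 0.1
        V = np.array([[1.0, 2.0, -1.0, 0.5]])
        rec = RecurrentParams(np.array([[w]]), np.array([[u]]), np.array([b]),
                              DenseParams([V], [np.zeros(4)]))
        x = np.array([[0.4], [0.9]])
        h1 = 1 / (1 + np.exp(-(w * 0.4 + b)))
        h2 = 1 / (1 + np.exp(-(w * 0.9 + u * h1 + b)))
        Y, H, _ = forward_drnn(rec, x)
        assert H[0, 0] == pytest.approx(h1)
        assert H[1, 0] == pytest.approx(h2)
        assert np.allclose(Y[0], V[0] * h1)
        assert np.allclose(Y[1], V[0] * h2)

    @pytest.mark.parametrize("L", [1, 5, 50])
    def test_output_length(self, L, rng):
        rec = init_recurrent([6, 4, 4], rng)
        Y, H, _ = forward_drnn(rec, rng.random((L, 6)))
        assert Y.shape == (L, 4) and H.shape == (L, 4)

    def test_empty_sequence_rejected(self, rng):
        rec = init_recurrent([6, 4, 4], rng)
        with pytest.raises(ValueError):
            forward_drnn(rec, np.empty((0, 6)))


class TestBPTT:
    def test_length_one_has_no_recurrent_gradient(self, rng):
        rec = init_recurrent([6, 4, 4], rng)
        g, _ = bptt_gradients(rec, rng.random((1, 6)), rng.random((1, 4)))
        assert np.all(g.U_rec == 0)

    def test_truncation_at_full_horizon_equals_full(self, rng):
        rec = init_recurrent([6, 5, 4], rng)
        L = 9
        X, T = rng.random((L, 6)), rng.random((L, 4))
        full, lf = bptt_gradients(rec, X, T, memory_length=L)
        trunc, lt = bptt_gradients(rec, X, T, memory_length=L - 1)
        assert lf == lt
        for a, b in zip(full.tensors(), trunc.tensors()):
            assert np.allclose(a, b, atol=1e-12)

    def test_shorter_memory_changes_recurrent_gradient(self, rng):
        rec = init_recurrent([6, 5, 4], rng)
        X, T = rng.random((12, 6)), rng.random((12, 4))
        full, _ = bptt_gradients(rec, X, T, memory_length=12)
        short, _ = bptt_gradients(rec, X, T, memory_length=1)
        assert not np.allclose(full.U_rec, short.U_rec)

    @pytest.mark.parametrize("trial", range(3))
    def test_finite_differences_on_short_sequences(self, trial, rng):
        rec = init_recurrent([5, 4, 3, 4], np.random.default_rng(100 + trial))
        X = rng.random((3, 5))
        T = rng.random((3, 4))

        def loss_fn():
            _, l = bptt_gradients(rec, X, T, memory_length=3)
            return l

        g, _ = bptt_gradients(rec, X, T, memory_length=3)
        err, _ = gradient_check(loss_fn, rec.to_vector, rec.from_vector,
                                g.to_vector())
        assert err < 1e-5


class TestCRBMEnergy:
    def test_reduces_to_rbm_at_zero_history(self, rng):
        W = rng.normal(0, 0.5, (3, 2))
        b, c = rng.normal(0, 1, 3), rng.normal(0, 1, 2)
        crbm = CRBMParams(W, b, c, rng.normal(0, 1, (3, 2)),
                          rng.normal(0, 1, (2, 2)))
        rbm = RBMParams(W, b, c)
        v = (rng.random(3) < 0.5).astype(float)
        h = (rng.random(2) < 0.5).astype(float)
        assert crbm_energy(crbm, v, h, np.zeros(2)) == pytest.approx(
            rbm_energy(rbm, v, h))

    def test_all_ones_toy(self):
        one = np.ones((1, 1))
        crbm = CRBMParams(one, np.ones(1), np.ones(1), one, one)
        assert crbm_energy(crbm, [1.0], [1.0], [1.0]) == pytest.approx(-5.0)

    def test_linear_in_history(self, rng):
        crbm = CRBMParams(rng.normal(0, 1, (2, 2)), rng.normal(0, 1, 2),
                          rng.normal(0, 1, 2), rng.normal(0, 1, (2, 3)),
                          rng.normal(0, 1, (2, 3)))
        v = np.array([1.0, 0.0])
        h = np.array([0.0, 1.0])
        e0 = crbm_energy(crbm, v, h, np.zeros(3))
        h1 = rng.random(3)
        h2 = rng.random(3)
        e1 = crbm_energy(crbm, v, h, h1)
        e2 = crbm_energy(crbm, v, h, h2)
        e12 = crbm_energy(crbm, v, h, h1 + h2)
        assert e12 - e0 == pytest.approx((e1 - e0) + (e2 - e0), abs=1e-10)


class TestCRBMUpdate:
    def _crbm(self, rng, nv=3, nh=2):
        return CRBMParams(rng.normal(0, 0.5, (nv, nh)), rng.normal(0, 0.3, nv),
                          rng.normal(0, 0.3, nh), rng.normal(0, 0.3, (nv, nh)),
                          rng.normal(0, 0.3, (nh, nh)))

    def test_zero_history_matches_plain_cd(self, rng):
        crbm = self._crbm(rng)
        batch = (rng.random((5, 3)) < 0.5).astype(float)
        g = crbm_cd_update(crbm, batch, np.zeros((5, 2)), seed=17)
        plain = cd_update(crbm.as_rbm(), batch, seed=17)
        assert np.allclose(g.V_cond, 0) and np.allclose(g.U_cond, 0)
        assert np.array_equal(g.W, plain.W)
        assert np.array_equal(g.b, plain.b)
        assert np.array_equal(g.c, plain.c)

    def test_scripted_chain_replay(self):
        # 2x2 CRBM with W = 0: the Gibbs chain is deterministic apart from
        # the hidden sample, which does not influence the reconstruction,
        # so every gradient block can be written down in closed form
        b = np.array([0.4, -0.6])
        c = np.array([0.2, 0.1])
        V = np.array([[0.3, -0.1], [0.2, 0.5]])
        U = np.array([[-0.4, 0.6], [0.1, -0.2]])
        crbm = CRBMParams(np.zeros((2, 2)), b, c, V, U)
        v0 = np.array([[1.0, 0.0]])
        hp = np.array([[0.8, 0.3]])
        b_eff = b + V @ hp[0]
        c_eff = c + U @ hp[0]
        v1 = sigmoid(b_eff)            # W = 0: independent of hidden sample
        h_p = sigmoid(c_eff)           # same in both phases
        g = crbm_cd_update(crbm, v0, hp, seed=5)
        assert np.allclose(g.b, v0[0] - v1)
        assert np.allclose(g.c, 0.0, atol=1e-15)
        assert np.allclose(g.V_cond, np.outer(v0[0] - v1, hp[0]))
        assert np.allclose(g.U_cond, 0.0, atol=1e-15)
        assert np.allclose(g.W, np.outer(v0[0], h_p) - np.outer(v1, h_p))

    def test_mean_update_matches_conditional_enumeration(self, rng):
        # averaged over seeds, the (W, b, c) block of CD-1 points along the
        # exact conditional-likelihood gradient at fixed h_prev
        crbm = self._crbm(rng, nv=2, nh=2)
        # biased data: the conditional likelihood gradient is well away
        # from zero, so its direction is meaningful
        batch = (rng.random((8, 2)) < 0.3).astype(float)
        hp = np.tile([0.6, 0.2], (8, 1))
        shifted = RBMParams(crbm.W, crbm.b + crbm.V_cond @ hp[0],
                            crbm.c + crbm.U_cond @ hp[0])
        exact = exact_loglik_grad(shifted, batch)
        acc = [np.zeros_like(crbm.W), np.zeros_like(crbm.b), np.zeros_like(crbm.c)]
        n_seeds = 10000
        for s in range(n_seeds):
            g = crbm_cd_update(crbm, batch, hp, seed=s)
            acc[0] += g.W
            acc[1] += g.b
            acc[2] += g.c
        mean = np.concatenate([a.ravel() / n_seeds for a in acc])
        ref = np.concatenate([exact.W.ravel(), exact.b, exact.c])
        cos = mean @ ref / (np.linalg.norm(mean) * np.linalg.norm(ref))
        assert cos > 0.9


class TestRecurrentPretrain:
    def test_frozen_conditional_reduces_to_plain_stack(self, rng):
        seqs = [rng.random((7, 10)), rng.random((9, 10)), rng.random((5, 10))]
        rp = pretrain_recurrent_stack([10, 6, 5, 4], seqs, epochs=3, seed=42,
                                      freeze_conditional=True)
        dp = pretrain_stack([10, 6, 5, 4], np.concatenate(seqs), epochs=3,
                            seed=42)
        assert np.array_equal(rp.W_in, dp.weights[0])
        assert np.array_equal(rp.b_h, dp.biases[0])
        assert np.all(rp.U_rec == 0)
        for a, b in zip(rp.head.weights, dp.weights[1:]):
            assert np.array_equal(a, b)
        for a, b in zip(rp.head.biases, dp.biases[1:]):
            assert np.array_equal(a, b)

    def test_shapes_match_architecture(self, rng):
        seqs = [rng.random((12, 8))]
        rp = pretrain_recurrent_stack([8, 6, 5, 4], seqs, epochs=1, seed=0)
        assert rp.W_in.shape == (8, 6)
        assert rp.U_rec.shape == (6, 6)
        assert rp.head.layer_sizes == [6, 5, 4]

    def test_layer1_reconstruction_improves(self, rng):
        # structured sequences: a slow binary drift the CRBM can model
        seqs = []
        for _ in range(6):
            base = (rng.random(10) < 0.5).astype(float)
            rows = [np.clip(base + rng.normal(0, 0.1, 10), 0, 1)]
            for _ in range(19):
                base = np.where(rng.random(10) < 0.05, 1 - base, base)
                rows.append(np.clip(base + rng.normal(0, 0.1, 10), 0, 1))
            seqs.append(np.array(rows))
        rp = pretrain_recurrent_stack([10, 8, 4], seqs, epochs=15, seed=3,
                                      lr=0.1)
        hist = rp.layer1_recon_history
        assert hist[-1] < hist[0]

    def test_same_seed_identical(self, rng):
        seqs = [rng.random((6, 5))]
        a = pretrain_recurrent_stack([5, 4, 4], seqs, epochs=2, seed=8)
        b = pretrain_recurrent_stack([5, 4, 4], seqs, epochs=2, seed=8)
        assert all(np.array_equal(x, y) for x, y in zip(a.tensors(), b.tensors()))

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            pretrain_recurrent_stack([5, 4, 4], [], epochs=1, seed=0)
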