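"""Consensus linear decoder: batch fits, consensus, evaluation, contributions."""

import numpy as np
import pytest

from reachpop.decoder import (
    DecoderModel,
    decode,
    evaluate,
    fit_batch,
    fit_consensus,
    heldout_arrays,
    partial_contribution,
    pearson_pooled,
)


def normal_equations(F, K):
    """Independent oracle: W = (F F^T)^-1 F K on full-rank instances."""
    return np.linalg.solve(F @ F.T, F @ K)


def linear_session(rng, n_units=6, n_mov=40, len_mov=30, noise=0.0):
    """Smooth random rates with an exact linear readout K = F^T W_true."""
    T = n_mov * len_mov
    F = rng.standard_normal((n_units, T))
    # temporal smoothing for realism
    k = np.hanning(9)
    k /= k.sum()
    F = np.apply_along_axis(lambda r: np.convolve(r, k, mode="same"), 1, F)
    W_true = rng.standard_normal((n_units, 2))
    K = F.T @ W_true + noise * rng.standard_normal((T, 2))
    windows = [np.arange(i * len_mov, (i + 1) * len_mov) for i in range(n_mov)]
    return F, K, W_true, windows


class TestFitBatch:
    def test_single_unit_identity_readout(self):
        rate = np.sin(np.linspace(0, 6, 100))[None, :]
        K = np.column_stack([rate[0], np.zeros(100)])
        W = fit_batch(rate, K)
        assert np.allclose(W, [[1.0, 0.0]], atol=1e-9)

    def test_recovers_true_weights(self, rng):
        F = rng.standard_normal((3, 50))
        W_true = rng.standard_normal((3, 2))
        W = fit_batch(F, F.T @ W_true)
        assert np.allclose(W, W_true, atol=1e-8)

    def test_zero_data_gives_zero_weights(self):
        W = fit_batch(np.zeros((4, 20)), np.ones((20, 2)))
        assert np.all(W == 0)

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(20):
            n_units = rng.integers(1, 10)
            T = int(rng.integers(n_units + 5, 100))
            F = rng.standard_normal((n_units, T))
            K = rng.standard_normal((T, 2))
            W = fit_batch(F, K)
            W_oracle = normal_equations(F, K)
            denom = max(np.abs(W_oracle).max(), 1e-12)
            assert np.abs(W - W_oracle).max() / denom < 1e-8

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            fit_batch(np.empty((0, 0)), np.empty((0, 2)))


class TestConsensus:
    def test_noiseless_linear_data_decodes_heldout(self, rng):
        F, K, _, windows = linear_session(rng)
        model = fit_consensus(F, K, windows, n_batches=20, batch_size=10,
                              rng=np.random.default_rng(0), n_shuffles=0)
        assert model.performance["r_pooled"] > 0.99

    def test_single_batch_consensus_equals_batch(self, rng):
        F, K, _, windows = linear_session(rng, n_mov=12)
        model = fit_consensus(F, K, windows, n_batches=1, batch_size=5,
                              rng=np.random.default_rng(3), n_shuffles=0)
        assert np.array_equal(model.W_decode, model.batch_decoders[0])

    def test_same_seed_reproduces_model(self, rng):
        F, K, _, windows = linear_session(rng, n_mov=15)
        m1 = fit_consensus(F, K, windows, n_batches=5, batch_size=5,
                           rng=np.random.default_rng(7))
        m2 = fit_consensus(F, K, windows, n_batches=5, batch_size=5,
                           rng=np.random.default_rng(7))
        assert np.array_equal(m1.W_decode, m2.W_decode)
        assert m1.performance == m2.performance

    def test_holdout_disjoint_from_batches(self, rng):
        F, K, _, windows = linear_session(rng, n_mov=20)
        model = fit_consensus(F, K, windows, n_batches=5, batch_size=5,
                              rng=np.random.default_rng(1), n_shuffles=0)
        assert 1 <= model.heldout_ids.size <= 3

    def test_too_few_movements_rejected(self, rng):
        F, K, _, windows = linear_session(rng, n_mov=1)
        with pytest.raises(ValueError):
            fit_consensus(F, K, windows, heldout_frac=0.99)


class TestDecodeEvaluate:
    def test_zero_weights_zero_prediction(self):
        model = DecoderModel(W_decode=np.zeros((3, 2)))
        assert np.all(decode(model, np.ones((3, 10))) == 0)

    def test_linearity_of_decode(self, rng):
        model = DecoderModel(W_decode=rng.standard_normal((4, 2)))
        F1 = rng.standard_normal((4, 25))
        F2 = rng.standard_normal((4, 25))
        lhs = decode(model, F1 + F2)
        rhs = decode(model, F1) + decode(model, F2)
        assert np.allclose(lhs, rhs, atol=1e-9)

    def test_unit_mismatch_rejected(self):
        model = DecoderModel(W_decode=np.zeros((3, 2)))
        with pytest.raises(ValueError, match="unit count"):
            decode(model, np.ones((4, 10)))

    def test_perfect_and_inverted_predictions(self, rng):
        K = rng.standard_normal((50, 2))
        assert pearson_pooled(K, K)["r_pooled"] == pytest.approx(1.0)
        assert pearson_pooled(-K, K)["r_pooled"] == pytest.approx(-1.0)

    def test_constant_prediction_flagged_zero(self):
        K = np.random.default_rng(0).standard_normal((30, 2))
        out = pearson_pooled(np.zeros_like(K), K)
        assert out["r_pooled"] == 0.0 and out["flagged"]

    def test_independent_traces_near_zero_and_shuffle_null(self, rng):
        n = 1000
        model = DecoderModel(W_decode=np.eye(2))
        F = rng.standard_normal((2, n))
        K = rng.standard_normal((n, 2))
        windows = [np.arange(i * 50, (i + 1) * 50) for i in range(20)]
        r_obs, shuffle = evaluate(model, F, K, windows=windows, n_shuffles=50,
                                  rng=np.random.default_rng(5))
        assert abs(r_obs["r_pooled"]) < 0.1
        assert abs(shuffle["mean"]) < 0.1


class TestPartialContribution:
    def _fitted(self, rng):
        F, K, _, windows = linear_session(rng, n_units=6)
        model = fit_consensus(F, K, windows, n_batches=10, batch_size=10,
                              rng=np.random.default_rng(2), n_shuffles=0)
        F_h, K_h, _ = heldout_arrays(F, K, windows, model.heldout_ids)
        return model, F_h, K_h

    def test_full_subset_gives_unit_fraction(self, rng):
        model, F_h, K_h = self._fitted(rng)
        out = partial_contribution(model, np.arange(model.n_units), F_h, K_h)
        assert out["fraction"] == pytest.approx(1.0)

    def test_subset_and_complement_predictions_sum_to_full(self, rng):
        model, F_h, K_h = self._fitted(rng)
        subset = np.array([0, 2, 5])
        comp = np.setdiff1d(np.arange(model.n_units), subset)
        W_s = np.zeros_like(model.W_decode)
        W_s[subset] = model.W_decode[subset]
        W_c = np.zeros_like(model.W_decode)
        W_c[comp] = model.W_decode[comp]
        lhs = decode(DecoderModel(W_decode=W_s), F_h) + decode(DecoderModel(W_decode=W_c), F_h)
        assert np.allclose(lhs, decode(model, F_h), atol=1e-9)

    def test_informative_units_outrank_noise_units(self, rng):
        # units 0-2 drive K; units 3-5 are pure noise
        n_mov, L = 40, 25
        T = n_mov * L
        F = rng.standard_normal((6, T))
        W_true = np.zeros((6, 2))
        W_true[:3] = rng.standard_normal((3, 2))
        K = F.T @ W_true + 0.05 * rng.standard_normal((T, 2))
        windows = [np.arange(i * L, (i + 1) * L) for i in range(n_mov)]
        model = fit_consensus(F, K, windows, n_batches=10, batch_size=15,
                              rng=np.random.default_rng(4), n_shuffles=0)
        F_h, K_h, _ = heldout_arrays(F, K, windows, model.heldout_ids)
        f_sig = partial_contribution(model, [0, 1, 2], F_h, K_h)["fraction"]
        f_noise = partial_contribution(model, [3, 4, 5], F_h, K_h)["fraction"]
        assert f_sig > f_noise

    def test_empty_subset_rejected(self, rng):
        model, F_h, K_h = self._fitted(rng)
        with pytest.raises(ValueError):
            partial_contribution(model, [], F_h, K_h)
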