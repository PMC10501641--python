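"""BlockHMM sampling, exact inference, EM fitting and model selection."""

import itertools

import numpy as np
import pytest

from blockhmm import (
    BlockHMM,
    TransitionParams,
    block_loglik,
    forward_backward,
    most_likely_states,
    normalized_cv_loglik,
    select_num_modes,
)


def brute_force_loglik(model: BlockHMM, Y: np.ndarray) -> float:
    """Exhaustive enumeration over all K^B hidden-state paths."""
    K = len(model.startprob_)
    B = Y.shape[0]
    emit = np.array(
        [[block_loglik(m, Y[b]) for m in model.modes_] for b in range(B)]
    )
    total = -np.inf
    for path in itertools.product(range(K), repeat=B):
        lp = np.log(model.startprob_[path[0]]) + emit[0, path[0]]
        for b in range(1, B):
            lp += np.log(model.transmat_[path[b - 1], path[b]]) + emit[b, path[b]]
        total = np.logaddexp(total, lp)
    return float(total)


def brute_force_posteriors(model: BlockHMM, Y: np.ndarray) -> np.ndarray:
    K = len(model.startprob_)
    B = Y.shape[0]
    emit = np.array(
        [[block_loglik(m, Y[b]) for m in model.modes_] for b in range(B)]
    )
    post = np.zeros((B, K))
    for path in itertools.product(range(K), repeat=B):
        lp = np.log(model.startprob_[path[0]]) + emit[0, path[0]]
        for b in range(1, B):
            lp += np.log(model.transmat_[path[b - 1], path[b]]) + emit[b, path[b]]
        w = np.exp(lp)
        for b, k in enumerate(path):
            post[b, k] += w
    return post / post.sum(axis=1, keepdims=True)


class TestSampling:
    def test_single_mode_states_identical(self):
        model = BlockHMM.from_params([TransitionParams(2, 1, 0.1)], [[1.0]])
        states, Y = model.sample(20, 15, random_state=0)
        assert np.all(states == 0)
        assert Y.shape == (20, 15)

    def test_identity_transmat_freezes_state(self, two_mode_model):
        frozen = BlockHMM.from_params(
            two_mode_model.modes_, np.eye(2), [0.3, 0.7]
        )
        states, _ = frozen.sample(50, 10, random_state=3)
        assert len(np.unique(states)) == 1

    def test_occupancy_matches_stationary_distribution(self, reference_model, reference_sample):
        # stationary vector from an eigen-decomposition oracle
        T = np.asarray(reference_model.transmat_)
        w, v = np.linalg.eig(T.T)
        stat = np.real(v[:, np.argmax(np.real(w))])
        stat = stat / stat.sum()
        states, _ = reference_sample
        occ = np.bincount(states, minlength=3) / len(states)
        # 3 s.e. allowing for autocorrelation of the sticky chain
        se = np.sqrt(stat * (1 - stat) / len(states)) * np.sqrt(40)
        assert np.all(np.abs(occ - stat) < 3 * se)

    def test_invalid_model_rejected(self):
        with pytest.raises(ValueError):
            BlockHMM.from_params([TransitionParams(1, 1, 0.1)], [[0.5]])


class TestForwardBackward:
    def test_single_mode_equals_block_loglik_sum(self, rng):
        params = TransitionParams(2, 1, 0.1)
        model = BlockHMM.from_params([params], [[1.0]])
        Y = rng.integers(0, 2, size=(7, 12))
        ll, post, _ = forward_backward(model, Y)
        expected = sum(block_loglik(params, row) for row in Y)
        assert ll == pytest.approx(expected, abs=1e-8)
        assert np.allclose(post, 1.0)

    @pytest.mark.parametrize("B", [1, 2, 3, 5])
    def test_matches_exhaustive_enumeration(self, two_mode_model, rng, B):
        Y = rng.integers(0, 2, size=(B, 10))
        ll, post, _ = forward_backward(two_mode_model, Y)
        assert ll == pytest.approx(brute_force_loglik(two_mode_model, Y), abs=1e-8)
        assert np.allclose(post, brute_force_posteriors(two_mode_model, Y), atol=1e-8)

    def test_three_modes_against_enumeration(self, reference_model, rng):
        Y = rng.integers(0, 2, size=(4, 8))
        ll, post, _ = forward_backward(reference_model, Y)
        assert ll == pytest.approx(brute_force_loglik(reference_model, Y), abs=1e-8)

    def test_symmetric_model_gives_uniform_posteriors(self, rng):
        mode = TransitionParams(2, 1, 0.2)
        model = BlockHMM.from_params(
            [mode, mode], np.full((2, 2), 0.5), [0.5, 0.5]
        )
        Y = rng.integers(0, 2, size=(6, 10))
        _, post, _ = forward_backward(model, Y)
        assert np.allclose(post, 0.5)

    def test_posterior_rows_sum_to_one(self, two_mode_model, rng):
        Y = rng.integers(0, 2, size=(40, 15))
        _, post, _ = forward_backward(two_mode_model, Y)
        assert np.allclose(post.sum(axis=1), 1.0, atol=1e-10)


class TestFitEM:
    def test_single_mode_matches_direct_mle(self, rng):
        # direct constrained single-sigmoid MLE as the independent oracle
        from scipy.optimize import minimize
        from scipy.special import expit

        true = TransitionParams(3, 0.8, 0.1)
        model = BlockHMM.from_params([true], [[1.0]])
        _, Y = model.sample(400, 20, random_state=7)

        t = np.arange(1, 21)
        n1, n0 = Y.sum(0), (1.0 - Y).sum(0)

        def nll(theta):
            s, a, e = theta
            p = np.clip(e + (1 - 2 * e) * expit(a * (t - s)), 1e-12, 1 - 1e-12)
            return -(n1 @ np.log(p) + n0 @ np.log1p(-p))

        oracle = min(
            (
                minimize(nll, x0, method="Nelder-Mead")
                for x0 in ([3, 1, 0.1], [1, 0.5, 0.2])
            ),
            key=lambda r: r.fun,
        )
        fit = BlockHMM(1, n_restarts=1, cv_fraction=0.0, random_state=0).fit(Y)
        assert fit.offsets_[0] == pytest.approx(oracle.x[0], abs=1e-2)
        assert fit.slopes_[0] == pytest.approx(oracle.x[1], abs=1e-2)
        assert fit.lapses_[0] == pytest.approx(oracle.x[2], abs=1e-3)

    def test_loglik_trace_monotone(self, two_mode_model):
        _, Y = two_mode_model.sample(150, 15, random_state=5)
        fit = BlockHMM(2, n_restarts=2, random_state=0).fit(Y)
        assert np.all(np.diff(fit.loglik_trace_) > -1e-6)

    def test_transmat_rows_stochastic(self, two_mode_model):
        _, Y = two_mode_model.sample(120, 15, random_state=6)
        fit = BlockHMM(2, n_restarts=1, random_state=0).fit(Y)
        assert np.allclose(fit.transmat_.sum(axis=1), 1.0, atol=1e-10)
        assert np.all(fit.transmat_ >= 0)
        assert np.isclose(fit.startprob_.sum(), 1.0)

    def test_box_constraints_respected(self, two_mode_model):
        _, Y = two_mode_model.sample(100, 15, random_state=8)
        fit = BlockHMM(2, n_restarts=1, random_state=0).fit(Y)
        assert np.all(fit.offsets_ >= 0.01)
        assert np.all(fit.slopes_ >= 0.01)
        assert np.all((fit.lapses_ >= 0.01) & (fit.lapses_ <= 0.5))

    def test_more_modes_than_blocks_rejected(self, rng):
        Y = rng.integers(0, 2, size=(2, 10))
        with pytest.raises(ValueError):
            BlockHMM(3).fit(Y)


class TestDecoding:
    def test_marginal_map_argmax(self, two_mode_model, rng):
        _, Y = two_mode_model.sample(30, 15, random_state=2)
        fit = BlockHMM(2, n_restarts=1, random_state=0).fit(Y)
        assert np.array_equal(most_likely_states(fit), np.argmax(fit.posteriors_, axis=1))

    def test_tie_breaks_to_lower_index(self, rng):
        # symmetric model: posteriors are exactly 0.5 everywhere
        mode = TransitionParams(2, 1, 0.2)
        model = BlockHMM.from_params([mode, mode], np.full((2, 2), 0.5))
        Y = rng.integers(0, 2, size=(5, 10))
        assert np.all(model.predict(Y) == 0)


class TestModelSelection:
    def test_cv_result_normalization_identity(self, two_mode_model):
        _, Y = two_mode_model.sample(200, 15, random_state=9)
        res = normalized_cv_loglik(Y, 2, random_state=0)
        assert res.L_norm == pytest.approx(
            (res.L_test - res.L_0) / (res.n_test * np.log(2))
        )

    def test_single_mode_data_selects_one(self):
        model = BlockHMM.from_params([TransitionParams(2, 1.2, 0.1)], [[1.0]])
        _, Y = model.sample(300, 15, random_state=4)
        assert select_num_modes(Y, range(1, 4), random_state=0) == 1

    def test_singleton_range(self, two_mode_model):
        _, Y = two_mode_model.sample(100, 15, random_state=3)
        assert select_num_modes(Y, [2], random_state=0) == 2

    def test_two_mode_data_beats_one_mode(self, two_mode_model):
        _, Y = two_mode_model.sample(400, 15, random_state=11)
        r1 = normalized_cv_loglik(Y, 1, random_state=0)
        r2 = normalized_cv_loglik(Y, 2, random_state=0)
        assert r2.L_norm > r1.L_norm


class TestSerialization:
    def test_json_round_trip(self, two_mode_model):
        restored = BlockHMM.from_json(two_mode_model.to_json())
        assert np.allclose(restored.transmat_, two_mode_model.transmat_)
        assert np.allclose(restored.offsets_, two_mode_model.offsets_)
        assert np.allclose(restored.startprob_, two_mode_model.startprob_)
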