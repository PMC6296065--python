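import numpy as np
import pytest

from conftest import load_sim, small_design, tiny_state
from pasnet.network import forward
from pasnet.training import (
    TrainConfig,
    fit,
    mfe_cost,
    per_class_gradients,
    select_subnetwork,
)


def total_loss(X, y, state, lam, dropout=None, rates=(0.0, 0.0)):
    """Independent scalar loss used by the finite-difference oracle."""
    post = forward(X, state, dropout, rates).posterior
    return mfe_cost(post, y, state, lam).total


def numerical_gradients(X, y, state, lam, h=1e-6):
    """Central finite differences over every active parameter."""
    gW = [np.zeros_like(W) for W in state.weights]
    gb = [np.zeros_like(b) for b in state.biases]
    for ell, W in enumerate(state.weights):
        for idx in np.ndindex(W.shape):
            if state.masks[ell][idx] == 0:
                continue
            orig = W[idx]
            W[idx] = orig + h
            up = total_loss(X, y, state, lam)
            W[idx] = orig - h
            down = total_loss(X, y, state, lam)
            W[idx] = orig
            gW[ell][idx] = (up - down) / (2 * h)
    for ell, b in enumerate(state.biases):
        for i in range(len(b)):
            orig = b[i]
            b[i] = orig + h
            up = total_loss(X, y, state, lam)
            b[i] = orig - h
            down = total_loss(X, y, state, lam)
            b[i] = orig
            gb[ell][i] = (up - down) / (2 * h)
    return gW, gb


class TestMFECost:
    def test_perfect_posteriors_cost_zero(self):
        post = np.array([[1.0, 0.0], [0.0, 1.0]])
        cost = mfe_cost(post, np.array([0, 1]))
        assert cost.total == pytest.approx(0.0, abs=1e-9)

    def test_hand_evaluated_per_class_means(self):
        # class 0: two samples at true-class posterior 0.5; class 1: one at 1.0
        post = np.array([[0.5, 0.5], [0.5, 0.5], [0.0, 1.0]])
        y = np.array([0, 0, 1])
        cost = mfe_cost(post, y)
        assert cost.per_class_costs[0] == pytest.approx(np.log(2))
        assert cost.per_class_costs[1] == pytest.approx(0.0, abs=1e-9)
        assert cost.total == pytest.approx(np.log(2))
        # pooled mean CE would differ, demonstrating the class normalization
        pooled = (2 * np.log(2)) / 3
        assert cost.total != pytest.approx(pooled)

    def test_equal_class_sizes_identity_with_pooled_mean(self, rng):
        post = rng.dirichlet([1, 1], size=40)
        y = np.array([0, 1] * 20)
        cost = mfe_cost(post, y)
        ce = -np.log(post[np.arange(40), y])
        assert cost.per_class_costs.sum() == pytest.approx(2 * ce.mean())

    def test_zero_posterior_clamped_never_nan(self):
        post = np.array([[0.0, 1.0]])
        cost = mfe_cost(post, np.array([0]))
        assert np.isfinite(cost.total)


class TestGradients:
    @pytest.mark.parametrize("lam", [0.0, 3e-4])
    def test_matches_central_finite_differences(self, lam):
        rng = np.random.default_rng(123)
        for trial in range(10):
            state, _ = tiny_state(seed=trial, m=4, n=2, h=2, K=2)
            for W in state.weights:
                W += rng.normal(size=W.shape) * 0.5
            state.weights[0] *= state.masks[0]
            X = rng.normal(size=(6, 4))
            y = rng.integers(0, 2, size=6)
            if len(np.unique(y)) < 2:
                y[0] = 1 - y[0]
            gW, gb = per_class_gradients(X, y, state, lam=lam, include_l2=True)
            nW, nb = numerical_gradients(X, y, state, lam)
            for a, n in zip(gW + gb, nW + nb):
                denom = max(np.abs(n).max(), 1e-8)
                assert np.abs(a - n).max() / denom < 1e-5

    def test_masked_positions_get_exact_zero_gradient(self, rng):
        state, _ = tiny_state(seed=2, m=5, n=3, h=3)
        state.masks[1][0, :] = 0.0
        X = rng.normal(size=(8, 5))
        y = np.array([0, 1] * 4)
        gW, _ = per_class_gradients(X, y, state, lam=1e-3)
        assert (gW[0][state.masks[0] == 0] == 0).all()
        assert (gW[1][state.masks[1] == 0] == 0).all()

    def test_duplicating_a_class_leaves_gradient_unchanged(self, rng):
        state, _ = tiny_state(seed=3, m=4, n=2, h=2)
        X = rng.normal(size=(6, 4))
        y = np.array([0, 0, 0, 0, 1, 1])
        g1W, g1b = per_class_gradients(X, y, state)
        X2 = np.vstack([X, X[y == 1]])
        y2 = np.concatenate([y, [1, 1]])
        g2W, g2b = per_class_gradients(X2, y2, state)
        for a, b in zip(g1W + g1b, g2W + g2b):
            np.testing.assert_allclose(a, b, atol=1e-12)

    def test_dropped_nodes_get_zero_gradient(self, rng):
        state, _ = tiny_state(seed=4, m=4, n=3, h=4)
        X = rng.normal(size=(6, 4))
        y = np.array([0, 1, 0, 1, 0, 1])
        keep_p = np.array([1.0, 0.0, 1.0])
        keep_h = np.array([0.0, 1.0, 1.0, 1.0])
        gW, gb = per_class_gradients(
            X, y, state, (keep_p, keep_h), (0.5, 0.25), lam=0.0
        )
        assert (gW[0][1, :] == 0).all() and gb[0][1] == 0
        assert (gW[1][0, :] == 0).all() and gb[1][0] == 0
        assert (gW[1][:, 1] == 0).all()
        assert (gW[2][:, 0] == 0).all()


class TestSelectSubnetwork:
    def test_rate_zero_keeps_everything(self, rng):
        kp, kh = select_subnetwork(10, 8, (0.0, 0.0), rng)
        assert kp.all() and kh.all()

    def test_binomial_keep_count(self):
        rng = np.random.default_rng(100)
        kept = [select_subnetwork(574, 5, (0.8, 0.0), rng)[0].sum()
                for _ in range(1000)]
        mean = np.mean(kept)
        expect = 574 * 0.2
        sigma = np.sqrt(574 * 0.2 * 0.8)
        assert abs(mean - expect) < 3 * sigma / np.sqrt(1000)

    def test_never_returns_all_dropped(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            kp, kh = select_subnetwork(3, 2, (0.9, 0.9), rng)
            assert kp.sum() >= 1 and kh.sum() >= 1

    def test_seeded_rng_reproduces_masks(self):
        a = select_subnetwork(20, 10, (0.5, 0.5), np.random.default_rng(7))
        b = select_subnetwork(20, 10, (0.5, 0.5), np.random.default_rng(7))
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])


class TestFit:
    def test_zero_epochs_returns_initial_state(self):
        X, y, A, _ = load_sim(small_design())
        cfg = TrainConfig(max_epochs=0, hidden_size=4, seed=1)
        state, log = fit(X, y, A, cfg)
        from pasnet.network import initialize

        ref = initialize(A, 4, 2, np.random.default_rng(1))
        for Wa, Wb in zip(state.weights, ref.weights):
            np.testing.assert_array_equal(Wa, Wb)
        assert log.empty

    def test_loss_decreases_on_separable_data(self):
        X, y, A, _ = load_sim(small_design(effect_size=2.0))
        cfg = TrainConfig(max_epochs=120, patience=10**9, hidden_size=8,
                          learning_rate=1e-2, seed=3)
        _, log = fit(X, y, A, cfg)
        assert log["loss"].iloc[-1] < log["loss"].iloc[0]

    def test_same_seed_gives_identical_final_weights(self):
        X, y, A, _ = load_sim(small_design())
        cfg = TrainConfig(max_epochs=25, hidden_size=6, learning_rate=1e-2, seed=9)
        s1, _ = fit(X, y, A, cfg)
        s2, _ = fit(X, y, A, cfg)
        for Wa, Wb in zip(s1.weights, s2.weights):
            np.testing.assert_array_equal(Wa, Wb)
        for Ma, Mb in zip(s1.masks, s2.masks):
            np.testing.assert_array_equal(Ma, Mb)

    def test_gene_pathway_mask_invariant_through_training(self, trained_small):
        state, A = trained_small["state"], trained_small["A"]
        np.testing.assert_array_equal(state.masks[0], A.matrix.astype(float))

    def test_single_class_rejected(self, toy_adjacency):
        X = np.zeros((4, toy_adjacency.n_genes))
        with pytest.raises(ValueError, match="two classes"):
            fit(X, np.zeros(4, dtype=int), toy_adjacency, TrainConfig(max_epochs=1))

    def test_sgd_decay_optimizer_decays_and_trains(self):
        X, y, A, _ = load_sim(small_design())
        cfg = TrainConfig(max_epochs=40, patience=10**9, hidden_size=6,
                          learning_rate=1e-2, seed=5, optimizer="sgd_decay")
        _, log = fit(X, y, A, cfg)
        assert np.isfinite(log["loss"]).all()
        assert log["loss"].iloc[-1] < log["loss"].iloc[0]
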