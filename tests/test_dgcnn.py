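import numpy as np
import pytest

from neurograph.dgcnn import (
    DGCNNConfig,
    bce_loss,
    forward,
    graph_conv_layer,
    init_params,
    predict,
    prepare_inputs,
    sort_pooling,
    train_model,
)
from neurograph.dgcnn import model as M
from neurograph.fc_network import MDD, NC, BinaryAdjacency, BrainGraph
from neurograph.synthetic_data import SyntheticCohortSpec, generate_cohort
from neurograph.cli_io import build_graphs

from conftest import random_graph


class TestGraphConvLayer:
    def test_isolated_node_is_tanh_xw(self):
        adj = np.zeros((1, 1), dtype=int)
        x = np.array([[0.7]])
        w = np.array([[1.3]])
        out = graph_conv_layer(adj, x, w)
        assert out[0, 0] == pytest.approx(np.tanh(0.7 * 1.3))

    def test_zero_weights_give_zero_output(self, rng):
        g = random_graph(rng, n=6, d=4)
        out = graph_conv_layer(g.adjacency, g.node_features, np.zeros((4, 3)))
        assert np.all(out == 0.0)

    def test_path_graph_matches_dense_oracle(self):
        # 3-node path 0-1-2, hand-set features and weights
        a = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]])
        x = np.array([[1.0, 0.0], [0.0, 2.0], [-1.0, 1.0]])
        w = np.array([[0.5, -0.2, 0.1], [0.3, 0.4, -0.6]])
        a_tilde = a + np.eye(3)
        d_inv = np.diag(1.0 / a_tilde.sum(axis=1))
        expected = np.tanh(d_inv @ a_tilde @ x @ w)
        out = graph_conv_layer(a, x, w)
        assert np.allclose(out, expected, atol=1e-12)

    def test_output_range_open_interval(self, rng):
        g = random_graph(rng, n=8, d=8)
        out = graph_conv_layer(g.adjacency, g.node_features, rng.standard_normal((8, 5)))
        assert out.min() > -1.0 and out.max() < 1.0

    def test_shape_mismatch_errors(self, rng):
        g = random_graph(rng, n=5, d=4)
        with pytest.raises(ValueError):
            graph_conv_layer(g.adjacency, g.node_features, np.zeros((3, 2)))


def lexsort_oracle(z, k):
    """Brute-force: full right-to-left lexicographic sort of row tuples."""
    keyed = sorted(
        range(z.shape[0]),
        key=lambda i: (tuple(-z[i, c] for c in reversed(range(z.shape[1]))), i),
    )
    out = np.zeros((k, z.shape[1]))
    m = min(k, z.shape[0])
    out[:m] = z[keyed[:m]]
    return out


class TestSortPooling:
    def test_pads_with_zero_rows(self):
        z = np.array([[1.0, 0.5], [2.0, 0.9]])
        out = sort_pooling(z, k=3)
        assert np.allclose(out[0], [2.0, 0.9])
        assert np.allclose(out[1], [1.0, 0.5])
        assert np.allclose(out[2], [0.0, 0.0])

    def test_k_one_keeps_max_last_channel_row(self, rng):
        z = rng.standard_normal((7, 4))
        out = sort_pooling(z, k=1)
        assert out[0, 3] == pytest.approx(z[:, 3].max())

    def test_ties_broken_by_second_to_last_channel(self):
        z = np.array([[0.0, 1.0, 0.5], [9.0, 2.0, 0.5], [1.0, 2.0, 0.5]])
        out = sort_pooling(z, k=3)
        # all tie on last channel; middle channel decides, then first channel
        assert np.allclose(out[0], [9.0, 2.0, 0.5])
        assert np.allclose(out[1], [1.0, 2.0, 0.5])
        assert np.allclose(out[2], [0.0, 1.0, 0.5])

    def test_matches_full_sort_oracle_with_ties(self):
        for seed in range(50):
            rng = np.random.default_rng(seed)
            # quantized values force frequent ties in every channel
            z = rng.integers(-2, 3, size=(6, 4)).astype(float) / 2.0
            for k in (1, 4, 6, 9):
                assert np.array_equal(sort_pooling(z, k), lexsort_oracle(z, k)), (seed, k)

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            sort_pooling(np.zeros((0, 3)), 2)
        with pytest.raises(ValueError):
            sort_pooling(np.zeros((3, 3)), 0)


class TestForward:
    @pytest.fixture
    def setup(self, rng, tiny_config):
        g = random_graph(rng, n=10)
        params = init_params(10, tiny_config, rng, k=10)
        return g, params, tiny_config

    def test_probabilities_sum_to_one(self, setup):
        g, params, cfg = setup
        pred = forward(g, params, cfg, mode="eval")
        assert pred.p_nc + pred.p_mdd == pytest.approx(1.0, abs=1e-9)

    def test_eval_mode_deterministic(self, setup):
        g, params, cfg = setup
        p1 = forward(g, params, cfg, mode="eval")
        p2 = forward(g, params, cfg, mode="eval")
        assert p1.p_mdd == p2.p_mdd and p1.p_nc == p2.p_nc

    def test_permutation_invariance(self, rng, tiny_config):
        for trial in range(5):
            g = random_graph(rng, n=10)
            params = init_params(10, tiny_config, rng, k=10)
            base = forward(g, params, tiny_config, mode="eval")
            perm = rng.permutation(10)
            g_perm = BrainGraph(
                adjacency=BinaryAdjacency(
                    entries=g.adjacency.entries[np.ix_(perm, perm)], threshold=0.3
                ),
                node_features=g.node_features[perm],
                label=g.label,
            )
            permuted = forward(g_perm, params, tiny_config, mode="eval")
            assert permuted.p_mdd == pytest.approx(base.p_mdd, abs=1e-6), trial

    def test_invalid_mode(self, setup):
        g, params, cfg = setup
        with pytest.raises(ValueError, match="mode"):
            forward(g, params, cfg, mode="test")

    def test_train_mode_needs_rng_when_dropout_on(self, rng):
        cfg = DGCNNConfig(
            conv_channels=(2,), conv1_filters=2, conv2_filters=2, dense_width=4, dropout_rate=0.5
        )
        g = random_graph(rng, n=12)
        params = init_params(12, cfg, rng, k=12)
        with pytest.raises(ValueError, match="rng"):
            forward(g, params, cfg, mode="train")


class TestDropout:
    def test_train_expectation_matches_eval(self, rng):
        """Inverted dropout: averaged stochastic passes converge to eval output."""
        cfg = DGCNNConfig(
            conv_channels=(2, 2),
            conv1_filters=2,
            conv2_filters=2,
            dense_width=6,
            dropout_rate=0.5,
        )
        g = random_graph(rng, n=10)
        params = init_params(10, cfg, rng, k=10)
        # shrink the final layer so the softmax is near-linear over the dropout noise
        params["dense2_w"] *= 0.3
        s, x, _ = prepare_inputs([g])
        eval_probs, _ = M.forward_batch(s, x, params, cfg, 10, train=False)
        acc = np.zeros(2)
        n_passes = 2000
        for _ in range(n_passes):
            p, _ = M.forward_batch(s, x, params, cfg, 10, train=True, rng=rng)
            acc += p[0]
        assert np.abs(acc / n_passes - eval_probs[0]).max() < 0.05


class TestBCELoss:
    def test_perfect_prediction_near_zero(self):
        assert bce_loss(np.array([1.0, 0.0]), np.array([1, 0])) < 1e-5

    def test_uniform_prediction_is_ln2(self):
        assert bce_loss(np.full(4, 0.5), np.array([1, 0, 1, 0])) == pytest.approx(np.log(2))

    def test_hand_computed_batch(self):
        loss = bce_loss(np.array([0.9, 0.2]), np.array([1, 0]))
        assert loss == pytest.approx((-np.log(0.9) - np.log(0.8)) / 2, abs=1e-9)
        assert loss == pytest.approx(0.16425, abs=1e-4)

    def test_empty_batch_errors(self):
        with pytest.raises(ValueError, match="nonempty"):
            bce_loss(np.array([]), np.array([]))

    def test_nonnegative(self, rng):
        p = rng.random(20)
        y = rng.integers(0, 2, 20)
        assert bce_loss(p, y) >= 0.0


class TestGradientCheck:
    def test_analytic_matches_finite_differences(self, rng, tiny_config):
        graphs = [random_graph(rng, n=10, label=MDD), random_graph(rng, n=10, label=NC)]
        s, x, y = prepare_inputs(graphs)
        params = init_params(10, tiny_config, rng, k=10)

        def loss_at():
            probs, _ = M.forward_batch(s, x, params, tiny_config, 10, train=False)
            return M.bce_loss_grad_logits(probs, y)[0]

        probs, cache = M.forward_batch(s, x, params, tiny_config, 10, train=False)
        _, d_logits = M.bce_loss_grad_logits(probs, y)
        grads = M.backward_batch(d_logits, cache, params, tiny_config)

        h = 1e-6
        for name, w in params.items():
            it = np.nditer(w, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                orig = w[idx]
                w[idx] = orig + h
                lp = loss_at()
                w[idx] = orig - h
                lm = loss_at()
                w[idx] = orig
                fd = (lp - lm) / (2 * h)
                analytic = grads[name][idx]
                denom = max(1e-6, abs(fd), abs(analytic))
                assert abs(fd - analytic) / denom < 1e-4, (name, idx, fd, analytic)


@pytest.fixture(scope="module")
def separable_graphs():
    spec = SyntheticCohortSpec(
        n_per_group=100, n_rois=12, T=150, n_blocks=3, effect_delta=0.4, site_count=2, seed=11
    )
    return build_graphs(generate_cohort(spec), 0.3)


class TestTraining:
    def test_identical_seeds_give_bit_identical_histories(self, random_graphs, tiny_config):
        train, val = random_graphs[:12], random_graphs[12:]
        p1, h1 = train_model(train, val, tiny_config)
        p2, h2 = train_model(train, val, tiny_config)
        assert h1.train_loss == h2.train_loss
        assert h1.val_loss == h2.val_loss
        assert h1.train_acc == h2.train_acc
        for key in p1:
            assert np.array_equal(p1[key], p2[key]), key

    def test_single_class_training_set_errors(self, rng, tiny_config):
        graphs = [random_graph(rng, n=10, label=MDD) for _ in range(6)]
        with pytest.raises(ValueError, match="single class"):
            train_model(graphs, None, tiny_config)

    def test_empty_training_set_errors(self, tiny_config):
        with pytest.raises(ValueError, match="empty"):
            train_model([], None, tiny_config)

    def test_learns_large_planted_effect(self, separable_graphs):
        cfg = DGCNNConfig(epochs=20, batch_size=50, seed=0)
        params, history = train_model(separable_graphs, None, cfg)
        assert history.train_acc[-1] >= 0.9

    def test_loss_decreases_on_separable_cohort(self, separable_graphs):
        cfg = DGCNNConfig(epochs=10, batch_size=50, seed=1)
        _, history = train_model(separable_graphs, None, cfg)
        assert history.train_loss[-1] < history.train_loss[0]

    def test_null_effect_stays_near_chance(self):
        spec = SyntheticCohortSpec(
            n_per_group=40, n_rois=12, T=100, n_blocks=3, effect_delta=0.0, site_count=2, seed=5
        )
        graphs = build_graphs(generate_cohort(spec), 0.3)
        cfg = DGCNNConfig(epochs=10, batch_size=40, seed=0)
        train, val = graphs[::2], graphs[1::2]
        _, history = train_model(train, val, cfg)
        # 40 validation subjects: 3-sigma binomial noise around 0.5 is ~0.24
        assert abs(history.val_acc[-1] - 0.5) <= 0.25

    def test_history_one_record_per_epoch(self, random_graphs, tiny_config):
        _, history = train_model(random_graphs[:12], random_graphs[12:], tiny_config)
        assert history.n_epochs == tiny_config.epochs
        assert all(loss >= 0 for loss in history.train_loss)


class TestPredict:
    def test_empty_list(self, tiny_config, rng):
        params = init_params(10, tiny_config, rng, k=10)
        assert predict(params, tiny_config, []) == []

    def test_matches_per_graph_forward(self, random_graphs, tiny_config, rng):
        params = init_params(10, tiny_config, rng, k=10)
        batch_preds = predict(params, tiny_config, random_graphs)
        for g, pred in zip(random_graphs, batch_preds):
            single = forward(g, params, tiny_config, mode="eval")
            assert pred.p_mdd == pytest.approx(single.p_mdd, abs=1e-12)

    def test_deterministic_across_calls(self, random_graphs, tiny_config, rng):
        params = init_params(10, tiny_config, rng, k=10)
        a = predict(params, tiny_config, random_graphs)
        b = predict(params, tiny_config, random_graphs)
        assert [p.p_mdd for p in a] == [p.p_mdd for p in b]

    def test_prediction_label_is_argmax(self):
        from neurograph.dgcnn.model import Prediction

        assert Prediction(p_nc=0.3, p_mdd=0.7).label == MDD
        assert Prediction(p_nc=0.8, p_mdd=0.2).label == NC
        with pytest.raises(ValueError):
            Prediction(p_nc=0.5, p_mdd=0.6)
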