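import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression

from patchseg.model import (
    NetworkSpec,
    TrainConfig,
    TrainingDivergedError,
    build_network,
    early_stop_epoch,
    shape_trace,
    split_discovery,
    train,
)
from patchseg.model.network import IncompatiblePatchEdgeError
from patchseg.sampling import PatchSet


def make_patchset(n, M=5, n_classes=2, separation=0.0, seed=0):
    rng = np.random.default_rng(seed)
    labels = np.arange(n) % n_classes
    patches = rng.standard_normal((n, M, M, 3)).astype(np.float32)
    patches += separation * labels[:, None, None, None]
    return PatchSet(
        patches=patches,
        labels=labels.astype(np.uint8),
        coords=np.zeros((n, 3), dtype=int),
        strata=labels.astype(np.uint8),
        subject_ids=np.array(["s"] * n),
    )


class TestNetworkSpec:
    def test_default_filter_total_is_360(self):
        spec = NetworkSpec()
        assert spec.total_filters == 360
        model = build_network(spec, 21)
        assert model.total_filters == 360

    def test_nine_layers(self):
        model = build_network(NetworkSpec(), 21)
        assert model.n_layers == 9

    def test_shape_trace_for_edge_21(self):
        # full padding: out = in + k - 1; pooling: floor(in / 2)
        trace = shape_trace(NetworkSpec(), 21)
        assert trace == [21, 25, 29, 14, 16, 8, 10, 5]
        model = build_network(NetworkSpec(), 21)
        dense = [l for l in model.layers if hasattr(l, "n_in")][0]
        assert dense.n_in == 192 * 5 * 5

    def test_incompatible_edge_names_layer(self):
        with pytest.raises(IncompatiblePatchEdgeError, match="layer"):
            build_network(NetworkSpec(padding="same", conv_kernels=(5, 5, 3, 3)), 3)

    def test_softmax_output_normalized(self, rng, tiny_spec):
        model = build_network(tiny_spec, 9, seed=0)
        tiles = rng.standard_normal((7, 9, 9, 3)).astype(np.float32)
        probs = model.predict_proba(tiles)
        assert probs.shape == (7, 2)
        assert (probs >= 0).all()
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_forward_deterministic_without_dropout(self, rng, tiny_spec):
        model = build_network(tiny_spec, 9, seed=3)
        tiles = rng.standard_normal((4, 9, 9, 3)).astype(np.float32)
        np.testing.assert_array_equal(
            model.predict_proba(tiles), model.predict_proba(tiles)
        )


class TestGradients:
    def test_backprop_matches_finite_differences(self, rng):
        from patchseg.model.layers import softmax_cross_entropy

        spec = NetworkSpec(
            conv_filters=(2, 4, 8, 16), conv_kernels=(5, 5, 3, 3), fc_width=8,
            dropout_fc=0.0, dropout_pool=0.0,
        )
        model = build_network(spec, 5, seed=0)
        for layer in model.layers:  # float64 for an accurate finite-difference probe
            for attr in ("W", "b", "gW", "gb"):
                if hasattr(layer, attr):
                    setattr(layer, attr, getattr(layer, attr).astype(np.float64))
        x = rng.standard_normal((3, 5, 5, 3))
        y = np.array([0, 1, 0])

        def forward(train):
            a = x.copy()
            for layer in model.layers:
                a = layer.forward(a, train=train)
            return a

        _, _, dlogits = softmax_cross_entropy(forward(True), y)
        d = dlogits.astype(np.float64)
        for layer in reversed(model.layers):
            d = layer.backward(d)
        for p, g in zip(model.params(), model.grads()):
            flat = p.ravel()
            for i in rng.choice(flat.size, size=min(4, flat.size), replace=False):
                eps, orig = 1e-5, flat[i]
                flat[i] = orig + eps
                lp, _, _ = softmax_cross_entropy(forward(False), y)
                flat[i] = orig - eps
                lm, _, _ = softmax_cross_entropy(forward(False), y)
                flat[i] = orig
                numeric = (lp - lm) / (2 * eps)
                analytic = g.ravel()[i]
                assert abs(numeric - analytic) <= 1e-4 * max(
                    1.0, abs(numeric) + abs(analytic)
                )


class TestSplitDiscovery:
    def test_700k_patch_accounting(self):
        ps = make_patchset(700_000, M=1)
        train_ps, test_ps = split_discovery(ps, train_fraction=0.8, seed=0)
        assert len(train_ps) == 560_000
        assert len(test_ps) == 140_000

    def test_small_exact_split(self):
        ps = make_patchset(10, M=1)
        train_ps, test_ps = split_discovery(ps, train_fraction=0.8, seed=1)
        assert len(train_ps) == 8
        assert len(test_ps) == 2

    def test_disjoint_exhaustive_balanced(self):
        ps = make_patchset(1000, M=1)
        train_ps, test_ps = split_discovery(ps, train_fraction=0.8, seed=2)
        # use coords slot to track identity
        ps.coords[:, 0] = np.arange(1000)
        all_idx = np.concatenate([train_ps.coords[:, 0], test_ps.coords[:, 0]])
        assert len(all_idx) == 1000
        for split in (train_ps, test_ps):
            balance = split.labels.mean()
            assert abs(balance - 0.5) < 0.01

    def test_determinism(self):
        ps = make_patchset(64, M=1)
        a1, b1 = split_discovery(ps, 0.8, seed=7)
        a2, b2 = split_discovery(ps, 0.8, seed=7)
        np.testing.assert_array_equal(a1.patches, a2.patches)
        np.testing.assert_array_equal(b1.patches, b2.patches)


class TestEarlyStopping:
    def test_spec_cost_sequence(self):
        costs = [1.0, 0.9, 0.8999, 0.8995, 0.8991, 0.8988, 0.8985]
        # improvements: inf, 0.1, then 1e-4, 4e-4, 4e-4, 3e-4, 3e-4 -> 5 in a row
        assert early_stop_epoch(costs, patience=5, tol=1e-3) == 7

    def test_no_trigger(self):
        costs = [1.0, 0.8, 0.6, 0.4, 0.2]
        assert early_stop_epoch(costs, patience=5, tol=1e-3) is None

    def test_infinite_tol_stops_after_patience(self):
        costs = [1.0, 0.5, 0.25, 0.1, 0.05, 0.01]
        assert early_stop_epoch(costs, patience=5, tol=np.inf) == 5

    def test_reset_on_improvement(self):
        costs = [1.0, 0.9999, 0.9998, 0.5, 0.4999, 0.4998, 0.4997, 0.4996, 0.4995]
        assert early_stop_epoch(costs, patience=5, tol=1e-3) == 9

    def test_pure_function_of_sequence(self):
        costs = (1.0, 0.9999, 0.9998, 0.9997, 0.9996, 0.9995)
        assert early_stop_epoch(list(costs), 5, 1e-3) == early_stop_epoch(costs, 5, 1e-3) == 6


class TestTrain:
    def test_separable_toy_problem(self, tiny_spec, fast_train_config):
        # two well-separated intensity clusters; logistic-regression oracle
        train_ps = make_patchset(400, M=5, separation=2.0, seed=1)
        test_ps = make_patchset(100, M=5, separation=2.0, seed=2)
        flat = train_ps.patches.reshape(len(train_ps), -1)
        oracle = LogisticRegression(max_iter=2000).fit(flat, train_ps.labels)
        assert oracle.score(flat, train_ps.labels) >= 0.99

        model = build_network(tiny_spec, 5, seed=0)
        cfg = TrainConfig(
            lr=1.0, batch_size=64, max_epochs=15, seed=0, improvement_tol=1e-4
        )
        model, history = train(model, train_ps, test_ps, cfg)
        assert history.train_accuracy[-1] >= 0.95

    def test_loss_decreases_on_toy_problem(self, tiny_spec):
        train_ps = make_patchset(256, M=5, separation=2.0, seed=3)
        test_ps = make_patchset(64, M=5, separation=2.0, seed=4)
        model = build_network(tiny_spec, 5, seed=1)
        cfg = TrainConfig(lr=1.0, batch_size=64, max_epochs=4, seed=1)
        _, history = train(model, train_ps, test_ps, cfg)
        assert history.train_cost[-1] < history.train_cost[0]

    def test_history_complete_through_stop(self, tiny_spec):
        train_ps = make_patchset(128, M=5, separation=3.0, seed=5)
        test_ps = make_patchset(64, M=5, separation=3.0, seed=6)
        model = build_network(tiny_spec, 5, seed=2)
        cfg = TrainConfig(lr=1.0, batch_size=64, max_epochs=3,
                          improvement_tol=np.inf, seed=2)
        _, history = train(model, train_ps, test_ps, cfg)
        assert history.stopped_epoch == len(history.test_cost)
        assert history.stop_reason in ("patience", "max_epochs")
        assert all(c >= 0 for c in history.train_cost)
        assert all(0 <= a <= 1 for a in history.test_accuracy)

    def test_single_class_set_rejected(self, tiny_spec, fast_train_config):
        ps = make_patchset(32, M=5)
        only_ones = ps.subset(np.flatnonzero(ps.labels == 1))
        model = build_network(tiny_spec, 5)
        with pytest.raises(ValueError, match="both classes"):
            train(model, only_ones, ps, fast_train_config)

    def test_divergence_raises_with_history(self, tiny_spec):
        train_ps = make_patchset(64, M=5, separation=1.0, seed=7)
        test_ps = make_patchset(32, M=5, separation=1.0, seed=8)
        model = build_network(tiny_spec, 5, seed=3)
        # blow up the parameters so the forward pass overflows float32
        for p in model.params():
            p += np.float32(1e30)
        cfg = TrainConfig(lr=1e6, batch_size=64, max_epochs=2, seed=3, l2_weight=0.0)
        with pytest.raises((TrainingDivergedError, FloatingPointError)):
            with np.errstate(over="raise", invalid="raise"):
                train(model, train_ps, test_ps, cfg)

    def test_training_deterministic_given_seed(self, tiny_spec):
        results = []
        for _ in range(2):
            train_ps = make_patchset(128, M=5, separation=2.0, seed=9)
            test_ps = make_patchset(64, M=5, separation=2.0, seed=10)
            model = build_network(tiny_spec, 5, seed=4)
            cfg = TrainConfig(lr=1.0, batch_size=64, max_epochs=2, seed=4)
            _, history = train(model, train_ps, test_ps, cfg)
            results.append((history.train_cost, history.test_cost))
        assert results[0] == results[1]
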