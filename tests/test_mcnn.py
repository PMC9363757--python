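"""Tests for the numpy CNN stack: input assembly, architecture/shape
chain, residual behavior, gradients, training and determinism."""

import numpy as np
import pytest

from mpeeg.core.types import ValidationError
from mpeeg.mcnn import (
    Conv2D,
    MCNNConfig,
    MaxPool2D,
    build_lenet5,
    build_mcnn,
    input_to_row,
    reshape_to_input,
    rows_to_tensor,
    train_model,
)


def make_separable(n_per_class=80, shift=2.0, seed=0, normalized=True):
    """Planted diagonal + off-diagonal difference, z-scored rows."""
    rng = np.random.default_rng(seed)

    def block(n, s):
        rows = rng.normal(0, 1, size=(n, 528))
        rows[:, :32] += s * 0.5       # diagonal (activation) block
        rows[:, 40:80] += s           # off-diagonal (connectivity) block
        return rows

    rows = np.vstack([block(n_per_class, 0.0), block(n_per_class, shift)])
    labels = np.r_[np.zeros(n_per_class, int), np.ones(n_per_class, int)]
    if normalized:
        rows = (rows - rows.mean(axis=0)) / rows.std(axis=0)
    return rows, labels


class TestReshape:
    def test_zero_row_zero_matrix(self):
        np.testing.assert_array_equal(reshape_to_input(np.zeros(528)),
                                      np.zeros((32, 32)))

    def test_round_trip(self, rng):
        row = rng.normal(size=528)
        mat = reshape_to_input(row)
        np.testing.assert_array_equal(input_to_row(mat), row)

    def test_planted_pair_symmetric(self):
        row = np.zeros(528)
        # pair (3, 7): position in the upper-triangle ordering
        pairs = [(i, j) for i in range(32) for j in range(i + 1, 32)]
        k = pairs.index((3, 7))
        row[32 + k] = 0.9
        mat = reshape_to_input(row)
        assert mat[3, 7] == mat[7, 3] == 0.9
        assert np.count_nonzero(mat) == 2

    def test_wrong_length_raises(self):
        with pytest.raises(ValidationError, match="528"):
            reshape_to_input(np.zeros(100))

    def test_rows_to_tensor_matches_scalar(self, rng):
        rows = rng.normal(size=(5, 528))
        tensor = rows_to_tensor(rows)
        assert tensor.shape == (5, 1, 32, 32)
        for i in range(5):
            np.testing.assert_array_equal(tensor[i, 0], reshape_to_input(rows[i]))


class TestArchitecture:
    @pytest.mark.parametrize("n_classes", [2, 3])
    def test_output_width(self, n_classes):
        model = build_mcnn(MCNNConfig(n_classes=n_classes, seed=0))
        out = model.forward(np.zeros((4, 1, 32, 32)))
        assert out.shape == (4, n_classes)
        assert np.all(np.isfinite(out))

    def test_invalid_n_classes(self):
        with pytest.raises(ValidationError):
            MCNNConfig(n_classes=5)

    def test_branch_dimensions(self):
        # Table-2 chain: branch1 flattens to 120, branch2 to 64*6*32
        model = build_mcnn(MCNNConfig(seed=0))
        x = np.zeros((2, 1, 32, 32))
        assert model.branch1.forward(x).shape == (2, 120)
        assert model.branch2.forward(x).shape == (2, 64 * 6 * 32)

    def test_shape_chain_error_reports_layer(self):
        from mpeeg.mcnn.models import _check_chain

        rng = np.random.default_rng(0)
        layers = [Conv2D(1, 4, 9, 0, rng), MaxPool2D(2), Conv2D(4, 8, 9, 0, rng)]
        with pytest.raises(ValidationError, match="layer"):
            _check_chain(layers, (1, 12, 12))

    def test_residual_identity_with_zero_weights(self):
        model = build_mcnn(MCNNConfig(seed=0))
        res = model.residual_block
        for p in res.params():
            p.value[:] = 0.0
        x = np.random.default_rng(1).normal(size=(3, 16, 12, 12))
        np.testing.assert_array_equal(res.forward(x), x)

    def test_lenet_smaller_than_mcnn(self):
        mcnn = build_mcnn(MCNNConfig(seed=0))
        lenet = build_lenet5(2)
        assert lenet.n_parameters() < mcnn.n_parameters()

    @pytest.mark.parametrize("n_classes", [2, 3])
    def test_lenet_output_width(self, n_classes):
        model = build_lenet5(n_classes)
        out = model.forward(np.zeros((2, 1, 32, 32)))
        assert out.shape == (2, n_classes)


class TestGradients:
    def _numeric_check(self, model, x, y, n_checks=5, eps=1e-5, seed=0):
        rng = np.random.default_rng(seed)
        logits = model.forward(x, train=False)
        _, d = model.loss_and_grad(logits, y)
        model.backward(d)
        for p in rng.choice(model.params(), size=n_checks, replace=False):
            idx = tuple(rng.integers(0, s) for s in p.value.shape)
            analytic = p.grad[idx]
            p.value[idx] += eps
            l1, _ = model.loss_and_grad(model.forward(x, train=False), y)
            p.value[idx] -= 2 * eps
            l2, _ = model.loss_and_grad(model.forward(x, train=False), y)
            p.value[idx] += eps
            numeric = (l1 - l2) / (2 * eps)
            assert analytic == pytest.approx(numeric, abs=1e-7, rel=1e-4)

    def test_mcnn_gradients_numeric(self, rng):
        model = build_mcnn(MCNNConfig(seed=2, dropout_rate=0.0))
        x = rng.normal(size=(3, 1, 32, 32))
        y = np.array([0, 1, 1])
        self._numeric_check(model, x, y)

    def test_lenet_gradients_numeric(self, rng):
        model = build_lenet5(3, seed=2)
        x = rng.normal(size=(3, 1, 32, 32))
        y = np.array([0, 1, 2])
        self._numeric_check(model, x, y)

    def test_gradient_flow_all_params_update(self, rng):
        # one SGD step on non-degenerate data changes every trainable tensor
        cfg = MCNNConfig(seed=3, max_epochs=1, batch_size=8,
                         learning_rate=0.01)
        model = build_mcnn(cfg)
        before = [p.value.copy() for p in model.params()]
        x = rng.normal(size=(8, 1, 32, 32))
        y = rng.integers(0, 2, size=8)
        train_model(model, x, y, x[:2], y[:2], cfg, checkpoint_best=False)
        changed = [not np.array_equal(b, p.value)
                   for b, p in zip(before, model.params())]
        assert all(changed), [p.name for p, c in zip(model.params(), changed) if not c]


class TestTraining:
    def test_separable_reaches_95(self):
        rows, labels = make_separable(n_per_class=80, shift=2.0, seed=4)
        xt = rows_to_tensor(rows)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(labels))
        tr, va = perm[:128], perm[128:]
        cfg = MCNNConfig(seed=1, max_epochs=10, batch_size=32, learning_rate=0.03)
        model = build_mcnn(cfg)
        history = train_model(model, xt[tr], labels[tr], xt[va], labels[va], cfg)
        assert history.n_epochs == 10
        assert max(history.val_accuracy) >= 0.95

    def test_permuted_labels_chance(self):
        rows, labels = make_separable(n_per_class=60, shift=2.0, seed=5)
        rng = np.random.default_rng(1)
        labels = rng.permutation(labels)
        xt = rows_to_tensor(rows)
        perm = rng.permutation(len(labels))
        tr, va = perm[:80], perm[80:]
        cfg = MCNNConfig(seed=1, max_epochs=6, batch_size=32, learning_rate=0.03)
        model = build_mcnn(cfg)
        history = train_model(model, xt[tr], labels[tr], xt[va], labels[va],
                              cfg, checkpoint_best=False)
        assert 0.40 <= history.val_accuracy[-1] <= 0.60

    def test_max_epochs_zero_untrained(self):
        cfg = MCNNConfig(seed=0, max_epochs=0)
        model = build_mcnn(cfg)
        before = [p.value.copy() for p in model.params()]
        history = train_model(model, np.zeros((4, 1, 32, 32)),
                              np.array([0, 1, 0, 1]),
                              np.zeros((2, 1, 32, 32)), np.array([0, 1]), cfg)
        assert history.n_epochs == 0
        for b, p in zip(before, model.params()):
            np.testing.assert_array_equal(b, p.value)

    def test_bad_labels_raise(self):
        cfg = MCNNConfig(seed=0, max_epochs=1)
        model = build_mcnn(cfg)
        with pytest.raises(ValidationError):
            train_model(model, np.zeros((2, 1, 32, 32)), np.array([0, 5]),
                        np.zeros((1, 1, 32, 32)), np.array([0]), cfg)

    def test_seed_determinism(self):
        rows, labels = make_separable(n_per_class=20, shift=1.0, seed=6)
        xt = rows_to_tensor(rows)

        def run():
            cfg = MCNNConfig(seed=9, max_epochs=3, batch_size=16,
                             learning_rate=0.01)
            model = build_mcnn(cfg)
            history = train_model(model, xt[:32], labels[:32], xt[32:],
                                  labels[32:], cfg)
            return history, [p.value.copy() for p in model.params()]

        h1, p1 = run()
        h2, p2 = run()
        assert h1.train_loss == h2.train_loss
        assert h1.val_accuracy == h2.val_accuracy
        for a, b in zip(p1, p2):
            np.testing.assert_array_equal(a, b)

    def test_lr_schedule_inverse_time(self):
        # two epochs with decay: second-epoch updates use lr0/(1+decay)
        cfg = MCNNConfig(seed=0, decay=0.5)
        lrs = [cfg.learning_rate / (1 + cfg.decay * t) for t in range(3)]
        assert lrs[0] == pytest.approx(0.001)
        assert lrs[1] == pytest.approx(0.001 / 1.5)
        assert lrs[2] == pytest.approx(0.001 / 2.0)

    def test_weight_decay_mode_runs(self):
        rows, labels = make_separable(n_per_class=10, shift=1.0, seed=7)
        xt = rows_to_tensor(rows)
        cfg = MCNNConfig(seed=0, max_epochs=1, batch_size=8,
                         decay_mode="weight_decay", decay=1e-4)
        model = build_mcnn(cfg)
        history = train_model(model, xt[:16], labels[:16], xt[16:], labels[16:], cfg)
        assert history.n_epochs == 1


class TestLeNetTraining:
    def test_lenet_trains_on_separable(self):
        # LeNet needs more rows than the multi-scale net to generalize on
        # pixel-wise (non-spatial) planted signal
        rows, labels = make_separable(n_per_class=150, shift=3.0, seed=10)
        xt = rows_to_tensor(rows)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(labels))
        tr, va = perm[:240], perm[240:]
        cfg = MCNNConfig(seed=1, max_epochs=15, batch_size=32, learning_rate=0.05)
        model = build_lenet5(2, seed=1)
        history = train_model(model, xt[tr], labels[tr], xt[va], labels[va], cfg)
        assert max(history.val_accuracy) >= 0.90


class TestCrossvalMCNN:
    def _fm(self, n_per_class=30, n_classes=2, seed=11):
        from mpeeg.classify import FeatureMatrix
        from mpeeg.features.bands import GAMMA

        rng = np.random.default_rng(seed)
        blocks, labels = [], []
        for c in range(n_classes):
            rows = rng.normal(0, 1, size=(n_per_class, 528))
            rows[:, c * 30 : c * 30 + 30] += 3.0
            blocks.append(rows)
            labels.append(np.full(n_per_class, c, dtype=int))
        rows = np.vstack(blocks)
        return FeatureMatrix(
            rows=rows, labels=np.concatenate(labels),
            subject_ids=np.array([f"s{i}" for i in range(len(rows))]),
            epoch_index=np.zeros(len(rows), int),
            feature_names=tuple(f"f{i}" for i in range(528)),
            band=GAMMA, mode="PSD_PLV",
            class_names=tuple(f"G{c}" for c in range(n_classes)),
        )

    def test_fold_bookkeeping_matches_svm(self):
        from mpeeg.classify import svm_crossval
        from mpeeg.mcnn.training import crossval_mcnn

        fm = self._fm()
        cfg = MCNNConfig(seed=3, max_epochs=1, batch_size=32, learning_rate=0.01)
        mcnn_res = crossval_mcnn(fm, k=3, cfg=cfg)
        svm_res = svm_crossval(fm, k=3, seed=3)
        np.testing.assert_array_equal(mcnn_res.fold_assignments,
                                      svm_res.fold_assignments)

    def test_three_class_per_class_metrics(self):
        from mpeeg.mcnn.training import crossval_mcnn

        fm = self._fm(n_per_class=15, n_classes=3)
        cfg = MCNNConfig(seed=4, n_classes=3, max_epochs=1, batch_size=16,
                         learning_rate=0.01)
        result = crossval_mcnn(fm, k=3, cfg=cfg)
        assert result.per_class_sensitivity.shape == (3,)
        assert result.per_class_specificity.shape == (3,)
        assert len(result.class_names) == 3


class TestAblation:
    def test_connectivity_signal_diagonal_only_ablation(self):
        # discriminative signal planted ONLY off-diagonal: full input must
        # beat (or match) diagonal-only input
        rng = np.random.default_rng(8)
        n = 60

        def block(shift):
            rows = rng.normal(0, 1, size=(n, 528))
            rows[:, 32 + 10 : 32 + 90] += shift  # off-diagonal only
            return rows

        rows = np.vstack([block(0.0), block(2.0)])
        labels = np.r_[np.zeros(n, int), np.ones(n, int)]
        rows = (rows - rows.mean(0)) / rows.std(0)
        perm = rng.permutation(2 * n)
        tr, va = perm[:96], perm[96:]

        def accuracy(mask_offdiag):
            r = rows.copy()
            if mask_offdiag:
                r[:, 32:] = 0.0
            xt = rows_to_tensor(r)
            cfg = MCNNConfig(seed=2, max_epochs=8, batch_size=32,
                             learning_rate=0.03)
            model = build_mcnn(cfg)
            h = train_model(model, xt[tr], labels[tr], xt[va], labels[va], cfg)
            return max(h.val_accuracy)

        assert accuracy(mask_offdiag=False) >= accuracy(mask_offdiag=True)
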