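"""Network architecture, gradients, normalization and training behavior."""

import numpy as np
import pytest

from fretsort import (
    ModelSpec,
    Trace,
    TrainedModel,
    TrainingConfig,
    build_model,
    normalize_trace,
    predict_batch,
    predict_frame_probs,
    train_model,
)
from fretsort.nn.layers import softmax_cross_entropy
from fretsort.nn.network import SequenceClassifier


TINY_SPEC = dict(
    n_res_blocks=2, base_filters=4, filter_doubling_period=1,
    kernel_start=5, kernel_decrement=2, kernel_min=2,
    recurrent_units=3, recurrent_dropout_rate=0.0,
)


class TestNormalizeTrace:
    def test_scaling_preserves_ratios(self, rng):
        dd = rng.uniform(0, 1000, 100)
        da = rng.uniform(0, 400, 100)
        tr = Trace(dd=dd, da=da, aa=rng.uniform(0, 800, 100))
        out = normalize_trace(tr)
        m = tr.channel_stack().max()
        assert out.channel_stack().max() == pytest.approx(1.0)
        nz = da != 0
        assert np.allclose((out.dd / out.da)[nz], (dd / da)[nz])
        assert np.allclose(out.dd, dd / m)

    def test_idempotent(self, rng):
        tr = Trace(dd=rng.uniform(size=50), da=rng.uniform(size=50))
        once = normalize_trace(tr)
        twice = normalize_trace(once)
        assert np.allclose(once.channel_stack(), twice.channel_stack())

    def test_all_nonpositive_rejected(self):
        with pytest.raises(ValueError, match="normalize"):
            normalize_trace(Trace(dd=np.zeros(10), da=np.zeros(10)))


class TestArchitecture:
    def test_full_scale_schedule(self):
        # 16 blocks: filters double and kernels shrink by 4 every 4th block
        filters, kernels = ModelSpec().schedule()
        assert filters == [32] * 4 + [64] * 4 + [128] * 4 + [256] * 4
        assert kernels == [16] * 4 + [12] * 4 + [8] * 4 + [4] * 4

    def test_invalid_channel_count(self):
        with pytest.raises(ValueError, match="channels"):
            ModelSpec(n_channels=4)

    def test_per_frame_output_shape(self):
        net = build_model(ModelSpec(n_channels=3, **TINY_SPEC), seed=0)
        x = np.random.default_rng(0).normal(size=(2, 300, 3))
        out = net.forward(x, training=False)
        assert out.shape == (2, 300, 6)

    def test_output_rows_softmax_to_one(self):
        net = build_model(ModelSpec(n_channels=2, **TINY_SPEC), seed=0)
        x = np.random.default_rng(1).normal(size=(3, 40, 2))
        probs = net.predict_proba(x)
        assert np.allclose(probs.sum(axis=2), 1.0, atol=1e-5)
        assert np.all(probs >= 0)

    def test_parameter_count_deterministic(self):
        spec = ModelSpec(n_channels=3, **TINY_SPEC)
        a, b = build_model(spec, seed=0), build_model(spec, seed=1)
        assert a.n_parameters() == b.n_parameters()

    def test_gradient_check(self):
        # numerical vs analytic gradient through conv/BN/residual/pool/LSTM
        net = SequenceClassifier(
            n_channels=3, n_res_blocks=2, base_filters=4,
            filter_doubling_period=1, kernel_start=5, kernel_decrement=2,
            kernel_min=2, recurrent_units=3, recurrent_dropout_rate=0.0,
            seed=1, dtype=np.float64,
        )
        rng = np.random.default_rng(2)
        x = rng.normal(size=(2, 9, 3))
        y = rng.dirichlet(np.ones(6), size=(2, 9))

        loss, d = softmax_cross_entropy(net.forward(x, training=True), y)
        net.backward(d)
        grads = [g.copy() for g in net.grads()]
        params = net.params()
        eps = 1e-5
        check_rng = np.random.default_rng(3)
        for p, g in zip(params, grads):
            flat = p.ravel()
            idx = check_rng.integers(flat.size)
            orig = flat[idx]
            flat[idx] = orig + eps
            lp, _ = softmax_cross_entropy(net.forward(x, training=True), y)
            flat[idx] = orig - eps
            lm, _ = softmax_cross_entropy(net.forward(x, training=True), y)
            flat[idx] = orig
            num = (lp - lm) / (2 * eps)
            ana = g.ravel()[idx]
            assert num == pytest.approx(ana, rel=1e-3, abs=1e-7)


@pytest.fixture(scope="module")
def trained():
    # tiny model trained briefly on two easily separable classes
    rng = np.random.default_rng(0)
    n, t = 60, 40
    x = np.zeros((n, t, 3))
    y = np.zeros((n, t, 6))
    for i in range(n):
        if i % 2 == 0:  # "static smFRET"-like: constant split
            x[i, :, 0] = 0.6
            x[i, :, 1] = 0.4
            x[i, :, 2] = 1.0
            y[i, :, 4] = 1.0
        else:  # "bleached"-like: zeros
            y[i, :, 0] = 1.0
        x[i] += rng.normal(0, 0.05, size=(t, 3))
    spec = ModelSpec(n_channels=3, **TINY_SPEC)
    cfg = TrainingConfig(seed=0, max_epochs=5)
    return train_model(x, y, spec=spec, config=cfg), x


class TestPrediction:
    def test_training_loss_decreases(self, trained):
        model, _ = trained
        hist = model.history["loss"]
        assert hist[-1] < hist[0]

    def test_rows_sum_to_one(self, trained):
        model, x = trained
        probs = model.network.predict_proba(x[:4])
        assert np.allclose(probs.sum(axis=2), 1.0, atol=1e-5)

    def test_batch_permutation_invariance(self, trained):
        model, x = trained
        probs = model.network.predict_proba(x[:8])
        perm = np.array([3, 0, 7, 2, 1, 6, 4, 5])
        probs_perm = model.network.predict_proba(x[:8][perm])
        assert np.allclose(probs_perm, probs[perm], atol=1e-10)

    def test_duplicated_trace_identical_outputs(self, trained):
        model, x = trained
        batch = np.concatenate([x[:1], x[:1]])
        probs = model.network.predict_proba(batch)
        assert np.allclose(probs[0], probs[1])

    def test_channel_mismatch_rejected(self, trained):
        model, _ = trained
        tr = Trace(dd=np.ones(40), da=np.ones(40))  # non-ALEX
        with pytest.raises(ValueError, match="channels"):
            predict_frame_probs(model, tr)

    def test_save_load_round_trip(self, trained, tmp_path):
        model, x = trained
        p = tmp_path / "model.npz"
        model.save(p)
        back = TrainedModel.load(p)
        assert back.classes == model.classes
        assert np.allclose(
            back.network.predict_proba(x[:3]),
            model.network.predict_proba(x[:3]),
        )


class TestTrainingConfigBehavior:
    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train_model(np.empty((0, 10, 3)), np.empty((0, 10, 6)))

    def test_single_class_warns(self):
        x = np.random.default_rng(0).normal(size=(8, 10, 3))
        y = np.zeros((8, 10, 6))
        y[:, :, 0] = 1.0
        spec = ModelSpec(n_channels=3, **TINY_SPEC)
        with pytest.warns(UserWarning, match="single-class"):
            train_model(x, y, spec=spec,
                        config=TrainingConfig(seed=0, max_epochs=1))

    def test_lr_drops_tenfold_on_plateau(self):
        from fretsort.nn.optim import Adam, ReduceLROnPlateau

        opt = Adam([np.zeros(1)], lr=1e-3)
        sched = ReduceLROnPlateau(opt, factor=10.0, patience=2)
        sched.step(1.0)   # first value becomes best
        sched.step(1.1)   # no improvement (1)
        assert opt.lr == pytest.approx(1e-3)
        sched.step(1.2)   # no improvement (2) -> decay
        assert opt.lr == pytest.approx(1e-4)

    def test_early_stopping_restores_best(self):
        from fretsort.nn.optim import EarlyStopping

        p = [np.array([1.0])]
        stopper = EarlyStopping(patience=2)
        stopper.step(1.0, p)
        p[0][0] = 2.0
        assert not stopper.step(1.5, p)
        assert stopper.step(1.6, p)
        stopper.restore(p)
        assert p[0][0] == 1.0

    def test_invalid_train_fraction(self):
        with pytest.raises(ValueError):
            TrainingConfig(train_fraction=1.0)
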