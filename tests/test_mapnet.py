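"""Network architecture contracts, autodiff correctness, and training behaviour."""

import numpy as np
import pytest
from sklearn.base import clone

from fundusseg import nn
from fundusseg.mapnet import (
    MapNet,
    MapNetConfig,
    MapNetSegmenter,
    apfe_features,
    build_model,
    predict_mask,
    train,
)
from fundusseg.nn import functional as F
from fundusseg.nn.autograd import Tensor
from fundusseg.synthetic import generate_dataset


# ---------------------------------------------------------------------------
# autodiff engine: finite-difference gradient checks


def numeric_grad(f, x, eps=1e-2):
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        hi = f()
        x[i] = orig - eps
        lo = f()
        x[i] = orig
        g[i] = (hi - lo) / (2 * eps)
        it.iternext()
    return g


def check_input_grad(op, shape, seed=0, atol=5e-3, distinct=False):
    """Compare d(sum(op(x) * w))/dx against central finite differences.

    ``distinct`` uses well-separated values so argmax-style ops cannot flip
    their selection inside the finite-difference step.
    """
    rng = np.random.default_rng(seed)
    if distinct:
        n = int(np.prod(shape))
        # unit-spaced values straddling zero, none closer than 0.5 to it
        vals = (rng.permutation(n) - n / 2 + 0.25).reshape(shape)
    else:
        vals = rng.normal(0, 1, shape)
    x = Tensor(vals.astype(np.float32), requires_grad=True)
    out = op(x)
    upstream = rng.normal(0, 1, out.shape).astype(np.float32)

    def loss_value():
        return float((op(Tensor(x.data)).data * upstream).sum())

    out._backward(upstream)
    expected = numeric_grad(loss_value, x.data)
    assert np.allclose(x.grad, expected, atol=atol), np.abs(x.grad - expected).max()


@pytest.mark.parametrize("name,op,shape", [
    ("relu", lambda x: F.relu(x), (2, 3, 4, 4)),
    ("avg_pool", lambda x: F.avg_pool2d(x, 2), (1, 2, 4, 4)),
    ("upsample", lambda x: F.upsample_bilinear(x, 2), (1, 2, 3, 3)),
    ("max_pool", lambda x: F.max_pool2d(x, 3, 2, 1), (1, 2, 6, 6)),
])
def test_input_gradients_match_finite_differences(name, op, shape):
    # distinct, unit-spaced inputs keep relu/argmax selections stable
    # inside the finite-difference step
    check_input_grad(op, shape, distinct=True)


def test_conv2d_gradients_match_finite_differences():
    rng = np.random.default_rng(1)
    x = Tensor(rng.normal(0, 1, (1, 2, 5, 5)).astype(np.float32), requires_grad=True)
    w = Tensor(rng.normal(0, 0.5, (3, 2, 3, 3)).astype(np.float32), requires_grad=True)
    b = Tensor(np.zeros(3, np.float32), requires_grad=True)
    upstream = rng.normal(0, 1, (1, 3, 5, 5)).astype(np.float32)

    def loss():
        return float((F.conv2d(Tensor(x.data), Tensor(w.data), Tensor(b.data),
                               1, 1).data * upstream).sum())

    out = F.conv2d(x, w, b, 1, 1)
    out._backward(upstream)
    assert np.allclose(x.grad, numeric_grad(loss, x.data), atol=5e-3)
    assert np.allclose(w.grad, numeric_grad(loss, w.data), atol=5e-3)
    assert np.allclose(b.grad, numeric_grad(loss, b.data), atol=5e-3)


def test_conv_transpose_gradients_match_finite_differences():
    rng = np.random.default_rng(2)
    x = Tensor(rng.normal(0, 1, (1, 2, 3, 3)).astype(np.float32), requires_grad=True)
    w = Tensor(rng.normal(0, 0.5, (2, 2, 4, 4)).astype(np.float32), requires_grad=True)
    upstream = rng.normal(0, 1, (1, 2, 6, 6)).astype(np.float32)

    def loss():
        return float((F.conv_transpose2d(Tensor(x.data), Tensor(w.data), None,
                                         2, 1).data * upstream).sum())

    out = F.conv_transpose2d(x, w, None, 2, 1)
    assert out.shape == (1, 2, 6, 6)
    out._backward(upstream)
    assert np.allclose(x.grad, numeric_grad(loss, x.data), atol=5e-3)
    assert np.allclose(w.grad, numeric_grad(loss, w.data), atol=5e-3)


def test_softmax_cross_entropy_gradient_and_value():
    rng = np.random.default_rng(3)
    logits = Tensor(rng.normal(0, 1, (2, 2, 3, 3)).astype(np.float32),
                    requires_grad=True)
    target = rng.integers(0, 2, (2, 3, 3))

    def loss():
        return float(F.softmax_cross_entropy(Tensor(logits.data), target).data)

    out = F.softmax_cross_entropy(logits, target)
    p = F.softmax(logits.data)
    picked = np.take_along_axis(p, target[:, None], axis=1)[:, 0]
    assert float(out.data) == pytest.approx(float(-np.log(picked).mean()), rel=1e-5)
    out.backward()
    assert np.allclose(logits.grad, numeric_grad(loss, logits.data, eps=5e-3),
                       atol=5e-3)


def test_identity_pooling_window_one():
    x = Tensor(np.random.default_rng(4).random((1, 3, 8, 8)).astype(np.float32))
    assert np.array_equal(F.avg_pool2d(x, 1).data, x.data)


# ---------------------------------------------------------------------------
# configuration and shape contracts


class TestConfig:
    def test_default_channel_arithmetic(self):
        cfg = MapNetConfig()
        assert cfg.dnfe_tap_channels == (128, 256, 1024)
        assert cfg.combined_channels == (512, 640, 1408)
        assert cfg.tap_sides == (128, 64, 32)

    def test_reduced_preserves_channel_arithmetic(self):
        cfg = MapNetConfig.reduced()
        taps = cfg.dnfe_tap_channels
        assert cfg.combined_channels == tuple(t + cfg.apfe_channels for t in taps)
        assert cfg.tap_sides == (32, 16, 8)

    @pytest.mark.parametrize("bad", [
        dict(input_side=100),                      # not divisible by 16
        dict(apfe_channels=100),                   # not divisible by 3
        dict(head_upsample_factors=(4, 8, 8)),     # does not restore input side
        dict(input_side=64),                       # pool window 8 > tap side 4
    ])
    def test_inconsistent_configs_rejected(self, bad):
        import dataclasses

        with pytest.raises(ValueError):
            dataclasses.replace(MapNetConfig(), **bad).validate()

    def test_json_round_trip(self):
        cfg = MapNetConfig.reduced(seed=9)
        assert MapNetConfig.from_json(cfg.to_json()) == cfg


@pytest.fixture(scope="module")
def reduced_summary():
    return MapNet(MapNetConfig.reduced()).shape_summary()


class TestArchitectureShapes:
    def test_tap_spatial_sides_quarter_eighth_sixteenth(self, reduced_summary):
        assert [s[:2] for s in reduced_summary["taps"]] == [(32, 32), (16, 16), (8, 8)]

    def test_apfe_outputs_at_tap_resolution_with_config_channels(self, reduced_summary):
        cfg = MapNetConfig.reduced()
        for (h, w, c), side in zip(reduced_summary["apfe"], cfg.tap_sides):
            assert (h, w) == (side, side) and c == cfg.apfe_channels

    def test_combined_channels_are_tap_plus_apfe(self, reduced_summary):
        cfg = MapNetConfig.reduced()
        assert [s[2] for s in reduced_summary["combined"]] == list(cfg.combined_channels)

    def test_heads_and_output_restore_input_side(self, reduced_summary):
        cfg = MapNetConfig.reduced()
        for shape in reduced_summary["heads"] + [reduced_summary["output"]]:
            assert shape == (cfg.input_side, cfg.input_side, cfg.num_output_channels)

    def test_wrong_input_size_rejected(self):
        model = MapNet(MapNetConfig.reduced())
        with pytest.raises(ValueError):
            model.forward(np.zeros((1, 3, 64, 64), np.float32))


class TestApfe:
    def test_default_output_channel_count(self):
        feat = np.random.default_rng(0).random((1, 16, 32, 32)).astype(np.float32)
        out = apfe_features(feat, pool_sizes=(2, 4, 8), out_channels=384)
        assert out.shape == (1, 384, 32, 32)

    def test_constant_input_gives_spatially_constant_features(self):
        feat = np.full((1, 8, 16, 16), 3.7, np.float32)
        out = apfe_features(feat, pool_sizes=(2, 4, 8), out_channels=12)
        spatial_ptp = out.max(axis=(2, 3)) - out.min(axis=(2, 3))
        assert np.all(spatial_ptp < 1e-4)

    def test_channel_count_must_divide_by_three(self):
        with pytest.raises(ValueError):
            apfe_features(np.zeros((1, 4, 8, 8), np.float32), out_channels=32)

    def test_window_larger_than_map_rejected(self):
        with pytest.raises(ValueError):
            apfe_features(np.zeros((1, 4, 4, 4), np.float32),
                          pool_sizes=(2, 4, 8), out_channels=12)


def test_ensemble_uses_every_head():
    """Zeroing any single head's contribution changes the final output."""
    model = MapNet(MapNetConfig.reduced())
    model.eval()
    x = np.random.default_rng(7).normal(0, 1, (1, 3, 128, 128)).astype(np.float32)
    from fundusseg.nn.autograd import no_grad

    with no_grad():
        _, info = model.forward(x, capture=True)
        heads = [h.data for h in info["heads"]]
        full = model.ensemble(F.concat([Tensor(h) for h in heads])).data
        for i in range(3):
            muted = [np.zeros_like(h) if j == i else h for j, h in enumerate(heads)]
            out = model.ensemble(F.concat([Tensor(h) for h in muted])).data
            assert not np.allclose(out, full)


# ---------------------------------------------------------------------------
# training behaviour (desk scale)


@pytest.fixture(scope="module")
def tiny_dataset(easy_sampler_128):
    data = generate_dataset(40, easy_sampler_128, seed=21)
    return [(s.image, s.disc_mask) for s in data]


def test_training_reduces_loss(tiny_dataset):
    cfg = MapNetConfig.reduced(max_epochs=5, seed=3)
    run = train(MapNet(cfg), tiny_dataset, cfg)
    assert run.train_loss[-1] < run.train_loss[0]
    assert len(run.train_loss) == len(run.val_loss) == 5


def test_training_is_deterministic_under_seed(tiny_dataset):
    cfg = MapNetConfig.reduced(max_epochs=2, seed=5)
    run1 = train(MapNet(cfg), tiny_dataset[:10], cfg)
    run2 = train(MapNet(cfg), tiny_dataset[:10], cfg)
    assert run1.train_loss == run2.train_loss
    assert run1.val_loss == run2.val_loss


def test_best_epoch_is_argmin_of_validation_curve(tiny_dataset):
    cfg = MapNetConfig.reduced(max_epochs=4, seed=1)
    run = train(MapNet(cfg), tiny_dataset[:16], cfg)
    assert run.best_epoch == int(np.argmin(run.val_loss))


def test_empty_dataset_rejected():
    cfg = MapNetConfig.reduced()
    with pytest.raises(ValueError):
        train(MapNet(cfg), [], cfg)


def test_predict_mask_is_binary(tiny_dataset):
    cfg = MapNetConfig.reduced(max_epochs=1, seed=2)
    model = MapNet(cfg)
    train(model, tiny_dataset[:8], cfg)
    mask = predict_mask(model, tiny_dataset[0][0])
    assert mask.shape == (128, 128)
    assert set(np.unique(mask)) <= {0, 1}


class TestEstimator:
    def test_sklearn_clone_and_params(self):
        est = MapNetSegmenter(epochs=3, seed=4)
        cloned = clone(est)
        assert cloned.get_params()["epochs"] == 3

    def test_input_validation(self):
        est = MapNetSegmenter()
        with pytest.raises(ValueError):
            est.fit(np.zeros((2, 128, 128)), np.zeros((2, 128, 128)))
        with pytest.raises(ValueError):
            est.fit(np.zeros((2, 64, 64, 3)), np.zeros((2, 64, 64)))  # wrong side

    def test_fit_predict_shapes_and_score(self, tiny_dataset):
        X = np.stack([img for img, _ in tiny_dataset[:12]])
        y = np.stack([m for _, m in tiny_dataset[:12]])
        est = MapNetSegmenter(epochs=2, seed=0).fit(X, y)
        pred = est.predict(X[:3])
        assert pred.shape == (3, 128, 128)
        proba = est.predict_proba(X[:2])
        assert proba.shape == (2, 128, 128)
        assert np.all((proba >= 0) & (proba <= 1))
        assert 0.0 <= est.score(X[:3], y[:3]) <= 1.0
        assert est.training_run_.best_epoch == int(np.argmin(est.training_run_.val_loss))

    def test_build_model_returns_validated_network(self):
        model = build_model(MapNetConfig.reduced())
        assert isinstance(model, MapNet)
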