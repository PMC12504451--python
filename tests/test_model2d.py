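import numpy as np
import pytest

from slecg import model2d as m


def _numeric_grad(f, arr, dout, eps=1e-6):
    g = np.zeros_like(arr)
    it = np.nditer(arr, flags=["multi_index"])
    for _ in it:
        ix = it.multi_index
        arr[ix] += eps
        yp = f()
        arr[ix] -= 2 * eps
        ym = f()
        arr[ix] += eps
        g[ix] = np.sum((yp - ym) * dout) / (2 * eps)
    return g


def _separable_images(n_per_class=200, seed=7):
    """Trivially separable 96x96 set: a bright band in the upper vs lower
    half, plus salt noise."""
    rng = np.random.default_rng(seed)
    images, labels = [], []
    for label in (0.0, 1.0):
        for _ in range(n_per_class):
            img = (rng.random((96, 96)) < 0.05).astype(float)
            row = rng.integers(10, 35) if label == 1.0 else rng.integers(60, 85)
            img[row:row + 6, :] = 1.0
            images.append(img)
            labels.append(label)
    return np.stack(images), np.asarray(labels)


class TestParameterCounts:
    def test_printed_per_layer_counts(self):
        report = m.count_parameters(m.build_model())
        assert report.conv == (320, 6208, 24704, 49280)
        assert report.dense == 295008
        assert report.core_total == 375520
        assert report.output == 97
        assert report.grand_total == 375617

    def test_flatten_size_is_3072(self):
        assert m.build_model().flatten_size == 3072  # 4 x 6 x 128

    @pytest.mark.parametrize("kernels,pools,shape", [
        (((3, 3), (3, 1), (3, 1), (3, 1)), ((2, 2),) * 3 + ((3, 2),), (96, 96, 1)),
        (((5, 5), (3, 3), (3, 3), (3, 1)), ((2, 2),) * 4, (96, 96, 1)),
        (((3, 3), (3, 1), (3, 1), (3, 1)), ((2, 2),) * 3 + ((3, 2),), (128, 96, 1)),
    ])
    def test_closed_form_identity(self, kernels, pools, shape):
        """Framework-reported counts equal (k_h*k_w*c_in + 1)*c_out for conv
        and (fan_in + 1)*units for dense, for any valid config."""
        cfg = m.ModelConfig(input_shape=shape, conv_kernels=kernels,
                            pool_sizes=pools)
        model = m.build_model(cfg)
        report = m.count_parameters(model)
        cin = shape[2]
        for (kh, kw), cout, got in zip(kernels, cfg.conv_filters, report.conv):
            assert got == (kh * kw * cin + 1) * cout
            cin = cout
        assert report.dense == (model.flatten_size + 1) * 96
        assert report.output == 97

    def test_odd_input_uses_floor_division_pooling(self):
        # 95 -> 47 -> 23 -> 11 -> (3,2) -> 3x5; documented floor behavior
        model = m.build_model(m.ModelConfig(input_shape=(95, 95, 1)))
        assert model.flatten_size == 3 * 5 * 128

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            m.ModelConfig(conv_filters=(16, 32, 64, 64))
        with pytest.raises(ValueError):
            m.ModelConfig(dense_units=128)
        with pytest.raises(ValueError):
            m.ModelConfig(dropout=(0.1, 0.25, 0.4, 0.5))
        with pytest.raises(ValueError):
            m.build_model(m.ModelConfig(input_shape=(8, 8, 1)))


class TestGradients:
    """Analytic backward passes agree with central differences (float64)."""

    def test_conv2d(self, rng):
        conv = m.Conv2D(3, 3, 2, 4, rng)
        conv.w = conv.w.astype(np.float64)
        conv.b = conv.b.astype(np.float64)
        x = rng.standard_normal((2, 6, 5, 2))
        dout = rng.standard_normal((2, 6, 5, 4))
        conv.forward(x, train=True)
        dx = conv.backward(dout)
        np.testing.assert_allclose(
            conv.dw, _numeric_grad(lambda: conv.forward(x, False), conv.w, dout),
            atol=1e-7)
        np.testing.assert_allclose(
            dx, _numeric_grad(lambda: conv.forward(x, False), x, dout),
            atol=1e-7)

    def test_dense(self, rng):
        dense = m.Dense(7, 3, rng)
        dense.w = dense.w.astype(np.float64)
        dense.b = dense.b.astype(np.float64)
        x = rng.standard_normal((4, 7))
        dout = rng.standard_normal((4, 3))
        dense.forward(x, train=True)
        dx = dense.backward(dout)
        np.testing.assert_allclose(
            dense.dw, _numeric_grad(lambda: dense.forward(x, False), dense.w, dout),
            atol=1e-7)
        np.testing.assert_allclose(
            dx, _numeric_grad(lambda: dense.forward(x, False), x, dout),
            atol=1e-7)

    def test_maxpool(self, rng):
        pool = m.MaxPool2D(3, 2)
        x = rng.standard_normal((2, 6, 6, 3))
        dout = rng.standard_normal((2, 2, 3, 3))
        pool.forward(x, train=True)
        dx = pool.backward(dout)
        np.testing.assert_allclose(
            dx, _numeric_grad(lambda: pool.forward(x, False), x, dout),
            atol=1e-6)


class TestTraining:
    def test_learns_separable_set(self):
        """400 separable images, 15 epochs, seed 7: validation accuracy
        reaches 0.95 and training loss decreases."""
        images, labels = _separable_images()
        cfg = m.ModelConfig(seed=7, epochs=15)
        model = m.build_model(cfg)
        m.train(model, images, labels, cfg)
        assert model.history["val_accuracy"][-1] >= 0.95
        assert model.history["loss"][-1] < model.history["loss"][0]
        assert model.trained

    def test_zero_epochs_returns_untrained(self):
        images, labels = _separable_images(n_per_class=4)
        cfg = m.ModelConfig(seed=0, epochs=0)
        model = m.build_model(cfg)
        m.train(model, images, labels, cfg)
        assert model.history["loss"] == []

    def test_single_class_rejected(self):
        cfg = m.ModelConfig(seed=0, epochs=1)
        model = m.build_model(cfg)
        with pytest.raises(ValueError, match="both classes"):
            m.train(model, np.zeros((8, 96, 96)), np.zeros(8), cfg)

    def test_wrong_image_shape_rejected(self):
        model = m.build_model(m.ModelConfig(seed=0, epochs=1))
        with pytest.raises(ValueError, match="shape"):
            m.train(model, np.zeros((8, 64, 64)),
                    np.r_[np.zeros(4), np.ones(4)], model.config)
        with pytest.raises(ValueError, match="shape"):
            m.predict_segment(model, np.zeros((64, 64)))


class TestInference:
    def test_scores_in_unit_interval_and_order_preserved(self, rng):
        model = m.build_model(m.ModelConfig(seed=1))
        batch = rng.random((5, 96, 96))
        scores = m.predict_segment(model, batch)
        assert scores.shape == (5,)
        assert np.all((scores >= 0) & (scores <= 1))
        singles = [m.predict_segment(model, img) for img in batch]
        np.testing.assert_allclose(scores, singles, atol=1e-5)

    def test_inference_is_deterministic(self, rng):
        """Dropout is disabled outside training."""
        model = m.build_model(m.ModelConfig(seed=2))
        img = rng.random((96, 96))
        assert m.predict_segment(model, img) == m.predict_segment(model, img)

    def test_save_load_round_trip(self, tmp_path, rng):
        model = m.build_model(m.ModelConfig(seed=3))
        img = rng.random((96, 96))
        before = m.predict_segment(model, img)
        m.save_model(model, tmp_path / "model.npz")
        loaded = m.load_model(tmp_path / "model.npz")
        assert m.predict_segment(loaded, img) == pytest.approx(before, abs=1e-7)
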