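import numpy as np
import pytest

from thyrocad.io import ValidationError
from thyrocad.network import (
    ClassWeights,
    NetworkConfig,
    build_model,
    class_weights,
    count_parameters,
    extract_kernels,
    per_sample_weights,
    predict,
    predict_proba,
    train_model,
    vote_probability,
    weighted_mse,
)
from thyrocad.preprocess import TARGET_SHAPE, NoduleSample


def fake_sample(rng, label, c1=1, c2=3, pid="p"):
    return NoduleSample(
        t2_block=rng.random(TARGET_SHAPE + (c1,), dtype=np.float32) if c1 else np.zeros(TARGET_SHAPE + (0,), np.float32),
        adc_block=rng.random(TARGET_SHAPE + (c2,), dtype=np.float32) if c2 else np.zeros(TARGET_SHAPE + (0,), np.float32),
        label=label,
        patient_id=pid,
    )


TINY = dict(conv_filters=4, compress_filters=2, hidden_units=3, epochs=1)


def shape_walk_count(config: NetworkConfig, c1: int, c2: int) -> int:
    """Independent parameter-count oracle: walk the layer shapes by hand."""
    kvol = int(np.prod(config.conv_kernel))
    total = 0
    spatial_lens = []
    for c in (c1, c2):
        if c < 1:
            continue
        shape = list(TARGET_SHAPE)
        in_c = c
        for _ in range(config.blocks_per_branch):
            total += kvol * in_c * config.conv_filters + config.conv_filters
            total += config.conv_filters * config.compress_filters + config.compress_filters
            if config.conv_padding == "valid":
                shape = [s - (k - 1) for s, k in zip(shape, config.conv_kernel)]
            shape = [s // p for s, p in zip(shape, config.pool_size)]
            in_c = config.compress_filters
        spatial_lens.append(int(np.prod(shape)) * config.compress_filters)
    feat = sum(spatial_lens)
    total += feat * config.hidden_units + config.hidden_units
    total += config.hidden_units * 1 + 1
    return total


class TestBuildModel:
    def test_default_parameter_count_magnitude(self):
        model = build_model(NetworkConfig(), 1, 3)
        n = count_parameters(model)
        assert n == shape_walk_count(NetworkConfig(), 1, 3)
        # compact two-branch model: ~1.3e5 learnable scalars
        assert 1e5 < n < 2e5

    @pytest.mark.parametrize("c1,c2", [(1, 3), (1, 1), (4, 0), (0, 3)])
    def test_count_matches_shape_walk(self, c1, c2):
        cfg = NetworkConfig(**TINY)
        model = build_model(cfg, c1, c2)
        assert count_parameters(model) == shape_walk_count(cfg, c1, c2)

    def test_single_dense_layer_count(self):
        from thyrocad._nn import Dense

        layer = Dense(10, 1)
        assert sum(p.size for p in layer.params()) == 11

    def test_first_layer_channels(self):
        model = build_model(NetworkConfig(**TINY), 1, 3)
        assert extract_kernels(model, "t2").shape == (4, 1, 3, 3, 3)
        assert extract_kernels(model, "adc").shape == (4, 3, 3, 3, 3)

    def test_branches_structurally_identical(self):
        model = build_model(NetworkConfig(**TINY), 2, 2)
        t2, adc = model.net.branches["t2"], model.net.branches["adc"]
        assert [type(l).__name__ for l in t2.layers] == [type(l).__name__ for l in adc.layers]
        for a, b in zip(t2.params(), adc.params()):
            assert a.value.shape == b.value.shape

    def test_seeded_build_is_deterministic(self):
        cfg = NetworkConfig(**TINY, seed=42)
        w1 = [p.value.copy() for p in build_model(cfg, 1, 3).net.params()]
        w2 = [p.value.copy() for p in build_model(cfg, 1, 3).net.params()]
        for a, b in zip(w1, w2):
            np.testing.assert_array_equal(a, b)

    def test_zero_weights_predict_half(self, rng):
        model = build_model(NetworkConfig(**TINY), 1, 3)
        for p in model.net.params():
            p.value[...] = 0.0
        assert predict(model, fake_sample(rng, 0)) == pytest.approx(0.5)

    def test_prediction_stateless(self, rng):
        model = build_model(NetworkConfig(**TINY), 1, 3)
        samples = [fake_sample(rng, i % 2, pid=f"p{i}") for i in range(4)]
        single = predict(model, samples[2])
        batch = predict_proba(model, samples)
        assert single == pytest.approx(batch[2], abs=1e-6)


class TestClassWeights:
    def test_paper_literal_ratios(self):
        cw = class_weights([1] * 16 + [0] * 32, convention="paper-literal")
        assert cw.ratio == pytest.approx(16 / 32)
        cw = class_weights([1] * 17 + [0] * 31, convention="paper-literal")
        assert cw.ratio == pytest.approx(17 / 31)

    def test_inverse_frequency_upweights_minority(self):
        cw = class_weights([1] * 16 + [0] * 32)
        assert cw.ratio == pytest.approx(32 / 16)
        w = per_sample_weights([1] * 16 + [0] * 32, cw)
        assert w.mean() == pytest.approx(1.0)

    def test_balanced_symmetric(self):
        for convention in ("inverse-frequency", "paper-literal"):
            cw = class_weights([0, 1, 0, 1], convention=convention)
            assert cw.ratio == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            class_weights([1, 1, 1])

    def test_positive_weights_required(self):
        with pytest.raises(ValidationError):
            ClassWeights(w_malignant=0.0, w_benign=1.0)


class TestWeightedMSE:
    def test_perfect_predictions(self):
        assert weighted_mse([0.0, 1.0], [0, 1], [1.0, 1.0]) == 0.0

    def test_explicit_sum(self):
        # (1*(0.5-0)^2 + 1*(0.5-1)^2) / 2 = 0.25
        assert weighted_mse([0.5, 0.5], [0, 1], [1.0, 1.0]) == pytest.approx(0.25)

    def test_weight_scaling_linearity(self, rng):
        p, y, w = rng.random(20), rng.integers(0, 2, 20), rng.random(20) + 0.1
        assert weighted_mse(p, y, 3.0 * w) == pytest.approx(3.0 * weighted_mse(p, y, w))

    def test_unit_weights_reduce_to_plain_mse(self, rng):
        p, y = rng.random(50), rng.integers(0, 2, 50)
        assert weighted_mse(p, y, np.ones(50)) == pytest.approx(np.mean((p - y) ** 2), abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            weighted_mse([0.5], [0, 1], [1.0, 1.0])


class TestTraining:
    def test_history_length_one_epoch(self, rng):
        samples = [fake_sample(rng, i % 2, pid=f"p{i}") for i in range(4)]
        cfg = NetworkConfig(**TINY, seed=0, validation_fraction=0.0)
        model = train_model(build_model(cfg, 1, 3), samples, cfg)
        assert len(model.history["train_loss"]) == 1

    def test_validation_split_quarter(self):
        from thyrocad.network import _validation_split

        labels = np.array([0] * 24 + [1] * 8)
        train, val = _validation_split(labels, 0.25, np.random.default_rng(0))
        assert val.size == 8  # 6 benign + 2 malignant held out
        assert np.intersect1d(train, val).size == 0
        assert train.size + val.size == 32

    def test_training_loss_decreases_on_separable_data(self, rng):
        # two well-separated constant-intensity classes, no noise
        samples = []
        for i in range(8):
            label = i % 2
            t2 = np.full(TARGET_SHAPE + (1,), 0.25 + 0.5 * label, dtype=np.float32)
            adc = np.full(TARGET_SHAPE + (1,), 0.75 - 0.5 * label, dtype=np.float32)
            samples.append(NoduleSample(t2, adc, label, f"p{i}"))
        cfg = NetworkConfig(**dict(TINY, epochs=8), seed=1, validation_fraction=0.0, batch_size=8)
        model = train_model(build_model(cfg, 1, 1), samples, cfg)
        losses = model.history["train_loss"]
        assert losses[-1] < losses[0]

    def test_deterministic_training(self, rng):
        samples = [fake_sample(rng, i % 2, pid=f"p{i}") for i in range(6)]
        cfg = NetworkConfig(**dict(TINY, epochs=2), seed=9)
        runs = []
        for _ in range(2):
            model = train_model(build_model(cfg, 1, 3), samples, cfg)
            runs.append(np.concatenate([p.value.ravel() for p in model.net.params()]))
        np.testing.assert_array_equal(runs[0], runs[1])

    def test_needs_both_classes(self, rng):
        samples = [fake_sample(rng, 0, pid="a"), fake_sample(rng, 0, pid="b")]
        cfg = NetworkConfig(**TINY)
        with pytest.raises(ValidationError):
            train_model(build_model(cfg, 1, 3), samples, cfg)


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        """Weighted-MSE gradient agrees with central differences to 1e-4 relative."""
        cfg = NetworkConfig(conv_filters=2, compress_filters=2, hidden_units=3,
                            epochs=1, dtype="float64", seed=5)
        net = build_model(cfg, 1, 2).net
        rng = np.random.default_rng(0)
        for p in net.params():  # move biases off the ReLU kink
            if p.name.endswith(".b"):
                p.value += rng.uniform(0.01, 0.05, p.value.shape)
        xt = rng.random((2, 48, 48, 20, 1))
        xa = rng.random((2, 48, 48, 20, 2))
        y = np.array([0.0, 1.0])
        w = np.array([1.0, 2.0])

        def loss():
            pr = net.forward(xt, xa, train=True)
            return np.mean(w * (pr - y) ** 2), pr

        _, pr = loss()
        net.backward((2.0 / 2) * w * (pr - y))
        grads = {q.name: q.grad.copy() for q in net.params()}
        for q in net.params():
            flat = q.value.ravel()
            for i in rng.choice(flat.size, size=min(3, flat.size), replace=False):
                h, old = 1e-6, flat[i]
                flat[i] = old + h
                lp, _ = loss()
                flat[i] = old - h
                lm, _ = loss()
                flat[i] = old
                fd = (lp - lm) / (2 * h)
                an = grads[q.name].ravel()[i]
                assert abs(fd - an) <= 1e-4 * max(abs(fd), abs(an), 1e-5), q.name


class TestKernelExtraction:
    def test_kernels_equal_init_draw_before_training(self):
        cfg = NetworkConfig(**TINY, seed=3)
        k1 = extract_kernels(build_model(cfg, 1, 3), "adc")
        k2 = extract_kernels(build_model(cfg, 1, 3), "adc")
        np.testing.assert_array_equal(k1, k2)

    def test_kernel_count_is_conv_filters(self):
        model = build_model(NetworkConfig(), 1, 3)
        assert extract_kernels(model, "t2").shape == (32, 1, 3, 3, 3)

    def test_unknown_branch_rejected(self):
        model = build_model(NetworkConfig(**TINY), 1, 3)
        with pytest.raises(ValidationError):
            extract_kernels(model, "dwi")


class TestVoting:
    def test_two_cnn_probability_voting(self):
        assert vote_probability(0.4, 0.8) == pytest.approx(0.6)
        np.testing.assert_allclose(vote_probability([0.0, 1.0], [1.0, 1.0]), [0.5, 1.0])


class TestSaveLoad:
    def test_round_trip(self, tmp_path, rng):
        cfg = NetworkConfig(**TINY, seed=2)
        model = build_model(cfg, 1, 3)
        samples = [fake_sample(rng, i % 2, pid=f"p{i}") for i in range(4)]
        train_model(model, samples, cfg)
        model.save(tmp_path / "m")
        from thyrocad.network import TrainedModel

        back = TrainedModel.load(tmp_path / "m")
        s = fake_sample(rng, 0, pid="q")
        assert predict(back, s) == pytest.approx(predict(model, s), abs=1e-7)
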