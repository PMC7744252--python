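import numpy as np
import pytest

from lesionft.nn.model import (ModelConfig, build_model, load_checkpoint,
                               receptive_field, save_checkpoint)
from lesionft.nn.ops import F32, softmax
from lesionft.training import softmax_ce_loss_grad


class TestReceptiveField:
    def test_single_undilated_layer(self):
        cfg = ModelConfig(dilation_schedule=(1,))
        assert receptive_field(cfg) == 3

    def test_thirteen_undilated_layers(self):
        cfg = ModelConfig(dilation_schedule=(1,) * 13)
        assert receptive_field(cfg) == 27

    def test_default_schedule(self):
        assert receptive_field(ModelConfig()) == 123


def test_default_concatenation_width_is_640():
    assert ModelConfig().concat_channels == 640


def test_invalid_schedule_rejected_at_build():
    cfg = ModelConfig(dilation_schedule=(1, 2, 3))
    with pytest.raises(ValueError, match="13"):
        build_model(cfg, np.random.default_rng(0))


@pytest.fixture(scope="module")
def net(tiny_model_cfg):
    return build_model(tiny_model_cfg, np.random.default_rng(7))


def _inputs(rng, b, h, w):
    return (rng.standard_normal((b, h, w, 2)).astype(F32),
            rng.standard_normal((b, h, w, 1)).astype(F32))


class TestForward:
    def test_probabilities_normalized_and_shape_preserved(self, net):
        rng = np.random.default_rng(0)
        xa, xb = _inputs(rng, 2, 32, 32)
        logits = net.forward(xa, xb, mode="eval")
        assert logits.shape == (2, 32, 32, 2)
        p = softmax(logits)
        np.testing.assert_allclose(p.sum(axis=-1), 1.0, atol=1e-5)

    def test_fully_convolutional_any_spatial_size(self, net):
        rng = np.random.default_rng(1)
        for h, w in ((9, 13), (40, 24), (1, 1)):
            xa, xb = _inputs(rng, 1, h, w)
            assert net.forward(xa, xb, mode="eval").shape == (1, h, w, 2)

    def test_constant_zero_input_yields_valid_probability_plane(self, net):
        prob = net.predict_slice(np.zeros((16, 16, 2), F32),
                                 np.zeros((16, 16, 1), F32))
        assert prob.shape == (16, 16)
        assert np.all((prob >= 0) & (prob <= 1))

    def test_channel_mismatch_raises(self, net):
        rng = np.random.default_rng(2)
        xa, _ = _inputs(rng, 1, 8, 8)
        with pytest.raises(ValueError, match="channel mismatch"):
            net.forward(xa, rng.standard_normal((1, 8, 8, 3)).astype(F32),
                        mode="eval")

    def test_zero_padding_affects_only_a_border_of_half_receptive_field(self):
        """Padding the input by 8 zeros and cropping the output reproduces
        the direct prediction for every pixel farther than half the
        receptive field from the original border (translation covariance of
        a same-padded FCN)."""
        cfg = ModelConfig(channels_per_pathway=(2, 1), kernels_per_conv=4,
                          head_channels=(8, 2),
                          dilation_schedule=(1,) * 13)  # receptive field 27
        net = build_model(cfg, np.random.default_rng(3))
        rng = np.random.default_rng(4)
        xa, xb = _inputs(rng, 1, 40, 40)
        direct = net.forward(xa, xb, mode="eval")
        pad = ((0, 0), (8, 8), (8, 8), (0, 0))
        padded = net.forward(np.pad(xa, pad), np.pad(xb, pad), mode="eval")
        cropped = padded[:, 8:-8, 8:-8, :]
        margin = receptive_field(cfg) // 2 + 1  # 14
        interior = (slice(None), slice(margin, -margin),
                    slice(margin, -margin), slice(None))
        np.testing.assert_allclose(direct[interior], cropped[interior],
                                   atol=2e-4)
        # and the border is genuinely affected, so the margin is not vacuous
        assert np.abs(direct - cropped).max() > 1e-3


class TestInitialization:
    def test_same_seed_identical_parameters(self, tiny_model_cfg):
        a = build_model(tiny_model_cfg, np.random.default_rng(5))
        b = build_model(tiny_model_cfg, np.random.default_rng(5))
        for k, v in a.named_parameters().items():
            np.testing.assert_array_equal(v, b.named_parameters()[k])

    def test_different_seed_differs(self, tiny_model_cfg):
        a = build_model(tiny_model_cfg, np.random.default_rng(5))
        b = build_model(tiny_model_cfg, np.random.default_rng(6))
        assert not np.array_equal(a.head_conv1.W, b.head_conv1.W)

    def test_parameter_count_is_config_determined(self, tiny_model_cfg):
        net = build_model(tiny_model_cfg, np.random.default_rng(0))
        k = tiny_model_cfg.kernels_per_conv
        c1, c2 = tiny_model_cfg.channels_per_pathway
        h1, ncls = tiny_model_cfg.head_channels
        conv_w = 9 * (c1 + c2) * k + 2 * 12 * 9 * k * k  # first + 12 deeper
        bn = 2 * 13 * 2 * k                              # gamma+beta
        concat = 10 * k
        head = concat * h1 + 2 * h1 + h1 * ncls + ncls
        assert net.parameter_count() == conv_w + bn + head


class TestHeadBodyPartition:
    def test_head_is_exactly_the_two_final_1x1_convolutions(self, net):
        head = set(net.head_parameter_names())
        assert head == {"head.conv1.W", "head.conv2.W", "head.conv2.b"}
        body = set(net.body_parameter_names())
        assert head.isdisjoint(body)
        assert head | body == set(net.named_parameters())
        # batch-norm parameters (including the head layer's) belong to the
        # frozen body
        assert "head.bn.gamma" in body


def test_fused_layer_matches_reference_composition():
    """The fused conv+BN+ReLU layer agrees with the plain composition of the
    reference Conv3x3, BatchNorm and ReLU layers -- forward (train and eval)
    and all gradients -- to float32 precision."""
    from lesionft.nn.ops import BatchNorm, Conv3x3, ConvBNReLU, ReLU
    rng = np.random.default_rng(0)
    fused = ConvBNReLU(4, 5, 2, np.random.default_rng(42))
    conv = Conv3x3(4, 5, 2, np.random.default_rng(0))
    conv.W = fused.W.copy()
    bn, relu = BatchNorm(5), ReLU()
    bn.gamma = fused.gamma = fused.gamma + np.float32(0.3)
    bn.beta = fused.beta = fused.beta + np.float32(0.1)

    x = rng.standard_normal((3, 7, 6, 4)).astype(F32)
    y_fused = fused.forward_train(x).copy()
    y_ref = relu.forward(bn.forward(conv.forward(x, True), True, True), True)
    np.testing.assert_allclose(y_fused, y_ref, atol=2e-6)
    np.testing.assert_allclose(fused.running_mean, bn.running_mean, atol=1e-6)

    dy = rng.standard_normal(y_fused.shape).astype(F32)
    dx_fused = fused.backward(dy.copy(), need_dx=True).copy()
    dx_ref = conv.backward(bn.backward(relu.backward(dy.copy())), True)
    np.testing.assert_allclose(dx_fused, dx_ref, atol=2e-6)
    np.testing.assert_allclose(fused.dW, conv.dW, atol=2e-5)
    np.testing.assert_allclose(fused.dgamma, bn.dgamma, atol=2e-6)
    np.testing.assert_allclose(fused.dbeta, bn.dbeta, atol=2e-6)

    y_fused = fused.forward_eval(x).copy()
    y_ref = np.maximum(bn.forward(conv.forward(x, False), False, False), 0)
    np.testing.assert_allclose(y_fused, y_ref, atol=2e-6)


def test_gradients_match_finite_differences_on_shallow_paths():
    """Central differences confirm analytic gradients for first-layer and
    head parameters (short chains keep float32 finite-difference noise
    manageable; deep-path gradients are covered by the layer-composition
    test above plus the chain rule)."""
    cfg = ModelConfig(channels_per_pathway=(2, 1), kernels_per_conv=3,
                      head_channels=(4, 2), dropout_rate=0.0)
    net = build_model(cfg, np.random.default_rng(0))
    rng = np.random.default_rng(1)
    xa, xb = _inputs(rng, 2, 6, 6)
    y = (rng.random((2, 6, 6)) < 0.3).astype(np.int64)

    def loss(backward=False):
        logits = net.forward(xa, xb, mode="train")
        p = softmax(logits.astype(np.float64))
        L = -np.log(np.take_along_axis(p, y[..., None], -1)).mean()
        if backward:
            onehot = np.eye(2)[y]
            net.backward(((p - onehot) / y.size).astype(F32))
        return L

    loss(backward=True)
    params, grads_fn = net.trainable()
    grads = [g.copy() for g in grads_fn()]
    idx_rng = np.random.default_rng(2)
    # first conv of each pathway and the three head parameter tensors
    for pi in (0, 39, 78, 79, 80):
        p = params[pi]
        for _ in range(3):
            idx = tuple(idx_rng.integers(0, s) for s in p.shape)
            old = p[idx]
            eps = 1e-3
            p[idx] = old + eps
            lp = loss()
            p[idx] = old - eps
            lm = loss()
            p[idx] = old
            num = (lp - lm) / (2 * eps)
            assert num == pytest.approx(float(grads[pi][idx]),
                                        rel=0.05, abs=1e-3)


def test_checkpoint_roundtrip_preserves_state_and_config(tmp_path,
                                                         tiny_model_cfg, net):
    path = tmp_path / "model.npz"
    save_checkpoint(net, path, meta={"stage": "test", "seed": 1})
    back, meta = load_checkpoint(path)
    assert meta == {"stage": "test", "seed": 1}
    assert back.config == tiny_model_cfg
    for k, v in net.state_arrays().items():
        np.testing.assert_array_equal(v, back.state_arrays()[k])
    rng = np.random.default_rng(8)
    xa, xb = _inputs(rng, 1, 12, 12)
    np.testing.assert_array_equal(net.forward(xa, xb, mode="eval"),
                                  back.forward(xa, xb, mode="eval"))


def test_training_loss_gradient_matches_plain_ce_when_unweighted():
    rng = np.random.default_rng(0)
    logits = rng.standard_normal((2, 5, 5, 2)).astype(F32)
    y = (rng.random((2, 5, 5)) < 0.5).astype(np.int64)
    loss, dl = softmax_ce_loss_grad(logits, y, class_weights=(1.0, 1.0))
    p = softmax(logits.astype(np.float64))
    onehot = np.eye(2)[y]
    np.testing.assert_allclose(dl, (p - onehot) / y.size, atol=1e-6)
    expected = -np.log(np.take_along_axis(p, y[..., None], -1)).mean()
    assert loss == pytest.approx(expected, rel=1e-5)
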