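"""Architecture contracts: shapes, channel bookkeeping, residual identities,
gradient flow, and evaluation-mode determinism."""

import numpy as np
import pytest

from triunet.networks import (
    BasicBlock,
    ConfigurationError,
    NetworkConfig,
    ResNet34_3D,
    TribleResBlock,
    TriUNet,
    UNet3D,
    build_resnet34_3d,
    build_triunet,
    build_unet3d_baseline,
    conv_block,
    load_checkpoint,
    predict_age,
    save_checkpoint,
)
from triunet.nn import tensor as T
from triunet.nn.tensor import Tensor

from conftest import tiny_network_config


def _x(rng, shape):
    return Tensor(rng.normal(size=shape).astype(np.float32))


# -- conv_block ---------------------------------------------------------------

def test_conv_block_shape_and_zero_input(rng):
    blk = conv_block(8, 16, np.random.default_rng(0))
    y = blk(_x(rng, (2, 6, 6, 6, 8)))
    assert y.shape == (2, 6, 6, 6, 16)
    y0 = blk(Tensor(np.zeros((1, 6, 6, 6, 8), dtype=np.float32)))
    assert np.all(np.isfinite(y0.data))


def test_conv_block_seeded_build_determinism(rng):
    x = _x(rng, (1, 6, 6, 6, 4))
    y1 = conv_block(4, 8, np.random.default_rng(3))(x)
    y2 = conv_block(4, 8, np.random.default_rng(3))(x)
    assert np.array_equal(y1.data, y2.data)


# -- basic_block --------------------------------------------------------------

def test_zeroed_basic_block_is_identity(rng):
    blk = BasicBlock(8, 8, np.random.default_rng(0))
    for _, p in blk.named_parameters():
        p.data[...] = 0.0 if p.data.ndim > 1 else p.data * 0.0
    # group-norm gains stay at their zeroed value too: conv output is zero,
    # normalization of zeros emits the (zero) shift, so the sum is the skip
    x = _x(rng, (2, 4, 4, 4, 8))
    y = blk(x)
    assert np.array_equal(y.data, x.data)


def test_basic_block_preserves_shape(rng):
    blk = BasicBlock(16, 16, np.random.default_rng(1))
    y = blk(_x(rng, (1, 8, 8, 8, 16)))
    assert y.shape == (1, 8, 8, 8, 16)


def test_basic_block_every_parameter_gets_gradient(rng):
    blk = BasicBlock(4, 6, np.random.default_rng(2))
    x = _x(rng, (2, 4, 4, 4, 4))
    loss = T.mean_all(T.square(blk(x)))
    loss.backward()
    for name, p in blk.named_parameters():
        assert p.grad is not None and np.any(p.grad != 0), name


def test_basic_block_gradient_matches_finite_difference(rng):
    """Spot-check autodiff through the full block on a few parameters."""
    blk = BasicBlock(3, 3, np.random.default_rng(4))
    x = _x(rng, (1, 4, 4, 4, 3))

    def loss_val():
        return T.mean_all(T.square(blk(x))).data.item()

    loss = T.mean_all(T.square(blk(x)))
    loss.backward()
    probes = [("stage1.layer0.weight", (0, 0, 0, 0, 0)), ("stage2.layer0.weight", (1, 1, 1, 1, 1)),
              ("stage1.layer1.gamma", (0,))]
    params = dict(blk.named_parameters())
    for name, idx in probes:
        p = params[name]
        ana = p.grad[idx]
        eps = 1e-3
        orig = p.data[idx]
        p.data[idx] = orig + eps
        up = loss_val()
        p.data[idx] = orig - eps
        dn = loss_val()
        p.data[idx] = orig
        num = (up - dn) / (2 * eps)
        assert abs(num - ana) / max(abs(num), abs(ana), 1e-4) < 5e-2, name


# -- Trible Res Block ---------------------------------------------------------

def test_trible_res_block_channel_arithmetic(rng):
    trb = TribleResBlock(8, 8, np.random.default_rng(0))
    y = trb(_x(rng, (2, 16, 16, 16, 8)))
    assert y.shape == (2, 16, 16, 16, 8 + 2 * 8)


def test_trible_res_block_identity_path_is_verbatim(rng):
    trb = TribleResBlock(4, 2, np.random.default_rng(1))
    x = _x(rng, (1, 8, 8, 8, 4))
    y = trb(x)
    assert np.array_equal(y.data[..., :4], x.data)


def test_trible_res_block_rejects_odd_spatial(rng):
    trb = TribleResBlock(4, 2, np.random.default_rng(1))
    with pytest.raises(ValueError, match="even"):
        trb(_x(rng, (1, 15, 15, 15, 4)))
    with pytest.raises(ValueError, match=">= 4"):
        trb(_x(rng, (1, 2, 2, 2, 4)))


# -- built networks -----------------------------------------------------------

def test_triunet_forward_batch_of_four_gives_four_scalars(rng):
    net = build_triunet(NetworkConfig(seed=0))
    y = net(_x(rng, (4, 32, 32, 32, 1)))
    assert y.shape == (4,)
    assert np.all(np.isfinite(y.data))


def test_identical_configs_build_identical_networks(rng):
    cfg = tiny_network_config(seed=5)
    n1, n2 = build_triunet(cfg), build_triunet(cfg)
    assert n1.n_parameters() == n2.n_parameters()
    x = _x(rng, (2, 16, 16, 16, 1))
    assert np.array_equal(n1(x).data, n2(x).data)


def test_unet_baseline_is_strict_submodel_of_triunet():
    cfg = tiny_network_config()
    assert build_unet3d_baseline(cfg).n_parameters() < build_triunet(cfg).n_parameters()


def test_unet_baseline_forward(rng):
    net = build_unet3d_baseline(tiny_network_config())
    y = net(_x(rng, (2, 16, 16, 16, 1)))
    assert y.shape == (2,) and np.all(np.isfinite(y.data))


@pytest.mark.parametrize("builder", [build_triunet, build_unet3d_baseline])
def test_every_parameter_receives_gradient(rng, builder):
    net = builder(tiny_network_config(seed=1))
    y = net(_x(rng, (2, 16, 16, 16, 1)))
    T.mean_all(T.square(y)).backward()
    dead = [n for n, p in net.named_parameters() if p.grad is None or not np.any(p.grad)]
    assert dead == []


def test_config_validation():
    with pytest.raises(ConfigurationError, match="divisible"):
        NetworkConfig(input_edge=20, depth=3)
    with pytest.raises(ConfigurationError, match=">= 16"):
        NetworkConfig(input_edge=8, depth=1)


# -- ResNet34-3D --------------------------------------------------------------

def test_resnet34_multichannel_forward(rng):
    net = build_resnet34_3d(in_channels=2, input_edge=32, width=8)
    y = net(_x(rng, (3, 32, 32, 32, 2)))
    assert y.shape == (3,) and np.all(np.isfinite(y.data))


def test_resnet34_first_layer_only_depends_on_in_channels():
    n1 = build_resnet34_3d(in_channels=1, input_edge=32, width=8, seed=0)
    n2 = build_resnet34_3d(in_channels=2, input_edge=32, width=8, seed=0)
    p1, p2 = dict(n1.named_parameters()), dict(n2.named_parameters())
    diff = [k for k in p1 if p1[k].data.shape != p2[k].data.shape]
    assert diff == ["stem.layer0.weight"]


def test_resnet34_minimum_edge_error_names_bound():
    with pytest.raises(ConfigurationError, match="16"):
        build_resnet34_3d(in_channels=1, input_edge=8)


def test_resnet34_channel_permutation_symmetry(rng):
    """With first-layer weights copied across channels, swapping the two
    input channels cannot change the prediction."""
    net = build_resnet34_3d(in_channels=2, input_edge=16, width=8, seed=0)
    wname = "stem.layer0.weight"
    params = dict(net.named_parameters())
    w = params[wname]
    w.data[:, :, :, 1, :] = w.data[:, :, :, 0, :]
    x = rng.normal(size=(2, 16, 16, 16, 2)).astype(np.float32)
    y1 = predict_age(net, x)
    y2 = predict_age(net, x[..., ::-1])
    assert np.allclose(y1, y2, atol=1e-4)


def test_resnet34_gradient_flow(rng):
    net = build_resnet34_3d(in_channels=1, input_edge=16, width=8, seed=2)
    y = net(_x(rng, (2, 16, 16, 16, 1)))
    T.mean_all(T.square(y)).backward()
    dead = [n for n, p in net.named_parameters() if p.grad is None or not np.any(p.grad)]
    assert dead == []


# -- predict_age --------------------------------------------------------------

def test_predictions_independent_of_batch_composition(rng):
    net = build_triunet(tiny_network_config(seed=3))
    vol = rng.normal(size=(16, 16, 16, 1)).astype(np.float32)
    batch = np.repeat(vol[None], 4, axis=0)
    preds = predict_age(net, batch)
    assert np.allclose(preds, preds[0], atol=1e-5)
    singles = np.array([predict_age(net, vol[None])[0] for _ in range(4)])
    assert np.allclose(preds, singles, atol=1e-4)


def test_predict_age_wrong_edge_raises(rng):
    net = build_triunet(tiny_network_config())
    with pytest.raises(ValueError, match="expected"):
        predict_age(net, rng.normal(size=(1, 32, 32, 32, 1)).astype(np.float32))


def test_partitioned_batches_match_full_batch(rng):
    net = build_triunet(tiny_network_config(seed=4))
    batch = rng.normal(size=(4, 16, 16, 16, 1)).astype(np.float32)
    full = predict_age(net, batch, batch_size=4)
    parts = np.concatenate([predict_age(net, batch[i : i + 1]) for i in range(4)])
    assert np.allclose(full, parts, atol=1e-4)


# -- checkpointing ------------------------------------------------------------

def test_checkpoint_roundtrip_preserves_predictions(tmp_path, rng):
    cfg = tiny_network_config(seed=6)
    net = build_triunet(cfg)
    x = rng.normal(size=(2, 16, 16, 16, 1)).astype(np.float32)
    before = predict_age(net, x)
    save_checkpoint(net, "triunet", cfg, tmp_path / "ck.npz")
    net2, name, cfg2 = load_checkpoint(tmp_path / "ck.npz")
    assert name == "triunet" and cfg2 == cfg
    assert np.array_equal(predict_age(net2, x), before)


def test_network_summary_lists_parameters():
    net = build_triunet(tiny_network_config())
    text = net.summary()
    assert "parameters" in text and "head" in text
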