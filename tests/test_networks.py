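"""Architecture contracts of the two generators and the discriminator."""

import numpy as np
import pytest

from trisr.networks import (RFB, DiscriminatorSpec, GeneratorSpec,
                            NoiseInjection, build_discriminator,
                            build_generator, contains_transposed_conv,
                            load_generator, save_checkpoint)
from trisr.nn import autograd as ag
from trisr.nn.autograd import Tensor, resize_linear


def test_stage1_generator_doubles_patch_size(toy_g1_spec, rng):
    g = build_generator(toy_g1_spec, seed=0).eval()
    y = g(Tensor(rng.random((2, 1, 16, 16))))
    assert y.shape == (2, 1, 32, 32)
    assert np.isfinite(y.data).all()
    assert y.data.min() >= 0.0 and y.data.max() <= 1.0


@pytest.mark.parametrize("hw", [(64, 64), (63, 63), (17, 29)])
def test_restoration_generator_preserves_size_including_odd(toy_g2_spec, rng, hw):
    g = build_generator(toy_g2_spec, seed=0)
    x = rng.random((1, 1, *hw))
    assert g(Tensor(x)).shape == (1, 1, *hw)


def test_zero_init_stage1_reduces_to_plain_interpolation(toy_g1_spec, rng):
    """At init the residual path is dead: output == bicubic x2 of the input."""
    from trisr.resample import resize_2d
    g = build_generator(toy_g1_spec, seed=3).eval()   # clamped inference path
    x = rng.random((2, 1, 12, 14))
    for n in range(2):
        ref = np.clip(resize_2d(x[n, 0], (24, 28), kernel="cubic"), 0, 1)
        assert np.abs(g(Tensor(x)).data[n, 0] - ref).max() <= 1e-6


def test_zero_init_restoration_network_is_identity(toy_g2_spec, rng):
    g = build_generator(toy_g2_spec, seed=3)
    x = rng.random((1, 1, 21, 17))
    assert np.abs(g(Tensor(x)).data - x).max() <= 1e-6


def test_noise_injection_zero_strength_is_bitwise_noop(rng):
    ni = NoiseInjection(4, seed=9)
    x = rng.random((2, 4, 6, 6))
    assert np.array_equal(ni(Tensor(x)).data, x)


def test_noise_injection_seeded_and_frozen_behaviour(rng):
    ni = NoiseInjection(4, seed=9)
    ni.strength.data[:] = 1.0
    x = rng.random((1, 4, 6, 6))
    a = ni(Tensor(x)).data            # training: fresh draws
    b = ni(Tensor(x)).data
    assert not np.array_equal(a, b)
    ni.eval()
    c = ni(Tensor(x)).data            # eval: frozen noise
    d = ni(Tensor(x)).data
    assert np.array_equal(c, d)
    # rebuilding with the same seed reproduces the same frozen noise
    ni2 = NoiseInjection(4, seed=9)
    ni2.strength.data[:] = 1.0
    ni2.eval()
    assert np.array_equal(c, ni2(Tensor(x)).data)


def test_nesrgan_with_noise_is_deterministic_in_eval(toy_g2_spec, rng):
    g = build_generator(toy_g2_spec, seed=1)
    for ni in (m for m in g.modules() if isinstance(m, NoiseInjection)):
        ni.strength.data[:] = 0.5
    # open the residual path (zero-initialized by default) so noise reaches
    # the output at all
    g.conv_last.weight.data[:] = np.random.default_rng(0).normal(
        0, 0.05, g.conv_last.weight.data.shape)
    g.eval()
    x = rng.random((1, 1, 20, 20))
    assert np.array_equal(g(Tensor(x)).data, g(Tensor(x)).data)
    g.train()
    assert not np.array_equal(g(Tensor(x), clamp=True).data,
                              g(Tensor(x), clamp=True).data)


def test_no_transposed_convolution_in_restoration_network(toy_g2_spec):
    g = build_generator(toy_g2_spec, seed=0)
    assert not contains_transposed_conv(g)


def test_rfb_block_preserves_shape_and_residual_identity(rng):
    rfb = RFB(8, np.random.default_rng(0))
    rfb.fuse.weight.data[:] = 0.0        # dead fuse -> pure residual
    x = rng.random((1, 8, 10, 12))
    assert np.array_equal(rfb(Tensor(x)).data, x)
    rfb2 = RFB(8, np.random.default_rng(1))
    assert rfb2(Tensor(x)).shape == (1, 8, 10, 12)


def test_gradient_reaches_every_rfb_branch(rng):
    rfb = RFB(8, np.random.default_rng(2))
    x = Tensor(rng.random((2, 8, 9, 9)), requires_grad=True)
    loss = ag.tmean(ag.tabs(rfb(x)))
    loss.backward()
    for name, p in rfb.named_parameters():
        assert p.grad is not None and np.any(p.grad != 0), (
            f"no gradient reached branch parameter {name}")


def test_parameter_count_is_monotone_in_depth():
    def n_params(depth):
        return build_generator(GeneratorSpec(
            kind="nesrgan", n_rrdb=depth, base_channels=8, growth=4,
            scale=1, noise=True), seed=0).n_parameters()
    assert n_params(1) < n_params(2) < n_params(3)


def test_spc_and_nni_upsampler_arithmetic(rng):
    from trisr.networks import UpsampleStage
    # sub-pixel: channels /4, spatial x2, for an identity-free check use
    # the raw pixel_shuffle op
    x = rng.random((1, 8, 5, 5))
    assert ag.pixel_shuffle(Tensor(x), 2).shape == (1, 2, 10, 10)
    st = UpsampleStage(4, "nni", np.random.default_rng(0))
    y = st(Tensor(rng.random((1, 4, 6, 6))))
    assert y.shape == (1, 4, 12, 12)
    st2 = UpsampleStage(4, "spc", np.random.default_rng(0))
    assert st2(Tensor(rng.random((1, 4, 6, 6)))).shape == (1, 4, 12, 12)


def test_scale4_generator_uses_alternating_upsample_stages(rng):
    g = build_generator(GeneratorSpec(kind="rfb_esrgan", n_rrdb=1, n_rrfdb=0,
                                      base_channels=8, growth=4, scale=4),
                        seed=0).eval()
    y = g(Tensor(rng.random((1, 1, 8, 8))))
    assert y.shape == (1, 1, 32, 32)
    modes = [g._modules[f"up{j}"].mode for j in range(2)]
    assert modes == ["nni", "spc"]   # NNI then sub-pixel as the final stage


@pytest.mark.parametrize("bad", [
    dict(kind="nesrgan", scale=2),
    dict(kind="rfb_esrgan", noise=True),
    dict(n_rrdb=0),
    dict(scale=3),
    dict(kind="unknown"),
])
def test_invalid_generator_specs_rejected(bad):
    with pytest.raises(ValueError):
        build_generator(GeneratorSpec(**bad), seed=0)


# -- discriminator ----------------------------------------------------------

def small_disc(input_size=16):
    return build_discriminator(
        DiscriminatorSpec(feature_widths=(8, 16), input_size=input_size),
        seed=0)


def test_discriminator_emits_one_logit_per_image(rng):
    d = small_disc()
    y = d(Tensor(rng.random((4, 1, 16, 16))))
    assert y.shape == (4,)
    assert np.isfinite(y.data).all()


def test_discriminator_duplicated_inputs_give_duplicated_logits(rng):
    d = small_disc()
    d.eval()   # batch statistics must not couple distinct rows
    x = rng.random((1, 1, 16, 16))
    batch = np.concatenate([x, x], axis=0)
    y = d(Tensor(batch)).data
    assert y[0] == pytest.approx(y[1], abs=1e-12)


def test_discriminator_handles_all_zero_input():
    d = small_disc()
    assert np.isfinite(d(Tensor(np.zeros((2, 1, 16, 16)))).data).all()


def test_discriminator_reports_minimal_valid_size():
    with pytest.raises(ValueError, match="minimal valid size is 4"):
        build_discriminator(
            DiscriminatorSpec(feature_widths=(8, 16), input_size=10))
    with pytest.raises(ValueError):
        build_discriminator(DiscriminatorSpec(feature_widths=(8, 12)))


# -- checkpoints ------------------------------------------------------------

def test_checkpoint_round_trip_preserves_outputs(tmp_path, toy_g2_spec, rng):
    g = build_generator(toy_g2_spec, seed=5)
    for p in g.parameters():
        p.data += rng.normal(0, 0.01, p.data.shape)
    x = rng.random((1, 1, 12, 12))
    g.eval()
    before = g(Tensor(x)).data
    save_checkpoint(g, tmp_path / "g.npz", spec=toy_g2_spec)
    # same build seed so the frozen noise streams are reproduced as well
    g2 = load_generator(tmp_path / "g.npz", seed=5)
    g2.eval()
    assert np.array_equal(g2(Tensor(x)).data, before)
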