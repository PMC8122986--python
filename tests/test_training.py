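"""Two-stage training schedule and the two-pass reconstruction pipeline."""

import numpy as np
import pytest

from trisr.losses import LossWeights, adversarial_d_loss
from trisr.networks import (DiscriminatorSpec, GeneratorSpec,
                            build_discriminator, build_generator,
                            load_checkpoint, save_checkpoint)
from trisr.nn import Adam
from trisr.nn.autograd import Tensor
from trisr.phantom import PhantomSpec, generate_phantom
from trisr.slicing import decimate, extract_slices, make_patch_pairs
from trisr.training import (TrainConfig, first_pass, reconstruct_volume,
                            second_pass_plane_policy, train_gan, train_stage1)
from trisr.volume_io import PLANES, Volume, downscale_volume

FAST_G1 = dict(kind="rfb_esrgan", n_rrdb=1, n_rrfdb=0, base_channels=8,
               growth=4, scale=2)
SMALL_DISC = DiscriminatorSpec(feature_widths=(8, 16), input_size=32)


@pytest.fixture(scope="module")
def toy_pairs():
    vol = generate_phantom(PhantomSpec(shape=(40, 40, 36), n_blobs=6, seed=2))
    pairs = []
    for plane in PLANES:
        stack = decimate(extract_slices(vol, plane), 1)
        pairs.extend(make_patch_pairs(stack, lr_size=16, stride=8))
    return pairs


def test_zero_iterations_leaves_initialization_untouched(toy_pairs, tmp_path):
    spec = GeneratorSpec(**FAST_G1)
    cfg = TrainConfig(stage="pretrain_l1", iters=0, seed=3,
                      generator_spec=spec, checkpoint_dir=tmp_path)
    gen, history = train_stage1(toy_pairs, cfg)
    assert history == []
    ref = build_generator(spec, seed=3)
    for (_, a), (_, b) in zip(gen.named_parameters(), ref.named_parameters()):
        assert np.array_equal(a.data, b.data)
    # checkpoint written and loadable
    header, state = load_checkpoint(tmp_path / "stage1.npz")
    assert header["spec"]["kind"] == "rfb_esrgan"


def test_short_stage1_training_reduces_running_l1(toy_pairs):
    cfg = TrainConfig(stage="pretrain_l1", iters=60, lr=1e-3, batch_size=8,
                      seed=0, generator_spec=GeneratorSpec(**FAST_G1))
    _, history = train_stage1(toy_pairs, cfg)
    assert np.mean(history[-10:]) < np.mean(history[:10])
    assert all(np.isfinite(history))


def test_training_is_deterministic_under_seed(toy_pairs):
    cfg = TrainConfig(stage="pretrain_l1", iters=8, lr=1e-3, batch_size=8,
                      seed=9, generator_spec=GeneratorSpec(**FAST_G1))
    g1, h1 = train_stage1(toy_pairs, cfg)
    g2, h2 = train_stage1(toy_pairs, cfg)
    assert h1 == h2
    for (_, a), (_, b) in zip(g1.named_parameters(), g2.named_parameters()):
        assert np.array_equal(a.data, b.data)


def test_empty_dataset_rejected():
    cfg = TrainConfig(generator_spec=GeneratorSpec(**FAST_G1))
    with pytest.raises(ValueError):
        train_stage1([], cfg)


def test_gan_with_zero_adversarial_weight_matches_continued_stage1(
        toy_pairs, tmp_path):
    """With lambda=0, eta=1 and no perceptual term the GAN stage follows the
    same trajectory as plain L1 training from the same checkpoint."""
    spec = GeneratorSpec(**FAST_G1)
    cfg0 = TrainConfig(stage="pretrain_l1", iters=10, lr=1e-3, batch_size=8,
                       seed=5, generator_spec=spec, checkpoint_dir=tmp_path)
    train_stage1(toy_pairs, cfg0)
    ckpt = tmp_path / "stage1.npz"

    cfg_l1 = TrainConfig(stage="pretrain_l1", iters=6, lr=1e-3, batch_size=8,
                         seed=5, generator_spec=spec)
    g_l1, _ = train_stage1(toy_pairs, cfg_l1, init_ckpt=ckpt)

    w = LossWeights(lambda_adv=0.0, eta_pix=1.0, perceptual=0.0)
    cfg_gan = TrainConfig(stage="gan_finetune", iters=6, lr=1e-3, batch_size=8,
                          seed=5, generator_spec=spec, loss_weights=w)
    g_gan, _, hist = train_gan(toy_pairs, cfg_gan, ckpt, disc_spec=SMALL_DISC)
    for (_, a), (_, b) in zip(g_l1.named_parameters(), g_gan.named_parameters()):
        assert np.allclose(a.data, b.data, atol=1e-12)
    assert all(np.isfinite(h["total"]) for h in hist)


def test_gan_requires_existing_stage1_checkpoint(toy_pairs, tmp_path):
    cfg = TrainConfig(stage="gan_finetune",
                      generator_spec=GeneratorSpec(**FAST_G1))
    with pytest.raises(FileNotFoundError):
        train_gan(toy_pairs, cfg, tmp_path / "missing.npz")


def test_discriminator_alone_learns_to_separate_real_from_fake(toy_pairs, rng):
    """Training D on a frozen generator decreases the relativistic D loss."""
    hr = np.stack([p.hr for p in toy_pairs[:16]])[:, None]
    fake = np.stack([p.lr.repeat(2, 0).repeat(2, 1)
                     for p in toy_pairs[:16]])[:, None]   # blocky fakes
    disc = build_discriminator(SMALL_DISC, seed=1)
    disc.train()
    opt = Adam(disc.parameters(), lr=1e-3)
    losses = []
    for _ in range(60):
        loss = adversarial_d_loss(disc(Tensor(hr)), disc(Tensor(fake)))
        opt.zero_grad()
        loss.backward()
        opt.step()
        losses.append(loss.item())
    assert np.mean(losses[-10:]) < np.mean(losses[:10])
    assert all(np.isfinite(losses))


# -- reconstruction pipeline ------------------------------------------------

def identity_generators(seed=0):
    g1 = build_generator(GeneratorSpec(**FAST_G1), seed=seed)
    g2 = build_generator(GeneratorSpec(kind="nesrgan", n_rrdb=1,
                                       base_channels=8, growth=4, scale=1),
                         seed=seed)
    return g1, g2


@pytest.mark.parametrize("shape", [(16, 16, 9), (9, 11, 5)])
def test_reconstruction_doubles_every_dimension(shape, rng):
    lr_vol = Volume(rng.random(shape))
    g1, g2 = identity_generators()
    out = reconstruct_volume(lr_vol, g1, g2)
    assert out.shape == tuple(2 * s for s in shape)
    assert np.isfinite(out.voxels).all()


def test_intermediate_missing_fraction_is_one_eighth(rng):
    lr_vol = Volume(rng.random((12, 12, 7)))
    g1, _ = identity_generators()
    rv = first_pass(lr_vol, g1)
    assert rv.missing_mask.mean() == pytest.approx(1.0 / 8.0)


def test_identity_init_pipeline_reduces_to_interpolated_rebuild(rng):
    """Zero-init generators: pass 1 is bicubic x2 per slice, pass 2 is the
    identity, so the output equals the bicubic-interpolated rebuild."""
    from trisr.reassembly import rebuild
    from trisr.resample import resize_2d
    from trisr.slicing import SliceStack

    lr_vol = Volume(rng.random((10, 10, 6)))
    g1, g2 = identity_generators(seed=4)
    out, rv = reconstruct_volume(lr_vol, g1, g2, return_intermediate=True)

    stacks = []
    for plane in PLANES:
        stack = extract_slices(lr_vol, plane)
        ups = [np.clip(resize_2d(s, tuple(2 * d for d in s.shape), "cubic"),
                       0, 1) for s in stack.slices]
        shape = [2 * d for d in lr_vol.shape]
        stacks.append(SliceStack(plane=plane, slices=ups,
                                 source_indices=[2 * i for i in
                                                 stack.source_indices],
                                 source_shape=tuple(shape)))
    expected = rebuild(stacks, tuple(2 * d for d in lr_vol.shape))
    assert np.allclose(rv.voxels, expected.voxels, atol=1e-12)
    # pass 2 with an identity network returns the rebuilt volume unchanged
    assert np.allclose(out.voxels, np.clip(expected.voxels, 0, 1), atol=1e-12)


def test_pipeline_end_to_end_determinism(rng):
    lr_vol = Volume(rng.random((10, 10, 6)))
    g1 = build_generator(GeneratorSpec(**FAST_G1), seed=8)
    g2 = build_generator(GeneratorSpec(kind="nesrgan", n_rrdb=1,
                                       base_channels=8, growth=4, scale=1,
                                       noise=True), seed=8)
    a = reconstruct_volume(lr_vol, g1, g2)
    b = reconstruct_volume(lr_vol, g1, g2)
    assert np.array_equal(a.voxels, b.voxels)


def test_generator_scale_contracts_enforced(rng):
    lr_vol = Volume(rng.random((8, 8, 8)))
    g1, g2 = identity_generators()
    with pytest.raises(ValueError):
        reconstruct_volume(lr_vol, g2, g2)   # wrong first-pass scale
    with pytest.raises(ValueError):
        reconstruct_volume(lr_vol, g1, g1)   # wrong second-pass scale


def test_second_pass_plane_policy(rng):
    vol = Volume(rng.random((10, 10, 6)))
    _, g2 = identity_generators(seed=2)
    # identity network, any plane subset: output equals input
    for planes in (("axial",), PLANES):
        out = second_pass_plane_policy(vol, g2, planes=planes)
        assert np.allclose(out.voxels, vol.voxels, atol=1e-12)
    with pytest.raises(ValueError):
        second_pass_plane_policy(vol, g2, planes=())
    with pytest.raises(ValueError):
        second_pass_plane_policy(vol, g2, planes=("oblique",))
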