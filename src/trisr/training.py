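"""Two-stage training schedule and the two-pass volume reconstruction.

Stage 1 pretrains the super-resolution generator with the pixel L1 loss
alone; stage 2 initializes from the stage-1 checkpoint and fine-tunes with
the composite loss (perceptual + relativistic adversarial + pixel) against a
freshly initialized discriminator, alternating D and G steps.  Reconstruction
follows the two-pass protocol: every slice of the half-resolution volume in
all three planes is super-resolved x2 and re-placed at its (even) source
index, producing a rebuilt volume with 1/8 missing voxels; the second pass
runs the restoration generator over every slice of every plane of that
rebuilt volume and merges the full stacks, leaving no missing voxels.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .losses import (LossWeights, adversarial_d_loss, generator_total,
                     identity_extractor, pixel_l1)
from .networks import (DiscriminatorSpec, GeneratorSpec, build_discriminator,
                       build_generator, load_generator, save_checkpoint)
from .nn import Adam
from .nn.autograd import Tensor
from .reassembly import ReassembledVolume, rebuild
from .slicing import PatchPair, SliceStack, extract_slices
from .volume_io import PLANES, Volume

log = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    stage: str = "pretrain_l1"          # or "gan_finetune"
    batch_size: int = 16
    lr: float = 1e-4                    # stage-2 default is 1e-5
    iters: int = 1000
    seed: int = 0
    generator_spec: GeneratorSpec = field(default_factory=GeneratorSpec)
    loss_weights: LossWeights = field(default_factory=LossWeights)
    checkpoint_dir: str | Path | None = None
    log_every: int = 10

    def validate(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.stage not in ("pretrain_l1", "gan_finetune"):
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.iters < 0:
            raise ValueError("iters must be >= 0")


def _to_batches(pairs: list[PatchPair]):
    lr = np.stack([p.lr for p in pairs])[:, None, :, :]
    hr = np.stack([p.hr for p in pairs])[:, None, :, :]
    return lr, hr


def _batch_iter(n: int, batch_size: int, rng: np.random.Generator):
    while True:
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            if len(idx) == batch_size:
                yield idx


def _write_log(log_path, record: dict):
    if log_path is not None:
        with open(log_path, "a") as fh:
            fh.write(json.dumps(record) + "\n")


def train_stage1(pairs: list[PatchPair], cfg: TrainConfig,
                 init_ckpt=None):
    """L1-only pretraining; returns (generator, history of per-step L1).

    ``history`` holds the raw per-step batch losses; an exponentially
    smoothed running L1 is also written to the JSONL log.  Loss-reduction
    claims should compare windowed means of the history (single steps are
    noisy single-batch estimates).
    """
    cfg.validate()
    if not pairs:
        raise ValueError("empty training dataset")
    lr_all, hr_all = _to_batches(pairs)
    gen = (load_generator(init_ckpt, seed=cfg.seed) if init_ckpt
           else build_generator(cfg.generator_spec, seed=cfg.seed))
    gen.train()
    opt = Adam(gen.parameters(), lr=cfg.lr)
    rng = np.random.default_rng(cfg.seed + 1)
    batches = _batch_iter(len(pairs), min(cfg.batch_size, len(pairs)), rng)

    ckpt_dir = Path(cfg.checkpoint_dir) if cfg.checkpoint_dir else None
    log_path = ckpt_dir / "stage1_log.jsonl" if ckpt_dir else None
    if ckpt_dir:
        ckpt_dir.mkdir(parents=True, exist_ok=True)

    history, running = [], None
    for step in range(cfg.iters):
        idx = next(batches)
        sr = gen(Tensor(lr_all[idx]), clamp=False)
        loss = pixel_l1(sr, Tensor(hr_all[idx]))
        opt.zero_grad()
        loss.backward()
        opt.step()
        val = loss.item()
        running = val if running is None else 0.95 * running + 0.05 * val
        history.append(val)
        if step % cfg.log_every == 0:
            _write_log(log_path, {"step": step, "l1": val, "running_l1": running})
    gen.eval()
    if ckpt_dir:
        save_checkpoint(gen, ckpt_dir / "stage1.npz", spec=cfg.generator_spec,
                        extra={"stage": "pretrain_l1", "iters": cfg.iters,
                               "seed": cfg.seed})
    return gen, history


def train_gan(pairs: list[PatchPair], cfg: TrainConfig, stage1_ckpt,
              feature_extractor=identity_extractor,
              disc_spec: DiscriminatorSpec | None = None):
    """GAN fine-tuning from a stage-1 checkpoint.

    Returns (generator, discriminator, history) where history is a list of
    per-step loss breakdowns.
    """
    cfg.validate()
    if not pairs:
        raise ValueError("empty training dataset")
    if isinstance(stage1_ckpt, (str, Path)):
        if not Path(stage1_ckpt).exists():
            raise FileNotFoundError(f"stage-1 checkpoint not found: {stage1_ckpt}")
        gen = load_generator(stage1_ckpt, seed=cfg.seed)
    else:
        gen = stage1_ckpt   # an already-built generator
    lr_all, hr_all = _to_batches(pairs)
    hr_size = hr_all.shape[2]
    if disc_spec is None:
        disc_spec = DiscriminatorSpec(input_size=hr_size)
    disc = build_discriminator(disc_spec, seed=cfg.seed + 7)
    gen.train()
    disc.train()
    g_opt = Adam(gen.parameters(), lr=cfg.lr)
    d_opt = Adam(disc.parameters(), lr=cfg.lr)
    rng = np.random.default_rng(cfg.seed + 1)
    batches = _batch_iter(len(pairs), min(cfg.batch_size, len(pairs)), rng)

    ckpt_dir = Path(cfg.checkpoint_dir) if cfg.checkpoint_dir else None
    log_path = ckpt_dir / "gan_log.jsonl" if ckpt_dir else None
    if ckpt_dir:
        ckpt_dir.mkdir(parents=True, exist_ok=True)

    history = []
    for step in range(cfg.iters):
        idx = next(batches)
        lr_b, hr_b = Tensor(lr_all[idx]), Tensor(hr_all[idx])

        # D step (generator output treated as constant)
        sr_const = Tensor(gen(lr_b, clamp=False).data)
        d_loss = adversarial_d_loss(disc(hr_b), disc(sr_const))
        d_opt.zero_grad()
        d_loss.backward()
        d_opt.step()

        # G step
        sr = gen(lr_b, clamp=False)
        logits_fake = disc(sr)
        logits_real = Tensor(disc(hr_b).data)
        g_loss, breakdown = generator_total(
            sr, hr_b, logits_real, logits_fake, cfg.loss_weights,
            feature_extractor=feature_extractor)
        g_opt.zero_grad()
        g_loss.backward()
        g_opt.step()

        breakdown["d_loss"] = d_loss.item()
        breakdown["step"] = step
        history.append(breakdown)
        if step % cfg.log_every == 0:
            _write_log(log_path, breakdown)
    gen.eval()
    disc.eval()
    if ckpt_dir:
        save_checkpoint(gen, ckpt_dir / "gan.npz", spec=cfg.generator_spec,
                        extra={"stage": "gan_finetune", "iters": cfg.iters,
                               "seed": cfg.seed})
    return gen, disc, history


# ---------------------------------------------------------------------------
# inference: per-slice application and the two-pass pipeline
# ---------------------------------------------------------------------------

def apply_to_stack(stack: SliceStack, gen, scale: int,
                   index_scale: int = 1) -> SliceStack:
    """Run a generator over every slice of a stack (whole-slice inference).

    ``index_scale`` multiplies source indices, mapping slice i of the
    half-resolution volume to index ``index_scale * i`` of the target grid.
    """
    out_slices = []
    gen.eval()
    for sl in stack.slices:
        y = gen(Tensor(sl[None, None, :, :]), clamp=True)
        out_slices.append(y.data[0, 0])
    shape = list(stack.source_shape)
    axis = stack.axis
    for i in range(3):
        if i != axis:
            shape[i] *= scale
    shape[axis] *= index_scale
    return SliceStack(plane=stack.plane, slices=out_slices,
                      source_indices=[index_scale * i
                                      for i in stack.source_indices],
                      source_shape=tuple(shape))


def first_pass(lr_vol: Volume, g1, merge: str = "mean") -> ReassembledVolume:
    """Per-plane x2 super-resolution of the half volume, rebuilt at 2x shape.

    Slice i along each plane of the half volume lands at even index 2i of
    the doubled grid, so voxels with all-odd coordinates stay missing.
    """
    scale = g1.spec.scale
    target = tuple(scale * s for s in lr_vol.shape)
    stacks = [apply_to_stack(extract_slices(lr_vol, p), g1, scale=scale,
                             index_scale=scale) for p in PLANES]
    return rebuild(stacks, target, merge=merge)


def second_pass_plane_policy(rebuilt: Volume, g2,
                             planes=PLANES, merge: str = "mean") -> Volume:
    """Apply the restoration generator to every slice of selected planes."""
    if not planes:
        raise ValueError("at least one plane must be selected")
    for p in planes:
        if p not in PLANES:
            raise ValueError(f"unknown plane {p!r}")
    stacks = [apply_to_stack(extract_slices(rebuilt, p), g2, scale=1)
              for p in planes]
    rv = rebuild(stacks, rebuilt.shape, merge=merge)
    assert not rv.missing_mask.any()
    return Volume(np.clip(rv.voxels, 0.0, 1.0))


def reconstruct_volume(lr_vol: Volume, g1, g2, merge: str = "mean",
                       planes=PLANES,
                       return_intermediate: bool = False):
    """Full two-pass reconstruction: half-resolution volume -> 2x volume."""
    if g1.spec.scale != 2:
        raise ValueError("first-pass generator must have scale 2")
    if g2.spec.scale != 1:
        raise ValueError("second-pass generator must have scale 1")
    rv = first_pass(lr_vol, g1, merge=merge)
    rebuilt = Volume(np.clip(rv.voxels, 0.0, 1.0))
    out = second_pass_plane_policy(rebuilt, g2, planes=planes, merge=merge)
    if return_intermediate:
        return out, rv
    return out
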