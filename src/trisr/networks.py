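"""Generator and discriminator architectures.

Two generators share the ESRGAN lineage:

* the stage-1 generator (``rfb_esrgan``) maps a low-resolution slice to 2x
  resolution through a trunk of residual-in-residual dense blocks (RRDB)
  followed by residual receptive-field dense blocks (RRFDB) whose multi-branch
  small/dilated kernels cheaply approximate a large receptive field, then a
  sub-pixel (or nearest-neighbor) upsampler;
* the stage-2 generator (``nesrgan``) restores a same-size slice: an
  interpolation-based entry downsampler halves the spatial extent so the
  trunk sees dense features, Gaussian noise with a learned per-channel scale
  (zero-initialized, hence an exact no-op at init) is injected after every
  dense block to seed high-frequency detail, and an interpolate-then-convolve
  upsampler restores the size.  No transposed convolution appears anywhere,
  which structurally rules out checkerboard artifacts.

Both generators carry a global interpolation skip whose final convolution is
zero-initialized, so a freshly built network is exactly its resampling path
(bilinear x2 for stage 1, the identity for stage 2); training only ever
learns a residual correction on top of that.  The shared discriminator is the
VGG-style stack of stride-1/stride-2 pairs ending in two fully connected
layers producing a single raw logit per image.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from math import ceil
from pathlib import Path

import numpy as np

from .nn import autograd as ag
from .nn.modules import BatchNorm2d, Conv2d, Dense, Module

GENERATOR_KINDS = ("rfb_esrgan", "nesrgan")
UPSAMPLE_MODES = ("nni_spc_alternating", "subpixel", "bilinear_conv")


@dataclass
class GeneratorSpec:
    kind: str = "rfb_esrgan"
    n_rrdb: int = 16
    n_rrfdb: int = 8            # rfb_esrgan only
    base_channels: int = 64
    growth: int = 32
    scale: int = 2              # 2 for stage 1, 1 for stage 2
    noise: bool = False         # nesrgan only
    upsample_mode: str = "nni_spc_alternating"
    entry_downsample: bool = True   # nesrgan: in-network 1/2 feature extraction

    def validate(self):
        if self.kind not in GENERATOR_KINDS:
            raise ValueError(f"unknown generator kind {self.kind!r}")
        if self.n_rrdb < 1:
            raise ValueError("n_rrdb must be >= 1")
        if self.scale not in (1, 2, 4):
            raise ValueError("scale must be one of 1, 2, 4")
        if self.noise and self.kind != "nesrgan":
            raise ValueError("noise injection is only valid for kind='nesrgan'")
        if self.upsample_mode not in UPSAMPLE_MODES:
            raise ValueError(f"unknown upsample mode {self.upsample_mode!r}")
        if self.kind == "nesrgan" and self.scale != 1:
            raise ValueError("nesrgan is a same-size restoration network (scale 1)")


@dataclass
class DiscriminatorSpec:
    feature_widths: tuple = (64, 128, 256, 512)
    input_size: int = 32
    kernel: int = 3
    hidden: int = 100
    in_channels: int = 1

    def validate(self):
        w = tuple(self.feature_widths)
        if len(w) < 1 or any(b != 2 * a for a, b in zip(w, w[1:])):
            raise ValueError("feature widths must strictly double")
        min_size = 2 ** len(w)
        if self.input_size % min_size != 0 or self.input_size < min_size:
            raise ValueError(
                f"input size {self.input_size} incompatible with the stride "
                f"stack; minimal valid size is {min_size} (and multiples)")


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

class NoiseInjection(Module):
    """features + strength (per channel) * eps,  eps ~ N(0, 1) per position.

    The strength is zero-initialized so the injection starts as an exact
    no-op.  In training mode fresh noise is drawn from the module rng; in
    eval mode noise is frozen (regenerated from a fixed seed), so repeated
    forwards are deterministic.
    """

    def __init__(self, channels: int, seed: int = 0):
        super().__init__()
        self.strength = ag.Tensor(np.zeros(channels), requires_grad=True)
        self.seed = int(seed)
        self.rng = np.random.default_rng(self.seed)

    def reseed(self, seed: int):
        self.seed = int(seed)
        self.rng = np.random.default_rng(self.seed)

    def forward(self, x):
        if self.training:
            eps = self.rng.standard_normal(x.shape)
        else:
            eps = np.random.default_rng(self.seed).standard_normal(x.shape)
        s = ag.reshape(self.strength, (1, x.shape[1], 1, 1))
        return x + ag.mul(s, ag.Tensor(eps))


class DenseBlock(Module):
    """Five densely connected 3x3 convolutions, residual-scaled by 0.2."""

    def __init__(self, channels: int, growth: int, rng, noise_seed=None):
        super().__init__()
        c, g = channels, growth
        for i in range(4):
            self.register(f"conv{i}", Conv2d(c + i * g, g, 3, rng=rng))
        self.register("conv4", Conv2d(c + 4 * g, c, 3, rng=rng))
        if noise_seed is not None:
            self.register("noise", NoiseInjection(c, seed=noise_seed))
        else:
            self.noise_mod = None

    def forward(self, x):
        feats = [x]
        for i in range(4):
            layer = self._modules[f"conv{i}"]
            feats.append(ag.leaky_relu(layer(ag.concat(feats, axis=1)), 0.2))
        out = self._modules["conv4"](ag.concat(feats, axis=1))
        if "noise" in self._modules:
            out = self._modules["noise"](out)
        return x + ag.mul(out, 0.2)


class RRDB(Module):
    """Residual-in-residual dense block: three dense blocks, outer residual."""

    def __init__(self, channels, growth, rng, noise_seeds=None):
        super().__init__()
        for i in range(3):
            seed = None if noise_seeds is None else noise_seeds[i]
            self.register(f"db{i}", DenseBlock(channels, growth, rng, seed))

    def forward(self, x):
        t = x
        for i in range(3):
            t = self._modules[f"db{i}"](t)
        return x + ag.mul(ag.add(t, ag.mul(x, -1.0)), 0.2)


class RFB(Module):
    """Receptive-field block: parallel small and dilated kernels.

    Branches: 1x1; 1x1-3x3; 1x1-3x3(dilation 3); 1x1-(1x3)-(3x1)-3x3
    (dilation 5); concatenated, fused by 1x1, residual-scaled by 0.2.
    """

    def __init__(self, channels: int, rng):
        super().__init__()
        ic = max(channels // 4, 1)
        self.register("b0", Conv2d(channels, ic, 1, rng=rng))
        self.register("b1a", Conv2d(channels, ic, 1, rng=rng))
        self.register("b1b", Conv2d(ic, ic, 3, rng=rng))
        self.register("b2a", Conv2d(channels, ic, 1, rng=rng))
        self.register("b2b", Conv2d(ic, ic, 3, dilation=3, rng=rng))
        self.register("b3a", Conv2d(channels, ic, 1, rng=rng))
        self.register("b3b", Conv2d(ic, ic, (1, 3), rng=rng))
        self.register("b3c", Conv2d(ic, ic, (3, 1), rng=rng))
        self.register("b3d", Conv2d(ic, ic, 3, dilation=5, rng=rng))
        self.register("fuse", Conv2d(4 * ic, channels, 1, rng=rng))

    def forward(self, x):
        r = ag.relu
        y0 = self.b0(x)
        y1 = self.b1b(r(self.b1a(x)))
        y2 = self.b2b(r(self.b2a(x)))
        y3 = self.b3d(r(self.b3c(r(self.b3b(r(self.b3a(x)))))))
        fused = self.fuse(ag.concat([y0, y1, y2, y3], axis=1))
        return x + ag.mul(fused, 0.2)


class RRFDB(Module):
    """Residual receptive-field dense block: chained RFB units, outer residual."""

    def __init__(self, channels: int, rng, n_rfb: int = 3):
        super().__init__()
        for i in range(n_rfb):
            self.register(f"rfb{i}", RFB(channels, rng))
        self.n_rfb = n_rfb

    def forward(self, x):
        t = x
        for i in range(self.n_rfb):
            t = self._modules[f"rfb{i}"](t)
        return x + ag.mul(ag.add(t, ag.mul(x, -1.0)), 0.2)


class UpsampleStage(Module):
    """x2 spatial upsampling: sub-pixel convolution, NNI+conv, or bilinear+conv."""

    def __init__(self, channels: int, mode: str, rng):
        super().__init__()
        self.mode = mode
        if mode == "spc":
            self.register("conv", Conv2d(channels, 4 * channels, 3, rng=rng))
        else:   # nni / bilinear: interpolate then convolve
            self.register("conv", Conv2d(channels, channels, 3, rng=rng))

    def forward(self, x):
        if self.mode == "spc":
            return ag.leaky_relu(ag.pixel_shuffle(self.conv(x), 2), 0.2)
        if self.mode == "nni":
            up = ag.upsample_nearest(x, 2)
        else:
            up = ag.resize_linear(x, 2 * x.shape[2], 2 * x.shape[3])
        return ag.leaky_relu(self.conv(up), 0.2)


def _stage_modes(upsample_mode: str, scale: int) -> list[str]:
    n_stages = {1: 0, 2: 1, 4: 2}[scale]
    if upsample_mode == "subpixel":
        return ["spc"] * n_stages
    if upsample_mode == "bilinear_conv":
        return ["bilinear"] * n_stages
    # alternating NNI/SPC; SPC is the final stage, so a single x2 stage is SPC
    modes = ["nni", "spc"] * n_stages
    return modes[-n_stages:] if n_stages else []


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

class RFBESRGAN(Module):
    """Stage-1 super-resolution generator (RRDB trunk + RRFDB tail + upsampler)."""

    def __init__(self, spec: GeneratorSpec, seed: int = 0):
        super().__init__()
        spec.validate()
        self.spec = spec
        rng = np.random.default_rng(seed)
        c = spec.base_channels
        self.register("conv_first", Conv2d(1, c, 3, rng=rng))
        for i in range(spec.n_rrdb):
            self.register(f"rrdb{i}", RRDB(c, spec.growth, rng))
        for i in range(spec.n_rrfdb):
            self.register(f"rrfdb{i}", RRFDB(c, rng))
        self.register("trunk_conv", Conv2d(c, c, 3, rng=rng))
        for j, mode in enumerate(_stage_modes(spec.upsample_mode, spec.scale)):
            self.register(f"up{j}", UpsampleStage(c, mode, rng))
        self.register("conv_hr", Conv2d(c, c, 3, rng=rng))
        self.register("conv_last", Conv2d(c, 1, 3, rng=rng, zero_init=True))

    def forward(self, x, clamp: bool | None = None):
        x = ag.as_tensor(x)
        s = self.spec.scale
        # global bicubic skip: the zero-initialized network IS bicubic
        # upscaling, and training learns a residual correction on top
        base = (x if s == 1
                else ag.resize_cubic(x, s * x.shape[2], s * x.shape[3]))
        f0 = self.conv_first(x)
        t = f0
        for i in range(self.spec.n_rrdb):
            t = self._modules[f"rrdb{i}"](t)
        for i in range(self.spec.n_rrfdb):
            t = self._modules[f"rrfdb{i}"](t)
        f = f0 + self.trunk_conv(t)
        j = 0
        while f"up{j}" in self._modules:
            f = self._modules[f"up{j}"](f)
            j += 1
        out = self.conv_last(ag.leaky_relu(self.conv_hr(f), 0.2))
        y = base + out
        if clamp is None:
            clamp = not self.training
        return ag.clamp(y, 0.0, 1.0) if clamp else y


class NESRGAN(Module):
    """Stage-2 same-size restoration generator with noise injection.

    Entry: interpolation downsampling to ceil(H/2) x ceil(W/2) (bypassable);
    trunk: RRDBs with per-dense-block noise injection; tail: linear
    interpolation back to exactly H x W followed by convolutions.  The global
    skip adds the raw input, so the zero-initialized network is the identity.
    """

    def __init__(self, spec: GeneratorSpec, seed: int = 0):
        super().__init__()
        spec.validate()
        if spec.kind != "nesrgan":
            raise ValueError("NESRGAN requires kind='nesrgan'")
        self.spec = spec
        rng = np.random.default_rng(seed)
        noise_rng = np.random.default_rng(seed + 1)
        c = spec.base_channels
        self.register("conv_first", Conv2d(1, c, 3, rng=rng))
        for i in range(spec.n_rrdb):
            seeds = (None if not spec.noise else
                     [int(noise_rng.integers(2 ** 31)) for _ in range(3)])
            self.register(f"rrdb{i}", RRDB(c, spec.growth, rng, noise_seeds=seeds))
        self.register("trunk_conv", Conv2d(c, c, 3, rng=rng))
        self.register("conv_up", Conv2d(c, c, 3, rng=rng))
        self.register("conv_hr", Conv2d(c, c, 3, rng=rng))
        self.register("conv_last", Conv2d(c, 1, 3, rng=rng, zero_init=True))

    def reseed_noise(self, seed: int):
        rng = np.random.default_rng(seed)
        for m in self.modules():
            if isinstance(m, NoiseInjection):
                m.reseed(int(rng.integers(2 ** 31)))

    def forward(self, x, clamp: bool | None = None):
        x = ag.as_tensor(x)
        H, W = x.shape[2], x.shape[3]
        d = (ag.resize_linear(x, ceil(H / 2), ceil(W / 2))
             if self.spec.entry_downsample else x)
        f0 = self.conv_first(d)
        t = f0
        for i in range(self.spec.n_rrdb):
            t = self._modules[f"rrdb{i}"](t)
        f = f0 + self.trunk_conv(t)
        if self.spec.entry_downsample:
            f = ag.leaky_relu(self.conv_up(ag.resize_linear(f, H, W)), 0.2)
        else:
            f = ag.leaky_relu(self.conv_up(f), 0.2)
        out = self.conv_last(ag.leaky_relu(self.conv_hr(f), 0.2))
        y = x + out
        if clamp is None:
            clamp = not self.training
        return ag.clamp(y, 0.0, 1.0) if clamp else y


class Discriminator(Module):
    """VGG-style relativistic discriminator emitting one raw logit per image."""

    def __init__(self, spec: DiscriminatorSpec, seed: int = 0):
        super().__init__()
        spec.validate()
        self.spec = spec
        rng = np.random.default_rng(seed)
        widths = tuple(spec.feature_widths)
        in_ch = spec.in_channels
        size = spec.input_size
        li = 0
        for w in widths:
            self.register(f"conv{li}", Conv2d(in_ch, w, spec.kernel, stride=1,
                                              rng=rng, init_scale=1.0))
            if li > 0:
                self.register(f"bn{li}", BatchNorm2d(w))
            li += 1
            self.register(f"conv{li}", Conv2d(w, w, spec.kernel, stride=2,
                                              rng=rng, init_scale=1.0))
            self.register(f"bn{li}", BatchNorm2d(w))
            li += 1
            in_ch = w
            size //= 2
        self.n_convs = li
        self.flat = widths[-1] * size * size
        self.register("fc0", Dense(self.flat, spec.hidden, rng=rng))
        self.register("fc1", Dense(spec.hidden, 1, rng=rng))

    def forward(self, x):
        x = ag.as_tensor(x)
        if x.shape[2] != self.spec.input_size or x.shape[3] != self.spec.input_size:
            raise ValueError(
                f"discriminator built for {self.spec.input_size}x"
                f"{self.spec.input_size} inputs, got {x.shape[2]}x{x.shape[3]}")
        for i in range(self.n_convs):
            x = self._modules[f"conv{i}"](x)
            if f"bn{i}" in self._modules:
                x = self._modules[f"bn{i}"](x)
            x = ag.leaky_relu(x, 0.2)
        x = ag.reshape(x, (x.shape[0], self.flat))
        x = ag.leaky_relu(self.fc0(x), 0.2)
        return ag.reshape(self.fc1(x), (x.shape[0],))


# ---------------------------------------------------------------------------
# factories, structural checks, checkpoints
# ---------------------------------------------------------------------------

def build_generator(spec: GeneratorSpec, seed: int = 0) -> Module:
    spec.validate()
    if spec.kind == "rfb_esrgan":
        return RFBESRGAN(spec, seed=seed)
    return NESRGAN(spec, seed=seed)


def build_discriminator(spec: DiscriminatorSpec, seed: int = 0) -> Discriminator:
    return Discriminator(spec, seed=seed)


def contains_transposed_conv(net: Module) -> bool:
    """Structural scan for any transposed-convolution module."""
    for m in net.modules():
        if getattr(m, "is_transposed", False) or "Transpose" in type(m).__name__:
            return True
    return False


def describe(net: Module) -> str:
    lines = [f"{type(net).__name__}: {net.n_parameters()} parameters"]
    for name, p in net.named_parameters():
        lines.append(f"  {name:<40} {str(p.data.shape):<20} {p.data.size}")
    return "\n".join(lines)


def save_checkpoint(net: Module, path, spec=None, extra: dict | None = None):
    """Serialize weights as npz with an embedded spec/metadata JSON header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = {"spec": asdict(spec) if spec is not None else None,
              "class": type(net).__name__, "extra": extra or {}}
    arrays = {"__header__": np.frombuffer(
        json.dumps(header).encode(), dtype=np.uint8)}
    for name, arr in net.state_dict().items():
        arrays["param:" + name] = arr
    np.savez(path, **arrays)


def load_checkpoint(path) -> tuple[dict, dict]:
    """Return (header dict, state dict) from an npz checkpoint."""
    with np.load(path) as z:
        header = json.loads(bytes(z["__header__"]).decode())
        state = {k[len("param:"):]: z[k] for k in z.files if k.startswith("param:")}
    return header, state


def load_generator(path, seed: int = 0) -> Module:
    header, state = load_checkpoint(path)
    if header["spec"] is None:
        raise ValueError("checkpoint has no generator spec header")
    spec = GeneratorSpec(**header["spec"])
    net = build_generator(spec, seed=seed)
    net.load_state_dict(state)
    return net
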