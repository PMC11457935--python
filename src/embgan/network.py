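"""Segmentor and critic networks.

The segmentor is a U-Net: a convolutional encoder-decoder with skip
connections. Each encoder level is a stride-2 downsampling convolution
(followed by batch normalization and ReLU) and a bottleneck-style residual
block (1x1, 3x3, 1x1 convolutions). Each decoder level mirrors it with a
bilinear 2x upsampling step, a convolution + batchnorm + ReLU, concatenation
of the matching encoder output, and a residual block. The final layer is a
linear 1x1 convolution, so the output is an unbounded, continuously varying
nucleus-score image (downstream postprocessing clips it; a squashing
activation would defeat that).

The critic mirrors the encoder half without residual blocks and emits one
feature map per level ("hierarchical features"). Each level's feature head is
a global convolution factorized into a kx1 followed by a 1xk convolution -
the factorization is what buys a large receptive field with few parameters.
The ordered per-level maps are what the multiscale feature loss consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Parameter, Tensor, concat, conv2d, upsample2x_bilinear

__all__ = [
    "SegmentorConfig",
    "CriticConfig",
    "MultiscaleFeatures",
    "Module",
    "Segmentor",
    "Critic",
    "segmentor_forward",
    "critic_features",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SegmentorConfig:
    """Architecture of the segmentor U-Net.

    ``n_levels`` downsampling stages mean input spatial dimensions must be
    divisible by ``2**n_levels``; callers pad (reflect) and crop around the
    forward pass when they are not. Channel widths double per level starting
    from ``base_channels``.
    """

    n_levels: int = 4
    base_channels: int = 32
    in_channels: int = 1
    out_channels: int = 1

    def __post_init__(self):
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")
        if self.base_channels < 1:
            raise ValueError("base_channels must be >= 1")


@dataclass(frozen=True)
class CriticConfig:
    """Architecture of the critic feature extractor.

    ``n_levels`` is the number of scales L in the multiscale loss; level i
    operates at 1/2**i of the input resolution. ``global_conv_k`` is the odd
    kernel length of the separable (kx1 then 1xk) global convolution feature
    head at each level.
    """

    n_levels: int = 4
    base_channels: int = 32
    in_channels: int = 1
    global_conv_k: int = 11

    def __post_init__(self):
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")
        if self.global_conv_k % 2 != 1:
            raise ValueError("global_conv_k must be odd")


@dataclass
class MultiscaleFeatures:
    """Ordered critic feature maps, one per level, finest first."""

    levels: list[Tensor] = field(default_factory=list)

    def __post_init__(self):
        # the halving contract applies to spatial (NCHW) feature maps; plain
        # per-level arrays (e.g. hand-built examples) are accepted as-is
        for a, b in zip(self.levels, self.levels[1:]):
            if getattr(a, "ndim", 0) != 4 or getattr(b, "ndim", 0) != 4:
                continue
            sa, sb = a.shape[-2:], b.shape[-2:]
            if not (sb[0] * 2 == sa[0] and sb[1] * 2 == sa[1]):
                raise ValueError(
                    f"feature levels must halve in size, got {sa} -> {sb}"
                )

    def __len__(self):
        return len(self.levels)

    def __iter__(self):
        return iter(self.levels)


# ---------------------------------------------------------------------------
# module system
# ---------------------------------------------------------------------------

class Module:
    """Tiny container base class: parameter discovery, train/eval state."""

    def __init__(self):
        self.training = True

    def _children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def parameters(self) -> list[Parameter]:
        params = [v for v in vars(self).values() if isinstance(v, Parameter)]
        for _, child in self._children():
            params.extend(child.parameters())
        return params

    def named_state(self, prefix: str = "") -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                state[prefix + name] = value.data
            elif isinstance(value, np.ndarray):  # buffers (running stats)
                state[prefix + name] = value
        for name, child in self._children():
            state.update(child.named_state(prefix + name + "."))
        return state

    def load_state(self, state: dict[str, np.ndarray], prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                value.data = np.array(state[prefix + name], dtype=np.float64)
            elif isinstance(value, np.ndarray):
                setattr(self, name, np.array(state[prefix + name]))
        for name, child in self._children():
            child.load_state(state, prefix + name + ".")

    def train(self):
        self.training = True
        for _, child in self._children():
            child.train()
        return self

    def eval(self):
        self.training = False
        for _, child in self._children():
            child.eval()
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d(Module):
    def __init__(self, rng, in_ch, out_ch, kernel, stride=1, padding=0, bias=True):
        super().__init__()
        kh, kw = (kernel, kernel) if isinstance(kernel, int) else kernel
        self.stride = stride
        self.padding = padding
        self.weight = Parameter(_he_init(rng, (out_ch, in_ch, kh, kw), in_ch * kh * kw))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class BatchNorm2d(Module):
    """Per-channel batch normalization with running statistics.

    In training mode the batch statistics are used and the running estimates
    updated (unless ``frozen_stats`` is set, which the alternating trainer
    uses to keep a network byte-identical during the other network's step).
    Evaluation mode uses the running estimates.
    """

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps
        self.frozen_stats = False

    def __call__(self, x: Tensor) -> Tensor:
        c = x.shape[1]
        g = self.gamma.reshape(1, c, 1, 1)
        b = self.beta.reshape(1, c, 1, 1)
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            if not self.frozen_stats:
                m = self.momentum
                self.running_mean = (1 - m) * self.running_mean + m * mu.data.reshape(c)
                self.running_var = (1 - m) * self.running_var + m * var.data.reshape(c)
            xn = xc * (var + self.eps) ** -0.5
        else:
            mu = self.running_mean.reshape(1, c, 1, 1)
            inv = (self.running_var.reshape(1, c, 1, 1) + self.eps) ** -0.5
            xn = (x - mu) * inv
        return xn * g + b


class DownBlock(Module):
    """Stride-2 convolution + batchnorm + ReLU."""

    def __init__(self, rng, in_ch, out_ch):
        super().__init__()
        self.conv = Conv2d(rng, in_ch, out_ch, 3, stride=2, padding=1)
        self.bn = BatchNorm2d(out_ch)

    def __call__(self, x):
        return self.bn(self.conv(x)).relu()


class ResidualBlock(Module):
    """Bottleneck residual block: 1x1, 3x3, 1x1 convolutions.

    When the input channel count differs from the output (after skip
    concatenation in the decoder) the identity path is a 1x1 projection.
    """

    def __init__(self, rng, in_ch, out_ch):
        super().__init__()
        self.conv1 = Conv2d(rng, in_ch, out_ch, 1)
        self.bn1 = BatchNorm2d(out_ch)
        self.conv2 = Conv2d(rng, out_ch, out_ch, 3, padding=1)
        self.bn2 = BatchNorm2d(out_ch)
        self.conv3 = Conv2d(rng, out_ch, out_ch, 1)
        self.bn3 = BatchNorm2d(out_ch)
        self.proj = Conv2d(rng, in_ch, out_ch, 1, bias=False) if in_ch != out_ch else None

    def __call__(self, x):
        y = self.bn1(self.conv1(x)).relu()
        y = self.bn2(self.conv2(y)).relu()
        y = self.bn3(self.conv3(y))
        identity = self.proj(x) if self.proj is not None else x
        return (identity + y).relu()


class UpBlock(Module):
    """Bilinear 2x upsampling + convolution + batchnorm + ReLU."""

    def __init__(self, rng, in_ch, out_ch):
        super().__init__()
        self.conv = Conv2d(rng, in_ch, out_ch, 3, padding=1)
        self.bn = BatchNorm2d(out_ch)

    def __call__(self, x):
        return self.bn(self.conv(upsample2x_bilinear(x))).relu()


# ---------------------------------------------------------------------------
# segmentor
# ---------------------------------------------------------------------------

class Segmentor(Module):
    """U-Net mapping a DIC slice to an unbounded nucleus-score image."""

    def __init__(self, config: SegmentorConfig = SegmentorConfig(), seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        chans = [config.base_channels * 2 ** i for i in range(config.n_levels)]
        self.down = []
        self.enc_res = []
        in_ch = config.in_channels
        for c in chans:
            self.down.append(DownBlock(rng, in_ch, c))
            self.enc_res.append(ResidualBlock(rng, c, c))
            in_ch = c
        self.up = []
        self.dec_res = []
        # decoder targets, coarsest-to-finest: chans[-2], ..., chans[0], base
        dec_targets = chans[-2::-1] + [config.base_channels]
        skip_chans = chans[-2::-1] + [config.in_channels]
        cur = chans[-1]
        for target, skip in zip(dec_targets, skip_chans):
            self.up.append(UpBlock(rng, cur, target))
            self.dec_res.append(ResidualBlock(rng, target + skip, target))
            cur = target
        self.head = Conv2d(rng, cur, config.out_channels, 1)

    def __call__(self, x: Tensor) -> Tensor:
        skips = [x]
        for down, res in zip(self.down, self.enc_res):
            x = res(down(x))
            skips.append(x)
        # skips[-1] is the bottleneck itself; decoder consumes the rest
        for i, (up, res) in enumerate(zip(self.up, self.dec_res)):
            x = up(x)
            x = res(concat([x, skips[-2 - i]], axis=1))
        return self.head(x)

    def forward_image(self, image: np.ndarray) -> np.ndarray:
        """Run one 2D image through the network, padding/cropping as needed."""
        return segmentor_forward(self, image)


def _pad_to_multiple(image: np.ndarray, multiple: int):
    h, w = image.shape
    ph = (-h) % multiple
    pw = (-w) % multiple
    if ph or pw:
        image = np.pad(image, ((0, ph), (0, pw)), mode="reflect")
    return image, (h, w)


def segmentor_forward(segmentor: Segmentor, image: np.ndarray) -> np.ndarray:
    """Apply the segmentor to one 2D image; output has the input's size."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError(f"expected a 2D image, got shape {image.shape}")
    mult = 2 ** segmentor.config.n_levels
    padded, (h, w) = _pad_to_multiple(image, mult)
    out = segmentor(Tensor(padded[None, None])).data[0, 0]
    return out[:h, :w]


# ---------------------------------------------------------------------------
# critic
# ---------------------------------------------------------------------------

class CriticLevel(Module):
    """One critic scale: stride-2 conv + batchnorm + ReLU, with a separable
    global-convolution feature head (kx1 then 1xk, linear).

    Batch normalization here keeps the hierarchical features on a bounded
    scale, which tames the otherwise unbounded growth a maximizing critic
    can exhibit during adversarial training; both masked branches must share
    one forward pass so they see the same batch statistics.
    """

    def __init__(self, rng, in_ch, out_ch, k):
        super().__init__()
        self.conv = Conv2d(rng, in_ch, out_ch, 3, stride=2, padding=1)
        self.bn = BatchNorm2d(out_ch)
        self.gconv_a = Conv2d(rng, out_ch, out_ch, (k, 1), padding=(k // 2, 0))
        self.gconv_b = Conv2d(rng, out_ch, out_ch, (1, k), padding=(0, k // 2))

    def __call__(self, x):
        x = self.bn(self.conv(x)).relu()
        feat = self.gconv_b(self.gconv_a(x))
        return x, feat


class Critic(Module):
    """Hierarchical feature extractor over masked images."""

    def __init__(self, config: CriticConfig = CriticConfig(), seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        self.levels = []
        in_ch = config.in_channels
        for i in range(config.n_levels):
            out_ch = config.base_channels * 2 ** i
            self.levels.append(CriticLevel(rng, in_ch, out_ch, config.global_conv_k))
            in_ch = out_ch

    def __call__(self, x: Tensor) -> MultiscaleFeatures:
        feats = []
        for level in self.levels:
            x, f = level(x)
            feats.append(f)
        return MultiscaleFeatures(feats)


def critic_features(critic: Critic, masked_image) -> MultiscaleFeatures:
    """Extract the critic's per-level feature maps from a masked 2D image."""
    if isinstance(masked_image, Tensor):
        x = masked_image
        if x.ndim == 2:
            x = x.reshape(1, 1, *x.shape)
    else:
        arr = np.asarray(masked_image, dtype=np.float64)
        if arr.ndim != 2:
            raise ValueError(f"expected a 2D image, got shape {arr.shape}")
        x = Tensor(arr[None, None])
    h, w = x.shape[-2:]
    mult = 2 ** critic.config.n_levels
    if h % mult or w % mult:
        raise ValueError(
            f"critic input size {(h, w)} must be divisible by {mult}"
        )
    return critic(x)
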