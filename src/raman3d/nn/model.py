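"""The depthwise separable 3D MultiResU-Net encoder-decoder assembly.

Encoder: per level a residual DS-conv block, then (optionally) the
multi-scale fusion module, then 2×2×2 max pooling.  Decoder mirrors it with
trilinear upsampling + DS conv, concatenation with the fused skip features,
and a residual block.  A final 1×1×1 convolution maps back to one channel;
with ``global_residual`` the network predicts a correction added to its
input, the standard residual formulation for denoisers.

Extents that are not divisible by ``2^n_levels`` are reflect-padded at the
trailing edge and cropped back after decoding, so cubes of any size (e.g.
58×58×812) pass through unchanged in shape.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from raman3d.errors import ConfigError
from raman3d.nn import functional as F
from raman3d.nn.autograd import Tensor, as_tensor
from raman3d.nn.layers import (
    ConvBNAct,
    Conv3d,
    DSConv3d,
    Module,
    ModuleList,
    MultiScaleFusion,
    ResidualBlock,
)


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture hyperparameters of the denoiser.

    The defaults (depth 3, base width 16, growth ×2) are sized for
    desk-scale CPU training and are fully configurable; the kernel and
    dilation inventory of the fusion module is the fixed multi-scale recipe:
    spatial 3×3×1 (×2) and 5×5×1 (×2), spectral 1×1×3, 1×1×5, dilated 1×1×5
    (rate 5) and dilated 1×1×7 (rate 7).
    """

    n_levels: int = 3
    base_channels: int = 16
    channel_growth: int = 2
    use_fusion: bool = True
    attention_reduction: int = 8
    spatial_kernels: tuple[int, ...] = (3, 3, 5, 5)
    spectral_kernels: tuple[tuple[int, int], ...] = ((3, 1), (5, 1), (5, 5), (7, 7))
    norm_then_act: bool = True
    global_residual: bool = True
    conv_kernel: tuple[int, int, int] = (3, 3, 3)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_levels < 1:
            raise ConfigError("n_levels must be >= 1")
        if self.base_channels < 1:
            raise ConfigError("base_channels must be >= 1")
        kernels = list(self.spatial_kernels) + [k for k, _ in self.spectral_kernels] + list(self.conv_kernel)
        if any(k % 2 == 0 for k in kernels):
            raise ConfigError("all kernel sizes must be odd")
        if any(d < 1 for _, d in self.spectral_kernels):
            raise ConfigError("dilations must be >= 1")

    @property
    def level_channels(self) -> list[int]:
        return [self.base_channels * self.channel_growth**i for i in range(self.n_levels + 1)]

    def to_dict(self) -> dict:
        return {
            "n_levels": self.n_levels,
            "base_channels": self.base_channels,
            "channel_growth": self.channel_growth,
            "use_fusion": self.use_fusion,
            "attention_reduction": self.attention_reduction,
            "spatial_kernels": list(self.spatial_kernels),
            "spectral_kernels": [list(p) for p in self.spectral_kernels],
            "norm_then_act": self.norm_then_act,
            "global_residual": self.global_residual,
            "conv_kernel": list(self.conv_kernel),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkSpec":
        d = dict(d)
        for key in ("spatial_kernels", "conv_kernel"):
            if key in d:
                d[key] = tuple(d[key])
        if "spectral_kernels" in d:
            d["spectral_kernels"] = tuple(tuple(p) for p in d["spectral_kernels"])
        return cls(**d)


class MultiResUNet3D(Module):
    """Encoder-decoder denoiser over (N, 1, H, W, B) normalized cubes."""

    def __init__(self, spec: NetworkSpec) -> None:
        super().__init__()
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        ch = spec.level_channels  # c_0 .. c_L
        nta = spec.norm_then_act
        kern = spec.conv_kernel

        self.stem = self.register_module("stem", ConvBNAct(1, ch[0], kern, nta, rng=rng))

        enc, fus = [], []
        for i in range(spec.n_levels):
            c_in = ch[i - 1] if i > 0 else ch[0]
            enc.append(ResidualBlock(c_in, ch[i], kern, nta, rng=rng))
            if spec.use_fusion:
                fus.append(
                    MultiScaleFusion(
                        ch[i], spec.spatial_kernels, spec.spectral_kernels,
                        spec.attention_reduction, rng=rng,
                    )
                )
        self.encoders = self.register_module("encoders", ModuleList(enc))
        self.fusions = self.register_module("fusions", ModuleList(fus))

        self.bottleneck = self.register_module(
            "bottleneck", ResidualBlock(ch[spec.n_levels - 1], ch[spec.n_levels], kern, nta, rng=rng)
        )

        ups, dec = [], []
        for i in reversed(range(spec.n_levels)):
            ups.append(ConvBNAct(ch[i + 1], ch[i], kern, nta, rng=rng))
            dec.append(ResidualBlock(2 * ch[i], ch[i], kern, nta, rng=rng))
        self.up_convs = self.register_module("up_convs", ModuleList(ups))
        self.decoders = self.register_module("decoders", ModuleList(dec))

        self.head = self.register_module("head", Conv3d(ch[0], 1, (1, 1, 1), rng=rng))
        if spec.global_residual:
            # zero-init the head so the residual model starts at the identity;
            # short training runs then only ever improve on the noisy input
            self.head.weight.data[...] = 0.0
            self.head.bias.data[...] = 0.0

    # -- geometry ---------------------------------------------------------
    @property
    def downsample_factor(self) -> int:
        return 2**self.spec.n_levels

    def required_padding(self, extent: tuple[int, int, int]) -> tuple[int, int, int]:
        f = self.downsample_factor
        return tuple((-e) % f for e in extent)  # type: ignore[return-value]

    # -- forward ----------------------------------------------------------
    def forward(self, x: Tensor, pad_if_needed: bool = True) -> Tensor:
        x = as_tensor(x)
        if x.ndim != 5 or x.shape[1] != 1:
            raise ConfigError(f"expected (N, 1, H, W, B) input, got {x.shape}")
        extent = x.shape[2:]
        pads = self.required_padding(extent)  # trailing-edge reflect pads
        if any(pads):
            if not pad_if_needed:
                raise ConfigError(
                    f"extent {extent} not divisible by {self.downsample_factor}; "
                    f"required padding {pads} (pass pad_if_needed=True)"
                )
            x = F.reflect_pad(x, tuple((0, p) for p in pads))  # type: ignore[arg-type]

        h = self.stem(x)
        skips: list[Tensor] = []
        for i, encoder in enumerate(self.encoders):
            h = encoder(h)
            if self.spec.use_fusion:
                h = self.fusions[i](h)
            skips.append(h)
            h = F.max_pool2(h)
        h = self.bottleneck(h)
        for up_conv, decoder, skip in zip(self.up_convs, self.decoders, reversed(skips)):
            h = up_conv(F.upsample2_trilinear(h))
            h = decoder(F.concat([h, skip], axis=1))
        out = self.head(h)
        if self.spec.global_residual:
            out = F.add(out, x)
        if any(pads):
            out = F.crop(out, extent)
        return out

    # -- reporting --------------------------------------------------------
    def parameter_table(self) -> list[tuple[str, tuple[int, ...], int]]:
        return [(name, p.data.shape, p.data.size) for name, p in self.named_parameters()]

    def summary(self) -> str:
        lines = [f"{'parameter':60s} {'shape':>20s} {'count':>10s}"]
        for name, shape, size in self.parameter_table():
            lines.append(f"{name:60s} {str(shape):>20s} {size:>10d}")
        lines.append(f"{'TOTAL':60s} {'':>20s} {self.n_params:>10d}")
        return "\n".join(lines)


def build_network(spec: NetworkSpec) -> MultiResUNet3D:
    """Construct a seeded network from its spec."""
    return MultiResUNet3D(spec)


def denoise_cube_array(
    model: MultiResUNet3D, cube_data: np.ndarray, batch_dtype=np.float32
) -> np.ndarray:
    """Run a single H×W×B normalized volume through the model (inference)."""
    from raman3d.nn.autograd import no_grad

    model.eval()
    x = cube_data.astype(batch_dtype)[None, None]
    with no_grad():
        y = model(Tensor(x))
    return np.asarray(y.data[0, 0], dtype=np.float64)
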