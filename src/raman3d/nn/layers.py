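"""Building blocks of the denoiser, as lightweight stateful modules.

Modules hold their parameters as :class:`~raman3d.nn.autograd.Tensor` leaves
(float32) plus any running statistics as plain arrays.  Initialization is
He-style fan-in scaling from a module-local ``numpy`` generator so a seeded
build is bit-reproducible.
"""

from __future__ import annotations

from typing import Iterator, Optional, Sequence

import numpy as np

from raman3d.errors import ConfigError, ShapeError
from raman3d.nn import functional as F
from raman3d.nn.autograd import Tensor

DTYPE = np.float32


class Module:
    """Minimal module base: parameter registry and train/eval mode."""

    def __init__(self) -> None:
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, "Module"] = {}
        self.training: bool = True

    def register_param(self, name: str, value: np.ndarray) -> Tensor:
        t = Tensor(np.asarray(value, dtype=DTYPE), requires_grad=True)
        self._params[name] = t
        return t

    def register_module(self, name: str, module: "Module") -> "Module":
        self._modules[name] = module
        return module

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, p in self._params.items():
            yield f"{prefix}{name}", p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix=f"{prefix}{name}.")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name in getattr(self, "_buffers", {}):
            yield f"{prefix}{name}", getattr(self, "_buffers")[name]
        for name, m in self._modules.items():
            yield from m.named_buffers(prefix=f"{prefix}{name}.")

    @property
    def n_params(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def train(self) -> "Module":
        self.training = True
        for m in self._modules.values():
            m.train()
        return self

    def eval(self) -> "Module":
        self.training = False
        for m in self._modules.values():
            m.eval()
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({f"buffer::{name}": b.copy() for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for key, value in state.items():
            if key.startswith("buffer::"):
                target = buffers[key[len("buffer::") :]]
                target[...] = value
            else:
                if params[key].data.shape != value.shape:
                    raise ShapeError(f"checkpoint shape mismatch for {key}")
                params[key].data[...] = value.astype(DTYPE)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class ModuleList(Module):
    def __init__(self, modules: Sequence[Module] = ()) -> None:
        super().__init__()
        self._list: list[Module] = []
        for m in modules:
            self.append(m)

    def append(self, module: Module) -> None:
        self.register_module(str(len(self._list)), module)
        self._list.append(module)

    def __iter__(self) -> Iterator[Module]:
        return iter(self._list)

    def __getitem__(self, i: int) -> Module:
        return self._list[i]

    def __len__(self) -> int:
        return len(self._list)


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class DSConv3d(Module):
    """Depthwise separable 3D convolution (depthwise k×k×k, pointwise 1×1×1).

    Weight count (excluding biases) is ``C_in·kh·kw·kb + C_in·C_out`` versus
    ``C_in·C_out·kh·kw·kb`` for the standard convolution it replaces.
    """

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: tuple[int, int, int] = (3, 3, 3),
        dilation: tuple[int, int, int] = (1, 1, 1),
        bias: bool = True,
        rng: Optional[np.random.Generator] = None,
    ) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        self.c_in, self.c_out = c_in, c_out
        self.kernel, self.dilation = tuple(kernel), tuple(dilation)
        k_vol = int(np.prod(kernel))
        self.depthwise = self.register_param("depthwise", _he_init(rng, (c_in,) + self.kernel, k_vol))
        self.pointwise = self.register_param("pointwise", _he_init(rng, (c_out, c_in), c_in))
        self.bias = self.register_param("bias", np.zeros(c_out)) if bias else None

    @property
    def weight_count(self) -> int:
        return self.depthwise.data.size + self.pointwise.data.size

    @staticmethod
    def standard_weight_count(c_in: int, c_out: int, kernel: tuple[int, int, int]) -> int:
        """Weights of the equivalent standard 3D convolution, for comparison."""
        return c_in * c_out * int(np.prod(kernel))

    def forward(self, x: Tensor) -> Tensor:
        return F.ds_conv3d(x, self.depthwise, self.pointwise, self.bias, self.dilation)


class Conv3d(Module):
    """Standard 3D convolution (used for pseudo-3D branches and projections)."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: tuple[int, int, int],
        dilation: tuple[int, int, int] = (1, 1, 1),
        bias: bool = True,
        rng: Optional[np.random.Generator] = None,
    ) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        self.c_in, self.c_out = c_in, c_out
        self.kernel, self.dilation = tuple(kernel), tuple(dilation)
        fan_in = c_in * int(np.prod(kernel))
        self.weight = self.register_param("weight", _he_init(rng, (c_out, c_in) + self.kernel, fan_in))
        self.bias = self.register_param("bias", np.zeros(c_out)) if bias else None

    @property
    def effective_span(self) -> tuple[int, int, int]:
        """Receptive-field span per axis: (k−1)·dilation + 1."""
        return tuple((k - 1) * d + 1 for k, d in zip(self.kernel, self.dilation))  # type: ignore[return-value]

    def forward(self, x: Tensor) -> Tensor:
        return F.conv3d(x, self.weight, self.bias, self.dilation)


class BatchNorm3d(Module):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.gamma = self.register_param("gamma", np.ones(c))
        self.beta = self.register_param("beta", np.zeros(c))
        self._buffers = {
            "running_mean": np.zeros(c, dtype=DTYPE),
            "running_var": np.ones(c, dtype=DTYPE),
        }

    def forward(self, x: Tensor) -> Tensor:
        return F.batch_norm(
            x, self.gamma, self.beta,
            self._buffers["running_mean"], self._buffers["running_var"],
            training=self.training, momentum=self.momentum, eps=self.eps,
        )


class PReLU(Module):
    def __init__(self, c: int, init: float = 0.25) -> None:
        super().__init__()
        self.alpha = self.register_param("alpha", np.full(c, init))

    def forward(self, x: Tensor) -> Tensor:
        return F.prelu(x, self.alpha)


class ConvBNAct(Module):
    """DS conv → batch norm → PReLU (order switchable to conv → act → norm)."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: tuple[int, int, int] = (3, 3, 3),
        norm_then_act: bool = True,
        rng: Optional[np.random.Generator] = None,
    ) -> None:
        super().__init__()
        self.norm_then_act = norm_then_act
        self.conv = self.register_module("conv", DSConv3d(c_in, c_out, kernel, rng=rng))
        self.bn = self.register_module("bn", BatchNorm3d(c_out))
        self.act = self.register_module("act", PReLU(c_out))

    def forward(self, x: Tensor) -> Tensor:
        y = self.conv(x)
        if self.norm_then_act:
            return self.act(self.bn(y))
        return self.bn(self.act(y))


class ResidualBlock(Module):
    """One DS-3D conv layer (with BN + PReLU) plus a shortcut.

    The shortcut is the identity when input and output widths match and a
    1×1×1 projection otherwise; no projection parameters are allocated in
    the matching case.
    """

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: tuple[int, int, int] = (3, 3, 3),
        norm_then_act: bool = True,
        rng: Optional[np.random.Generator] = None,
    ) -> None:
        super().__init__()
        self.transform = self.register_module(
            "transform", ConvBNAct(c_in, c_out, kernel, norm_then_act, rng=rng)
        )
        self.shortcut: Optional[Conv3d] = None
        if c_in != c_out:
            self.shortcut = self.register_module(
                "shortcut", Conv3d(c_in, c_out, (1, 1, 1), bias=False, rng=rng)
            )

    def forward(self, x: Tensor) -> Tensor:
        identity = x if self.shortcut is None else self.shortcut(x)
        return F.add(self.transform(x), identity)


class ChannelAttention(Module):
    """Squeeze-and-excitation gating: pool → C→C/r→C → sigmoid → rescale."""

    def __init__(self, c: int, reduction: int = 8, rng: Optional[np.random.Generator] = None) -> None:
        super().__init__()
        if c < reduction:
            raise ConfigError(f"channel count {c} < attention reduction {reduction}")
        hidden = max(c // reduction, 1)
        rng = rng or np.random.default_rng()
        self.fc1 = self.register_param("fc1", _he_init(rng, (hidden, c), c))
        self.b1 = self.register_param("b1", np.zeros(hidden))
        self.fc2 = self.register_param("fc2", _he_init(rng, (c, hidden), hidden))
        self.b2 = self.register_param("b2", np.zeros(c))

    def weights(self, x: Tensor) -> Tensor:
        """The per-channel gate values in (0, 1), shape (N, C, 1, 1, 1).

        The gate path runs in float64 (it is a tiny N×C vector) so the
        sigmoid stays strictly inside (0, 1) even for large activations.
        """
        pooled = F.cast(F.global_avg_pool(x), np.float64)
        hidden = F.relu(F.pointwise_conv(pooled, self.fc1, self.b1))
        return F.sigmoid(F.pointwise_conv(hidden, self.fc2, self.b2))

    def forward(self, x: Tensor) -> Tensor:
        return F.mul(x, F.cast(self.weights(x), x.dtype))


class MultiScaleFusion(Module):
    """Pseudo-3D multi-scale convolution followed by channel attention.

    Default inventory: four spatial branches (two 3×3×1, two 5×5×1 standard
    convolutions) and four spectral branches (1×1×3; 1×1×5; 1×1×5 with
    dilation 5; 1×1×7 with dilation 7).  Each branch emits C/n_branches
    channels; the concatenation restores C, so fusion is width- and
    extent-neutral and can sit on any skip path.
    """

    def __init__(
        self,
        c: int,
        spatial_kernels: Sequence[int] = (3, 3, 5, 5),
        spectral_kernels: Sequence[tuple[int, int]] = ((3, 1), (5, 1), (5, 5), (7, 7)),
        attention_reduction: int = 8,
        rng: Optional[np.random.Generator] = None,
    ) -> None:
        super().__init__()
        n_branches = len(spatial_kernels) + len(spectral_kernels)
        if c % n_branches:
            raise ConfigError(f"channel count {c} not divisible by {n_branches} fusion branches")
        c_branch = c // n_branches
        branches: list[Conv3d] = []
        for k in spatial_kernels:
            branches.append(Conv3d(c, c_branch, (k, k, 1), rng=rng))
        for k, d in spectral_kernels:
            branches.append(Conv3d(c, c_branch, (1, 1, k), dilation=(1, 1, d), rng=rng))
        self.branches = self.register_module("branches", ModuleList(branches))
        self.attention = self.register_module(
            "attention", ChannelAttention(c, attention_reduction, rng=rng)
        )

    def branch_inventory(self) -> list[dict]:
        """Kernel/dilation bookkeeping for every branch, for introspection."""
        out = []
        for br in self.branches:
            kind = "spatial" if br.kernel[2] == 1 else "spectral"
            out.append(
                dict(kind=kind, kernel=br.kernel, dilation=br.dilation, effective_span=br.effective_span)
            )
        return out

    def forward(self, x: Tensor) -> Tensor:
        fused = F.concat([br(x) for br in self.branches], axis=1)
        return self.attention(fused)
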