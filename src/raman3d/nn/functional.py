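"""Differentiable operations on ``(N, C, H, W, B)`` feature volumes.

Convolutions use "same" zero padding and are computed tap-by-tap: each
kernel tap is one fused multiply-add over the whole volume (depthwise) or
one channel-mixing contraction (standard / pointwise), which keeps the inner
loops in BLAS/numpy kernels.  Backward rules are hand-derived transposes of
the forward maps.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from raman3d.errors import ShapeError
from raman3d.nn import _kernels as _K
from raman3d.nn.autograd import Tensor, as_tensor, make_op, unbroadcast

# flip to False to force the pure-numpy conv paths (used by equivalence tests)
USE_JIT: bool = _K.HAVE_NUMBA

# ---------------------------------------------------------------------------
# elementwise algebra
# ---------------------------------------------------------------------------


def add(a: Tensor, b: Tensor) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data + b.data

    def backward(g: np.ndarray) -> None:
        if a.requires_grad:
            a.accumulate_grad(unbroadcast(g, a.shape))
        if b.requires_grad:
            b.accumulate_grad(unbroadcast(g, b.shape))

    return make_op(out_data, (a, b), backward)


def sub(a: Tensor, b: Tensor) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data - b.data

    def backward(g: np.ndarray) -> None:
        if a.requires_grad:
            a.accumulate_grad(unbroadcast(g, a.shape))
        if b.requires_grad:
            b.accumulate_grad(unbroadcast(-g, b.shape))

    return make_op(out_data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data * b.data

    def backward(g: np.ndarray) -> None:
        if a.requires_grad:
            a.accumulate_grad(unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b.accumulate_grad(unbroadcast(g * a.data, b.shape))

    return make_op(out_data, (a, b), backward)


def scale(a: Tensor, s: float) -> Tensor:
    a = as_tensor(a)

    def backward(g: np.ndarray) -> None:
        if a.requires_grad:
            a.accumulate_grad(g * s)

    return make_op(a.data * s, (a,), backward)


def absolute(a: Tensor) -> Tensor:
    a = as_tensor(a)
    sign = np.sign(a.data)

    def backward(g: np.ndarray) -> None:
        if a.requires_grad:
            a.accumulate_grad(g * sign)

    return make_op(np.abs(a.data), (a,), backward)


def square(a: Tensor) -> Tensor:
    a = as_tensor(a)

    def backward(g: np.ndarray) -> None:
        if a.requires_grad:
            a.accumulate_grad(g * (2.0 * a.data))

    return make_op(a.data * a.data, (a,), backward)


def mean_all(a: Tensor) -> Tensor:
    a = as_tensor(a)
    inv = 1.0 / a.data.size

    def backward(g: np.ndarray) -> None:
        if a.requires_grad:
            a.accumulate_grad(np.full_like(a.data, float(g) * inv))

    return make_op(np.asarray(a.data.mean(), dtype=a.dtype), (a,), backward)


def sigmoid(a: Tensor) -> Tensor:
    a = as_tensor(a)
    s = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g: np.ndarray) -> None:
        if a.requires_grad:
            a.accumulate_grad(g * s * (1.0 - s))

    return make_op(s, (a,), backward)


def relu(a: Tensor) -> Tensor:
    a = as_tensor(a)
    mask = a.data > 0

    def backward(g: np.ndarray) -> None:
        if a.requires_grad:
            a.accumulate_grad(g * mask)

    return make_op(a.data * mask, (a,), backward)


def prelu(x: Tensor, alpha: Tensor) -> Tensor:
    """Per-channel parametric ReLU; ``alpha`` has shape (C,)."""
    x, alpha = as_tensor(x), as_tensor(alpha)
    a_resh = alpha.data.reshape((1, -1) + (1,) * (x.ndim - 2))
    pos = x.data > 0
    out_data = np.where(pos, x.data, a_resh * x.data)

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            x.accumulate_grad(np.where(pos, g, a_resh * g))
        if alpha.requires_grad:
            neg = np.where(pos, 0.0, g * x.data)
            axes = (0,) + tuple(range(2, x.ndim))
            alpha.accumulate_grad(neg.sum(axis=axes).astype(alpha.dtype))

    return make_op(out_data, (x, alpha), backward)


def cast(a: Tensor, dtype) -> Tensor:
    a = as_tensor(a)
    src_dtype = a.dtype

    def backward(g: np.ndarray) -> None:
        if a.requires_grad:
            a.accumulate_grad(g.astype(src_dtype))

    return make_op(a.data.astype(dtype), (a,), backward)


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g: np.ndarray) -> None:
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                index = [slice(None)] * g.ndim
                index[axis] = slice(lo, hi)
                t.accumulate_grad(g[tuple(index)])

    return make_op(out_data, tuple(tensors), backward)


# ---------------------------------------------------------------------------
# convolutions
# ---------------------------------------------------------------------------


def _check_odd(kernel: Sequence[int]) -> None:
    if any(k % 2 == 0 for k in kernel):
        raise ShapeError(f"kernel sizes must be odd, got {tuple(kernel)}")


def _pad_same(x: np.ndarray, kernel: Sequence[int], dilation: Sequence[int]) -> tuple[np.ndarray, tuple[int, int, int]]:
    ph, pw, pb = ((k - 1) // 2 * d for k, d in zip(kernel, dilation))
    xpad = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw), (pb, pb)))
    return xpad, (ph, pw, pb)


def pointwise_conv(x: Tensor, weight: Tensor, bias: Optional[Tensor] = None) -> Tensor:
    """1×1×1 channel mixing: ``weight`` is (C_out, C_in), ``bias`` (C_out,)."""
    x, weight = as_tensor(x), as_tensor(weight)
    n, c, h, w, b = x.shape
    s = h * w * b
    x2 = np.ascontiguousarray(x.data).reshape(n, c, s)
    out_data = np.matmul(weight.data, x2).reshape(n, -1, h, w, b)
    if bias is not None:
        out_data += bias.data.reshape(1, -1, 1, 1, 1)
    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g: np.ndarray) -> None:
        g2 = g.reshape(n, -1, s)
        if weight.requires_grad:
            weight.accumulate_grad(np.matmul(g2, x2.transpose(0, 2, 1)).sum(axis=0))
        if x.requires_grad:
            x.accumulate_grad(np.matmul(weight.data.T, g2).reshape(n, c, h, w, b))
        if bias is not None and bias.requires_grad:
            bias.accumulate_grad(g.sum(axis=(0, 2, 3, 4)))

    return make_op(out_data, parents, backward)


def depthwise_conv3d(
    x: Tensor,
    weight: Tensor,
    bias: Optional[Tensor] = None,
    dilation: tuple[int, int, int] = (1, 1, 1),
) -> Tensor:
    """Per-channel 3D convolution, "same" zero padding.

    ``weight`` has shape (C, kh, kw, kb): one kernel per input channel, no
    channel mixing (that is the job of :func:`pointwise_conv`).
    """
    x, weight = as_tensor(x), as_tensor(weight)
    n, c, h, w, b = x.shape
    cw, kh, kw_, kb = weight.shape
    if cw != c:
        raise ShapeError(f"depthwise weight channels {cw} != input channels {c}")
    _check_odd((kh, kw_, kb))
    dh, dw, db = dilation
    xpad, (ph, pw, pb) = _pad_same(x.data, (kh, kw_, kb), dilation)
    use_jit = USE_JIT and _K.HAVE_NUMBA

    if use_jit:
        out_data = _K.depthwise_fwd(xpad, weight.data, dh, dw, db, h, w, b)
    else:
        out_data = np.zeros_like(x.data)
        for i in range(kh):
            for j in range(kw_):
                for l in range(kb):
                    tap = weight.data[:, i, j, l].reshape(1, c, 1, 1, 1)
                    out_data += tap * xpad[:, :, i * dh : i * dh + h, j * dw : j * dw + w, l * db : l * db + b]
    if bias is not None:
        out_data += bias.data.reshape(1, -1, 1, 1, 1)
    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g: np.ndarray) -> None:
        g = np.ascontiguousarray(g)
        if weight.requires_grad:
            if use_jit:
                dw_ = _K.depthwise_bwd_w(xpad, g, kh, kw_, kb, dh, dw, db)
            else:
                dw_ = np.empty_like(weight.data)
                for i in range(kh):
                    for j in range(kw_):
                        for l in range(kb):
                            view = xpad[:, :, i * dh : i * dh + h, j * dw : j * dw + w, l * db : l * db + b]
                            dw_[:, i, j, l] = (g * view).sum(axis=(0, 2, 3, 4))
            weight.accumulate_grad(dw_)
        if x.requires_grad:
            if use_jit:
                gpad = _K.depthwise_bwd_x(np.array(xpad.shape), weight.data, g, dh, dw, db)
            else:
                gpad = np.zeros_like(xpad)
                for i in range(kh):
                    for j in range(kw_):
                        for l in range(kb):
                            tap = weight.data[:, i, j, l].reshape(1, c, 1, 1, 1)
                            gpad[:, :, i * dh : i * dh + h, j * dw : j * dw + w, l * db : l * db + b] += tap * g
            x.accumulate_grad(gpad[:, :, ph : ph + h, pw : pw + w, pb : pb + b])
        if bias is not None and bias.requires_grad:
            bias.accumulate_grad(g.sum(axis=(0, 2, 3, 4)))

    return make_op(out_data, parents, backward)


def conv3d(
    x: Tensor,
    weight: Tensor,
    bias: Optional[Tensor] = None,
    dilation: tuple[int, int, int] = (1, 1, 1),
) -> Tensor:
    """Standard 3D convolution, "same" zero padding.

    ``weight`` has shape (C_out, C_in, kh, kw, kb).  Used for the pseudo-3D
    fusion branches (k×k×1 and dilated 1×1×k kernels) and 1×1×1 projections.
    """
    x, weight = as_tensor(x), as_tensor(weight)
    n, c, h, w, b = x.shape
    c_out, c_in, kh, kw_, kb = weight.shape
    if c_in != c:
        raise ShapeError(f"conv weight in-channels {c_in} != input channels {c}")
    _check_odd((kh, kw_, kb))
    dh, dw, db = dilation
    xpad, (ph, pw, pb) = _pad_same(x.data, (kh, kw_, kb), dilation)

    s = h * w * b
    use_jit = USE_JIT and _K.HAVE_NUMBA
    if use_jit:
        out_data = _K.conv_fwd(xpad, weight.data, dh, dw, db, h, w, b)
    else:
        out2 = np.zeros((n, c_out, s), dtype=x.dtype)
        for i in range(kh):
            for j in range(kw_):
                for l in range(kb):
                    view = np.ascontiguousarray(
                        xpad[:, :, i * dh : i * dh + h, j * dw : j * dw + w, l * db : l * db + b]
                    ).reshape(n, c, s)
                    out2 += np.matmul(weight.data[:, :, i, j, l], view)
        out_data = out2.reshape(n, c_out, h, w, b)
    if bias is not None:
        out_data += bias.data.reshape(1, -1, 1, 1, 1)
    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g: np.ndarray) -> None:
        g = np.ascontiguousarray(g)
        g2 = g.reshape(n, c_out, s)
        if weight.requires_grad:
            if use_jit:
                dw_ = _K.conv_bwd_w(xpad, g, kh, kw_, kb, dh, dw, db)
            else:
                dw_ = np.empty_like(weight.data)
                for i in range(kh):
                    for j in range(kw_):
                        for l in range(kb):
                            view = xpad[:, :, i * dh : i * dh + h, j * dw : j * dw + w, l * db : l * db + b]
                            dw_[:, :, i, j, l] = np.tensordot(g, view, axes=([0, 2, 3, 4], [0, 2, 3, 4]))
            weight.accumulate_grad(dw_)
        if x.requires_grad:
            if use_jit:
                gpad = _K.conv_bwd_x(np.array(xpad.shape), weight.data, g, dh, dw, db)
            else:
                gpad = np.zeros_like(xpad)
                for i in range(kh):
                    for j in range(kw_):
                        for l in range(kb):
                            t = np.matmul(weight.data[:, :, i, j, l].T, g2).reshape(n, c, h, w, b)
                            gpad[:, :, i * dh : i * dh + h, j * dw : j * dw + w, l * db : l * db + b] += t
            x.accumulate_grad(gpad[:, :, ph : ph + h, pw : pw + w, pb : pb + b])
        if bias is not None and bias.requires_grad:
            bias.accumulate_grad(g.sum(axis=(0, 2, 3, 4)))

    return make_op(out_data, parents, backward)


def ds_conv3d(
    x: Tensor,
    depthwise_weight: Tensor,
    pointwise_weight: Tensor,
    bias: Optional[Tensor] = None,
    dilation: tuple[int, int, int] = (1, 1, 1),
) -> Tensor:
    """Depthwise separable 3D convolution: per-channel k×k×k filtering
    followed by 1×1×1 channel mixing.

    Weight count is ``C_in·k³ + C_in·C_out`` versus ``C_in·C_out·k³`` for a
    standard 3D convolution at the same receptive field.
    """
    return pointwise_conv(depthwise_conv3d(x, depthwise_weight, None, dilation), pointwise_weight, bias)


# ---------------------------------------------------------------------------
# normalization, pooling, resampling
# ---------------------------------------------------------------------------


def batch_norm(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Batch normalization over (N, H, W, B) per channel.

    ``running_mean``/``running_var`` are plain arrays owned by the layer and
    updated in place during training (biased variance, torch convention for
    the normalization itself).
    """
    x = as_tensor(x)
    axes = (0, 2, 3, 4)
    shape_c = (1, -1, 1, 1, 1)
    if training:
        mean = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mean, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean.reshape(shape_c)) * inv_std.reshape(shape_c)
    out_data = gamma.data.reshape(shape_c) * xhat + beta.data.reshape(shape_c)

    def backward(g: np.ndarray) -> None:
        if gamma.requires_grad:
            gamma.accumulate_grad((g * xhat).sum(axis=axes))
        if beta.requires_grad:
            beta.accumulate_grad(g.sum(axis=axes))
        if x.requires_grad:
            gscale = g * gamma.data.reshape(shape_c)
            if training:
                m = x.data.size // x.shape[1]
                mean_g = gscale.mean(axis=axes).reshape(shape_c)
                mean_gx = (gscale * xhat).mean(axis=axes).reshape(shape_c)
                dx = inv_std.reshape(shape_c) * (gscale - mean_g - xhat * mean_gx)
            else:
                dx = inv_std.reshape(shape_c) * gscale
            x.accumulate_grad(dx)

    return make_op(out_data, (x, gamma, beta), backward)


def max_pool2(x: Tensor) -> Tensor:
    """2×2×2 max pooling; all three trailing extents must be even."""
    x = as_tensor(x)
    n, c, h, w, b = x.shape
    if h % 2 or w % 2 or b % 2:
        raise ShapeError(f"max_pool2 needs even extents, got {(h, w, b)}")
    windows = (
        x.data.reshape(n, c, h // 2, 2, w // 2, 2, b // 2, 2)
        .transpose(0, 1, 2, 4, 6, 3, 5, 7)
        .reshape(n, c, h // 2, w // 2, b // 2, 8)
    )
    idx = windows.argmax(axis=-1)
    out_data = np.take_along_axis(windows, idx[..., None], axis=-1)[..., 0]

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            gw = np.zeros_like(windows)
            np.put_along_axis(gw, idx[..., None], g[..., None], axis=-1)
            gx = (
                gw.reshape(n, c, h // 2, w // 2, b // 2, 2, 2, 2)
                .transpose(0, 1, 2, 5, 3, 6, 4, 7)
                .reshape(n, c, h, w, b)
            )
            x.accumulate_grad(gx)

    return make_op(out_data, (x,), backward)


def _up2_axis(a: np.ndarray, axis: int) -> np.ndarray:
    a = np.moveaxis(a, axis, -1)
    left = np.concatenate([a[..., :1], a[..., :-1]], axis=-1)
    right = np.concatenate([a[..., 1:], a[..., -1:]], axis=-1)
    out = np.empty(a.shape[:-1] + (2 * a.shape[-1],), dtype=a.dtype)
    out[..., 0::2] = 0.25 * left + 0.75 * a
    out[..., 1::2] = 0.75 * a + 0.25 * right
    return np.moveaxis(out, -1, axis)


def _up2_axis_back(g: np.ndarray, axis: int) -> np.ndarray:
    g = np.moveaxis(g, axis, -1)
    ge = g[..., 0::2]
    go = g[..., 1::2]
    dx = 0.75 * (ge + go)
    dx[..., :-1] += 0.25 * ge[..., 1:]
    dx[..., 1:] += 0.25 * go[..., :-1]
    dx[..., 0] += 0.25 * ge[..., 0]
    dx[..., -1] += 0.25 * go[..., -1]
    return np.moveaxis(dx, -1, axis)


def upsample2_trilinear(x: Tensor) -> Tensor:
    """Double every (H, W, B) extent by separable linear interpolation."""
    x = as_tensor(x)
    out_data = x.data
    for axis in (2, 3, 4):
        out_data = _up2_axis(out_data, axis)

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            for axis in (4, 3, 2):
                g = _up2_axis_back(g, axis)
            x.accumulate_grad(g)

    return make_op(out_data, (x,), backward)


def global_avg_pool(x: Tensor) -> Tensor:
    """Mean over (H, W, B), keeping dims — shape (N, C, 1, 1, 1)."""
    x = as_tensor(x)
    out_data = x.data.mean(axis=(2, 3, 4), keepdims=True)
    inv = 1.0 / (x.shape[2] * x.shape[3] * x.shape[4])

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            x.accumulate_grad(np.broadcast_to(g * inv, x.shape).copy())

    return make_op(out_data, (x,), backward)


def _reflect_pad_axis(a: np.ndarray, axis: int, before: int, after: int) -> np.ndarray:
    pad = [(0, 0)] * a.ndim
    pad[axis] = (before, after)
    return np.pad(a, pad, mode="reflect")


def reflect_pad(x: Tensor, pads: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]) -> Tensor:
    """Symmetric reflect padding of the (H, W, B) extents."""
    x = as_tensor(x)
    out_data = x.data
    for axis, (before, after) in zip((2, 3, 4), pads):
        if before or after:
            out_data = _reflect_pad_axis(out_data, axis, before, after)

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            for axis, (before, after) in zip((4, 3, 2), reversed(pads)):
                if not (before or after):
                    continue
                g = np.moveaxis(g, axis, -1)
                n = g.shape[-1] - before - after
                core = g[..., before : before + n].copy()
                if before:
                    core[..., 1 : before + 1] += g[..., :before][..., ::-1]
                if after:
                    core[..., n - after - 1 : n - 1] += g[..., before + n :][..., ::-1]
                g = np.moveaxis(core, -1, axis)
            x.accumulate_grad(g)

    return make_op(out_data, (x,), backward)


def crop(x: Tensor, extent: tuple[int, int, int]) -> Tensor:
    """Crop the (H, W, B) extents back to ``extent`` (top-left anchored)."""
    x = as_tensor(x)
    h, w, b = extent
    out_data = x.data[:, :, :h, :w, :b]

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            gx[:, :, :h, :w, :b] = g
            x.accumulate_grad(gx)

    return make_op(out_data, (x,), backward)
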