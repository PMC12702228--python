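"""JIT-compiled inner loops for the 3D convolutions.

The autograd ops in :mod:`raman3d.nn.functional` have pure-numpy
implementations; on CPUs the tap-by-tap numpy versions spend most of their
time on temporaries, so when numba is importable these fused loops are used
instead.  Loop order keeps the spectral axis innermost (contiguous) and
reuses each padded row across spectral taps, which keeps the working set in
cache.  Results are identical to the numpy path up to float32 summation
order.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore[misc]
        def wrap(fn):
            return fn

        return wrap(args[0]) if args and callable(args[0]) else wrap


@njit(fastmath=True)
def depthwise_fwd(xpad, w, dh, dw, db, h, ww_, b):
    n_batch, c = xpad.shape[0], xpad.shape[1]
    kh, kw, kb = w.shape[1], w.shape[2], w.shape[3]
    out = np.zeros((n_batch, c, h, ww_, b), dtype=xpad.dtype)
    for n in range(n_batch):
        for ch in range(c):
            for hh in range(h):
                for wi in range(ww_):
                    orow = out[n, ch, hh, wi]
                    for i in range(kh):
                        for j in range(kw):
                            xrow = xpad[n, ch, hh + i * dh, wi + j * dw]
                            for l in range(kb):
                                wv = w[ch, i, j, l]
                                lb = l * db
                                for bb in range(b):
                                    orow[bb] += wv * xrow[lb + bb]
    return out


@njit(fastmath=True)
def depthwise_bwd_w(xpad, g, kh, kw, kb, dh, dw, db):
    n_batch, c, h, ww_, b = g.shape
    dweight = np.zeros((c, kh, kw, kb), dtype=g.dtype)
    for n in range(n_batch):
        for ch in range(c):
            for hh in range(h):
                for wi in range(ww_):
                    grow = g[n, ch, hh, wi]
                    for i in range(kh):
                        for j in range(kw):
                            xrow = xpad[n, ch, hh + i * dh, wi + j * dw]
                            for l in range(kb):
                                lb = l * db
                                acc = 0.0
                                for bb in range(b):
                                    acc += grow[bb] * xrow[lb + bb]
                                dweight[ch, i, j, l] += acc
    return dweight


@njit(fastmath=True)
def depthwise_bwd_x(gpad_shape_arr, w, g, dh, dw, db):
    n_batch, c, h, ww_, b = g.shape
    kh, kw, kb = w.shape[1], w.shape[2], w.shape[3]
    gpad = np.zeros(
        (gpad_shape_arr[0], gpad_shape_arr[1], gpad_shape_arr[2], gpad_shape_arr[3], gpad_shape_arr[4]),
        dtype=g.dtype,
    )
    for n in range(n_batch):
        for ch in range(c):
            for hh in range(h):
                for wi in range(ww_):
                    grow = g[n, ch, hh, wi]
                    for i in range(kh):
                        for j in range(kw):
                            prow = gpad[n, ch, hh + i * dh, wi + j * dw]
                            for l in range(kb):
                                wv = w[ch, i, j, l]
                                lb = l * db
                                for bb in range(b):
                                    prow[lb + bb] += wv * grow[bb]
    return gpad


@njit(fastmath=True)
def conv_fwd(xpad, w, dh, dw, db, h, ww_, b):
    n_batch, c = xpad.shape[0], xpad.shape[1]
    c_out, _, kh, kw, kb = w.shape
    out = np.zeros((n_batch, c_out, h, ww_, b), dtype=xpad.dtype)
    for n in range(n_batch):
        for hh in range(h):
            for wi in range(ww_):
                for o in range(c_out):
                    orow = out[n, o, hh, wi]
                    for ch in range(c):
                        for i in range(kh):
                            for j in range(kw):
                                xrow = xpad[n, ch, hh + i * dh, wi + j * dw]
                                for l in range(kb):
                                    wv = w[o, ch, i, j, l]
                                    lb = l * db
                                    for bb in range(b):
                                        orow[bb] += wv * xrow[lb + bb]
    return out


@njit(fastmath=True)
def conv_bwd_w(xpad, g, kh, kw, kb, dh, dw, db):
    n_batch, c_out, h, ww_, b = g.shape
    c = xpad.shape[1]
    dweight = np.zeros((c_out, c, kh, kw, kb), dtype=g.dtype)
    for n in range(n_batch):
        for hh in range(h):
            for wi in range(ww_):
                for o in range(c_out):
                    grow = g[n, o, hh, wi]
                    for ch in range(c):
                        for i in range(kh):
                            for j in range(kw):
                                xrow = xpad[n, ch, hh + i * dh, wi + j * dw]
                                for l in range(kb):
                                    lb = l * db
                                    acc = 0.0
                                    for bb in range(b):
                                        acc += grow[bb] * xrow[lb + bb]
                                    dweight[o, ch, i, j, l] += acc
    return dweight


@njit(fastmath=True)
def conv_bwd_x(gpad_shape_arr, w, g, dh, dw, db):
    n_batch, c_out, h, ww_, b = g.shape
    c = w.shape[1]
    kh, kw, kb = w.shape[2], w.shape[3], w.shape[4]
    gpad = np.zeros(
        (gpad_shape_arr[0], gpad_shape_arr[1], gpad_shape_arr[2], gpad_shape_arr[3], gpad_shape_arr[4]),
        dtype=g.dtype,
    )
    for n in range(n_batch):
        for hh in range(h):
            for wi in range(ww_):
                for o in range(c_out):
                    grow = g[n, o, hh, wi]
                    for ch in range(c):
                        for i in range(kh):
                            for j in range(kw):
                                prow = gpad[n, ch, hh + i * dh, wi + j * dw]
                                for l in range(kb):
                                    wv = w[o, ch, i, j, l]
                                    lb = l * db
                                    for bb in range(b):
                                        prow[lb + bb] += wv * grow[bb]
    return gpad
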