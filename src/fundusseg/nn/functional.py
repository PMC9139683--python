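"""Differentiable array operations (NCHW layout throughout)."""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .autograd import Tensor, as_tensor, make_result

# ---------------------------------------------------------------------------
# im2col / col2im


def _im2col(x: np.ndarray, k: int, stride: int, pad: int) -> np.ndarray:
    """(N,C,H,W) -> (N, C*k*k, OH*OW) patch matrix."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    n, c, h, w = x.shape
    oh = (h - k) // stride + 1
    ow = (w - k) // stride + 1
    win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    # (N,C,OH,OW,k,k) -> (N, C,k,k, OH*OW)
    cols = win.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * k * k, oh * ow)
    return np.ascontiguousarray(cols)


def _col2im(cols: np.ndarray, xshape, k: int, stride: int, pad: int) -> np.ndarray:
    """Scatter-add patches back; adjoint of :func:`_im2col`."""
    n, c, h, w = xshape
    hp, wp = h + 2 * pad, w + 2 * pad
    oh = (hp - k) // stride + 1
    ow = (wp - k) // stride + 1
    cols = cols.reshape(n, c, k, k, oh, ow)
    out = np.zeros((n, c, hp, wp), dtype=cols.dtype)
    for i in range(k):
        hi = i + stride * oh
        for j in range(k):
            wj = j + stride * ow
            out[:, :, i:hi:stride, j:wj:stride] += cols[:, :, i, j]
    if pad:
        out = out[:, :, pad:-pad, pad:-pad]
    return np.ascontiguousarray(out)


# ---------------------------------------------------------------------------
# convolution


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, pad: int = 0) -> Tensor:
    """2-D convolution; ``w`` is (Cout, Cin, k, k)."""
    x, w = as_tensor(x), as_tensor(w)
    n, cin, h, _ = x.shape
    cout, _, k, _ = w.shape
    if k == 1 and stride == 1 and pad == 0:
        # 1x1 conv is a channel-mixing matmul; skip the patch matrix
        xf = x.data.reshape(n, cin, -1)
        y = np.matmul(w.data.reshape(cout, cin), xf).reshape(n, cout, h, x.shape[3])
        cols = None
    else:
        cols = _im2col(x.data, k, stride, pad)
        wf = w.data.reshape(cout, -1)
        y = np.matmul(wf, cols)
        oh = (h + 2 * pad - k) // stride + 1
        y = y.reshape(n, cout, oh, -1)
    if b is not None:
        y += b.data.reshape(1, cout, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def backward(g: np.ndarray) -> None:
        gf = g.reshape(n, cout, -1)
        if b is not None and b.requires_grad:
            b.accumulate(gf.sum(axis=(0, 2)))
        if k == 1 and stride == 1 and pad == 0:
            xf2 = x.data.reshape(n, cin, -1)
            if w.requires_grad:
                gw = np.einsum("nop,ncp->oc", gf, xf2, optimize=True)
                w.accumulate(gw.reshape(w.shape))
            if x.requires_grad or x._parents:
                gx = np.matmul(w.data.reshape(cout, cin).T, gf)
                x.accumulate(gx.reshape(x.shape))
        else:
            if w.requires_grad:
                gw = np.einsum("nop,nqp->oq", gf, cols, optimize=True)
                w.accumulate(gw.reshape(w.shape))
            if x.requires_grad or x._parents:
                gcols = np.matmul(w.data.reshape(cout, -1).T, gf)
                x.accumulate(_col2im(gcols, x.shape, k, stride, pad))

    return make_result(y, parents, backward)


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int, pad: int = 0) -> Tensor:
    """Transposed convolution; ``w`` is (Cin, Cout, k, k).

    Output spatial side = (H-1)*stride + k - 2*pad. With k = 2*stride and
    pad = stride//2 this is an exact x``stride`` upsampler.
    """
    x, w = as_tensor(x), as_tensor(w)
    n, cin, h, wdt = x.shape
    _, cout, k, _ = w.shape
    oh = (h - 1) * stride + k - 2 * pad
    ow = (wdt - 1) * stride + k - 2 * pad
    wf = w.data.reshape(cin, -1)  # (Cin, Cout*k*k)
    cols = np.matmul(wf.T, x.data.reshape(n, cin, -1))
    y = _col2im(cols, (n, cout, oh, ow), k, stride, pad)
    if b is not None:
        y += b.data.reshape(1, cout, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def backward(g: np.ndarray) -> None:
        if b is not None and b.requires_grad:
            b.accumulate(g.sum(axis=(0, 2, 3)))
        gcols = _im2col(g, k, stride, pad)  # (N, Cout*k*k, H*W)
        if w.requires_grad:
            gw = np.einsum("ncp,nqp->cq", x.data.reshape(n, cin, -1), gcols, optimize=True)
            w.accumulate(gw.reshape(w.shape))
        if x.requires_grad or x._parents:
            gx = np.matmul(wf, gcols)
            x.accumulate(gx.reshape(x.shape))

    return make_result(y, parents, backward)


# ---------------------------------------------------------------------------
# pooling / resampling


def avg_pool2d(x: Tensor, k: int) -> Tensor:
    """Non-overlapping k x k mean pooling; spatial sides must divide by k."""
    x = as_tensor(x)
    n, c, h, w = x.shape
    if k > h or k > w:
        raise ValueError(f"pool window {k} larger than feature map {h}x{w}")
    if h % k or w % k:
        raise ValueError(f"pool window {k} must divide feature map side {h}x{w}")
    y = x.data.reshape(n, c, h // k, k, w // k, k).mean(axis=(3, 5))

    def backward(g: np.ndarray) -> None:
        gx = np.repeat(np.repeat(g, k, axis=2), k, axis=3) / (k * k)
        x.accumulate(gx)

    return make_result(y, (x,), backward)


def max_pool2d(x: Tensor, k: int, stride: int, pad: int) -> Tensor:
    x = as_tensor(x)
    n, c, h, w = x.shape
    cols = _im2col(x.data, k, stride, pad).reshape(n, c, k * k, -1)
    idx = cols.argmax(axis=2)
    y_flat = np.take_along_axis(cols, idx[:, :, None, :], axis=2)[:, :, 0, :]
    oh = (h + 2 * pad - k) // stride + 1
    y = y_flat.reshape(n, c, oh, -1)

    def backward(g: np.ndarray) -> None:
        gcols = np.zeros_like(cols)
        np.put_along_axis(gcols, idx[:, :, None, :], g.reshape(n, c, 1, -1), axis=2)
        x.accumulate(_col2im(gcols.reshape(n, c * k * k, -1), x.shape, k, stride, pad))

    return make_result(y, (x,), backward)


def _linear_weights(n_out: int, factor: int):
    """Source indices/weights for 1-D bilinear scaling by an integer factor."""
    src = (np.arange(n_out) + 0.5) / factor - 0.5
    i0 = np.floor(src).astype(int)
    frac = (src - i0).astype(np.float32)
    n_in = n_out // factor
    i0c = np.clip(i0, 0, n_in - 1)
    i1c = np.clip(i0 + 1, 0, n_in - 1)
    return i0c, i1c, frac


def upsample_bilinear(x: Tensor, factor: int) -> Tensor:
    """Bilinear upsampling by an integer factor (half-pixel centers)."""
    x = as_tensor(x)
    n, c, h, w = x.shape
    oh, ow = h * factor, w * factor
    r0, r1, rf = _linear_weights(oh, factor)
    c0, c1, cf = _linear_weights(ow, factor)
    rf_ = rf[:, None]
    yr = x.data[:, :, r0, :] * (1 - rf_) + x.data[:, :, r1, :] * rf_
    y = yr[:, :, :, c0] * (1 - cf) + yr[:, :, :, c1] * cf

    def backward(g: np.ndarray) -> None:
        gyr = np.zeros((n, c, oh, w), dtype=np.float32)
        np.add.at(gyr, (slice(None), slice(None), slice(None), c0), g * (1 - cf))
        np.add.at(gyr, (slice(None), slice(None), slice(None), c1), g * cf)
        gx = np.zeros_like(x.data)
        np.add.at(gx, (slice(None), slice(None), r0, slice(None)), gyr * (1 - rf_))
        np.add.at(gx, (slice(None), slice(None), r1, slice(None)), gyr * rf_)
        x.accumulate(gx)

    return make_result(y, (x,), backward)


# ---------------------------------------------------------------------------
# elementwise / shape


def relu(x: Tensor) -> Tensor:
    x = as_tensor(x)
    mask = x.data > 0
    y = np.where(mask, x.data, 0)

    def backward(g: np.ndarray) -> None:
        x.accumulate(g * mask)

    return make_result(y, (x,), backward)


def add(a: Tensor, b: Tensor) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    y = a.data + b.data

    def backward(g: np.ndarray) -> None:
        if a.requires_grad or a._parents:
            a.accumulate(g)
        if b.requires_grad or b._parents:
            b.accumulate(g)

    return make_result(y, (a, b), backward)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    y = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g: np.ndarray) -> None:
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad or t._parents:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t.accumulate(g[tuple(sl)])

    return make_result(y, tuple(tensors), backward)


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor, running_mean: np.ndarray,
               running_var: np.ndarray, training: bool, momentum: float = 0.9,
               eps: float = 1e-5) -> Tensor:
    """Channelwise batch normalisation; updates running stats in place."""
    x = as_tensor(x)
    c = x.shape[1]
    if training:
        mean = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= momentum
        running_mean += (1 - momentum) * mean
        running_var *= momentum
        running_var += (1 - momentum) * var
    else:
        mean, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean.reshape(1, c, 1, 1)) * inv.reshape(1, c, 1, 1)
    y = gamma.data.reshape(1, c, 1, 1) * xhat + beta.data.reshape(1, c, 1, 1)

    def backward(g: np.ndarray) -> None:
        if beta.requires_grad:
            beta.accumulate(g.sum(axis=(0, 2, 3)))
        if gamma.requires_grad:
            gamma.accumulate((g * xhat).sum(axis=(0, 2, 3)))
        if x.requires_grad or x._parents:
            m = g.shape[0] * g.shape[2] * g.shape[3]
            gxhat = g * gamma.data.reshape(1, c, 1, 1)
            if training:
                s1 = gxhat.sum(axis=(0, 2, 3), keepdims=True)
                s2 = (gxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
                gx = (gxhat - s1 / m - xhat * s2 / m) * inv.reshape(1, c, 1, 1)
            else:
                gx = gxhat * inv.reshape(1, c, 1, 1)
            x.accumulate(gx)

    return make_result(y, (x, gamma, beta), backward)


def softmax_cross_entropy(logits: Tensor, target: np.ndarray) -> Tensor:
    """Mean per-pixel cross-entropy; logits (N,C,H,W), integer target (N,H,W)."""
    logits = as_tensor(logits)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    n, c, h, w = p.shape
    idx = target.astype(np.intp)
    picked = np.take_along_axis(p, idx[:, None, :, :], axis=1)[:, 0]
    loss = -np.log(np.maximum(picked, 1e-12)).mean()

    def backward(g: np.ndarray) -> None:
        onehot = np.zeros_like(p)
        np.put_along_axis(onehot, idx[:, None, :, :], 1.0, axis=1)
        logits.accumulate(g * (p - onehot) / (n * h * w))

    return make_result(np.float32(loss), (logits,), backward)


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=axis, keepdims=True)
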