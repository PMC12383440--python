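"""Minimal NumPy neural-network primitives with explicit backward passes.

Functional style: each ``*_forward`` returns ``(output, cache)`` and the paired
``*_backward`` consumes ``(grad_out, cache)`` and returns the input gradient plus
parameter gradients.  Parameters live in plain dicts of float64/float32 arrays so
optimizers and checkpointing stay trivial.  Convolutions use im2col + matmul,
which is fast enough for the small encoders and decoders this package trains on
CPU.
"""

from __future__ import annotations

import numpy as np

# ---------------------------------------------------------------------------
# im2col helpers


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int) -> tuple[np.ndarray, tuple]:
    """(B,C,H,W) -> (B, C*kh*kw, OH*OW) patch matrix."""
    b, c, h, w = x.shape
    oh = (h + 2 * pad - kh) // stride + 1
    ow = (w + 2 * pad - kw) // stride + 1
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    # strided view: (B, C, kh, kw, OH, OW)
    s = x.strides
    view = np.lib.stride_tricks.as_strided(
        x,
        shape=(b, c, kh, kw, oh, ow),
        strides=(s[0], s[1], s[2], s[3], s[2] * stride, s[3] * stride),
        writeable=False,
    )
    cols = view.reshape(b, c * kh * kw, oh * ow)
    return np.ascontiguousarray(cols), (x.shape, oh, ow)


def _col2im(cols: np.ndarray, x_padded_shape: tuple, kh: int, kw: int, stride: int, pad: int,
            out_shape: tuple) -> np.ndarray:
    """Adjoint of _im2col: scatter-add patch gradients back onto the image."""
    b, c, hp, wp = x_padded_shape
    oh, ow = out_shape
    cols = cols.reshape(b, c, kh, kw, oh, ow)
    dx = np.zeros((b, c, hp, wp), dtype=cols.dtype)
    for i in range(kh):
        for j in range(kw):
            dx[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride] += cols[:, :, i, j]
    if pad:
        dx = dx[:, :, pad:-pad, pad:-pad]
    return dx


# ---------------------------------------------------------------------------
# layers


def conv2d_forward(x, W, b, stride=1, pad=0):
    """x (B,Cin,H,W); W (Cout,Cin,kh,kw); b (Cout,)."""
    cout, cin, kh, kw = W.shape
    cols, (xp_shape, oh, ow) = _im2col(x, kh, kw, stride, pad)
    out = np.einsum("ok,bkp->bop", W.reshape(cout, -1), cols, optimize=True)
    out += b[None, :, None]
    out = out.reshape(x.shape[0], cout, oh, ow)
    cache = (cols, xp_shape, x.shape, W.shape, stride, pad, oh, ow)
    return out, cache


def conv2d_backward(dout, cache, W):
    cols, xp_shape, x_shape, w_shape, stride, pad, oh, ow = cache
    cout = w_shape[0]
    dflat = dout.reshape(x_shape[0], cout, oh * ow)
    dW = np.einsum("bop,bkp->ok", dflat, cols, optimize=True).reshape(w_shape)
    db = dflat.sum(axis=(0, 2))
    dcols = np.einsum("ok,bop->bkp", W.reshape(cout, -1), dflat, optimize=True)
    dx = _col2im(dcols, xp_shape, w_shape[2], w_shape[3], stride, pad, (oh, ow))
    return dx, dW, db


def linear_forward(x, W, b):
    """x (..., Din); W (Dout, Din); b (Dout,)."""
    out = x @ W.T + b
    return out, x


def linear_backward(dout, cache, W):
    x = cache
    dW = dout.reshape(-1, dout.shape[-1]).T @ x.reshape(-1, x.shape[-1])
    db = dout.reshape(-1, dout.shape[-1]).sum(axis=0)
    dx = dout @ W
    return dx, dW, db


def relu_forward(x):
    mask = x > 0
    return x * mask, mask


def relu_backward(dout, mask):
    return dout * mask


def sigmoid_forward(x):
    out = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
    return out, out


def sigmoid_backward(dout, out):
    return dout * out * (1.0 - out)


def gap_forward(x):
    """Global average pool over the two trailing spatial dims."""
    return x.mean(axis=(-2, -1)), x.shape


def gap_backward(dout, x_shape):
    h, w = x_shape[-2:]
    return np.broadcast_to(dout[..., None, None], x_shape) / (h * w)


def upsample2_forward(x):
    """Nearest-neighbour 2x upsampling of (B,C,H,W)."""
    return np.repeat(np.repeat(x, 2, axis=-2), 2, axis=-1), x.shape


def upsample2_backward(dout, x_shape):
    b, c, h, w = x_shape
    return dout.reshape(b, c, h, 2, w, 2).sum(axis=(3, 5))


# ---------------------------------------------------------------------------
# initialization and optimization


def he_conv(rng: np.random.Generator, cout: int, cin: int, k: int) -> np.ndarray:
    fan_in = cin * k * k
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, cin, k, k))


def he_linear(rng: np.random.Generator, dout: int, din: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / din), size=(dout, din))


class AdamW:
    """Decoupled weight-decay Adam over a dict of named parameter arrays.

    Weight decay is applied only to parameters whose name is not in
    ``no_decay`` (biases are conventionally excluded).
    """

    def __init__(self, params: dict, lr: float = 1e-4, weight_decay: float = 0.01,
                 betas=(0.9, 0.999), eps: float = 1e-8, no_decay: set | None = None):
        self.lr = lr
        self.wd = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.no_decay = no_decay if no_decay is not None else set()

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for k, g in grads.items():
            p = params[k]
            m = self.m[k]
            v = self.v[k]
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if k not in self.no_decay:
                update = update + self.wd * p
            p -= self.lr * update
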