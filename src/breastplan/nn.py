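"""Minimal NumPy implementation of a 2D U-Net with manual backpropagation.

The network is an encoder--decoder with skip connections and (optionally)
depthwise-separable "Xception-style" 3x3 convolutions.  Everything runs on
the CPU in float32 with channels-last layout ``(batch, H, W, C)``.

Only the pieces this package needs are implemented: 3x3 (separable) convs,
1x1 convs, ReLU, 2x2 max pooling, nearest-neighbour upsampling, MSE loss
and the Adam optimizer.  Gradients are derived by hand per layer; there is
no autograd graph.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["UNet2D", "Adam", "mse_loss_and_grad"]

_F32 = np.float32


@njit(cache=True, fastmath=True)
def _dw_conv(xp, w):
    """Depthwise 3x3 valid convolution of a pre-padded array.

    xp: (B, H+2, W+2, C); w: (3, 3, C) -> (B, H, W, C).
    """
    b_n, hp, wp, c_n = xp.shape
    h, wdt = hp - 2, wp - 2
    out = np.zeros((b_n, h, wdt, c_n), np.float32)
    for b in range(b_n):
        for y in range(h):
            for i in range(3):
                for j in range(3):
                    for x in range(wdt):
                        for c in range(c_n):
                            out[b, y, x, c] += xp[b, y + i, x + j, c] * w[i, j, c]
    return out


@njit(cache=True, fastmath=True)
def _dw_wgrad(xp, gmid):
    """Gradient of _dw_conv w.r.t. the depthwise kernel."""
    b_n, hp, wp, c_n = xp.shape
    h, wdt = hp - 2, wp - 2
    gw = np.zeros((3, 3, c_n), np.float32)
    for b in range(b_n):
        for y in range(h):
            for i in range(3):
                for j in range(3):
                    for x in range(wdt):
                        for c in range(c_n):
                            gw[i, j, c] += xp[b, y + i, x + j, c] * gmid[b, y, x, c]
    return gw


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class _Layer:
    """Base class: layers own their parameters and gradients."""

    def params(self):  # list of (name, array) pairs; arrays are updated in place
        return []

    def grads(self):
        return []

    def forward(self, x):
        raise NotImplementedError

    def backward(self, gout):
        raise NotImplementedError


class ReLU(_Layer):
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, _F32(0.0))

    def backward(self, gout):
        return np.where(self._mask, gout, _F32(0.0))


class Conv1x1(_Layer):
    """Pointwise convolution, i.e. a per-pixel dense layer."""

    def __init__(self, cin, cout, rng, bias_init=0.0, init_scale=1.0):
        scale = init_scale * np.sqrt(2.0 / cin)
        self.w = (rng.standard_normal((cin, cout)) * scale).astype(_F32)
        self.b = np.full(cout, bias_init, dtype=_F32)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.gw, self.gb]

    def forward(self, x):
        self._x = x
        return x @ self.w + self.b

    def backward(self, gout):
        xm = self._x.reshape(-1, self._x.shape[-1])
        gm = gout.reshape(-1, gout.shape[-1])
        self.gw[...] = xm.T @ gm
        self.gb[...] = gm.sum(axis=0)
        return gout @ self.w.T


class Conv3x3(_Layer):
    """Full 3x3 convolution with 'same' zero padding."""

    def __init__(self, cin, cout, rng):
        scale = np.sqrt(2.0 / (9 * cin))
        self.w = (rng.standard_normal((3, 3, cin, cout)) * scale).astype(_F32)
        self.b = np.zeros(cout, dtype=_F32)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.gw, self.gb]

    def forward(self, x):
        b, h, wdt, c = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        self._xp = xp
        out = np.zeros((b, h, wdt, self.w.shape[-1]), dtype=_F32)
        for i in range(3):
            for j in range(3):
                out += xp[:, i:i + h, j:j + wdt, :] @ self.w[i, j]
        out += self.b
        return out

    def backward(self, gout):
        b, h, wdt, _ = gout.shape
        xp = self._xp
        gxp = np.zeros_like(xp)
        gm = gout.reshape(-1, gout.shape[-1])
        for i in range(3):
            for j in range(3):
                win = xp[:, i:i + h, j:j + wdt, :]
                self.gw[i, j] = win.reshape(-1, win.shape[-1]).T @ gm
                gxp[:, i:i + h, j:j + wdt, :] += gout @ self.w[i, j].T
        self.gb[...] = gm.sum(axis=0)
        return gxp[:, 1:-1, 1:-1, :]


class SepConv3x3(_Layer):
    """Depthwise-separable 3x3 convolution (depthwise 3x3 + pointwise 1x1)."""

    def __init__(self, cin, cout, rng):
        self.dw = (rng.standard_normal((3, 3, cin)) * np.sqrt(2.0 / 9)).astype(_F32)
        self.pw = (rng.standard_normal((cin, cout)) * np.sqrt(2.0 / cin)).astype(_F32)
        self.b = np.zeros(cout, dtype=_F32)
        self.gdw = np.zeros_like(self.dw)
        self.gpw = np.zeros_like(self.pw)
        self.gb = np.zeros_like(self.b)

    def params(self):
        return [self.dw, self.pw, self.b]

    def grads(self):
        return [self.gdw, self.gpw, self.gb]

    def forward(self, x):
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        self._xp = xp
        mid = _dw_conv(xp, self.dw)
        self._mid = mid
        return mid @ self.pw + self.b

    def backward(self, gout):
        gm = gout.reshape(-1, gout.shape[-1])
        midm = self._mid.reshape(-1, self._mid.shape[-1])
        self.gpw[...] = midm.T @ gm
        self.gb[...] = gm.sum(axis=0)
        gmid = np.ascontiguousarray(gout @ self.pw.T)
        self.gdw[...] = _dw_wgrad(self._xp, gmid)
        # input gradient: correlation of gmid with the flipped kernel
        gmid_p = np.pad(gmid, ((0, 0), (1, 1), (1, 1), (0, 0)))
        return _dw_conv(gmid_p, np.ascontiguousarray(self.dw[::-1, ::-1]))


class MaxPool2(_Layer):
    def forward(self, x):
        b, h, w, c = x.shape
        xr = x.reshape(b, h // 2, 2, w // 2, 2, c)
        out = xr.max(axis=(2, 4))
        # mask of argmax positions (ties propagate gradient to every maximum;
        # harmless for optimisation)
        self._mask = xr == out[:, :, None, :, None, :]
        self._shape = x.shape
        return out

    def backward(self, gout):
        b, h, w, c = self._shape
        g = self._mask * gout[:, :, None, :, None, :]
        return g.reshape(b, h, w, c)


class Upsample2(_Layer):
    """Nearest-neighbour 2x upsampling."""

    def forward(self, x):
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, gout):
        b, h2, w2, c = gout.shape
        return gout.reshape(b, h2 // 2, 2, w2 // 2, 2, c).sum(axis=(2, 4))


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------

def _conv(cin, cout, rng, separable):
    return SepConv3x3(cin, cout, rng) if separable else Conv3x3(cin, cout, rng)


class _Block:
    """Two conv+ReLU pairs."""

    def __init__(self, cin, cout, rng, separable):
        self.c1, self.r1 = _conv(cin, cout, rng, separable), ReLU()
        self.c2, self.r2 = _conv(cout, cout, rng, separable), ReLU()
        self.layers = [self.c1, self.r1, self.c2, self.r2]

    def forward(self, x):
        for lay in self.layers:
            x = lay.forward(x)
        return x

    def backward(self, g):
        for lay in reversed(self.layers):
            g = lay.backward(g)
        return g


class UNet2D:
    """Encoder--decoder dose regressor with skip connections.

    Parameters
    ----------
    in_channels : number of input channels (CT + structure masks).
    base_filters : channels of the first encoder level; doubled per level.
    depth : number of resolution levels (>= 2), e.g. depth 3 at 64x64 uses
        feature maps at 64, 32 and 16 pixels.
    separable : use depthwise-separable (Xception-style) convolutions.
    seed : parameter-initialisation seed.
    output_scale : predictions are trained/produced in units of
        ``dose / output_scale``; callers multiply back (see dosenet).
    """

    def __init__(self, in_channels, base_filters=16, depth=3, separable=True,
                 seed=0, output_scale=1.0):
        if depth < 2:
            raise ValueError("depth must be >= 2")
        if base_filters < 8:
            raise ValueError("base_filters must be >= 8")
        rng = np.random.default_rng(seed)
        self.in_channels = in_channels
        self.depth = depth
        self.output_scale = float(output_scale)
        chans = [base_filters * 2 ** i for i in range(depth)]
        self.enc = []
        cin = in_channels
        for lvl in range(depth - 1):
            self.enc.append(_Block(cin, chans[lvl], rng, separable))
            cin = chans[lvl]
        self.pool = [MaxPool2() for _ in range(depth - 1)]
        self.bottleneck = _Block(cin, chans[-1], rng, separable)
        self.up = [Upsample2() for _ in range(depth - 1)]
        self.dec = []
        cup = chans[-1]
        for lvl in reversed(range(depth - 1)):
            self.dec.append(_Block(cup + chans[lvl], chans[lvl], rng, separable))
            cup = chans[lvl]
        # linear 1x1 dose head; negative raw outputs are clamped to zero at
        # prediction time (a hard-ReLU head can die under MSE early on).
        # Small init scale keeps initial predictions near zero so the first
        # Adam steps are well-conditioned regardless of network depth.
        self.head = Conv1x1(cup, 1, rng, bias_init=0.05, init_scale=0.05)

    # -- plumbing -----------------------------------------------------------
    def _all_layers(self):
        out = []
        for blk in self.enc:
            out.extend(blk.layers)
        out.extend(self.bottleneck.layers)
        for blk in self.dec:
            out.extend(blk.layers)
        out.append(self.head)
        return out

    def parameters(self):
        ps = []
        for lay in self._all_layers():
            ps.extend(lay.params())
        return ps

    def gradients(self):
        gs = []
        for lay in self._all_layers():
            gs.extend(lay.grads())
        return gs

    def get_weights(self):
        return [p.copy() for p in self.parameters()]

    def set_weights(self, weights):
        ps = self.parameters()
        if len(ps) != len(weights):
            raise ValueError("weight list does not match architecture")
        for p, w in zip(ps, weights):
            if p.shape != w.shape:
                raise ValueError(f"shape mismatch {p.shape} vs {w.shape}")
            p[...] = w

    def save_weights(self, path):
        np.savez_compressed(path, *self.parameters())

    def load_weights(self, path):
        with np.load(path) as data:
            self.set_weights([data[k] for k in data.files])

    # -- forward / backward -------------------------------------------------
    def forward(self, x):
        x = np.ascontiguousarray(x, dtype=_F32)
        skips = []
        for lvl in range(self.depth - 1):
            x = self.enc[lvl].forward(x)
            skips.append(x)
            x = self.pool[lvl].forward(x)
        x = self.bottleneck.forward(x)
        self._skip_channels = []
        for i, lvl in enumerate(reversed(range(self.depth - 1))):
            x = self.up[i].forward(x)
            skip = skips[lvl]
            self._skip_channels.append(skip.shape[-1])
            x = np.concatenate([skip, x], axis=-1)
            x = self.dec[i].forward(x)
        return self.head.forward(x)

    def backward(self, gout):
        g = self.head.backward(gout)
        gskips = {}
        for i in reversed(range(self.depth - 1)):
            g = self.dec[i].backward(g)
            csk = self._skip_channels[i]
            gskip, g = g[..., :csk], g[..., csk:]
            g = self.up[i].backward(g)
            gskips[self.depth - 2 - i] = gskip
        g = self.bottleneck.backward(g)
        for lvl in reversed(range(self.depth - 1)):
            g = self.pool[lvl].backward(g)
            g = g + gskips[lvl]
            g = self.enc[lvl].backward(g)
        return g

    def predict(self, x, batch_size=32):
        """Inference without storing per-layer state between batches."""
        x = np.asarray(x, dtype=_F32)
        outs = [self.forward(x[i:i + batch_size])
                for i in range(0, len(x), batch_size)]
        return np.concatenate(outs, axis=0)


# ---------------------------------------------------------------------------
# loss + optimizer
# ---------------------------------------------------------------------------

def mse_loss_and_grad(pred, target):
    diff = pred - target
    loss = float(np.mean(diff.astype(np.float64) ** 2))
    grad = (2.0 / diff.size) * diff
    return loss, grad.astype(_F32)


class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1, b2 = self.b1, self.b2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= (self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)).astype(p.dtype)
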