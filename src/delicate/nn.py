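"""Minimal 3D convolutional network machinery on numpy.

Implements exactly what the star-convex segmentation backend needs: same-
padded 3×3×3 convolutions (im2col + BLAS matmul, with the transposed-kernel
trick for the input gradient), ReLU, 2× max pooling, nearest-neighbour
upsampling, channel concatenation, residual blocks, and an Adam optimizer
with the AMSGrad variant.  Everything is float32 and fully deterministic
for a fixed seed (single-threaded numpy ops plus BLAS matmul).

Tensors are (C, D, H, W) — unbatched; the training loop accumulates
gradients over a mini-batch by summing per-sample backward passes, which
keeps memory flat and is numerically identical to batched SGD.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _im2col(x: np.ndarray, k: int = 3) -> np.ndarray:
    """(C, D, H, W) -> (D*H*W, C*k^3) with same padding."""
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (p, p)))
    win = sliding_window_view(xp, (k, k, k), axis=(1, 2, 3))  # C,D,H,W,k,k,k
    win = win.transpose(1, 2, 3, 0, 4, 5, 6)
    C = x.shape[0]
    return np.ascontiguousarray(win).reshape(-1, C * k ** 3)


class Conv3d:
    """Same-padded 3D convolution, kernel k (3 or 1)."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        fan_in = cin * k ** 3
        scale = np.sqrt(2.0 / fan_in)  # He init for ReLU nets
        self.W = (rng.normal(0.0, scale, size=(fan_in, cout))
                  .astype(np.float32))
        self.b = np.zeros(cout, dtype=np.float32)
        self.k = k
        self.cin, self.cout = cin, cout
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._shape: tuple | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._shape = x.shape
        if self.k == 1:
            cols = x.reshape(self.cin, -1).T
        else:
            cols = _im2col(x, self.k)
        out = cols @ self.W + self.b
        self._cols = cols if train else None
        d, h, w = x.shape[1:]
        return out.T.reshape(self.cout, d, h, w)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        gmat = grad.reshape(self.cout, -1).T  # (DHW, cout)
        self.dW += self._cols.T @ gmat
        self.db += gmat.sum(axis=0)
        if self.k == 1:
            dx = (gmat @ self.W.T).T.reshape(self._shape)
            return dx
        # input gradient = conv of grad with flipped, transposed kernel
        k = self.k
        Wk = self.W.reshape(self.cin, k, k, k, self.cout)
        Wk = Wk[:, ::-1, ::-1, ::-1, :]
        Wt = np.ascontiguousarray(Wk.transpose(4, 1, 2, 3, 0)).reshape(
            self.cout * k ** 3, self.cin)
        gcols = _im2col(grad, k)
        dx = (gcols @ Wt).T.reshape(self._shape)
        return dx

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class ReLU:
    def forward(self, x, train=True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask

    def params(self):
        return []


class MaxPool2:
    """2× max pooling; gradients split evenly across tied maxima."""

    def forward(self, x, train=True):
        c, d, h, w = x.shape
        xr = x.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(2, 4, 6))
        if train:
            m = xr == out[:, :, None, :, None, :, None]
            counts = m.sum(axis=(2, 4, 6), keepdims=True)
            self._dist = (m / counts).astype(np.float32)
            self._shape = x.shape
        return out

    def backward(self, grad):
        g = grad[:, :, None, :, None, :, None] * self._dist
        c, d, h, w = self._shape
        return g.reshape(c, d, h, w)

    def params(self):
        return []


class Upsample2:
    """Nearest-neighbour 2× upsampling."""

    def forward(self, x, train=True):
        self._shape = x.shape
        return x.repeat(2, axis=1).repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, grad):
        c, d, h, w = self._shape
        g = grad.reshape(c, d, 2, h, 2, w, 2)
        return g.sum(axis=(2, 4, 6))

    def params(self):
        return []


class ConvBlock:
    """conv3 -> relu."""

    def __init__(self, cin, cout, rng):
        self.conv = Conv3d(cin, cout, 3, rng)
        self.act = ReLU()

    def forward(self, x, train=True):
        return self.act.forward(self.conv.forward(x, train), train)

    def backward(self, grad):
        return self.conv.backward(self.act.backward(grad))

    def params(self):
        return self.conv.params()


class ResBlock:
    """y = relu(x + conv(relu(conv(x)))) — identity-width residual unit."""

    def __init__(self, channels, rng):
        self.c1 = Conv3d(channels, channels, 3, rng)
        self.a1 = ReLU()
        self.c2 = Conv3d(channels, channels, 3, rng)
        self.a2 = ReLU()

    def forward(self, x, train=True):
        h = self.a1.forward(self.c1.forward(x, train), train)
        h = self.c2.forward(h, train)
        return self.a2.forward(x + h, train)

    def backward(self, grad):
        g = self.a2.backward(grad)
        gh = self.c1.backward(self.a1.backward(self.c2.backward(g)))
        return g + gh

    def params(self):
        return self.c1.params() + self.c2.params()


class UNet3D:
    """Small U-Net with residual blocks and two output heads.

    ``depth`` is the number of 2× poolings; channel width doubles per
    level from ``base_channels``.  Head outputs are raw: objectness is a
    single logit map (sigmoid applied by the caller/loss) and distances
    are passed through softplus by the caller so they stay non-negative
    by construction.
    """

    def __init__(self, n_rays: int = 64, depth: int = 2,
                 base_channels: int = 4, seed: int = 0):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
        self.n_rays = n_rays
        self.depth = depth
        self.base_channels = base_channels
        cb = base_channels
        self.enc = [(ConvBlock(1, cb, rng), ResBlock(cb, rng))]
        ch = cb
        for _ in range(depth):
            self.enc.append((ConvBlock(ch, ch * 2, rng), ResBlock(ch * 2, rng)))
            ch *= 2
        self.pools = [MaxPool2() for _ in range(depth)]
        self.ups = [Upsample2() for _ in range(depth)]
        self.dec = []
        for lvl in range(depth - 1, -1, -1):
            skip_ch = cb * 2 ** lvl
            self.dec.append((ConvBlock(ch + skip_ch, skip_ch, rng),
                             ResBlock(skip_ch, rng)))
            ch = skip_ch
        self.head_obj = Conv3d(ch, 1, 1, rng)
        self.head_dist = Conv3d(ch, n_rays, 1, rng)
        # prior-informed head biases: background-dominated objectness and
        # distances near a typical nucleus radius (softplus(2) ~ 2.1 voxels)
        self.head_obj.b[...] = -2.0
        self.head_dist.b[...] = 2.0

    # -- forward/backward -------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = True
                ) -> tuple[np.ndarray, np.ndarray]:
        """x: (1, D, H, W) with D,H,W divisible by 2**depth.

        Returns (objectness logits (D,H,W), distance pre-activations
        (n_rays, D, H, W)).
        """
        skips = []
        h = x
        for i, (cb_, rb) in enumerate(self.enc):
            h = rb.forward(cb_.forward(h, train), train)
            if i < self.depth:
                skips.append(h)
                h = self.pools[i].forward(h, train)
        self._concat_ch = []
        for i, (cb_, rb) in enumerate(self.dec):
            h = self.ups[i].forward(h, train)
            skip = skips[self.depth - 1 - i]
            self._concat_ch.append(h.shape[0])
            h = np.concatenate([h, skip], axis=0)
            h = rb.forward(cb_.forward(h, train), train)
        obj = self.head_obj.forward(h, train)[0]
        dist = self.head_dist.forward(h, train)
        return obj, dist

    def backward(self, gobj: np.ndarray, gdist: np.ndarray) -> None:
        g = self.head_obj.backward(gobj[None])
        g = g + self.head_dist.backward(gdist)
        skip_grads: dict[int, np.ndarray] = {}
        for i in range(len(self.dec) - 1, -1, -1):
            cb_, rb = self.dec[i]
            g = cb_.backward(rb.backward(g))
            nch = self._concat_ch[i]
            skip_grads[self.depth - 1 - i] = g[nch:]
            g = self.ups[i].backward(g[:nch])
        for i in range(len(self.enc) - 1, -1, -1):
            cb_, rb = self.enc[i]
            if i < self.depth:
                g = self.pools[i].backward(g)
                g = g + skip_grads[i]
            g = cb_.backward(rb.backward(g))

    def params(self):
        out = []
        for cb_, rb in self.enc + self.dec:
            out += cb_.params() + rb.params()
        out += self.head_obj.params() + self.head_dist.params()
        return out

    def zero_grad(self):
        for _, gr in self.params():
            gr[...] = 0.0

    # -- (de)serialization -------------------------------------------------
    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p, _ in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        ps = self.params()
        if len(weights) != len(ps):
            raise ValueError("weight list does not match architecture")
        for (p, _), w in zip(ps, weights):
            p[...] = w


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softplus(x: np.ndarray) -> np.ndarray:
    return np.where(x > 20, x, np.log1p(np.exp(np.minimum(x, 20.0))))


class Adam:
    """Adam with optional AMSGrad and decoupled weight decay."""

    def __init__(self, params, lr=5e-3, betas=(0.9, 0.999), eps=1e-8,
                 weight_decay=1e-5, amsgrad=True):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.amsgrad = amsgrad
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.vhat = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, (p, g) in enumerate(self.params):
            if self.weight_decay:
                p *= (1.0 - self.lr * self.weight_decay)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            if self.amsgrad:
                np.maximum(self.vhat[i], self.v[i], out=self.vhat[i])
                denom = np.sqrt(self.vhat[i] / b2t) + self.eps
            else:
                denom = np.sqrt(self.v[i] / b2t) + self.eps
            p -= self.lr * (self.m[i] / b1t) / denom


def bce_with_logits(logits: np.ndarray, target: np.ndarray
                    ) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy; returns (loss, dloss/dlogits)."""
    n = logits.size
    p = sigmoid(logits)
    # numerically stable loss: max(z,0) - z*y + log(1+exp(-|z|))
    loss = float(np.mean(np.maximum(logits, 0) - logits * target
                         + np.log1p(np.exp(-np.abs(logits)))))
    return loss, (p - target) / n


def masked_l1(pre: np.ndarray, target: np.ndarray, mask: np.ndarray
              ) -> tuple[float, np.ndarray]:
    """Mean absolute error of softplus(pre) vs target on masked voxels.

    ``pre`` is (n_rays, D, H, W), ``mask`` is (D, H, W) foreground.
    Returns (loss, dloss/dpre); loss is 0 when the mask is empty.
    """
    m = mask.sum()
    if m == 0:
        return 0.0, np.zeros_like(pre)
    d = softplus(pre)
    diff = d - target
    w = mask[None].astype(np.float32)
    loss = float((np.abs(diff) * w).sum() / (m * pre.shape[0]))
    grad = np.sign(diff) * w * sigmoid(pre) / (m * pre.shape[0])
    return loss, grad.astype(np.float32)
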